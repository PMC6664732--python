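"""End-to-end orchestration: simulate -> preprocess -> features -> evaluate.

``PipelineConfig`` gathers the per-stage parameter objects, validates
them eagerly (any invalid section is rejected before computation
starts), and ``run_pipeline`` executes the whole chain, writing reports
plus a ``RunManifest`` (config snapshot, stage timings, output
checksums) into the output directory.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .baselines import DEFAULT_BANDS, BandTable, StftSpec, WpdSpec
from .errors import ConfigurationError
from .evaluate import (
    METHOD_NAMES,
    ClassifierSpec,
    CvSpec,
    compare_methods,
    cross_validate,
    make_extractor,
)
from .io import sha256_of
from .pca import ReductionSpec
from .pcanet import PCANetSpec
from .preprocess import EpochSet, preprocess_recording
from .simulate import LabelledRecording, SimulationConfig, generate_dataset

__all__ = [
    "PreprocessSpec",
    "PipelineConfig",
    "RunManifest",
    "prepare_epochs",
    "run_pipeline",
]


@dataclass
class PreprocessSpec:
    target_rate: float = 200.0
    low: float = 0.1
    high: float = 45.0
    order: int = 3
    window: float = 10.0
    analysis_span: float | None = 1200.0
    zero_phase: bool = False

    def __post_init__(self) -> None:
        if self.target_rate <= 0 or self.window <= 0:
            raise ConfigurationError("rates and window must be positive")
        if not 0 < self.low < self.high:
            raise ConfigurationError("need 0 < low < high")
        if self.high >= self.target_rate / 2:
            raise ConfigurationError("high cutoff must be below target Nyquist")


@dataclass
class PipelineConfig:
    n_subjects: int = 2
    per_state_duration: float = 200.0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocessing: PreprocessSpec = field(default_factory=PreprocessSpec)
    reduction: ReductionSpec = field(default_factory=ReductionSpec)
    pcanet: PCANetSpec = field(default_factory=PCANetSpec)
    stft: StftSpec = field(default_factory=StftSpec)
    bands: BandTable = field(default_factory=lambda: DEFAULT_BANDS)
    wpd: WpdSpec = field(default_factory=WpdSpec)
    cv: CvSpec = field(default_factory=CvSpec)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    methods: tuple = ("modified_pcanet",)
    seed: int = 0
    output_dir: str = "fatiguenet_out"

    def __post_init__(self) -> None:
        for m in self.methods:
            if m not in METHOD_NAMES:
                raise ConfigurationError(f"unknown method {m!r}")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        section_types = {
            "simulation": SimulationConfig,
            "preprocessing": PreprocessSpec,
            "reduction": ReductionSpec,
            "pcanet": PCANetSpec,
            "stft": StftSpec,
            "wpd": WpdSpec,
            "cv": CvSpec,
            "classifier": ClassifierSpec,
        }
        for key, value in raw.items():
            if key in section_types:
                kwargs[key] = section_types[key](**(value or {}))
            elif key == "methods":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def snapshot(self) -> dict:
        snap = asdict(self)
        snap["bands"] = [
            {"name": b.name, "low": b.low, "high": b.high} for b in self.bands
        ]
        snap["methods"] = list(self.methods)
        return snap


@dataclass
class RunManifest:
    config: dict
    version: str
    timings: dict
    outputs: dict

    def write(self, path) -> None:
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(
            {"config": self.config, "version": self.version,
             "timings": self.timings, "outputs": self.outputs},
            indent=2, default=str))
        tmp.replace(path)  # atomic on POSIX


def prepare_epochs(
    recordings: list[LabelledRecording], pp: PreprocessSpec | None = None
) -> dict[str, tuple[list, list]]:
    """Preprocess labelled recordings into per-subject epoch lists.

    Returns subject_id -> (epochs, labels) ready for the evaluator.
    """
    pp = pp if pp is not None else PreprocessSpec()
    dataset: dict[str, tuple[list, list]] = {}
    for lr in recordings:
        eset: EpochSet = preprocess_recording(
            lr.recording,
            target_rate=pp.target_rate,
            low=pp.low,
            high=pp.high,
            order=pp.order,
            window=pp.window,
            analysis_span=pp.analysis_span,
            zero_phase=pp.zero_phase,
            label=lr.state,
            subject_id=lr.subject_id,
        )
        epochs, labels = dataset.setdefault(lr.subject_id, ([], []))
        epochs.extend(eset.epochs)
        labels.extend(eset.labels)
    return dataset


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full chain and write reports + manifest to disk."""
    from .version import __version__

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}

    t0 = time.perf_counter()
    recordings = generate_dataset(
        config.n_subjects, config.per_state_duration,
        config.simulation, seed=config.seed,
    )
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    dataset = prepare_epochs(recordings, config.preprocessing)
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if len(config.methods) > 1 and len(dataset) >= 2:
        reports, comparisons = compare_methods(
            dataset, config.methods, config.cv, config.classifier,
            config.reduction, None,
        )
    else:
        reports = []
        comparisons = []
        for subject_id, (epochs, labels) in dataset.items():
            from .evaluate import _binary_labels

            for method in config.methods:
                def factory(method=method):
                    return make_extractor(method, config.reduction, None)

                rep = cross_validate(
                    epochs, _binary_labels(labels), config.cv,
                    config.classifier, extractor_factory=factory,
                )
                rep.method = method
                rep.subject_id = subject_id
                reports.append(rep)
    timings["evaluate"] = time.perf_counter() - t0

    report_path = out_dir / "reports.json"
    report_path.write_text(json.dumps(
        {
            "reports": [r.as_dict() for r in reports],
            "comparisons": [
                {"pair": [c.method_a, c.method_b], "t": c.t, "p": c.p,
                 "metric": c.metric}
                for c in comparisons
            ],
            "epoch_counts": {
                s: len(ep) for s, (ep, _) in dataset.items()
            },
        },
        indent=2))
    outputs[str(report_path)] = sha256_of(report_path)

    manifest = RunManifest(
        config=config.snapshot(),
        version=__version__,
        timings=timings,
        outputs=outputs,
    )
    manifest.write(out_dir / "manifest.json")
    return manifest
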