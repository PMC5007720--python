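"""Config-driven end-to-end pipeline runs.

A :class:`PipelineConfig` (usually loaded from a YAML file) names a session
source — a recorded session on disk or the synthetic generator — the
windowing and normalization settings, the methods to compare and the
evaluation protocol.  :func:`run_pipeline` executes the whole chain and
writes a report directory: the comparison table, pairwise test results,
per-method confusion matrices, serialized trained models and a run log with
every seed, so a run is reproducible (byte-identical tables) from its config
snapshot.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classifiers import TrainConfig
from .errors import ConfigurationError
from .evaluation import EvalConfig, compare_methods
from .features import WindowSpec, extract_features
from .pipeline import METHODS, MethodSpec, fit_pipeline
from .session import read_session
from .synth import SynthConfig, generate_session


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible pipeline run."""

    session: str = "synthetic"           # path or the literal "synthetic"
    synth: SynthConfig = field(default_factory=SynthConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    normalization: str = "zscore"
    zc_threshold: float = 0.0
    ssc_threshold: float = 0.0
    methods: tuple[str, ...] = ("lda", "glm-irls", "glm-scg", "mlp-gd", "mlp-scg")
    output_type: str = "single"
    hidden: tuple[int, ...] = (32,)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    out_dir: str = "emgpr-report"

    def __post_init__(self):
        for m in self.methods:
            if m not in METHODS:
                raise ConfigurationError(
                    f"unknown method {m!r}; choose from {METHODS}"
                )

    def method_specs(self) -> list[MethodSpec]:
        return [
            MethodSpec(m, self.output_type, tuple(self.hidden),
                       self.normalization, self.train)
            for m in self.methods
        ]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs: dict = {}
        for key in ("session", "normalization", "output_type", "out_dir",
                    "zc_threshold", "ssc_threshold"):
            if key in raw:
                kwargs[key] = raw[key]
        if "methods" in raw:
            kwargs["methods"] = tuple(raw["methods"])
        if "hidden" in raw:
            h = raw["hidden"]
            kwargs["hidden"] = tuple(h) if isinstance(h, (list, tuple)) else (h,)
        if "synth" in raw:
            kwargs["synth"] = SynthConfig(**raw["synth"])
        if "window" in raw:
            kwargs["window"] = WindowSpec(**raw["window"])
        if "train" in raw:
            kwargs["train"] = TrainConfig(**raw["train"])
        if "eval" in raw:
            kwargs["eval"] = EvalConfig(**raw["eval"])
        return cls(**kwargs)

    def snapshot(self) -> dict:
        d = asdict(self)
        d["synth"]["activation_matrix"] = np.asarray(
            self.synth.activation_matrix
        ).tolist()
        return d


def _load_session(config: PipelineConfig):
    if config.session == "synthetic":
        return generate_session(config.synth)
    return read_session(config.session)


def _format_table(table) -> str:
    """Fixed-precision TSV so identical runs are byte-identical.

    Wall-clock training time is excluded here (it varies between runs) and
    written to a separate timings file instead.
    """
    out = table[["method", "output_type", "acc", "sd"]].copy()
    for col in ("acc", "sd"):
        out[col] = out[col].map(lambda v: f"{v:.6f}")
    return out.to_csv(sep="\t", index=False)


def _format_timings(table) -> str:
    out = table[["method", "output_type", "train_seconds"]].copy()
    out["train_seconds"] = out["train_seconds"].map(lambda v: f"{v:.3f}")
    return out.to_csv(sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run session -> features -> evaluation and write the report directory.

    Returns a summary dict with the comparison table and output paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session = _load_session(config)
    fm = extract_features(session, config.window, config.zc_threshold,
                          config.ssc_threshold)
    specs = config.method_specs()
    table, pairwise = compare_methods(fm, specs, config.eval)
    report_path = out / "comparison.tsv"
    report_path.write_text(_format_table(table), encoding="utf-8")
    (out / "timings.tsv").write_text(_format_timings(table), encoding="utf-8")
    pair_path = out / "pairwise_wilcoxon.tsv"
    with open(pair_path, "w", encoding="utf-8") as fh:
        fh.write("method_a\tmethod_b\tp_value\tsignificant\tdirection\n")
        for (a, b), res in sorted(pairwise.items()):
            fh.write(f"{a}\t{b}\t{res.p_value:.6g}\t"
                     f"{int(res.significant)}\t{res.direction}\n")
    # one fully trained model per method on a final stratified split
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    confusion_dir = out / "confusion"
    confusion_dir.mkdir(exist_ok=True)
    from .evaluation import make_splits, repeated_split_evaluate
    single_split_cfg = EvalConfig(
        n_repetitions=1,
        train_windows_per_movement=config.eval.train_windows_per_movement,
        test_windows_per_movement=config.eval.test_windows_per_movement,
        alpha=config.eval.alpha,
        rng_seed=config.eval.rng_seed,
    )
    for spec in specs:
        res = repeated_split_evaluate(fm, spec, single_split_cfg)
        stem = spec.name.replace("/", "_")
        np.savetxt(confusion_dir / f"{stem}.tsv", res.confusion,
                   fmt="%d", delimiter="\t")
        split = make_splits(fm.class_indices, single_split_cfg)[0]
        pipe = fit_pipeline(fm.values[split[0]], fm.class_indices[split[0]],
                            spec.with_seed((config.eval.rng_seed + 1) * 100003),
                            fm.label_table)
        pipe.save(models_dir / f"{stem}.json")
    log = {
        "emgpr_version": __version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "config": config.snapshot(),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2),
                                      encoding="utf-8")
    return {
        "table": table,
        "pairwise": pairwise,
        "report_path": str(report_path),
        "out_dir": str(out),
    }
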