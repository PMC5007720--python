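"""Repeated-holdout evaluation, Wilcoxon comparison and the hidden-unit sweep.

Evaluation follows the standard offline protocol for myoelectric
classification: for each repetition a fresh stratified split draws a fixed
number of windows per movement for training and a disjoint fixed number for
testing (defaults 72/49), normalization is fitted on the training partition
only, the model is trained, and accuracy = correct / total classifications
is recorded.  Mean accuracy (Acc) and its standard deviation (SD) are taken
over the repetitions (default 100).

Methods are compared with the two-sided Wilcoxon signed-rank test on
repetition-paired accuracies; pairing uses a shared split sequence (common
random numbers) so differences reflect the method, not the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .features import FeatureMatrix
from .pipeline import MethodSpec, TrainedPipeline, fit_pipeline

__all__ = [
    "EvalConfig",
    "EvaluationResult",
    "WilcoxonResult",
    "SweepResult",
    "make_splits",
    "repeated_split_evaluate",
    "wilcoxon_signed_rank",
    "hidden_unit_sweep",
    "compare_methods",
]


@dataclass
class EvalConfig:
    """Repeated random-split protocol parameters."""

    n_repetitions: int = 100
    train_windows_per_movement: int = 72
    test_windows_per_movement: int = 49
    alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_repetitions < 1:
            raise ConfigurationError("n_repetitions must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.train_windows_per_movement < 1 or self.test_windows_per_movement < 1:
            raise ConfigurationError("per-movement window counts must be >= 1")


@dataclass
class EvaluationResult:
    """Per-repetition accuracies with summary statistics."""

    method: str
    accuracies: np.ndarray
    confusion: np.ndarray          # (n_classes, n_classes), summed over reps
    train_seconds: float = 0.0
    final_train_errors: np.ndarray | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        if self.accuracies.size < 2:
            return 0.0
        return float(np.std(self.accuracies, ddof=1))


def make_splits(class_indices: np.ndarray, config: EvalConfig
                ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified train/test index pairs, one per repetition.

    Every repetition draws, per movement class, exactly
    ``train_windows_per_movement`` training windows and a disjoint
    ``test_windows_per_movement`` test windows, uniformly without
    replacement.  Deterministic given ``config.rng_seed``.
    """
    y = np.asarray(class_indices)
    rng = np.random.default_rng(config.rng_seed)
    per_class = {c: np.flatnonzero(y == c) for c in np.unique(y)}
    need = config.train_windows_per_movement + config.test_windows_per_movement
    for c, idx in per_class.items():
        if idx.size < need:
            raise ConfigurationError(
                f"class {c} has {idx.size} windows; need >= {need} "
                f"({config.train_windows_per_movement} train + "
                f"{config.test_windows_per_movement} test)"
            )
    splits = []
    for _ in range(config.n_repetitions):
        train, test = [], []
        for c in sorted(per_class):
            perm = rng.permutation(per_class[c])
            train.append(perm[: config.train_windows_per_movement])
            test.append(perm[config.train_windows_per_movement : need])
        splits.append((np.concatenate(train), np.concatenate(test)))
    return splits


def _evaluate_once(fm: FeatureMatrix, spec: MethodSpec, train_idx, test_idx
                   ) -> tuple[float, np.ndarray, TrainedPipeline]:
    pipe = fit_pipeline(fm.values[train_idx], fm.class_indices[train_idx],
                        spec, fm.label_table)
    pred = np.array([lab.class_index
                     for lab in pipe.classify(fm.values[test_idx])])
    truth = fm.class_indices[test_idx]
    n_classes = len(fm.label_table)
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(confusion, (truth, pred), 1)
    return float(np.mean(pred == truth)), confusion, pipe


def repeated_split_evaluate(fm: FeatureMatrix, spec: MethodSpec,
                            config: EvalConfig,
                            splits=None) -> EvaluationResult:
    """Run the repeated stratified-holdout protocol for one method.

    ``splits`` may be precomputed (shared across methods for paired
    comparisons); otherwise they are drawn from ``config.rng_seed``.  Each
    repetition derives its model seed from the base seed and the repetition
    index, so two runs with equal seed and config are identical.
    """
    fm.validate()
    if splits is None:
        splits = make_splits(fm.class_indices, config)
    n_classes = len(fm.label_table)
    accs = np.empty(len(splits))
    errors = np.full(len(splits), np.nan)
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    seconds = 0.0
    for rep, (train_idx, test_idx) in enumerate(splits):
        rep_spec = spec.with_seed((config.rng_seed + 1) * 100003 + rep)
        acc, conf, pipe = _evaluate_once(fm, rep_spec, train_idx, test_idx)
        accs[rep] = acc
        confusion += conf
        seconds += pipe.train_seconds
        if getattr(pipe.model, "training", None) is not None:
            errors[rep] = pipe.model.training.final_error
    return EvaluationResult(spec.name, accs, confusion, seconds, errors)


# -- Wilcoxon signed-rank test ----------------------------------------------

@dataclass
class WilcoxonResult:
    p_value: float
    statistic: float               # W+ (sum of positive-difference ranks)
    n_nonzero: int
    direction: int                 # sign of the median paired difference
    no_evidence: bool = False      # all differences were zero
    significant: bool = False

    def __iter__(self):  # allow ``p, direction = result`` style unpacking
        return iter((self.p_value, self.direction))


def _exact_sf_counts(ranks: np.ndarray) -> np.ndarray:
    """Distribution of W+ over all sign assignments by convolution.

    Average ranks under ties are multiples of 1/2, so doubled ranks are
    integers and the null distribution is an exact polynomial product.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        counts[r:] += counts[: total + 1 - r]
    return counts  # index = 2 * W+


def wilcoxon_signed_rank(paired_a, paired_b, alpha: float = 0.05,
                         exact_limit: int = 25) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Zero differences are discarded; ties in |difference| receive average
    ranks.  For up to ``exact_limit`` non-zero pairs the p-value is computed
    from the exact null distribution of W+ (enumeration of all 2**n sign
    assignments via convolution); above that a normal approximation with tie
    correction and continuity correction is used.  If every difference is
    zero the test returns p = 1 with ``no_evidence`` set.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigurationError("paired vectors must be equal-length 1-D")
    d = a - b
    nz = d[d != 0]
    n = nz.size
    if n == 0:
        return WilcoxonResult(1.0, 0.0, 0, 0, no_evidence=True)
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    direction = int(np.sign(np.median(d)))
    if direction == 0:
        direction = int(np.sign(w_plus - ranks.sum() / 2))
    if n <= exact_limit:
        counts = _exact_sf_counts(ranks)
        total = counts.sum()
        iw = int(round(2 * w_plus))
        p_le = counts[: iw + 1].sum() / total
        p_ge = counts[iw:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
        from scipy.stats import norm

        p = min(1.0, 2.0 * norm.sf(abs(z)))
    return WilcoxonResult(p, w_plus, n, direction,
                          significant=bool(p < alpha))


# -- hidden-unit sweep -------------------------------------------------------

@dataclass
class SweepResult:
    hidden_units: list[int]
    accuracies: np.ndarray         # (n_hu, nets_per_hu)
    selected: int
    p_values: dict[int, float] = field(default_factory=dict)

    @property
    def mean_accuracies(self) -> np.ndarray:
        return self.accuracies.mean(axis=1)


def hidden_unit_sweep(fm: FeatureMatrix, output_type: str = "single",
                      hidden_range=range(1, 101), nets_per_hu: int = 10,
                      config: EvalConfig | None = None,
                      method: str = "mlp-scg",
                      train: "TrainConfig | None" = None) -> SweepResult:
    """Accuracy as a function of MLP hidden-layer size.

    For each candidate size, ``nets_per_hu`` networks are trained and
    evaluated, each on its own stratified split (shared across sizes).  The
    selected size is the smallest one whose accuracies are not significantly
    worse (Wilcoxon, level ``config.alpha``) than those of the best-scoring
    size — i.e. the smallest network beyond which no significant improvement
    is available.
    """
    hidden_range = list(hidden_range)
    if not hidden_range:
        raise ConfigurationError("hidden_range must be nonempty")
    config = config or EvalConfig()
    eval_cfg = replace(config, n_repetitions=nets_per_hu)
    splits = make_splits(fm.class_indices, eval_cfg)
    accs = np.empty((len(hidden_range), nets_per_hu))
    for i, hu in enumerate(hidden_range):
        spec = MethodSpec(method, output_type, hidden=(hu,))
        if train is not None:
            spec = replace(spec, train=train)
        result = repeated_split_evaluate(fm, spec, eval_cfg, splits)
        accs[i] = result.accuracies
    means = accs.mean(axis=1)
    best = int(np.argmax(means))
    p_values: dict[int, float] = {}
    selected = hidden_range[best]
    for i, hu in enumerate(hidden_range):
        res = wilcoxon_signed_rank(accs[i], accs[best], config.alpha)
        p_values[hu] = res.p_value
        worse = res.significant and means[i] < means[best]
        if not worse:
            selected = hu
            break
    return SweepResult(hidden_range, accs, selected, p_values)


# -- method comparison -------------------------------------------------------

def compare_methods(fm: FeatureMatrix, methods: list[MethodSpec],
                    config: EvalConfig | None = None
                    ) -> tuple[pd.DataFrame, dict[tuple[str, str], WilcoxonResult]]:
    """Evaluate several methods on a shared split sequence.

    Returns a table with one row per method (Acc, SD, training time) and a
    dict of pairwise Wilcoxon results on the repetition-paired accuracies.
    With a single method the table has one row and no p-values.
    """
    config = config or EvalConfig()
    splits = make_splits(fm.class_indices, config)
    results = [repeated_split_evaluate(fm, spec, config, splits)
               for spec in methods]
    rows = [
        {
            "method": spec.method,
            "output_type": spec.output_type,
            "acc": res.mean_accuracy,
            "sd": res.sd,
            "train_seconds": res.train_seconds,
        }
        for spec, res in zip(methods, results)
    ]
    table = pd.DataFrame(rows)
    pairwise: dict[tuple[str, str], WilcoxonResult] = {}
    for i in range(len(methods)):
        for j in range(i + 1, len(methods)):
            pairwise[(methods[i].name, methods[j].name)] = wilcoxon_signed_rank(
                results[i].accuracies, results[j].accuracies, config.alpha
            )
    return table, pairwise
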