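"""SVM decoding of single trials with repeated cross-validation, two-stage
RBF hyperparameter grid search, and binomial above-chance inference.

Accuracy is the mean held-out classification rate over repeated stratified
10-fold cross-validation (fold assignment reshuffled each repetition).  The
RBF kernel is parameterized as ``K(x, x') = exp(-||x - x'||^2 / (2 s^2))``
with kernel scale ``s``; the box constraint is the SVM cost parameter C.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "SvmSpec",
    "GridSpec",
    "ClassificationResult",
    "crossval_accuracy",
    "fold_predictions",
    "binomial_above_chance",
    "permutation_pvalue",
    "grid_search_rbf",
]


@dataclass
class SvmSpec:
    kernel: str = "linear"
    kernel_scale: float = 1.0
    box_constraint: float = 1.0
    folds: int = 10
    repetitions: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.folds < 2 or self.repetitions < 1:
            raise ValueError("need folds >= 2 and repetitions >= 1")
        if self.kernel_scale <= 0 or self.box_constraint <= 0:
            raise ValueError("kernel_scale and box_constraint must be positive")


@dataclass
class GridSpec:
    """Two-stage logarithmic hyperparameter grid for the RBF SVM."""

    grid_size: int = 9
    kernel_scale_range: tuple[float, float] = (1e-3, 1e15)
    box_constraint_range: tuple[float, float] = (1e-3, 1e9)

    def stage1_grids(self) -> tuple[np.ndarray, np.ndarray]:
        ks = np.logspace(
            np.log10(self.kernel_scale_range[0]),
            np.log10(self.kernel_scale_range[1]),
            self.grid_size,
        )
        bc = np.logspace(
            np.log10(self.box_constraint_range[0]),
            np.log10(self.box_constraint_range[1]),
            self.grid_size,
        )
        return ks, bc


@dataclass
class ClassificationResult:
    mean_accuracy: float
    per_repetition_accuracies: np.ndarray
    n_trials: int
    p_binomial: float | None = None
    chosen_params: dict = field(default_factory=dict)


def _make_svc(spec: SvmSpec) -> SVC:
    if spec.kernel == "linear":
        return SVC(kernel="linear", C=spec.box_constraint, max_iter=1_000_000)
    gamma = 1.0 / (2.0 * spec.kernel_scale**2)
    return SVC(kernel="rbf", C=spec.box_constraint, gamma=gamma, max_iter=1_000_000)


def fold_predictions(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    spec: SvmSpec,
) -> np.ndarray:
    """Held-out predictions for one fold; only training-fold labels are used
    for fitting (test-fold labels never influence the model)."""
    clf = _make_svc(spec)
    clf.fit(X[train_idx], y[train_idx])
    return clf.predict(X[test_idx])


def _one_crossval(
    X: np.ndarray, y: np.ndarray, spec: SvmSpec, random_state: int
) -> float:
    """Pooled held-out accuracy of a single stratified k-fold pass."""
    skf = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=random_state)
    correct = 0
    for train_idx, test_idx in skf.split(X, y):
        pred = fold_predictions(X, y, train_idx, test_idx, spec)
        correct += int(np.sum(pred == y[test_idx]))
    return correct / len(y)


def crossval_accuracy(X, y=None, spec: SvmSpec | None = None) -> ClassificationResult:
    """Mean held-out accuracy over repeated stratified k-fold CV.

    ``X`` may be a FeatureMatrix (labels taken from it) or an array with
    explicit ``y``.  Fold assignment is reshuffled each repetition from the
    spec seed; the mean over repetitions of the pooled held-out accuracy is
    reported, with the one-sided binomial above-chance p-value attached.
    """
    if hasattr(X, "X"):
        X, y = X.X, X.y
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if spec is None:
        spec = SvmSpec()
    if len(y) < spec.folds:
        raise ValueError("fewer trials than folds")
    rng = np.random.default_rng(spec.seed)
    accs = np.empty(spec.repetitions)
    for r in range(spec.repetitions):
        accs[r] = _one_crossval(X, y, spec, int(rng.integers(0, 2**31 - 1)))
    result = ClassificationResult(
        mean_accuracy=float(accs.mean()),
        per_repetition_accuracies=accs,
        n_trials=len(y),
        chosen_params={
            "kernel": spec.kernel,
            "kernel_scale": spec.kernel_scale,
            "box_constraint": spec.box_constraint,
        },
    )
    result.p_binomial = binomial_above_chance(result)
    return result


def binomial_above_chance(result, chance: float = 0.5) -> float:
    """One-sided upper-tail binomial p-value that classification exceeded
    chance: k = round(mean_accuracy * n) successes out of n trials."""
    if hasattr(result, "mean_accuracy"):
        mean_acc, n = result.mean_accuracy, result.n_trials
    else:
        mean_acc, n = result
    if n < 1:
        raise ValueError("need at least one trial")
    k = int(np.rint(mean_acc * n))
    return float(stats.binom.sf(k - 1, n, chance))


def permutation_pvalue(
    X: np.ndarray,
    y: np.ndarray,
    spec: SvmSpec | None = None,
    n_perm: int = 100,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Permutation p-value for decoding accuracy (calibrated alternative to
    the binomial test, which ignores dependence between CV folds).

    The observed statistic is a single repeated-CV mean accuracy; the null
    redraws it with labels permuted.  Returns (p, observed, null
    accuracies).
    """
    if spec is None:
        spec = SvmSpec(repetitions=1)
    rng = np.random.default_rng(seed)
    obs = crossval_accuracy(X, y, spec).mean_accuracy
    null = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        null[i] = crossval_accuracy(X, yp, spec).mean_accuracy
    p = (1 + int(np.sum(null >= obs))) / (n_perm + 1)
    return float(p), float(obs), null


def grid_search_rbf(
    X,
    y=None,
    grid: GridSpec | None = None,
    seed: int = 0,
    folds: int = 10,
) -> tuple[float, float, dict]:
    """Two-stage 9 x 9 logarithmic grid search for (kernel_scale,
    box_constraint).

    Stage 1 evaluates each grid pair with a single stratified k-fold CV
    (one shared fold assignment); stage 2 repeats on a fresh 9 x 9 log grid
    spanning +/- one stage-1 grid step around the stage-1 winner, clipped to
    the stage-1 ranges.  Ties prefer the lowest box constraint, then the
    lowest kernel scale (simplest model).  Returns (kernel_scale,
    box_constraint, details) where details holds both stages' grids and
    accuracy tables.
    """
    if hasattr(X, "X"):
        X, y = X.X, X.y
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if grid is None:
        grid = GridSpec()
    ks1, bc1 = grid.stage1_grids()

    def evaluate(ks_vals, bc_vals, random_state):
        acc = np.empty((len(ks_vals), len(bc_vals)))
        with warnings.catch_warnings():
            # extreme grid corners legitimately hit the iteration cap
            warnings.simplefilter("ignore", ConvergenceWarning)
            for i, s in enumerate(ks_vals):
                for j, c in enumerate(bc_vals):
                    spec = SvmSpec(
                        kernel="rbf", kernel_scale=s, box_constraint=c, folds=folds,
                        repetitions=1, seed=0,
                    )
                    acc[i, j] = _one_crossval(X, y, spec, random_state)
        return acc

    def argbest(acc, ks_vals, bc_vals):
        best = acc.max()
        ties = np.argwhere(acc >= best - 1e-12)
        # simplest model: lowest box constraint, then lowest kernel scale
        order = sorted(ties, key=lambda ij: (bc_vals[ij[1]], ks_vals[ij[0]]))
        i, j = order[0]
        return ks_vals[i], bc_vals[j]

    acc1 = evaluate(ks1, bc1, seed)
    ks_best, bc_best = argbest(acc1, ks1, bc1)

    if grid.grid_size > 1:
        step_ks = (ks1[-1] / ks1[0]) ** (1.0 / (len(ks1) - 1))
        step_bc = (bc1[-1] / bc1[0]) ** (1.0 / (len(bc1) - 1))
        lo_ks = max(ks_best / step_ks, grid.kernel_scale_range[0])
        hi_ks = min(ks_best * step_ks, grid.kernel_scale_range[1])
        lo_bc = max(bc_best / step_bc, grid.box_constraint_range[0])
        hi_bc = min(bc_best * step_bc, grid.box_constraint_range[1])
        if (lo_ks, hi_ks) != (ks_best / step_ks, ks_best * step_ks) or (
            lo_bc,
            hi_bc,
        ) != (bc_best / step_bc, bc_best * step_bc):
            logger.info("stage-2 grid clipped at stage-1 range boundary")
        ks2 = np.logspace(np.log10(lo_ks), np.log10(hi_ks), grid.grid_size)
        bc2 = np.logspace(np.log10(lo_bc), np.log10(hi_bc), grid.grid_size)
        acc2 = evaluate(ks2, bc2, seed + 1)
        ks_final, bc_final = argbest(acc2, ks2, bc2)
    else:
        ks2, bc2, acc2 = ks1, bc1, acc1
        ks_final, bc_final = ks_best, bc_best

    details = {
        "stage1": {"kernel_scales": ks1, "box_constraints": bc1, "accuracy": acc1},
        "stage2": {"kernel_scales": ks2, "box_constraints": bc2, "accuracy": acc2},
        "stage1_best": (ks_best, bc_best),
        "fold_seed": seed,
    }
    return float(ks_final), float(bc_final), details
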