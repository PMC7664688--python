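"""Random-forest-based automatic feature selection.

Two selectors, both applied to training folds only:

* :func:`boruta_select` — all-relevant selection by comparing each real
  feature's random-forest importance against the best of shuffled "shadow"
  copies across iterations, with a Bonferroni-corrected two-sided binomial
  test classifying features as confirmed / rejected (remainder tentative).
* :func:`varselrf_select` — minimal-set selection by backward elimination:
  rank once by importance, repeatedly drop the worst fraction, track
  out-of-bag error, and return the smallest set within one standard error of
  the minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from eegintent.seeding import as_rng


def oob_permutation_drops(
    X: np.ndarray, y: np.ndarray, n_trees: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-tree out-of-bag accuracy drops under single-column permutation.

    Fits a bagged ensemble of sqrt-feature decision trees; for each tree the
    accuracy on its out-of-bag rows is compared with the accuracy after
    permuting one column at a time (only columns the tree actually split on
    can have a nonzero drop).  Returns an (n_trees, n_features) matrix of
    drops — mean over axis 0 is the classic mean-decrease-accuracy importance,
    mean/standard-error its z-score.
    """
    n, p = X.shape
    drops = np.zeros((n_trees, p))
    for t in range(n_trees):
        idx = rng.integers(0, n, n)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        oob = np.nonzero(~mask)[0]
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2**31))
        )
        tree.fit(X[idx], y[idx])
        if len(oob) == 0:
            continue
        Xo, yo = X[oob], y[oob]
        base = (tree.predict(Xo) == yo).mean()
        used = np.unique(tree.tree_.feature)
        for j in used[used >= 0]:
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(len(oob)), j]
            drops[t, j] = base - (tree.predict(Xp) == yo).mean()
    return drops


def oob_z_importance(X, y, n_trees, rng) -> np.ndarray:
    """Z-scored mean-decrease-accuracy importance (mean drop / its SE)."""
    drops = oob_permutation_drops(X, y, n_trees, rng)
    mean = drops.mean(axis=0)
    sd = drops.std(axis=0, ddof=1)
    se = sd / np.sqrt(drops.shape[0])
    return np.where(sd > 0, mean / (se + 1e-12), 0.0)


@dataclass(frozen=True)
class BorutaConfig:
    max_iter: int = 30
    alpha: float = 0.01
    rf_trees: int = 50
    importance: str = "oob_permutation"  # "oob_permutation" | "impurity"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class VarSelRFConfig:
    drop_fraction: float = 0.2
    initial_trees: int = 200
    iter_trees: int = 200
    importance: str = "oob_permutation"  # "oob_permutation" | "impurity"
    min_features: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.drop_fraction < 1:
            raise ValueError("drop_fraction must be in (0, 1)")


@dataclass
class FeatureDecision:
    """Outcome of a selection run; statuses partition the input columns."""

    columns: list
    status: dict  # column -> "confirmed" | "tentative" | "rejected"
    importance_history: list[np.ndarray] = field(default_factory=list)
    n_iter: int = 0
    seed: int | None = None

    @property
    def confirmed(self) -> list:
        return [c for c in self.columns if self.status[c] == "confirmed"]

    @property
    def tentative(self) -> list:
        return [c for c in self.columns if self.status[c] == "tentative"]

    @property
    def rejected(self) -> list:
        return [c for c in self.columns if self.status[c] == "rejected"]

    @property
    def selected(self) -> list:
        """Downstream feature set: confirmed plus tentative (inclusive policy)."""
        return [c for c in self.columns if self.status[c] != "rejected"]

    def to_frame(self) -> pd.DataFrame:
        med = (
            np.median(np.vstack(self.importance_history), axis=0)
            if self.importance_history
            else np.full(len(self.columns), np.nan)
        )
        return pd.DataFrame(
            {"feature": self.columns,
             "status": [self.status[c] for c in self.columns],
             "median_importance": med}
        )


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, list(range(X.shape[1]))


def _validate_xy(X, y):
    y = np.asarray(y)
    if X.shape[0] != len(y):
        raise ValueError("X and y have different numbers of rows")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("y must contain at least 2 classes")
    if X.shape[0] < 2 * len(classes):
        raise ValueError("need at least 2 rows per class")
    return y


def _rf_impurity_importance(X, y, n_trees, rng):
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(rng.integers(2**31)), n_jobs=1
    ).fit(X, y)
    return forest.feature_importances_


def boruta_select(X, y, config: BorutaConfig | None = None, seed=0) -> FeatureDecision:
    """Shadow-feature wrapper selection around a random forest.

    Each iteration appends a shuffled copy of every still-active column, fits
    a forest, and scores a "hit" for real columns whose importance exceeds the
    best shadow importance.  Hit counts are tested against Binomial(k, 1/2)
    two-sided with Bonferroni correction over the initial column count;
    rejected columns leave the design matrix.  Stops early once no column is
    undecided.  Deterministic given seed.
    """
    config = config or BorutaConfig()
    Xm, columns = _as_matrix(X)
    y = _validate_xy(Xm, y)
    g = as_rng(seed)
    p = len(columns)
    threshold = config.alpha / p

    status = {c: "tentative" for c in columns}
    undecided = list(range(p))
    confirmed: list[int] = []
    hits = np.zeros(p, dtype=int)
    history: list[np.ndarray] = []
    n_iter = 0

    for it in range(1, config.max_iter + 1):
        n_iter = it
        active = sorted(undecided + confirmed)
        Xa = Xm[:, active]
        shadows = Xa.copy()
        for j in range(shadows.shape[1]):
            g.shuffle(shadows[:, j])
        design = np.hstack([Xa, shadows])
        if config.importance == "oob_permutation":
            imp = oob_z_importance(design, y, config.rf_trees, g)
        else:
            imp = _rf_impurity_importance(design, y, config.rf_trees, g)
        real_imp, shadow_imp = imp[: len(active)], imp[len(active):]
        shadow_max = shadow_imp.max()

        full_imp = np.full(p, np.nan)
        for k, j in enumerate(active):
            full_imp[j] = real_imp[k]
        history.append(full_imp)

        for k, j in enumerate(active):
            if j in undecided and real_imp[k] > shadow_max:
                hits[j] += 1

        still = []
        for j in undecided:
            p_hi = stats.binom.sf(hits[j] - 1, it, 0.5)   # P(X >= hits)
            p_lo = stats.binom.cdf(hits[j], it, 0.5)      # P(X <= hits)
            if p_hi < threshold:
                status[columns[j]] = "confirmed"
                confirmed.append(j)
            elif p_lo < threshold:
                status[columns[j]] = "rejected"
            else:
                still.append(j)
        undecided = still
        if not undecided:
            break

    return FeatureDecision(
        columns=columns, status=status, importance_history=history,
        n_iter=n_iter, seed=seed if isinstance(seed, int) else None,
    )


def varselrf_select(X, y, config: VarSelRFConfig | None = None, seed=0) -> list:
    """Backward-elimination selection guided by out-of-bag error.

    An initial forest ranks features once (importance not recomputed while
    eliminating); the worst ``drop_fraction`` is removed per step down to
    ``min_features`` columns, and the smallest set whose OOB error is within
    one standard error of the minimum is returned.  Deterministic given seed.
    """
    config = config or VarSelRFConfig()
    Xm, columns = _as_matrix(X)
    y = _validate_xy(Xm, y)
    g = as_rng(seed)

    def fit_oob(cols: list[int], trees: int):
        f = RandomForestClassifier(
            n_estimators=trees,
            oob_score=True,
            bootstrap=True,
            random_state=int(g.integers(2**31)),
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sparse-OOB warning on tiny folds
            f.fit(Xm[:, cols], y)
        return f, 1.0 - f.oob_score_

    all_cols = list(range(len(columns)))
    forest, err0 = fit_oob(all_cols, config.initial_trees)
    if config.importance == "oob_permutation":
        # unscaled mean decrease in OOB accuracy, the original's ranking measure
        imp = oob_permutation_drops(Xm, y, config.initial_trees, g).mean(axis=0)
    else:
        imp = forest.feature_importances_
    ranked = [c for c in np.argsort(imp)[::-1]]  # best first

    history: list[tuple[list[int], float]] = [(all_cols, err0)]
    current = list(ranked)
    while len(current) > config.min_features:
        keep = max(config.min_features,
                   len(current) - max(1, int(np.floor(config.drop_fraction * len(current)))))
        current = current[:keep]
        _, err = fit_oob(sorted(current), config.iter_trees)
        history.append((list(current), err))

    n = len(y)
    errs = np.array([e for _, e in history])
    err_min = errs.min()
    se = float(np.sqrt(err_min * (1.0 - err_min) / n))
    # smallest set within 1 SE of the minimum OOB error
    best = min(
        (h for h in history if h[1] <= err_min + se),
        key=lambda h: len(h[0]),
    )
    return [columns[j] for j in sorted(best[0])]
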