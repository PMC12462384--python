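"""Two-step dimensionality reduction plus an SVD projection.

Step 1 filters features by a two-sided Mann-Whitney U test between the two
classes (keep iff p < alpha, no multiplicity adjustment by default; an FDR
switch is available).  Step 2 fits an extremely-randomized-trees ensemble on
the surviving features and keeps the ``top_k`` by mean impurity-decrease
importance.  A centered truncated SVD is provided separately for model
exploration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import ExtraTreesClassifier

from .errors import CppkitError, EmptySampleError, SingleClassError
from .matrix import FeatureMatrix

__all__ = [
    "MWUResult",
    "SelectionReport",
    "mann_whitney_u",
    "filter_by_mwu",
    "ert_select",
    "select_features",
    "SVDReducer",
    "svd_reduce",
]

# exact null distribution is cheap up to this per-sample size (and only
# valid without ties)
_EXACT_MAX_N = 8


@dataclass(frozen=True)
class MWUResult:
    u_statistic: float  # U for the first sample
    p_value: float      # two-sided
    method: str         # "exact" | "normal-approximation"


@dataclass
class SelectionReport:
    """Outcome of the two-step reduction.

    ``p_values`` covers every input feature; ``kept`` is the subset passing
    the alpha filter; ``importances`` (normalized to sum 1) covers the kept
    features; ``selected`` is the final ordered list, descending importance
    with alphabetical tie-break.
    """

    feature_names: list[str]
    p_values: dict[str, float] | None = None
    kept: list[str] | None = None
    importances: dict[str, float] | None = None
    selected: list[str] = field(default_factory=list)
    alpha: float | None = None
    top_k: int | None = None
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_features": len(self.feature_names),
            "alpha": self.alpha,
            "top_k": self.top_k,
            "seed": self.seed,
            "p_values": self.p_values,
            "kept": self.kept,
            "importances": self.importances,
            "selected": self.selected,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionReport":
        payload = json.loads(Path(path).read_text())
        kept = payload.get("kept")
        names = payload.get("p_values")
        return cls(
            feature_names=list(names) if names else list(kept or payload["selected"]),
            p_values=payload.get("p_values"),
            kept=kept,
            importances=payload.get("importances"),
            selected=list(payload["selected"]),
            alpha=payload.get("alpha"),
            top_k=payload.get("top_k"),
            seed=payload.get("seed"),
        )


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(x, y) -> MWUResult:
    """Two-sided Mann-Whitney U test; U is reported for the first sample.

    The exact null distribution is used when both samples have at most 8
    observations and the pooled data is tie-free; otherwise the normal
    approximation with tie and continuity corrections applies.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EmptySampleError("both samples must be non-empty")
    if x.size <= _EXACT_MAX_N and y.size <= _EXACT_MAX_N and not _has_ties(x, y):
        method = "exact"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = "normal-approximation"
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    p = float(res.pvalue)
    if np.isnan(p):  # zero-variance pooled sample: no evidence either way
        p = 1.0
    return MWUResult(u_statistic=float(res.statistic), p_value=min(p, 1.0), method=method)


def _split_classes(m: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    if m.labels is None:
        raise SingleClassError("feature matrix carries no labels")
    pos = m.values[m.labels == 1]
    neg = m.values[m.labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise SingleClassError("both classes must be non-empty")
    return pos, neg


def filter_by_mwu(
    m: FeatureMatrix, alpha: float = 0.05, fdr: bool = False
) -> SelectionReport:
    """Per-feature Mann-Whitney filter: keep iff p < alpha.

    Constant features are assigned p = 1 and dropped.  With ``fdr=True`` the
    Benjamini-Hochberg adjusted p-values are compared to alpha instead (off
    by default).
    """
    pos, neg = _split_classes(m)
    d = m.n_features
    p_values = np.ones(d)
    constant = np.ptp(m.values, axis=0) == 0.0
    live = ~constant
    if live.any():
        if min(len(pos), len(neg)) > _EXACT_MAX_N:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = stats.mannwhitneyu(
                    pos[:, live],
                    neg[:, live],
                    alternative="two-sided",
                    method="asymptotic",
                    use_continuity=True,
                    axis=0,
                )
            p_live = np.nan_to_num(res.pvalue, nan=1.0)
        else:
            p_live = np.array(
                [
                    mann_whitney_u(pos[:, j], neg[:, j]).p_value
                    for j in np.flatnonzero(live)
                ]
            )
        p_values[live] = np.minimum(p_live, 1.0)
    compare = p_values.copy()
    if fdr:
        compare = _benjamini_hochberg(p_values)
    kept_mask = (compare < alpha) & live
    kept = [n for n, keep in zip(m.names, kept_mask) if keep]
    return SelectionReport(
        feature_names=list(m.names),
        p_values={n: float(p) for n, p in zip(m.names, p_values)},
        kept=kept,
        alpha=alpha,
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    d = len(p)
    order = np.argsort(p)
    adjusted = np.empty(d)
    running = 1.0
    for rank in range(d, 0, -1):
        j = order[rank - 1]
        running = min(running, p[j] * d / rank)
        adjusted[j] = running
    return adjusted


def ert_select(
    m: FeatureMatrix,
    top_k: int,
    n_estimators: int = 500,
    seed: int = 42,
) -> SelectionReport:
    """Rank features by extra-trees mean impurity-decrease importance.

    Fits one ensemble on the full matrix and returns the ``top_k`` names in
    descending importance (alphabetical tie-break), deterministically for a
    fixed seed.  Constant features never split and get importance zero.
    """
    if top_k > m.n_features:
        raise CppkitError(f"top_k={top_k} exceeds {m.n_features} features")
    pos, neg = _split_classes(m)  # label check
    del pos, neg
    forest = ExtraTreesClassifier(
        n_estimators=n_estimators,
        criterion="gini",
        max_features="sqrt",
        bootstrap=False,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(m.values, m.labels)
    importances = forest.feature_importances_
    total = importances.sum()
    if total > 0:
        importances = importances / total
    order = sorted(range(m.n_features), key=lambda j: (-importances[j], m.names[j]))
    selected = [m.names[j] for j in order[:top_k]]
    return SelectionReport(
        feature_names=list(m.names),
        importances={n: float(v) for n, v in zip(m.names, importances)},
        selected=selected,
        top_k=top_k,
        seed=seed,
    )


def select_features(
    m: FeatureMatrix,
    alpha: float = 0.05,
    top_k: int = 522,
    n_estimators: int = 500,
    seed: int = 42,
    fdr: bool = False,
) -> tuple[FeatureMatrix, SelectionReport]:
    """The full two-step pipeline: Mann-Whitney filter first, ERT ranking second.

    ``top_k`` is clamped to the number of features surviving the filter.
    Returns the reduced matrix (columns in selected order) and a merged
    report carrying p-values, kept set, importances and the final list.
    """
    mwu = filter_by_mwu(m, alpha=alpha, fdr=fdr)
    if not mwu.kept:
        return m.subset([]), mwu
    reduced = m.subset(mwu.kept)
    reduced.labels = m.labels
    k = min(top_k, len(mwu.kept))
    ert = ert_select(reduced, top_k=k, n_estimators=n_estimators, seed=seed)
    report = SelectionReport(
        feature_names=list(m.names),
        p_values=mwu.p_values,
        kept=mwu.kept,
        importances=ert.importances,
        selected=ert.selected,
        alpha=alpha,
        top_k=k,
        seed=seed,
    )
    final = m.subset(ert.selected)
    final.labels = m.labels
    return final, report


class SVDReducer:
    """Centered truncated SVD fitted on training rows, reusable on new rows."""

    def __init__(self, n_components: int):
        self.n_components = n_components
        self._pca: PCA | None = None
        self.explained_variance_ratio_: np.ndarray | None = None

    def fit(self, values: np.ndarray) -> "SVDReducer":
        n, d = values.shape
        if not 1 <= self.n_components <= min(n, d):
            raise CppkitError(
                f"n_components={self.n_components} outside [1, {min(n, d)}]"
            )
        pca = PCA(n_components=min(self.n_components, n, d), svd_solver="full")
        pca.fit(values)
        s = pca.singular_values_
        tol = np.max(s, initial=0.0) * max(n, d) * np.finfo(float).eps
        rank = int(np.sum(s > tol))
        if rank < self.n_components:
            warnings.warn(
                f"requested {self.n_components} components but centered rank is "
                f"{rank}; clamping",
                stacklevel=2,
            )
            pca = PCA(n_components=max(rank, 1), svd_solver="full")
            pca.fit(values)
            self.n_components = max(rank, 1)
        self._pca = pca
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self._pca is None:
            raise CppkitError("reducer is not fitted")
        return self._pca.transform(values)

    def inverse_transform(self, reduced: np.ndarray) -> np.ndarray:
        if self._pca is None:
            raise CppkitError("reducer is not fitted")
        return self._pca.inverse_transform(reduced)


def svd_reduce(
    m: FeatureMatrix, n_components: int
) -> tuple[FeatureMatrix, SVDReducer]:
    """Project a matrix onto its leading centered singular directions.

    Returns the projected matrix (columns ``SVD_1..SVD_k``) and the fitted
    reducer for transforming unseen rows.
    """
    reducer = SVDReducer(n_components).fit(m.values)
    projected = reducer.transform(m.values)
    names = [f"SVD_{i + 1}" for i in range(projected.shape[1])]
    out = FeatureMatrix(
        ids=list(m.ids),
        names=names,
        values=projected,
        labels=None if m.labels is None else m.labels.copy(),
    )
    return out, reducer
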