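"""Ensemble filter scoring and rank fusion.

Every embedded feature is discretized into equal-width bins (shared by all
three filters so they score the same contingency tables), scored by
information gain, chi-square and symmetrical uncertainty, converted to
average-tie ranks (rank 1 = most relevant), and fused by the per-feature
median. A top-m candidate pool gates entry to the thresholding stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

DEFAULT_BINS = 10

FILTER_MODES = ("fusion_median", "fusion_mean", "ig_only", "cs_only", "su_only")


@dataclass
class DiscretizationModel:
    """Per-feature equal-width bin grid fitted on training data.

    Values are min-shifted to nonnegativity; out-of-range values clamp to
    the boundary bins. Constant features occupy bin 0.
    """

    mins: np.ndarray
    widths: np.ndarray  # full range width per feature; 0 for constant columns
    n_bins: int


@dataclass
class FilterRankTable:
    ig: np.ndarray
    chi2: np.ndarray
    su: np.ndarray
    r_ig: np.ndarray
    r_cs: np.ndarray
    r_su: np.ndarray
    r_fused: np.ndarray

    @property
    def n_features(self) -> int:
        return int(self.ig.shape[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": np.arange(self.n_features),
                "ig": self.ig,
                "chi2": self.chi2,
                "su": self.su,
                "r_ig": self.r_ig,
                "r_cs": self.r_cs,
                "r_su": self.r_su,
                "r_fused": self.r_fused,
            }
        )

    def save(self, path, delimiter: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=delimiter, index=False)


def fit_discretizer(Z_train: np.ndarray, n_bins: int = DEFAULT_BINS) -> DiscretizationModel:
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    Z_train = np.asarray(Z_train, dtype=np.float64)
    mins = Z_train.min(axis=0)
    widths = Z_train.max(axis=0) - mins
    return DiscretizationModel(mins=mins, widths=widths, n_bins=int(n_bins))


def discretize(model: DiscretizationModel, Z: np.ndarray) -> np.ndarray:
    """Map values to integer bin ids in [0, B-1], clamping out-of-range."""
    Z = np.asarray(Z, dtype=np.float64)
    shifted = Z - model.mins[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(model.widths[None, :] > 0, shifted / model.widths[None, :], 0.0)
    bins = np.floor(frac * model.n_bins).astype(np.int64)
    return np.clip(bins, 0, model.n_bins - 1)


def _contingency(column: np.ndarray, y: np.ndarray, n_bins: int, n_classes: int) -> np.ndarray:
    flat = column * n_classes + y
    counts = np.bincount(flat, minlength=n_bins * n_classes)
    return counts.reshape(n_bins, n_classes).astype(np.float64)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _mutual_information(table: np.ndarray) -> float:
    n = table.sum()
    if n == 0:
        return 0.0
    joint = table / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    return float((joint[nz] * np.log(joint[nz] / outer[nz])).sum())


def _per_feature_tables(D: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    D = np.asarray(D, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    n_bins = int(D.max()) + 1 if D.size else 1
    n_classes = int(y.max()) + 1
    return [_contingency(D[:, j], y, n_bins, n_classes) for j in range(D.shape[1])]


def information_gain_scores(D: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Plug-in mutual information (natural log) between bins and labels."""
    return np.array([_mutual_information(t) for t in _per_feature_tables(D, y)])


def chi_square_scores(D: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson chi-square of the bin x class contingency table.

    Cells with zero expected count contribute nothing (their observed count
    is necessarily zero too).
    """
    out = []
    for table in _per_feature_tables(D, y):
        n = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
        mask = expected > 0
        out.append(float(((table[mask] - expected[mask]) ** 2 / expected[mask]).sum()))
    return np.array(out)


def symmetrical_uncertainty_scores(D: np.ndarray, y: np.ndarray) -> np.ndarray:
    """``2 I(X;Y) / (H(X) + H(Y))`` in [0, 1]; 0 when both entropies vanish."""
    out = []
    for table in _per_feature_tables(D, y):
        n = table.sum()
        hx = _entropy(table.sum(axis=1) / n)
        hy = _entropy(table.sum(axis=0) / n)
        denom = hx + hy
        out.append(2.0 * _mutual_information(table) / denom if denom > 0 else 0.0)
    return np.array(out)


def rank_features(scores: np.ndarray) -> np.ndarray:
    """Descending-score ranks starting at 1, average ranks on ties."""
    scores = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    return rankdata(-scores, method="average")


def median_fuse(r_ig: np.ndarray, r_cs: np.ndarray, r_su: np.ndarray) -> np.ndarray:
    """Elementwise median of the three rank vectors."""
    r_ig, r_cs, r_su = (np.asarray(r) for r in (r_ig, r_cs, r_su))
    if not (r_ig.shape == r_cs.shape == r_su.shape):
        raise ValueError("rank vectors must share one length")
    return np.median(np.vstack([r_ig, r_cs, r_su]), axis=0)


def mean_fuse(r_ig: np.ndarray, r_cs: np.ndarray, r_su: np.ndarray) -> np.ndarray:
    """Elementwise arithmetic mean of the three rank vectors (ablation mode)."""
    r_ig, r_cs, r_su = (np.asarray(r) for r in (r_ig, r_cs, r_su))
    if not (r_ig.shape == r_cs.shape == r_su.shape):
        raise ValueError("rank vectors must share one length")
    return np.mean(np.vstack([r_ig, r_cs, r_su]), axis=0)


def build_rank_table(
    Z_train: np.ndarray,
    y_train: np.ndarray,
    n_bins: int = DEFAULT_BINS,
    mode: str = "fusion_median",
) -> FilterRankTable:
    """Score, rank and fuse all features in one pass.

    ``mode`` selects the fused-rank column: median fusion (default), mean
    fusion, or a single filter's ranks verbatim.
    """
    if mode not in FILTER_MODES:
        raise ValueError(f"unknown filter mode {mode!r}; valid: {FILTER_MODES}")
    disc = fit_discretizer(Z_train, n_bins)
    D = discretize(disc, Z_train)
    ig = information_gain_scores(D, y_train)
    chi2 = chi_square_scores(D, y_train)
    su = symmetrical_uncertainty_scores(D, y_train)
    r_ig = rank_features(ig)
    r_cs = rank_features(chi2)
    r_su = rank_features(su)
    if mode == "fusion_median":
        fused = median_fuse(r_ig, r_cs, r_su)
    elif mode == "fusion_mean":
        fused = mean_fuse(r_ig, r_cs, r_su)
    elif mode == "ig_only":
        fused = r_ig.copy()
    elif mode == "cs_only":
        fused = r_cs.copy()
    else:
        fused = r_su.copy()
    return FilterRankTable(
        ig=ig, chi2=chi2, su=su, r_ig=r_ig, r_cs=r_cs, r_su=r_su, r_fused=fused
    )


def select_candidate_pool(fused: np.ndarray, m: int) -> np.ndarray:
    """Indices of the m smallest fused ranks, ties broken by feature index.

    The result is ordered by (fused rank, index).
    """
    fused = np.asarray(fused, dtype=np.float64)
    p = fused.shape[0]
    if not 1 <= m <= p:
        raise ValueError(f"pool size m={m} out of range [1, {p}]")
    order = np.lexsort((np.arange(p), fused))  # fused rank first, index second
    return order[:m]
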