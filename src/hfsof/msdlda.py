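"""Scatter-difference discriminant scoring and quantile thresholding.

Each feature is scored by between-class scatter minus within-class scatter:
``MS_j = sum_c n_c (mu_jc - mu_j)^2 - sum_c sum_{i in c} (x_ij - mu_jc)^2``.
Features at or above the empirical (1 - alpha) quantile of the scores
survive to the wrapper stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MsdldaResult:
    sb: np.ndarray
    sw: np.ndarray
    ms: np.ndarray
    tau: float
    alpha: float
    selected: np.ndarray  # ascending feature indices with ms >= tau

    def to_frame(self) -> pd.DataFrame:
        flags = np.zeros(self.ms.shape[0], dtype=int)
        flags[self.selected] = 1
        return pd.DataFrame(
            {
                "feature_id": np.arange(self.ms.shape[0]),
                "sb": self.sb,
                "sw": self.sw,
                "ms": self.ms,
                "selected": flags,
            }
        )

    def save(self, path, delimiter: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=delimiter, index=False)


def msdlda_scores(
    Z: np.ndarray, y: np.ndarray, return_components: bool = False
):
    """Per-feature scatter-difference scores ``SB(j) - SW(j)``.

    SB weights squared class-mean deviations by class size; SW is the raw
    within-class sum of squares (no normalization).
    """
    Z = np.asarray(Z, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    classes = np.unique(y)
    if classes.shape[0] < 2:
        raise ValueError("msdlda needs >= 2 classes present")
    mu = Z.mean(axis=0)
    sb = np.zeros(Z.shape[1])
    sw = np.zeros(Z.shape[1])
    for c in classes:
        rows = Z[y == c]
        n_c = rows.shape[0]
        mu_c = rows.mean(axis=0)
        sb += n_c * (mu_c - mu) ** 2
        sw += ((rows - mu_c) ** 2).sum(axis=0)
    ms = sb - sw
    if return_components:
        return ms, sb, sw
    return ms


def threshold_select(ms: np.ndarray, alpha: float) -> tuple[float, np.ndarray]:
    """Retain features with score >= the (1 - alpha) empirical quantile.

    Uses the linear-interpolation quantile convention; the surviving index
    set must have >= 2 members for the wrapper stage.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    ms = np.asarray(ms, dtype=np.float64)
    tau = float(np.quantile(ms, 1.0 - alpha, method="linear"))
    selected = np.flatnonzero(ms >= tau)
    if selected.shape[0] < 2:
        raise ValueError(
            "wrapper needs >= 2 candidate features; threshold retained "
            f"{selected.shape[0]}"
        )
    return tau, selected


def run_msdlda(Z_pool: np.ndarray, y: np.ndarray, alpha: float) -> MsdldaResult:
    ms, sb, sw = msdlda_scores(Z_pool, y, return_components=True)
    tau, selected = threshold_select(ms, alpha)
    return MsdldaResult(sb=sb, sw=sw, ms=ms, tau=tau, alpha=alpha, selected=selected)
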