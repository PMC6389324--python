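"""Per-gene recombination rate from a Marey map (genetic vs physical position).

Local-linear loess (tricube weights, default span 0.2) smooths the map;
the recombination rate of a gene is the analytic slope of the local fit at
the gene midpoint, in cM/Mb, clamped at zero.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["MareyMap", "LoessFit", "fit_loess", "gene_rate"]

MIN_MARKERS = 5


@dataclass
class MareyMap:
    chromosome: str
    physical_bp: np.ndarray
    genetic_cm: np.ndarray

    def __post_init__(self) -> None:
        self.physical_bp = np.asarray(self.physical_bp, dtype=float)
        self.genetic_cm = np.asarray(self.genetic_cm, dtype=float)
        if len(self.physical_bp) != len(self.genetic_cm):
            raise ValueError("marker arrays differ in length")
        order = np.argsort(self.physical_bp, kind="stable")
        self.physical_bp = self.physical_bp[order]
        self.genetic_cm = self.genetic_cm[order]

    def __len__(self) -> int:
        return len(self.physical_bp)

    def cleaned(self) -> "MareyMap":
        """Remove non-monotone outlier markers.

        Keeps the longest nondecreasing subsequence of genetic positions
        (markers ordered by physical position); everything else is treated
        as a mapping error and dropped.
        """
        keep = _longest_nondecreasing(self.genetic_cm)
        return MareyMap(
            self.chromosome, self.physical_bp[keep], self.genetic_cm[keep]
        )


def _longest_nondecreasing(values: np.ndarray) -> list[int]:
    """Indices of a longest nondecreasing subsequence (O(n log n))."""
    tails: list[float] = []  # tail value of LNDS of each length
    tails_idx: list[int] = []
    prev = [-1] * len(values)
    for i, v in enumerate(values):
        j = bisect.bisect_right(tails, v)
        if j == len(tails):
            tails.append(v)
            tails_idx.append(i)
        else:
            tails[j] = v
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    out = []
    i = tails_idx[-1]
    while i != -1:
        out.append(i)
        i = prev[i]
    return out[::-1]


class LoessFit:
    """Local-linear tricube-weighted regression of genetic on physical position."""

    def __init__(self, marey: MareyMap, span: float = 0.2):
        cleaned = marey.cleaned()
        if len(cleaned) < MIN_MARKERS:
            raise ValueError(
                f"{marey.chromosome}: fewer than {MIN_MARKERS} usable markers"
            )
        self.x = cleaned.physical_bp
        self.y = cleaned.genetic_cm
        self.span = span
        self.k = max(2, math.ceil(span * len(self.x)))
        self.x_min = float(self.x[0])
        self.x_max = float(self.x[-1])

    def _local_fit(self, x0: float) -> tuple[float, float]:
        """Weighted linear fit around x0; returns (value, slope per bp)."""
        d = np.abs(self.x - x0)
        # k nearest markers define the bandwidth
        idx = np.argpartition(d, self.k - 1)[: self.k]
        dmax = d[idx].max()
        if dmax == 0:
            return float(np.mean(self.y[idx])), 0.0
        u = d[idx] / dmax
        w = np.clip(1.0 - u**3, 0.0, None) ** 3
        if w.sum() == 0 or np.count_nonzero(w) < 2:
            w = np.ones_like(w)
        xs = self.x[idx] - x0
        ys = self.y[idx]
        sw = w.sum()
        mx = (w * xs).sum() / sw
        my = (w * ys).sum() / sw
        sxx = (w * (xs - mx) ** 2).sum()
        if sxx == 0:
            return float(my), 0.0
        slope = (w * (xs - mx) * (ys - my)).sum() / sxx
        return float(my - slope * mx), float(slope)

    def predict(self, x0: float) -> float:
        self._check_range(x0)
        return self._local_fit(x0)[0]

    def derivative(self, x0: float) -> float:
        """Slope of the local fit, in cM per bp."""
        self._check_range(x0)
        return self._local_fit(x0)[1]

    def _check_range(self, x0: float) -> None:
        if not self.x_min <= x0 <= self.x_max:
            raise ValueError(f"position {x0} outside fitted range")


def fit_loess(marey: MareyMap, span: float = 0.2) -> LoessFit:
    return LoessFit(marey, span)


def gene_rate(fit: LoessFit, interval: tuple[float, float]) -> float | None:
    """Recombination rate (cM/Mb) at the gene midpoint; None outside the map.

    Negative loess slopes are clamped to zero.
    """
    mid = 0.5 * (interval[0] + interval[1])
    if not fit.x_min <= mid <= fit.x_max:
        return None
    slope_cm_per_bp = fit.derivative(mid)
    return max(0.0, slope_cm_per_bp * 1e6)
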