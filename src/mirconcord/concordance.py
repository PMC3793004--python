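"""Pairwise detection-concordance statistics.

For each pair of platforms, every data point detected by at least one pair
member is classified by (a) whether both members or only one detected it and
(b) how many of the remaining platforms corroborate it — yielding the six
buckets (-, --, ---, +, ++, +++).  From these come the percent detected by
both, and a weighted pair score in [-1, 1]: each point contributes +1 (both
detect) or -1 (one detects), weighted by its expression percentile and by
outside-platform corroboration, so that a highly expressed, widely
corroborated miRNA counts more than a scarce singleton.  A score of 1 means
the two platforms detect exactly the same set of points; -1 means they share
none.  Venn subset counts and the expression-quintile dispersion of
single-platform vs all-platform detections complete the picture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairScore",
    "pair_counts",
    "percent_both",
    "weighted_pair_score",
    "venn_counts",
    "quintile_dispersion",
    "QUINTILE_EDGES",
]

QUINTILE_EDGES = (0.2, 0.4, 0.6, 0.8)
QUINTILE_LABELS = ("0-20%", "20-40%", "40-60%", "60-80%", "80-100%")


def _check_pair(cube: pd.DataFrame, pair: Sequence[str]) -> tuple[str, str]:
    a, b = pair
    if a == b:
        raise ValueError(f"pair members must differ (got {a!r} twice)")
    for p in (a, b):
        if p not in cube.columns:
            raise KeyError(f"unknown platform {p!r}")
    return a, b


@dataclass
class PairScore:
    """Detection-concordance breakdown for one platform pair.

    ``counts`` maps bucket labels to data-point counts: the sign marks
    both-member ('+') vs single-member ('-') detection, the repetition how
    many non-pair platforms also detect the point (0, 1 or 2 extra symbols).
    """

    pair: tuple[str, str]
    counts: dict[str, int]
    weighted_score: float | None = field(default=None)

    @property
    def n_single(self) -> int:
        return sum(v for k, v in self.counts.items() if k.startswith("-"))

    @property
    def n_both(self) -> int:
        return sum(v for k, v in self.counts.items() if k.startswith("+"))

    @property
    def percent_both(self) -> float | None:
        return percent_both(self)


def pair_counts(cube: pd.DataFrame, pair: Sequence[str]) -> PairScore:
    """Classify every point detected by >= 1 pair member into the buckets."""
    a, b = _check_pair(cube, pair)
    det_a = cube[a].to_numpy(bool)
    det_b = cube[b].to_numpy(bool)
    others = [c for c in cube.columns if c not in (a, b)]
    k = cube[others].to_numpy(bool).sum(axis=1) if others else np.zeros(len(cube), int)
    either = det_a | det_b
    both = det_a & det_b
    counts: dict[str, int] = {}
    n_others = len(others)
    for sign, mask in (("+", both), ("-", either & ~both)):
        for kk in range(n_others + 1):
            counts[sign * (kk + 1)] = int(np.sum(mask & (k == kk)))
    return PairScore(pair=(a, b), counts=counts)


def percent_both(score: PairScore) -> float | None:
    """Percent of either-member points detected by both; None when empty.

    The unrounded value is returned; reports round to the nearest integer.
    """
    denom = score.n_both + score.n_single
    if denom == 0:
        return None
    return 100.0 * score.n_both / denom


def weighted_pair_score(
    cube: pd.DataFrame,
    percentiles: pd.DataFrame,
    pair: Sequence[str],
) -> float:
    """Expression- and corroboration-weighted pair concordance in [-1, 1].

    Over data points m detected by at least one pair member::

        s_m = +1 if both members detect m else -1
        w_m = p_m * (1 + k_m) / (1 + K)
        score = sum(s_m * w_m) / sum(w_m)

    where p_m is the mean expression percentile across *all* platforms
    detecting m (only detecting platforms carry expression evidence), k_m
    the number of non-pair platforms detecting m, and K the number of
    non-pair platforms (2 in a four-platform study).  The score is 1 exactly
    when the members detect identical sets, -1 when the sets are disjoint;
    reports print it to 2 decimals.  NaN when no point is detected by either
    member.
    """
    a, b = _check_pair(cube, pair)
    det = cube.to_numpy(bool)
    cols = list(cube.columns)
    ia, ib = cols.index(a), cols.index(b)
    others = [i for i in range(len(cols)) if i not in (ia, ib)]
    either = det[:, ia] | det[:, ib]
    if not either.any():
        return float("nan")
    det_e = det[either]
    pct = percentiles.reindex(cube.index).to_numpy(float)[either]
    s = np.where(det_e[:, ia] & det_e[:, ib], 1.0, -1.0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(np.where(det_e, pct, 0.0), axis=1) / det_e.sum(axis=1)
    k = det_e[:, others].sum(axis=1) if others else np.zeros(len(det_e))
    w = p * (1.0 + k) / (1.0 + len(others))
    return float(np.sum(s * w) / np.sum(w))


def venn_counts(
    cube: pd.DataFrame, pooled: bool = False
) -> dict[tuple[str, ...], int]:
    """Data-point counts per non-empty detection subset of platforms.

    With ``pooled=True`` the unit is the miRNA (detected in >= 1 cell line
    per platform) rather than the (miRNA, cell line) point, mirroring a
    detection Venn diagram pooled over samples.  The subsets partition all
    detected units.
    """
    if cube.shape[1] < 2:
        raise ValueError("venn counts need at least 2 platforms")
    frame = cube
    if pooled:
        frame = cube.groupby(level="canonical_id").any()
    platforms = list(frame.columns)
    det = frame.to_numpy(bool)
    out: dict[tuple[str, ...], int] = {}
    codes = det @ (1 << np.arange(len(platforms)))
    for code in np.unique(codes):
        if code == 0:
            continue
        subset = tuple(p for i, p in enumerate(platforms) if code >> i & 1)
        out[subset] = int(np.sum(codes == code))
    return out


def quintile_dispersion(
    cube: pd.DataFrame,
    percentiles: pd.DataFrame,
    subset_rule: str = "single_platform",
) -> pd.DataFrame:
    """Expression-quintile distribution of qualifying detections, per platform.

    ``subset_rule="single_platform"`` takes, for each platform, the points
    detected by that platform alone; ``"all_platforms"`` the points detected
    by every platform.  Each qualifying point is binned by the platform's
    own percentile rank into [0,.2), [.2,.4), [.4,.6), [.6,.8), [.8,1]; the
    returned platform x bin fractions sum to 1 per platform whenever any
    point qualifies (NaN rows otherwise).
    """
    if subset_rule not in ("single_platform", "all_platforms"):
        raise ValueError(f"unknown subset_rule {subset_rule!r}")
    det = cube.to_numpy(bool)
    pct = percentiles.reindex(cube.index).to_numpy(float)
    n_det = det.sum(axis=1)
    rows = {}
    for j, platform in enumerate(cube.columns):
        if subset_rule == "single_platform":
            mask = det[:, j] & (n_det == 1)
        else:
            mask = n_det == cube.shape[1]
        p = pct[mask, j]
        p = p[~np.isnan(p)]
        if len(p) == 0:
            rows[platform] = [float("nan")] * 5
            continue
        bins = np.digitize(p, QUINTILE_EDGES, right=False)
        rows[platform] = [float(np.mean(bins == i)) for i in range(5)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(QUINTILE_LABELS))
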