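"""Detection cube assembly, consensus truth labels, sensitivity/specificity.

With no synthetic spike-in ground truth, "present" is defined by consensus:
a (miRNA, cell line) data point is a true positive when at least 3 of the 4
platforms detect it, and a true negative otherwise.  Only the concordant
panel — miRNAs targeted by every platform — enters the truth, so no platform
is penalized for targets it never assayed.  Sensitivity of a platform is the
fraction of true positives it detects; specificity the fraction of true
negatives it leaves undetected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import pandas as pd

from .tables import NormalizedProfile

__all__ = [
    "call_detection",
    "percentile_frame",
    "DetectionTruth",
    "define_truth",
    "sensitivity",
    "specificity",
]


def _cube_index(ids, cell_lines) -> pd.MultiIndex:
    return pd.MultiIndex.from_product(
        [list(ids), list(cell_lines)], names=["canonical_id", "cell_line"]
    )


def _assemble(profiles: Sequence[NormalizedProfile], column: str) -> pd.DataFrame:
    """Stack one profile column into a (id, cell line) x platform frame."""
    platforms: list[str] = []
    lines: list[str] = []
    for p in profiles:
        if p.platform not in platforms:
            platforms.append(p.platform)
        if p.cell_line not in lines:
            lines.append(p.cell_line)
    by_key = {(p.platform, p.cell_line): p for p in profiles}
    missing = [
        (pl, ln) for pl in platforms for ln in lines if (pl, ln) not in by_key
    ]
    if missing:
        raise ValueError(f"missing profile for platform/cell line: {missing}")
    all_ids = sorted(set().union(*(set(p.data.index) for p in profiles)))
    idx = _cube_index(all_ids, lines)
    out = pd.DataFrame(index=idx, columns=platforms, dtype=float)
    for (pl, ln), prof in by_key.items():
        col = prof.data[column].reindex(all_ids).astype(float)
        out.loc[(slice(None), ln), pl] = col.to_numpy()
    return out


def call_detection(profiles: Sequence[NormalizedProfile]) -> pd.DataFrame:
    """Boolean detection cube indexed (canonical_id, cell_line) x platform.

    A target absent from a platform's profile (outside its panel) is False
    for that platform; downstream statistics restrict to the relevant panel
    so absence is never counted against the platform.
    """
    cube = _assemble(profiles, "detected")
    return cube.fillna(0.0) > 0


def percentile_frame(profiles: Sequence[NormalizedProfile]) -> pd.DataFrame:
    """Percentile ranks aligned with the detection cube (NaN = undetected)."""
    return _assemble(profiles, "percentile").astype(float)


class RatioResult(NamedTuple):
    ratio: float
    detected: int
    total: int


@dataclass
class DetectionTruth:
    """Detection cube restricted to the concordant panel, plus truth labels.

    ``truth`` is a boolean Series over (canonical_id, cell_line): True for
    true-positive data points (detected by >= ``min_platforms`` platforms).
    """

    detection: pd.DataFrame
    truth: pd.Series
    restricted_ids: list[str]
    min_platforms: int

    @property
    def platforms(self) -> list[str]:
        return list(self.detection.columns)

    @property
    def n_points(self) -> int:
        return len(self.truth)

    @property
    def n_true_positive(self) -> int:
        return int(self.truth.sum())

    @property
    def n_true_negative(self) -> int:
        return int((~self.truth).sum())

    def to_frame(self) -> pd.DataFrame:
        out = self.detection.astype(int).copy()
        out["truth"] = self.truth.map({True: "true_positive", False: "true_negative"})
        return out


def define_truth(
    cube: pd.DataFrame,
    concordant_ids: Sequence[str],
    min_platforms: int = 3,
) -> DetectionTruth:
    """Label every concordant (miRNA, cell line) point true positive/negative.

    A point is a true positive when detected by at least ``min_platforms``
    of the platforms in the cube (3 of 4 by default); otherwise a true
    negative.  The number of data points is |concordant ids| x |cell lines|.
    """
    if cube.shape[1] < min_platforms:
        raise ValueError(
            f"cube has {cube.shape[1]} platforms < min_platforms={min_platforms}"
        )
    ids = sorted(concordant_ids)
    have = set(cube.index.get_level_values("canonical_id"))
    offenders = [i for i in ids if i not in have]
    if offenders:
        raise KeyError(f"concordant ids missing from cube: {offenders[:10]}")
    lines = list(dict.fromkeys(cube.index.get_level_values("cell_line")))
    restricted = cube.reindex(_cube_index(ids, lines)).astype(bool)
    truth = restricted.sum(axis=1) >= min_platforms
    return DetectionTruth(
        detection=restricted,
        truth=truth,
        restricted_ids=ids,
        min_platforms=min_platforms,
    )


def sensitivity(truth: DetectionTruth, platform: str) -> RatioResult:
    """Detected true positives / total true positives for one platform."""
    if platform not in truth.detection.columns:
        raise KeyError(f"unknown platform {platform!r}")
    total = truth.n_true_positive
    if total == 0:
        raise ValueError("sensitivity undefined: no true positives")
    detected = int(truth.detection.loc[truth.truth, platform].sum())
    return RatioResult(detected / total, detected, total)


def specificity(truth: DetectionTruth, platform: str) -> RatioResult:
    """Undetected true negatives / total true negatives for one platform."""
    if platform not in truth.detection.columns:
        raise KeyError(f"unknown platform {platform!r}")
    total = truth.n_true_negative
    if total == 0:
        raise ValueError("specificity undefined: no true negatives")
    undetected = int((~truth.detection.loc[~truth.truth, platform]).sum())
    return RatioResult(undetected / total, undetected, total)
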