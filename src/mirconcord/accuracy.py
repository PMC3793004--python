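"""Fold-change accuracy statistics between platform pairs.

Accuracy here is a platform's ability to report the same expression *change*
between two cell lines as another platform, not the same absolute level —
per-miRNA capture biases are fixed across samples on a platform and cancel
in the ratio.  Fold changes are computed per platform over every cell-line
pair, on miRNAs detected in both lines; platform pairs are then compared on
their shared records by Pearson correlation of log2 fold changes (with a
Fisher-z 95% interval), by percent sign agreement (up vs down), and by sign
agreement binned over expression percentile or fold-change magnitude.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import QUINTILE_EDGES, QUINTILE_LABELS
from .tables import NormalizedProfile

__all__ = [
    "fold_changes",
    "platform_fold_changes",
    "pearson_log2fc",
    "sign_agreement",
    "agreement_by_percentile",
    "agreement_by_magnitude",
    "MAGNITUDE_EDGES",
]

#: log2 bin edges ~ 1.5-fold, 2-fold and 3-fold changes.
MAGNITUDE_EDGES = (0.585, 1.0, 1.585)
MAGNITUDE_LABELS = ("<1.5-fold", "1.5-2-fold", "2-3-fold", ">=3-fold")


def _pair_label(line_pair: Sequence[str]) -> str:
    return f"{line_pair[0]}/{line_pair[1]}"


def fold_changes(
    profiles: Sequence[NormalizedProfile],
    platform: str,
    line_pair: Sequence[str],
) -> pd.DataFrame:
    """log2 fold changes of one platform between two cell lines.

    Records are restricted to miRNAs detected in *both* lines on this
    platform (no pseudo-counts for dropouts).  Columns: ``log2_fc`` =
    log2(linear_X / linear_Y) and ``base_percentile`` = mean percentile rank
    of the miRNA in the two lines.  Swapping the pair negates ``log2_fc``
    exactly.
    """
    x_name, y_name = line_pair
    by_line = {p.cell_line: p for p in profiles if p.platform == platform}
    for name in (x_name, y_name):
        if name not in by_line:
            raise KeyError(f"no profile for platform {platform!r}, cell line {name!r}")
    px, py = by_line[x_name].data, by_line[y_name].data
    ids = px.index.intersection(py.index)
    px, py = px.loc[ids], py.loc[ids]
    both = px["detected"].to_numpy(bool) & py["detected"].to_numpy(bool)
    lx = px.loc[both, "linear"].to_numpy(float)
    ly = py.loc[both, "linear"].to_numpy(float)
    if np.any(lx <= 0) or np.any(ly <= 0):
        bad = ids[both][(lx <= 0) | (ly <= 0)]
        raise ValueError(
            f"detected target(s) with non-positive linear value: {list(bad[:5])}"
        )
    return pd.DataFrame(
        {
            "log2_fc": np.log2(lx / ly),
            "base_percentile": (
                px.loc[both, "percentile"].to_numpy(float)
                + py.loc[both, "percentile"].to_numpy(float)
            )
            / 2.0,
        },
        index=ids[both],
    )


def platform_fold_changes(
    profiles: Sequence[NormalizedProfile],
    platform: str,
    line_pairs: Sequence[Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Fold-change records over all cell-line pairs, MultiIndexed by
    (canonical_id, line_pair)."""
    if line_pairs is None:
        lines = list(dict.fromkeys(p.cell_line for p in profiles if p.platform == platform))
        line_pairs = list(combinations(lines, 2))
    parts = []
    for pair in line_pairs:
        fc = fold_changes(profiles, platform, pair)
        fc.index = pd.MultiIndex.from_arrays(
            [fc.index, [_pair_label(pair)] * len(fc)],
            names=["canonical_id", "line_pair"],
        )
        parts.append(fc)
    return pd.concat(parts) if parts else pd.DataFrame(
        columns=["log2_fc", "base_percentile"]
    )


class PearsonResult(NamedTuple):
    r: float
    ci95: tuple[float, float]
    p_value: float
    n: int


def _shared(records_a: pd.DataFrame, records_b: pd.DataFrame):
    ids = records_a.index.intersection(records_b.index)
    return records_a.loc[ids], records_b.loc[ids]


def pearson_log2fc(records_a: pd.DataFrame, records_b: pd.DataFrame) -> PearsonResult:
    """Pearson R of two platforms' log2 fold changes on shared records.

    The 95% confidence interval uses the Fisher z transform; the p-value is
    two-sided.  Requires at least 3 shared records.
    """
    a, b = _shared(records_a, records_b)
    n = len(a)
    if n < 3:
        raise ValueError(f"need >= 3 shared records, got {n}")
    res = stats.pearsonr(a["log2_fc"].to_numpy(), b["log2_fc"].to_numpy())
    ci = res.confidence_interval(0.95)
    return PearsonResult(
        r=float(res.statistic),
        ci95=(float(ci.low), float(ci.high)),
        p_value=float(res.pvalue),
        n=n,
    )


def _signs_agree(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise sign agreement; a fold change of exactly 0 agrees with any."""
    sa, sb = np.sign(a), np.sign(b)
    return (sa == sb) | (sa == 0) | (sb == 0)


def sign_agreement(records_a: pd.DataFrame, records_b: pd.DataFrame) -> float:
    """Percent of shared records whose fold changes point the same way."""
    a, b = _shared(records_a, records_b)
    if len(a) == 0:
        raise ValueError("no shared records")
    agree = _signs_agree(a["log2_fc"].to_numpy(), b["log2_fc"].to_numpy())
    return 100.0 * float(np.mean(agree))


def agreement_by_percentile(
    records_a: pd.DataFrame, records_b: pd.DataFrame
) -> pd.Series:
    """Sign-agreement percent per expression quintile.

    Shared records are binned by the mean of the two platforms'
    ``base_percentile`` into quintiles; empty bins report NaN.
    """
    a, b = _shared(records_a, records_b)
    agree = _signs_agree(a["log2_fc"].to_numpy(), b["log2_fc"].to_numpy())
    base = (
        a["base_percentile"].to_numpy(float) + b["base_percentile"].to_numpy(float)
    ) / 2.0
    bins = np.digitize(base, QUINTILE_EDGES, right=False)
    vals = [
        100.0 * float(np.mean(agree[bins == i])) if np.any(bins == i) else float("nan")
        for i in range(5)
    ]
    return pd.Series(vals, index=list(QUINTILE_LABELS))


def agreement_by_magnitude(
    records: Mapping[str, pd.DataFrame],
    mode: str = "Paired",
    edges: Sequence[float] = MAGNITUDE_EDGES,
) -> pd.Series:
    """Sign-agreement percent binned by fold-change magnitude.

    ``Paired`` mode compares exactly two platforms: shared records are
    binned by the mean |log2 fc| of the two, agreement is same-sign between
    them.  ``AP`` ("all platforms") mode requires >= 3 platforms: records
    shared by all are binned by the mean |log2 fc| across platforms, and a
    record agrees when every platform shares the sign of the cross-platform
    mean fold change.  Default bin edges 0.585/1.0/1.585 log2 units separate
    <1.5-fold, 1.5-2-fold, 2-3-fold and >=3-fold changes.
    """
    frames = dict(records)
    if mode == "Paired":
        if len(frames) != 2:
            raise ValueError("Paired mode takes exactly 2 platforms")
    elif mode == "AP":
        if len(frames) < 3:
            raise ValueError("AP mode needs at least 3 platforms")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    idx = None
    for f in frames.values():
        idx = f.index if idx is None else idx.intersection(f.index)
    fc = np.column_stack([f.loc[idx, "log2_fc"].to_numpy(float) for f in frames.values()])

    mag = np.mean(np.abs(fc), axis=1)
    if mode == "Paired":
        agree = _signs_agree(fc[:, 0], fc[:, 1])
    else:
        mean_fc = np.mean(fc, axis=1)
        sm = np.sign(mean_fc)[:, None]
        s = np.sign(fc)
        agree = np.all((s == sm) | (s == 0) | (sm == 0), axis=1)

    edges = tuple(edges)
    labels = (
        list(MAGNITUDE_LABELS)
        if edges == MAGNITUDE_EDGES
        else [f"bin{i}" for i in range(len(edges) + 1)]
    )
    bins = np.digitize(mag, edges, right=False)
    vals = [
        100.0 * float(np.mean(agree[bins == i])) if np.any(bins == i) else float("nan")
        for i in range(len(edges) + 1)
    ]
    return pd.Series(vals, index=labels)
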