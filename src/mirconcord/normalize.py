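"""Per-technology pre-processing and the shared linear total-count scaling.

Each technology needs its own pre-processing before platforms can be
compared:

* hybridization probe counts get a per-sample technical factor from the six
  positive spike controls, then background subtraction at the negative-probe
  mean plus two standard deviations;
* RT-qPCR quantification cycles (Cq) are linearized as ``2**(cutoff - Cq)``
  with the detection cutoff (Cq 36 by default) as the zero baseline, so that
  a censored or missing Cq maps to abundance 0;
* sequencing read counts need no pre-processing.

All platforms then share a single normalization — linear total-count
scaling — which multiplies every sample so sample totals agree.  Because the
scaling (and any per-miRNA capture bias fixed across samples) is a global
multiplicative factor, fold changes between cell lines are unaffected by it;
this bias cancellation is what makes cross-platform fold-change comparison
meaningful at all.

Replicates are combined after scaling: a target is called detected when the
platform's detection rule passes in a strict majority of replicates, and its
reported linear value is the mean over replicates with failing replicates
contributing 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import (
    UNIT_CQ,
    UNIT_PROBE_COUNT,
    UNIT_READ_COUNT,
    MeasurementTable,
    NormalizedProfile,
)

__all__ = [
    "NormalizeConfig",
    "subtract_background",
    "spike_normalize",
    "cq_to_linear",
    "linear_to_cq",
    "total_count_scale",
    "normalize_platform",
    "percentile_ranks",
]

DEFAULT_CQ_CUTOFF = 36.0


@dataclass(frozen=True)
class NormalizeConfig:
    """Thresholds applied during normalization and detection.

    cq_cutoff : Cq at or above which a qPCR measurement counts as
        background ("not detected"); also the zero baseline of the
        linearization.
    min_reads : minimum raw annotated reads for a sequencing replicate to
        count as detecting a target.
    target_total : common per-sample total after scaling; the string
        ``"mean"`` uses the arithmetic mean of the sample totals, which
        preserves each platform's overall magnitude.
    """

    cq_cutoff: float = DEFAULT_CQ_CUTOFF
    min_reads: float = 1.0
    target_total: float | str = "mean"


def subtract_background(
    table: MeasurementTable,
) -> tuple[MeasurementTable, pd.Series]:
    """Background-correct a probe-count table.

    Per sample, the detection threshold is the mean of the negative probes
    plus two sample standard deviations (n-1 denominator); every value is
    replaced by ``max(0, value - threshold)``.  Values at or below the
    threshold therefore become 0 and are treated as not detected downstream.
    Returns the corrected table and the per-sample thresholds.
    """
    if table.unit_kind != UNIT_PROBE_COUNT:
        raise ValueError("background subtraction applies to probe_count tables")
    neg = table.negative_probes
    if len(neg) < 2:
        raise ValueError("need at least 2 negative probes to estimate background sd")
    thresholds = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)
    corrected = (table.values - thresholds).clip(lower=0.0)
    return table.with_values(corrected), thresholds


def spike_normalize(
    table: MeasurementTable,
) -> tuple[MeasurementTable, pd.Series]:
    """Apply the positive-spike technical normalization factor.

    Per sample the factor is (mean over samples of the spike-control sum) /
    (this sample's spike sum); target values *and* negative probes are
    multiplied by it, so later background correction sees the same scale.
    Returns the adjusted table and the per-sample factors.
    """
    if table.unit_kind != UNIT_PROBE_COUNT:
        raise ValueError("spike normalization applies to probe_count tables")
    sums = table.positive_spikes.sum(axis=0)
    zero = sums.index[sums == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero spike sum: {list(zero)}")
    factors = sums.mean() / sums
    return (
        table.with_values(
            table.values * factors,
            positive_spikes=table.positive_spikes * factors,
            negative_probes=table.negative_probes * factors,
        ),
        factors,
    )


def cq_to_linear(cq, cutoff: float = DEFAULT_CQ_CUTOFF):
    """Linearize Cq with the detection cutoff as zero baseline.

    Returns ``2**(cutoff - cq)``, or 0 when the Cq is missing or at/above
    the cutoff (one PCR cycle is one log2 unit, so the value is the
    abundance relative to the detection limit).  Accepts scalars or arrays.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    cq = np.asarray(cq, dtype=float)
    with np.errstate(over="ignore"):
        lin = np.where(np.isnan(cq) | (cq >= cutoff), 0.0, 2.0 ** (cutoff - cq))
    return lin if lin.ndim else float(lin)


def linear_to_cq(linear, cutoff: float = DEFAULT_CQ_CUTOFF):
    """Back-convert a linear abundance to the Cq scale.

    Exact inverse of :func:`cq_to_linear` below the cutoff; an abundance of
    0 maps to the cutoff itself, the not-detected sentinel.
    """
    linear = np.asarray(linear, dtype=float)
    if np.any(linear < 0):
        raise ValueError("linear abundance must be non-negative")
    with np.errstate(divide="ignore"):
        cq = np.where(linear == 0, cutoff, cutoff - np.log2(np.where(linear > 0, linear, 1.0)))
    return cq if cq.ndim else float(cq)


def total_count_scale(
    values: pd.DataFrame, target_total: float | str = "mean"
) -> tuple[pd.DataFrame, pd.Series]:
    """Linear total-count scaling: equalize per-sample totals.

    Every sample (column) is multiplied by ``target_total / sample_total``;
    with ``"mean"`` the target is the arithmetic mean of the sample totals.
    Within-sample ratios between targets are unchanged.  Returns the scaled
    frame and the per-sample factors.
    """
    totals = values.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total: {list(zero)}")
    target = float(totals.mean()) if isinstance(target_total, str) else float(target_total)
    factors = target / totals
    return values * factors, factors


def percentile_ranks(linear: pd.Series, detected: pd.Series) -> pd.Series:
    """Percentile rank in (0, 1] of each detected target; NaN otherwise.

    Ties get the average rank; the top-expressed target has rank 1.
    """
    det = detected.astype(bool)
    ranks = linear[det].rank(method="average") / int(det.sum()) if det.any() else pd.Series(dtype=float)
    return ranks.reindex(linear.index)


def _replicate_detection(table: MeasurementTable, config: NormalizeConfig) -> pd.DataFrame:
    """Per-replicate boolean detection on the raw (pre-scaling) values."""
    if table.unit_kind == UNIT_CQ:
        return table.values.notna() & (table.values < config.cq_cutoff)
    if table.unit_kind == UNIT_READ_COUNT:
        return table.values >= config.min_reads
    # probe_count: caller passes the background-corrected table
    return table.values > 0


def normalize_platform(
    table: MeasurementTable, config: NormalizeConfig | None = None
) -> list[NormalizedProfile]:
    """Run the full per-platform normalization, one profile per cell line.

    Pipeline per unit kind (the table must already be on canonical ids):

    * ``probe_count``: spike factor -> background subtraction -> scaling;
    * ``cq``: linearization at the cutoff -> scaling;
    * ``read_count``: scaling only.

    Detection is decided per replicate on the pre-scaling rule (Cq below
    cutoff; corrected probe count > 0; raw reads >= ``min_reads``) and a
    target is detected in a cell line when a strict majority of its
    replicates detect it.  Linear values are averaged over replicates with
    failing replicates entering as 0; an undetected target reports linear 0.
    """
    config = config or NormalizeConfig()
    meta: dict = {"platform": table.platform, "unit_kind": table.unit_kind}

    if table.unit_kind == UNIT_PROBE_COUNT:
        table, factors = spike_normalize(table)
        table, thresholds = subtract_background(table)
        meta["spike_factors"] = factors
        meta["background_thresholds"] = thresholds
        linear = table.values
    elif table.unit_kind == UNIT_CQ:
        linear = pd.DataFrame(
            cq_to_linear(table.values.to_numpy(), config.cq_cutoff),
            index=table.values.index,
            columns=table.values.columns,
        )
    else:
        linear = table.values.astype(float)

    det_rep = _replicate_detection(table, config)
    scaled, scale_factors = total_count_scale(linear, config.target_total)
    meta["scale_factors"] = scale_factors

    profiles = []
    for line in table.cell_lines:
        cols = table.replicate_columns(line)
        det_line = det_rep[cols]
        detected = det_line.sum(axis=1) * 2 > len(cols)  # strict majority
        rep_lin = scaled[cols].where(det_line, 0.0)
        lin = rep_lin.mean(axis=1).where(detected, 0.0)
        with np.errstate(divide="ignore"):
            log2 = np.log2(lin.where(lin > 0))
        if table.unit_kind == UNIT_CQ:
            log2 = (config.cq_cutoff - log2).fillna(config.cq_cutoff)
        data = pd.DataFrame(
            {
                "linear": lin,
                "log2": log2,
                "detected": detected,
                "percentile": percentile_ranks(lin, detected),
            }
        )
        profiles.append(
            NormalizedProfile(
                platform=table.platform, cell_line=line, data=data, meta=dict(meta)
            )
        )
    return profiles
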