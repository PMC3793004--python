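"""Seeded generator of ground-truth abundances and four-platform tables.

The generator emulates the statistical structure the concordance analysis
assumes: a shared set of mature miRNAs with log-normal baseline abundances;
a configurable fraction of differentially expressed miRNAs with per-cell-
line log2 effects; per-(miRNA, platform) capture biases fixed across cell
lines (the library-preparation bias that cancels in fold changes); per-
platform target panels with a known concordant intersection; and platform-
specific measurement processes:

* NGS-like: Poisson read counts at a given sequencing depth over relative
  abundances (optionally negative-binomial via gamma mixing, or exact
  expected counts for noise-free runs);
* qPCR-like: Cq = c0 - log2(abundance) plus Gaussian cycle noise, censored
  at the detection cutoff (emitted as missing);
* hybridization-like: linear gain times abundance plus additive Gaussian
  background, with positive spike controls scaled by a per-sample
  efficiency and negative probes carrying background only.

All randomness flows from a single seed per call; identical seed and
parameters give bit-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .refpanel import MiRNATarget, ReferencePanel
from .tables import (
    UNIT_CQ,
    UNIT_PROBE_COUNT,
    UNIT_READ_COUNT,
    MeasurementTable,
)

__all__ = [
    "SyntheticTruth",
    "generate_truth",
    "simulate_ngs",
    "simulate_qpcr",
    "simulate_hyb",
    "DEFAULT_PLATFORMS",
    "DEFAULT_SPIKE_LEVELS",
]

DEFAULT_PLATFORMS = ("ngs1", "ngs2", "qpcr", "hyb")

#: Geometric spike ladder (arbitrary count units).
DEFAULT_SPIKE_LEVELS = (32.0, 64.0, 128.0, 256.0, 512.0, 1024.0)

# Panel sizes proportional to a 1719-target reference with NGS covering all
# of it, a 722-target qPCR panel, a 631-target hybridization panel, and a
# 517-target all-platform intersection.
_PANEL_FRACTIONS = {"ngs": 1.0, "qpcr": 722 / 1719, "hyb": 631 / 1719}
_CONCORDANT_FRACTION = 517 / 1719


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated multi-platform experiment."""

    seed: int
    mirna_ids: list[str]
    cell_lines: list[str]
    baseline_log2: pd.Series
    de_spec: pd.DataFrame  # miRNA x cell line, log2 effect (0 = not DE)
    platform_bias_log2: pd.DataFrame  # miRNA x platform
    panels: dict[str, list[str]]
    params: dict = field(default_factory=dict)

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_lines(self) -> int:
        return len(self.cell_lines)

    @property
    def platforms(self) -> list[str]:
        return list(self.platform_bias_log2.columns)

    @property
    def de_ids(self) -> list[str]:
        mask = (self.de_spec != 0).any(axis=1)
        return list(self.de_spec.index[mask])

    def abundance_log2(self, cell_line: str) -> pd.Series:
        """True log2 abundance of every miRNA in one cell line (bias-free)."""
        return self.baseline_log2 + self.de_spec[cell_line]

    def true_log2_fc(self, line_x: str, line_y: str) -> pd.Series:
        """True log2 fold change between two lines: platform-independent."""
        return self.de_spec[line_x] - self.de_spec[line_y]

    def reference_panel(self) -> ReferencePanel:
        """The truth as a reference panel (ids are already canonical)."""
        targets = [MiRNATarget(i, (i,)) for i in self.mirna_ids]
        return ReferencePanel(targets, {p: set(v) for p, v in self.panels.items()})

    def to_tsv(self, path) -> None:
        out = pd.DataFrame({"baseline_log2": self.baseline_log2})
        for line in self.cell_lines:
            out[f"de_{line}"] = self.de_spec[line]
        for p in self.platforms:
            out[f"bias_{p}"] = self.platform_bias_log2[p]
        out.index.name = "canonical_id"
        out.to_csv(path, sep="\t")


def _derive_rng(seed: int, label: str) -> np.random.Generator:
    # crc32 gives a stable per-stream key (Python's str hash is salted per run)
    key = zlib.crc32(label.encode("utf-8")) % 2**31
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def generate_truth(
    n_mirna: int = 1719,
    n_lines: int = 4,
    de_fraction: float = 0.3,
    effect_range_log2: tuple[float, float] = (1.0, 4.0),
    bias_sd_log2: float = 0.5,
    baseline_mean_log2: float = 4.0,
    baseline_sd_log2: float = 4.0,
    platforms: Sequence[str] = DEFAULT_PLATFORMS,
    platform_kinds: dict[str, str] | None = None,
    panel_sizes: dict[str, int] | None = None,
    concordant_size: int | None = None,
    seed: int = 0,
) -> SyntheticTruth:
    """Draw ground-truth abundances, effects, biases and panels.

    Baselines are Normal(``baseline_mean_log2``, ``baseline_sd_log2``) on
    the log2 scale (a wide log-normal dynamic range, so low-tail miRNAs sit
    near each platform's detection limit).  Exactly
    ``round(de_fraction * n_mirna)`` miRNAs are differentially expressed,
    drawn without replacement; each DE miRNA gets an independent per-line
    effect with random sign and magnitude uniform on ``effect_range_log2``.
    Capture biases are Normal(0, ``bias_sd_log2``) per (miRNA, platform),
    identical across cell lines.

    Default panels mirror a four-platform study: the NGS-like platforms
    target the full reference while qPCR-like and hybridization-like panels
    are proportional subsets built so the all-platform intersection has a
    known size (517/1719 of the reference by default).
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must be in [0, 1]")
    lo, hi = effect_range_log2
    if not (0 < lo <= hi):
        raise ValueError("effect_range_log2 must be a positive interval")
    if bias_sd_log2 < 0:
        raise ValueError("bias_sd_log2 must be non-negative")

    platforms = list(platforms)
    kinds = platform_kinds or {
        p: ("qpcr" if "qpcr" in p else "hyb" if "hyb" in p else "ngs")
        for p in platforms
    }
    rng = _derive_rng(seed, "truth")
    width = max(4, len(str(n_mirna)))
    ids = [f"mir-{i:0{width}d}" for i in range(1, n_mirna + 1)]
    lines = [f"line{chr(ord('A') + i)}" for i in range(n_lines)]

    baseline = pd.Series(
        rng.normal(baseline_mean_log2, baseline_sd_log2, n_mirna), index=ids
    )
    n_de = int(round(de_fraction * n_mirna))
    de_idx = rng.choice(n_mirna, size=n_de, replace=False)
    de = pd.DataFrame(0.0, index=ids, columns=lines)
    for line in lines:
        mag = rng.uniform(lo, hi, n_de)
        sign = rng.choice([-1.0, 1.0], n_de)
        de.iloc[de_idx, de.columns.get_loc(line)] = sign * mag
    bias = pd.DataFrame(
        rng.normal(0.0, bias_sd_log2, (n_mirna, len(platforms))),
        index=ids,
        columns=platforms,
    )

    if panel_sizes is None:
        panel_sizes = {
            p: int(round(_PANEL_FRACTIONS[kinds[p]] * n_mirna)) for p in platforms
        }
    if concordant_size is None:
        concordant_size = int(round(_CONCORDANT_FRACTION * n_mirna))
    panels = _draw_panels(ids, platforms, panel_sizes, concordant_size, rng)

    return SyntheticTruth(
        seed=seed,
        mirna_ids=ids,
        cell_lines=lines,
        baseline_log2=baseline,
        de_spec=de,
        platform_bias_log2=bias,
        panels=panels,
        params={
            "de_fraction": de_fraction,
            "effect_range_log2": (lo, hi),
            "bias_sd_log2": bias_sd_log2,
            "baseline_mean_log2": baseline_mean_log2,
            "baseline_sd_log2": baseline_sd_log2,
            "platform_kinds": kinds,
        },
    )


def _draw_panels(
    ids: list[str],
    platforms: list[str],
    panel_sizes: dict[str, int],
    concordant_size: int,
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """Panels with the requested sizes and all-platform intersection.

    The concordant core is shared by every platform; each platform's extra
    targets are drawn from the remainder, disjoint across the sub-reference
    platforms so the intersection stays exactly the core (platforms
    targeting the full reference take everything).
    """
    n = len(ids)
    for p in platforms:
        if not 0 < panel_sizes[p] <= n:
            raise ValueError(f"panel size for {p!r} out of range")
    if concordant_size > min(panel_sizes.values()):
        raise ValueError("concordant size exceeds smallest panel")
    partial = [p for p in platforms if panel_sizes[p] < n]
    extra_needed = sum(panel_sizes[p] - concordant_size for p in partial)
    if concordant_size + extra_needed > n:
        raise ValueError("panel sizes and concordant size exceed the reference")
    perm = [ids[i] for i in rng.permutation(n)]
    core = perm[:concordant_size]
    cursor = concordant_size
    panels: dict[str, list[str]] = {}
    for p in platforms:
        if panel_sizes[p] == n:
            panels[p] = sorted(ids)
        else:
            extra = perm[cursor : cursor + panel_sizes[p] - concordant_size]
            cursor += len(extra)
            panels[p] = sorted(core + extra)
    return panels


def _sample_columns(lines: Sequence[str], n_replicates: int) -> list[str]:
    return [f"{line}.{r + 1}" for line in lines for r in range(n_replicates)]


def simulate_ngs(
    truth: SyntheticTruth,
    platform: str,
    depth: float = 2e7,
    n_replicates: int = 2,
    seed: int = 0,
    dispersion: float = 0.0,
    sampling: str = "poisson",
) -> MeasurementTable:
    """Sequencing-like read-count table for one platform.

    Per replicate, counts are Poisson(depth * relative abundance * bias)
    over the platform's panel, so the expected total equals ``depth``.  A
    positive ``dispersion`` switches to negative binomial via gamma mixing
    (variance = mean + dispersion * mean^2) for biological overdispersion;
    ``sampling="expected"`` emits the exact expected counts (noise-free).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if platform not in truth.panels:
        raise KeyError(f"platform {platform!r} has no panel in the truth")
    if sampling not in ("poisson", "expected"):
        raise ValueError(f"unknown sampling {sampling!r}")
    rng = _derive_rng(seed, f"ngs:{platform}")
    panel = truth.panels[platform]
    bias = truth.platform_bias_log2.loc[panel, platform]
    cols = _sample_columns(truth.cell_lines, n_replicates)
    out = pd.DataFrame(index=pd.Index(panel, name="id"), columns=cols, dtype=float)
    for line in truth.cell_lines:
        lam_rel = 2.0 ** (truth.abundance_log2(line).loc[panel] + bias)
        p = lam_rel / lam_rel.sum()
        lam = (depth * p).to_numpy()
        for r in range(n_replicates):
            if sampling == "expected":
                counts = lam
            else:
                rate = lam
                if dispersion > 0:
                    rate = rng.gamma(1.0 / dispersion, dispersion * lam)
                counts = rng.poisson(rate).astype(float)
            out[f"{line}.{r + 1}"] = counts
    return MeasurementTable(platform=platform, unit_kind=UNIT_READ_COUNT, values=out)


def simulate_qpcr(
    truth: SyntheticTruth,
    platform: str,
    c0: float = 30.0,
    noise_sd: float = 0.25,
    cutoff: float = 36.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> MeasurementTable:
    """qPCR-like Cq table: Cq = c0 - log2 abundance + noise, censored.

    ``c0`` is the cycle at which a unit-abundance (log2 = 0) target
    amplifies; one abundance doubling lowers Cq by one cycle.  Cq values at
    or above ``cutoff`` are emitted as missing (censored), matching the
    assay's background rule.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if platform not in truth.panels:
        raise KeyError(f"platform {platform!r} has no panel in the truth")
    rng = _derive_rng(seed, f"qpcr:{platform}")
    panel = truth.panels[platform]
    bias = truth.platform_bias_log2.loc[panel, platform]
    cols = _sample_columns(truth.cell_lines, n_replicates)
    out = pd.DataFrame(index=pd.Index(panel, name="id"), columns=cols, dtype=float)
    for line in truth.cell_lines:
        clean = c0 - (truth.abundance_log2(line).loc[panel] + bias)
        for r in range(n_replicates):
            cq = clean + rng.normal(0.0, noise_sd, len(panel)) if noise_sd > 0 else clean.copy()
            cq = cq.to_numpy(float) if isinstance(cq, pd.Series) else cq
            cq[cq >= cutoff] = np.nan
            # keep Cq physical (positive); extremely abundant targets clip at cycle 1
            out[f"{line}.{r + 1}"] = np.clip(cq, 1.0, None)
    return MeasurementTable(platform=platform, unit_kind=UNIT_CQ, values=out)


def simulate_hyb(
    truth: SyntheticTruth,
    platform: str,
    gain: float = 2.0,
    bg_mean: float = 20.0,
    bg_sd: float = 10.0,
    spike_levels: Sequence[float] = DEFAULT_SPIKE_LEVELS,
    n_replicates: int = 3,
    efficiency_sd: float = 0.15,
    seed: int = 0,
) -> MeasurementTable:
    """Hybridization-like probe-count table with spike and negative controls.

    Target counts are ``efficiency * gain * abundance * bias`` plus additive
    Gaussian background (mean ``bg_mean``, sd ``bg_sd``), floored at 0.  The
    six positive spikes are ``spike_levels`` times the per-sample efficiency
    (drawn log-normal around 1 with sd ``efficiency_sd``); the eight
    negative probes carry background only.
    """
    if gain < 0:
        raise ValueError("gain must be non-negative")
    if bg_mean < 0 or bg_sd < 0:
        raise ValueError("background parameters must be non-negative")
    if len(spike_levels) != 6:
        raise ValueError("expected 6 spike levels")
    if platform not in truth.panels:
        raise KeyError(f"platform {platform!r} has no panel in the truth")
    rng = _derive_rng(seed, f"hyb:{platform}")
    panel = truth.panels[platform]
    bias = truth.platform_bias_log2.loc[panel, platform]
    cols = _sample_columns(truth.cell_lines, n_replicates)
    values = pd.DataFrame(index=pd.Index(panel, name="id"), columns=cols, dtype=float)
    spikes = pd.DataFrame(index=range(6), columns=cols, dtype=float)
    negatives = pd.DataFrame(index=range(8), columns=cols, dtype=float)
    for line in truth.cell_lines:
        signal = gain * 2.0 ** (truth.abundance_log2(line).loc[panel] + bias)
        for r in range(n_replicates):
            col = f"{line}.{r + 1}"
            eff = float(np.exp(rng.normal(0.0, efficiency_sd))) if efficiency_sd > 0 else 1.0
            noise_t = rng.normal(0.0, bg_sd, len(panel)) if bg_sd > 0 else 0.0
            values[col] = np.clip(eff * signal.to_numpy() + bg_mean + noise_t, 0.0, None)
            noise_n = rng.normal(0.0, bg_sd, 8) if bg_sd > 0 else np.zeros(8)
            negatives[col] = np.clip(bg_mean + noise_n, 0.0, None)
            spikes[col] = np.asarray(spike_levels, dtype=float) * eff
    return MeasurementTable(
        platform=platform,
        unit_kind=UNIT_PROBE_COUNT,
        values=values,
        positive_spikes=spikes,
        negative_probes=negatives,
    )
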