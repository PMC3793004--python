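"""Measurement and profile containers shared by every pipeline stage.

A :class:`MeasurementTable` holds the raw per-target output of one profiling
platform: annotated read counts for sequencing, quantification cycles (Cq)
for RT-qPCR, or probe counts for a hybridization assay.  Columns are samples
(one cell line x replicate each); rows are assay targets.  Hybridization
tables additionally carry the assay's control records: positive spike probes
(a known input ladder, used for a technical normalization factor) and
negative probes (no target, used to estimate background hybridization).

A :class:`NormalizedProfile` is the per-(platform, cell line) result of the
normalization stage: linear abundance on a common scale, its log2
representation, a detection flag, and the expression percentile rank of each
detected target within the profile.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Recognised measurement unit kinds.
UNIT_READ_COUNT = "read_count"
UNIT_CQ = "cq"
UNIT_PROBE_COUNT = "probe_count"
UNIT_KINDS = (UNIT_READ_COUNT, UNIT_CQ, UNIT_PROBE_COUNT)

#: Row-id prefixes marking control records in probe-count TSV files.
POS_PREFIX = "POS_"
NEG_PREFIX = "NEG_"


@dataclass(frozen=True)
class Sample:
    """One measured sample: a cell line and a replicate index (1-based)."""

    cell_line: str
    replicate: int

    @property
    def label(self) -> str:
        return f"{self.cell_line}.{self.replicate}"

    @classmethod
    def from_label(cls, label: str) -> "Sample":
        line, _, rep = label.rpartition(".")
        if not line:
            raise ValueError(f"sample column {label!r} is not 'cellline.replicate'")
        return cls(line, int(rep))


@dataclass
class MeasurementTable:
    """Raw per-target measurements for one platform.

    Parameters
    ----------
    platform : str
        Platform name; used as a key throughout the pipeline.
    unit_kind : str
        One of ``read_count``, ``cq``, ``probe_count``.
    values : pandas.DataFrame
        Targets x samples.  Column labels are ``cellline.replicate``.
        Counts are non-negative; Cq values are positive or missing (NaN);
        a missing Cq is never encoded as 0.
    positive_spikes, negative_probes : pandas.DataFrame, optional
        Control matrices for ``probe_count`` tables only, with the same
        sample columns as ``values``.
    """

    platform: str
    unit_kind: str
    values: pd.DataFrame
    positive_spikes: pd.DataFrame | None = None
    negative_probes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.unit_kind not in UNIT_KINDS:
            raise ValueError(f"unknown unit_kind {self.unit_kind!r}")
        vals = self.values.to_numpy(dtype=float)
        if self.unit_kind == UNIT_CQ:
            if np.any(vals[~np.isnan(vals)] <= 0):
                raise ValueError("Cq values must be positive or missing (NaN)")
        else:
            if np.any(np.isnan(vals)):
                raise ValueError(f"{self.unit_kind} values must not be missing")
            if np.any(vals < 0):
                raise ValueError(f"{self.unit_kind} values must be non-negative")
        if self.unit_kind == UNIT_PROBE_COUNT:
            for name, ctrl in (
                ("positive_spikes", self.positive_spikes),
                ("negative_probes", self.negative_probes),
            ):
                if ctrl is None:
                    raise ValueError(f"probe_count table requires {name}")
                if list(ctrl.columns) != list(self.values.columns):
                    raise ValueError(f"{name} columns differ from value columns")
        elif self.positive_spikes is not None or self.negative_probes is not None:
            raise ValueError("control matrices only belong to probe_count tables")

    # -- sample bookkeeping -------------------------------------------------

    @property
    def samples(self) -> list[Sample]:
        return [Sample.from_label(c) for c in self.values.columns]

    @property
    def cell_lines(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.cell_line, None)
        return list(seen)

    def replicate_columns(self, cell_line: str) -> list[str]:
        return [c for c in self.values.columns if Sample.from_label(c).cell_line == cell_line]

    def with_values(
        self,
        values: pd.DataFrame,
        positive_spikes: pd.DataFrame | None = None,
        negative_probes: pd.DataFrame | None = None,
    ) -> "MeasurementTable":
        """Copy of this table with replaced matrices (controls kept if not given)."""
        return MeasurementTable(
            platform=self.platform,
            unit_kind=self.unit_kind,
            values=values,
            positive_spikes=(
                positive_spikes if positive_spikes is not None else self.positive_spikes
            ),
            negative_probes=(
                negative_probes if negative_probes is not None else self.negative_probes
            ),
        )

    # -- TSV round trip -----------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write the table (controls inlined with POS_/NEG_ id prefixes)."""
        frames = [self.values]
        if self.unit_kind == UNIT_PROBE_COUNT:
            pos = self.positive_spikes.copy()
            pos.index = [f"{POS_PREFIX}{i + 1}" for i in range(len(pos))]
            neg = self.negative_probes.copy()
            neg.index = [f"{NEG_PREFIX}{i + 1}" for i in range(len(neg))]
            frames += [pos, neg]
        out = pd.concat(frames)
        out.index.name = "id"
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path, platform: str, unit_kind: str) -> "MeasurementTable":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        df.index = df.index.astype(str)
        is_pos = df.index.str.startswith(POS_PREFIX)
        is_neg = df.index.str.startswith(NEG_PREFIX)
        body = df.loc[~(is_pos | is_neg)]
        kwargs = {}
        if unit_kind == UNIT_PROBE_COUNT:
            kwargs = {
                "positive_spikes": df.loc[is_pos],
                "negative_probes": df.loc[is_neg],
            }
        return cls(platform=platform, unit_kind=unit_kind, values=body, **kwargs)


@dataclass
class NormalizedProfile:
    """Normalized expression profile for one (platform, cell line).

    ``data`` is indexed by canonical miRNA id with columns:

    ``linear``
        Normalized abundance on the linear scale (0 when not detected).
    ``log2``
        log2 of the linear value; for Cq platforms the back-converted
        normalized Cq (``cutoff - log2(linear)``) so the column stays in
        cycle units.  NaN (or the Cq cutoff sentinel) when not detected.
    ``detected``
        Boolean platform detection call for this cell line.
    ``percentile``
        Rank of the linear value among detected targets, average rank for
        ties, scaled into (0, 1].  NaN when not detected.
    """

    platform: str
    cell_line: str
    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {"linear", "log2", "detected", "percentile"} - set(self.data.columns)
        if missing:
            raise ValueError(f"profile data missing columns {sorted(missing)}")
        det = self.data["detected"].to_numpy(dtype=bool)
        if np.any(self.data.loc[~det, "linear"].to_numpy() != 0):
            raise ValueError("undetected targets must have linear value 0")

    @property
    def detected_ids(self) -> pd.Index:
        return self.data.index[self.data["detected"].to_numpy(dtype=bool)]


def profiles_to_frame(profiles: list[NormalizedProfile]) -> pd.DataFrame:
    """Long-format view of profiles (one row per platform/cell line/target)."""
    rows = []
    for p in profiles:
        d = p.data.copy()
        d.insert(0, "platform", p.platform)
        d.insert(1, "cell_line", p.cell_line)
        d.index.name = "canonical_id"
        rows.append(d.reset_index())
    return pd.concat(rows, ignore_index=True)


def profiles_to_tsv(profiles: list[NormalizedProfile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False, na_rep="NA")


def profiles_from_tsv(path) -> list[NormalizedProfile]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    out = []
    for (platform, line), grp in df.groupby(["platform", "cell_line"], sort=False):
        data = grp.set_index("canonical_id")[["linear", "log2", "detected", "percentile"]]
        data["detected"] = data["detected"].astype(bool)
        out.append(NormalizedProfile(platform=str(platform), cell_line=str(line), data=data))
    return out


def read_tsv_text(text: str, **kwargs) -> pd.DataFrame:
    """Parse a TSV string (convenience used by tests and docs)."""
    return pd.read_csv(io.StringIO(text), sep="\t", **kwargs)
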