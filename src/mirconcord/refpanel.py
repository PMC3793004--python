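"""Harmonized mature-miRNA reference panels.

Different profiling platforms address overlapping but unequal sets of mature
miRNAs, under assay ids that need not match.  This module builds a single
harmonized reference in which

* targets with an identical mature sequence (same ~22 nt product from
  different genomic loci) collapse into one canonical target, and
* targets a technology cannot tell apart (near-identical sequences probed by
  one assay) are merged by explicit merge groups supplied as input;

declares which canonical targets each platform's panel addresses; and
computes the *concordant* subset — the intersection targeted by every
platform — on which all cross-platform statistics are run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import UNIT_CQ, MeasurementTable

__all__ = [
    "MiRNATarget",
    "ReferencePanel",
    "merge_reference",
    "concordant_set",
    "map_assays",
    "collapse_assays",
]


@dataclass(frozen=True)
class MiRNATarget:
    """One canonical mature-miRNA target.

    ``member_ids`` lists every source id merged into this target; the
    canonical id is the lexicographically smallest member, which makes
    merging deterministic and reversible.  ``mature_sequence`` is kept only
    when all merged members share it.
    """

    canonical_id: str
    member_ids: tuple[str, ...]
    mature_sequence: str | None = None
    per_platform_assay: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError(f"target {self.canonical_id!r} has no members")
        if self.canonical_id not in self.member_ids:
            raise ValueError(
                f"canonical id {self.canonical_id!r} not among its members"
            )


class ReferencePanel:
    """A set of canonical targets plus per-platform targeted subsets."""

    def __init__(
        self,
        targets: Sequence[MiRNATarget],
        platform_panels: Mapping[str, Iterable[str]] | None = None,
    ) -> None:
        self.targets = list(targets)
        ids = [t.canonical_id for t in self.targets]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate canonical ids: {dupes}")
        self._canonical = set(ids)
        self.member_to_canonical: dict[str, str] = {}
        for t in self.targets:
            for m in t.member_ids:
                if m in self.member_to_canonical:
                    raise ValueError(f"member id {m!r} appears in two targets")
                self.member_to_canonical[m] = t.canonical_id
        self.platform_panels: dict[str, set[str]] = {}
        for platform, subset in (platform_panels or {}).items():
            subset = set(subset)
            extra = subset - self._canonical
            if extra:
                raise ValueError(
                    f"panel for {platform!r} lists unknown ids: {sorted(extra)[:5]}"
                )
            self.platform_panels[platform] = subset

    @property
    def canonical_ids(self) -> list[str]:
        return sorted(self._canonical)

    def __len__(self) -> int:
        return len(self.targets)

    def target(self, canonical_id: str) -> MiRNATarget:
        for t in self.targets:
            if t.canonical_id == canonical_id:
                return t
        raise KeyError(canonical_id)

    def concordant_set(self, platforms: Sequence[str] | None = None) -> list[str]:
        """Canonical ids targeted by every named platform, sorted.

        An empty intersection is legal but raises a warning, since every
        cross-platform statistic downstream would then be empty.
        """
        if platforms is None:
            platforms = list(self.platform_panels)
        if not platforms:
            raise ValueError("no platforms declared")
        for p in platforms:
            if p not in self.platform_panels:
                raise KeyError(f"unknown platform {p!r}")
        common = set.intersection(*(self.platform_panels[p] for p in platforms))
        if not common:
            warnings.warn(
                "concordant set is empty for platforms " + ", ".join(platforms),
                stacklevel=2,
            )
        return sorted(common)

    # -- TSV round trip -----------------------------------------------------

    def to_tsv(self, targets_path, panels_path=None) -> None:
        rows = [
            {
                "id": t.canonical_id,
                "mature_sequence": t.mature_sequence or "",
                "member_ids": ",".join(t.member_ids),
            }
            for t in self.targets
        ]
        pd.DataFrame(rows).to_csv(targets_path, sep="\t", index=False)
        if panels_path is not None:
            panel_rows = [
                {"platform": p, "canonical_id": cid}
                for p, ids in self.platform_panels.items()
                for cid in sorted(ids)
            ]
            pd.DataFrame(panel_rows, columns=["platform", "canonical_id"]).to_csv(
                panels_path, sep="\t", index=False
            )

    @classmethod
    def from_tsv(cls, targets_path, panels_path=None) -> "ReferencePanel":
        df = pd.read_csv(targets_path, sep="\t", dtype=str).fillna("")
        targets = [
            MiRNATarget(
                canonical_id=row["id"],
                member_ids=tuple(row.get("member_ids", "").split(","))
                if row.get("member_ids")
                else (row["id"],),
                mature_sequence=row.get("mature_sequence") or None,
            )
            for row in df.to_dict("records")
        ]
        panels = None
        if panels_path is not None:
            pdf = pd.read_csv(panels_path, sep="\t", dtype=str)
            panels = {
                p: set(grp["canonical_id"]) for p, grp in pdf.groupby("platform")
            }
        return cls(targets, panels)


class _UnionFind:
    def __init__(self, items: Iterable[str]) -> None:
        self.parent = {i: i for i in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def merge_reference(
    raw_targets: Sequence[tuple[str, str | None]],
    merge_groups: Sequence[Iterable[str]] = (),
) -> list[MiRNATarget]:
    """Collapse raw reference entries into canonical targets.

    Targets with an identical (non-missing) mature sequence are merged, and
    every explicit merge group (ids a platform cannot distinguish) collapses
    into one canonical target whose members are the union.  Overlapping
    groups merge transitively — {1,2} and {2,3} yield one target {1,2,3}.
    The canonical id of a merged target is its lexicographically smallest
    member.  Applying the operation to its own output is the identity.
    """
    ids = [i for i, _ in raw_targets]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate raw target ids: {dupes}")
    seqs = dict(raw_targets)

    uf = _UnionFind(ids)
    by_seq: dict[str, str] = {}
    for i, seq in raw_targets:
        if seq is None or seq == "":
            continue
        if seq in by_seq:
            uf.union(by_seq[seq], i)
        else:
            by_seq[seq] = i
    for group in merge_groups:
        group = list(group)
        for g in group:
            if g not in seqs:
                raise KeyError(f"merge group names unknown id {g!r}")
        for g in group[1:]:
            uf.union(group[0], g)

    members: dict[str, list[str]] = {}
    for i in ids:
        members.setdefault(uf.find(i), []).append(i)

    targets = []
    for root, mem in sorted(members.items()):
        mem = tuple(sorted(mem))
        mseqs = {seqs[m] for m in mem if seqs[m]}
        targets.append(
            MiRNATarget(
                canonical_id=mem[0],
                member_ids=mem,
                mature_sequence=mseqs.pop() if len(mseqs) == 1 else None,
            )
        )
    return targets


def concordant_set(panel: ReferencePanel, platforms: Sequence[str]) -> list[str]:
    """Functional alias for :meth:`ReferencePanel.concordant_set`."""
    return panel.concordant_set(platforms)


def map_assays(
    platform_table_ids: Sequence[str],
    panel: ReferencePanel,
    platform: str | None = None,
) -> tuple[dict[str, str], list[str]]:
    """Map platform assay ids onto canonical ids.

    Returns ``(mapping, discarded)`` where ``discarded`` lists the assay ids
    absent from the reference (obsolete entries), in input order.  Every
    input id lands in exactly one of the two; nothing is silently dropped.
    Two assay ids may map to one canonical id when their targets were
    merged; downstream values are then combined by :func:`collapse_assays`.
    """
    if platform is not None and panel.platform_panels and platform not in panel.platform_panels:
        raise KeyError(f"unknown platform {platform!r}")
    mapping: dict[str, str] = {}
    discarded: list[str] = []
    for aid in platform_table_ids:
        cid = panel.member_to_canonical.get(aid)
        if cid is None:
            discarded.append(aid)
        else:
            mapping[aid] = cid
    return mapping, discarded


def collapse_assays(
    table: MeasurementTable, panel: ReferencePanel
) -> tuple[MeasurementTable, list[str]]:
    """Re-index a raw table onto canonical ids, combining merged assays.

    Rows whose assay ids map to the same canonical target are combined:
    counts (read or probe) are summed, Cq values take the row minimum
    (the strongest signal), so total signal and detection status survive the
    merge.  Unmapped assay ids are dropped from the table and returned as
    the discard list.
    """
    mapping, discarded = map_assays(list(table.values.index), panel, table.platform)
    kept = table.values.loc[list(mapping)]
    canon = kept.rename(index=mapping)
    if table.unit_kind == UNIT_CQ:
        combined = canon.groupby(level=0).min()
    else:
        combined = canon.groupby(level=0).sum()
    combined = combined.sort_index()
    if table.unit_kind == UNIT_CQ:
        # all-missing groups must stay missing, not become 0
        all_na = canon.isna().groupby(level=0).all()
        combined = combined.mask(all_na.loc[combined.index], np.nan)
    return table.with_values(combined), discarded
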