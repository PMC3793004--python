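"""End-to-end pipeline: configuration, stage composition, report assembly.

A :class:`RunConfig` declares the platforms (each backed by an input table
on disk or a simulation block), the detection thresholds and the seed;
:func:`run` executes reference building, normalization, detection, pairwise
detection concordance and fold-change accuracy, and writes a set of TSV
reports plus one machine-readable JSON summary that contains every number
in the human-readable tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import accuracy, concordance, detect, normalize, synthdata
from .refpanel import ReferencePanel, collapse_assays
from .tables import (
    MeasurementTable,
    NormalizedProfile,
    profiles_to_tsv,
)

__all__ = [
    "PlatformConfig",
    "RunConfig",
    "demo_scenario",
    "simulate_tables",
    "run",
    "panel_summary",
]

log = logging.getLogger("mirconcord")

SUMMARY_SCHEMA_VERSION = 1

_SIM_KIND_TO_UNIT = {"ngs": "read_count", "qpcr": "cq", "hyb": "probe_count"}


@dataclass
class PlatformConfig:
    """One platform: either a table on disk or a simulation block."""

    name: str
    kind: str  # ngs | qpcr | hyb
    table_path: str | None = None
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _SIM_KIND_TO_UNIT:
            raise ValueError(f"unknown platform kind {self.kind!r}")

    @property
    def unit_kind(self) -> str:
        return _SIM_KIND_TO_UNIT[self.kind]


@dataclass
class RunConfig:
    """Full run configuration; round-trips through YAML unchanged."""

    platforms: list[PlatformConfig]
    seed: int = 0
    truth: dict = field(default_factory=dict)  # generate_truth kwargs
    cq_cutoff: float = 36.0
    min_reads: float = 1.0
    min_platforms: int = 3
    outdir: str | None = None
    reference_path: str | None = None
    panels_path: str | None = None

    def __post_init__(self) -> None:
        names = [p.name for p in self.platforms]
        if len(set(names)) != len(names):
            raise ValueError("platform names must be unique")
        for p in self.platforms:
            if p.table_path is None and not self.truth and not p.sim:
                raise ValueError(
                    f"platform {p.name!r} needs a table_path or a simulation block"
                )

    @property
    def platform_names(self) -> list[str]:
        return [p.name for p in self.platforms]

    def normalize_config(self) -> normalize.NormalizeConfig:
        return normalize.NormalizeConfig(
            cq_cutoff=self.cq_cutoff, min_reads=self.min_reads
        )

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "truth": dict(self.truth),
            "cq_cutoff": self.cq_cutoff,
            "min_reads": self.min_reads,
            "min_platforms": self.min_platforms,
            "outdir": self.outdir,
            "reference_path": self.reference_path,
            "panels_path": self.panels_path,
            "platforms": [
                {
                    "name": p.name,
                    "kind": p.kind,
                    "table_path": p.table_path,
                    "sim": dict(p.sim),
                }
                for p in self.platforms
            ],
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        platforms = [PlatformConfig(**p) for p in d.pop("platforms")]
        return cls(platforms=platforms, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def demo_scenario(
    n_mirna: int = 300,
    seed: int = 0,
    depth: float = 2e6,
    qpcr_noise_sd: float = 0.25,
    hyb_bg_mean: float = 20.0,
    hyb_bg_sd: float = 10.0,
    de_fraction: float = 0.3,
    noise_free: bool = False,
    **truth_kwargs,
) -> RunConfig:
    """A simulated four-platform scenario scaled down from the study design.

    Two NGS-like platforms target the full reference; a qPCR-like platform
    (Cq censoring at 36) and a hybridization-like platform (spike and
    negative controls) target proportional sub-panels with a known
    concordant intersection.  ``noise_free=True`` switches every stochastic
    measurement step off (expected NGS counts, zero Cq noise with an
    un-censorable baseline, zero hybridization background) for parameter-
    recovery checks.
    """
    truth = {
        "n_mirna": n_mirna,
        "de_fraction": de_fraction,
        **truth_kwargs,
    }
    if noise_free:
        truth.setdefault("baseline_mean_log2", 8.0)
        truth.setdefault("baseline_sd_log2", 2.0)
        truth.setdefault("bias_sd_log2", 0.0)
        truth.setdefault("panel_sizes", {p: n_mirna for p in synthdata.DEFAULT_PLATFORMS})
        truth.setdefault("concordant_size", n_mirna)
        sims = {
            "ngs1": {"depth": depth, "sampling": "expected"},
            "ngs2": {"depth": depth, "sampling": "expected"},
            "qpcr": {"noise_sd": 0.0, "c0": 25.0},
            "hyb": {"bg_mean": 0.0, "bg_sd": 0.0, "efficiency_sd": 0.15},
        }
    else:
        sims = {
            "ngs1": {"depth": depth},
            "ngs2": {"depth": depth},
            "qpcr": {"noise_sd": qpcr_noise_sd},
            "hyb": {"bg_mean": hyb_bg_mean, "bg_sd": hyb_bg_sd},
        }
    platforms = [
        PlatformConfig(name=name, kind=kind, sim=sims[name])
        for name, kind in zip(synthdata.DEFAULT_PLATFORMS, ("ngs", "ngs", "qpcr", "hyb"))
    ]
    return RunConfig(platforms=platforms, seed=seed, truth=truth)


def simulate_tables(
    config: RunConfig,
) -> tuple[synthdata.SyntheticTruth, dict[str, MeasurementTable]]:
    """Generate the ground truth and one measurement table per platform."""
    kinds = {p.name: p.kind for p in config.platforms}
    truth = synthdata.generate_truth(
        platforms=config.platform_names,
        platform_kinds=kinds,
        seed=config.seed,
        **config.truth,
    )
    tables = {}
    for p in config.platforms:
        sim = {k: v for k, v in p.sim.items()}
        sim.setdefault("seed", config.seed)
        if p.kind == "ngs":
            tables[p.name] = synthdata.simulate_ngs(truth, p.name, **sim)
        elif p.kind == "qpcr":
            sim.setdefault("cutoff", config.cq_cutoff)
            tables[p.name] = synthdata.simulate_qpcr(truth, p.name, **sim)
        else:
            tables[p.name] = synthdata.simulate_hyb(truth, p.name, **sim)
    return truth, tables


def panel_summary(panel: ReferencePanel, cube: pd.DataFrame) -> pd.DataFrame:
    """Per-platform screening summary (targeted / observed counts).

    ``observed`` counts targets detected in at least one cell line,
    ``observed_all_lines`` those detected in every line; percentages are of
    the platform's targeted panel and of the full reference, rounded to the
    nearest integer for reporting alongside the raw counts.
    """
    n_ref = len(panel)
    rows = []
    per_mirna_any = cube.groupby(level="canonical_id").any()
    per_mirna_all = cube.groupby(level="canonical_id").all()
    for platform in cube.columns:
        targeted = panel.platform_panels.get(platform, set(per_mirna_any.index))
        tlist = [t for t in per_mirna_any.index if t in targeted]
        observed = int(per_mirna_any.loc[tlist, platform].sum())
        observed_all = int(per_mirna_all.loc[tlist, platform].sum())
        rows.append(
            {
                "platform": platform,
                "targeted": len(targeted),
                "observed": observed,
                "observed_all_lines": observed_all,
                "pct_of_targeted": round(100.0 * observed / len(targeted)),
                "pct_of_reference": round(100.0 * observed / n_ref),
            }
        )
    return pd.DataFrame(rows).set_index("platform")


@dataclass
class RunResult:
    """Everything a pipeline run computed, plus the JSON-ready summary."""

    config: RunConfig
    panel: ReferencePanel
    truth_spec: synthdata.SyntheticTruth | None
    profiles: list[NormalizedProfile]
    cube: pd.DataFrame
    percentiles: pd.DataFrame
    detection_truth: detect.DetectionTruth
    pair_scores: dict[tuple[str, str], concordance.PairScore]
    summary: dict


def _load_table(p: PlatformConfig) -> MeasurementTable:
    return MeasurementTable.from_tsv(p.table_path, platform=p.name, unit_kind=p.unit_kind)


def run(config: RunConfig) -> RunResult:
    """Execute every stage and assemble reports.

    Stages: build/collect tables -> reference panel -> per-platform
    normalization -> detection cube and consensus truth -> per-platform
    sensitivity/specificity -> pairwise detection concordance (bucket
    counts, percent-both, weighted scores, Venn, quintile dispersion) ->
    fold-change accuracy for every platform pair (Pearson R with CI, sign
    agreement, percentile- and magnitude-binned agreement, all-platform
    mode).  When ``config.outdir`` is set, TSV reports and ``summary.json``
    are written there.
    """
    truth_spec = None
    simulated = any(not p.table_path for p in config.platforms)
    if simulated:
        truth_spec, tables = simulate_tables(config)
        panel = truth_spec.reference_panel()
    else:
        tables = {p.name: _load_table(p) for p in config.platforms}
        if config.reference_path:
            panel = ReferencePanel.from_tsv(config.reference_path, config.panels_path)
        else:
            # no external reference: table ids are taken as canonical
            from .refpanel import MiRNATarget

            ids = sorted(set().union(*(set(t.values.index) for t in tables.values())))
            panel = ReferencePanel(
                [MiRNATarget(i, (i,)) for i in ids],
                {name: set(t.values.index) for name, t in tables.items()},
            )

    ncfg = config.normalize_config()
    profiles: list[NormalizedProfile] = []
    discards: dict[str, list[str]] = {}
    for name, table in tables.items():
        mapped, discarded = collapse_assays(table, panel)
        discards[name] = discarded
        prof = normalize.normalize_platform(mapped, ncfg)
        profiles.extend(prof)
        log.info(
            "normalize %s: %d targets, %d samples, %d discarded assay ids",
            name, len(mapped.values), mapped.values.shape[1], len(discarded),
        )

    cube = detect.call_detection(profiles)
    percentiles = detect.percentile_frame(profiles)
    names = config.platform_names
    concordant = panel.concordant_set(names)
    dt = detect.define_truth(cube, concordant, config.min_platforms)
    log.info(
        "detect: %d concordant ids, %d data points, %d true positive",
        len(concordant), dt.n_points, dt.n_true_positive,
    )

    def _ratio_or_none(fn, p):
        try:
            return fn(dt, p)
        except ValueError:  # no true positives / negatives at all
            log.warning("%s undefined for %s", fn.__name__, p)
            return None

    sens = {p: _ratio_or_none(detect.sensitivity, p) for p in names}
    spec = {p: _ratio_or_none(detect.specificity, p) for p in names}

    pair_scores: dict[tuple[str, str], concordance.PairScore] = {}
    ccube, cpct = dt.detection, percentiles.reindex(dt.detection.index)
    for pair in combinations(names, 2):
        ps = concordance.pair_counts(ccube, pair)
        ps.weighted_score = concordance.weighted_pair_score(ccube, cpct, pair)
        pair_scores[pair] = ps
    venn = concordance.venn_counts(ccube, pooled=True)
    venn_points = concordance.venn_counts(ccube, pooled=False)
    quint_single = concordance.quintile_dispersion(ccube, cpct, "single_platform")
    quint_all = concordance.quintile_dispersion(ccube, cpct, "all_platforms")

    records = {p: accuracy.platform_fold_changes(profiles, p) for p in names}
    agreements = {}
    for pair in combinations(names, 2):
        a, b = pair
        try:
            pr = accuracy.pearson_log2fc(records[a], records[b])
        except ValueError:
            pr = None
        shared = records[a].index.intersection(records[b].index)
        agreements[pair] = {
            "n": int(len(shared)),
            "pearson_r": None if pr is None else pr.r,
            "ci95": None if pr is None else list(pr.ci95),
            "p_value": None if pr is None else pr.p_value,
            "sign_agreement_pct": (
                accuracy.sign_agreement(records[a], records[b]) if len(shared) else None
            ),
            "by_percentile": accuracy.agreement_by_percentile(
                records[a], records[b]
            ).to_dict()
            if len(shared)
            else None,
            "by_magnitude_paired": accuracy.agreement_by_magnitude(
                {a: records[a], b: records[b]}, mode="Paired"
            ).to_dict()
            if len(shared)
            else None,
        }
    ap = (
        accuracy.agreement_by_magnitude(records, mode="AP").to_dict()
        if len(names) >= 3
        else None
    )

    psum = panel_summary(panel, cube)

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "platforms": names,
        "thresholds": {
            "cq_cutoff": config.cq_cutoff,
            "min_reads": config.min_reads,
            "min_platforms": config.min_platforms,
        },
        "n_concordant": len(concordant),
        "n_data_points": dt.n_points,
        "n_true_positive": dt.n_true_positive,
        "n_true_negative": dt.n_true_negative,
        "pct_true_positive": round(100.0 * dt.n_true_positive / dt.n_points)
        if dt.n_points
        else None,
        "panel_summary": psum.reset_index().to_dict("records"),
        "discarded_assays": {k: len(v) for k, v in discards.items()},
        "sensitivity": {
            p: None
            if r is None
            else {"ratio": round(r.ratio, 3), "detected": r.detected, "total": r.total}
            for p, r in sens.items()
        },
        "specificity": {
            p: None
            if r is None
            else {"ratio": round(r.ratio, 3), "detected_tn": r.total - r.detected,
                  "undetected_tn": r.detected, "total": r.total}
            for p, r in spec.items()
        },
        "pairs": {
            "|".join(pair): {
                "counts": ps.counts,
                "n_single": ps.n_single,
                "n_both": ps.n_both,
                "percent_both": None
                if ps.percent_both is None
                else round(ps.percent_both),
                "weighted_score": None
                if ps.weighted_score is None or np.isnan(ps.weighted_score)
                else round(ps.weighted_score, 2),
            }
            for pair, ps in pair_scores.items()
        },
        "venn_pooled": {"|".join(k): v for k, v in venn.items()},
        "venn_points": {"|".join(k): v for k, v in venn_points.items()},
        "quintile_single_platform": quint_single.to_dict("index"),
        "quintile_all_platforms": quint_all.to_dict("index"),
        "accuracy": {"|".join(pair): vals for pair, vals in agreements.items()},
        "agreement_by_magnitude_ap": ap,
    }

    result = RunResult(
        config=config,
        panel=panel,
        truth_spec=truth_spec,
        profiles=profiles,
        cube=cube,
        percentiles=percentiles,
        detection_truth=dt,
        pair_scores=pair_scores,
        summary=summary,
    )
    if config.outdir:
        _write_reports(result, tables)
    return result


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_reports(result: RunResult, tables: dict[str, MeasurementTable]) -> None:
    out = Path(result.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        table.to_tsv(out / f"table_{name}.tsv")
    if result.truth_spec is not None:
        result.truth_spec.to_tsv(out / "truth.tsv")
    result.panel.to_tsv(out / "reference.tsv", out / "panels.tsv")
    profiles_to_tsv(result.profiles, out / "profiles.tsv")
    result.detection_truth.to_frame().to_csv(out / "detection.tsv", sep="\t")

    rows = []
    for pair, ps in result.pair_scores.items():
        row = {"pair": "|".join(pair), **ps.counts,
               "n_single": ps.n_single, "n_both": ps.n_both,
               "percent_both": None if ps.percent_both is None else round(ps.percent_both),
               "weighted_score": None if ps.weighted_score is None else round(ps.weighted_score, 2)}
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "pair_report.tsv", sep="\t", index=False)

    pd.DataFrame(
        [{"subset": k, "count": v} for k, v in result.summary["venn_pooled"].items()]
    ).to_csv(out / "venn.tsv", sep="\t", index=False)
    pd.DataFrame(result.summary["panel_summary"]).to_csv(
        out / "panel_summary.tsv", sep="\t", index=False
    )

    acc_rows = []
    for key, vals in result.summary["accuracy"].items():
        acc_rows.append({"pair": key, **{k: v for k, v in vals.items()
                                         if not isinstance(v, dict)}})
    pd.DataFrame(acc_rows).to_csv(out / "accuracy.tsv", sep="\t", index=False)

    (out / "summary.json").write_text(
        json.dumps(result.summary, indent=2, sort_keys=True, default=_json_default)
    )
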