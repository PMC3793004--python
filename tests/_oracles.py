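"""Brute-force reference implementations used only as test oracles.

Everything here iterates over data points one by one with plain Python,
independently of the vectorized library code it checks.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def truth_labels_loop(cube: pd.DataFrame, min_platforms: int) -> dict:
    out = {}
    for point in cube.index:
        n = sum(bool(cube.loc[point, p]) for p in cube.columns)
        out[point] = n >= min_platforms
    return out


def sensitivity_loop(cube: pd.DataFrame, platform: str, min_platforms: int) -> tuple[int, int]:
    labels = truth_labels_loop(cube, min_platforms)
    total = detected = 0
    for point, is_tp in labels.items():
        if is_tp:
            total += 1
            if bool(cube.loc[point, platform]):
                detected += 1
    return detected, total


def specificity_loop(cube: pd.DataFrame, platform: str, min_platforms: int) -> tuple[int, int]:
    labels = truth_labels_loop(cube, min_platforms)
    total = undetected = 0
    for point, is_tp in labels.items():
        if not is_tp:
            total += 1
            if not bool(cube.loc[point, platform]):
                undetected += 1
    return undetected, total


def pair_counts_loop(cube: pd.DataFrame, pair) -> dict[str, int]:
    a, b = pair
    others = [c for c in cube.columns if c not in (a, b)]
    counts: dict[str, int] = {}
    for sign in "+-":
        for k in range(len(others) + 1):
            counts[sign * (k + 1)] = 0
    for point in cube.index:
        da, db = bool(cube.loc[point, a]), bool(cube.loc[point, b])
        if not (da or db):
            continue
        k = sum(bool(cube.loc[point, o]) for o in others)
        sign = "+" if (da and db) else "-"
        counts[sign * (k + 1)] += 1
    return counts


def weighted_score_loop(cube: pd.DataFrame, percentiles: pd.DataFrame, pair) -> float:
    a, b = pair
    others = [c for c in cube.columns if c not in (a, b)]
    num = den = 0.0
    for point in cube.index:
        da, db = bool(cube.loc[point, a]), bool(cube.loc[point, b])
        if not (da or db):
            continue
        s = 1.0 if (da and db) else -1.0
        detecting = [c for c in cube.columns if bool(cube.loc[point, c])]
        p = sum(float(percentiles.loc[point, c]) for c in detecting) / len(detecting)
        k = sum(bool(cube.loc[point, o]) for o in others)
        w = p * (1 + k) / (1 + len(others))
        num += s * w
        den += w
    return num / den


def venn_loop(cube: pd.DataFrame, pooled: bool) -> dict[tuple, int]:
    frame = cube
    if pooled:
        ids = sorted(set(cube.index.get_level_values("canonical_id")))
        rows = {}
        for i in ids:
            sub = cube.xs(i, level="canonical_id")
            rows[i] = {p: bool(sub[p].any()) for p in cube.columns}
        frame = pd.DataFrame.from_dict(rows, orient="index")
    out: dict[tuple, int] = {}
    for point in frame.index:
        subset = tuple(p for p in frame.columns if bool(frame.loc[point, p]))
        if subset:
            out[subset] = out.get(subset, 0) + 1
    return out


def quintile_bin(p: float) -> int:
    for i, edge in enumerate((0.2, 0.4, 0.6, 0.8)):
        if p < edge:
            return i
    return 4


def quintile_loop(cube: pd.DataFrame, percentiles: pd.DataFrame, rule: str) -> dict:
    out = {}
    for platform in cube.columns:
        tally = [0] * 5
        total = 0
        for point in cube.index:
            det = [c for c in cube.columns if bool(cube.loc[point, c])]
            if rule == "single_platform":
                ok = det == [platform]
            else:
                ok = len(det) == len(cube.columns)
            if not ok:
                continue
            p = float(percentiles.loc[point, platform])
            if math.isnan(p):
                continue
            tally[quintile_bin(p)] += 1
            total += 1
        out[platform] = [t / total for t in tally] if total else [float("nan")] * 5
    return out


def signs_agree(x: float, y: float) -> bool:
    sx, sy = np.sign(x), np.sign(y)
    return sx == sy or sx == 0 or sy == 0


def sign_agreement_loop(rec_a: pd.DataFrame, rec_b: pd.DataFrame) -> float:
    shared = [i for i in rec_a.index if i in set(rec_b.index)]
    agree = sum(
        signs_agree(rec_a.loc[i, "log2_fc"], rec_b.loc[i, "log2_fc"]) for i in shared
    )
    return 100.0 * agree / len(shared)


def agreement_by_percentile_loop(rec_a: pd.DataFrame, rec_b: pd.DataFrame) -> list:
    shared = [i for i in rec_a.index if i in set(rec_b.index)]
    tall = [[0, 0] for _ in range(5)]
    for i in shared:
        base = (rec_a.loc[i, "base_percentile"] + rec_b.loc[i, "base_percentile"]) / 2
        b = quintile_bin(base)
        tall[b][1] += 1
        if signs_agree(rec_a.loc[i, "log2_fc"], rec_b.loc[i, "log2_fc"]):
            tall[b][0] += 1
    return [100.0 * a / n if n else float("nan") for a, n in tall]


def magnitude_bin(mag: float, edges=(0.585, 1.0, 1.585)) -> int:
    for i, edge in enumerate(edges):
        if mag < edge:
            return i
    return len(edges)


def agreement_by_magnitude_loop(records: dict[str, pd.DataFrame], mode: str) -> list:
    frames = list(records.values())
    shared = set(frames[0].index)
    for f in frames[1:]:
        shared &= set(f.index)
    tall = [[0, 0] for _ in range(4)]
    for i in sorted(shared):
        fcs = [float(f.loc[i, "log2_fc"]) for f in frames]
        mag = sum(abs(x) for x in fcs) / len(fcs)
        b = magnitude_bin(mag)
        tall[b][1] += 1
        if mode == "Paired":
            ok = signs_agree(fcs[0], fcs[1])
        else:
            m = sum(fcs) / len(fcs)
            ok = all(signs_agree(x, m) for x in fcs)
        if ok:
            tall[b][0] += 1
    return [100.0 * a / n if n else float("nan") for a, n in tall]
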