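from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirconcord import demo_scenario


def make_cube(
    seed: int,
    n_ids: int = 30,
    n_lines: int = 4,
    platforms: tuple[str, ...] = ("P1", "P2", "P3", "P4"),
    p_detect: float = 0.6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random detection cube plus consistent percentile ranks.

    Percentiles are real ranks of random expression values among the
    detected targets of each (platform, cell line), so they satisfy the
    profile invariants (in (0, 1], monotone in expression, NaN undetected).
    """
    rng = np.random.default_rng(seed)
    ids = [f"m{i:03d}" for i in range(n_ids)]
    lines = [f"L{j}" for j in range(n_lines)]
    idx = pd.MultiIndex.from_product([ids, lines], names=["canonical_id", "cell_line"])
    det = pd.DataFrame(
        rng.random((len(idx), len(platforms))) < p_detect,
        index=idx,
        columns=list(platforms),
    )
    expr = pd.DataFrame(
        rng.random((len(idx), len(platforms))), index=idx, columns=list(platforms)
    )
    pct = pd.DataFrame(np.nan, index=idx, columns=list(platforms))
    for platform in platforms:
        for line in lines:
            sel = idx.get_level_values("cell_line") == line
            d = det.loc[sel, platform]
            vals = expr.loc[sel, platform][d]
            if len(vals):
                ranks = vals.rank(method="average") / len(vals)
                pct.loc[ranks.index, platform] = ranks
    return det, pct


@pytest.fixture
def small_cube():
    return make_cube(seed=7)


@pytest.fixture(scope="session")
def noise_free_run():
    """End-to-end pipeline result on a noise-free, bias-free scenario."""
    from mirconcord import run

    return run(demo_scenario(n_mirna=150, seed=11, noise_free=True))


def fig4_scenario(seed: int):
    """Scenario contrasting matched-noise platforms with a hybridization
    platform whose additive background swamps low-expressed targets.

    Every miRNA carries a continuous per-line effect (no exact-zero fold
    changes, as between real cell lines); NGS depth keeps Poisson noise
    small everywhere, qPCR cycle noise is constant on the log2 scale.
    """
    cfg = demo_scenario(
        n_mirna=600,
        seed=seed,
        depth=1e7,
        qpcr_noise_sd=0.25,
        hyb_bg_mean=100.0,
        hyb_bg_sd=50.0,
        de_fraction=1.0,
        effect_range_log2=(0.25, 3.0),
        baseline_sd_log2=2.0,
        bias_sd_log2=0.3,
    )
    for p in cfg.platforms:
        if p.name == "hyb":
            p.sim["gain"] = 20.0
    return cfg
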