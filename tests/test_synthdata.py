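"""Ground-truth generator and the three platform simulators."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirconcord.detect import call_detection, define_truth, sensitivity
from mirconcord.normalize import normalize_platform, spike_normalize
from mirconcord.accuracy import fold_changes
from mirconcord.synthdata import (
    generate_truth,
    simulate_hyb,
    simulate_ngs,
    simulate_qpcr,
)


@pytest.fixture(scope="module")
def truth():
    return generate_truth(n_mirna=100, seed=42)


class TestGenerateTruth:
    def test_same_seed_is_bit_identical(self):
        a = generate_truth(n_mirna=80, seed=5)
        b = generate_truth(n_mirna=80, seed=5)
        pd.testing.assert_series_equal(a.baseline_log2, b.baseline_log2)
        pd.testing.assert_frame_equal(a.de_spec, b.de_spec)
        pd.testing.assert_frame_equal(a.platform_bias_log2, b.platform_bias_log2)
        assert a.panels == b.panels

    def test_de_fraction_zero_means_no_fold_changes(self):
        t = generate_truth(n_mirna=50, de_fraction=0.0, seed=1)
        assert (t.true_log2_fc("lineA", "lineB") == 0).all()

    def test_exact_de_count(self):
        t = generate_truth(n_mirna=1000, de_fraction=0.2, seed=2)
        assert len(t.de_ids) == 200

    def test_panel_sizes_and_intersection_scale_with_reference(self):
        t = generate_truth(n_mirna=1719, seed=0)
        sizes = {p: len(ids) for p, ids in t.panels.items()}
        assert sizes == {"ngs1": 1719, "ngs2": 1719, "qpcr": 722, "hyb": 631}
        concordant = set.intersection(*(set(v) for v in t.panels.values()))
        assert len(concordant) == 517

    def test_fold_change_is_platform_bias_free(self, truth):
        fc = truth.true_log2_fc("lineA", "lineC")
        pd.testing.assert_series_equal(
            fc, truth.de_spec["lineA"] - truth.de_spec["lineC"], check_names=False
        )

    @pytest.mark.parametrize(
        "kwargs", [{"de_fraction": 1.5}, {"effect_range_log2": (0.0, 2.0)},
                   {"effect_range_log2": (3.0, 1.0)}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_truth(n_mirna=10, seed=0, **kwargs)


class TestSimulateNgs:
    def test_deterministic_per_seed(self, truth):
        a = simulate_ngs(truth, "ngs1", depth=1e5, seed=3)
        b = simulate_ngs(truth, "ngs1", depth=1e5, seed=3)
        pd.testing.assert_frame_equal(a.values, b.values)
        c = simulate_ngs(truth, "ngs1", depth=1e5, seed=4)
        assert not a.values.equals(c.values)

    def test_total_reads_near_depth(self, truth):
        """Sum of Poisson(depth * p_m) is Poisson(depth): totals stay within
        a few sqrt(depth) of the depth (frozen seeds)."""
        depth = 1e5
        for seed in range(20):
            t = simulate_ngs(truth, "ngs1", depth=depth, n_replicates=1, seed=seed)
            totals = t.values.sum(axis=0).to_numpy()
            assert np.all(np.abs(totals - depth) < 4 * np.sqrt(depth))

    def test_expected_mode_is_exact(self, truth):
        t = simulate_ngs(truth, "ngs1", depth=1e6, sampling="expected", seed=0)
        np.testing.assert_allclose(t.values.sum(axis=0).to_numpy(), 1e6)
        # replicates identical: no sampling noise
        pd.testing.assert_series_equal(
            t.values["lineA.1"], t.values["lineA.2"], check_names=False
        )

    def test_dispersion_inflates_variance(self, truth):
        reps = 40
        lam = {}
        for disp in (0.0, 0.5):
            t = simulate_ngs(truth, "ngs1", depth=1e5, n_replicates=reps,
                             seed=7, dispersion=disp)
            cols = [f"lineA.{r + 1}" for r in range(reps)]
            lam[disp] = t.values[cols]
        top = lam[0.0].mean(axis=1).idxmax()
        assert lam[0.5].loc[top].var() > 2 * lam[0.0].loc[top].var()

    def test_matched_platforms_recover_large_effects(self):
        """Two equally parameterized NGS runs agree on the sign of every
        strong fold change at high depth."""
        t = generate_truth(n_mirna=150, de_fraction=0.4, effect_range_log2=(2.0, 4.0),
                           baseline_sd_log2=2.0, seed=9)
        prof = {}
        for name, seed in (("ngs1", 1), ("ngs2", 2)):
            table = simulate_ngs(t, name, depth=1e6, seed=seed)
            prof[name] = normalize_platform(table)
        strong = t.true_log2_fc("lineA", "lineB").abs() >= 2
        agree = ok = 0
        fa = fold_changes(prof["ngs1"], "ngs1", ("lineA", "lineB"))
        fb = fold_changes(prof["ngs2"], "ngs2", ("lineA", "lineB"))
        shared = fa.index.intersection(fb.index)
        for m in shared[strong.reindex(shared).fillna(False)]:
            ok += 1
            if np.sign(fa.loc[m, "log2_fc"]) == np.sign(fb.loc[m, "log2_fc"]):
                agree += 1
        assert ok > 20
        assert agree / ok > 0.97

    def test_invalid_depth(self, truth):
        with pytest.raises(ValueError):
            simulate_ngs(truth, "ngs1", depth=0.0)


class TestSimulateQpcr:
    def test_noise_free_doubling_shifts_cq_by_minus_one(self):
        t = generate_truth(n_mirna=60, de_fraction=0.0, seed=3)
        t.de_spec.loc[:, "lineB"] = 1.0  # double every abundance in line B
        table = simulate_qpcr(t, "qpcr", noise_sd=0.0, seed=0)
        delta = table.values["lineB.1"] - table.values["lineA.1"]
        observed = delta[table.values[["lineA.1", "lineB.1"]].notna().all(axis=1)]
        assert np.allclose(observed, -1.0)

    def test_low_abundance_censored_to_missing(self):
        t = generate_truth(n_mirna=40, baseline_mean_log2=-10.0, baseline_sd_log2=0.5,
                           de_fraction=0.0, bias_sd_log2=0.0, seed=1)
        table = simulate_qpcr(t, "qpcr", c0=30.0, noise_sd=0.0, cutoff=36.0, seed=0)
        assert table.values.isna().all().all()
        panel_ids = table.values.index
        profs = normalize_platform(table_or_empty(table))
        for p in profs:
            assert not p.data.loc[panel_ids, "detected"].any()

    def test_noise_free_pipeline_recovers_true_fold_change(self):
        t = generate_truth(n_mirna=80, de_fraction=0.3, baseline_mean_log2=10.0,
                           baseline_sd_log2=1.0, seed=4)
        table = simulate_qpcr(t, "qpcr", c0=20.0, noise_sd=0.0, seed=0)
        profs = normalize_platform(table)
        fc = fold_changes(profs, "qpcr", ("lineA", "lineD"))
        true_fc = t.true_log2_fc("lineA", "lineD").loc[fc.index]
        # total-count scaling adds one constant per line pair; remove it
        shift = (fc["log2_fc"] - true_fc).median()
        np.testing.assert_allclose(fc["log2_fc"] - shift, true_fc, atol=1e-9)

    def test_negative_noise_rejected(self):
        t = generate_truth(n_mirna=10, seed=0)
        with pytest.raises(ValueError):
            simulate_qpcr(t, "qpcr", noise_sd=-0.1)


def table_or_empty(table):
    """qPCR tables that are entirely censored still normalize: linearized
    values are all zero only if every target is censored, which would be a
    zero-total error — pad one synthetic positive so the pipeline runs."""
    if table.values.notna().any().any():
        return table
    padded = table.values.copy()
    pad = pd.DataFrame(
        20.0, index=pd.Index(["spikein-pad"]), columns=padded.columns
    )
    return table.with_values(pd.concat([padded, pad]))


class TestSimulateHyb:
    def test_spike_normalization_removes_efficiency(self):
        """A per-sample efficiency factor is multiplicative on targets and
        spikes alike, so the spike factor cancels it (background-free)."""
        t = generate_truth(n_mirna=50, seed=6)
        table = simulate_hyb(t, "hyb", bg_mean=0.0, bg_sd=0.0,
                             efficiency_sd=0.4, seed=1)
        normed, factors = spike_normalize(table)
        # replicates of one cell line share the clean signal and differ only
        # by efficiency, which the spike factor must cancel
        reps = [c for c in table.values.columns if c.startswith("lineA.")]
        base = normed.values[reps[0]]
        for c in reps[1:]:
            assert not table.values[c].equals(table.values[reps[0]])
            np.testing.assert_allclose(
                normed.values[c].to_numpy(), base.to_numpy(), rtol=1e-6
            )

    def test_zero_gain_indistinguishable_from_background(self):
        from mirconcord.normalize import subtract_background

        t = generate_truth(n_mirna=50, seed=2)
        table = simulate_hyb(t, "hyb", gain=0.0, bg_mean=50.0, bg_sd=10.0, seed=3)
        normed, _ = spike_normalize(table)
        corrected, _ = subtract_background(normed)
        # targets carry background only; almost all fall below mean + 2 sd
        positive_rate = (corrected.values.to_numpy() > 0).mean()
        assert positive_rate < 0.1

    def test_low_abundance_dropout_frequency_matches_normal_tail(self):
        """With flat biasless abundance, a target replicate crosses the
        mean+2sd negative-probe threshold at the frequency the Gaussian
        tail predicts (conditioning on the realized thresholds)."""
        from scipy import stats

        t = generate_truth(n_mirna=400, baseline_mean_log2=0.0, baseline_sd_log2=0.0,
                           de_fraction=0.0, bias_sd_log2=0.0, seed=8)
        gain, bg_mean, bg_sd = 5.0, 100.0, 10.0
        rates, predicted = [], []
        for seed in range(20):
            table = simulate_hyb(t, "hyb", gain=gain, bg_mean=bg_mean, bg_sd=bg_sd,
                                 efficiency_sd=0.0, n_replicates=1, seed=seed)
            thr = table.negative_probes.mean() + 2 * table.negative_probes.std(ddof=1)
            rates.append((table.values.sub(thr) > 0).to_numpy().mean())
            # normal-tail oracle: value ~ N(bg_mean + gain, bg_sd) per target
            predicted.append(float(np.mean(
                stats.norm.sf((thr.to_numpy() - (bg_mean + gain)) / bg_sd)
            )))
        assert np.mean(rates) == pytest.approx(np.mean(predicted), abs=0.02)

    def test_increasing_background_lowers_sensitivity(self):
        """The proposed mechanism for a hybridization platform's low
        sensitivity: more background monotonically erodes detection."""
        sens = []
        for bg in (0.0, 60.0, 240.0):
            vals = []
            for seed in (0, 1, 2):
                t = generate_truth(n_mirna=120, seed=seed)
                tables = {
                    "ngs1": simulate_ngs(t, "ngs1", depth=1e6, seed=seed),
                    "ngs2": simulate_ngs(t, "ngs2", depth=1e6, seed=seed + 50),
                    "qpcr": simulate_qpcr(t, "qpcr", seed=seed),
                    "hyb": simulate_hyb(t, "hyb", gain=5.0, bg_mean=bg,
                                        bg_sd=max(bg / 2, 1.0), seed=seed),
                }
                profiles = []
                for table in tables.values():
                    profiles.extend(normalize_platform(table))
                cube = call_detection(profiles)
                ids = sorted(set.intersection(*(set(v) for v in t.panels.values())))
                truth = define_truth(cube, ids)
                vals.append(sensitivity(truth, "hyb").ratio)
            sens.append(np.mean(vals))
        assert sens[0] > sens[1] > sens[2]

    def test_control_matrix_shapes(self):
        t = generate_truth(n_mirna=20, seed=0)
        table = simulate_hyb(t, "hyb", seed=0)
        assert table.positive_spikes.shape[0] == 6
        assert table.negative_probes.shape[0] == 8

    def test_bad_parameters(self):
        t = generate_truth(n_mirna=10, seed=0)
        with pytest.raises(ValueError):
            simulate_hyb(t, "hyb", bg_mean=-1.0)
        with pytest.raises(ValueError):
            simulate_hyb(t, "hyb", spike_levels=(1.0, 2.0))
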