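"""Synthetic-study generation: determinism, moments, and round trips."""

import numpy as np
import pytest

from corrmr import (
    AR1,
    Blocks,
    Directional,
    Independent,
    SimConfig,
    compute_ld,
    gls_egger,
    gls_ivw,
    harmonize,
    load_panel,
    read_sumstats,
    simulate,
    write_fixture,
)


def cfg(**kw):
    base = dict(k_variants=20, seed=11, n_panel=1000, n_exposure_gwas=20000,
                n_outcome_gwas=20000)
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a, b = simulate(cfg()), simulate(cfg())
        np.testing.assert_array_equal(a.panel.dosages, b.panel.dosages)
        assert [(r.beta, r.se, r.pval) for r in a.exposure_stats] == [
            (r.beta, r.se, r.pval) for r in b.exposure_stats
        ]
        np.testing.assert_array_equal(a.truth.beta_exp, b.truth.beta_exp)

    def test_different_seed_differs(self):
        a, b = simulate(cfg()), simulate(cfg(seed=12))
        assert not np.array_equal(a.panel.dosages, b.panel.dosages)


class TestMoments:
    def test_se_scales_as_inverse_sqrt_n(self):
        small = simulate(cfg(seed=3, n_exposure_gwas=10000))
        large = simulate(cfg(seed=3, n_exposure_gwas=40000))
        med_small = np.median([r.se for r in small.exposure_stats])
        med_large = np.median([r.se for r in large.exposure_stats])
        assert med_large == pytest.approx(med_small / 2, rel=0.10)

    def test_ar1_lag1_panel_correlation(self):
        study = simulate(cfg(k_variants=40, n_panel=5000, seed=5,
                             ld_structure=AR1(0.7)))
        d = study.panel.dosages
        lag1 = np.mean(
            [np.corrcoef(d[:, i], d[:, i + 1])[0, 1] for i in range(39)]
        )
        assert lag1 == pytest.approx(0.7, abs=0.05)

    def test_block_structure_pairwise_correlation(self):
        study = simulate(cfg(k_variants=30, n_panel=8000, seed=6,
                             ld_structure=Blocks(size=5, rho=0.5)))
        d = study.panel.dosages
        within = [
            np.corrcoef(d[:, b * 5 + i], d[:, b * 5 + j])[0, 1]
            for b in range(6)
            for i in range(5)
            for j in range(i + 1, 5)
        ]
        across = [np.corrcoef(d[:, 0], d[:, 7])[0, 1],
                  np.corrcoef(d[:, 12], d[:, 21])[0, 1]]
        assert np.mean(within) == pytest.approx(0.5, abs=0.05)
        assert max(abs(x) for x in across) < 0.1

    def test_exposure_chisq_mean_matches_generative_model(self):
        """E[z^2] = 1 + n * per-variant explained variance (10% tolerance)."""
        study = simulate(cfg(k_variants=400, seed=9, n_exposure_gwas=20000,
                             variant_effect_sd=0.02))
        z2 = np.array([(r.beta / r.se) ** 2 for r in study.exposure_stats])
        var_g = 2 * study.truth.mafs * (1 - study.truth.mafs)
        expected = 1 + 20000 * np.mean(study.truth.beta_exp**2 * var_g)
        assert z2.mean() == pytest.approx(expected, rel=0.10)

    def test_null_slope_recovery_with_true_ld(self):
        """Downstream IVW is centred on zero under a null causal effect."""
        reps = 200
        est = np.empty(reps)
        for i in range(reps):
            study = simulate(
                SimConfig(k_variants=50, seed=1000 + i, n_panel=2,
                          n_exposure_gwas=50000, n_outcome_gwas=50000,
                          true_slope=0.0)
            )
            bx = np.array([r.beta for r in study.exposure_stats])
            by = np.array([r.beta for r in study.outcome_stats])
            sy = np.array([r.se for r in study.outcome_stats])
            est[i] = gls_ivw(bx, by, sy, study.truth.ld).slope
        mc_se = est.std(ddof=1) / np.sqrt(reps)
        assert abs(est.mean()) < 3 * mc_se

    def test_directional_pleiotropy_reaches_egger_intercept(self):
        """Instruments passing the strength screen recover the pleiotropy
        mean; near-null variants would otherwise attenuate the intercept."""
        reps = 200
        intercepts = np.empty(reps)
        for i in range(reps):
            study = simulate(
                SimConfig(k_variants=50, seed=2000 + i, n_panel=2,
                          n_exposure_gwas=50000, n_outcome_gwas=50000,
                          true_slope=0.2, pleiotropy=Directional(0.05, 0.02))
            )
            bx = np.array([r.beta for r in study.exposure_stats])
            sx = np.array([r.se for r in study.exposure_stats])
            by = np.array([r.beta for r in study.outcome_stats])
            sy = np.array([r.se for r in study.outcome_stats])
            keep = (bx / sx) ** 2 > 24
            ids = [v for v, k in zip(study.truth.ld.variant_ids, keep) if k]
            fit = gls_egger(bx[keep], by[keep], sy[keep],
                            study.truth.ld.subset(ids))
            intercepts[i] = fit.intercept
        mc_se = intercepts.std(ddof=1) / np.sqrt(reps)
        assert abs(intercepts.mean() - 0.05) < 3 * mc_se


class TestLDAwareCoverage:
    def test_gls_covers_while_identity_ld_undercovers(self):
        """Correlated instruments (rho=0.7): ignoring LD shrinks the SE."""
        reps, k = 400, 30
        hit_gls = hit_naive = 0
        for i in range(reps):
            study = simulate(
                SimConfig(k_variants=k, seed=3000 + i, n_panel=2,
                          n_exposure_gwas=50000, n_outcome_gwas=50000,
                          true_slope=0.2, ld_structure=AR1(0.7))
            )
            bx = np.array([r.beta for r in study.exposure_stats])
            by = np.array([r.beta for r in study.outcome_stats])
            sy = np.array([r.se for r in study.outcome_stats])
            f_gls = gls_ivw(bx, by, sy, study.truth.ld)
            f_naive = gls_ivw(bx, by, sy, None)
            hit_gls += f_gls.ci_low <= 0.2 <= f_gls.ci_high
            hit_naive += f_naive.ci_low <= 0.2 <= f_naive.ci_high
        assert 0.92 <= hit_gls / reps <= 0.975
        assert hit_naive / reps < 0.92


class TestFixtureRoundTrip:
    def test_write_then_read_matches_memory(self, tmp_path):
        study = simulate(cfg(k_variants=10, n_panel=200, seed=21))
        paths = write_fixture(study, tmp_path)
        exp = read_sumstats(paths["exposure"]).records
        out = read_sumstats(paths["outcome"]).records
        assert [r.beta for r in exp] == [r.beta for r in study.exposure_stats]
        harm = harmonize(exp, out).instruments
        assert len(harm) == 10  # all variants non-palindromic by construction
        for h, e, o in zip(harm, study.exposure_stats, study.outcome_stats):
            assert h.beta_exp == e.beta and h.beta_out == o.beta

    def test_truth_json_carries_exact_slope(self, tmp_path):
        import json

        study = simulate(cfg(k_variants=5, n_panel=50, seed=22, true_slope=0.37))
        paths = write_fixture(study, tmp_path)
        truth = json.loads(paths["truth"].read_text())
        assert truth["true_slope"] == 0.37

    def test_panel_file_reload_reproduces_ld(self, tmp_path):
        study = simulate(cfg(k_variants=8, n_panel=300, seed=23,
                             ld_structure=AR1(0.5)))
        paths = write_fixture(study, tmp_path)
        panel = load_panel(paths["panel"])
        ld_disk = compute_ld(panel, condition=False)
        ld_mem = compute_ld(study.panel, condition=False)
        np.testing.assert_allclose(ld_disk.r, ld_mem.r, atol=1e-12)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(k_variants=0),
            dict(maf_range=(0.0, 0.4)),
            dict(maf_range=(0.4, 0.1)),
            dict(variant_effect_sd=0.0),
            dict(outcome_binary=True, case_fraction=0.0),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            cfg(**bad)

    def test_infeasible_ld_structure_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(k_variants=2, seed=1, ld_structure=AR1(1.5))

    def test_binary_outcome_se_reflects_case_fraction(self):
        bal = simulate(cfg(seed=8, outcome_binary=True, case_fraction=0.5))
        rare = simulate(cfg(seed=8, outcome_binary=True, case_fraction=0.05))
        se_bal = np.median([r.se for r in bal.outcome_stats])
        se_rare = np.median([r.se for r in rare.outcome_stats])
        # 1/sqrt(cf(1-cf)): 0.05 cases inflate SEs by sqrt(0.25/0.0475)
        assert se_rare / se_bal == pytest.approx(np.sqrt(0.25 / 0.0475), rel=1e-6)
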