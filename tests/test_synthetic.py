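"""Generator contracts: cohort composition, log-normal biomarkers with
cross-media correlation and censoring, planted coupling, and AR(1) modular
time series."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import shapiro, spearmanr

from neuroexposome.reference import BiomarkerSpec, METALS, MEDIA, get_spec, reference_specs
from neuroexposome.synthetic import (
    EffectSpec,
    gen_biomarkers,
    gen_cohort,
    gen_timeseries,
    plant_effect,
)


def _cell(panel, metal, medium):
    sub = panel[(panel.metal == metal) & (panel.medium == medium)]
    return sub.set_index("subject_id")["value"]


class TestGenCohort:
    @pytest.mark.parametrize(
        "n,frac,expected_females",
        [(124, 0.57, 71), (10, 0.0, 0), (10, 1.0, 10)],
    )
    def test_sex_counts_exact(self, n, frac, expected_females):
        demo = gen_cohort(n, female_frac=frac, seed=0)
        assert sum(d.sex for d in demo) == expected_females
        assert len(demo) == n

    def test_ages_within_range_and_deterministic(self):
        a = gen_cohort(50, 0.5, (13, 25), seed=42)
        b = gen_cohort(50, 0.5, (13, 25), seed=42)
        assert all(13 <= d.age <= 25 for d in a)
        assert a == b

    def test_invalid_age_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            gen_cohort(10, 0.5, age_range=(25, 13), seed=0)


class TestGenBiomarkers:
    def test_blood_lead_gm_recovered(self):
        demo = gen_cohort(10_000, 0.5, seed=1)
        panel = gen_biomarkers(None, demo, corr=0.3, seed=2)
        gm = np.exp(np.log(_cell(panel, "Pb", "blood")).mean())
        assert gm == pytest.approx(8.409, rel=0.03)

    def test_degenerate_gsd_returns_gm(self, small_cohort):
        specs = [
            BiomarkerSpec(s.metal, s.medium, gm=s.gm, gsd=1.0, lod=0.0, pct_above_lod=100)
            for s in reference_specs()
        ]
        panel = gen_biomarkers(specs, small_cohort, corr=0.0, seed=3)
        vals = _cell(panel, "Cu", "hair")
        assert np.allclose(vals, get_spec("Cu", "hair").gm)

    def test_cross_media_correlation_matches_request(self):
        demo = gen_cohort(5_000, 0.5, seed=4)
        panel = gen_biomarkers(None, demo, corr=0.8, seed=5)
        x = np.log(_cell(panel, "Mn", "hair"))
        y = np.log(_cell(panel, "Mn", "blood")).loc[x.index]
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.8, abs=0.05)

    def test_different_metals_uncorrelated(self):
        demo = gen_cohort(5_000, 0.5, seed=4)
        panel = gen_biomarkers(None, demo, corr=0.8, seed=5)
        x = np.log(_cell(panel, "Mn", "hair"))
        y = np.log(_cell(panel, "Zn", "blood")).loc[x.index]
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.05

    def test_censoring_flags_values_below_lod(self, small_panel):
        below = small_panel.value < small_panel.lod
        assert (small_panel.censored == below).all()

    def test_log_concentrations_normal(self):
        """Shapiro normality of ln-concentrations: median p over 20 seeds."""
        pvals = []
        for seed in range(20):
            demo = gen_cohort(500, 0.5, seed=seed)
            panel = gen_biomarkers(None, demo, corr=0.3, seed=seed + 1000)
            pvals.append(shapiro(np.log(_cell(panel, "Pb", "urine"))).pvalue)
        assert np.median(pvals) > 0.01

    def test_uncensored_specs_recover_gm_within_3pct(self):
        demo = gen_cohort(10_000, 0.5, seed=6)
        panel = gen_biomarkers(None, demo, corr=0.3, seed=7)
        for spec in reference_specs():
            if spec.pct_above_lod == 100:
                gm = np.exp(np.log(_cell(panel, spec.metal, spec.medium)).mean())
                assert gm == pytest.approx(spec.gm, rel=0.03), (spec.metal, spec.medium)

    def test_incomplete_grid_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            gen_biomarkers(reference_specs()[:-1], small_cohort, seed=0)


class TestPlantEffect:
    def test_null_effect_constant(self, small_panel, small_cohort):
        truth = plant_effect(
            small_panel,
            small_cohort,
            EffectSpec((("Pb", "urine"),), (-1,), (0.0,)),
            beta_age=0.0,
            beta_sex=0.0,
        )
        assert np.ptp(truth["coupling"]) == 0

    def test_single_negative_feature_is_monotone_decreasing(self, small_panel, small_cohort):
        truth = plant_effect(
            small_panel,
            small_cohort,
            EffectSpec((("Pb", "urine"),), (-1,), (1.0,)),
            beta_age=0.0,
            beta_sex=0.0,
        )
        upb = _cell(small_panel, "Pb", "urine").loc[truth["subject_id"]]
        assert spearmanr(truth["coupling"], upb).statistic == pytest.approx(-1.0)

    def test_two_feature_magnitudes_recovered_by_ols(self):
        """Regressing coupling on the two z-scored features returns +/- the
        planted magnitudes (independent features, no covariate terms)."""
        demo = gen_cohort(2_000, 0.5, seed=8)
        panel = gen_biomarkers(None, demo, corr=0.0, seed=9)
        effect = EffectSpec((("Pb", "urine"), ("Zn", "blood")), (-1, 1), (0.7, 0.7))
        truth = plant_effect(panel, demo, effect, beta_age=0.0, beta_sex=0.0)
        z = []
        for metal, medium in effect.target_features:
            logv = np.log(_cell(panel, metal, medium).loc[truth["subject_id"]])
            z.append((logv - logv.mean()) / logv.std(ddof=1))
        X = np.column_stack([np.ones(len(demo))] + z)
        beta, *_ = np.linalg.lstsq(X, truth["coupling"].to_numpy(), rcond=None)
        assert beta[1] == pytest.approx(-0.7, abs=0.03)
        assert beta[2] == pytest.approx(0.7, abs=0.03)

    def test_latent_ge_monotone_in_coupling(self, small_panel, small_cohort):
        truth = plant_effect(small_panel, small_cohort, EffectSpec.default(1.0))
        order = np.argsort(truth["coupling"].to_numpy())
        assert (np.diff(truth["latent_ge"].to_numpy()[order]) >= 0).all()

    def test_zero_variance_feature_rejected(self, small_cohort):
        specs = [
            BiomarkerSpec(s.metal, s.medium, gm=s.gm, gsd=1.0, lod=0.0, pct_above_lod=100)
            for s in reference_specs()
        ]
        panel = gen_biomarkers(specs, small_cohort, corr=0.0, seed=3)
        with pytest.raises(ValueError, match="zero-variance"):
            plant_effect(panel, small_cohort, EffectSpec.default(1.0))


class TestGenTimeseries:
    def test_latent_correlation_recovered_without_noise(self):
        bundles = gen_timeseries(
            [0.0],
            n_nodes=2,
            T=50_000,
            ar1=0.0,
            nuisance_amp=0.0,
            seed=3,
            n_modules=1,
            r_within=0.5,
            sd_within=0.0,
            sd_between=0.0,
        )
        r = np.corrcoef(bundles[0].Y, rowvar=False)[0, 1]
        assert r == pytest.approx(0.5, abs=0.02)

    def test_ar1_coefficient_recovered(self):
        bundles = gen_timeseries(
            [0.0], n_nodes=5, T=20_000, ar1=0.6, nuisance_amp=0.0, seed=4
        )
        Y = bundles[0].Y
        Yc = Y - Y.mean(axis=0)
        rho1 = (Yc[1:] * Yc[:-1]).sum(axis=0) / (Yc**2).sum(axis=0)
        assert rho1.mean() == pytest.approx(0.6, abs=0.03)

    def test_bit_identical_under_fixed_seed(self):
        a = gen_timeseries([0.2, -0.2], n_nodes=8, T=60, seed=9)
        b = gen_timeseries([0.2, -0.2], n_nodes=8, T=60, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.Y, y.Y)
            assert np.array_equal(x.motion, y.motion)

    def test_nuisance_adds_shared_signal(self):
        quiet = gen_timeseries([0.0], n_nodes=10, T=500, nuisance_amp=0.0, seed=5)[0]
        noisy = gen_timeseries([0.0], n_nodes=10, T=500, nuisance_amp=3.0, seed=5)[0]
        # contaminated series correlate with their own motion regressors
        r_noisy = np.abs(np.corrcoef(noisy.motion[:, 0], noisy.Y[:, 0])[0, 1])
        r_quiet = np.abs(np.corrcoef(quiet.motion[:, 0], quiet.Y[:, 0])[0, 1])
        assert r_noisy > r_quiet

    def test_measured_efficiency_increases_across_coupling_tertiles(self):
        """Planted-effect monotonicity through the full measurement chain."""
        from neuroexposome.connectome import (
            binarize_proportional,
            global_efficiency,
            pearson_matrix,
        )
        from neuroexposome.prewhiten import prewhiten_two_step

        rng = np.random.default_rng(10)
        coupling = rng.standard_normal(45) * 0.5  # magnitude-0.5 scale
        bundles = gen_timeseries(coupling, n_nodes=60, T=400, seed=11)
        ge = np.array(
            [
                global_efficiency(
                    binarize_proportional(pearson_matrix(prewhiten_two_step(b)[0]), 0.15)
                )
                for b in bundles
            ]
        )
        thirds = np.array_split(np.argsort(coupling), 3)
        means = [ge[t].mean() for t in thirds]
        assert means[0] < means[1] < means[2]
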