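"""Differential-abundance inference against independent oracles:
brute-force Poisson likelihood maximization, closed-form balanced-design
variance components, statsmodels MixedLM, and exhaustive BH step-up
enumeration."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from lfqdiff import SimulationTruth
from lfqdiff.diff import (
    TERMS,
    adjust_bh,
    adjust_fit_results,
    build_design_matrix,
    fit_poisson_glm,
    fit_xic_mixed_model,
    merge_methods,
    results_to_frame,
    sc_prefilter,
    term_name,
    _levels_of,
    ProteinFitResult,
)
from lfqdiff.lmm import fit_random_intercept
from lfqdiff.simulate import simulate_peptide_intensities, simulate_spectral_counts


def sc_frame(design, counts):
    return pd.DataFrame(
        {"protein": "P1", "sample_id": design["sample_id"], "count": counts}
    )


class TestScPrefilter:
    def test_flat_protein_excluded(self, design):
        counts = sc_frame(design, np.full(len(design), 5))
        assert sc_prefilter(counts, design) == set()

    def test_range_eleven_retained(self, design):
        # combination means {2,...,2,13}: range 11 >= 10
        counts = design.merge(
            design[["strain", "medium", "time"]].drop_duplicates().assign(mean=2),
            on=["strain", "medium", "time"],
        )
        vals = np.where(
            (design.strain == "S2") & (design.medium == "M2") & (design.time == "T3"),
            13,
            2,
        )
        counts = sc_frame(design, vals)
        assert sc_prefilter(counts, design) == {"P1"}

    def test_threshold_is_inclusive(self, design):
        vals = np.where(
            (design.strain == "S1") & (design.medium == "M1") & (design.time == "T1"),
            12,
            2,
        )
        counts = sc_frame(design, vals)
        assert sc_prefilter(counts, design, min_avg_diff=10) == {"P1"}
        assert sc_prefilter(counts, design, min_avg_diff=10.5) == set()


def poisson_loglik(beta, X, y):
    eta = X @ beta
    return float(np.sum(y * eta - np.exp(eta) - special.gammaln(y + 1)))


class TestPoissonGlm:
    def test_all_counts_equal_gives_p_one(self, design):
        counts = sc_frame(design, np.full(len(design), 7))
        fit = fit_poisson_glm(counts, design)
        assert all(p == 1.0 for p in fit.pvalues.values())

    def test_strain_coefficient_log4_and_bruteforce_likelihood(self, design):
        truth = SimulationTruth(
            mu=np.log(10), strain=np.array([np.log(2), -np.log(2)]), seed=3
        )
        counts = simulate_spectral_counts(truth, design, 1)
        fit = fit_poisson_glm(counts, design, protein="P1")
        assert fit.estimates["strain"] == pytest.approx(np.log(4), abs=0.15)
        # independent oracle: numeric maximization of the Poisson likelihood
        data = counts.merge(design, on="sample_id")
        levels = _levels_of(design, ("strain", "medium", "time", "replicate"))
        X = build_design_matrix(data, TERMS, levels, extra_factors=("replicate",))
        y = data["count"].to_numpy(float)
        res = optimize.minimize(
            lambda b: -poisson_loglik(b, X, y),
            np.zeros(X.shape[1]),
            method="BFGS",
            options={"gtol": 1e-10, "maxiter": 2000},
        )
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)

    def test_deviance_identity(self, design):
        """Model deviance equals 2*(loglik saturated - loglik fitted)."""
        import statsmodels.api as sm

        truth = SimulationTruth(mu=np.log(8), seed=5)
        counts = simulate_spectral_counts(truth, design, 1)
        data = counts.merge(design, on="sample_id")
        levels = _levels_of(design, ("strain", "medium", "time", "replicate"))
        X = build_design_matrix(data, TERMS, levels, extra_factors=("replicate",))
        y = data["count"].to_numpy(float)
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        with np.errstate(divide="ignore", invalid="ignore"):
            ll_sat = float(np.sum(np.where(y > 0, y * np.log(y), 0.0) - y - special.gammaln(y + 1)))
        assert res.deviance == pytest.approx(2 * (ll_sat - res.llf), abs=1e-8)

    def test_missing_cell_reported(self, design):
        counts = sc_frame(design, np.full(len(design), 5))
        cut = counts.merge(design, on="sample_id")
        cut = cut[~((cut.strain == "S1") & (cut.medium == "M1") & (cut.time == "T1"))]
        with pytest.raises(ValueError, match="S1"):
            fit_poisson_glm(cut[["protein", "sample_id", "count"]], design)


class TestXicMixedModel:
    def test_zero_theta_matches_ols(self, design):
        """Data with no between-sample variability pins the REML theta
        component at its boundary, where the fit equals least squares."""
        truth = SimulationTruth(
            sigma_theta=0.0, sigma_eps=0.2, peptide_offset_sd=0.2, seed=8
        )
        tab = simulate_peptide_intensities(truth, design, 1, 3)
        # remove every source of sample-level variation, noise included
        tab["log10_intensity"] -= tab.groupby("sample_id")[
            "log10_intensity"
        ].transform("mean")
        fit = fit_xic_mixed_model(tab, design)
        assert fit.sigma_theta2 < 1e-4
        # fixed effects match plain least squares
        data = tab.merge(design, on="sample_id")
        data = data.assign(
            peptide_charge=data["peptide"].astype(str) + "/" + data["charge"].astype(str)
        )
        levels = _levels_of(design, ("strain", "medium", "time", "replicate"))
        levels["peptide_charge"] = sorted(data["peptide_charge"].unique())
        X = build_design_matrix(
            data, TERMS, levels, extra_factors=("replicate", "peptide_charge")
        )
        y = data["log10_intensity"].to_numpy()
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        lmm_fit = fit_random_intercept(y, X, data["sample_id"].to_numpy(), reml=True)
        assert lmm_fit.sigma_theta2 == 0.0
        np.testing.assert_allclose(lmm_fit.beta, beta_ols, atol=1e-6)

    def test_balanced_reml_matches_closed_form(self):
        """REML on a balanced one-factor layout equals the ANOVA
        variance-component estimators (MS_between, MS_within)."""
        rng = np.random.default_rng(0)
        S, p = 48, 2
        theta = rng.normal(0, 0.15, S)
        y = (5 + theta[None, :] + rng.normal(0, 0.25, (p, S))).ravel()
        groups = np.tile(np.arange(S), p)
        X = np.ones((p * S, 1))
        fit = fit_random_intercept(y, X, groups, reml=True)
        ybar = y.reshape(p, S).mean(axis=0)
        ms_between = p * np.var(ybar, ddof=1)
        ms_within = ((y.reshape(p, S) - ybar) ** 2).sum() / (S * (p - 1))
        assert fit.sigma_eps2 == pytest.approx(ms_within, abs=1e-6)
        assert fit.sigma_theta2 == pytest.approx((ms_between - ms_within) / p, abs=1e-6)

    def test_against_statsmodels_mixedlm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        S, p = 30, 3
        theta = rng.normal(0, 0.2, S)
        y = (4 + theta[None, :] + rng.normal(0, 0.3, (p, S))).ravel()
        groups = np.tile(np.arange(S), p)
        X = np.column_stack([np.ones(p * S), rng.normal(size=p * S)])
        for reml in (True, False):
            mine = fit_random_intercept(y, X, groups, reml=reml)
            ref = sm.MixedLM(y, X, groups=groups).fit(reml=reml)
            assert mine.loglik == pytest.approx(ref.llf, abs=1e-5)
            assert mine.sigma_eps2 == pytest.approx(ref.scale, rel=1e-4)
            np.testing.assert_allclose(mine.beta, ref.fe_params, atol=1e-5)

    def test_identical_intensities_degenerate(self, design):
        tab = simulate_peptide_intensities(
            SimulationTruth(
                sigma_theta=0, sigma_eps=0, peptide_offset_sd=0, rt_jitter_sd=0, seed=0
            ),
            design, 1, 2,
        )
        fit = fit_xic_mixed_model(tab, design)
        assert all(p == 1.0 for p in fit.pvalues.values())
        assert fit.sigma_theta2 == 0.0 and fit.sigma_eps2 == 0.0

    def test_single_peptide_falls_back_to_ols(self, design):
        truth = SimulationTruth(sigma_theta=0.1, sigma_eps=0.2, seed=12)
        tab = simulate_peptide_intensities(truth, design, 1, 1)
        fit = fit_xic_mixed_model(tab, design)
        assert "single peptide" in fit.note
        assert fit.sigma_theta2 == 0.0

    def test_strain_effect_estimate(self, design):
        truth = SimulationTruth(
            strain=np.array([0.25, -0.25]), sigma_theta=0.1, sigma_eps=0.2, seed=6
        )
        tab = simulate_peptide_intensities(truth, design, 1, 4)
        fit = fit_xic_mixed_model(tab, design)
        assert fit.estimates["strain"] == pytest.approx(0.5, abs=0.15)
        assert fit.pvalues["strain"] < 1e-6


def bh_by_enumeration(pvals):
    """Independent oracle: adjusted p_i = smallest level alpha (over the
    finite candidate set) at which the BH step-up procedure rejects i."""
    p = np.asarray(pvals, float)
    m = len(p)
    candidates = sorted({p[j] * m / r for j in range(m) for r in range(1, m + 1)})
    out = np.ones(m)
    for i in range(m):
        for alpha in candidates:
            srt = np.sort(p)
            k = 0
            for j in range(m):
                if srt[j] <= (j + 1) * alpha / m:
                    k = j + 1
            if k and p[i] <= srt[k - 1]:
                out[i] = min(alpha, 1.0)
                break
    return out


class TestAdjustBh:
    def test_single_p_unchanged(self):
        assert adjust_bh([0.03])[0] == pytest.approx(0.03)

    def test_equal_spacing_collapses(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_enumeration_on_grid(self):
        grid = [0.001, 0.01, 0.04, 0.2, 0.6, 1.0]
        rng = np.random.default_rng(0)
        for length in range(1, 7):
            for _ in range(20):
                p = rng.choice(grid, size=length)
                np.testing.assert_allclose(
                    adjust_bh(p), bh_by_enumeration(p), atol=1e-12
                )

    def test_nan_excluded_and_reinserted(self):
        out = adjust_bh([0.01, np.nan, 0.03])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], adjust_bh([0.01, 0.03]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([-0.1, 0.5])
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        adj = adjust_bh(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()


def make_fit(protein, method, p_strain):
    f = ProteinFitResult(protein=protein, method=method)
    for t in TERMS:
        f.pvalues[term_name(t)] = 0.9
    f.pvalues["strain"] = p_strain
    return f


class TestMergeMethods:
    def make_sets(self, n_both, n_sc_only, n_xic_only):
        sc, xic = [], []
        for i in range(n_both):
            sc.append(make_fit(f"B{i}", "SC", 1e-6))
            xic.append(make_fit(f"B{i}", "XIC", 1e-6))
        for i in range(n_sc_only):
            sc.append(make_fit(f"S{i}", "SC", 1e-6))
            xic.append(make_fit(f"S{i}", "XIC", 0.9))
        for i in range(n_xic_only):
            sc.append(make_fit(f"X{i}", "SC", 0.9))
            xic.append(make_fit(f"X{i}", "XIC", 1e-6))
        adjust_fit_results(sc)
        adjust_fit_results(xic)
        return sc, xic

    def test_disjoint_sets(self):
        sc, xic = self.make_sets(0, 2, 3)
        _, part = merge_methods(sc, xic)
        assert part["union"] == 5 and part["both"] == 0

    def test_both_prefers_xic(self):
        sc, xic = self.make_sets(2, 0, 0)
        merged, part = merge_methods(sc, xic)
        assert part["both"] == 2
        assert all(f.method == "XIC" for f in merged)

    def test_printed_partition_sizes(self):
        sc, xic = self.make_sets(350, 295, 395)
        _, part = merge_methods(sc, xic)
        assert part["union"] == 1040
        assert part["sc_total"] == 645 and part["xic_total"] == 745

    def test_duplicate_protein_rejected(self):
        sc, xic = self.make_sets(1, 1, 0)
        sc.append(sc[0])
        with pytest.raises(ValueError, match="duplicate"):
            merge_methods(sc, xic)


def test_results_frame_has_seven_terms_per_protein(design):
    truth = SimulationTruth(sigma_theta=0.05, sigma_eps=0.1, seed=2)
    tab = simulate_peptide_intensities(truth, design, 2, 2)
    fits = [fit_xic_mixed_model(tab, design, protein=p) for p in ("P1", "P2")]
    adjust_fit_results(fits)
    frame = results_to_frame(fits)
    assert len(frame) == 14
    assert (frame.groupby("protein").size() == 7).all()
    assert (frame["p_adj"] >= frame["p_raw"] - 1e-15).all()
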