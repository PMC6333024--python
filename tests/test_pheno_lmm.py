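"""Tests of the EM-REML / BLUP machinery against independent oracles."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from gsbreeder import pheno_lmm, simdata
from gsbreeder.pheno_lmm import (
    LMMDesign,
    RandomFactor,
    VarianceComponents,
    blup_solve,
    build_design,
    correct_phenotypes,
    individual_h2,
    phenotypic_accuracy,
    reml_fit,
    restricted_loglik_direct,
)


def one_way_design(y, groups):
    """Intercept-only design with a single random factor."""
    y = np.asarray(y, dtype=float)
    levels = sorted(set(groups))
    codes = np.asarray([levels.index(g) for g in groups])
    factor = RandomFactor("g", levels, codes)
    records = pd.DataFrame(
        {
            "individual": [str(g) for g in groups],
            "family": "f",
            "pop_type": "p",
            "plot": "pl",
            "year": 1,
        }
    )
    return LMMDesign(
        y=y, X=np.ones((y.size, 1)), fixed_levels=["mu"],
        factors=[factor], records=records,
    )


def simulated_table(h2, seed, n_markers=600, n_qtl=200):
    ped = simdata.simulate_pedigree(seed=seed)
    panel = simdata.simulate_genotypes(ped, n_markers=n_markers, seed=seed + 1000)
    table, truth = simdata.simulate_phenotypes(
        panel, ped, [simdata.make_trait("t", h2, n_qtl)], seed=seed + 2000
    )
    return table, truth


class TestDesign:
    def test_dimensions_and_alias_detection(self):
        table, _ = simulated_table(0.4, 1)
        design = build_design(table, "t")
        assert design.y.size == 585
        assert design.X.shape == (585, 3)
        aliased = {f.name: f.aliased_with for f in design.factors}
        # one plant per genotype: p duplicates g, ind x year duplicates e
        assert aliased == {"g": None, "p": "g", "r": None, "b": None, "i": "residual"}

    def test_family_level_design_fully_identifiable(self):
        table, _ = simulated_table(0.4, 2)
        design = build_design(table, "t", genetic_level="family")
        assert all(f.aliased_with is None for f in design.factors)
        assert design.factor("g").n_levels == 13
        assert design.factor("p").n_levels == 195
        assert design.factor("i").n_levels == 39

    def test_missing_records_dropped(self):
        table, _ = simulated_table(0.4, 3)
        table.loc[table.index[0], "value"] = np.nan
        design = build_design(table, "t")
        assert design.y.size == 584
        assert design.n_dropped == 1

    def test_single_year_rejected(self):
        table, _ = simulated_table(0.4, 4)
        with pytest.raises(ValueError):
            build_design(table[table["year"] == 1], "t")

    def test_unknown_trait_rejected(self):
        table, _ = simulated_table(0.4, 5)
        with pytest.raises(ValueError):
            build_design(table, "nope")


class TestREML:
    def test_balanced_anova_equivalence(self):
        """On a balanced one-way design EM-REML equals the ANOVA estimators."""
        rng = np.random.default_rng(12)
        n_groups, reps = 20, 3
        groups = np.repeat(np.arange(n_groups), reps)
        effects = rng.normal(0, 1.2, n_groups)
        y = 5.0 + effects[groups] + rng.normal(0, 0.8, groups.size)
        design = one_way_design(y, groups)
        vc = reml_fit(design, tol=1e-10)

        ybar = y.mean()
        gmeans = y.reshape(n_groups, reps).mean(axis=1)
        msb = reps * np.sum((gmeans - ybar) ** 2) / (n_groups - 1)
        mse = np.sum((y.reshape(n_groups, reps) - gmeans[:, None]) ** 2) / (
            n_groups * (reps - 1)
        )
        assert vc.sigma2["e"] == pytest.approx(mse, abs=1e-6)
        assert vc.sigma2["g"] == pytest.approx((msb - mse) / reps, abs=1e-6)

    def test_loglik_monotone_and_matches_direct_formula(self):
        table, _ = simulated_table(0.5, 6)
        design = build_design(table, "t")
        vc = reml_fit(design)
        diffs = np.diff(vc.loglik_trace)
        assert (diffs > -1e-6 * np.abs(vc.loglik_trace[:-1])).all()
        # MME-identity likelihood equals the dense-V likelihood up to a constant
        ll_direct = restricted_loglik_direct(design, vc)
        vc2 = VarianceComponents(
            sigma2={**vc.sigma2, "g": vc.sigma2["g"] * 1.3},
            converged=True, n_iterations=0, loglik=np.nan,
        )
        # compare likelihood *differences* to cancel the constant
        from gsbreeder.pheno_lmm import _assemble_mme, _restricted_loglik

        def mme_ll(components):
            active = [f for f in design.active_factors if components.sigma2[f.name] > 0]
            Zs = [f.incidence() for f in active]
            sig = np.array([components.sigma2[f.name] for f in active])
            q = np.array([z.shape[1] for z in Zs])
            se = components.sigma2["e"]
            C, rhs, _ = _assemble_mme(design.X, Zs, se / sig, design.y)
            sol = np.linalg.solve(C, rhs)
            return _restricted_loglik(
                C, sol, rhs, design.y, se, sig, q, design.y.size, design.X.shape[1]
            )

        d_mme = mme_ll(vc) - mme_ll(vc2)
        d_direct = restricted_loglik_direct(design, vc) - restricted_loglik_direct(
            design, vc2
        )
        assert d_mme == pytest.approx(d_direct, rel=1e-8)
        assert ll_direct == ll_direct  # finite

    def test_null_genetic_variance_estimated_near_zero(self):
        ests = []
        for rep in range(10):
            table, _ = simulated_table(0.0, 50 + rep, n_qtl=10)
            vc = reml_fit(build_design(table, "t"))
            ests.append(vc.sigma2["g"] / vc.total)
        assert np.median(ests) < 0.05

    def test_h2_recovery_moderate_trait(self):
        """A PH-like trait (h2 = 0.46) is recovered within +-0.15."""
        ests = []
        for rep in range(10):
            table, _ = simulated_table(0.46, 80 + rep)
            vc = reml_fit(build_design(table, "t"))
            ests.append(individual_h2(vc))
        assert abs(np.mean(ests) - 0.46) < 0.15

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_against_lme4(self, tmp_path):
        """Variance components agree with lme4's REML on the same data."""
        table, _ = simulated_table(0.5, 7)
        design = build_design(table, "t")
        vc = reml_fit(design, tol=1e-10)
        sub = table.copy()
        csv = tmp_path / "d.csv"
        sub.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            """
            suppressMessages(library(lme4))
            d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
            d$year <- factor(d$year)
            m <- lmer(value ~ 0 + year + (1|individual) + (1|pop_type) + (1|plot),
                      data=d, REML=TRUE,
                      control=lmerControl(check.conv.singular="ignore"))
            v <- as.data.frame(VarCorr(m))
            write.csv(v[, c("grp", "vcov")], row.names=FALSE)
            """
        )
        out = subprocess.run(
            ["Rscript", str(script), str(csv)], capture_output=True, text=True,
            timeout=300,
        )
        assert out.returncode == 0, out.stderr
        lines = [l for l in out.stdout.strip().splitlines() if "," in l]
        ref = {}
        for line in lines[1:]:
            grp, vcov = line.replace('"', "").split(",")
            ref[grp] = float(vcov)
        assert vc.sigma2["g"] == pytest.approx(ref["individual"], rel=2e-3, abs=1e-4)
        assert vc.sigma2["r"] == pytest.approx(ref["pop_type"], rel=2e-3, abs=1e-4)
        assert vc.sigma2["b"] == pytest.approx(ref["plot"], rel=2e-3, abs=1e-4)
        assert vc.sigma2["e"] == pytest.approx(ref["Residual"], rel=2e-3, abs=1e-4)


class TestBLUP:
    def test_matches_gls_oracle(self):
        """MME solution equals direct GLS / covariance-based BLUP on a small fixture."""
        rng = np.random.default_rng(3)
        n_groups, reps = 8, 3
        groups = np.repeat(np.arange(n_groups), reps)
        y = rng.normal(0, 1, groups.size) + np.repeat(rng.normal(0, 2, n_groups), reps)
        design = one_way_design(y, groups)
        vc = VarianceComponents(
            sigma2={"g": 1.7, "p": 0, "r": 0, "b": 0, "i": 0, "e": 0.6},
            converged=True, n_iterations=1, loglik=np.nan,
        )
        sol = blup_solve(design, vc)

        Z = design.factors[0].incidence()
        X = design.X
        V = 1.7 * Z @ Z.T + 0.6 * np.eye(y.size)
        Vinv = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
        u = 1.7 * Z.T @ Vinv @ (y - X @ beta)
        np.testing.assert_allclose(sol.fixed_estimates.to_numpy(), beta, atol=1e-8)
        np.testing.assert_allclose(sol.blups["g"].to_numpy(), u, atol=1e-8)
        # PEV against the joint-covariance identity
        P = Vinv - Vinv @ X @ np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv)
        pev = np.diag(1.7 * np.eye(n_groups) - 1.7 * Z.T @ P @ Z * 1.7)
        np.testing.assert_allclose(sol.pev["g"].to_numpy(), pev, atol=1e-8)

    def test_shrinkage_bounded_by_raw_deviations(self):
        rng = np.random.default_rng(4)
        groups = np.repeat(np.arange(12), 4)
        y = rng.normal(0, 1, groups.size) + np.repeat(rng.normal(0, 1, 12), 4)
        design = one_way_design(y, groups)
        vc = reml_fit(design)
        sol = blup_solve(design, vc)
        raw_dev = y.reshape(12, 4).mean(axis=1) - y.mean()
        assert (np.abs(sol.blups["g"].to_numpy()) <= np.abs(raw_dev) + 1e-9).all()

    def test_zero_variances_give_zero_blups(self):
        table, _ = simulated_table(0.4, 8)
        design = build_design(table, "t")
        vc = VarianceComponents(
            sigma2={"g": 0, "p": 0, "r": 0, "b": 0, "i": 0, "e": 1.0},
            converged=True, n_iterations=1, loglik=np.nan,
        )
        sol = blup_solve(design, vc)
        for name in ("g", "r", "b"):
            assert (sol.blups[name] == 0).all()

    def test_noiseless_limit_recovers_effects(self):
        """With sigma_e -> 0 the genetic BLUPs reproduce the true group deviations."""
        rng = np.random.default_rng(5)
        n_groups, reps = 10, 3
        groups = np.repeat(np.arange(n_groups), reps)
        effects = rng.normal(0, 1, n_groups)
        effects -= effects.mean()
        y = 2.0 + effects[groups]
        design = one_way_design(y, groups)
        vc = VarianceComponents(
            sigma2={"g": 1.0, "p": 0, "r": 0, "b": 0, "i": 0, "e": 1e-10},
            converged=True, n_iterations=1, loglik=np.nan,
        )
        sol = blup_solve(design, vc)
        np.testing.assert_allclose(sol.blups["g"].to_numpy(), effects, atol=1e-4)


class TestAccuracyAndCorrection:
    def test_r_yy_approaches_one_with_dominant_genetic_variance(self):
        rng = np.random.default_rng(6)
        groups = np.repeat(np.arange(30), 10)
        y = np.repeat(rng.normal(0, 10, 30), 10) + rng.normal(0, 0.1, 300)
        design = one_way_design(y, groups)
        vc = reml_fit(design)
        _, r_yy = phenotypic_accuracy(design, vc)
        # the intercept/genetic-mean confounding keeps a ~sigma_g/n_groups
        # floor in the PEV, so the limit is just below 1
        assert r_yy > 0.97

    def test_r_yy_zero_when_no_genetic_variance(self):
        table, _ = simulated_table(0.3, 9)
        design = build_design(table, "t")
        vc = VarianceComponents(
            sigma2={"g": 0, "p": 0, "r": 0, "b": 0, "i": 0, "e": 1.0},
            converged=True, n_iterations=1, loglik=np.nan,
        )
        h2, r_yy = phenotypic_accuracy(design, vc)
        assert h2 == 0.0 and r_yy == 0.0

    def test_r_yy_tracks_sqrt_h2_pattern(self):
        """For a high-h2 trait, r_yy is close to sqrt(h2_phen)."""
        table, _ = simulated_table(0.75, 10)
        design = build_design(table, "t")
        vc = reml_fit(design)
        h2_phen, r_yy = phenotypic_accuracy(design, vc)
        assert r_yy == pytest.approx(np.sqrt(h2_phen), abs=0.06)
        _, r_alt = phenotypic_accuracy(design, vc, method="sqrt_h2")
        assert r_alt == pytest.approx(np.sqrt(h2_phen))

    def test_known_year_offsets_removed_exactly(self, clean_panel, pedigree):
        trait = simdata.TraitSpec(
            name="t", variance={"genotype": 1.0, "residual": 1e-12},
            n_qtl=60, year_means=(3.0, 7.0, -2.0),
        )
        table, truth = simdata.simulate_phenotypes(clean_panel, pedigree, [trait], seed=11)
        design = build_design(table, "t")
        vc = reml_fit(design)
        sol = blup_solve(design, vc)
        corrected = correct_phenotypes(design, sol)
        bv = truth.true_breeding_values["t"]
        resid = corrected.reindex(bv.index) - bv
        # corrected phenotype = BV up to one common constant
        assert resid.std() < 1e-3

    def test_correction_trivial_case_and_order_invariance(self):
        table, _ = simulated_table(0.4, 12)
        design = build_design(table, "t")
        vc = reml_fit(design)
        sol = blup_solve(design, vc)
        ref = correct_phenotypes(design, sol)
        shuffled = table.sample(frac=1.0, random_state=0)
        design2 = build_design(shuffled, "t")
        vc2 = reml_fit(design2)
        sol2 = blup_solve(design2, vc2)
        out2 = correct_phenotypes(design2, sol2)
        pd.testing.assert_series_equal(ref, out2.reindex(ref.index), atol=1e-6, rtol=0)

    @pytest.mark.parametrize(
        "sigma2, expected",
        [
            ({"g": 1, "p": 0.2, "r": 0.2, "b": 0.2, "i": 0.2, "e": 0.2}, 0.5),
            ({"g": 0, "p": 1, "r": 0, "b": 0, "i": 0, "e": 1}, 0.0),
            ({"g": 0.26, "p": 0, "r": 0.1, "b": 0.1, "i": 0.14, "e": 0.4}, 0.26),
        ],
    )
    def test_individual_h2(self, sigma2, expected):
        vc = VarianceComponents(
            sigma2=sigma2, converged=True, n_iterations=1, loglik=np.nan
        )
        assert individual_h2(vc) == pytest.approx(expected)

    def test_individual_h2_zero_total_rejected(self):
        vc = VarianceComponents(
            sigma2={k: 0.0 for k in ("g", "p", "r", "b", "i", "e")},
            converged=True, n_iterations=1, loglik=np.nan,
        )
        with pytest.raises(ValueError):
            individual_h2(vc)
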