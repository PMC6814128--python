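"""Univariate REML engine: oracles, invariances and model behaviour."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import provblup as pb
from provblup._engine import RandomTerm, SparseREML, reduce_to_full_rank
from provblup.models import DesignError, assemble_design, compute_aic_value, solve_group_mme
from provblup.simulate import SimulationConfig, simulate_trial


def dense_reml_neg2loglik(y, X, covs):
    """Direct dense evaluation of -2 logL_R for V = sum_k s2_k * cov_k.

    Independent oracle route: no mixed-model equations, just the textbook
    restricted likelihood with explicit matrices.
    """
    n, p = X.shape
    V = sum(s2 * C for s2, C in covs)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    sign, ld_v = np.linalg.slogdet(V)
    sign2, ld_x = np.linalg.slogdet(XtViX)
    return ld_v + ld_x + float(y @ P @ y) + (n - p) * np.log(2 * np.pi)


@pytest.fixture(scope="module")
def one_way_data():
    rng = np.random.default_rng(3)
    f, k = 40, 12
    fam = np.repeat(np.arange(f), k)
    y = rng.standard_normal(f)[fam] * np.sqrt(0.4) + rng.standard_normal(f * k) * np.sqrt(1.1)
    Z = sp.csr_matrix((np.ones(f * k), (np.arange(f * k), fam)), shape=(f * k, f))
    return y, fam, Z, f, k


class TestEngineOracles:
    def test_balanced_one_way_matches_anova(self, one_way_data):
        y, fam, Z, f, k = one_way_data
        res = SparseREML(y, np.ones((len(y), 1)), [RandomTerm("family", Z)]).fit()
        df = pd.DataFrame({"y": y, "fam": fam})
        gm = df.groupby("fam")["y"].transform("mean")
        msb = k * ((df.groupby("fam")["y"].mean() - y.mean()) ** 2).sum() / (f - 1)
        msw = ((df["y"] - gm) ** 2).sum() / (f * (k - 1))
        assert res.theta[0] == pytest.approx((msb - msw) / k, abs=1e-8)
        assert res.theta[1] == pytest.approx(msw, abs=1e-8)
        assert res.converged

    def test_loglik_matches_dense_oracle(self, rng):
        n, f, r = 60, 8, 5
        fam = rng.integers(0, f, n)
        rep = rng.integers(0, r, n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        Zf = sp.csr_matrix((np.ones(n), (np.arange(n), fam)), shape=(n, f))
        Zr = sp.csr_matrix((np.ones(n), (np.arange(n), rep)), shape=(n, r))
        eng = SparseREML(y, X, [RandomTerm("fam", Zf), RandomTerm("rep", Zr)])
        for theta in ([0.3, 0.2, 0.8], [1.2, 0.05, 0.4]):
            covs = [
                (theta[0], (Zf @ Zf.T).toarray()),
                (theta[1], (Zr @ Zr.T).toarray()),
                (theta[2], np.eye(n)),
            ]
            dense = dense_reml_neg2loglik(y, X, covs)
            assert -2.0 * eng.loglik(np.array(theta)) == pytest.approx(dense, abs=1e-8)

    def test_lme4_reference_fit(self, tmp_path, rng):
        n, f, r = 400, 25, 8
        fam = rng.integers(0, f, n)
        rep = rng.integers(0, r, n)
        y = (
            rng.standard_normal(f)[fam] * 0.7
            + rng.standard_normal(r)[rep] * 0.4
            + rng.standard_normal(n)
        )
        df = pd.DataFrame({"y": y, "fam": fam, "rep": rep})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        out = tmp_path / "vc.csv"
        script = tmp_path / "fit.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                m <- lmer(y ~ 1 + (1|fam) + (1|rep), data=d, REML=TRUE)
                vc <- as.data.frame(VarCorr(m))
                vc$logLik <- as.numeric(logLik(m, REML=TRUE))
                write.csv(vc, "{out}", row.names=FALSE)
                """
            )
        )
        subprocess.run(["Rscript", "--vanilla", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(out).set_index("grp")["vcov"]
        Zf = sp.csr_matrix((np.ones(n), (np.arange(n), fam)), shape=(n, f))
        Zr = sp.csr_matrix((np.ones(n), (np.arange(n), rep)), shape=(n, r))
        res = SparseREML(
            y, np.ones((n, 1)), [RandomTerm("fam", Zf), RandomTerm("rep", Zr)]
        ).fit()
        assert res.theta[0] == pytest.approx(ref["fam"], rel=1e-4)
        assert res.theta[1] == pytest.approx(ref["rep"], rel=1e-4)
        assert res.theta[2] == pytest.approx(ref["Residual"], rel=1e-4)
        ref_ll = pd.read_csv(out)["logLik"].iloc[0]
        assert res.loglik == pytest.approx(ref_ll, abs=1e-4)


class TestInvariances:
    def test_reml_invariant_to_fixed_reparameterisation(self, small_trial):
        ped, pheno, _ = small_trial
        base = pb.fit_reml(pheno, ped, trait="y", variant="ablup_f", compute_pev=False)
        # recode provenance dummies by shifting the reference level: same
        # column space, so the restricted likelihood must not move
        relab = pheno.copy()
        order = {p: f"Z{i}" for i, p in enumerate(sorted(set(relab["provenance"]) - {""}))}
        relab["provenance"] = relab["provenance"].map(lambda p: order.get(p, p))
        alt = pb.fit_reml(relab, [
            r.__class__(r.individual, r.dam, r.sire, order.get(r.provenance, r.provenance))
            for r in ped
        ], trait="y", variant="ablup_f", compute_pev=False)
        assert alt.loglik == pytest.approx(base.loglik, abs=1e-6)
        assert alt.varcomp["additive"] == pytest.approx(base.varcomp["additive"], rel=1e-5)

    def test_doubling_scale_quadruples_variances(self, small_trial):
        ped, pheno, _ = small_trial
        base = pb.fit_reml(pheno, ped, trait="y", variant="ablup_f", compute_pev=False)
        doubled = pheno.copy()
        doubled["y"] = 2.0 * doubled["y"]
        scaled = pb.fit_reml(doubled, ped, trait="y", variant="ablup_f", compute_pev=False)
        from provblup.parameters import heritability_normal

        for comp in ("additive", "residual", "replicate"):
            assert scaled.varcomp[comp] == pytest.approx(4.0 * base.varcomp[comp], rel=1e-4)
        assert heritability_normal(scaled.varcomp).value == pytest.approx(
            heritability_normal(base.varcomp).value, abs=1e-6
        )


class TestDesign:
    def test_set_nested_within_replicate(self, small_trial):
        ped, pheno, _ = small_trial
        est = pb.AnimalModelREML(trait="y", variant="ablup_f")
        aug = est._augment(ped)
        design = assemble_design(pheno, "ablup_f", aug, "y")
        nested = next(t for t in design.terms if t.name == "set_within_rep")
        n_rep = pheno["replicate"].nunique()
        n_set = pheno["set"].nunique()
        assert nested.q == n_rep * n_set

    def test_reference_coding_for_provenance(self, small_trial):
        ped, pheno, _ = small_trial
        est = pb.AnimalModelREML(trait="y", variant="ablup_f")
        aug = est._augment(ped)
        design = assemble_design(pheno, "ablup_f", aug, "y")
        n_prov = pheno.loc[pheno["provenance"] != "", "provenance"].nunique()
        assert sum(nm.startswith("provenance:") for nm in design.x_names) == n_prov - 1

    def test_missing_trait_records_dropped(self, small_trial):
        ped, pheno, _ = small_trial
        holed = pheno.copy()
        holed.loc[holed.index[:25], "y"] = np.nan
        est = pb.AnimalModelREML(trait="y", variant="ablup_f")
        aug = est._augment(ped)
        design = assemble_design(holed, "ablup_f", aug, "y")
        assert len(design.y) == len(pheno) - 25

    def test_unlinked_tree_raises(self, small_trial):
        ped, pheno, _ = small_trial
        bad = pheno.copy()
        bad.loc[bad.index[0], "tree"] = "GHOST"
        est = pb.AnimalModelREML(trait="y", variant="ablup_f")
        aug = est._augment(ped)
        with pytest.raises(DesignError, match="GHOST"):
            assemble_design(bad, "ablup_f", aug, "y")

    def test_rank_reduction_drops_trailing_dependent_columns(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), np.arange(10.0) + 1.0])
        Xr, kept = reduce_to_full_rank(X)
        assert kept == [0, 1] and Xr.shape[1] == 2


class TestModelBehaviour:
    def test_null_genetic_variance_pinned_at_floor(self):
        import warnings

        cfg = SimulationConfig.from_targets(
            0.3, 0.2, n_provenances=4, mothers_per_provenance=8, offspring_per_mother=6,
            replicates=6, sets_per_replicate=2, seed=9,
        )
        cfg.sigma2_g = 0.0
        cfg.sigma2_p = 0.0
        ped, pheno, _ = simulate_trial(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = pb.fit_reml(pheno, ped, trait="y", variant="ablup_f", compute_pev=False)
        assert fit.varcomp["additive"] < 0.02
        # all phenotypic variance lands in the residual (truth 0.7)
        assert fit.varcomp["residual"] == pytest.approx(0.7, rel=0.2)

    def test_gc2_and_f_share_likelihood_and_components(self, small_trial):
        ped, pheno, _ = small_trial
        f = pb.fit_reml(pheno, ped, trait="y", variant="ablup_f", compute_pev=False)
        gc2 = pb.fit_reml(pheno, ped, trait="y", variant="ablup_gc2", compute_pev=False)
        assert gc2.loglik == pytest.approx(f.loglik, abs=1e-5)
        assert gc2.varcomp["additive"] == pytest.approx(f.varcomp["additive"], rel=1e-4)

    def test_pev_bounded_by_additive_variance(self, small_trial):
        ped, pheno, _ = small_trial
        fit = pb.fit_reml(pheno, ped, trait="y", variant="ablup_f")
        s2g = fit.varcomp["additive"]
        assert fit.pev is not None and len(fit.pev) > 0
        assert (fit.pev > 0).all()
        assert (fit.pev <= s2g + 1e-10).all()
        acc = fit.accuracy_ if hasattr(fit, "accuracy_") else None

    def test_group_mme_matches_explicit_fit(self, small_trial):
        ped, pheno, _ = small_trial
        est = pb.AnimalModelREML(trait="y", variant="ablup_gc1", compute_pev=False)
        est.fit(pheno, ped)
        fit = est.result_
        aug = est._augment(ped)
        design = assemble_design(pheno, "ablup_gc1", aug, "y")
        kept_names = set(fit.beta.index)
        pinned = [
            nm.split(":", 1)[1] for nm in design.group_cols if nm not in kept_names
        ]
        ebv2 = solve_group_mme(design, fit.varcomp.components, pinned)
        diff = (fit.breeding_values - ebv2).abs().max()
        assert diff < 1e-6


class TestAIC:
    def test_arithmetic(self):
        assert compute_aic_value(-100.0, 4) == pytest.approx(208.0)

    def test_free_parameter_counts(self, small_trial):
        ped, pheno, _ = small_trial
        f = pb.fit_reml(pheno, ped, trait="y", variant="ablup_f", compute_pev=False)
        r = pb.fit_reml(pheno, ped, trait="y", variant="ablup_r", compute_pev=False)
        assert f.n_free_varparams == 4
        assert r.n_free_varparams == 5
        assert f.aic == pytest.approx(-2 * f.loglik + 8)
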