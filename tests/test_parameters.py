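"""Derived genetic parameters: formulas, errors and delta-method SEs."""

import numpy as np
import pandas as pd
import pytest

import provblup as pb
from provblup.models import VarianceComponents
from provblup.parameters import (
    accuracy,
    genetic_correlation,
    heritability_binary,
    heritability_normal,
    heritability_with_provenance,
    latitude_ebv_correlation,
    qst,
)


def vc_of(**components):
    return VarianceComponents(components=components, cov=None)


class TestHeritability:
    def test_published_growth_trait_components(self):
        # additive 211, residual 671 -> 0.24 at two decimals
        h2 = heritability_normal(vc_of(additive=211.0, residual=671.0))
        assert round(h2.value, 2) == 0.24

    @pytest.mark.parametrize(
        "g, e, expected", [(0.0, 1.0, 0.0), (1.0, 1.0, 0.5)]
    )
    def test_edge_values(self, g, e, expected):
        assert heritability_normal(vc_of(additive=g, residual=e)).value == pytest.approx(expected)

    def test_undefined_when_total_zero(self):
        with pytest.raises(ValueError):
            heritability_normal(vc_of(additive=0.0, residual=0.0))

    def test_provenance_in_denominator(self):
        # provenance 140, additive 212, residual 671 -> 0.21
        h2 = heritability_with_provenance(vc_of(provenance=140.0, additive=212.0, residual=671.0))
        assert round(h2.value, 2) == 0.21

    def test_provenance_zero_reduces_to_normal(self):
        a = heritability_with_provenance(vc_of(provenance=0.0, additive=0.3, residual=0.7))
        b = heritability_normal(vc_of(additive=0.3, residual=0.7))
        assert a.value == pytest.approx(b.value)

    def test_never_exceeds_normal_form(self, rng):
        for _ in range(20):
            p, g, e = rng.uniform(0.01, 2.0, 3)
            with_p = heritability_with_provenance(vc_of(provenance=p, additive=g, residual=e))
            without = heritability_normal(vc_of(additive=g, residual=e))
            assert with_p.value <= without.value + 1e-12

    def test_binary_formula(self):
        c = np.pi**2 / 3.0
        assert heritability_binary(vc_of(additive=0.0, theta=1.0)).value == 0.0
        assert heritability_binary(vc_of(additive=c, theta=1.0)).value == pytest.approx(0.5)
        assert heritability_binary(vc_of(additive=1.0, theta=1.0)).value == pytest.approx(
            1.0 / (1.0 + c), abs=1e-4
        )
        with pytest.raises(ValueError):
            heritability_binary(vc_of(additive=1.0, theta=0.0))


class TestQst:
    def test_published_components(self):
        # provenance 140, additive 212 -> 0.25
        q = qst(vc_of(provenance=140.0, additive=212.0))
        assert round(q.value, 2) == 0.25

    @pytest.mark.parametrize("p, g, expected", [(0.0, 1.0, 0.0), (2.0, 1.0, 0.5)])
    def test_edge_values(self, p, g, expected):
        assert qst(vc_of(provenance=p, additive=g)).value == pytest.approx(expected)

    def test_undefined_when_both_zero(self):
        with pytest.raises(ValueError):
            qst(vc_of(provenance=0.0, additive=0.0))

    def test_significance_flag_uses_two_se(self):
        cov = pd.DataFrame(
            [[1e-6, 0.0], [0.0, 1e-6]], index=["provenance", "additive"],
            columns=["provenance", "additive"],
        )
        vc = VarianceComponents(components=dict(provenance=0.3, additive=0.3), cov=cov)
        assert qst(vc).significant is True


class TestAccuracy:
    @pytest.mark.parametrize("pev, expected", [(0.0, 1.0), (1.0, 0.0), (0.75, 0.5)])
    def test_pointwise(self, pev, expected):
        r = accuracy([pev], sigma2_g=1.0)
        assert r.per_individual.iloc[0] == pytest.approx(expected)

    def test_clamped_with_warning_when_pev_exceeds_variance(self):
        with pytest.warns(RuntimeWarning):
            r = accuracy([1.5], sigma2_g=1.0)
        assert r.per_individual.iloc[0] == 0.0

    def test_monotone_decreasing_in_pev(self):
        r = accuracy(np.linspace(0.0, 1.0, 11), sigma2_g=1.0)
        assert (np.diff(r.per_individual.to_numpy()) <= 0).all()


class TestGeneticCorrelation:
    @pytest.mark.parametrize(
        "cov, v1, v2, expected",
        [(1.0, 1.0, 1.0, 1.0), (0.0, 1.0, 2.0, 0.0), (0.5, 1.0, 1.0, 0.5)],
    )
    def test_formula(self, cov, v1, v2, expected):
        assert genetic_correlation(cov, v1, v2).value == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            genetic_correlation(0.1, 0.0, 1.0)

    def test_invariant_to_trait_rescaling(self):
        # scaling trait 2 by c scales cov by c and var2 by c^2
        base = genetic_correlation(0.4, 1.0, 2.0).value
        scaled = genetic_correlation(0.4 * 10, 1.0, 2.0 * 100).value
        assert scaled == pytest.approx(base)


class TestLatitudeCorrelation:
    def test_exact_negative_cline(self):
        lat = pd.Series([36.0, 40.0, 44.0, 48.0])
        assert latitude_ebv_correlation(-lat, lat) == pytest.approx(-1.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            latitude_ebv_correlation([1.0, 2.0], [36.0, 40.0])
        with pytest.raises(ValueError):
            latitude_ebv_correlation([1.0, 1.0, 1.0], [36.0, 40.0, 44.0])

    def test_recovers_generating_cline_sign(self):
        from provblup.simulate import SimulationConfig, simulate_trial

        cfg = SimulationConfig.from_targets(
            0.35, 0.05, n_provenances=8, mothers_per_provenance=8, offspring_per_mother=6,
            replicates=6, sets_per_replicate=2, cline_slope=-0.15, seed=21,
        )
        ped, pheno, truth = simulate_trial(cfg)
        fit = pb.fit_reml(pheno, ped, trait="y", variant="ablup_gc1", compute_pev=False)
        prov_of = {r.individual: r.provenance for r in ped}
        lat_of = truth.latitudes
        trees = [t for t in fit.breeding_values.index if prov_of.get(t, "")]
        ebv = fit.breeding_values[trees]
        lat = pd.Series([lat_of[prov_of[t]] for t in trees], index=trees)
        assert latitude_ebv_correlation(ebv, lat) < 0


class TestDeltaSEs:
    def test_se_nonnegative_and_shrinks_with_n(self):
        from provblup.simulate import SimulationConfig, simulate_trial

        ses = []
        for mothers, off in ((6, 4), (14, 10)):
            cfg = SimulationConfig.from_targets(
                0.3, 0.2, n_provenances=6, mothers_per_provenance=mothers,
                offspring_per_mother=off, replicates=max(off, 4), sets_per_replicate=2,
                seed=5,
            )
            ped, pheno, _ = simulate_trial(cfg)
            fit = pb.fit_reml(pheno, ped, trait="y", variant="ablup_r", compute_pev=False)
            h2 = heritability_with_provenance(fit.varcomp)
            q = qst(fit.varcomp)
            assert h2.se >= 0 and q.se >= 0
            ses.append((h2.se, q.se))
        assert ses[1][0] < ses[0][0]
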