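"""Genetic parameters derived from fitted variance components.

Formulas (all ratios of REML variance components, standard errors by the
delta method on the component sampling covariance):

* narrow-sense heritability,          h2  = s2_g / (s2_g + s2_e)
* heritability with provenance random, h2 = s2_g / (s2_p + s2_g + s2_e)
* binary-trait heritability,          h2  = s2_g / (s2_g + theta pi^2 / 3)
* quantitative genetic divergence,    Qst = s2_p / (s2_p + 2 s2_g)
* breeding-value accuracy,            r   = sqrt(1 - PEV / s2_g)
* genetic correlation,                r_G = s_gigj / sqrt(s2_gi s2_gj)

Replicate and set block variances are excluded from the heritability
denominator: the block effects are experimental-design noise removed by
the trial layout, not part of the phenotypic variance a breeder selects
on.  Q_ST compares the among-provenance variance with the total additive
variance; the factor 2 converts the within-population additive variance to
its between-population equivalent under neutral expectations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PI = np.pi


@dataclass
class ParameterEstimate:
    """A derived genetic parameter with its delta-method standard error."""

    value: float
    se: float
    formula: str
    significant: bool | None = None
    per_individual: pd.Series | None = field(default=None, repr=False)

    def __float__(self):
        return float(self.value)


def _delta_se(vc, names, grad) -> float:
    cov = getattr(vc, "cov", None)
    if cov is None:
        return float("nan")
    have = [n for n in names if n in cov.index]
    if len(have) < len(names):
        return float("nan")
    V = cov.loc[names, names].to_numpy()
    g = np.asarray(grad, dtype=float)
    return float(np.sqrt(max(g @ V @ g, 0.0)))


def heritability_normal(vc) -> ParameterEstimate:
    """h2 = s2_g / (s2_g + s2_e) for identity-link fits."""
    g = vc["additive"]
    e = vc["residual"]
    den = g + e
    if den <= 0:
        raise ValueError("sigma2_g + sigma2_e is zero; heritability undefined")
    h2 = g / den
    se = _delta_se(vc, ["additive", "residual"], [e / den**2, -g / den**2])
    return ParameterEstimate(h2, se, "h2_normal")


def heritability_with_provenance(vc) -> ParameterEstimate:
    """h2 with the provenance variance in the denominator (provenance-random fits)."""
    p = vc.get("provenance")
    if p is None:
        raise ValueError("fit has no provenance variance component")
    g = vc["additive"]
    e = vc["residual"]
    den = p + g + e
    if den <= 0:
        raise ValueError("denominator is zero; heritability undefined")
    h2 = g / den
    se = _delta_se(
        vc,
        ["provenance", "additive", "residual"],
        [-g / den**2, (p + e) / den**2, -g / den**2],
    )
    return ParameterEstimate(h2, se, "h2_with_prov")


def heritability_binary(vc) -> ParameterEstimate:
    """h2 = s2_g / (s2_g + theta pi^2/3) on the logit liability scale."""
    theta = vc.get("theta")
    if theta is None or theta <= 0:
        raise ValueError("binary heritability needs a positive dispersion theta")
    g = vc["additive"]
    c = PI**2 / 3.0
    den = g + theta * c
    h2 = g / den
    se = _delta_se(vc, ["additive", "theta"], [theta * c / den**2, -g * c / den**2])
    return ParameterEstimate(h2, se, "h2_binary")


def qst(vc) -> ParameterEstimate:
    """Q_ST = s2_p / (s2_p + 2 s2_g), flagged significant when > 2 SE."""
    p = vc.get("provenance")
    if p is None:
        raise ValueError("Q_ST needs a provenance variance component")
    g = vc["additive"]
    den = p + 2.0 * g
    if den <= 0:
        raise ValueError("both components are zero; Q_ST undefined")
    q = p / den
    se = _delta_se(vc, ["provenance", "additive"], [2.0 * g / den**2, -2.0 * p / den**2])
    sig = bool(q > 2.0 * se) if np.isfinite(se) else None
    return ParameterEstimate(q, se, "qst", significant=sig)


def accuracy(pev, sigma2_g: float) -> ParameterEstimate:
    """Breeding-value accuracy r = sqrt(1 - PEV/s2_g), per individual + mean.

    PEV above sigma2_g (a numerical artefact near the boundary) is clamped
    to accuracy 0 with a warning.  The summary value is the mean over the
    individuals supplied (phenotyped, non-control genotypes by
    convention).
    """
    if sigma2_g <= 0:
        raise ValueError("accuracy undefined for non-positive additive variance")
    pev_s = pd.Series(pev, dtype=float)
    ratio = 1.0 - pev_s / sigma2_g
    if (ratio < 0).any():
        warnings.warn(
            "PEV larger than the additive variance for some individuals; "
            "their accuracy is clamped to 0",
            RuntimeWarning,
        )
    per = np.sqrt(ratio.clip(lower=0.0))
    return ParameterEstimate(
        float(per.mean()), float("nan"), "accuracy", per_individual=per
    )


def genetic_correlation(cov_ij: float, var_i: float, var_j: float, vcov=None, names=None) -> ParameterEstimate:
    """r_G = cov / sqrt(var_i var_j) with an optional delta-method SE.

    ``vcov`` is the 3x3 sampling covariance of (cov_ij, var_i, var_j) in
    that order (``names`` ignored when provided positionally).
    """
    if var_i <= 0 or var_j <= 0:
        raise ValueError("genetic correlation undefined for non-positive variances")
    den = np.sqrt(var_i * var_j)
    rg = cov_ij / den
    se = float("nan")
    if vcov is not None:
        grad = np.array(
            [1.0 / den, -0.5 * cov_ij / (den * var_i), -0.5 * cov_ij / (den * var_j)]
        )
        V = np.asarray(vcov, dtype=float)
        se = float(np.sqrt(max(grad @ V @ grad, 0.0)))
    return ParameterEstimate(rg, se, "rg")


def latitude_ebv_correlation(ebv, latitude) -> float:
    """Pearson correlation of breeding values with latitude of origin."""
    e = pd.Series(ebv, dtype=float)
    l = pd.Series(latitude, dtype=float)
    df = pd.concat([e.rename("ebv"), l.rename("lat")], axis=1).dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 individuals with EBV and latitude")
    if df["ebv"].std() == 0 or df["lat"].std() == 0:
        raise ValueError("zero variance in EBV or latitude; correlation undefined")
    return float(df["ebv"].corr(df["lat"]))
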