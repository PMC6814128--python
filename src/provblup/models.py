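"""Univariate animal-model fits for provenance/progeny trials.

The observation model is

    y = X b + Z g + Z r + Z r(s) + e

with a random additive genetic effect per tree (``var(g) = A sigma2_g``),
random replicate and set-within-replicate block effects, and i.i.d.
residuals.  The provenance structure enters in one of four ways:

``ablup_f``
    provenance as a fixed factor (reference-level coding);
``ablup_r``
    provenance as an i.i.d. random factor — the partition of additive
    variance into within- and among-provenance parts that yields Q_ST;
``ablup_gc1`` / ``ablup_gc2``
    contemporary genetic groups in the pedigree.  Internally these are
    fitted through the exactly equivalent explicit formulation: the
    group-fraction columns ``Q`` enter the fixed design (rank-deficient
    columns dropped deterministically) and the additive effect keeps the
    base-pedigree ``A``; reported breeding values are group-inclusive,
    ``Q g_hat + a_hat``.

Binary traits use a logit-link penalised quasi-likelihood fit with the
residual variance fixed (reported as 1) and an over/under-dispersion
coefficient ``theta`` estimated in its place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._engine import ConvergenceError, RandomTerm, SparseREML, reduce_to_full_rank
from .pedigree import (
    AugmentedPedigree,
    GroupScheme,
    augment_with_groups,
    build_Ainv_with_groups,
    build_group_fractions,
    log_det_A,
    sort_and_validate,
)

VARIANTS = ("ablup_f", "ablup_r", "ablup_gc1", "ablup_gc2")

#: canonical component order in reports
COMPONENT_ORDER = ("provenance", "additive", "replicate", "set_within_rep", "residual", "theta")


class DesignError(ValueError):
    """Phenotype records that cannot be linked to the model structure."""


@dataclass
class VarianceComponents:
    """Estimated variance components with their sampling covariance."""

    components: dict
    cov: pd.DataFrame | None = None
    boundary: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.components[key]

    def get(self, key, default=None):
        return self.components.get(key, default)

    def se(self, key) -> float:
        if self.cov is None or key not in getattr(self.cov, "index", []):
            return float("nan")
        return float(np.sqrt(max(self.cov.loc[key, key], 0.0)))


@dataclass
class FitResult:
    """One converged univariate REML fit."""

    variant: str
    trait: str
    varcomp: VarianceComponents
    loglik: float
    aic: float
    n_free_varparams: int
    beta: pd.Series
    breeding_values: pd.Series
    pev: pd.Series | None
    converged: bool
    n_iter: int
    n_obs: int
    fixed_rank: int
    link: str = "identity"

    @property
    def accuracy(self) -> pd.Series:
        """Per-individual breeding-value accuracy sqrt(1 - PEV/sigma2_g)."""
        from .parameters import accuracy as _acc

        if self.pev is None:
            raise ValueError("fit was run without PEV computation")
        return _acc(self.pev, self.varcomp["additive"]).per_individual


@dataclass
class DesignMatrices:
    """Assembled response, fixed design and random-term incidences."""

    y: np.ndarray
    X: np.ndarray
    x_names: list
    terms: list  # RandomTerm list (order: provenance?, additive, replicate, set_within_rep)
    trees: pd.Series  # tree id per kept record
    aug: AugmentedPedigree
    q_obs: np.ndarray | None  # group fractions per record (gc variants)
    group_cols: list  # names of group columns inside X
    logdet_a: float


def _indicator(levels: pd.Series, level_list) -> sp.csr_matrix:
    idx = pd.Categorical(levels, categories=level_list).codes
    if np.any(idx < 0):
        raise DesignError("record level outside the declared level set")
    n = len(levels)
    return sp.csr_matrix((np.ones(n), (np.arange(n), idx)), shape=(n, len(level_list)))


def _control_labels(col: pd.Series) -> pd.Series:
    """Normalise the control column: '' for pedigree trees, a lot label otherwise."""

    def norm(v):
        if pd.isna(v):
            return ""
        if isinstance(v, (bool, np.bool_)):
            return "control" if v else ""
        s = str(v).strip()
        return "" if s in ("", "0", "False", "false") else s

    return col.map(norm) if col is not None else pd.Series("", index=col.index)


def build_fixed_design(df: pd.DataFrame, variant: str, aug: AugmentedPedigree):
    """Fixed design for one record block: intercept, control lots, and the
    provenance dummies (``ablup_f``) or group-fraction columns (gc variants).

    Returns ``(X, names, group_cols, q_obs)``.
    """
    n = len(df)
    ctrl = _control_labels(df["control"]) if "control" in df.columns else pd.Series([""] * n)
    ctrl_levels = sorted({c for c in ctrl if c})

    x_cols = [np.ones(n)]
    x_names = ["intercept"]
    for lot in ctrl_levels:
        x_cols.append((ctrl == lot).to_numpy(float))
        x_names.append(f"control:{lot}")

    group_cols = []
    q_obs = None
    if variant == "ablup_f":
        prov = df["provenance"].fillna("").astype(str)
        prov_levels = sorted({p for p in prov if p})
        for p in prov_levels[1:]:  # reference coding
            x_cols.append((prov == p).to_numpy(float))
            x_names.append(f"provenance:{p}")
    elif variant in ("ablup_gc1", "ablup_gc2"):
        Q = build_group_fractions(aug)
        q_obs = Q.loc[df["tree"].astype(str)].to_numpy()
        for j, gname in enumerate(Q.columns):
            x_cols.append(q_obs[:, j])
            x_names.append(f"group:{gname}")
            group_cols.append(f"group:{gname}")
    return np.column_stack(x_cols), x_names, group_cols, q_obs


def assemble_design(
    table: pd.DataFrame,
    variant: str,
    aug: AugmentedPedigree,
    trait: str,
) -> DesignMatrices:
    """Build the mixed-model design for one trait under one variant.

    Records with a missing trait value are dropped.  The fixed design holds
    an intercept, one indicator per control lot, provenance dummies
    (reference coding) for ``ablup_f``, and the group-fraction columns for
    the genetic-group variants.  The set factor is nested within replicate.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if trait not in table.columns:
        raise DesignError(f"trait {trait!r} not in the phenotype table")
    df = table.loc[table[trait].notna()].reset_index(drop=True)
    if len(df) == 0:
        raise DesignError(f"no non-missing records for trait {trait!r}")
    missing = set(df["tree"].astype(str)) - set(aug.individuals)
    if missing:
        raise DesignError(
            f"trees absent from the pedigree: {sorted(missing)[:5]}"
            + ("..." if len(missing) > 5 else "")
        )

    y = df[trait].to_numpy(dtype=float)
    n = len(df)
    X, x_names, group_cols, q_obs = build_fixed_design(df, variant, aug)

    tree_idx = np.array([aug.index_of(t) for t in df["tree"].astype(str)])
    Za = sp.csr_matrix(
        (np.ones(n), (np.arange(n), tree_idx)), shape=(n, aug.n_individuals)
    )
    ainv = build_Ainv_with_groups(aug, include_groups=False).tocsr()
    terms = []
    if variant == "ablup_r":
        prov = df["provenance"].fillna("").astype(str)
        prov_levels = sorted({p for p in prov if p})
        Zp_full = _indicator(
            prov.where(prov != "", prov_levels[0]), prov_levels
        ).tolil()
        blank = (prov == "").to_numpy()
        Zp_full[blank.nonzero()[0], :] = 0.0  # controls carry no provenance effect
        terms.append(RandomTerm("provenance", Zp_full.tocsr()))
    terms.append(RandomTerm("additive", Za, ginv=ainv, logdet_g=log_det_A(aug)))
    rep = df["replicate"].astype(str)
    rep_levels = sorted(rep.unique())
    terms.append(RandomTerm("replicate", _indicator(rep, rep_levels)))
    rs = rep + "/" + df["set"].astype(str)
    rs_levels = sorted(rs.unique())
    terms.append(RandomTerm("set_within_rep", _indicator(rs, rs_levels)))

    return DesignMatrices(
        y=y,
        X=X,
        x_names=x_names,
        terms=terms,
        trees=df["tree"].astype(str),
        aug=aug,
        q_obs=q_obs,
        group_cols=group_cols,
        logdet_a=log_det_A(aug),
    )


class AnimalModelREML:
    """Pedigree-based animal-model REML, sklearn-estimator style.

    Parameters
    ----------
    trait : str
        Column of the phenotype table to analyse.
    variant : {"ablup_f", "ablup_r", "ablup_gc1", "ablup_gc2"}
        Treatment of the provenance structure.
    link : {"identity", "logit"}
        ``logit`` triggers the binary-trait PQL fit.
    compute_pev : bool
        Whether to extract per-individual prediction error variances for
        phenotyped non-control trees (one sparse solve each).
    start : dict or None
        Optional starting values keyed by component name.

    Fitted attributes (trailing underscore): ``varcomp_``, ``loglik_``,
    ``aic_``, ``beta_``, ``breeding_values_``, ``pev_``, ``accuracy_``,
    ``converged_``, ``n_iter_``, ``result_``.
    """

    def __init__(
        self,
        trait: str = "y",
        variant: str = "ablup_f",
        link: str = "identity",
        compute_pev: bool = True,
        max_iter: int = 200,
        rel_tol_loglik: float = 1e-8,
        rel_tol_params: float = 1e-6,
        start: dict | None = None,
    ):
        self.trait = trait
        self.variant = variant
        self.link = link
        self.compute_pev = compute_pev
        self.max_iter = max_iter
        self.rel_tol_loglik = rel_tol_loglik
        self.rel_tol_params = rel_tol_params
        self.start = start

    # sklearn-compatible parameter plumbing
    def get_params(self, deep=True):
        return {
            k: getattr(self, k)
            for k in (
                "trait",
                "variant",
                "link",
                "compute_pev",
                "max_iter",
                "rel_tol_loglik",
                "rel_tol_params",
                "start",
            )
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _augment(self, pedigree) -> AugmentedPedigree:
        if isinstance(pedigree, AugmentedPedigree):
            return pedigree
        records = sort_and_validate(list(pedigree))
        mode = {"ablup_gc1": "gc1", "ablup_gc2": "gc2"}.get(self.variant, "none")
        scheme = GroupScheme.for_provenances(
            [r.provenance for r in records], mode
        )
        return augment_with_groups(records, scheme, ungrouped="founder")

    def fit(self, phenotypes: pd.DataFrame, pedigree) -> "AnimalModelREML":
        aug = self._augment(pedigree)
        design = assemble_design(phenotypes, self.variant, aug, self.trait)
        if self.link == "logit":
            result = _fit_pql(design, self)
        else:
            result = _fit_gaussian(design, self)
        self.result_ = result
        self.varcomp_ = result.varcomp
        self.loglik_ = result.loglik
        self.aic_ = result.aic
        self.beta_ = result.beta
        self.breeding_values_ = result.breeding_values
        self.pev_ = result.pev
        self.converged_ = result.converged
        self.n_iter_ = result.n_iter
        if result.pev is not None and result.varcomp["additive"] > 0:
            from .parameters import accuracy as _acc

            self.accuracy_ = _acc(result.pev, result.varcomp["additive"]).per_individual
        else:
            self.accuracy_ = None
        return self


def _theta_from_start(start: dict | None, names: list, y: np.ndarray):
    if start is None:
        return None
    vy = float(np.var(y))
    theta = []
    for nm in names:
        theta.append(start.get(nm, 0.1 * vy))
    return np.array(theta)


def _collect_fit(
    design: DesignMatrices,
    model: AnimalModelREML,
    engine: SparseREML,
    res,
    extra_free_params: int = 0,
    theta_names: list | None = None,
    link: str = "identity",
    vc_overrides: dict | None = None,
) -> FitResult:
    names = theta_names if theta_names is not None else res.names
    comp = {nm: float(th) for nm, th in zip(names, res.theta)}
    cov = pd.DataFrame(res.vcov_theta, index=names, columns=names)
    boundary = {nm: bool(b) for nm, b in zip(names, res.boundary)}
    if vc_overrides:
        comp.update(vc_overrides)
    vc = VarianceComponents(components=comp, cov=cov, boundary=boundary)

    x_kept = [design.x_names[j] for j in engine.kept_cols]
    beta = pd.Series(res.beta, index=x_kept)

    ahat = pd.Series(res.u["additive"], index=design.aug.individuals)
    if design.q_obs is not None:
        Q = build_group_fractions(design.aug)
        ghat = pd.Series(0.0, index=[f"group:{g}" for g in Q.columns])
        for nm in beta.index:
            if nm in ghat.index:
                ghat[nm] = beta[nm]
        ebv = pd.Series(Q.to_numpy() @ ghat.to_numpy(), index=design.aug.individuals) + ahat
    else:
        ebv = ahat

    pev = None
    if model.compute_pev:
        # phenotyped non-control genotypes (controls carry no provenance label)
        prov_of = {r.individual: r.provenance for r in design.aug.records}
        uniq = sorted({t for t in design.trees if prov_of.get(t, "")})
        idx = np.array([design.aug.index_of(t) for t in uniq], dtype=np.int64)
        if design.q_obs is not None:
            Q = build_group_fractions(design.aug)
            p = engine.p
            fw = np.zeros((len(uniq), p))
            name_to_pos = {nm: j for j, nm in enumerate(x_kept)}
            for col in design.group_cols:
                if col in name_to_pos:
                    gname = col.split(":", 1)[1]
                    fw[:, name_to_pos[col]] = Q.loc[uniq, gname].to_numpy()
            pv = engine.pev(res, "additive", idx, fixed_weights=fw)
        else:
            pv = engine.pev(res, "additive", idx)
        pev = pd.Series(pv, index=uniq)

    t_free = len(res.theta) + extra_free_params
    loglik = float(res.loglik)
    aic = compute_aic_value(loglik, t_free)
    return FitResult(
        variant=model.variant,
        trait=model.trait,
        varcomp=vc,
        loglik=loglik,
        aic=aic,
        n_free_varparams=t_free,
        beta=beta,
        breeding_values=ebv,
        pev=pev,
        converged=res.converged,
        n_iter=res.n_iter,
        n_obs=res.n_obs,
        fixed_rank=res.p_fixed,
        link=link,
    )


def _fit_gaussian(design: DesignMatrices, model: AnimalModelREML) -> FitResult:
    engine = SparseREML(
        design.y,
        design.X,
        design.terms,
        max_iter=model.max_iter,
        rel_tol_loglik=model.rel_tol_loglik,
        rel_tol_params=model.rel_tol_params,
    )
    names = [t.name for t in design.terms] + ["residual"]
    res = engine.fit(_theta_from_start(model.start, names, design.y))
    if not res.converged:
        warnings.warn(
            f"REML did not reach the convergence criteria in {res.n_iter} iterations "
            f"(trait {model.trait!r}, variant {model.variant!r})",
            RuntimeWarning,
        )
    return _collect_fit(design, model, engine, res)


def _fit_pql(design: DesignMatrices, model: AnimalModelREML, max_outer: int = 50) -> FitResult:
    """Logit-link PQL with working-variate iteration.

    The working linear model is refitted by REML at each outer step with
    weights mu(1-mu); the residual variance parameter of the working model
    is the over/under-dispersion coefficient theta (the observation-scale
    residual is reported as 1, as is conventional for this fit).
    """
    y = design.y
    uy = np.unique(y)
    if not np.all(np.isin(uy, (0.0, 1.0))):
        raise ValueError("logit link requires a 0/1 response")
    if len(uy) < 2:
        raise ValueError("binary response is constant; nothing to fit")

    # separation diagnostic per replicate stratum
    rep_term = next(t for t in design.terms if t.name == "replicate")
    rep_idx = rep_term.Z.argmax(axis=1).A1 if hasattr(rep_term.Z, "A1") else np.asarray(
        rep_term.Z.argmax(axis=1)
    ).ravel()
    for lev in np.unique(rep_idx):
        vals = y[rep_idx == lev]
        if len(vals) > 1 and (vals.min() == vals.max()):
            warnings.warn(
                "complete separation: a replicate stratum has an all-0 or all-1 response",
                RuntimeWarning,
            )
            break

    mu = (y + 0.5) / 2.0
    eta = np.log(mu / (1 - mu))
    theta0 = None
    engine = res = None
    max_outer = min(max_outer, 30)
    damp = 0.5  # fixed-point damping; the binary animal model is runaway-prone

    def inner(z, w, theta0, final):
        eng = SparseREML(
            z,
            design.X,
            design.terms,
            weights=w,
            max_iter=min(model.max_iter, 60) if final else 15,
            rel_tol_loglik=max(model.rel_tol_loglik, 1e-9) if final else 1e-6,
            rel_tol_params=max(model.rel_tol_params, 1e-7) if final else 1e-4,
        )
        return eng, eng.fit(theta0)

    for outer in range(max_outer):
        w = np.clip(mu * (1 - mu), 1e-4, None)
        z = eta + (y - mu) / w
        engine, res = inner(z, w, theta0, final=False)
        theta0 = res.theta
        fitted = engine.M @ np.concatenate(
            [res.beta] + [res.u[t.name] for t in design.terms]
        )
        # engine rows are sqrt(w)-scaled; recover the unscaled linear predictor
        eta_new = fitted / np.sqrt(w)
        eta_new = eta + damp * (eta_new - eta)
        step = float(np.max(np.abs(eta_new - eta)))
        eta = np.clip(eta_new, -8.0, 8.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        if step < 1e-4:
            break
    else:
        warnings.warn("PQL outer loop hit its iteration cap", RuntimeWarning)
    # polish the variance components at the final working variates
    w = np.clip(mu * (1 - mu), 1e-4, None)
    z = eta + (y - mu) / w
    engine, res = inner(z, w, theta0, final=True)

    theta_names = [t.name for t in design.terms] + ["theta"]
    return _collect_fit(
        design,
        model,
        engine,
        res,
        theta_names=theta_names,
        link="logit",
        vc_overrides={"residual": 1.0},
    )


def compute_aic_value(loglik: float, n_free_varparams: int) -> float:
    """AIC of a REML fit: -2 logL + 2 t over the free variance parameters."""
    return -2.0 * loglik + 2.0 * n_free_varparams


def compute_aic(fit: FitResult) -> float:
    return compute_aic_value(fit.loglik, fit.n_free_varparams)


def fit_reml(
    phenotypes: pd.DataFrame, pedigree, trait: str, variant: str = "ablup_f", **kwargs
) -> FitResult:
    """Functional wrapper around :class:`AnimalModelREML` (identity link)."""
    est = AnimalModelREML(trait=trait, variant=variant, **kwargs)
    est.fit(phenotypes, pedigree)
    return est.result_


def fit_binary(
    phenotypes: pd.DataFrame, pedigree, trait: str, variant: str = "ablup_f", **kwargs
) -> FitResult:
    """Binary-trait (logit PQL) wrapper around :class:`AnimalModelREML`."""
    est = AnimalModelREML(trait=trait, variant=variant, link="logit", **kwargs)
    est.fit(phenotypes, pedigree)
    return est.result_


def solve_group_mme(
    design: DesignMatrices,
    varcomps: dict,
    pinned_groups: list | None = None,
) -> pd.Series:
    """Breeding values from the group-augmented MME at fixed components.

    Builds the sparse system over (groups + individuals) with the
    Quaas-style A-inverse of :func:`build_Ainv_with_groups` and solves it
    directly — the independent route against the explicit group-covariate
    fit.  ``pinned_groups`` are constrained to zero (the identification
    constraint; pass the groups whose explicit columns were dropped).
    Returns the group-inclusive breeding values per individual.
    """
    aug = design.aug
    g = aug.n_groups
    n = aug.n_individuals
    nrec = len(design.y)
    s2e = varcomps["residual"]
    s2g = varcomps["additive"]

    tree_idx = np.array([aug.index_of(t) for t in design.trees])
    Za = sp.csr_matrix(
        (np.ones(nrec), (np.arange(nrec), g + tree_idx)), shape=(nrec, g + n)
    )
    # fixed design without the group columns
    keep_x = [j for j, nm in enumerate(design.x_names) if nm not in design.group_cols]
    X = design.X[:, keep_x]
    X, _ = reduce_to_full_rank(X)
    blocks = [sp.csr_matrix(X), Za]
    binv = [sp.csr_matrix((X.shape[1], X.shape[1])), build_Ainv_with_groups(aug) / s2g]
    for t in design.terms:
        if t.name == "additive":
            continue
        blocks.append(t.Z)
        binv.append(sp.identity(t.q, format="csr") / varcomps[t.name])
    M = sp.hstack(blocks).tocsr()
    C = (M.T @ M) / s2e + sp.block_diag(binv)
    rhs = M.T @ design.y / s2e

    pinned = set(pinned_groups or [])
    pin_idx = [X.shape[1] + aug.equation_index(gr) for gr in pinned]
    keep = np.setdiff1d(np.arange(C.shape[0]), np.array(pin_idx, dtype=np.int64))
    C = C.tocsr()[keep][:, keep].tocsc()
    sol = sp.linalg.spsolve(C, rhs[keep])
    full = np.zeros(M.shape[1])
    full[keep] = sol
    ebv = full[X.shape[1] + g : X.shape[1] + g + n]
    return pd.Series(ebv, index=aug.individuals)
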