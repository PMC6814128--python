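"""Bivariate animal-model REML for genetic correlations.

Two record blocks ("slots") — two traits at one site, or one trait at two
sites — are stacked into a single mixed model

    Y = X b + Z g + Z r + Z r(s) + e

with Kronecker covariance structures: unstructured 2x2 additive
(co)variance times the pedigree ``A`` (``G1 (x) A``), diagonal 2x2
replicate and set-within-replicate structures (one variance per slot), and
an unstructured 2x2 residual within site (trees measured for both traits)
or a diagonal residual across sites (no tree is measured twice, so the
residual covariance is dropped from the model entirely).

The REML surface is maximised by a quasi-Newton search on a transformed
scale — log variances and atanh correlations — which keeps the 2x2
additive and residual blocks positive definite by construction (no
bending step is ever needed).  Standard errors come from the inverse
average-information matrix on the covariance scale at the optimum; the
genetic correlation SE is the delta method on (cov, var_1, var_2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize as sopt
import scipy.sparse as sp
import scipy.sparse.linalg as spl

from ._engine import LOG2PI, reduce_to_full_rank
from .models import AnimalModelREML, build_fixed_design
from .parameters import ParameterEstimate, genetic_correlation
from .pedigree import build_Ainv_with_groups, log_det_A

ATANH_CAP = 4.0  # |corr| <= tanh(4) ~ 0.99933


class IdentifiabilityError(ValueError):
    """The requested genetic covariance is not identified by the data."""


@dataclass
class BivariateFit:
    """Fitted 2-slot covariance structures and the genetic correlation."""

    slot_labels: tuple
    G1: pd.DataFrame  # 2x2 additive (co)variance
    G2: pd.DataFrame  # 2x2 diagonal replicate variances
    G3: pd.DataFrame  # 2x2 diagonal set-within-replicate variances
    R: pd.DataFrame  # 2x2 residual; off-diagonal fixed 0 across sites
    loglik: float
    rg: ParameterEstimate
    vcov_params: pd.DataFrame
    converged: bool
    n_obs: int
    residual_covariance: bool

    @property
    def genetic_correlation(self) -> float:
        return float(self.rg.value)


class _BivariateProblem:
    """Assembled stacked system; evaluates -2 logL over the parameter vector.

    Parameter order: g11, g12, g22, r1, r2, s1, s2, e11, [e12,] e22.
    """

    def __init__(self, slot_frames, value_cols, variant, aug, residual_covariance):
        self.aug = aug
        self.residual_covariance = residual_covariance
        self.n_ind = aug.n_individuals

        self.ainv = build_Ainv_with_groups(aug, include_groups=False).tocsc()
        self.logdet_a = log_det_A(aug)
        self._ainv_lu = None

        ys, Xblocks = [], []
        slot_of, tree_of = [], []
        self.frames = []
        for s, (df, col) in enumerate(zip(slot_frames, value_cols)):
            df = df.loc[df[col].notna()].reset_index(drop=True)
            if len(df) == 0:
                raise ValueError(f"slot {s} has no observations")
            self.frames.append(df)
            ys.append(df[col].to_numpy(dtype=float))
            X, names, _, _ = build_fixed_design(df, variant, aug)
            Xblocks.append((X, [f"s{s+1}:{nm}" for nm in names]))
            slot_of.append(np.full(len(df), s))
            tree_of.append(df["tree"].astype(str).to_numpy())
        self.y = np.concatenate(ys)
        self.n = len(self.y)
        self.slot_of = np.concatenate(slot_of)
        self.tree_of = np.concatenate(tree_of)

        X = np.zeros((self.n, sum(xb[0].shape[1] for xb in Xblocks)))
        ofs = r0 = 0
        self.x_names = []
        for Xb, names in Xblocks:
            X[r0 : r0 + Xb.shape[0], ofs : ofs + Xb.shape[1]] = Xb
            ofs += Xb.shape[1]
            r0 += Xb.shape[0]
            self.x_names.extend(names)
        self.X, _ = reduce_to_full_rank(X)
        self.p = self.X.shape[1]

        # additive incidence onto (slot, individual) equations
        tree_idx = np.array([aug.index_of(t) for t in self.tree_of])
        a_cols = self.slot_of * self.n_ind + tree_idx
        self.Za = sp.csr_matrix(
            (np.ones(self.n), (np.arange(self.n), a_cols)), shape=(self.n, 2 * self.n_ind)
        )
        self.Za_slot = [
            sp.csr_matrix(
                (
                    np.ones(int((self.slot_of == s).sum())),
                    (np.flatnonzero(self.slot_of == s), tree_idx[self.slot_of == s]),
                ),
                shape=(self.n, self.n_ind),
            )
            for s in (0, 1)
        ]

        # per-slot replicate and set-within-replicate terms
        self.iid_terms = []
        r0 = 0
        for s, df in enumerate(self.frames):
            for label, levels in (
                ("rep", df["replicate"].astype(str)),
                ("set", df["replicate"].astype(str) + "/" + df["set"].astype(str)),
            ):
                levs = sorted(levels.unique())
                codes = pd.Categorical(levels, categories=levs).codes
                Z = sp.csr_matrix(
                    (np.ones(len(df)), (r0 + np.arange(len(df)), codes)),
                    shape=(self.n, len(levs)),
                )
                self.iid_terms.append((f"{label}{s+1}", Z))
            r0 += len(df)

        # residual pairing: trees observed in both slots (within-site only)
        self.pair_rows = np.empty((0, 2), dtype=np.int64)
        if residual_covariance:
            n0 = int((self.slot_of == 0).sum())
            pos0 = {t: i for i, t in enumerate(self.tree_of[:n0])}
            pairs = [
                (pos0[t], n0 + j)
                for j, t in enumerate(self.tree_of[n0:])
                if t in pos0
            ]
            self.pair_rows = np.array(pairs, dtype=np.int64).reshape(-1, 2)

        self.M = sp.hstack(
            [sp.csr_matrix(self.X), self.Za] + [Z for _, Z in self.iid_terms]
        ).tocsr()
        self.offsets = {"additive": (self.p, self.p + 2 * self.n_ind)}
        pos = self.p + 2 * self.n_ind
        for nm, Z in self.iid_terms:
            self.offsets[nm] = (pos, pos + Z.shape[1])
            pos += Z.shape[1]
        self.dim = pos

        # precomputed pieces of M' R^{-1} M: per-slot crossproducts and, for
        # paired residuals, the pair-row crossproducts (coefficients depend
        # on the residual parameters only)
        m0 = self.slot_of == 0
        M0 = self.M.multiply(m0[:, None].astype(float)).tocsr()
        M1 = self.M.multiply((~m0)[:, None].astype(float)).tocsr()
        self._MtM0 = (M0.T @ M0).tocsr()
        self._MtM1 = (M1.T @ M1).tocsr()
        if len(self.pair_rows):
            P0 = self.M[self.pair_rows[:, 0]]
            P1 = self.M[self.pair_rows[:, 1]]
            self._PtP0 = (P0.T @ P0).tocsr()
            self._PtP1 = (P1.T @ P1).tocsr()
            cross = (P0.T @ P1).tocsr()
            self._PtX = (cross + cross.T).tocsr()
        else:
            self._PtP0 = self._PtP1 = self._PtX = None

        self.param_names = ["g11", "g12", "g22", "r1", "r2", "s1", "s2", "e11"]
        if residual_covariance:
            self.param_names += ["e12"]
        self.param_names += ["e22"]

    # ---- parameter handling ----------------------------------------------
    def theta_to_mats(self, theta):
        d = dict(zip(self.param_names, theta))
        G1 = np.array([[d["g11"], d["g12"]], [d["g12"], d["g22"]]])
        R = np.array([[d["e11"], d.get("e12", 0.0)], [d.get("e12", 0.0), d["e22"]]])
        iid = [d["r1"], d["r2"], d["s1"], d["s2"]]
        return G1, iid, R

    def transform(self, theta):
        """Covariance scale -> unconstrained optimiser scale."""
        G1, iid, R = self.theta_to_mats(theta)
        out = [
            np.log(G1[0, 0]),
            np.log(G1[1, 1]),
            np.arctanh(np.clip(G1[0, 1] / np.sqrt(G1[0, 0] * G1[1, 1]), -0.999, 0.999)),
        ]
        out += [np.log(v) for v in iid]
        out += [np.log(R[0, 0]), np.log(R[1, 1])]
        if self.residual_covariance:
            out += [np.arctanh(np.clip(R[0, 1] / np.sqrt(R[0, 0] * R[1, 1]), -0.999, 0.999))]
        return np.array(out)

    def untransform(self, phi):
        g11, g22 = np.exp(phi[0]), np.exp(phi[1])
        g12 = np.tanh(np.clip(phi[2], -ATANH_CAP, ATANH_CAP)) * np.sqrt(g11 * g22)
        r1, r2, s1, s2 = np.exp(phi[3:7])
        e11, e22 = np.exp(phi[7]), np.exp(phi[8])
        theta = [g11, g12, g22, r1, r2, s1, s2, e11]
        if self.residual_covariance:
            e12 = np.tanh(np.clip(phi[9], -ATANH_CAP, ATANH_CAP)) * np.sqrt(e11 * e22)
            theta += [e12]
        theta += [e22]
        return np.array(theta)

    # ---- likelihood -------------------------------------------------------
    def _w_blocks(self, R):
        """Residual inverse as a sparse matrix plus log|R|."""
        n = self.n
        e = np.where(self.slot_of == 0, R[0, 0], R[1, 1]).astype(float)
        vals = (1.0 / e).tolist()
        logdet_r = float(np.log(e).sum())
        rows = list(range(n))
        cols = list(range(n))
        if self.residual_covariance and len(self.pair_rows):
            det = R[0, 0] * R[1, 1] - R[0, 1] ** 2
            for i0, i1 in self.pair_rows:
                vals[i0] = R[1, 1] / det
                vals[i1] = R[0, 0] / det
                rows += [i0, i1]
                cols += [i1, i0]
                vals += [-R[0, 1] / det, -R[0, 1] / det]
                logdet_r += float(np.log(det) - np.log(R[0, 0] * R[1, 1]))
        W = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        return W, logdet_r

    def _C(self, theta):
        G1, iid, R = self.theta_to_mats(theta)
        W, logdet_r = self._w_blocks(R)
        # M'WM from the precomputed crossproducts
        C = self._MtM0 * (1.0 / R[0, 0]) + self._MtM1 * (1.0 / R[1, 1])
        if self.residual_covariance and self._PtP0 is not None:
            det = R[0, 0] * R[1, 1] - R[0, 1] ** 2
            C = (
                C
                + self._PtP0 * (R[1, 1] / det - 1.0 / R[0, 0])
                + self._PtP1 * (R[0, 0] / det - 1.0 / R[1, 1])
                + self._PtX * (-R[0, 1] / det)
            )
        G1inv = np.linalg.inv(G1)
        o = self.offsets["additive"][0]
        big = sp.kron(sp.csr_matrix(G1inv), self.ainv, format="csr")
        pad_pre = sp.csr_matrix((o, o))
        pad_post_dim = self.dim - o - 2 * self.n_ind
        pad_post = sp.csr_matrix((pad_post_dim, pad_post_dim))
        C = C + sp.block_diag([pad_pre, big, pad_post], format="csr")
        for k, (nm, _) in enumerate(self.iid_terms):
            a, b = self.offsets[nm]
            idx = np.arange(a, b)
            C = C + sp.csr_matrix(
                (np.full(b - a, 1.0 / iid[k]), (idx, idx)), shape=(self.dim, self.dim)
            )
        logdet_g = (
            self.n_ind * np.log(max(np.linalg.det(G1), 1e-300))
            + 2.0 * self.logdet_a
            + sum(
                Z.shape[1] * np.log(v)
                for v, (_, Z) in zip(iid, self.iid_terms)
            )
        )
        return C.tocsc(), W, logdet_r, logdet_g

    def neg2_loglik(self, theta, want_solution=False):
        C, W, logdet_r, logdet_g = self._C(theta)
        lu = spl.splu(C, permc_spec="MMD_AT_PLUS_A", options=dict(SymmetricMode=True))
        logdet_c = float(np.log(np.abs(lu.U.diagonal())).sum())
        Wy = W @ self.y
        rhs = self.M.T @ Wy
        sol = lu.solve(rhs)
        ypy = float(self.y @ Wy - sol @ rhs)
        neg2 = logdet_r + logdet_g + logdet_c + ypy + (self.n - self.p) * LOG2PI
        if want_solution:
            return neg2, sol, lu, W
        return neg2

    # ---- average information at the optimum -------------------------------
    def ai_matrix(self, theta):
        neg2, sol, lu, W = self.neg2_loglik(theta, want_solution=True)
        py = W @ (self.y - self.M @ sol)
        if self._ainv_lu is None:
            self._ainv_lu = spl.splu(
                self.ainv, permc_spec="MMD_AT_PLUS_A", options=dict(SymmetricMode=True)
            )
        x = [self._ainv_lu.solve(np.asarray((Z.T @ py)).ravel()) for Z in self.Za_slot]
        yk = {
            "g11": self.Za_slot[0] @ x[0],
            "g12": self.Za_slot[0] @ x[1] + self.Za_slot[1] @ x[0],
            "g22": self.Za_slot[1] @ x[1],
        }
        for k, (nm, Z) in enumerate(self.iid_terms):
            yk[["r1", "r2", "s1", "s2"][k]] = Z @ (Z.T @ py)
        m0 = self.slot_of == 0
        yk["e11"] = np.where(m0, py, 0.0)
        yk["e22"] = np.where(~m0, py, 0.0)
        if self.residual_covariance:
            v = np.zeros(self.n)
            if len(self.pair_rows):
                v[self.pair_rows[:, 0]] = py[self.pair_rows[:, 1]]
                v[self.pair_rows[:, 1]] = py[self.pair_rows[:, 0]]
            yk["e12"] = v

        def P(v):
            wv = W @ v
            return wv - W @ (self.M @ lu.solve(self.M.T @ wv))

        names = self.param_names
        pv = {nm: P(yk[nm]) for nm in names}
        AI = np.zeros((len(names), len(names)))
        for a in range(len(names)):
            for b in range(a, len(names)):
                AI[a, b] = AI[b, a] = 0.5 * float(yk[names[a]] @ pv[names[b]])
        return AI


def _univariate_starts(frame, col, variant, aug):
    est = AnimalModelREML(
        trait=col,
        variant=variant,
        compute_pev=False,
        max_iter=50,
        rel_tol_loglik=1e-6,
        rel_tol_params=1e-4,
    )
    est.fit(frame, aug)
    c = est.varcomp_.components
    return c["additive"], c["replicate"], c["set_within_rep"], c["residual"]


def _fit_bivariate(
    slot_frames,
    value_cols,
    variant,
    aug,
    residual_covariance,
    slot_labels,
    starts=None,
    maxiter=250,
):
    prob = _BivariateProblem(list(slot_frames), value_cols, variant, aug, residual_covariance)
    if starts is None:
        s = [
            _univariate_starts(df, col, variant, aug)
            for df, col in zip(prob.frames, value_cols)
        ]
        g11, r1, s1v, e11 = s[0]
        g22, r2, s2v, e22 = s[1]
        floor = 1e-8 * max(e11, e22, g11, g22, 1e-12)
        theta0 = np.array(
            [
                max(g11, floor),
                0.1 * np.sqrt(max(g11, floor) * max(g22, floor)),
                max(g22, floor),
                max(r1, floor),
                max(r2, floor),
                max(s1v, floor),
                max(s2v, floor),
                max(e11, floor),
            ]
            + ([0.0] if residual_covariance else [])
            + [max(e22, floor)]
        )
    else:
        theta0 = np.asarray(starts, dtype=float)
    phi0 = prob.transform(theta0)

    def obj(phi):
        try:
            return prob.neg2_loglik(prob.untransform(phi))
        except (RuntimeError, np.linalg.LinAlgError):
            # numerically singular system (degenerate corner of the
            # correlation cube): steer the search away
            return 1e12

    opt = sopt.minimize(
        obj, phi0, method="L-BFGS-B", options=dict(maxiter=maxiter, ftol=1e-10, gtol=1e-5)
    )
    theta = prob.untransform(opt.x)
    converged = bool(opt.success or opt.status == 1)
    if not converged:
        warnings.warn(f"bivariate REML: {opt.message}", RuntimeWarning)

    try:
        AI = prob.ai_matrix(theta)
        vcov = np.linalg.inv(AI)
    except (RuntimeError, np.linalg.LinAlgError):
        try:
            vcov = np.linalg.pinv(AI)
        except Exception:
            vcov = np.full((len(prob.param_names),) * 2, np.nan)
    names = prob.param_names
    vcov = pd.DataFrame(vcov, index=names, columns=names)
    d = dict(zip(names, theta))
    idx3 = ["g12", "g11", "g22"]
    rg = genetic_correlation(d["g12"], d["g11"], d["g22"], vcov.loc[idx3, idx3].to_numpy())

    lab = list(slot_labels)
    G1 = pd.DataFrame([[d["g11"], d["g12"]], [d["g12"], d["g22"]]], index=lab, columns=lab)
    G2 = pd.DataFrame(np.diag([d["r1"], d["r2"]]), index=lab, columns=lab)
    G3 = pd.DataFrame(np.diag([d["s1"], d["s2"]]), index=lab, columns=lab)
    R = pd.DataFrame(
        [[d["e11"], d.get("e12", 0.0)], [d.get("e12", 0.0), d["e22"]]], index=lab, columns=lab
    )
    return BivariateFit(
        slot_labels=tuple(lab),
        G1=G1,
        G2=G2,
        G3=G3,
        R=R,
        loglik=-0.5 * float(opt.fun),
        rg=rg,
        vcov_params=vcov,
        converged=converged,
        n_obs=prob.n,
        residual_covariance=residual_covariance,
    )


def fit_bivariate_within_site(
    table, trait_i, trait_j, variant="ablup_f", pedigree=None, starts=None, maxiter=250
) -> BivariateFit:
    """Genetic correlation between two traits measured at one site.

    Records missing one trait are kept for the other; the residual
    covariance applies only to trees measured for both.
    """
    for tr in (trait_i, trait_j):
        if tr not in table.columns:
            raise ValueError(f"trait {tr!r} not in the phenotype table")
    aug = AnimalModelREML(variant=variant)._augment(pedigree)
    return _fit_bivariate(
        [table.copy(), table.copy()],
        [trait_i, trait_j],
        variant,
        aug,
        residual_covariance=True,
        slot_labels=(trait_i, trait_j),
        starts=starts,
        maxiter=maxiter,
    )


def fit_bivariate_cross_site(
    table_a, table_b, trait, variant="ablup_f", pedigree=None, starts=None, maxiter=250
) -> BivariateFit:
    """Genetic correlation of one trait across two sites (GxE).

    No tree may appear on both sites; the residual covariance is fixed at
    zero (absent from the model), and the genetic covariance is identified
    through families shared across sites — absent that, an
    :class:`IdentifiabilityError` is raised.
    """
    def _noncontrol_trees(t):
        sub = t.loc[t[trait].notna()]
        if "control" in sub.columns:
            ctrl = sub["control"].fillna("").astype(str)
            sub = sub.loc[ctrl.isin(["", "0", "False", "false"])]
        return set(sub["tree"].astype(str))

    ta = _noncontrol_trees(table_a)
    tb = _noncontrol_trees(table_b)
    if ta & tb:
        raise ValueError("a pedigreed tree appears on both sites; sites must be disjoint")
    aug = AnimalModelREML(variant=variant)._augment(pedigree)
    dam_of = {r.individual: r.dam for r in aug.records}
    fam_a = {dam_of.get(t, "") for t in ta} - {""}
    fam_b = {dam_of.get(t, "") for t in tb} - {""}
    shared = {f for f in (fam_a & fam_b) if not aug.is_group(f)}
    if not shared:
        raise IdentifiabilityError(
            "no families shared across sites; the cross-site genetic covariance "
            "is not identified"
        )
    site_a = str(table_a["site"].iloc[0]) if "site" in table_a.columns else "siteA"
    site_b = str(table_b["site"].iloc[0]) if "site" in table_b.columns else "siteB"
    return _fit_bivariate(
        [table_a.copy(), table_b.copy()],
        [trait, trait],
        variant,
        aug,
        residual_covariance=False,
        slot_labels=(site_a, site_b),
        starts=starts,
        maxiter=maxiter,
    )


class BivariateREML:
    """Estimator-style wrapper for bivariate fits.

    ``mode="within_site"`` expects one phenotype table and two trait
    columns; ``mode="cross_site"`` expects the two sites' tables and one
    trait.  Fitted attributes: ``fit_``, ``rg_``, ``loglik_``.
    """

    def __init__(self, trait_i="y", trait_j="y", variant="ablup_f", mode="within_site", maxiter=250):
        self.trait_i = trait_i
        self.trait_j = trait_j
        self.variant = variant
        self.mode = mode
        self.maxiter = maxiter

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in ("trait_i", "trait_j", "variant", "mode", "maxiter")}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, phenotypes, pedigree, phenotypes_b=None):
        if self.mode == "within_site":
            self.fit_ = fit_bivariate_within_site(
                phenotypes, self.trait_i, self.trait_j, self.variant, pedigree, maxiter=self.maxiter
            )
        elif self.mode == "cross_site":
            if phenotypes_b is None:
                raise ValueError("cross_site mode needs the second site's table")
            self.fit_ = fit_bivariate_cross_site(
                phenotypes, phenotypes_b, self.trait_i, self.variant, pedigree, maxiter=self.maxiter
            )
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        self.rg_ = self.fit_.rg
        self.loglik_ = self.fit_.loglik
        return self
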