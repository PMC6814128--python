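"""Sparse average-information REML for univariate mixed models.

Solves Henderson's mixed-model equations for

    y = X b + sum_k Z_k u_k + e,   u_k ~ N(0, G_k sigma2_k),  e ~ N(0, W^{-1} sigma2_e)

with sparse ``G_k^{-1}`` (pedigree A-inverse, or identity), and maximises
the residual likelihood over the variance parameters by Newton steps using
the average-information matrix, with step halving and EM-flavoured
fallbacks.  All likelihood pieces are exact: the coefficient matrix is
factorised by block elimination of a mutually uncoupled subset of the
random-effect equations (in progeny-trial pedigrees, the terminal
offspring), leaving a small dense core whose inverse provides the selected
elements of ``C^{-1}`` needed for exact REML first derivatives.

Known weights ``w`` enter by scaling rows with ``sqrt(w)``; the residual
log-determinant correction ``-sum log w`` is carried in the constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

LOG2PI = float(np.log(2.0 * np.pi))


class ConvergenceError(RuntimeError):
    """REML iteration failed to converge within the iteration cap."""


@dataclass
class RandomTerm:
    """One random effect: incidence ``Z`` and inverse covariance structure."""

    name: str
    Z: sp.csr_matrix
    ginv: sp.csr_matrix | None = None  # None -> identity
    logdet_g: float = 0.0  # log|G| (0 for identity)

    @property
    def q(self) -> int:
        return self.Z.shape[1]


def reduce_to_full_rank(X: np.ndarray, tol: float = 1e-8):
    """Drop trailing linearly dependent columns, keeping earlier ones.

    Returns (X_reduced, kept_indices).  Deterministic: columns are scanned
    left to right and kept when they add rank.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    kept = []
    basis = np.zeros((n, 0))
    for j in range(p):
        col = X[:, j]
        nrm = np.linalg.norm(col)
        if nrm == 0:
            continue
        resid = col - basis @ (basis.T @ col)
        # reorthogonalise once for numerical safety
        resid -= basis @ (basis.T @ resid)
        if np.linalg.norm(resid) > tol * nrm:
            kept.append(j)
            basis = np.hstack([basis, (resid / np.linalg.norm(resid))[:, None]])
    return X[:, kept], kept


class _Factor:
    """Block-elimination factorisation of the MME coefficient matrix.

    The equation set ``E`` (pattern-wise mutually uncoupled) is absorbed,
    leaving a dense Cholesky of the Schur complement on the remaining
    equations.  Provides solves, log-determinant and the selected entries
    of the inverse needed for REML traces.
    """

    def __init__(self, C: sp.csr_matrix, e_idx: np.ndarray, r_idx: np.ndarray):
        self.e_idx = e_idx
        self.r_idx = r_idx
        self.dim = C.shape[0]
        Ce = C[e_idx]
        self.d = np.asarray(Ce[:, e_idx].diagonal())
        if np.any(self.d <= 0):
            raise np.linalg.LinAlgError("non-positive pivot in absorbed block")
        self.U = Ce[:, r_idx].tocsr()
        S = np.asarray(C[r_idx][:, r_idx].todense())
        Ud = self.U.multiply(1.0 / self.d[:, None]).tocsr()
        S -= (self.U.T @ Ud).toarray()
        self._Ud = Ud
        self.cho = sla.cho_factor(S, lower=True, check_finite=False)
        self.logdet = float(np.log(self.d).sum() + 2.0 * np.log(np.diag(self.cho[0])).sum())
        self._Rinv = None

    def solve(self, b: np.ndarray) -> np.ndarray:
        b = np.asarray(b, dtype=float)
        one_d = b.ndim == 1
        if one_d:
            b = b[:, None]
        be = b[self.e_idx]
        br = b[self.r_idx]
        rhs = br - self.U.T @ (be / self.d[:, None])
        xr = sla.cho_solve(self.cho, rhs, check_finite=False)
        xe = (be - self.U @ xr) / self.d[:, None]
        out = np.empty_like(b)
        out[self.e_idx] = xe
        out[self.r_idx] = xr
        return out[:, 0] if one_d else out

    @property
    def core_inverse(self) -> np.ndarray:
        """Dense inverse of the Schur complement (C^{-1} on the core block)."""
        if self._Rinv is None:
            eye = np.eye(len(self.r_idx))
            self._Rinv = sla.cho_solve(self.cho, eye, check_finite=False)
        return self._Rinv

    def inverse_entries(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Selected entries ``C^{-1}[rows, cols]``.

        Supported patterns: both indices on the core block, both equal and
        anywhere, or one absorbed / one core index.  Entries between two
        distinct absorbed equations are zero-coupled by construction and
        are not supported.
        """
        pos = np.full(self.dim, -1, dtype=np.int64)
        pos[self.r_idx] = np.arange(len(self.r_idx))
        epos = np.full(self.dim, -1, dtype=np.int64)
        epos[self.e_idx] = np.arange(len(self.e_idx))
        R = self.core_inverse
        out = np.empty(len(rows))
        rows = np.asarray(rows)
        cols = np.asarray(cols)

        in_core_r = pos[rows] >= 0
        in_core_c = pos[cols] >= 0
        # core-core
        m = in_core_r & in_core_c
        out[m] = R[pos[rows[m]], pos[cols[m]]]
        # absorbed diagonal: 1/d + u' R u / d^2
        m = ~in_core_r & ~in_core_c
        if np.any(m):
            if np.any(rows[m] != cols[m]):
                raise ValueError("off-diagonal entries between absorbed equations")
            ei = epos[rows[m]]
            quad = self._absorbed_quad(ei)
            out[m] = 1.0 / self.d[ei] + quad / self.d[ei] ** 2
        # mixed: -(R u_e)_r / d_e
        for m, e_side in (((~in_core_r) & in_core_c, "row"), (in_core_r & ~in_core_c, "col")):
            if not np.any(m):
                continue
            ei = epos[rows[m]] if e_side == "row" else epos[cols[m]]
            rj = pos[cols[m]] if e_side == "row" else pos[rows[m]]
            vals = np.zeros(m.sum())
            U = self.U
            for t, (e, j) in enumerate(zip(ei, rj)):
                sl = slice(U.indptr[e], U.indptr[e + 1])
                vals[t] = U.data[sl] @ R[U.indices[sl], j]
            out[m] = -vals / self.d[ei]
        return out

    def _absorbed_quad(self, ei: np.ndarray) -> np.ndarray:
        """u_e' R u_e for absorbed equations ``ei`` (vectorised)."""
        U, R = self.U, self.core_inverse
        quad = np.zeros(len(ei))
        for t, e in enumerate(ei):
            sl = slice(U.indptr[e], U.indptr[e + 1])
            idx = U.indices[sl]
            v = U.data[sl]
            quad[t] = v @ R[np.ix_(idx, idx)] @ v
        return quad


def _independent_set(C: sp.csr_matrix, candidates: np.ndarray) -> np.ndarray:
    """Greedy pattern-independent subset of ``candidates`` (low degree first)."""
    Cc = C.tocsr()
    cand = set(int(i) for i in candidates)
    deg = np.asarray((Cc != 0).sum(axis=1)).ravel()
    order = sorted(cand, key=lambda i: (deg[i], i))
    selected = set()
    blocked = set()
    for i in order:
        if i in blocked:
            continue
        sl = slice(Cc.indptr[i], Cc.indptr[i + 1])
        nbrs = Cc.indices[sl]
        if any((j in selected) for j in nbrs if j != i):
            continue
        selected.add(i)
        blocked.update(int(j) for j in nbrs if j != i and j in cand)
    return np.array(sorted(selected), dtype=np.int64)


@dataclass
class REMLResult:
    theta: np.ndarray  # variance components, residual last
    names: list
    loglik: float
    beta: np.ndarray
    u: dict  # term name -> solution vector
    vcov_theta: np.ndarray
    boundary: np.ndarray
    converged: bool
    n_iter: int
    n_obs: int
    p_fixed: int
    trace: list = field(default_factory=list)
    factor: "_Factor" = None
    offsets: dict = None
    dense_max: int = 2000


class SparseREML:
    """REML engine over one response with arbitrary sparse random terms."""

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        terms: list,
        weights: np.ndarray | None = None,
        max_iter: int = 200,
        rel_tol_loglik: float = 1e-8,
        rel_tol_params: float = 1e-6,
        var_floor_frac: float = 1e-10,
    ):
        y = np.asarray(y, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != len(y):
            raise ValueError("X and y disagree on the number of records")
        self.n = len(y)
        self.terms = terms
        self.max_iter = max_iter
        self.rel_tol_loglik = rel_tol_loglik
        self.rel_tol_params = rel_tol_params

        if weights is None:
            sw = None
            self.const_logw = 0.0
        else:
            weights = np.asarray(weights, dtype=float)
            sw = np.sqrt(weights)
            self.const_logw = -float(np.log(weights).sum())

        X, self.kept_cols = reduce_to_full_rank(X)
        self.p = X.shape[1]
        Xs = X * sw[:, None] if sw is not None else X
        self.ys = y * sw if sw is not None else y

        blocks = [sp.csr_matrix(Xs)]
        self.offsets = {}
        pos = self.p
        for t in terms:
            Zs = t.Z.multiply(sw[:, None]).tocsr() if sw is not None else t.Z
            blocks.append(Zs)
            self.offsets[t.name] = (pos, pos + t.q)
            pos += t.q
        self.dim = pos
        M = sp.hstack(blocks).tocsr()
        self.M = M
        self.MtM = (M.T @ M).tocsr()
        self.Mty = M.T @ self.ys
        self.yty = float(self.ys @ self.ys)
        self.var_floor = var_floor_frac * max(float(np.var(y)), 1e-12)

        # inverse-structure template: block-diagonal ginv contributions
        rows, cols, vals = [], [], []
        for t in terms:
            o = self.offsets[t.name][0]
            if t.ginv is None:
                rows.extend(range(o, o + t.q))
                cols.extend(range(o, o + t.q))
                vals.extend([1.0] * t.q)
            else:
                g = t.ginv.tocoo()
                rows.extend((g.row + o).tolist())
                cols.extend((g.col + o).tolist())
                vals.extend(g.data.tolist())
        self._B_parts = {}
        start = 0
        # store each term's expanded ginv separately for fast C assembly
        for t in terms:
            o = self.offsets[t.name][0]
            if t.ginv is None:
                B = sp.csr_matrix(
                    (np.ones(t.q), (np.arange(o, o + t.q), np.arange(o, o + t.q))),
                    shape=(self.dim, self.dim),
                )
            else:
                g = t.ginv.tocoo()
                B = sp.csr_matrix((g.data, (g.row + o, g.col + o)), shape=(self.dim, self.dim))
            self._B_parts[t.name] = B

        self._absorb_plan = None

    # -- assembly -----------------------------------------------------------
    def _C(self, theta: np.ndarray) -> sp.csr_matrix:
        C = self.MtM * (1.0 / theta[-1])
        for k, t in enumerate(self.terms):
            C = C + self._B_parts[t.name] * (1.0 / theta[k])
        return C.tocsr()

    def _plan(self, C: sp.csr_matrix):
        if self._absorb_plan is not None:
            return self._absorb_plan
        if self.dim <= 1500:
            e_idx = np.array([], dtype=np.int64)
        else:
            cand = []
            for t in self.terms:
                if t.q > 500:
                    o = self.offsets[t.name]
                    cand.extend(range(o[0], o[1]))
            e_idx = _independent_set(C, np.array(cand, dtype=np.int64))
        r_idx = np.setdiff1d(np.arange(self.dim), e_idx)
        if len(r_idx) > 4000:
            raise MemoryError(
                f"dense core of {len(r_idx)} equations is too large; "
                "the absorbed-block REML engine needs a sparser structure"
            )
        self._absorb_plan = (e_idx, r_idx)
        return self._absorb_plan

    def _factorise(self, theta: np.ndarray) -> _Factor:
        C = self._C(theta)
        e_idx, r_idx = self._plan(C)
        return _Factor(C, e_idx, r_idx)

    # -- likelihood ---------------------------------------------------------
    def _loglik_parts(self, theta: np.ndarray, factor: _Factor | None = None):
        if factor is None:
            factor = self._factorise(theta)
        sol = factor.solve(self.Mty / theta[-1])
        ypy = (self.yty / theta[-1]) - sol @ (self.Mty / theta[-1])
        neg2 = factor.logdet + self.n * np.log(theta[-1]) + ypy + self.const_logw
        for k, t in enumerate(self.terms):
            neg2 += t.q * np.log(theta[k]) + t.logdet_g
        neg2 += (self.n - self.p) * LOG2PI
        return -0.5 * neg2, sol, ypy, factor

    def loglik(self, theta: np.ndarray) -> float:
        return self._loglik_parts(theta)[0]

    # -- derivatives --------------------------------------------------------
    def _trace_ginv_cinv(self, factor: _Factor, term: RandomTerm) -> float:
        """tr(G_k^{-1} C^{kk}) for one random term."""
        o = self.offsets[term.name][0]
        if term.ginv is None:
            idx = np.arange(o, o + term.q)
            return float(factor.inverse_entries(idx, idx).sum())
        g = term.ginv.tocoo()
        ent = factor.inverse_entries(g.row + o, g.col + o)
        return float(g.data @ ent)

    def _score_and_traces(self, theta, factor, sol, ypy):
        K = len(self.terms)
        score = np.zeros(K + 1)
        tr_pv = np.zeros(K + 1)
        for k, t in enumerate(self.terms):
            o = self.offsets[t.name]
            u = sol[o[0] : o[1]]
            gu = u if t.ginv is None else t.ginv @ u
            ugu = float(u @ gu)
            tr = self._trace_ginv_cinv(factor, t)
            tr_pv[k] = (t.q - tr / theta[k]) / theta[k]
            score[k] = -0.5 * (tr_pv[k] - ugu / theta[k] ** 2)
        # residual via tr(PV) = n - p
        resid_scaled = self.ys - self.M @ sol
        py = resid_scaled / theta[-1]
        tr_pv[-1] = (self.n - self.p - float(theta[:-1] @ tr_pv[:-1])) / theta[-1]
        score[-1] = -0.5 * (tr_pv[-1] - float(py @ py))
        return score, py, tr_pv

    def _ai_matrix(self, theta, factor, sol, py):
        K = len(self.terms)
        ny = []
        for k, t in enumerate(self.terms):
            o = self.offsets[t.name]
            ny.append(t.Z @ sol[o[0] : o[1]] / theta[k])
        ny.append(py)
        AI = np.zeros((K + 1, K + 1))
        pv = []
        for v in ny:
            rhs = self.M.T @ v / theta[-1]
            w = factor.solve(rhs)
            pv.append((v - self.M @ w) / theta[-1])
        for a in range(K + 1):
            for b in range(a, K + 1):
                AI[a, b] = AI[b, a] = 0.5 * float(ny[a] @ pv[b])
        return AI

    # -- main loop ----------------------------------------------------------
    def fit(self, theta0: np.ndarray | None = None) -> REMLResult:
        K = len(self.terms)
        vy = max(float(np.var(self.ys)), self.var_floor * 10)
        if theta0 is None:
            theta = np.full(K + 1, 0.0)
            theta[:-1] = 0.5 * vy / max(K, 1)
            theta[-1] = 0.5 * vy
        else:
            theta = np.asarray(theta0, dtype=float).copy()
        theta = np.maximum(theta, self.var_floor)

        ll, sol, ypy, factor = self._loglik_parts(theta)
        history = [ll]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            score, py, tr_pv = self._score_and_traces(theta, factor, sol, ypy)
            # active set: parameters at the floor whose gradient points
            # further out stay fixed there this iteration
            at_floor = theta <= self.var_floor * (1 + 1e-8)
            active = ~(at_floor & (score < 0))
            if not np.any(active):
                converged = True
                break
            AI = self._ai_matrix(theta, factor, sol, py)
            ia = np.flatnonzero(active)
            step = None
            try:
                sub = AI[np.ix_(ia, ia)]
                step_a = np.linalg.solve(sub + 1e-12 * np.eye(len(ia)) * np.trace(sub), score[ia])
                step = np.zeros(K + 1)
                step[ia] = step_a
            except np.linalg.LinAlgError:
                step = None
            accepted = False
            if step is not None:
                # cap each proposal: flat (ridge-like) directions otherwise
                # produce wild steps and waste line-search factorisations
                cap = 2.0 * np.abs(theta) + 0.5 * np.var(self.ys) + self.var_floor
                step = np.clip(step, -cap, cap)
                frac = 1.0
                for _ in range(8):
                    cand = np.maximum(theta + frac * step, self.var_floor)
                    try:
                        ll_new, sol_new, ypy_new, factor_new = self._loglik_parts(cand)
                    except (np.linalg.LinAlgError, MemoryError):
                        frac *= 0.5
                        continue
                    if ll_new >= ll - 1e-10:
                        accepted = True
                        break
                    frac *= 0.5
            if not accepted:
                # EM-flavoured fallback: guaranteed-direction update
                cand = theta.copy()
                for k, t in enumerate(self.terms):
                    if not active[k]:
                        continue
                    o = self.offsets[t.name]
                    u = sol[o[0] : o[1]]
                    gu = u if t.ginv is None else t.ginv @ u
                    tr = self._trace_ginv_cinv(factor, t)
                    cand[k] = max((float(u @ gu) + tr) / t.q, self.var_floor)
                if active[-1]:
                    cand[-1] = max(theta[-1] * ypy / max(self.n - self.p, 1), self.var_floor)
                ll_new, sol_new, ypy_new, factor_new = self._loglik_parts(cand)
                if ll_new < ll - 1e-8 * max(abs(ll), 1.0):
                    # EM failed to improve as well: stop at current point
                    break
            d_ll = abs(ll_new - ll) / max(abs(ll_new), 1.0)
            rel = np.abs(cand - theta) / np.maximum(np.abs(theta), self.var_floor * 10)
            d_th = np.max(rel[ia]) if len(ia) else 0.0
            theta, ll, sol, ypy, factor = cand, ll_new, sol_new, ypy_new, factor_new
            history.append(ll)
            if d_ll < self.rel_tol_loglik and d_th < self.rel_tol_params:
                converged = True
                break

        score, py, tr_pv = self._score_and_traces(theta, factor, sol, ypy)
        AI = self._ai_matrix(theta, factor, sol, py)
        try:
            vcov = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(AI)
        boundary = theta <= self.var_floor * (1 + 1e-6)
        u = {}
        for t in self.terms:
            o = self.offsets[t.name]
            u[t.name] = sol[o[0] : o[1]].copy()
        return REMLResult(
            theta=theta,
            names=[t.name for t in self.terms] + ["residual"],
            loglik=float(ll),
            beta=sol[: self.p].copy(),
            u=u,
            vcov_theta=vcov,
            boundary=boundary,
            converged=converged,
            n_iter=it,
            n_obs=self.n,
            p_fixed=self.p,
            trace=history,
            factor=factor,
            offsets=dict(self.offsets),
        )

    # -- prediction error variance ------------------------------------------
    def pev(self, result: REMLResult, term: str, indices: np.ndarray, fixed_weights=None):
        """PEV of selected effects of ``term`` (optionally plus fixed columns).

        ``fixed_weights``: optional (len(indices), p) array ``Q`` giving, per
        requested effect, weights on the fixed columns so that the PEV is
        var(Q b_hat + u_hat - u); used for group-inclusive breeding values.
        Computed column-by-column through the factorisation.
        """
        o = self.offsets[term][0]
        factor = result.factor
        out = np.empty(len(indices))
        for t, i in enumerate(np.asarray(indices)):
            v = np.zeros(self.dim)
            v[o + i] = 1.0
            if fixed_weights is not None:
                v[: self.p] = fixed_weights[t]
            out[t] = float(v @ factor.solve(v))
        return out
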