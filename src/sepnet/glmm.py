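"""Crossed sender/receiver random-effects logistic regression.

The separable tie models are logistic regressions with two crossed Gaussian
random effects: a sender effect ``theta_i ~ N(0, sigma^2)`` for the
nominating actor and a receiver effect ``eta_j ~ N(0, tau^2)`` for the
nominated actor, entering additively on the logit scale alongside the fixed
effects (intercept, exam dummies, lagged inbound-tie term, trait and control
predictors).

Estimation is Laplace-approximate maximum likelihood.  For candidate
variance components the inner loop finds the joint conditional mode of
(beta, theta, eta) by penalized iteratively reweighted least squares,
exploiting the crossed structure: the sender and receiver blocks of the
Hessian are diagonal, so one block is eliminated diagonally and only the
other requires a dense Cholesky factorization.  The outer loop maximizes
the Laplace log-likelihood over (log sigma, log tau) with Nelder-Mead.
Standard errors for the fixed effects come from the profiled observed
information (variance components held at their estimates), and p-values are
two-tailed normal tail probabilities of the Wald z-statistics.

A tensor-product Gauss-Hermite quadrature evaluation of the exact marginal
likelihood is provided for tiny instances (at most 8 random effects in
total) and serves as an independent oracle for the Laplace machinery.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.special import expit, log_expit
from scipy.stats import norm

__all__ = [
    "CrossedGLMMData",
    "GLMMParams",
    "GLMMFit",
    "fit_laplace",
    "laplace_loglik",
    "integrated_loglik_quadrature",
    "wald_report",
]

_SD_FLOOR = 1e-6     # optimizer floor for a standard deviation
_SD_ZERO = 1e-4      # below this an estimate is reported as exactly 0


@dataclass
class CrossedGLMMData:
    """Design for one side (dissolution or formation) of the separable model.

    ``sender_ids`` / ``receiver_ids`` are per-row actor labels; they are
    factorized internally.  ``fixed_matrix`` must be full column rank.
    """

    outcome: np.ndarray
    fixed_matrix: np.ndarray
    sender_ids: np.ndarray
    receiver_ids: np.ndarray
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.outcome = np.asarray(self.outcome, dtype=float).ravel()
        self.fixed_matrix = np.atleast_2d(np.asarray(self.fixed_matrix, dtype=float))
        n, p = self.fixed_matrix.shape
        if self.outcome.shape[0] != n:
            raise ValueError("outcome and fixed_matrix row counts differ")
        if not np.isin(self.outcome, (0.0, 1.0)).all():
            raise ValueError("outcome must be 0/1 with no missing values")
        if np.isnan(self.fixed_matrix).any():
            raise ValueError("fixed_matrix contains missing values")
        if not self.column_names:
            self.column_names = [f"x{k}" for k in range(p)]
        if len(self.column_names) != p:
            raise ValueError("column_names length mismatch")
        self.sender_ids = np.asarray(self.sender_ids)
        self.receiver_ids = np.asarray(self.receiver_ids)
        if len(self.sender_ids) != n or len(self.receiver_ids) != n:
            raise ValueError("sender/receiver index length mismatch")
        self.sender_levels, self.sender_index = np.unique(self.sender_ids, return_inverse=True)
        self.receiver_levels, self.receiver_index = np.unique(self.receiver_ids, return_inverse=True)
        # canonical row order: makes every fitted quantity exactly invariant
        # to the order rows were supplied in (floating-point reductions
        # otherwise depend on summation order)
        order = np.lexsort((*self.fixed_matrix.T[::-1], self.outcome,
                            self.receiver_index, self.sender_index))
        for attr in ("outcome", "sender_ids", "receiver_ids",
                     "sender_index", "receiver_index"):
            setattr(self, attr, getattr(self, attr)[order])
        self.fixed_matrix = self.fixed_matrix[order]
        self._check_rank()

    def _check_rank(self):
        X = self.fixed_matrix
        _q, R, piv = sla.qr(X, mode="economic", pivoting=True)
        d = np.abs(np.diag(R))
        tol = d.max() * max(X.shape) * np.finfo(float).eps if d.size else 0.0
        rank = int((d > tol).sum())
        if rank < X.shape[1]:
            bad = [self.column_names[j] for j in piv[rank:]]
            raise ValueError(f"fixed_matrix is rank deficient; collinear column(s): {bad}")

    @property
    def n_rows(self) -> int:
        return self.fixed_matrix.shape[0]

    @property
    def n_senders(self) -> int:
        return len(self.sender_levels)

    @property
    def n_receivers(self) -> int:
        return len(self.receiver_levels)


@dataclass
class GLMMParams:
    """Fixed effects, random-effect SDs and conditional modes."""

    beta: pd.Series
    sigma: float
    tau: float
    theta: pd.Series
    eta: pd.Series


@dataclass
class GLMMFit:
    """Fitted crossed GLMM with Wald inference."""

    params: GLMMParams
    se: pd.Series
    vcov: pd.DataFrame
    loglik_laplace: float
    converged: bool
    boundary_sigma: bool
    boundary_tau: bool
    n_rows: int
    n_senders: int
    n_receivers: int
    warnings: list[str] = field(default_factory=list)
    scale: dict = field(default_factory=dict)

    @property
    def z(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params.beta / self.se

    @property
    def p_two_tailed(self) -> pd.Series:
        return pd.Series(2.0 * norm.sf(np.abs(self.z.to_numpy())), index=self.se.index)

    @property
    def coef_correlations(self) -> pd.DataFrame:
        v = self.vcov.to_numpy()
        d = np.sqrt(np.diag(v))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = v / np.outer(d, d)
        return pd.DataFrame(corr, index=self.vcov.index, columns=self.vcov.columns)


# ---------------------------------------------------------------------------
# inner loop: penalized IRLS at fixed variance components
# ---------------------------------------------------------------------------

def _bernoulli_ll(y, lin):
    # sum of y*lin - log(1 + e^lin), computed stably
    return float(np.sum(np.where(y == 1.0, log_expit(lin), log_expit(-lin))))


def _penalized_ll(y, lin, th, et, pen_s, pen_t):
    ll = _bernoulli_ll(y, lin)
    if th is not None:
        ll -= 0.5 * pen_s * float(th @ th)
    if et is not None:
        ll -= 0.5 * pen_t * float(et @ et)
    return ll


class _Inner:
    """Joint (beta, theta, eta) mode finder with warm starts."""

    def __init__(self, data: CrossedGLMMData, fixed_beta: np.ndarray | None = None):
        self.d = data
        self.fixed_beta = fixed_beta
        n, p = data.fixed_matrix.shape
        self.beta = np.zeros(p) if fixed_beta is None else np.asarray(fixed_beta, float)
        self.th = np.zeros(data.n_senders)
        self.et = np.zeros(data.n_receivers)

    def linpred(self, has_s, has_r):
        d = self.d
        lin = d.fixed_matrix @ self.beta
        if has_s:
            lin = lin + self.th[d.sender_index]
        if has_r:
            lin = lin + self.et[d.receiver_index]
        return lin

    def solve(self, sigma: float, tau: float, tol: float = 1e-9, max_iter: int = 100):
        """Newton with step halving; returns a dict of mode quantities."""
        d = self.d
        has_s = sigma > 0
        has_r = tau > 0
        pen_s = 1.0 / sigma**2 if has_s else 0.0
        pen_t = 1.0 / tau**2 if has_r else 0.0
        if not has_s:
            self.th[:] = 0.0
        if not has_r:
            self.et[:] = 0.0
        free_beta = self.fixed_beta is None

        lin = self.linpred(has_s, has_r)
        h = _penalized_ll(d.outcome, lin, self.th if has_s else None,
                          self.et if has_r else None, pen_s, pen_t)
        converged = False
        for _ in range(max_iter):
            mu = expit(lin)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            resid = d.outcome - mu
            step = self._newton_direction(w, resid, pen_s, pen_t, has_s, has_r, free_beta)
            db, ds_, dr_ = step
            # step halving on the penalized log-likelihood
            scale = 1.0
            for _half in range(30):
                nb = self.beta + scale * db if free_beta else self.beta
                nth = self.th + scale * ds_ if has_s else self.th
                net = self.et + scale * dr_ if has_r else self.et
                nlin = d.fixed_matrix @ nb
                if has_s:
                    nlin = nlin + nth[d.sender_index]
                if has_r:
                    nlin = nlin + net[d.receiver_index]
                nh = _penalized_ll(d.outcome, nlin, nth if has_s else None,
                                   net if has_r else None, pen_s, pen_t)
                if nh >= h - 1e-12:
                    break
                scale *= 0.5
            self.beta, self.th, self.et, lin = nb, nth, net, nlin
            if abs(nh - h) < tol:
                h = nh
                converged = True
                break
            h = nh

        # final Hessian pieces at the mode, for the Laplace log-det and SEs
        mu = expit(lin)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        logdet_uu, S_beta = self._mode_info(w, pen_s, pen_t, has_s, has_r)
        cond_ll = _bernoulli_ll(d.outcome, lin)
        quad = 0.0
        if has_s:
            quad += pen_s * float(self.th @ self.th)
        if has_r:
            quad += pen_t * float(self.et @ self.et)
        logdet_lambda = 0.0
        if has_s:
            logdet_lambda += 2.0 * d.n_senders * math.log(sigma)
        if has_r:
            logdet_lambda += 2.0 * d.n_receivers * math.log(tau)
        laplace = cond_ll - 0.5 * quad - 0.5 * logdet_lambda - 0.5 * logdet_uu
        return {"loglik": laplace, "beta": self.beta.copy(), "theta": self.th.copy(),
                "eta": self.et.copy(), "S_beta": S_beta, "converged": converged,
                "cond_ll": cond_ll}

    # -- linear algebra ----------------------------------------------------

    def _blocks(self, w, pen_s, pen_t, has_s, has_r):
        d = self.d
        X = d.fixed_matrix
        p = X.shape[1]
        Hbb = (X * w[:, None]).T @ X
        ds = dr = C = Bs = Br = None
        if has_s:
            ds = np.bincount(d.sender_index, weights=w, minlength=d.n_senders) + pen_s
            Bs = np.vstack([np.bincount(d.sender_index, weights=w * X[:, k],
                                        minlength=d.n_senders) for k in range(p)])
        if has_r:
            dr = np.bincount(d.receiver_index, weights=w, minlength=d.n_receivers) + pen_t
            Br = np.vstack([np.bincount(d.receiver_index, weights=w * X[:, k],
                                        minlength=d.n_receivers) for k in range(p)])
        if has_s and has_r:
            C = sp.coo_matrix((w, (d.sender_index, d.receiver_index)),
                              shape=(d.n_senders, d.n_receivers)).tocsr()
        return Hbb, Bs, Br, ds, dr, C

    def _newton_direction(self, w, resid, pen_s, pen_t, has_s, has_r, free_beta):
        d = self.d
        X = d.fixed_matrix
        p = X.shape[1]
        Hbb, Bs, Br, ds, dr, C = self._blocks(w, pen_s, pen_t, has_s, has_r)
        gb = X.T @ resid if free_beta else np.zeros(p)
        gs = (np.bincount(d.sender_index, weights=resid, minlength=d.n_senders)
              - pen_s * self.th) if has_s else None
        gr = (np.bincount(d.receiver_index, weights=resid, minlength=d.n_receivers)
              - pen_t * self.et) if has_r else None

        if has_s and has_r:
            ds_inv = 1.0 / ds
            Ct = C.T.tocsr()
            S_r = np.diag(dr) - (Ct @ C.multiply(ds_inv[:, None])).toarray()
            Brp = Br - (Bs * ds_inv) @ C
            Hbbp = Hbb - (Bs * ds_inv) @ Bs.T
            rhs_r = gr - Ct @ (ds_inv * gs)
            cf = sla.cho_factor(S_r, lower=True, check_finite=False)
            if free_beta:
                rhs_b = gb - Bs @ (ds_inv * gs)
                M = sla.cho_solve(cf, Brp.T, check_finite=False)
                S_beta = Hbbp - Brp @ M
                t1 = sla.cho_solve(cf, rhs_r, check_finite=False)
                db = sla.solve(S_beta, rhs_b - Brp @ t1, assume_a="pos")
            else:
                db = np.zeros(p)
            det_ = sla.cho_solve(cf, rhs_r - Brp.T @ db, check_finite=False)
            ds_ = ds_inv * (gs - Bs.T @ db - C @ det_)
            return db, ds_, det_
        if has_s:
            ds_inv = 1.0 / ds
            if free_beta:
                S_beta = Hbb - (Bs * ds_inv) @ Bs.T
                db = sla.solve(S_beta, gb - Bs @ (ds_inv * gs), assume_a="pos")
            else:
                db = np.zeros(p)
            return db, ds_inv * (gs - Bs.T @ db), None
        if has_r:
            dr_inv = 1.0 / dr
            if free_beta:
                S_beta = Hbb - (Br * dr_inv) @ Br.T
                db = sla.solve(S_beta, gb - Br @ (dr_inv * gr), assume_a="pos")
            else:
                db = np.zeros(p)
            return db, None, dr_inv * (gr - Br.T @ db)
        db = sla.solve(Hbb, gb, assume_a="pos") if free_beta else np.zeros(p)
        return db, None, None

    def _mode_info(self, w, pen_s, pen_t, has_s, has_r):
        """(log det of the random-effect Hessian block, profiled info of beta)."""
        Hbb, Bs, Br, ds, dr, C = self._blocks(w, pen_s, pen_t, has_s, has_r)
        if has_s and has_r:
            ds_inv = 1.0 / ds
            Ct = C.T.tocsr()
            S_r = np.diag(dr) - (Ct @ C.multiply(ds_inv[:, None])).toarray()
            L = sla.cholesky(S_r, lower=True, check_finite=False)
            logdet = float(np.sum(np.log(ds))) + 2.0 * float(np.sum(np.log(np.diag(L))))
            Brp = Br - (Bs * ds_inv) @ C
            Hbbp = Hbb - (Bs * ds_inv) @ Bs.T
            M = sla.cho_solve((L, True), Brp.T, check_finite=False)
            S_beta = Hbbp - Brp @ M
            return logdet, S_beta
        if has_s:
            ds_inv = 1.0 / ds
            return float(np.sum(np.log(ds))), Hbb - (Bs * ds_inv) @ Bs.T
        if has_r:
            dr_inv = 1.0 / dr
            return float(np.sum(np.log(dr))), Hbb - (Br * dr_inv) @ Br.T
        return 0.0, Hbb


# ---------------------------------------------------------------------------
# outer loop
# ---------------------------------------------------------------------------

def laplace_loglik(data: CrossedGLMMData, beta, sigma: float, tau: float) -> float:
    """Laplace-approximate marginal log-likelihood at given parameters.

    ``beta`` is held fixed; the random-effect conditional modes are found by
    the inner loop.
    """
    inner = _Inner(data, fixed_beta=np.asarray(beta, float))
    return inner.solve(float(sigma), float(tau))["loglik"]


def fit_laplace(data: CrossedGLMMData, fix_sigma: float | None = None,
                fix_tau: float | None = None, start_sd: float = 0.5,
                inner_tol: float = 1e-9, outer_xatol: float = 2e-3,
                outer_fatol: float = 1e-6, max_outer: int = 200) -> GLMMFit:
    """Fit the crossed random-effects logistic model by Laplace ML.

    ``fix_sigma`` / ``fix_tau`` pin a variance component (0 removes that
    random effect entirely, reducing to fewer integrals; both 0 reduces to
    plain logistic ML).  Estimated SDs are floored at 1e-6 during
    optimization; estimates below 1e-4 are reported as exactly 0 with a
    boundary flag rather than an error.
    """
    from scipy.optimize import minimize

    inner = _Inner(data)
    free: list[str] = []
    if fix_sigma is None:
        free.append("sigma")
    if fix_tau is None:
        free.append("tau")

    def sd_of(log_sd):
        return float(np.exp(np.clip(log_sd, math.log(_SD_FLOOR), math.log(50.0))))

    state = {}

    def objective(x):
        vals = dict(zip(free, x))
        sigma = sd_of(vals["sigma"]) if "sigma" in vals else float(fix_sigma)
        tau = sd_of(vals["tau"]) if "tau" in vals else float(fix_tau)
        res = inner.solve(sigma, tau, tol=inner_tol)
        state.update(res, sigma=sigma, tau=tau)
        return -res["loglik"]

    opt_ok = True
    if free:
        x0 = np.full(len(free), math.log(start_sd))
        opt = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": outer_xatol, "fatol": outer_fatol,
                                "maxiter": max_outer, "maxfev": max_outer})
        objective(opt.x)  # leave `state` at the optimum
        opt_ok = bool(opt.success)
    else:
        objective(np.empty(0))

    sigma, tau = state["sigma"], state["tau"]
    boundary_sigma = fix_sigma is None and sigma < _SD_ZERO or (fix_sigma == 0)
    boundary_tau = fix_tau is None and tau < _SD_ZERO or (fix_tau == 0)
    sigma_rep = 0.0 if (sigma < _SD_ZERO) else sigma
    tau_rep = 0.0 if (tau < _SD_ZERO) else tau

    names = data.column_names
    beta = pd.Series(state["beta"], index=names)
    try:
        vcov_arr = sla.inv(state["S_beta"])
    except sla.LinAlgError:
        vcov_arr = np.full((len(names), len(names)), np.nan)
    vcov = pd.DataFrame(vcov_arr, index=names, columns=names)
    se = pd.Series(np.sqrt(np.clip(np.diag(vcov_arr), 0.0, None)), index=names)
    params = GLMMParams(
        beta=beta, sigma=sigma_rep, tau=tau_rep,
        theta=pd.Series(state["theta"], index=data.sender_levels),
        eta=pd.Series(state["eta"], index=data.receiver_levels))
    msgs = []
    if not state["converged"]:
        msgs.append("inner PIRLS did not meet its tolerance")
    if not opt_ok:
        msgs.append("outer variance-component optimization did not converge")
    return GLMMFit(params=params, se=se, vcov=vcov, loglik_laplace=state["loglik"],
                   converged=state["converged"] and opt_ok,
                   boundary_sigma=bool(boundary_sigma), boundary_tau=bool(boundary_tau),
                   n_rows=data.n_rows, n_senders=data.n_senders,
                   n_receivers=data.n_receivers, warnings=msgs)


# ---------------------------------------------------------------------------
# quadrature oracle
# ---------------------------------------------------------------------------

def integrated_loglik_quadrature(data: CrossedGLMMData, beta, sigma: float,
                                 tau: float, nodes: int = 21) -> float:
    """Marginal log-likelihood by Gauss-Hermite quadrature (small instances).

    The crossed random effects do not factorize jointly, so the integral is
    taken over the full random-effect vector: conditioning on a grid over
    one side's effects, the other side's units become independent and are
    integrated unit by unit.  This is algebraically identical to the full
    tensor-product rule.  Limited to ``n_senders + n_receivers <= 8``.
    """
    if data.n_senders + data.n_receivers > 8:
        raise ValueError("too many random effects for quadrature; use the Laplace fit")
    beta = np.asarray(beta, dtype=float)
    y = data.outcome
    lin0 = data.fixed_matrix @ beta
    x_nodes, w_nodes = np.polynomial.hermite.hermgauss(nodes)
    logw = np.log(w_nodes) - 0.5 * math.log(math.pi)
    sq2 = math.sqrt(2.0)

    active_s = sigma > 0
    active_r = tau > 0
    if not active_s and not active_r:
        return float(np.sum(np.where(y == 1.0, log_expit(lin0), log_expit(-lin0))))

    if active_s and not active_r:
        return _one_side_quad(y, lin0, data.sender_index, data.n_senders, sigma,
                              x_nodes, logw)
    if active_r and not active_s:
        return _one_side_quad(y, lin0, data.receiver_index, data.n_receivers, tau,
                              x_nodes, logw)

    # both sides active: tensor grid over the smaller side
    if data.n_senders <= data.n_receivers:
        q_out, out_idx, sd_out = data.n_senders, data.sender_index, sigma
        in_idx, q_in, sd_in = data.receiver_index, data.n_receivers, tau
    else:
        q_out, out_idx, sd_out = data.n_receivers, data.receiver_index, tau
        in_idx, q_in, sd_in = data.sender_index, data.n_senders, sigma

    grid = np.array(list(itertools.product(range(nodes), repeat=q_out)))  # (G, q_out)
    V = sq2 * sd_out * x_nodes[grid]                                      # (G, q_out)
    logw_outer = logw[grid].sum(axis=1)                                   # (G,)
    G = grid.shape[0]
    total = np.zeros(G)
    for j in range(q_in):
        rows = np.nonzero(in_idx == j)[0]
        if rows.size == 0:
            continue
        a0 = lin0[rows][None, :] + V[:, out_idx[rows]]                    # (G, m)
        yj = y[rows][None, :]
        acc = np.empty((G, nodes))
        for k in range(nodes):
            lp = a0 + sq2 * sd_in * x_nodes[k]
            ll = np.where(yj == 1.0, log_expit(lp), log_expit(-lp)).sum(axis=1)
            acc[:, k] = ll + logw[k]
        m = acc.max(axis=1)
        total += m + np.log(np.exp(acc - m[:, None]).sum(axis=1))
    m = (total + logw_outer).max()
    return float(m + math.log(np.exp(total + logw_outer - m).sum()))


def _one_side_quad(y, lin0, idx, q, sd, x_nodes, logw):
    sq2 = math.sqrt(2.0)
    out = 0.0
    for j in range(q):
        rows = np.nonzero(idx == j)[0]
        lp = lin0[rows][None, :] + sq2 * sd * x_nodes[:, None]
        ll = np.where(y[rows][None, :] == 1.0, log_expit(lp), log_expit(-lp)).sum(axis=1)
        acc = ll + logw
        m = acc.max()
        out += m + math.log(np.exp(acc - m).sum())
    return float(out)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def wald_report(fit: GLMMFit, key_terms: list[str] | None = None) -> pd.DataFrame:
    """Coefficient table: estimate, SE, z, two-tailed p, significance flag.

    Key predictors (if named) are listed first, then the remaining fixed
    effects, then the sender/receiver random-effect SD rows (no SEs are
    reported for the SDs).
    """
    key_terms = [t for t in (key_terms or []) if t in fit.params.beta.index]
    rest = [t for t in fit.params.beta.index if t not in key_terms]
    order = key_terms + rest
    z = fit.z
    p = fit.p_two_tailed
    rows = []
    for t in order:
        rows.append({"term": t, "estimate": fit.params.beta[t], "se": fit.se[t],
                     "z": z[t], "p": p[t], "significant": bool(p[t] < 0.05),
                     "block": "key" if t in key_terms else "other"})
    for label, val in (("SD (ego)", fit.params.sigma), ("SD (alter)", fit.params.tau)):
        rows.append({"term": label, "estimate": val, "se": np.nan, "z": np.nan,
                     "p": np.nan, "significant": False, "block": "sd"})
    return pd.DataFrame(rows)
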