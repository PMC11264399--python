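"""Maximum-likelihood fitting of the panel GVAR, SEs, pruning and model search.

Fitting maximizes the FIML log-likelihood over the free parameters of an
:class:`~panelgvar.gvar.EdgePattern` with L-BFGS-B and analytic gradients;
stationarity and positive-definiteness are maintained by rejecting invalid
proposals with a penalty value during line search.  The optimizer works on
the per-person mean negative log-likelihood, so the convergence thresholds
are sample-size free.

Standard errors come from the inverse of the numerically differentiated
observed information at the optimum.  Pruning fixes all edge parameters with
two-sided Wald p > alpha to zero simultaneously and refits; model search
greedily re-introduces the single zeroed edge that most decreases BIC, then
re-prunes, until BIC stops improving.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats

from .gvar import (
    EdgePattern,
    FimlStats,
    GVARModelError,
    GVARParameters,
    fiml_loglik_and_grad,
    spectral_radius,
)
from .panel_data import PanelDataset

logger = logging.getLogger(__name__)

__all__ = [
    "FittedModel",
    "FitIndices",
    "fit_gvar",
    "standard_errors",
    "prune",
    "model_search",
    "fit_indices",
    "compare_bic",
    "saturated_loglik",
]

_PENALTY = 1.0e8
_MAX_RHO = 0.9995  # stationarity guard inside the optimizer


class _Packer:
    """Maps between the free-parameter vector and the GVAR matrices."""

    def __init__(self, pattern: EdgePattern, n_waves: int):
        self.pattern = pattern
        self.n_waves = n_waves
        p = pattern.p
        self.p = p
        self.b_idx = [(i, j) for i in range(p) for j in range(p) if pattern.temporal[i, j]]
        self.kz_idx = [(i, i) for i in range(p)] + [
            (i, j) for i in range(p) for j in range(i + 1, p) if pattern.contemporaneous[i, j]
        ]
        self.kb_idx = [(i, i) for i in range(p)] + [
            (i, j) for i in range(p) for j in range(i + 1, p) if pattern.between[i, j]
        ]
        self.n_free = len(self.b_idx) + len(self.kz_idx) + len(self.kb_idx) + n_waves * p

    def pack(self, params: GVARParameters) -> np.ndarray:
        theta = np.empty(self.n_free)
        k = 0
        for i, j in self.b_idx:
            theta[k] = params.B[i, j]; k += 1
        for i, j in self.kz_idx:
            theta[k] = params.K_zeta[i, j]; k += 1
        for i, j in self.kb_idx:
            theta[k] = params.K_between[i, j]; k += 1
        theta[k:] = params.nu.reshape(-1)
        return theta

    def unpack(self, theta: np.ndarray, item_ids: tuple = ()) -> GVARParameters:
        p = self.p
        B = np.zeros((p, p)); Kz = np.zeros((p, p)); Kb = np.zeros((p, p))
        k = 0
        for i, j in self.b_idx:
            B[i, j] = theta[k]; k += 1
        for i, j in self.kz_idx:
            Kz[i, j] = theta[k]; Kz[j, i] = theta[k]; k += 1
        for i, j in self.kb_idx:
            Kb[i, j] = theta[k]; Kb[j, i] = theta[k]; k += 1
        nu = theta[k:].reshape(self.n_waves, p)
        return GVARParameters(B, Kz, Kb, nu, item_ids)

    def pack_grad(self, grads: dict[str, np.ndarray]) -> np.ndarray:
        g = np.empty(self.n_free)
        k = 0
        gB, gKz, gKb = grads["B"], grads["K_zeta"], grads["K_between"]
        for i, j in self.b_idx:
            g[k] = gB[i, j]; k += 1
        for i, j in self.kz_idx:
            g[k] = gKz[i, j] + (gKz[j, i] if i != j else 0.0); k += 1
        for i, j in self.kb_idx:
            g[k] = gKb[i, j] + (gKb[j, i] if i != j else 0.0); k += 1
        g[k:] = grads["nu"].reshape(-1)
        return g


@dataclass
class FittedModel:
    """A fitted panel GVAR: parameters, pattern, likelihood and diagnostics."""

    params: GVARParameters
    pattern: EdgePattern
    loglik: float
    n_params: int
    n_persons: int
    se: dict[str, np.ndarray] | None
    converged: bool
    n_iterations: int
    grad_norm: float = float("nan")

    def bic(self, n: int | None = None) -> float:
        n = self.n_persons if n is None else n
        return -2.0 * self.loglik + self.n_params * float(np.log(n))

    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params


def _default_init(ds: PanelDataset, pattern: EdgePattern) -> GVARParameters:
    p = ds.n_items
    nu = np.zeros((ds.n_waves, p))
    v = np.ones(p)
    for j in range(p):
        vals = ds.scores[:, :, j][~ds.missing_mask[:, :, j]]
        v[j] = max(vals.var(ddof=1), 1e-3) if vals.size > 1 else 1.0
        for t in range(ds.n_waves):
            wv = ds.scores[:, t, j][~ds.missing_mask[:, t, j]]
            nu[t, j] = wv.mean() if wv.size else 0.0
    # split total variance into between (30%) and innovation (70%) parts
    Kz = np.diag(1.0 / (0.7 * v))
    Kb = np.diag(1.0 / (0.3 * v))
    return GVARParameters(np.zeros((p, p)), Kz, Kb, nu, ds.schema.item_ids)


def _objective_factory(packer: _Packer, fstats: FimlStats, item_ids: tuple):
    n_eff = max(sum(g[1] for g in fstats.groups), 1)

    def fun(theta: np.ndarray):
        params = packer.unpack(theta, item_ids)
        rho = spectral_radius(params.B)
        if not np.isfinite(rho) or rho >= _MAX_RHO:
            return _PENALTY * (1.0 + rho), np.zeros_like(theta)
        try:
            ll, grads = fiml_loglik_and_grad(params, fstats)
        except GVARModelError:
            return _PENALTY, np.zeros_like(theta)
        if not np.isfinite(ll):
            return _PENALTY, np.zeros_like(theta)
        return -ll / n_eff, -packer.pack_grad(grads) / n_eff

    return fun, n_eff


def _numeric_hessian(grad_fn, theta: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central finite differences of a gradient function; symmetrized."""
    k = theta.size
    H = np.empty((k, k))
    for a in range(k):
        h = step * max(1.0, abs(theta[a]))
        e = np.zeros(k)
        e[a] = h
        H[:, a] = (grad_fn(theta + e) - grad_fn(theta - e)) / (2.0 * h)
    return (H + H.T) / 2.0


def _newton_polish(fun, theta, f_val, g_val, gtol, max_hessians=10, max_inner=6):
    """Damped Newton steps to push the gradient below tolerance when the
    quasi-Newton optimizer stalls close to the optimum.

    The observed information is ill-conditioned for weakly identified
    saturated models, so each (expensive) Hessian factorization is reused for
    several steps and refreshed only when progress stalls.
    """
    gnorm = float(np.max(np.abs(g_val)))
    best = (theta, f_val, g_val, gnorm)  # smallest gradient norm seen
    for _ in range(max_hessians):
        if gnorm < gtol:
            break
        H = _numeric_hessian(lambda th: fun(th)[1], theta, step=1e-4)
        w, V = np.linalg.eigh(H)
        if w.max() <= 0:
            break
        # floor tiny/negative curvature: keeps the step bounded in the
        # near-flat directions of weakly identified saturated models
        w_clipped = np.maximum(w, 1e-4 * w.max())
        progressed = False
        for _ in range(max_inner):
            d = -(V / w_clipped) @ (V.T @ g_val)
            for scale in (1.0, 0.5, 0.25, 0.1):
                f_new, g_new = fun(theta + scale * d)
                if f_new < _PENALTY / 2 and (
                    float(np.max(np.abs(g_new))) < gnorm or f_new < f_val - 1e-14
                ):
                    theta, f_val, g_val = theta + scale * d, f_new, g_new
                    gnorm = float(np.max(np.abs(g_val)))
                    if gnorm < best[3]:
                        best = (theta, f_val, g_val, gnorm)
                    progressed = True
                    break
            else:
                break
            if gnorm < gtol:
                return theta, f_val, g_val
        if not progressed:
            break
    # an f-improving excursion can inflate the gradient in a near-flat
    # direction; report the best-gradient point visited instead
    return best[0], best[1], best[2]


def fit_gvar(
    ds: PanelDataset,
    pattern: EdgePattern | None = None,
    init: GVARParameters | None = None,
    *,
    gtol: float = 1e-5,
    max_iter: int = 2000,
    fstats: FimlStats | None = None,
) -> FittedModel:
    """Fit the panel GVAR under an edge pattern by FIML.

    Deterministic given ``init`` (default: diagonal variance split, zero
    temporal matrix, observed wave means).  Never raises on non-convergence;
    the returned model carries ``converged=False`` instead, which the
    stability protocol relies on.
    """
    if ds.n_waves < 3:
        raise GVARModelError("panel GVAR fitting requires >= 3 waves")
    if pattern is None:
        pattern = EdgePattern.saturated(ds.n_items)
    if fstats is None:
        fstats = FimlStats.from_dataset(ds)
    packer = _Packer(pattern, ds.n_waves)
    start = init if init is not None else _default_init(ds, pattern)
    theta0 = packer.pack(start)
    fun, n_eff = _objective_factory(packer, fstats, ds.schema.item_ids)

    theta, n_it, converged, gnorm = theta0, 0, False, float("inf")
    best_f = np.inf
    for attempt in range(2):
        res = optimize.minimize(
            fun, theta, jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "maxfun": 10 * max_iter,
                     "ftol": 1e-13, "gtol": gtol * 1e-2},
        )
        n_it += res.nit
        f_val, g_val = fun(res.x)
        gnorm = float(np.max(np.abs(g_val))) if np.size(g_val) else 0.0
        if f_val < best_f:
            best_f, theta = f_val, res.x
        converged = gnorm < gtol and f_val < _PENALTY / 2
        if converged or res.nit == 0:
            break
    if not converged and best_f < _PENALTY / 2:
        f_val, g_val = fun(theta)
        theta, f_val, g_val = _newton_polish(fun, theta, f_val, g_val, gtol)
        gnorm = float(np.max(np.abs(g_val)))
        if f_val < best_f:
            best_f = f_val
        converged = gnorm < gtol and f_val < _PENALTY / 2
    params = packer.unpack(theta, ds.schema.item_ids)
    ll = -best_f * n_eff if best_f < _PENALTY / 2 else float("nan")
    if not np.isfinite(ll):
        converged = False
    return FittedModel(
        params=params, pattern=pattern, loglik=float(ll),
        n_params=packer.n_free, n_persons=n_eff, se=None,
        converged=converged, n_iterations=n_it, grad_norm=gnorm,
    )


def standard_errors(
    model: FittedModel, ds: PanelDataset, *, step: float = 1e-5,
    fstats: FimlStats | None = None,
) -> dict[str, np.ndarray]:
    """SEs from the inverse observed information (central differences of the
    analytic gradient at the optimum).  NaN where the pattern fixes a
    parameter to zero; symmetric entries share one SE."""
    if not model.converged:
        raise GVARModelError("standard errors require a converged model")
    if fstats is None:
        fstats = FimlStats.from_dataset(ds)
    packer = _Packer(model.pattern, ds.n_waves)
    theta = packer.pack(model.params)
    item_ids = ds.schema.item_ids

    def grad_total(th):
        _, grads = fiml_loglik_and_grad(packer.unpack(th, item_ids), fstats)
        return -packer.pack_grad(grads)  # gradient of total negative loglik

    k = theta.size
    cov = None
    H = None
    for h_step in (step, 1e-4, 1e-6):
        try:
            H_try = _numeric_hessian(grad_total, theta, step=h_step)
        except GVARModelError:
            # a perturbation left the PD region (boundary solution)
            continue
        H = H_try
        try:
            c, low = linalg.cho_factor(H)
            cov = linalg.cho_solve((c, low), np.eye(k))
            break
        except linalg.LinAlgError:
            continue
    if cov is None and H is None:
        raise GVARModelError(
            "observed information could not be evaluated; solution on the "
            "parameter-space boundary"
        )
    if cov is None:
        # tolerate finite-difference noise in near-flat directions: clip
        # tiny negative eigenvalues, but refuse substantive indefiniteness
        w, V = np.linalg.eigh(H)
        if w.max() <= 0 or w.min() < -1e-6 * w.max():
            raise GVARModelError(
                "observed information not positive-definite; model likely not identified"
            )
        w = np.maximum(w, 1e-12 * w.max())
        cov = (V / w) @ V.T
    se_vec = np.sqrt(np.maximum(np.diag(cov), 0.0))

    p = packer.p
    se = {
        "B": np.full((p, p), np.nan),
        "K_zeta": np.full((p, p), np.nan),
        "K_between": np.full((p, p), np.nan),
        "nu": np.full((ds.n_waves, p), np.nan),
    }
    idx = 0
    for i, j in packer.b_idx:
        se["B"][i, j] = se_vec[idx]; idx += 1
    for i, j in packer.kz_idx:
        se["K_zeta"][i, j] = se_vec[idx]; se["K_zeta"][j, i] = se_vec[idx]; idx += 1
    for i, j in packer.kb_idx:
        se["K_between"][i, j] = se_vec[idx]; se["K_between"][j, i] = se_vec[idx]; idx += 1
    se["nu"] = se_vec[idx:].reshape(ds.n_waves, p)
    model.se = se
    return se


def _wald_p(est: float, se: float) -> float:
    if not (np.isfinite(se) and se > 0):
        return 1.0
    return float(2.0 * stats.norm.sf(abs(est) / se))


def prune(
    model: FittedModel, ds: PanelDataset, alpha: float = 0.01, *,
    exempt_autoregressions: bool = False, fstats: FimlStats | None = None,
) -> FittedModel:
    """Fix all edge parameters with two-sided Wald p > alpha to zero and refit.

    Edges are the free entries of B (self-loops included unless exempted) and
    the off-diagonal entries of both precisions.  Means and precision
    diagonals are never pruned.  The refit model's SEs are recomputed so the
    result can be pruned or searched again.
    """
    if fstats is None:
        fstats = FimlStats.from_dataset(ds)
    if model.se is None:
        standard_errors(model, ds, fstats=fstats)
    pat = model.pattern
    p = pat.p
    new_t = pat.temporal.copy()
    new_c = pat.contemporaneous.copy()
    new_b = pat.between.copy()
    for i in range(p):
        for j in range(p):
            if pat.temporal[i, j] and not (exempt_autoregressions and i == j):
                if _wald_p(model.params.B[i, j], model.se["B"][i, j]) > alpha:
                    new_t[i, j] = False
        for j in range(i + 1, p):
            if pat.contemporaneous[i, j]:
                if _wald_p(model.params.K_zeta[i, j], model.se["K_zeta"][i, j]) > alpha:
                    new_c[i, j] = new_c[j, i] = False
            if pat.between[i, j]:
                if _wald_p(model.params.K_between[i, j], model.se["K_between"][i, j]) > alpha:
                    new_b[i, j] = new_b[j, i] = False
    new_pattern = EdgePattern(new_t, new_c, new_b)
    init = GVARParameters(
        B=np.where(new_t, model.params.B, 0.0),
        K_zeta=np.where(new_c | np.eye(p, dtype=bool), model.params.K_zeta, 0.0),
        K_between=np.where(new_b | np.eye(p, dtype=bool), model.params.K_between, 0.0),
        nu=model.params.nu,
        item_ids=model.params.item_ids,
    )
    refit = fit_gvar(ds, new_pattern, init, fstats=fstats)
    if refit.converged:
        try:
            standard_errors(refit, ds, fstats=fstats)
        except GVARModelError:
            pass
    return refit


def _iter_candidate_edges(pattern: EdgePattern):
    """Zeroed edges in deterministic (matrix, row, column) lexical order."""
    p = pattern.p
    for i in range(p):
        for j in range(p):
            if not pattern.temporal[i, j]:
                yield ("temporal", i, j)
    for name, M in (("contemporaneous", pattern.contemporaneous), ("between", pattern.between)):
        for i in range(p):
            for j in range(i + 1, p):
                if not M[i, j]:
                    yield (name, i, j)


def _add_edge(pattern: EdgePattern, edge) -> EdgePattern:
    name, i, j = edge
    t, c, b = pattern.temporal.copy(), pattern.contemporaneous.copy(), pattern.between.copy()
    if name == "temporal":
        t[i, j] = True
    elif name == "contemporaneous":
        c[i, j] = c[j, i] = True
    else:
        b[i, j] = b[j, i] = True
    return EdgePattern(t, c, b)


def model_search(
    model: FittedModel, ds: PanelDataset, alpha: float = 0.01, *,
    max_steps: int = 50, fstats: FimlStats | None = None,
) -> FittedModel:
    """Greedy stepwise BIC search from a pruned model.

    Repeatedly re-introduce the single fixed-to-zero edge whose addition most
    decreases BIC (ties broken by lexical order), re-prune at ``alpha``, and
    stop when no addition improves BIC or a pattern repeats.
    """
    if fstats is None:
        fstats = FimlStats.from_dataset(ds)
    current = model
    seen = {_pattern_key(current.pattern)}
    for _ in range(max_steps):
        if not current.converged:
            return current
        best_bic = current.bic()
        best_model = None
        for edge in _iter_candidate_edges(current.pattern):
            cand_pattern = _add_edge(current.pattern, edge)
            cand = fit_gvar(ds, cand_pattern, current.params, fstats=fstats)
            if cand.converged and cand.bic() < best_bic - 1e-9:
                best_bic = cand.bic()
                best_model = cand
        if best_model is None:
            return current
        pruned = prune(best_model, ds, alpha, fstats=fstats)
        nxt = pruned if pruned.converged and pruned.bic() <= best_model.bic() + 1e-9 else best_model
        key = _pattern_key(nxt.pattern)
        if key in seen or nxt.bic() >= current.bic() - 1e-9:
            return current if current.bic() <= nxt.bic() else nxt
        seen.add(key)
        current = nxt
    return current


def _pattern_key(pattern: EdgePattern) -> bytes:
    return (
        pattern.temporal.tobytes()
        + np.triu(pattern.contemporaneous, 1).tobytes()
        + np.triu(pattern.between, 1).tobytes()
    )


# --------------------------------------------------------------------------
# comparison models and fit indices


def saturated_loglik(ds: PanelDataset, *, tol: float = 1e-9, max_iter: int = 5000) -> tuple[float, int]:
    """FIML log-likelihood and parameter count of the saturated MVN model
    (unrestricted stacked mean and covariance), fitted by EM under
    missingness; closed form when data are complete."""
    Y, obs = ds.stacked()
    use = obs.any(axis=1)
    Y, obs = Y[use], obs[use]
    n, D = Y.shape
    k = D + D * (D + 1) // 2
    if obs.all():
        mu = Y.mean(axis=0)
        Yc = Y - mu
        Sigma = (Yc.T @ Yc) / n
        sign, logdet = np.linalg.slogdet(Sigma)
        if sign <= 0:
            raise GVARModelError("saturated covariance singular")
        ll = -0.5 * n * (D * np.log(2 * np.pi) + logdet + D)
        return float(ll), k

    mu = np.zeros(D)
    var = np.ones(D)
    for j in range(D):
        v = Y[obs[:, j], j]
        if v.size:
            mu[j] = v.mean()
            var[j] = max(v.var(), 1e-6)
    Sigma = np.diag(var)
    patterns = {}
    keys = np.packbits(obs, axis=1)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    for g in np.unique(inverse):
        rows = np.flatnonzero(inverse == g)
        patterns[g] = (rows, np.flatnonzero(obs[rows[0]]))

    ll_old = -np.inf
    ll = -np.inf
    for _ in range(max_iter):
        sum_y = np.zeros(D)
        sum_yy = np.zeros((D, D))
        ll = 0.0
        for rows, o in patterns.values():
            m = np.setdiff1d(np.arange(D), o)
            So = Sigma[np.ix_(o, o)]
            c, low = linalg.cho_factor(So, lower=True, check_finite=False)
            logdet = 2.0 * np.sum(np.log(np.diag(c)))
            Yo = Y[np.ix_(rows, o)]
            d = Yo - mu[o]
            sol = linalg.cho_solve((c, low), d.T, check_finite=False).T  # (n_g, |o|)
            ll += -0.5 * (len(rows) * (o.size * np.log(2 * np.pi) + logdet)
                          + float(np.sum(d * sol)))
            Ey = np.zeros((len(rows), D))
            Ey[:, o] = Yo
            if m.size:
                Smo = Sigma[np.ix_(m, o)]
                Ey[:, m] = mu[m] + sol @ Smo.T
                cond_cov = Sigma[np.ix_(m, m)] - Smo @ linalg.cho_solve(
                    (c, low), Smo.T, check_finite=False)
            sum_y += Ey.sum(axis=0)
            cross = Ey.T @ Ey
            if m.size:
                cross[np.ix_(m, m)] += len(rows) * cond_cov
            sum_yy += cross
        mu = sum_y / n
        Sigma = sum_yy / n - np.outer(mu, mu)
        Sigma = (Sigma + Sigma.T) / 2.0 + 1e-10 * np.eye(D)
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            break
        ll_old = ll
    return float(ll), k


def _baseline_loglik(ds: PanelDataset) -> tuple[float, int]:
    """Independence baseline: free means and variances, all covariances zero.
    With a diagonal covariance the FIML likelihood separates by coordinate."""
    Y, obs = ds.stacked()
    D = Y.shape[1]
    ll = 0.0
    for j in range(D):
        v = Y[obs[:, j], j]
        nj = v.size
        if nj == 0:
            continue
        s2 = max(v.var(), 1e-12)
        ll += -0.5 * nj * (np.log(2 * np.pi) + np.log(s2) + 1.0)
    return float(ll), 2 * D


@dataclass(frozen=True)
class FitIndices:
    """Chi-square against the saturated model plus CFI/TLI/RMSEA/BIC/AIC."""

    chi2: float
    df: int
    cfi: float
    tli: float
    rmsea: float
    bic: float
    aic: float
    chi2_baseline: float = float("nan")
    df_baseline: int = 0
    loglik: float = float("nan")
    loglik_saturated: float = float("nan")
    rmsea_undefined: bool = False


def indices_from_chi2(chi2_m: float, df_m: int, chi2_b: float, df_b: int,
                      n_persons: int) -> tuple[float, float, float]:
    """CFI, TLI (truncated at 1) and RMSEA from model/baseline chi-squares."""
    num = max(chi2_m - df_m, 0.0)
    cfi_den = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    cfi = 1.0 - num / cfi_den if cfi_den > 0 else 1.0
    if df_b > 0 and df_m > 0 and chi2_b / df_b > 1.0:
        tli = ((chi2_b / df_b) - (chi2_m / df_m)) / ((chi2_b / df_b) - 1.0)
        tli = min(tli, 1.0)
    else:
        tli = 1.0
    rmsea = float(np.sqrt(num / (df_m * max(n_persons - 1, 1)))) if df_m > 0 else 0.0
    return float(cfi), float(tli), rmsea


def fit_indices(
    model: FittedModel, ds: PanelDataset, *,
    saturated: tuple[float, int] | None = None,
) -> FitIndices:
    """SEM-style fit evaluation of a fitted panel GVAR.

    chi2 = 2(LL_sat - LL_model) with df = k_sat - k_model; CFI and TLI
    compare against the independence baseline; RMSEA uses N-1 with N the
    number of persons contributing data; BIC = -2LL + k ln(N).
    """
    if saturated is None:
        saturated = saturated_loglik(ds)
    ll_sat, k_sat = saturated
    ll_base, k_base = _baseline_loglik(ds)
    N = model.n_persons
    chi2_m = max(2.0 * (ll_sat - model.loglik), 0.0)
    df_m = k_sat - model.n_params
    chi2_b = max(2.0 * (ll_sat - ll_base), 0.0)
    df_b = k_sat - k_base
    if df_m <= 0:
        return FitIndices(
            chi2=chi2_m, df=max(df_m, 0), cfi=1.0, tli=1.0, rmsea=0.0,
            bic=model.bic(), aic=model.aic(), chi2_baseline=chi2_b,
            df_baseline=df_b, loglik=model.loglik, loglik_saturated=ll_sat,
            rmsea_undefined=True,
        )
    cfi, tli, rmsea = indices_from_chi2(chi2_m, df_m, chi2_b, df_b, N)
    return FitIndices(
        chi2=chi2_m, df=df_m, cfi=cfi, tli=tli, rmsea=rmsea,
        bic=model.bic(), aic=model.aic(), chi2_baseline=chi2_b,
        df_baseline=df_b, loglik=model.loglik, loglik_saturated=ll_sat,
    )


@dataclass(frozen=True)
class BicComparison:
    delta: float
    favored: str  # "m1" | "m2" | "tie"
    bic1: float
    bic2: float


def compare_bic(m1: FittedModel, m2: FittedModel, ds: PanelDataset | None = None) -> BicComparison:
    """Signed BIC difference m1 - m2; the lower-BIC model is favored."""
    b1, b2 = m1.bic(), m2.bic()
    favored = "tie" if np.isclose(b1, b2) else ("m1" if b1 < b2 else "m2")
    return BicComparison(delta=float(b1 - b2), favored=favored, bic1=b1, bic2=b2)
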