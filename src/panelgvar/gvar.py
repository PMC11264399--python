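"""The panel graphical vector-autoregression (GVAR) probability model.

The model decomposes repeated multivariate observations ``y_{it}`` (person i,
wave t, p items) into a person-level random intercept and a within-person
lag-1 process:

    y_{it} = nu_t + b_i + e_{it}
    e_{it} = B e_{i,t-1} + zeta_{it}

with ``b_i ~ N(0, Sigma_B)``, innovations ``zeta_{it} ~ N(0, Sigma_zeta)``
and the initial deviation drawn from the stationary distribution
``Sigma_* = B Sigma_* B' + Sigma_zeta`` (discrete Lyapunov equation).  The
estimands are the temporal coefficient matrix ``B`` (row = receiver, column =
predictor), the contemporaneous precision ``K_zeta = Sigma_zeta^{-1}``, the
between-person precision ``K_between = Sigma_B^{-1}`` and the wave means
``nu``.  Off-diagonal precision entries are the (negated, scaled) partial
correlations of the contemporaneous and between-person Gaussian graphical
models.

Stacking the waves gives a multivariate normal with block covariance
``Cov(y_t, y_s) = B^{t-s} Sigma_* + Sigma_B`` (t >= s), which is what the
full-information maximum-likelihood (FIML) log-likelihood evaluates on each
person's observed cells — unbiased under missing-at-random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .panel_data import PanelDataset

__all__ = [
    "GVARParameters",
    "EdgePattern",
    "GVARModelError",
    "stationary_covariance",
    "implied_covariance",
    "fiml_loglik",
    "FimlStats",
    "fiml_loglik_and_grad",
    "spectral_radius",
]

LOG_2PI = float(np.log(2.0 * np.pi))


class GVARModelError(ValueError):
    """Invalid parameters (non-stationary B, non-PD precision, bad shapes)."""


def spectral_radius(B: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(B)))) if B.size else 0.0


def _chol_inv(M: np.ndarray, what: str) -> tuple[np.ndarray, float]:
    """(inverse, logdet) via Cholesky; raises GVARModelError if not PD."""
    try:
        c, low = linalg.cho_factor(M, lower=True, check_finite=False)
    except linalg.LinAlgError as e:
        raise GVARModelError(f"{what} is not positive-definite") from e
    inv = linalg.cho_solve((c, low), np.eye(M.shape[0]), check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    return inv, logdet


@dataclass
class GVARParameters:
    """Parameter set of the panel GVAR model.

    ``B[j, i]`` is the lag-1 effect of item i on item j (receiver row,
    predictor column).  ``nu`` has shape (n_waves, p).
    """

    B: np.ndarray
    K_zeta: np.ndarray
    K_between: np.ndarray
    nu: np.ndarray
    item_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        self.K_zeta = np.asarray(self.K_zeta, dtype=float)
        self.K_between = np.asarray(self.K_between, dtype=float)
        self.nu = np.atleast_2d(np.asarray(self.nu, dtype=float))
        p = self.B.shape[0]
        for name, M in (("B", self.B), ("K_zeta", self.K_zeta), ("K_between", self.K_between)):
            if M.shape != (p, p):
                raise GVARModelError(f"{name} must be {p}x{p}")
        for name, M in (("K_zeta", self.K_zeta), ("K_between", self.K_between)):
            if not np.allclose(M, M.T, atol=1e-12):
                raise GVARModelError(f"{name} must be symmetric")
        if self.nu.shape[1] != p:
            raise GVARModelError("nu rows must have length p")
        if not self.item_ids:
            self.item_ids = tuple(f"V{i + 1}" for i in range(p))

    @property
    def p(self) -> int:
        return self.B.shape[0]

    @property
    def n_waves(self) -> int:
        return self.nu.shape[0]

    def validate(self) -> None:
        """Stationarity and positive-definiteness checks (Cholesky-based)."""
        if spectral_radius(self.B) >= 1.0:
            raise GVARModelError("spectral radius of B must be < 1 (stationarity)")
        _chol_inv(self.K_zeta, "K_zeta")
        _chol_inv(self.K_between, "K_between")

    def to_dict(self) -> dict:
        return {
            "item_ids": list(self.item_ids),
            "B": self.B.tolist(),
            "K_zeta": self.K_zeta.tolist(),
            "K_between": self.K_between.tolist(),
            "nu": self.nu.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GVARParameters":
        return cls(
            B=np.array(d["B"]), K_zeta=np.array(d["K_zeta"]),
            K_between=np.array(d["K_between"]), nu=np.array(d["nu"]),
            item_ids=tuple(d.get("item_ids", ())),
        )


@dataclass
class EdgePattern:
    """Free/fixed-to-zero structure of the three parameter matrices.

    ``temporal[j, i]`` marks B[j, i] free; ``contemporaneous`` and ``between``
    mark off-diagonal precision entries free (matrices kept symmetric,
    diagonals always free regardless of the stored value).
    """

    temporal: np.ndarray
    contemporaneous: np.ndarray
    between: np.ndarray

    def __post_init__(self) -> None:
        self.temporal = np.asarray(self.temporal, dtype=bool)
        self.contemporaneous = np.asarray(self.contemporaneous, dtype=bool)
        self.between = np.asarray(self.between, dtype=bool)
        p = self.temporal.shape[0]
        for name, M in (("contemporaneous", self.contemporaneous), ("between", self.between)):
            if M.shape != (p, p):
                raise GVARModelError(f"{name} pattern must be {p}x{p}")
            if not (M == M.T).all():
                raise GVARModelError(f"{name} pattern must be symmetric")
        np.fill_diagonal(self.contemporaneous, True)
        np.fill_diagonal(self.between, True)

    @property
    def p(self) -> int:
        return self.temporal.shape[0]

    @classmethod
    def saturated(cls, p: int) -> "EdgePattern":
        return cls(np.ones((p, p), bool), np.ones((p, p), bool), np.ones((p, p), bool))

    def n_free(self, n_waves: int) -> int:
        """Free parameter count under this pattern, wave means included."""
        p = self.p
        n_offdiag = lambda M: int(np.triu(M, 1).sum())
        return (
            int(self.temporal.sum())
            + p + n_offdiag(self.contemporaneous)
            + p + n_offdiag(self.between)
            + n_waves * p
        )

    def is_subset_of(self, other: "EdgePattern") -> bool:
        return (
            bool((~self.temporal | other.temporal).all())
            and bool((~self.contemporaneous | other.contemporaneous).all())
            and bool((~self.between | other.between).all())
        )


def stationary_covariance(B: np.ndarray, Sigma_zeta: np.ndarray) -> np.ndarray:
    """Solve the discrete Lyapunov equation Sigma* = B Sigma* B' + Sigma_zeta."""
    B = np.asarray(B, float)
    Sigma_zeta = np.asarray(Sigma_zeta, float)
    if spectral_radius(B) >= 1.0:
        raise GVARModelError("spectral radius of B must be < 1 (stationarity)")
    S = linalg.solve_discrete_lyapunov(B, Sigma_zeta)
    return (S + S.T) / 2.0


def implied_covariance(params: GVARParameters, n_waves: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Stacked (n_waves*p) model-implied covariance and mean.

    Block (t, s) with t >= s is ``B^(t-s) Sigma* + Sigma_B``; blocks with
    t < s are the transposes.  Exactly symmetric by construction; positive
    definiteness is verified by Cholesky.
    """
    if n_waves is None:
        n_waves = params.n_waves
    if n_waves != params.n_waves:
        raise GVARModelError("n_waves inconsistent with params.nu")
    p = params.p
    Sigma_zeta, _ = _chol_inv(params.K_zeta, "K_zeta")
    Sigma_B, _ = _chol_inv(params.K_between, "K_between")
    Sstar = stationary_covariance(params.B, Sigma_zeta)
    D = n_waves * p
    Sigma = np.empty((D, D))
    Bpow = [np.eye(p)]
    for _ in range(1, n_waves):
        Bpow.append(Bpow[-1] @ params.B)
    for t in range(n_waves):
        for s in range(t + 1):
            block = Bpow[t - s] @ Sstar + Sigma_B
            if t == s:
                block = (block + block.T) / 2.0
            Sigma[t * p:(t + 1) * p, s * p:(s + 1) * p] = block
            if t != s:
                Sigma[s * p:(s + 1) * p, t * p:(t + 1) * p] = block.T
    _chol_inv(Sigma, "implied covariance")
    mu = params.nu.reshape(-1)
    return Sigma, mu


@dataclass
class FimlStats:
    """Per-missingness-pattern sufficient statistics of a panel dataset.

    Persons are grouped by their observed-cell pattern over the stacked
    (waves x items) vector; each group stores observed indices, count, mean
    and scatter about the group mean.  Persons with zero observed cells
    contribute nothing to the likelihood.
    """

    D: int
    n_persons: int
    groups: list = field(default_factory=list)  # (obs_idx, n_g, mean_g, scatter_g)

    @classmethod
    def from_dataset(cls, ds: PanelDataset) -> "FimlStats":
        Y, obs = ds.stacked()
        D = Y.shape[1]
        groups = []
        keys = np.packbits(obs, axis=1)
        _, inverse = np.unique(keys, axis=0, return_inverse=True)
        for g in np.unique(inverse):
            rows = np.flatnonzero(inverse == g)
            o = np.flatnonzero(obs[rows[0]])
            if o.size == 0:
                continue
            X = Y[np.ix_(rows, o)]
            m = X.mean(axis=0)
            Xc = X - m
            groups.append((o, len(rows), m, Xc.T @ Xc))
        return cls(D=D, n_persons=Y.shape[0], groups=groups)


def _pattern_loglik(Sigma: np.ndarray, mu: np.ndarray, stats: FimlStats,
                    want_grad: bool) -> tuple[float, np.ndarray | None, np.ndarray | None]:
    D = stats.D
    ll = 0.0
    G = np.zeros((D, D)) if want_grad else None
    g_mu = np.zeros(D) if want_grad else None
    for o, n_g, m, S in stats.groups:
        sub = Sigma[np.ix_(o, o)]
        try:
            c, low = linalg.cho_factor(sub, lower=True, check_finite=False)
        except linalg.LinAlgError as e:
            raise GVARModelError(
                f"implied covariance singular on missingness pattern {o.tolist()}"
            ) from e
        inv = linalg.cho_solve((c, low), np.eye(o.size), check_finite=False)
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        d = m - mu[o]
        quad = float(np.sum(inv * S)) + n_g * float(d @ inv @ d)
        ll += -0.5 * (n_g * (o.size * LOG_2PI + logdet) + quad)
        if want_grad:
            A = S + n_g * np.outer(d, d)
            G[np.ix_(o, o)] += -0.5 * (n_g * inv - inv @ A @ inv)
            g_mu[o] += n_g * (inv @ d)
    return ll, G, g_mu


def fiml_loglik(params: GVARParameters, ds: PanelDataset) -> float:
    """FIML log-likelihood: sum over persons of the MVN log-density of their
    observed cells under the model-implied stacked mean/covariance."""
    stats = FimlStats.from_dataset(ds)
    Sigma, mu = implied_covariance(params, ds.n_waves)
    ll, _, _ = _pattern_loglik(Sigma, mu, stats, want_grad=False)
    return ll


def fiml_loglik_and_grad(
    params: GVARParameters, stats: FimlStats
) -> tuple[float, dict[str, np.ndarray]]:
    """Log-likelihood and its analytic gradient w.r.t. B, K_zeta, K_between, nu.

    The gradient is assembled by the adjoint (reverse-mode) chain: MVN
    pattern derivatives w.r.t. the stacked covariance are pushed through the
    block-Toeplitz structure, the discrete Lyapunov equation (via its adjoint
    Lyapunov solve) and the precision-to-covariance inversions.
    """
    p = params.p
    T = params.n_waves
    Sigma_zeta, _ = _chol_inv(params.K_zeta, "K_zeta")
    Sigma_B, _ = _chol_inv(params.K_between, "K_between")
    Sstar = stationary_covariance(params.B, Sigma_zeta)
    Bpow = [np.eye(p)]
    for _ in range(1, T):
        Bpow.append(Bpow[-1] @ params.B)

    D = T * p
    Sigma = np.empty((D, D))
    for t in range(T):
        for s in range(t + 1):
            block = Bpow[t - s] @ Sstar + Sigma_B
            if t == s:
                block = (block + block.T) / 2.0
            Sigma[t * p:(t + 1) * p, s * p:(s + 1) * p] = block
            if t != s:
                Sigma[s * p:(s + 1) * p, t * p:(t + 1) * p] = block.T
    mu = params.nu.reshape(-1)

    ll, G, g_mu = _pattern_loglik(Sigma, mu, stats, want_grad=True)
    G = (G + G.T) / 2.0

    blocks = [[G[t * p:(t + 1) * p, s * p:(s + 1) * p] for s in range(T)] for t in range(T)]
    # between covariance appears in every block
    G_SigB = np.zeros((p, p))
    G_star = np.zeros((p, p))
    g_B = np.zeros((p, p))
    for t in range(T):
        for s in range(T):
            Gts = blocks[t][s]
            G_SigB += Gts
            if t >= s:
                G_star += Bpow[t - s].T @ Gts
            else:
                G_star += Gts @ Bpow[s - t]
    # direct dependence of off-diagonal blocks on B through B^k
    for t in range(T):
        for s in range(t):
            k = t - s
            G2 = 2.0 * blocks[t][s]
            for j in range(k):
                g_B += Bpow[j].T @ G2 @ Sstar @ Bpow[k - 1 - j].T

    G_star = (G_star + G_star.T) / 2.0
    Lam = linalg.solve_discrete_lyapunov(params.B.T, G_star)
    Lam = (Lam + Lam.T) / 2.0
    g_B += 2.0 * Lam @ params.B @ Sstar
    g_Kzeta = -Sigma_zeta @ Lam @ Sigma_zeta
    G_SigB = (G_SigB + G_SigB.T) / 2.0
    g_Kbetween = -Sigma_B @ G_SigB @ Sigma_B
    g_nu = g_mu.reshape(T, p)

    return ll, {"B": g_B, "K_zeta": g_Kzeta, "K_between": g_Kbetween, "nu": g_nu}
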