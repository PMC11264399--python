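"""Synthetic panels with known ground truth, ordinalization and attrition.

This module generates the data regime the estimation pipeline assumes it is
facing: a latent panel GVAR process with a known sparse network, mapped onto
right-skewed 4-category Likert items through per-item normal-quantile
thresholds calibrated to printed item means/SDs of a postnatal-depression
item battery (EPDS), and thinned by monotone score-dependent attrition (MAR
given observed history).  Continuous complete-data mode isolates estimator
correctness; the ordinal + attrition mode exercises the full measurement
regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .gvar import GVARParameters, implied_covariance, spectral_radius, stationary_covariance, _chol_inv
from .panel_data import ItemSchema, PanelDataset

__all__ = [
    "TruthSpec",
    "AttritionSpec",
    "make_truth",
    "simulate_panel",
    "ordinalize",
    "calibrate_thresholds",
    "apply_attrition",
    "lin_preset",
    "SyntheticStudy",
    "LIN_T1_MOMENTS",
]


@dataclass(frozen=True)
class TruthSpec:
    """Recipe for a random sparse ground-truth parameter set."""

    p: int = 6
    temporal_density: float = 0.15
    contemporaneous_density: float = 0.25
    between_density: float = 0.25
    weight_range: tuple[float, float] = (0.25, 0.45)
    ar_range: tuple[float, float] = (0.15, 0.35)
    target_spectral_radius: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.temporal_density, self.contemporaneous_density, self.between_density):
            if not 0 <= d <= 1:
                raise ValueError("densities must be in [0, 1]")
        if not 0 < self.target_spectral_radius < 1:
            raise ValueError("target_spectral_radius must be in (0, 1)")


@dataclass(frozen=True)
class AttritionSpec:
    """Per-transition logistic dropout: P = expit(logit(base) + slope * total).

    ``base_rate`` is one rate per wave transition (scalar broadcast); ``slope``
    is the log-odds increase per unit of the previous wave's symptom total, so
    slope > 0 makes higher-scoring persons drop out more — the mechanism that
    produces the completers-vs-dropouts baseline difference.
    """

    base_rate: tuple[float, ...] | float = 0.10
    slope: float = 0.0

    def rates(self, n_transitions: int) -> np.ndarray:
        r = np.atleast_1d(np.asarray(self.base_rate, float))
        if r.size == 1:
            r = np.repeat(r, n_transitions)
        if r.size != n_transitions:
            raise ValueError("base_rate length must equal number of wave transitions")
        if ((r < 0) | (r >= 1)).any():
            raise ValueError("base rates must be in [0, 1)")
        return r


def _sparse_precision(rng: np.random.Generator, p: int, density: float,
                      weight_range: tuple[float, float]) -> np.ndarray:
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    n_edges = int(round(density * len(pairs)))
    K = np.eye(p)
    if n_edges:
        chosen = rng.choice(len(pairs), size=n_edges, replace=False)
        for c in chosen:
            i, j = pairs[c]
            w = rng.uniform(*weight_range) * rng.choice([-1.0, 1.0])
            K[i, j] = K[j, i] = -w  # partial correlation ~ +w under unit diagonal
    # diagonal dominance guarantees positive definiteness
    row = np.abs(K - np.diag(np.diag(K))).sum(axis=1)
    np.fill_diagonal(K, 1.0 + np.where(row > 0, 1.05 * row, 0.0))
    np.linalg.cholesky(K)
    return K


def make_truth(spec: TruthSpec) -> GVARParameters:
    """Draw a reproducible sparse ground-truth parameter set.

    B gets autoregressive diagonal entries plus randomly placed cross-lagged
    weights and is rescaled so its spectral radius equals the target exactly;
    the precisions are sparse symmetric with diagonal dominance.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.p
    B = np.diag(rng.uniform(*spec.ar_range, size=p))
    cells = [(i, j) for i in range(p) for j in range(p) if i != j]
    n_edges = int(round(spec.temporal_density * len(cells)))
    if n_edges:
        chosen = rng.choice(len(cells), size=n_edges, replace=False)
        for c in chosen:
            i, j = cells[c]
            B[i, j] = rng.uniform(*spec.weight_range) * rng.choice([-1.0, 1.0])
    rho = spectral_radius(B)
    if rho > 0:
        B *= spec.target_spectral_radius / rho
    K_zeta = _sparse_precision(rng, p, spec.contemporaneous_density, spec.weight_range)
    K_between = _sparse_precision(rng, p, spec.between_density, spec.weight_range)
    nu = np.zeros((3, p))
    return GVARParameters(B, K_zeta, K_between, nu)


def simulate_panel(
    params: GVARParameters,
    n_persons: int,
    n_waves: int | None = None,
    seed: int = 0,
    *,
    wave_labels: tuple[str, ...] | None = None,
    n_categories: int = 4,
) -> PanelDataset:
    """Simulate a continuous panel from the GVAR generative process.

    Person intercepts are drawn from N(0, Sigma_B), the wave-1 within-person
    deviation from the stationary distribution N(0, Sigma*), and subsequent
    deviations via the lag-1 recursion with N(0, Sigma_zeta) innovations;
    observed score = wave mean + intercept + deviation.
    """
    if n_waves is None:
        n_waves = params.n_waves
    p = params.p
    rng = np.random.default_rng(seed)
    Sigma_zeta, _ = _chol_inv(params.K_zeta, "K_zeta")
    Sigma_B, _ = _chol_inv(params.K_between, "K_between")
    Sstar = stationary_covariance(params.B, Sigma_zeta)
    L_B = np.linalg.cholesky(Sigma_B)
    L_star = np.linalg.cholesky(Sstar)
    L_zeta = np.linalg.cholesky(Sigma_zeta)

    intercepts = rng.standard_normal((n_persons, p)) @ L_B.T
    dev = rng.standard_normal((n_persons, p)) @ L_star.T
    scores = np.empty((n_persons, n_waves, p))
    nu = params.nu
    if nu.shape[0] < n_waves:
        nu = np.vstack([nu, np.tile(nu[-1], (n_waves - nu.shape[0], 1))])
    for t in range(n_waves):
        if t > 0:
            dev = dev @ params.B.T + rng.standard_normal((n_persons, p)) @ L_zeta.T
        scores[:, t, :] = nu[t] + intercepts + dev
    if wave_labels is None:
        wave_labels = tuple(f"T{t + 1}" for t in range(n_waves))
    schema = ItemSchema(params.item_ids, n_categories, wave_labels)
    return PanelDataset(schema, scores, np.zeros_like(scores, dtype=bool), ordinal=False)


def ordinalize(ds: PanelDataset, thresholds) -> PanelDataset:
    """Cut continuous latent scores into categories at per-item thresholds.

    ``thresholds`` maps item id -> strictly ascending cut list (or a (p,
    n_cuts) array); the category is the number of thresholds below the
    latent value.
    """
    p = ds.n_items
    if isinstance(thresholds, dict):
        T = np.array([np.asarray(thresholds[item], float) for item in ds.schema.item_ids])
    else:
        T = np.asarray(thresholds, float)
    if T.shape[0] != p:
        raise ValueError("one threshold row per item required")
    if not (np.diff(T, axis=1) > 0).all():
        raise ValueError("thresholds must be strictly ascending per item")
    n_cat = T.shape[1] + 1
    scores = np.zeros_like(ds.scores)
    for j in range(p):
        scores[:, :, j] = (ds.scores[:, :, j][..., None] > T[j]).sum(axis=-1)
    scores[ds.missing_mask] = np.nan
    schema = ItemSchema(ds.schema.item_ids, n_cat, ds.schema.wave_labels)
    return PanelDataset(schema, scores, ds.missing_mask.copy(), ds.person_ids, ds.group, ordinal=True)


def _categorical_moments(u: np.ndarray) -> tuple[float, float]:
    """Mean and SD of the category index when the latent is standard normal
    and the standardized thresholds are u (ascending)."""
    cdf = stats.norm.cdf(u)
    probs = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
    k = np.arange(probs.size)
    mean = float(probs @ k)
    var = float(probs @ (k - mean) ** 2)
    return mean, float(np.sqrt(max(var, 0.0)))


def feasible_sd_interval(target_mean: float, n_categories: int = 4) -> tuple[float, float]:
    """Attainable SD range for a categorical mean on {0..n_categories-1}."""
    m = n_categories - 1
    if not 0 < target_mean < m:
        return (0.0, 0.0)
    frac = target_mean - np.floor(target_mean)
    lo = float(np.sqrt(frac * (1 - frac)))
    hi = float(np.sqrt(target_mean * (m - target_mean)))
    return lo, hi


def calibrate_thresholds(
    target_mean: float,
    target_sd: float,
    latent_sd: float = 1.0,
    *,
    n_categories: int = 4,
    tol: float = 0.01,
    on_infeasible_sd: str = "error",
) -> np.ndarray:
    """Find normal-quantile thresholds matching a categorical mean and SD.

    Solves for ``n_categories - 1`` ascending thresholds on a N(0,
    latent_sd^2) latent such that the implied categorical mean and SD match
    the targets within ``tol``.  The system is underdetermined by one degree
    of freedom; a small regularizer toward equal threshold spacing pins it
    down.  If the SD is unattainable for the mean, behaviour follows
    ``on_infeasible_sd``: "error" (default, reporting the feasible interval)
    or "mean_only" (match the mean with a geometric category profile).
    """
    m = n_categories - 1
    if not 0 < target_mean < m:
        raise ValueError(f"target mean must be strictly inside (0, {m})")
    lo, hi = feasible_sd_interval(target_mean, n_categories)
    sd_feasible = lo + 1e-9 < target_sd < hi - 1e-9
    if not sd_feasible:
        if on_infeasible_sd == "error":
            raise ValueError(
                f"target SD {target_sd} unattainable for mean {target_mean}; "
                f"feasible interval is ({lo:.4f}, {hi:.4f})"
            )
        return _mean_only_thresholds(target_mean, latent_sd, n_categories)

    def residuals(x):
        u = np.concatenate([[x[0]], x[0] + np.cumsum(np.exp(x[1:]))])
        mean, sd = _categorical_moments(u)
        gaps = np.diff(u)
        reg = 1e-3 * (gaps - gaps.mean()) if gaps.size > 1 else np.zeros(0)
        return np.concatenate([[mean - target_mean, sd - target_sd], reg])

    best = None
    for spread in (0.5, 1.0, 1.5):
        u0 = _mean_only_thresholds(target_mean, 1.0, n_categories)
        x0 = np.concatenate([[u0[0]], np.log(np.maximum(np.diff(u0) * spread, 1e-3))])
        sol = optimize.least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        u = np.concatenate([[sol.x[0]], sol.x[0] + np.cumsum(np.exp(sol.x[1:]))])
        mean, sd = _categorical_moments(u)
        err = max(abs(mean - target_mean), abs(sd - target_sd))
        if best is None or err < best[0]:
            best = (err, u)
        if err < tol / 10:
            break
    err, u = best
    if err > tol:
        if on_infeasible_sd == "error":
            raise ValueError(
                f"threshold calibration failed: moment error {err:.4g} > {tol}"
            )
        return _mean_only_thresholds(target_mean, latent_sd, n_categories)
    return u * latent_sd


def _mean_only_thresholds(target_mean: float, latent_sd: float, n_categories: int) -> np.ndarray:
    """Thresholds of a geometric category profile p_k ~ r^k matched to the mean."""
    m = n_categories - 1
    k = np.arange(n_categories)

    def mean_of(r):
        w = r ** k
        return (w @ k) / w.sum()

    r = optimize.brentq(lambda r: mean_of(r) - target_mean, 1e-12, 1e12, xtol=1e-14)
    probs = r ** k
    probs /= probs.sum()
    cum = np.clip(np.cumsum(probs)[:-1], 1e-12, 1 - 1e-12)
    u = stats.norm.ppf(cum)
    # enforce strict ascent in degenerate tails
    for i in range(1, u.size):
        if u[i] <= u[i - 1]:
            u[i] = u[i - 1] + 1e-6
    return u * latent_sd


def apply_attrition(ds: PanelDataset, spec: AttritionSpec, seed: int = 0) -> PanelDataset:
    """Monotone wave dropout with logistic dependence on the previous total.

    At each wave transition every person still in the study drops out with
    probability expit(logit(base_rate) + slope * previous-wave total); once
    dropped, all later waves are missing entirely.  Missingness depends only
    on observed history, hence MAR.
    """
    rates = spec.rates(ds.n_waves - 1)
    rng = np.random.default_rng(seed)
    mask = ds.missing_mask.copy()
    active = np.ones(ds.n_persons, dtype=bool)
    for t in range(1, ds.n_waves):
        base = rates[t - 1]
        if base <= 0 and spec.slope == 0:
            continue
        prev_total = np.where(
            (~mask[:, t - 1, :]).any(axis=1),
            np.nansum(np.where(mask[:, t - 1, :], 0.0, ds.scores[:, t - 1, :]), axis=1),
            0.0,
        )
        logit = np.log(base / (1 - base)) if base > 0 else -np.inf
        p_drop = 1.0 / (1.0 + np.exp(-(logit + spec.slope * prev_total)))
        drop = active & (rng.random(ds.n_persons) < p_drop)
        active &= ~drop
        mask[drop, t:, :] = True
    out = ds.scores.copy()
    out[mask] = np.nan
    return PanelDataset(ds.schema, out, mask, ds.person_ids, ds.group, ds.ordinal)


# --------------------------------------------------------------------------
# study-calibrated preset

#: Printed wave-1 item means and SDs (0-3 scale) used as calibration targets.
LIN_T1_MOMENTS: dict[str, list[tuple[float, float]]] = {
    "mothers": [
        (0.114, 0.371), (0.119, 0.379), (0.532, 0.720), (0.667, 0.786),
        (0.192, 0.493), (0.648, 0.681), (0.160, 0.474), (0.405, 0.611),
        (0.175, 0.410), (0.012, 0.135),
    ],
    "fathers": [
        (0.100, 0.333), (0.123, 0.382), (0.468, 0.668), (0.473, 0.691),
        (0.105, 0.354), (0.565, 0.689), (0.192, 0.499), (0.304, 0.534),
        (0.042, 0.216), (0.014, 0.144),
    ],
}

#: Per-transition dropout hazards implied by the printed cumulative dropout
#: percentages (mothers 11.74% by T2, 15.30% by T3; fathers 4.84%, 10.36%).
LIN_ATTRITION_HAZARDS = {"mothers": (0.1174, 0.0403), "fathers": (0.0484, 0.0580)}

LIN_DEFAULT_N = {"mothers": 869, "fathers": 579}

_LIN_ITEM_IDS = tuple(f"EPDS{i}" for i in range(1, 11))
_LIN_TRUTH_SEED = 20120901  # fixed: the ground truth is part of the scenario
_LIN_ATTRITION_SLOPE = 0.08  # log-odds per point of the previous-wave total


@dataclass
class SyntheticStudy:
    """A generated study-like dataset with its ground truth."""

    dataset: PanelDataset  # ordinal, with attrition applied
    truth: GVARParameters  # 10-item truth (modelled 9 + near-constant item)
    thresholds: np.ndarray
    group: str
    seed: int


def lin_truth(group: str = "mothers") -> GVARParameters:
    """Fixed 10-item ground truth: a sparse 9-item network plus a 10th item
    (the near-constant suicidal-ideation analogue) kept independent of the
    rest so that screening it out leaves an exact 9-item panel GVAR."""
    base = make_truth(TruthSpec(
        p=9, temporal_density=0.12, contemporaneous_density=0.28,
        between_density=0.25, weight_range=(0.3, 0.45), ar_range=(0.2, 0.35),
        target_spectral_radius=0.55,
        seed=_LIN_TRUTH_SEED + (0 if group == "mothers" else 1),
    ))
    p = 10
    B = np.zeros((p, p)); B[:9, :9] = base.B; B[9, 9] = 0.2
    Kz = np.eye(p); Kz[:9, :9] = base.K_zeta
    Kb = np.eye(p); Kb[:9, :9] = base.K_between
    return GVARParameters(B, Kz, Kb, np.zeros((3, p)), _LIN_ITEM_IDS)


def lin_preset(group: str = "mothers", n_persons: int | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate a study-regime dataset: 10 ordinal items (one near-constant),
    3 waves, thresholds calibrated to the printed wave-1 moments, and
    score-dependent monotone attrition matching the printed dropout rates."""
    if group not in LIN_T1_MOMENTS:
        raise ValueError(f"unknown group {group!r}")
    if n_persons is None:
        n_persons = LIN_DEFAULT_N[group]
    truth = lin_truth(group)
    latent = simulate_panel(truth, n_persons, seed=seed)
    Sigma, _ = implied_covariance(truth)
    latent_sd = np.sqrt(np.diag(Sigma)[: truth.p])
    thresholds = np.array([
        calibrate_thresholds(mean, sd, latent_sd[j], on_infeasible_sd="mean_only")
        for j, (mean, sd) in enumerate(LIN_T1_MOMENTS[group])
    ])
    ordinal = ordinalize(latent, thresholds)
    # intercept offset keeps the marginal dropout near the printed hazard
    mean_total = sum(m for m, _ in LIN_T1_MOMENTS[group])
    hazards = LIN_ATTRITION_HAZARDS[group]
    adj = tuple(
        float(1.0 / (1.0 + np.exp(-(np.log(h / (1 - h)) - _LIN_ATTRITION_SLOPE * mean_total))))
        for h in hazards
    )
    spec = AttritionSpec(base_rate=adj, slope=_LIN_ATTRITION_SLOPE)
    ds = apply_attrition(ordinal, spec, seed=seed + 1)
    ds.group = group
    return SyntheticStudy(dataset=ds, truth=truth, thresholds=thresholds, group=group, seed=seed)
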