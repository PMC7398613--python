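"""Synthetic claims cohort generator.

No patient-level extract of the source claims database can be shipped, so
this module generates a cohort whose *computed* summary statistics
reproduce the published moment tables: a Gaussian copula (NORTA) draws the
ten study variables with the published correlation structure, each mapped
through a moment-matched marginal, and a claims realizer then lays down
pharmacy fills whose recomputed MPR/PDC land on each patient's profile
values.  Every upstream stage of the pipeline is therefore testable
end-to-end on data with known ground truth.

Marginal families (calibrated once per target SSD):

* age — truncated normal on [18, 95], rounded to integer years;
* utilization counts — negative binomial matched to the printed
  mean/variance (this alone reproduces the printed zero masses, e.g. 3.0%
  of patients with >= 1 hospitalization, so no explicit zero-inflation
  component is needed);
* all-medication fills and comorbidity score — 1 + negative binomial
  (every cohort member has >= 1 fill; asthma itself contributes a
  chronic-pulmonary point), score capped at 33;
* PDC — Beta matched to mean and SD (PDC is bounded away from 0 by cohort
  construction);
* MPR — point mass at zero (the single-fill coding rule) mixed with a
  Beta body, then floored at the same patient's PDC.

The floor is not a convenience: for any multi-fill patient MPR >= PDC is an
identity of the two formulas (total supply >= distinct covered days, and
the first-to-last-fill span is contained in the first-fill-to-period-end
window), so the observed cohort necessarily satisfies it and an unconstrained
copula draw would not.  The MPR mixture parameters and the MPR–PDC latent
correlation are therefore calibrated *through* the floor by simulation, so
the post-floor margin and correlation match the printed values.

The latent Gaussian correlation for every other pair is found by
root-finding on the exact NORTA map (two-dimensional Gauss–Hermite
quadrature), so the transformed variables carry the *linear* target
correlations, not rank approximations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .claims import (DrugClass, MedicalEventCounts, PatientRecord,
                     PharmacyClaim, patient_table)
from .ssd import SummaryDataset, build_ssd, to_correlation


class CalibrationError(ValueError):
    """Raised when a marginal family cannot match the requested moments."""


# ---------------------------------------------------------------------------
# Marginal families (each exposes a quantile function ppf: [0,1] -> value)
# ---------------------------------------------------------------------------

@dataclass
class Marginal:
    """Quantile function plus, for discrete families, the exact step layout.

    ``values``/``u_edges`` describe the ppf as a step function: the variable
    equals ``values[k]`` for uniforms in ``(u_edges[k-1], u_edges[k]]``.
    The NORTA inversion integrates these pieces exactly; continuous
    marginals (``values is None``) are handled by quadrature.
    ``jumps`` lists interior discontinuities of a continuous ppf (the MPR
    zero mass) so quadrature can split there.
    """

    name: str
    ppf: Callable[[np.ndarray], np.ndarray]
    integer: bool = False
    values: np.ndarray | None = None
    u_edges: np.ndarray | None = None
    jumps: tuple[float, ...] = ()

    @property
    def discrete(self) -> bool:
        return self.values is not None


def _merge_pieces(values: np.ndarray, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse adjacent equal-valued pieces (arises from capping)."""
    keep = np.r_[np.diff(values) != 0, True]
    return values[keep], edges[keep]


def _truncnorm_marginal(name: str, mean: float, sd: float,
                        lo: float = 18.0, hi: float = 95.0) -> Marginal:
    """Truncated normal with the *truncated* moments matched to (mean, sd)."""

    def moments(params: np.ndarray) -> np.ndarray:
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        d = stats.truncnorm(a, b, loc=mu, scale=sigma)
        return np.array([d.mean() - mean, d.std() - sd])

    sol = optimize.root(moments, x0=np.array([mean, math.log(sd)]), tol=1e-12)
    if not sol.success:
        raise CalibrationError(f"{name}: truncated-normal moment match failed")
    mu, sigma = sol.x[0], math.exp(sol.x[1])
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    dist = stats.truncnorm(a, b, loc=mu, scale=sigma)
    values = np.arange(int(lo), int(hi) + 1, dtype=float)
    edges = np.r_[dist.cdf(values[:-1] + 0.5), 1.0]
    values, edges = _merge_pieces(values, edges)
    return Marginal(name, lambda u: np.round(dist.ppf(u)), integer=True,
                    values=values, u_edges=edges)


def _nbinom_marginal(name: str, mean: float, var: float,
                     shift: int = 0, cap: int | None = None) -> Marginal:
    """Negative binomial matched to mean/variance, optionally shifted/capped."""
    m = mean - shift
    if m <= 0 or var <= m:
        raise CalibrationError(
            f"{name}: mean {mean} / variance {var} infeasible for a "
            f"(shifted) negative binomial (variance must exceed the mean)")
    r = m * m / (var - m)
    p = r / (r + m)
    dist = stats.nbinom(r, p)

    def ppf(u: np.ndarray) -> np.ndarray:
        x = dist.ppf(u) + shift
        return np.minimum(x, cap) if cap is not None else x

    k_max = int(dist.ppf(1 - 1e-11))
    k = np.arange(k_max + 1)
    values = (k + shift).astype(float)
    if cap is not None:
        values = np.minimum(values, cap)
    edges = np.r_[dist.cdf(k[:-1]), 1.0]  # tail mass beyond k_max -> last value
    values, edges = _merge_pieces(values, edges)
    return Marginal(name, ppf, integer=True, values=values, u_edges=edges)


def _beta_marginal(name: str, mean: float, sd: float) -> Marginal:
    nu = mean * (1 - mean) / sd ** 2 - 1
    if nu <= 0:
        raise CalibrationError(f"{name}: SD {sd} too large for a Beta with mean {mean}")
    dist = stats.beta(mean * nu, (1 - mean) * nu)
    return Marginal(name, dist.ppf)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohortConfig:
    """Cohort size, seed, target moments, and claims-level detail."""

    target: SummaryDataset
    medians: dict[str, float]
    n: int = 37_359
    seed: int = 20180401
    supply_days: int = 30          # nominal per-fill days of supply
    max_supply_days: int = 90      # dispensing cap when the fill budget binds
    period_length: int = 365
    los_moments: tuple[float, float, float] = (5.61, 6.80, 4.0)  # mean, sd, median

    def __post_init__(self) -> None:
        if self.n < 2:
            raise CalibrationError("cohort size must be >= 2")


def default_marginals(config: SyntheticCohortConfig) -> dict[str, Marginal]:
    """Moment-matched marginal per study variable (MPR handled separately)."""
    t = config.target
    var = {name: float(t.cov[i, i]) for i, name in enumerate(t.names)}
    mean = dict(zip(t.names, t.means))
    sd = dict(zip(t.names, t.sds))
    out: dict[str, Marginal] = {}
    for name in t.names:
        if name == "mpr":
            continue  # calibrated through the PDC floor, see calibrate()
        if name == "age":
            out[name] = _truncnorm_marginal(name, mean[name], sd[name])
        elif name == "qci_score":
            out[name] = _nbinom_marginal(name, mean[name], var[name], shift=1, cap=33)
        elif name == "pharmacy_fills":
            out[name] = _nbinom_marginal(name, mean[name], var[name], shift=1)
        elif name == "pdc":
            out[name] = _beta_marginal(name, mean[name], sd[name])
        else:  # utilization counts
            out[name] = _nbinom_marginal(name, mean[name], var[name])
    return out


# ---------------------------------------------------------------------------
# NORTA latent-correlation calibration
# ---------------------------------------------------------------------------

_GH_NODES = 48
_U_EPS = 1e-12


def _norm_u(z: np.ndarray) -> np.ndarray:
    """Normal CDF clipped away from {0, 1} (discrete ppfs return inf at 1)."""
    return np.clip(stats.norm.cdf(z), _U_EPS, 1 - _U_EPS)


def _outer_nodes(m: Marginal, per_piece: int = 8, n_cont: int = 200):
    """Quadrature nodes/weights on u in (0,1) for E[q_i(u) h(u)] integrals.

    Discrete marginals integrate each constant piece exactly (Gauss–Legendre
    inside every piece); continuous ones use composite Gauss–Legendre split
    at any interior jump of the ppf.
    """
    gl_x, gl_w = np.polynomial.legendre.leggauss(per_piece)
    if m.discrete:
        edges = np.r_[0.0, m.u_edges]
    else:
        cuts = np.r_[0.0, np.sort(np.asarray(m.jumps, dtype=float)), 1.0]
        edges = np.unique(np.concatenate(
            [np.linspace(cuts[i], cuts[i + 1], n_cont + 1) for i in range(len(cuts) - 1)]))
    lo, hi = edges[:-1], edges[1:]
    half = (hi - lo) / 2.0
    centers = (hi + lo) / 2.0
    u = (centers[:, None] + half[:, None] * gl_x[None, :]).ravel()
    w = (half[:, None] * gl_w[None, :]).ravel()
    u = np.clip(u, _U_EPS, 1 - _U_EPS)
    return u, w


def _conditional_mean(m: Marginal, mean_z: np.ndarray, sd_z: float) -> np.ndarray:
    """E[q_m(Phi(Z))] for Z ~ N(mean_z, sd_z^2), vectorized over mean_z.

    Exact for discrete marginals (sum over pieces of normal rectangle
    probabilities at the jump thresholds); Gauss–Hermite for continuous.
    """
    if m.discrete:
        t = stats.norm.ppf(np.clip(m.u_edges[:-1], _U_EPS, 1 - _U_EPS))
        cdf = stats.norm.cdf((t[None, :] - mean_z[:, None]) / sd_z)
        probs = np.diff(np.concatenate(
            [np.zeros((len(mean_z), 1)), cdf, np.ones((len(mean_z), 1))], axis=1), axis=1)
        return probs @ m.values
    x, wx = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    w = wx / wx.sum()
    z = mean_z[:, None] + sd_z * x[None, :]
    return m.ppf(_norm_u(z)) @ w


def _norta_pair_corr(mi: Marginal, mj: Marginal, rho: float,
                     mu: tuple[float, float], sigma: tuple[float, float]) -> float:
    """Linear correlation of (F_i^-1(Phi(z1)), F_j^-1(Phi(z2))) for latent corr rho."""
    u, w = _outer_nodes(mi)
    qi = mi.ppf(u)
    z1 = stats.norm.ppf(u)
    sd = math.sqrt(max(1 - rho * rho, 1e-12))
    h = _conditional_mean(mj, rho * z1, sd)
    exy = float(np.dot(w, qi * h))
    return (exy - mu[0] * mu[1]) / (sigma[0] * sigma[1])


def _marginal_moments(m: Marginal) -> tuple[float, float]:
    if m.discrete:
        p = np.diff(np.r_[0.0, m.u_edges])
        mu = float(p @ m.values)
        var = float(p @ (m.values - mu) ** 2)
        return mu, math.sqrt(var)
    u, w = _outer_nodes(m)
    q = m.ppf(u)
    mu = float(w @ q)
    var = float(w @ (q - mu) ** 2)
    return mu, math.sqrt(var)


def latent_correlation(
    marginals: Sequence[Marginal],
    target_corr: np.ndarray,
    frozen: dict[tuple[int, int], float] | None = None,
) -> tuple[np.ndarray, list[tuple[str, str, float, float]]]:
    """Invert the NORTA map pairwise; returns (latent matrix, clamped pairs).

    ``frozen`` pins selected latent entries (used for the MPR–PDC pair,
    whose latent correlation is calibrated through the feasibility floor
    rather than by the plain NORTA map).  Targets outside the
    copula-achievable range are clamped to the boundary and reported.  The
    assembled matrix is repaired to the nearest PSD correlation matrix.
    """
    k = len(marginals)
    moments = [_marginal_moments(m) for m in marginals]
    L = np.eye(k)
    clamped: list[tuple[str, str, float, float]] = []
    frozen = frozen or {}
    for i in range(k):
        for j in range(i + 1, k):
            if (i, j) in frozen:
                L[i, j] = L[j, i] = frozen[(i, j)]
                continue
            r_t = float(target_corr[i, j])
            if abs(r_t) < 1e-12:
                continue
            mu = (moments[i][0], moments[j][0])
            sg = (moments[i][1], moments[j][1])
            f = lambda rho: _norta_pair_corr(marginals[i], marginals[j], rho, mu, sg) - r_t
            lo, hi = -0.9995, 0.9995
            flo, fhi = f(lo), f(hi)
            if fhi < 0:  # target above the achievable maximum
                clamped.append((marginals[i].name, marginals[j].name, r_t, fhi + r_t))
                rho = hi
            elif flo > 0:
                clamped.append((marginals[i].name, marginals[j].name, r_t, flo + r_t))
                rho = lo
            else:
                rho = optimize.brentq(f, lo, hi, xtol=1e-6)
            L[i, j] = L[j, i] = rho
    w, v = np.linalg.eigh(L)
    if w[0] < 1e-10:
        w = np.clip(w, 1e-10, None)
        L = (v * w) @ v.T
        d = np.sqrt(np.diag(L))
        L = L / np.outer(d, d)
        np.fill_diagonal(L, 1.0)
    return L, clamped


# ---------------------------------------------------------------------------
# Adherence-pair calibration through the feasibility floor
# ---------------------------------------------------------------------------

@dataclass
class AdherenceParams:
    """Zero-mass weight, Beta body, and MPR–PDC latent correlation."""

    p0: float
    alpha: float
    beta: float
    rho_latent: float

    def mpr_raw(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u)
        out = np.zeros_like(u, dtype=float)
        mask = u >= self.p0
        scaled = (u[mask] - self.p0) / (1 - self.p0)
        out[mask] = stats.beta.ppf(scaled, self.alpha, self.beta)
        return out


def apply_adherence_floor(mpr_raw: np.ndarray, pdc: np.ndarray) -> np.ndarray:
    """MPR >= PDC for multi-fill patients; zero-coded patients keep MPR = 0."""
    return np.where(mpr_raw > 0, np.maximum(mpr_raw, pdc), 0.0)


def calibrate_adherence(
    mean: float, sd: float, median: float, corr: float,
    pdc_marginal: Marginal,
    n_sim: int = 60_000,
    sim_seed: int = 20200101,
) -> AdherenceParams:
    """Find (p0, alpha, beta, rho) whose post-floor MPR matches the targets.

    Uses common random numbers (one fixed latent draw reused across
    evaluations) so the simulated moments are smooth in the parameters, and
    a least-squares solve over [mean, sd, median, corr(mpr, pdc)].
    """
    rng = np.random.default_rng(sim_seed)
    z1 = rng.standard_normal(n_sim)
    z2 = rng.standard_normal(n_sim)
    u1 = _norm_u(z1)

    def realized(x: np.ndarray) -> np.ndarray:
        p0 = 0.5 / (1 + math.exp(-x[0]))            # (0, 0.5)
        alpha, beta = math.exp(x[1]), math.exp(x[2])
        rho = math.tanh(x[3])
        params = AdherenceParams(p0, alpha, beta, rho)
        za = rho * z1 + math.sqrt(1 - rho * rho) * z2
        a = pdc_marginal.ppf(_norm_u(za))
        m = apply_adherence_floor(params.mpr_raw(u1), a)
        return np.array([
            m.mean() - mean,
            m.std(ddof=1) - sd,
            float(np.median(m)) - median,
            float(np.corrcoef(m, a)[0, 1]) - corr,
        ])

    x0 = np.array([math.log(0.13 / (0.5 - 0.13)), math.log(0.9),
                   math.log(0.5), math.atanh(0.45)])
    sol = optimize.least_squares(realized, x0, xtol=1e-12, ftol=1e-12)
    resid = np.abs(sol.fun)
    if np.any(resid > np.array([5e-3, 5e-3, 1e-2, 2e-2])):
        raise CalibrationError(
            f"adherence calibration did not converge (residuals {sol.fun})")
    x = sol.x
    return AdherenceParams(0.5 / (1 + math.exp(-x[0])), math.exp(x[1]),
                           math.exp(x[2]), math.tanh(x[3]))


def _mpr_cross_latent(
    adh: AdherenceParams,
    pdc_marginal: Marginal,
    x_marginal: Marginal,
    r_x_pdc_latent: float,
    target: float,
    draws: tuple[np.ndarray, np.ndarray, np.ndarray],
) -> tuple[float, bool]:
    """Latent correlation between a covariate and the MPR driver.

    The observed MPR is a function of *two* latents (its own driver and,
    through the feasibility floor, the PDC driver), so the plain NORTA map
    does not apply.  This inverts corr(x, mpr_final) = target by simulation
    with common random numbers, holding the covariate's already-known
    latent correlation with the PDC driver fixed.
    """
    z1, z2, z3 = draws
    rho = adh.rho_latent
    s = math.sqrt(1 - rho * rho)
    a = pdc_marginal.ppf(_norm_u(rho * z1 + s * z2))
    m = apply_adherence_floor(adh.mpr_raw(_norm_u(z1)), a)

    def gap(theta: float) -> float:
        b2 = (r_x_pdc_latent - theta * rho) / s
        c = max(1.0 - theta * theta - b2 * b2, 0.0)
        zx = theta * z1 + b2 * z2 + math.sqrt(c) * z3
        xv = x_marginal.ppf(_norm_u(zx))
        return float(np.corrcoef(xv, m)[0, 1]) - target

    # admissible interval for theta (unit-variance constraint on z_x)
    disc = math.sqrt(max((1 - rho ** 2) * (1 - r_x_pdc_latent ** 2), 0.0))
    lo = r_x_pdc_latent * rho - disc + 1e-9
    hi = r_x_pdc_latent * rho + disc - 1e-9
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo > 0:
        return lo, True
    if g_hi < 0:
        return hi, True
    return optimize.brentq(gap, lo, hi, xtol=1e-6), False


@dataclass
class CohortCalibration:
    """Everything deterministic the sampler needs: marginals + latent matrix."""

    names: list[str]
    marginals: dict[str, Marginal]
    adherence: AdherenceParams
    latent: np.ndarray
    clamped_pairs: list[tuple[str, str, float, float]]


_CALIBRATION_CACHE: dict[bytes, CohortCalibration] = {}


def calibrate(config: SyntheticCohortConfig,
              n_sim: int = 60_000, sim_seed: int = 20200101) -> CohortCalibration:
    """One-off calibration of all marginals and the latent correlation.

    Deterministic in its inputs, hence memoized: repeated cohort draws
    (tests, CLI, sensitivity reruns) skip the ~20 s solve.
    """
    t = config.target
    key = (t.cov.tobytes() + t.means.tobytes()
           + repr(sorted(config.medians.items())).encode()
           + f"{n_sim}:{sim_seed}".encode())
    cached = _CALIBRATION_CACHE.get(key)
    if cached is not None:
        return cached
    marginals = default_marginals(config)
    mean = dict(zip(t.names, t.means))
    sd = dict(zip(t.names, t.sds))
    R = to_correlation(t).to_numpy()
    i_mpr, i_pdc = t.index("mpr"), t.index("pdc")
    adh = calibrate_adherence(
        mean["mpr"], sd["mpr"], config.medians["mpr"],
        float(R[i_mpr, i_pdc]), marginals["pdc"],
        n_sim=n_sim, sim_seed=sim_seed,
    )
    marginals["mpr"] = Marginal("mpr", adh.mpr_raw, jumps=(adh.p0,))
    ordered = [marginals[name] for name in t.names]
    key = (min(i_mpr, i_pdc), max(i_mpr, i_pdc))
    L, clamped = latent_correlation(ordered, R, frozen={key: adh.rho_latent})
    # the MPR column needs the floor-aware inversion, not the raw NORTA map
    rng = np.random.default_rng(sim_seed + 1)
    draws = tuple(rng.standard_normal((3, n_sim)))
    for j, name in enumerate(t.names):
        if j in (i_mpr, i_pdc):
            continue
        theta, was_clamped = _mpr_cross_latent(
            adh, marginals["pdc"], marginals[name],
            float(L[j, i_pdc]), float(R[i_mpr, j]), draws,
        )
        L[i_mpr, j] = L[j, i_mpr] = theta
        if was_clamped:
            clamped.append((name, "mpr", float(R[i_mpr, j]), math.nan))
    w, v = np.linalg.eigh(L)
    if w[0] < 1e-10:
        w = np.clip(w, 1e-10, None)
        L = (v * w) @ v.T
        d = np.sqrt(np.diag(L))
        L = L / np.outer(d, d)
        np.fill_diagonal(L, 1.0)
    result = CohortCalibration(list(t.names), marginals, adh, L, clamped)
    _CALIBRATION_CACHE[key] = result
    return result


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_profiles(
    config: SyntheticCohortConfig,
    calibration: CohortCalibration | None = None,
) -> pd.DataFrame:
    """Draw the per-patient study-variable table (one row per patient).

    The returned MPR column is already floored at PDC for multi-fill
    patients, i.e. every row is geometrically realizable as claims.
    """
    t = config.target
    cal = calibration if calibration is not None else calibrate(config)
    ordered = [cal.marginals[name] for name in t.names]
    # scrambled-Sobol draws: same target law as iid normals but with far
    # smaller integration error, so sampled moments sit on the targets
    engine = stats.qmc.MultivariateNormalQMC(
        mean=np.zeros(t.k), cov=cal.latent, seed=config.seed)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # n not a power of two
        z = engine.random(config.n)
    u = _norm_u(z)
    cols = {}
    for idx, m in enumerate(ordered):
        x = m.ppf(u[:, idx])
        cols[m.name] = x.astype(int) if m.integer else x
    df = pd.DataFrame(cols, index=[f"P{i:06d}" for i in range(config.n)])
    df["mpr"] = apply_adherence_floor(df["mpr"].to_numpy(), df["pdc"].to_numpy())
    df.index.name = "patient_id"
    return df


# ---------------------------------------------------------------------------
# Claims realization
# ---------------------------------------------------------------------------

@dataclass
class RealizationDiagnostics:
    pdc_below_floor: int = 0      # PDC target below a single fill's minimum
    supply_cap_clamps: int = 0    # fill budget + supply cap truncated coverage
    span_clamps: int = 0          # span rounding pinned at the window edge


def _split_supply(total: int, n_fills: int) -> list[int]:
    base, extra = divmod(total, n_fills)
    return [base + 1] * extra + [base] * (n_fills - extra)


def realize_claims(
    patient_id: str,
    mpr_target: float,
    pdc_target: float,
    total_fills: int,
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    diagnostics: RealizationDiagnostics | None = None,
) -> list[PharmacyClaim]:
    """Lay down pharmacy fills realizing the profile's MPR and PDC.

    Geometry (window ``W`` runs from the first fill to the period end; the
    profile satisfies MPR >= PDC for multi-fill rows by construction):

    * ``mpr_target == 0`` — a single controller fill, placed late enough in
      the period that supply/W matches the PDC target (the single-fill MPR
      coding rule decouples the two metrics; a late first starter with one
      fill legitimately carries a high PDC under the first-fill
      denominator).
    * ``0 < mpr_target <= 1`` — covered days ``C = round(pdc * W)`` laid as
      a contiguous run of fills with supplies summing exactly to C (about
      30 days each), plus a final fill ending the first-to-last span at
      ``round(C / mpr)``; realized MPR = C/span, PDC = C/W.
    * ``mpr_target > 1`` (overlapping supply) — span = C with total supply
      ``round(mpr * C)`` spread evenly across the covered run.

    The all-medication fill budget is respected by growing per-fill supply
    up to ``max_supply_days``; only when coverage exceeds budget x cap does
    the realizer truncate (tallied).  Non-controller fills pad the claim
    count up to the profile's total.
    """
    diag = diagnostics if diagnostics is not None else RealizationDiagnostics()
    s_nom = config.supply_days
    s_max = config.max_supply_days
    period = config.period_length
    eligible: list[tuple[int, int]] = []  # (fill_date, days_supply)

    def controller_class() -> DrugClass:
        u = rng.random()
        if u < 0.815:
            return DrugClass.ICS_LABA_COMBO
        return DrugClass.LABA if u > 0.99 else DrugClass.ICS

    if mpr_target <= 0:
        # one fill; choose (supply, window) minimizing the PDC error
        a = max(pdc_target, s_nom / period)
        if pdc_target < s_nom / period:
            diag.pdc_below_floor += 1
        best = None
        for s0 in range(s_nom, s_max + 1, s_nom):
            W = min(max(int(round(s0 / a)), s0), period)
            err = abs(s0 / W - a)
            if best is None or err < best[0]:
                best = (err, s0, W)
        _, s0, W = best
        eligible.append((period - W, s0))
    else:
        W = period
        C = max(int(round(pdc_target * W)), 2)
        budget = max(total_fills, 2)
        m = mpr_target
        if m <= 1.0:
            total_supply = C
            span = min(max(int(round(C / m)), C), W)
        else:
            span = C
            total_supply = int(round(m * C))
        f = int(np.clip(round(total_supply / s_nom), 2, budget))
        if math.ceil(total_supply / s_max) > f:
            # coverage outruns the fill budget at the nominal dispensing
            # cap: first stretch supplies to (rare) half-year fills, and
            # only then let the claim count exceed the budget, keeping the
            # realized PDC exact either way
            f = max(f, math.ceil(total_supply / (2 * s_max + 2)))
            if math.ceil(total_supply / s_max) > budget:
                diag.supply_cap_clamps += 1
        supplies = _split_supply(total_supply, f)
        if m <= 1.0:
            # contiguous run of the first f-1 fills + span-setting last fill
            starts = list(np.cumsum([0] + supplies[:-2]).astype(int))
            starts.append(span - supplies[-1])
        else:
            # overlapping fills spread evenly across the covered run
            starts = [int(round(i * (span - supplies[-1]) / (f - 1))) for i in range(f)]
        eligible.extend((d, s) for d, s in zip(starts, supplies))

    claims = [PharmacyClaim(patient_id, d, s, controller_class())
              for d, s in eligible]
    n_other = max(0, int(total_fills) - len(eligible))
    if n_other:
        other_dates = rng.integers(0, period - s_nom + 1, size=n_other)
        claims.extend(
            PharmacyClaim(patient_id, int(d), s_nom, DrugClass.OTHER)
            for d in other_dates
        )
    return claims


def _length_of_stay(rng: np.random.Generator, moments: tuple[float, float, float]) -> int:
    """Right-skewed integer LOS (per-patient aggregate): lognormal anchored
    at the printed median with the printed mean matched."""
    mean, _, median = moments
    mu = math.log(median)
    sigma = math.sqrt(max(2 * (math.log(mean) - mu), 1e-6))
    return max(1, int(round(rng.lognormal(mu, sigma))))


# ---------------------------------------------------------------------------
# End-to-end generation
# ---------------------------------------------------------------------------

@dataclass
class GeneratorReport:
    max_abs_mean_error: float
    max_abs_corr_error: float
    mean_error: pd.Series
    corr_error: pd.DataFrame
    marginals: pd.DataFrame           # per-variable mean / sd / median achieved
    realization: RealizationDiagnostics
    clamped_pairs: list = field(default_factory=list)


def generate_cohort(
    config: SyntheticCohortConfig,
    profiles: pd.DataFrame | None = None,
    calibration: CohortCalibration | None = None,
) -> tuple[list[PatientRecord], GeneratorReport]:
    """Sample profiles, realize claims, and report recovery of the target moments.

    The report's errors compare ``build_ssd`` of the *recomputed* patient
    table (MPR/PDC recalculated from the generated fills) against the
    target SSD, closing the loop over the whole pipeline.
    """
    clamped = calibration.clamped_pairs if calibration is not None else []
    if profiles is None:
        if calibration is None:
            calibration = calibrate(config)
            clamped = calibration.clamped_pairs
        profiles = sample_profiles(config, calibration)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    diag = RealizationDiagnostics()
    records: list[PatientRecord] = []
    for pid, row in profiles.iterrows():
        claims = realize_claims(
            str(pid), float(row["mpr"]), float(row["pdc"]),
            int(row["pharmacy_fills"]), config, rng, diag,
        )
        hosp = int(row["inpatient_hospitalizations"])
        events = MedicalEventCounts(
            inpatient_hospitalizations=hosp,
            er_visits=int(row["er_visits"]),
            pcp_office_visits=int(row["pcp_office_visits"]),
            specialist_office_visits=int(row["specialist_office_visits"]),
            other_outpatient_services=int(row["other_outpatient_services"]),
            length_of_stay=max(_length_of_stay(rng, config.los_moments), hosp)
            if hosp else None,
        )
        records.append(PatientRecord(
            patient_id=str(pid),
            age_years=int(row["age"]),
            qci_score=int(min(row["qci_score"], 33)),
            events=events,
            claims=claims,
        ))

    table = patient_table(records)
    achieved = build_ssd(table, variables=config.target.names)
    mean_err = pd.Series(achieved.means - config.target.means, index=config.target.names)
    corr_err = (to_correlation(achieved) - to_correlation(config.target))
    marg = pd.DataFrame({
        "mean": table[config.target.names].mean(),
        "sd": table[config.target.names].std(ddof=1),
        "median": table[config.target.names].median(),
    })
    report = GeneratorReport(
        max_abs_mean_error=float(mean_err.abs().max()),
        max_abs_corr_error=float(corr_err.abs().to_numpy().max()),
        mean_error=mean_err,
        corr_error=corr_err,
        marginals=marg,
        realization=diag,
        clamped_pairs=list(clamped),
    )
    return records, report
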