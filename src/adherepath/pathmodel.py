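"""Recursive observed-variable path models estimated from summary statistics.

The model is a layered system of regressions

    mediator_m  = sum_e b_me * exog_e + u_m
    outcome     = sum_e b_ye * exog_e + sum_m b_ym * mediator_m + e_y

with exogenous covariances fixed at their sample values and mediator
residuals mutually uncorrelated (a recursive system).  For such models the
maximum-likelihood estimate of each equation is its own least-squares fit,
so every coefficient solves the normal equations assembled directly from
the covariance matrix:

    beta = Sigma_XX^{-1} Sigma_Xy,     sigma^2_e = sigma^2_y - beta' Sigma_Xy.

Standardized effects propagate along directed paths; the total effect
matrix is (I - B)^{-1} - I, i.e. the sum of edge-coefficient products over
every directed path.  For a saturated layered model the total effect of an
exogenous variable on the outcome collapses to the coefficient of the
reduced-form regression of the outcome on the exogenous block alone — the
identity the test-suite uses as its oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ssd import SSDError, SummaryDataset, to_correlation


class SpecError(ValueError):
    """Invalid path-model specification."""


class EstimationError(RuntimeError):
    """Estimation failure (collinearity, nonconvergent decomposition...)."""


@dataclass(frozen=True)
class PathModelSpec:
    """Layered model structure: exogenous -> mediators -> outcome."""

    exogenous: tuple[str, ...]
    mediators: tuple[str, ...]
    outcome: str
    edges: frozenset[tuple[str, str]]  # (predictor, dependent)

    def __post_init__(self) -> None:
        names = list(self.exogenous) + list(self.mediators) + [self.outcome]
        if len(set(names)) != len(names):
            raise SpecError("exogenous, mediator, and outcome names must be disjoint")
        layer = {n: 0 for n in self.exogenous}
        layer.update({n: 1 for n in self.mediators})
        layer[self.outcome] = 2
        for pred, dep in self.edges:
            if pred not in layer or dep not in layer:
                raise SpecError(f"edge ({pred!r}, {dep!r}) references unknown variable")
            if layer[pred] >= layer[dep]:
                raise SpecError(f"edge ({pred!r}, {dep!r}) violates the layering")

    @property
    def variables(self) -> list[str]:
        return list(self.exogenous) + list(self.mediators) + [self.outcome]

    @property
    def endogenous(self) -> list[str]:
        return list(self.mediators) + [self.outcome]

    def predictors_of(self, dep: str) -> list[str]:
        order = {n: i for i, n in enumerate(self.variables)}
        preds = [p for (p, d) in self.edges if d == dep]
        return sorted(preds, key=order.__getitem__)

    def drop_edges(self, removed: Iterable[tuple[str, str]]) -> "PathModelSpec":
        return PathModelSpec(self.exogenous, self.mediators, self.outcome,
                             self.edges - frozenset(removed))


def saturated_mediation_spec(
    exogenous: Sequence[str],
    mediators: Sequence[str],
    outcome: str,
) -> PathModelSpec:
    """Fully saturated layered spec: every exog->mediator, exog->outcome,
    mediator->outcome edge; exogenous covariances left free."""
    edges = {(e, m) for e in exogenous for m in mediators}
    edges |= {(e, outcome) for e in exogenous}
    edges |= {(m, outcome) for m in mediators}
    return PathModelSpec(tuple(exogenous), tuple(mediators), outcome, frozenset(edges))


@dataclass
class PathFit:
    """Estimated coefficients and fit statistics for one path model.

    Coefficient matrices are DataFrames with rows = dependent variable,
    columns = predictor, zero where the spec has no edge.
    """

    spec: PathModelSpec
    n: int
    B_raw: pd.DataFrame
    B_std: pd.DataFrame
    se: pd.DataFrame
    z: pd.DataFrame
    p: pd.DataFrame
    residual_variances: pd.Series
    exog_cov: pd.DataFrame
    sds: pd.Series
    sample_cov: pd.DataFrame
    fit: dict[str, float] = field(default_factory=dict)

    def coefficient_cov(self, dep: str) -> pd.DataFrame:
        """Normal-theory covariance of the unstandardized coefficients of one equation."""
        preds = self.spec.predictors_of(dep)
        S = self.sample_cov.loc[preds, preds].to_numpy()
        k = len(preds)
        dof = self.n - k - 1
        sigma2 = self.residual_variances[dep] * (self.n - 1) / dof
        cov = sigma2 * np.linalg.inv(S) / (self.n - 1)
        return pd.DataFrame(cov, index=preds, columns=preds)


def fit_path_model(ssd: SummaryDataset, spec: PathModelSpec) -> PathFit:
    """Estimate a recursive path model from an SSD, equation by equation."""
    missing = [v for v in spec.variables if v not in ssd.names]
    if missing:
        raise SpecError(f"spec variables absent from SSD: {missing}")
    sub = ssd.subset(spec.variables)
    names = sub.names
    S = pd.DataFrame(sub.cov, index=names, columns=names)
    sds = pd.Series(sub.sds, index=names)

    zeros = pd.DataFrame(0.0, index=names, columns=names)
    B_raw, se, z, p = (zeros.copy() for _ in range(4))
    resid = pd.Series(0.0, index=spec.endogenous)

    for dep in spec.endogenous:
        preds = spec.predictors_of(dep)
        if not preds:
            resid[dep] = float(S.loc[dep, dep])
            continue
        Sxx = S.loc[preds, preds].to_numpy()
        Sxy = S.loc[preds, dep].to_numpy()
        try:
            beta = np.linalg.solve(Sxx, Sxy)
        except np.linalg.LinAlgError as e:
            raise EstimationError(
                f"singular predictor covariance in equation for {dep!r}; "
                f"collinear set: {preds}"
            ) from e
        sigma2 = float(S.loc[dep, dep] - beta @ Sxy)
        resid[dep] = max(sigma2, 0.0)
        k = len(preds)
        dof = sub.n - k - 1
        if dof <= 0:
            raise EstimationError(f"no degrees of freedom for equation {dep!r}")
        # normal-theory OLS standard errors reconstructed from the moments
        coef_cov = max(sigma2, 0.0) * (sub.n - 1) / dof * np.linalg.inv(Sxx) / (sub.n - 1)
        ses = np.sqrt(np.diag(coef_cov))
        for j, pred in enumerate(preds):
            B_raw.loc[dep, pred] = beta[j]
            se.loc[dep, pred] = ses[j]
            if ses[j] > 0:
                z.loc[dep, pred] = beta[j] / ses[j]
                p.loc[dep, pred] = 2 * stats.norm.sf(abs(z.loc[dep, pred]))

    B_std = B_raw * np.outer(1.0 / sds.to_numpy(), sds.to_numpy())
    exog = list(spec.exogenous)
    return PathFit(
        spec=spec, n=sub.n, B_raw=B_raw, B_std=pd.DataFrame(B_std, index=names, columns=names),
        se=se, z=z, p=p, residual_variances=resid,
        exog_cov=S.loc[exog, exog].copy(), sds=sds, sample_cov=S,
    )


# ---------------------------------------------------------------------------
# Effect decomposition
# ---------------------------------------------------------------------------

@dataclass
class EffectsTable:
    """Standardized direct / indirect / total effects with delta-method inference.

    Matrices are (row = source, column = target); total = direct + indirect
    elementwise.  ``p_total`` carries delta-method p-values for the total
    effects (exact normal-theory values for direct-only entries).
    """

    direct: pd.DataFrame
    indirect: pd.DataFrame
    total: pd.DataFrame
    se_total: pd.DataFrame
    p_total: pd.DataFrame

    def stars(self, source: str, target: str) -> str:
        p = self.p_total.loc[source, target]
        if p < 0.01:
            return "***"
        if p < 0.05:
            return "**"
        if p < 0.10:
            return "*"
        return ""


def _total_from_B(B_std: np.ndarray) -> np.ndarray:
    """Total-effect matrix (I - B)^{-1} - I in (source, target) orientation.

    ``B_std`` is (dependent, predictor); the result is transposed so that
    entry (i, j) is the effect of variable i on variable j.
    """
    k = B_std.shape[0]
    eye = np.eye(k)
    rho = np.max(np.abs(np.linalg.eigvals(B_std))) if k else 0.0
    if rho >= 1.0:
        raise EstimationError(f"path coefficient matrix has spectral radius {rho:.3f} >= 1")
    total_dep_pred = np.linalg.solve(eye - B_std, eye) - eye
    return total_dep_pred.T


def decompose_effects(fit: PathFit) -> EffectsTable:
    """Standardized direct, indirect, and total effects for every ordered pair.

    Total effects sum edge-coefficient products over all directed paths,
    computed in closed form as (I - B)^{-1} - I.  Standard errors for the
    totals come from the multivariate delta method, with the per-equation
    normal-theory coefficient covariances and zero covariance across
    equations (residuals are uncorrelated in a recursive system).
    """
    names = list(fit.B_std.index)
    B = fit.B_std.to_numpy()
    direct = fit.B_std.T.copy()  # (source, target)
    total = pd.DataFrame(_total_from_B(B), index=names, columns=names)
    indirect = total - direct

    se_tot, p_tot = _delta_method_totals(fit, names)
    return EffectsTable(direct=direct, indirect=indirect, total=total,
                        se_total=se_tot, p_total=p_tot)


def _delta_method_totals(fit: PathFit, names: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    spec = fit.spec
    params: list[tuple[str, str]] = []  # (dep, pred) free coefficients
    for dep in spec.endogenous:
        for pred in spec.predictors_of(dep):
            params.append((dep, pred))
    if not params:
        k = len(names)
        zero = pd.DataFrame(0.0, index=names, columns=names)
        return zero, pd.DataFrame(1.0, index=names, columns=names)

    # block-diagonal covariance of the standardized coefficients
    idx = {n: i for i, n in enumerate(names)}
    sds = fit.sds.to_numpy()
    cov_blocks = []
    for dep in spec.endogenous:
        preds = spec.predictors_of(dep)
        if not preds:
            continue
        raw_cov = fit.coefficient_cov(dep).to_numpy()
        scale = np.array([sds[idx[p]] / sds[idx[dep]] for p in preds])
        cov_blocks.append(raw_cov * np.outer(scale, scale))
    from scipy.linalg import block_diag
    theta_cov = block_diag(*cov_blocks)

    # jacobian of vec(total) with respect to the free standardized coefficients
    B0 = fit.B_std.to_numpy()
    T0 = _total_from_B(B0)
    k = len(names)
    eps = 1e-7
    grads = np.zeros((len(params), k, k))
    for a, (dep, pred) in enumerate(params):
        Bp = B0.copy()
        Bp[idx[dep], idx[pred]] += eps
        grads[a] = (_total_from_B(Bp) - T0) / eps

    G = grads.reshape(len(params), k * k)
    var_vec = np.einsum("ak,ab,bk->k", G, theta_cov, G)
    se = np.sqrt(np.clip(var_vec, 0.0, None)).reshape(k, k)
    se_tot = pd.DataFrame(se, index=names, columns=names)
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = np.where(se > 0, T0 / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(se > 0, 2 * stats.norm.sf(np.abs(zvals)), 1.0)
    p_tot = pd.DataFrame(p, index=names, columns=names)
    return se_tot, p_tot


# ---------------------------------------------------------------------------
# Fit statistics
# ---------------------------------------------------------------------------

def implied_covariance(fit: PathFit) -> pd.DataFrame:
    """Model-implied covariance Sigma(theta) over the spec's variables.

    Assembled from the structural coefficients, the (fixed) exogenous
    covariances, and the residual variances:  with x = (I - B)^{-1} (G u),
    Sigma = (I - B)^{-1} Psi (I - B)^{-T}, where Psi holds the exogenous
    block and the diagonal residual variances.
    """
    names = list(fit.B_raw.index)
    k = len(names)
    idx = {n: i for i, n in enumerate(names)}
    B = fit.B_raw.to_numpy()
    psi = np.zeros((k, k))
    exog = list(fit.spec.exogenous)
    for a in exog:
        for b in exog:
            psi[idx[a], idx[b]] = fit.exog_cov.loc[a, b]
    for dep in fit.spec.endogenous:
        psi[idx[dep], idx[dep]] = fit.residual_variances[dep]
    inv = np.linalg.inv(np.eye(k) - B)
    sigma = inv @ psi @ inv.T
    return pd.DataFrame(sigma, index=names, columns=names)


def srmr(ssd: SummaryDataset, fit: PathFit) -> float:
    """Standardized root mean-squared residual.

    Root mean square of the differences between sample and model-implied
    correlations over the unique elements of the matrix, including the
    diagonal of standardized residual variances (the common software
    convention).  Exactly 0 for a saturated model.
    """
    names = list(fit.B_raw.index)
    sub = ssd.subset(names)
    S = sub.cov
    sigma = implied_covariance(fit).to_numpy()
    d_s = np.sqrt(np.diag(S))
    d_m = np.sqrt(np.diag(sigma))
    R_s = S / np.outer(d_s, d_s)
    R_m = sigma / np.outer(d_s, d_s)  # standardized by *sample* SDs
    k = len(names)
    resid = []
    for i in range(k):
        for j in range(i + 1):
            if i == j:
                resid.append(1.0 - sigma[i, i] / S[i, i])
            else:
                resid.append(R_s[i, j] - R_m[i, j])
    return float(np.sqrt(np.mean(np.square(resid))))


def cd(ssd: SummaryDataset, fit: PathFit) -> float:
    """Coefficient of determination: 1 - det(residual cov) / det(sample cov)
    over the endogenous variables — the determinant generalization of R^2.
    For a single-equation model this reduces to that equation's R^2.
    """
    endog = fit.spec.endogenous
    sub = ssd.subset(list(fit.B_raw.index))
    S = pd.DataFrame(sub.cov, index=sub.names, columns=sub.names)
    S_end = S.loc[endog, endog].to_numpy()
    det_s = np.linalg.det(S_end)
    if det_s <= 0:
        raise EstimationError("singular endogenous sample covariance in CD")
    psi = np.diag([fit.residual_variances[d] for d in endog])
    return float(1.0 - np.linalg.det(psi) / det_s)


# ---------------------------------------------------------------------------
# Reporting and pruning
# ---------------------------------------------------------------------------

def effects_report(
    effects: EffectsTable,
    spec: PathModelSpec,
    predictors: Sequence[str] | None = None,
    decimals: int = 4,
) -> pd.DataFrame:
    """Total-effects table on the outcome, one row per predictor.

    Predictors absent from the model print as ``N/A``.  Stars mark delta-
    method significance at the 90 / 95 / 99% levels.
    """
    outcome = spec.outcome
    in_model = [n for n in spec.variables if n != outcome]
    rows = []
    for name in (predictors if predictors is not None else in_model):
        if name not in in_model:
            rows.append({"predictor": name, "total_effect": "N/A", "stars": ""})
            continue
        val = effects.total.loc[name, outcome]
        rows.append({
            "predictor": name,
            "total_effect": f"{val:.{decimals}f}",
            "stars": effects.stars(name, outcome),
        })
    return pd.DataFrame(rows).set_index("predictor")


def prune_and_refit(
    ssd: SummaryDataset,
    spec: PathModelSpec,
    alpha: float = 0.10,
) -> tuple[PathFit, PathModelSpec]:
    """Drop edges with p > alpha from an initial fit and refit once.

    A sensitivity mode: published path diagrams often display (and report)
    only the statistically significant paths of a larger fitted model.
    """
    first = fit_path_model(ssd, spec)
    removed = [
        (pred, dep)
        for (pred, dep) in spec.edges
        if first.p.loc[dep, pred] > alpha
    ]
    pruned = spec.drop_edges(removed)
    return fit_path_model(ssd, pruned), pruned
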