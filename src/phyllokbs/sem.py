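"""Maximum-likelihood path analysis over observed variables.

A recursive (acyclic) linear system x = B x + zeta over p observed
variables, with free path coefficients on the specified edges, free
variances for every variable (residual variances for endogenous ones)
and free covariances among exogenous variables.  The model-implied
covariance is Sigma = (I-B)^-1 Psi (I-B)^-T and parameters minimise the
ML discrepancy

    F(theta) = log|Sigma| + tr(S Sigma^-1) - log|S| - p,

giving chi^2 = (n-1) F at the optimum, GFI and RMSEA as fit indices,
standardized coefficients via model-implied standard deviations, and
total effects (I-B)^-1 - I on the standardized coefficients.  For a
recursive model the equation-by-equation OLS solution is the ML optimum,
which we use as the starting point; a quasi-Newton polish plus seeded
random restarts guards against flat regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .io_core import SampleMetadata, SOIL_VARS

log = logging.getLogger("phyllokbs")

_PSI_FLOOR = 1e-8


@dataclass
class PathModel:
    variables: list[str]
    edges: list[tuple[str, str]]  # (cause, effect)

    def __post_init__(self) -> None:
        unknown = {v for e in self.edges for v in e} - set(self.variables)
        if unknown:
            raise ValueError(f"edge variables not declared: {unknown}")
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("path model must be acyclic")
        self._graph = g

    @property
    def exogenous(self) -> list[str]:
        return [v for v in self.variables if self._graph.in_degree(v) == 0]

    @property
    def n_free(self) -> int:
        n_exo = len(self.exogenous)
        return len(self.edges) + len(self.variables) + n_exo * (n_exo - 1) // 2

    @property
    def df(self) -> int:
        p = len(self.variables)
        return p * (p + 1) // 2 - self.n_free


def saturated_model(variables: list[str]) -> PathModel:
    """Complete recursive model in the given order (df = 0)."""
    edges = [
        (variables[i], variables[j])
        for i in range(len(variables))
        for j in range(i + 1, len(variables))
    ]
    return PathModel(list(variables), edges)


@dataclass
class SEMFit:
    model: PathModel
    estimates: pd.DataFrame  # per-path: estimate, std_estimate, se, z, p
    chi_square: float
    df: int
    gfi: float
    rmsea: float
    f_min: float
    n: int
    sigma: np.ndarray
    b_std: np.ndarray  # standardized coefficient matrix, [effect, cause]
    psi: np.ndarray = field(repr=False, default=None)

    def total_effects(self) -> pd.DataFrame:
        return total_effects(self)


def _unpack(theta, model: PathModel, p, var_index, exo_pairs):
    n_e = len(model.edges)
    b = np.zeros((p, p))
    for k, (src, dst) in enumerate(model.edges):
        b[var_index[dst], var_index[src]] = theta[k]
    psi = np.zeros((p, p))
    psi[np.diag_indices(p)] = theta[n_e : n_e + p]
    for k, (a, c) in enumerate(exo_pairs):
        psi[a, c] = psi[c, a] = theta[n_e + p + k]
    return b, psi


def _implied_sigma(b, psi):
    p = b.shape[0]
    inv = np.linalg.inv(np.eye(p) - b)
    return inv @ psi @ inv.T


def fit_sem(data: pd.DataFrame, model: PathModel, seed: int = 0, n_restarts: int = 10) -> SEMFit:
    """Fit a path model by maximum likelihood."""
    data = data[model.variables]
    n, p = data.shape
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    if model.df < 0:
        raise ValueError("model has negative degrees of freedom")
    raw = data.to_numpy(dtype=float)
    # the ML discrepancy is invariant to per-variable rescaling, so fit on
    # unit-variance columns for numerical conditioning and map back after
    scale = raw.std(axis=0, ddof=1)
    if (scale <= 0).any():
        bad = [v for v, s in zip(model.variables, scale) if s <= 0]
        raise ValueError(f"constant variables cannot enter the fit: {bad}")
    x_scaled = raw / scale
    S = np.cov(x_scaled, rowvar=False, ddof=1)
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance matrix is not positive definite")

    var_index = {v: i for i, v in enumerate(model.variables)}
    exo_idx = [var_index[v] for v in model.exogenous]
    exo_pairs = [
        (exo_idx[i], exo_idx[j])
        for i in range(len(exo_idx))
        for j in range(i + 1, len(exo_idx))
    ]
    n_e = len(model.edges)

    def objective(theta):
        b, psi = _unpack(theta, model, p, var_index, exo_pairs)
        sigma = _implied_sigma(b, psi)
        sgn, logdet = np.linalg.slogdet(sigma)
        if sgn <= 0:
            return 1e10
        try:
            sigma_inv = np.linalg.inv(sigma)
        except np.linalg.LinAlgError:
            return 1e10
        return logdet + float(np.trace(S @ sigma_inv)) - logdet_s - p

    # OLS start: exact ML for recursive models with this parameterization
    theta0 = np.zeros(model.n_free)
    x = x_scaled
    resid_var = {v: S[var_index[v], var_index[v]] for v in model.variables}
    parents: dict[str, list[str]] = {v: [] for v in model.variables}
    for src, dst in model.edges:
        parents[dst].append(src)
    for v in model.variables:
        pa = parents[v]
        if not pa:
            continue
        X = x[:, [var_index[q] for q in pa]]
        X = np.column_stack([np.ones(n), X])
        y = x[:, var_index[v]]
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        fittedres = y - X @ coef
        resid_var[v] = float(fittedres @ fittedres) / (n - 1)
        for q, c in zip(pa, coef[1:]):
            theta0[model.edges.index((q, v))] = c
    for i, v in enumerate(model.variables):
        theta0[n_e + i] = max(resid_var[v], _PSI_FLOOR)
    for k, (a, c) in enumerate(exo_pairs):
        theta0[n_e + p + k] = S[a, c]

    bounds = (
        [(None, None)] * n_e
        + [(_PSI_FLOOR, None)] * p
        + [(None, None)] * len(exo_pairs)
    )
    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts + 1):
        start = theta0 if r == 0 else theta0 * (1 + 0.3 * rng.standard_normal(theta0.size))
        start[n_e : n_e + p] = np.maximum(start[n_e : n_e + p], _PSI_FLOOR)
        res = optimize.minimize(objective, start, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if not best.success and best.fun > 1e-6:
        log.warning("fit_sem: optimizer did not report convergence (%s)", best.message)
    theta = best.x
    if (theta[n_e : n_e + p] <= _PSI_FLOOR * 10).any():
        log.warning("fit_sem: residual variance at boundary (Heywood case)")

    b, psi = _unpack(theta, model, p, var_index, exo_pairs)
    sigma = _implied_sigma(b, psi)
    f_min = max(float(best.fun), 0.0)
    chi2 = (n - 1) * f_min
    sigma_inv = np.linalg.inv(sigma)
    m = sigma_inv @ S
    gfi = 1.0 - np.trace((m - np.eye(p)) @ (m - np.eye(p))) / np.trace(m @ m)
    df = model.df
    rmsea = (
        float(np.sqrt(max((chi2 - df) / (df * (n - 1)), 0.0))) if df > 0 else 0.0
    )

    sd = np.sqrt(np.diag(sigma))
    b_std = b * (sd[None, :] / sd[:, None])

    se = np.full(model.n_free, np.nan)
    try:
        hess = _numerical_hessian(objective, theta)
        cov = 2.0 / (n - 1) * np.linalg.pinv(hess)
        diag = np.diag(cov)
        se = np.sqrt(np.where(diag > 0, diag, np.nan))
    except Exception:  # pragma: no cover
        log.warning("fit_sem: Hessian-based standard errors unavailable")

    rows = []
    for k, (src, dst) in enumerate(model.edges):
        back = scale[var_index[dst]] / scale[var_index[src]]
        est = theta[k] * back  # original-scale coefficient
        sek = se[k] * back
        z = theta[k] / se[k] if np.isfinite(se[k]) and se[k] > 0 else np.nan
        rows.append(
            {
                "cause": src,
                "effect": dst,
                "estimate": est,
                "std_estimate": b_std[var_index[dst], var_index[src]],
                "se": sek,
                "z": z,
                "p": 2 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
            }
        )
    estimates = pd.DataFrame(rows)
    return SEMFit(model, estimates, float(chi2), df, float(gfi), rmsea, f_min, n, sigma, b_std, psi)


def _numerical_hessian(f, x, eps: float = 1e-5) -> np.ndarray:
    k = len(x)
    h = np.zeros((k, k))
    f0 = f(x)
    steps = eps * np.maximum(np.abs(x), 1.0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = steps[i]
            ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return h


def total_effects(fit: SEMFit) -> pd.DataFrame:
    """Total (direct + indirect) standardized effects, cause -> effect.

    T = (I - B)^-1 - I on the standardized coefficient matrix; entry
    [effect, cause] sums every directed path from cause to effect.
    """
    p = len(fit.model.variables)
    t = np.linalg.inv(np.eye(p) - fit.b_std) - np.eye(p)
    return pd.DataFrame(t, index=fit.model.variables, columns=fit.model.variables)


# ---------------------------------------------------------------------------
# Study model assembly
# ---------------------------------------------------------------------------

STUDY_VARIABLES = [
    "soil_pc1",
    "community_pcoa1",
    "keystone_abundance",
    "kbs_abundance",
    "yield",
]

#: Hypothesised causal structure: soil chemistry shapes the community and
#: yield directly; community structure determines keystone abundance;
#: KBS are a subset of keystones; keystones act on yield through KBS.
STUDY_EDGES = [
    ("soil_pc1", "community_pcoa1"),
    ("soil_pc1", "yield"),
    ("community_pcoa1", "keystone_abundance"),
    ("community_pcoa1", "yield"),
    ("keystone_abundance", "kbs_abundance"),
    ("kbs_abundance", "yield"),
]


def soil_pc1(soil: np.ndarray) -> np.ndarray:
    """First principal axis of z-scored soil variables.

    Equivalent to PCoA axis 1 of Euclidean distances on the z-scored
    matrix; sign oriented to correlate positively with DOC so the axis
    is deterministic.
    """
    soil = np.asarray(soil, dtype=float)
    z = (soil - soil.mean(axis=0)) / soil.std(axis=0, ddof=1)
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    pc1 = z @ vt[0]
    doc = soil[:, SOIL_VARS.index("DOC")]
    if np.corrcoef(pc1, doc)[0, 1] < 0:
        pc1 = -pc1
    return pc1


def build_study_model(
    community_pcoa1: pd.Series,
    keystone_abundance: pd.Series,
    kbs_abundance: pd.Series,
    metadata: SampleMetadata,
    sample_ids: list[str] | None = None,
    edges: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, PathModel]:
    """Assemble the five-variable observed dataset and the default paths."""
    if sample_ids is None:
        sample_ids = list(community_pcoa1.index)
    soil = metadata.table.loc[sample_ids, list(SOIL_VARS)].to_numpy(dtype=float)
    data = pd.DataFrame(
        {
            "soil_pc1": soil_pc1(soil),
            "community_pcoa1": community_pcoa1.reindex(sample_ids).to_numpy(),
            "keystone_abundance": keystone_abundance.reindex(sample_ids).to_numpy(),
            "kbs_abundance": kbs_abundance.reindex(sample_ids).to_numpy(),
            "yield": metadata.table.loc[sample_ids, "yield"].to_numpy(dtype=float),
        },
        index=sample_ids,
    )
    model = PathModel(list(STUDY_VARIABLES), list(edges or STUDY_EDGES))
    return data, model
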