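"""Sloan neutral community model: occupancy predicted from abundance.

A taxon with mean relative abundance p is detected in a sample (at
detection limit d = one read, i.e. 1/N) with probability
1 - BetaCDF(d; N*m*p, N*m*(1-p)), where N is the read depth and m the
migration (immigration) rate.  m is estimated by least squares between
observed occurrence frequencies and this prediction; fit quality is the
usual R^2 on frequencies (possibly negative for poor fits).  Per-taxon
95% bands are Wilson binomial intervals around the predicted frequency
at the observed sample count, and taxa are labelled above / within /
below the band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .io_core import CountTable

log = logging.getLogger("phyllokbs")

M_BOUNDS = (1e-6, 1.0)


@dataclass
class NCMFit:
    m: float
    N: float
    detection_limit: float
    r2: float
    taxa: pd.DataFrame  # p, observed_freq, predicted_freq, ci_lo, ci_hi, position
    n_samples: int

    def position_fractions(self) -> pd.Series:
        frac = self.taxa["position"].value_counts(normalize=True)
        return frac.reindex(["above", "within", "below"], fill_value=0.0)


def predicted_frequency(p: np.ndarray, m: float, N: float, d: float) -> np.ndarray:
    """Occurrence frequency predicted by the neutral model."""
    p = np.asarray(p, dtype=float)
    a = N * m * p
    b = N * m * (1.0 - p)
    return 1.0 - sps.beta.cdf(d, np.maximum(a, 1e-300), np.maximum(b, 1e-300))


def _wilson(p_hat: np.ndarray, n: int, z: float = 1.959963984540054) -> tuple[np.ndarray, np.ndarray]:
    denom = 1 + z**2 / n
    centre = (p_hat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p_hat * (1 - p_hat) / n + z**2 / (4 * n**2)) / denom
    return np.clip(centre - half, 0, 1), np.clip(centre + half, 0, 1)


def fit_ncm(table: CountTable) -> NCMFit:
    """Fit the neutral model to a count table's occupancy-abundance data."""
    counts = table.counts
    occ = (counts > 0).sum(axis=1)
    keep = occ > 0
    if keep.sum() < 10:
        raise ValueError("need >= 10 taxa with nonzero occupancy to fit the NCM")
    n_samples = table.n_samples
    f_obs = occ[keep] / n_samples
    p = table.relative_abundance()[keep, :].mean(axis=1)
    if np.allclose(f_obs, f_obs[0]):
        raise ValueError("degenerate fit: all observed frequencies equal")
    N = float(counts.sum(axis=0).mean())
    d = 1.0 / N

    def sse(m: float) -> float:
        resid = f_obs - predicted_frequency(p, m, N, d)
        return float(resid @ resid)

    # coarse log-grid then bounded refinement; the objective can be flat
    # near the bounds so a single local search is not trusted
    grid = np.geomspace(M_BOUNDS[0], M_BOUNDS[1], 50)
    grid_sse = np.array([sse(m) for m in grid])
    best = int(np.argmin(grid_sse))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(sse, bounds=(lo, hi), method="bounded")
    m_hat = float(res.x) if res.fun <= grid_sse[best] else float(grid[best])
    if m_hat <= M_BOUNDS[0] * 1.01 or m_hat >= M_BOUNDS[1] * 0.999:
        log.warning("fit_ncm: estimated m at the boundary (m=%.4g)", m_hat)

    pred = predicted_frequency(p, m_hat, N, d)
    sst = float(((f_obs - f_obs.mean()) ** 2).sum())
    r2 = 1.0 - sse(m_hat) / sst
    ci_lo, ci_hi = _wilson(pred, n_samples)
    position = np.where(f_obs > ci_hi, "above", np.where(f_obs < ci_lo, "below", "within"))
    taxa = pd.DataFrame(
        {
            "p": p,
            "observed_freq": f_obs,
            "predicted_freq": pred,
            "ci_lo": ci_lo,
            "ci_hi": ci_hi,
            "position": position,
        },
        index=[t for t, k in zip(table.taxon_ids, keep) if k],
    )
    return NCMFit(m_hat, N, d, float(r2), taxa, n_samples)


def compare_ncm(fit_a: NCMFit, fit_b: NCMFit, labels=("A", "B")) -> pd.DataFrame:
    """Side-by-side m, R^2 and band fractions for two fitted communities."""
    rows = []
    for lab, fit in zip(labels, (fit_a, fit_b)):
        frac = fit.position_fractions()
        rows.append(
            {
                "community": lab,
                "m": fit.m,
                "r2": fit.r2,
                "N": fit.N,
                "frac_above": frac["above"],
                "frac_within": frac["within"],
                "frac_below": frac["below"],
            }
        )
    df = pd.DataFrame(rows).set_index("community")
    df.attrs["m_difference_sign"] = int(np.sign(fit_a.m - fit_b.m))
    return df
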