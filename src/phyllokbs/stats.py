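"""Group-comparison utilities: t-tests, one-way ANOVA with LSD letters.

LSD (least significant difference) post hoc follows its classical
definition: pairwise t-tests using the pooled ANOVA mean-square error at
alpha = 0.05, without multiplicity correction, summarised by a compact
letter display (groups sharing a letter are not significantly different).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TwoGroupTest:
    statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    method: str


def two_group_t(a, b, welch: bool = True) -> TwoGroupTest:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    if np.isnan(t):  # identical constant groups
        t, p = 0.0, 1.0
    return TwoGroupTest(
        float(t), float(p), float(a.mean()), float(b.mean()),
        "welch_t" if welch else "student_t",
    )


@dataclass
class AnovaLSD:
    f_statistic: float
    p_value: float
    group_means: dict[str, float]
    letters: dict[str, str]
    pairwise_p: pd.DataFrame


def _lsd_pairwise(values: dict[str, np.ndarray], mse: float, df_err: int) -> pd.DataFrame:
    names = list(values)
    p = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, gi in enumerate(names):
        for j in range(i + 1, len(names)):
            gj = names[j]
            ni, nj = len(values[gi]), len(values[gj])
            se = np.sqrt(mse * (1 / ni + 1 / nj))
            if se == 0:
                pij = 1.0 if values[gi].mean() == values[gj].mean() else 0.0
            else:
                t = (values[gi].mean() - values[gj].mean()) / se
                pij = 2 * sps.t.sf(abs(t), df_err)
            p.iloc[i, j] = p.iloc[j, i] = pij
    return p


def _compact_letters(order: list[str], sig: pd.DataFrame, alpha: float) -> dict[str, str]:
    """Insert-and-absorb compact letter display over mean-ordered groups."""
    letter_sets: list[set[str]] = []
    for g in order:
        placed = False
        for s in letter_sets:
            if all(sig.loc[g, other] >= alpha for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb subsets
    keep = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    letters = {g: "" for g in order}
    for s, ch in zip(keep, "abcdefghijklmnopqrstuvwxyz"):
        for g in order:
            if g in s:
                letters[g] += ch
    return letters


def anova_lsd(values_by_group: dict[str, np.ndarray], alpha: float = 0.05) -> AnovaLSD:
    """One-way ANOVA followed by LSD pairwise letters."""
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("every group needs >= 2 observations")
    f, p = sps.f_oneway(*groups.values())
    if np.isnan(f):
        f, p = 0.0, 1.0
    n = sum(len(v) for v in groups.values())
    g = len(groups)
    grand = np.concatenate(list(groups.values())).mean()
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_err = n - g
    mse = ss_within / df_err if df_err > 0 else 0.0
    pairwise = _lsd_pairwise(groups, mse, df_err)
    order = sorted(groups, key=lambda k: -groups[k].mean())
    letters = _compact_letters(order, pairwise, alpha)
    return AnovaLSD(
        float(f), float(p),
        {k: float(v.mean()) for k, v in groups.items()},
        letters, pairwise,
    )


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and p; (nan, nan) when either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
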