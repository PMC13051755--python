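"""Keystone beneficial specialist (KBS) screen and downstream summaries.

A taxon is a KBS when it simultaneously (i) holds a non-peripheral
topological role in the co-occurrence network (module hub, connector or
network hub), (ii) is a niche specialist under the fixed-margin
permutation null, and (iii) carries a genus (configurable rank) flagged
in the beneficial-taxa list.  The screen is an exact three-way set
intersection with per-criterion provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import BeneficialList, CountTable, SampleMetadata, Taxonomy
from .network import CoNetwork
from .niche import NicheClassification
from .stats import pearson, two_group_t

log = logging.getLogger("phyllokbs")


@dataclass
class KBSResult:
    kbs_taxa: list[str]
    provenance: pd.DataFrame  # keystone_role, niche_label, beneficial_key per taxon
    counts: dict[str, int]  # per-criterion and intersection sizes

    def __len__(self) -> int:
        return len(self.kbs_taxa)


def screen_kbs(
    net: CoNetwork,
    niche: NicheClassification,
    taxonomy: Taxonomy,
    beneficial: BeneficialList,
    kingdom: str | None = "bacteria",
) -> KBSResult:
    """Intersect keystone, specialist and beneficial taxon sets.

    ``kingdom='bacteria'`` restricts the keystone set to bacterial nodes
    (the default focus of the screen); pass None to keep both kingdoms.
    """
    keystones = net.keystone_taxa()
    if kingdom is not None and "kingdom" in net.nodes.columns:
        keystones = {
            t for t in keystones if net.nodes.at[t, "kingdom"] == kingdom
        }
    specialists = niche.taxa_with_label("specialist")
    screen_universe = sorted(keystones | specialists)
    known = set(taxonomy.table.index)
    unknown = (keystones | specialists) - known
    if unknown:
        raise KeyError(
            f"{len(unknown)} screened taxa missing from taxonomy, "
            f"e.g. {sorted(unknown)[:3]}"
        )
    beneficial_taxa = beneficial.match_taxa(taxonomy, screen_universe)

    kbs = sorted(keystones & specialists & beneficial_taxa)
    if not keystones:
        log.warning("screen_kbs: keystone set is empty; KBS screen returns nothing")
    counts = {
        "keystone": len(keystones),
        "specialist": len(specialists),
        "beneficial": len(beneficial_taxa),
        "keystone_and_specialist": len(keystones & specialists),
        "keystone_and_beneficial": len(keystones & beneficial_taxa),
        "specialist_and_beneficial": len(specialists & beneficial_taxa),
        "kbs": len(kbs),
    }
    prov = pd.DataFrame(
        {
            "keystone_role": [net.nodes.at[t, "role"] for t in kbs],
            "niche_label": [niche.table.at[t, "label"] for t in kbs],
            "beneficial_key": [
                taxonomy.rank(t, beneficial.rank).lower() for t in kbs
            ],
        },
        index=kbs,
    )
    return KBSResult(kbs, prov, counts)


def kbs_abundance(result: KBSResult, table: CountTable) -> pd.Series:
    """Per-sample summed relative abundance of the KBS taxa."""
    rel = table.relative_abundance()
    idx = [table.taxon_ids.index(t) for t in result.kbs_taxa if t in table.taxon_ids]
    values = rel[idx, :].sum(axis=0) if idx else np.zeros(table.n_samples)
    return pd.Series(values, index=table.sample_ids, name="kbs_relative_abundance")


def kbs_abundance_by_class(
    abundance: pd.Series, metadata: SampleMetadata
) -> dict:
    """Class means +/- se and a t-test between resistance classes."""
    res = metadata.table["resistance"].reindex(abundance.index)
    out = {}
    for cls in ("resistant", "susceptible"):
        v = abundance[res == cls]
        out[cls] = {
            "mean": float(v.mean()),
            "se": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan,
            "n": int(len(v)),
        }
    t = two_group_t(abundance[res == "resistant"], abundance[res == "susceptible"])
    out["t_test"] = {"t": t.statistic, "p": t.p_value}
    return out


def kbs_composition(
    result: KBSResult, taxonomy: Taxonomy, table: CountTable, rank: str = "class"
) -> pd.Series:
    """Mean relative abundance per taxonomic class, normalised within KBS."""
    if not result.kbs_taxa:
        return pd.Series(dtype=float)
    rel = table.relative_abundance()
    shares = {}
    for t in result.kbs_taxa:
        if t not in table.taxon_ids:
            continue
        cls = taxonomy.rank(t, rank) or "unclassified"
        shares[cls] = shares.get(cls, 0.0) + rel[table.taxon_ids.index(t), :].mean()
    s = pd.Series(shares).sort_values(ascending=False)
    total = s.sum()
    return s / total if total > 0 else s


def kbs_yield_correlation(
    abundance: pd.Series, metadata: SampleMetadata
) -> pd.DataFrame:
    """Pearson r, p and OLS slope of yield on KBS abundance per class."""
    rows = []
    for cls in ("resistant", "susceptible"):
        sids = [s for s in abundance.index if metadata.table.at[s, "resistance"] == cls]
        if len(sids) < 3:
            rows.append({"class": cls, "r": np.nan, "p": np.nan, "slope": np.nan,
                         "n": len(sids)})
            continue
        x = abundance[sids].to_numpy()
        y = metadata.table.loc[sids, "yield"].to_numpy(dtype=float)
        r, p = pearson(x, y)
        slope = np.nan
        if not np.isnan(r) and x.std() > 0:
            slope = float(np.polyfit(x, y, 1)[0])
        if np.isnan(r):
            log.warning("kbs_yield_correlation: undefined correlation for %s", cls)
        rows.append({"class": cls, "r": r, "p": p, "slope": slope, "n": len(sids)})
    return pd.DataFrame(rows).set_index("class")
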