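"""End-to-end pipeline: synth -> diversity -> assembly -> ncm -> niche ->
network -> kbs -> sem, driven by one config dict (or YAML file) carrying
a single master seed from which every stage's seed derives
deterministically.  Null/permutation counts are configurable so the full
chain can run at reduced cost.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly as asm
from . import diversity as dv
from . import kbs as kbsmod
from . import ncm as ncmmod
from . import network as netmod
from . import niche as nichemod
from . import sem as semmod
from .io_core import filter_low_count, rarefy
from .synth import SynthSpec, generate_study, stage_rng, write_bundle

log = logging.getLogger("phyllokbs")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synth": {},  # SynthSpec field overrides
    "min_total_count": 20,
    "rarefy_depth": None,  # None -> min sample sum
    "n_null_assembly": 999,
    "n_perm_niche": 1000,
    "n_perm_permanova": 999,
    "rho_min": 0.6,
    "p_max": 0.01,
    "prevalence_min": 0.2,
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_CONFIG, **user}
    cfg["synth"] = {**DEFAULT_CONFIG["synth"], **(user.get("synth") or {})}
    return cfg


def _stage_seed(master: int, label: str) -> int:
    return int(stage_rng(master, label).integers(2**31 - 1))


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the whole inference chain on a freshly generated synthetic study.

    Returns a nested results dict (JSON-serialisable summaries plus the
    fitted objects under ``_objects``); when ``out_dir`` is given, writes
    the input bundle and per-stage summary files there.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = {**DEFAULT_CONFIG, **config}
    seed = int(cfg["seed"])

    spec = SynthSpec(seed=_stage_seed(seed, "synth"), **cfg["synth"])
    bundle = generate_study(spec)
    meta = bundle.metadata
    results: dict = {"config": {k: v for k, v in cfg.items() if k != "synth"},
                     "spec": {"n_taxa": spec.n_taxa, "n_samples": spec.n_samples,
                              "reads_per_sample": spec.reads_per_sample,
                              "migration_m": spec.migration_m}}
    objects: dict = {"bundle": bundle}

    # --- io: abundance filter + rarefaction -------------------------------
    tables = {}
    for kingdom, raw in (("bacteria", bundle.bacteria), ("fungi", bundle.fungi)):
        t = filter_low_count(raw, cfg["min_total_count"])
        depth = cfg["rarefy_depth"] or int(t.sample_sums().min())
        tables[kingdom] = rarefy(t, depth, _stage_seed(seed, f"rarefy:{kingdom}"))
    results["io"] = {
        k: {"n_taxa": t.n_taxa, "n_samples": t.n_samples, "depth": int(t.sample_sums()[0])}
        for k, t in tables.items()
    }

    resistance = meta.table["resistance"]
    classes = ("resistant", "susceptible")
    class_samples = {c: meta.samples_in_class(c) for c in classes}

    # --- diversity --------------------------------------------------------
    bact = tables["bacteria"]
    dist = dv.bray_curtis(bact)
    ordination = dv.pcoa(dist)
    perma = dv.permanova(
        dist, resistance, n_perm=cfg["n_perm_permanova"],
        seed=_stage_seed(seed, "permanova"),
    )
    results["diversity"] = {
        "richness_mean": float(dv.richness(bact).mean()),
        "permanova": perma,
        "pcoa1_prop_explained": float(ordination.proportion_explained[0]),
    }
    objects["distance"] = dist
    objects["ordination"] = ordination

    # --- assembly (both kingdoms, within-class pairs) ---------------------
    trees = {"bacteria": bundle.tree_bacteria, "fungi": bundle.tree_fungi}
    results["assembly"], objects["assembly_pairs"] = {}, {}
    for kingdom, t in tables.items():
        part, fracs = asm.assembly_analysis(
            t, trees[kingdom], resistance, pair_mode="within",
            n_null=cfg["n_null_assembly"], seed=_stage_seed(seed, f"assembly:{kingdom}"),
        )
        results["assembly"][kingdom] = {
            "process_fractions": fracs.to_dict(), "n_pairs": int(len(part))
        }
        objects["assembly_pairs"][kingdom] = part

    # --- ncm (per kingdom x cultivar class) -------------------------------
    fits: dict = {}
    results["ncm"] = {}
    for kingdom, t in tables.items():
        fits[kingdom] = {}
        results["ncm"][kingdom] = {}
        for c in classes:
            sub = t.select_samples(class_samples[c]).drop_empty_taxa()
            fit = ncmmod.fit_ncm(sub)
            fits[kingdom][c] = fit
            results["ncm"][kingdom][c] = {"m": fit.m, "r2": fit.r2}
    objects["ncm_fits"] = fits

    # --- niche ------------------------------------------------------------
    niche_by_class = {}
    for c in classes:
        sub = bact.select_samples(class_samples[c]).drop_empty_taxa()
        niche_by_class[c] = nichemod.classify_niche(
            sub, n_perm=cfg["n_perm_niche"], seed=_stage_seed(seed, f"niche:{c}")
        )
    results["niche"] = {
        c: niche_by_class[c].label_fractions().to_dict() for c in classes
    }
    objects["niche"] = niche_by_class

    # --- network + kbs + sem per cultivar class ---------------------------
    results["network"], results["kbs"], results["sem"] = {}, {}, {}
    objects["networks"], objects["kbs"], objects["sem"] = {}, {}, {}
    for c in classes:
        sids = class_samples[c]
        sub_b = bact.select_samples(sids)
        sub_f = tables["fungi"].select_samples(sids)
        net = netmod.build_network(
            [sub_b, sub_f], rho_min=cfg["rho_min"], p_max=cfg["p_max"],
            prevalence_min=cfg["prevalence_min"],
            niche_labels=niche_by_class[c].labels(),
        )
        topo = netmod.topology(net)
        netmod.detect_modules(net, seed=_stage_seed(seed, f"louvain:{c}"))
        netmod.zi_pi(net)
        netmod.keystone_scores(net)
        results["network"][c] = {
            "n_nodes": topo["n_nodes"], "n_edges": topo["n_edges"],
            "avg_degree": topo["avg_degree"],
            "n_keystones": int(net.nodes["keystone"].sum()),
            "edge_type_proportions": topo["edge_type_proportions"],
        }
        objects["networks"][c] = net

        screen = kbsmod.screen_kbs(
            net, niche_by_class[c], bundle.taxonomy, bundle.beneficial
        )
        abund = kbsmod.kbs_abundance(screen, sub_b)
        corr = kbsmod.kbs_yield_correlation(abund, meta)
        results["kbs"][c] = {
            "counts": screen.counts,
            "mean_abundance": float(abund.mean()),
            "yield_r": float(corr.at[c, "r"]),
            "yield_p": float(corr.at[c, "p"]),
        }
        objects["kbs"][c] = {"screen": screen, "abundance": abund}

        # SEM inputs: per-class community ordination + abundances
        sub_dist = dist.submatrix(sids)
        pcoa1 = pd.Series(dv.pcoa(sub_dist).pcoa1, index=sids)
        rel = sub_b.relative_abundance()
        key_taxa = [t for t in net.keystone_taxa() if t in sub_b.taxon_ids]
        key_idx = [sub_b.taxon_ids.index(t) for t in key_taxa]
        key_abund = pd.Series(
            rel[key_idx].sum(axis=0) if key_idx else np.zeros(len(sids)), index=sids
        )
        data, model = semmod.build_study_model(pcoa1, key_abund, abund, meta, sids)
        # degenerate columns (e.g. empty KBS set) cannot enter the covariance fit
        degenerate = [v for v in data.columns if data[v].std() == 0]
        if degenerate:
            log.warning("pipeline: skipping SEM for %s (constant: %s)", c, degenerate)
            results["sem"][c] = {"skipped_constant": degenerate}
            continue
        try:
            fit = semmod.fit_sem(data, model, seed=_stage_seed(seed, f"sem:{c}"))
        except ValueError as exc:
            # e.g. keystone and KBS sets coincide -> collinear columns
            log.warning("pipeline: SEM not estimable for %s (%s)", c, exc)
            results["sem"][c] = {"skipped": str(exc)}
            continue
        te = fit.total_effects()
        results["sem"][c] = {
            "chi_square": fit.chi_square, "df": fit.df,
            "gfi": fit.gfi, "rmsea": fit.rmsea,
            "total_effect_on_yield": {
                v: float(te.at["yield", v]) for v in model.variables if v != "yield"
            },
            "paths": fit.estimates[["cause", "effect", "std_estimate", "p"]]
            .to_dict("records"),
        }
        objects["sem"][c] = fit

    results["_objects"] = objects
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_bundle(bundle, out / "inputs")
        serialisable = {k: v for k, v in results.items() if k != "_objects"}
        (out / "pipeline_summary.json").write_text(
            json.dumps(serialisable, indent=2, default=float)
        )
        part.to_csv(out / "assembly_pairs.tsv", sep="\t", index=False)
    return results
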