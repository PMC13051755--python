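"""The KBS screen: keystone x specialist x beneficial, and yield coupling.

Applies the three-criterion screen per cultivar class, quantifies KBS
relative abundance and class-level taxonomic composition, and tests the
KBS-yield correlation — the genotype-dependent relationship at the
heart of the study design.
"""

from common import pipeline_results, save

from phyllokbs.kbs import kbs_composition, kbs_yield_correlation


def main() -> None:
    res = pipeline_results()
    bundle = res["_objects"]["bundle"]
    print(f"Planted KBS ground truth: {bundle.truth.kbs_taxa}")
    payload = {"planted": bundle.truth.kbs_taxa}
    for cls, r in res["kbs"].items():
        screen = res["_objects"]["kbs"][cls]["screen"]
        ab = res["_objects"]["kbs"][cls]["abundance"]
        comp = kbs_composition(screen, bundle.taxonomy,
                               bundle.bacteria.select_samples(list(ab.index)))
        corr = kbs_yield_correlation(ab, bundle.metadata)
        print(
            f"  {cls:12s} screen {r['counts']['keystone']} keystone / "
            f"{r['counts']['specialist']} specialist / {r['counts']['beneficial']} "
            f"beneficial -> {r['counts']['kbs']} KBS {screen.kbs_taxa}"
        )
        if screen.kbs_taxa:
            print(
                f"    mean abundance {100 * r['mean_abundance']:.2f}%, "
                f"yield r={corr.at[cls, 'r']:+.2f} (p={corr.at[cls, 'p']:.3g}); "
                f"composition: {({k: round(float(v), 2) for k, v in comp.items()})}"
            )
        payload[cls] = {
            **r,
            "kbs_taxa": screen.kbs_taxa,
            "composition": comp.to_dict(),
        }
    save("07_kbs.json", payload)


if __name__ == "__main__":
    main()
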