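"""Path models of yield per cultivar class.

Fits the five-variable path model (soil PC1, community PCoA1, keystone
abundance, KBS abundance, yield) by maximum likelihood per cultivar
class and reports fit indices, standardized paths and total effects on
yield.
"""

from common import pipeline_results, save


def main() -> None:
    res = pipeline_results()
    print("Path analysis of yield (per cultivar class):")
    for cls, r in res["sem"].items():
        if "chi_square" not in r:
            print(f"  {cls:12s} skipped: {r}")
            continue
        print(
            f"  {cls:12s} chi2={r['chi_square']:.2f} (df={r['df']}), "
            f"GFI={r['gfi']:.3f}, RMSEA={r['rmsea']:.3f}"
        )
        for k, v in r["total_effect_on_yield"].items():
            print(f"    total effect {k:20s} -> yield: {v:+.3f}")
    save("08_sem.json", res["sem"])


if __name__ == "__main__":
    main()
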