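"""Levins niche breadth: specialists vs generalists per cultivar class.

Classifies every bacterial taxon against the fixed-margin permutation
null within each cultivar class and compares mean breadth between
classes, as the study does with t-tests.
"""

from common import pipeline_results, save

from phyllokbs.niche import compare_breadth


def main() -> None:
    res = pipeline_results()
    print("Niche classification (bacteria, per cultivar class):")
    for cls, fr in res["niche"].items():
        print(
            f"  {cls:12s} specialists {100 * fr['specialist']:.0f}%  "
            f"neutral {100 * fr['neutral_taxon']:.0f}%  "
            f"generalists {100 * fr['generalist']:.1f}%"
        )
    niche_obj = res["_objects"]["niche"]
    rep = compare_breadth(
        niche_obj["resistant"], niche_obj["susceptible"],
        labels=("resistant", "susceptible"),
    )
    print(
        f"Breadth t-test resistant vs susceptible: mean B "
        f"{rep['mean_b']['resistant']:.2f} vs {rep['mean_b']['susceptible']:.2f}, "
        f"p={rep['p']:.3g}"
    )
    save("05_niche.json", {"fractions": res["niche"], "breadth_comparison": rep})


if __name__ == "__main__":
    main()
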