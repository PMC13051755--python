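"""Alpha/beta diversity of the synthetic phyllosphere communities.

Reports mean OTU richness, the PERMANOVA contrast between resistant and
susceptible cultivars on Bray-Curtis distances, and the leading PCoA
axis, mirroring the community-structure stage of the study pipeline.
"""

from common import pipeline_results, save


def main() -> None:
    res = pipeline_results()
    div = res["diversity"]
    print("Community structure (bacteria, rarefied counts):")
    print(f"  mean OTU richness per sample: {div['richness_mean']:.1f}")
    p = div["permanova"]
    print(
        f"  PERMANOVA resistant vs susceptible: pseudo-F={p['pseudo_F']:.2f}, "
        f"R2={p['R2']:.3f}, p={p['p']:.4f} ({p['n_perm']} permutations)"
    )
    print(f"  PCoA1 explains {100 * div['pcoa1_prop_explained']:.1f}% of variation")
    save("02_diversity.json", div)


if __name__ == "__main__":
    main()
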