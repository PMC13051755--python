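"""Generate the synthetic phyllosphere study and describe its ground truth.

Emits the full input bundle (OTU tables for both kingdoms, trees,
taxonomy, metadata, beneficial list) under scratch/pipeline/inputs and a
small ground-truth summary under results/.
"""

from common import pipeline_results, save


def main() -> None:
    res = pipeline_results()
    bundle = res["_objects"]["bundle"]
    truth = bundle.truth
    print("Synthetic study generated:")
    print(f"  bacteria: {bundle.bacteria.n_taxa} taxa x {bundle.bacteria.n_samples} samples")
    print(f"  fungi:    {bundle.fungi.n_taxa} taxa x {bundle.fungi.n_samples} samples")
    print(f"  planted module hubs: {truth.hub_ids}")
    print(f"  planted KBS taxa:    {truth.kbs_taxa}")
    print(f"  habitat-restricted samples: {truth.restricted_samples}")
    save(
        "01_ground_truth.json",
        {
            "migration_m": truth.migration_m,
            "hub_ids": truth.hub_ids,
            "kbs_taxa": truth.kbs_taxa,
            "restricted_samples": truth.restricted_samples,
            "yield_coefficients": vars(truth.yield_coefficients),
            "n_beneficial_genera": len(truth.beneficial_genera),
            "io_summary": res["io"],
        },
    )


if __name__ == "__main__":
    main()
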