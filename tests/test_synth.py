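import dataclasses

import numpy as np
import pytest

from phyllokbs.io_core import read_count_table, read_metadata, read_taxonomy, read_tree
from phyllokbs.synth import (
    SynthSpec,
    YieldCoefficients,
    design_frame,
    gen_correlated_abundances,
    gen_metadata_yield,
    gen_neutral_counts,
    gen_selected_counts,
    gen_tree,
    generate_study,
    write_bundle,
)


class TestGenTree:
    def test_two_taxa_single_cherry(self):
        t = gen_tree(2, seed=1)
        assert len(t.tip_labels) == 2

    @pytest.mark.parametrize("n", [5, 40])
    def test_tip_count(self, n):
        assert len(gen_tree(n, seed=2).tip_labels) == n

    def test_ultrametric_unit_depth(self):
        t = gen_tree(30, seed=3)
        depths = [leaf.distance_from_root() for leaf in t.tree.leaf_node_iter()]
        assert np.var(depths) < 1e-9
        assert max(depths) == pytest.approx(1.0, abs=1e-9)


class TestNeutralCounts:
    def test_design_dimensions(self):
        spec = SynthSpec(seed=0)
        t = gen_neutral_counts(spec)
        assert t.n_samples == 60 and t.n_taxa == 400
        assert (t.sample_sums() == spec.reads_per_sample).all()
        d = design_frame(spec)
        assert (d["resistance"] == "resistant").sum() == 30

    def test_pure_function_of_spec(self):
        a = gen_neutral_counts(SynthSpec(seed=9))
        b = gen_neutral_counts(SynthSpec(seed=9))
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_high_migration_large_n_tracks_metacommunity(self):
        # m -> 1 with many reads: sample frequencies approach the source pool
        spec = SynthSpec(seed=4, n_taxa=50, migration_m=1.0, reads_per_sample=100_000,
                         n_cultivars=2, n_resistant=1, n_replicates=1, module_size=10)
        t = gen_neutral_counts(spec)
        from phyllokbs.synth import _metacommunity
        p = _metacommunity(spec)
        freqs = t.relative_abundance()
        assert np.abs(freqs - p[:, None]).max() < 0.05

    def test_zero_probability_taxon_never_occurs(self):
        from phyllokbs.synth import _sample_counts
        spec = SynthSpec(seed=5, n_taxa=10, module_size=2)
        p = np.array([0.0, *np.full(9, 1 / 9)])
        counts = _sample_counts(spec, p[None, :], np.zeros(60, dtype=int))
        assert (counts[0, :] == 0).all()

    def test_invalid_migration_rate_rejected(self):
        with pytest.raises(ValueError):
            SynthSpec(migration_m=0.0)


class TestSelectedCounts:
    def test_zero_strength_reduces_to_neutral_bitwise(self):
        spec = SynthSpec(seed=6, n_taxa=80, reads_per_sample=500, module_size=20)
        tree = gen_tree(80, seed=7)
        for leaf, tid in zip(tree.tree.leaf_node_iter(), spec.taxon_ids()):
            leaf.taxon.label = tid
        np.testing.assert_array_equal(
            gen_selected_counts(spec, tree).counts, gen_neutral_counts(spec).counts
        )

    def test_selection_shifts_group_compositions_apart(self):
        spec = SynthSpec(seed=6, n_taxa=80, reads_per_sample=2000, selection_strength=8.0, module_size=20)
        tree = gen_tree(80, seed=7)
        for leaf, tid in zip(tree.tree.leaf_node_iter(), spec.taxon_ids()):
            leaf.taxon.label = tid
        t = gen_selected_counts(spec, tree)
        d = design_frame(spec)
        res = (d["resistance"] == "resistant").to_numpy()
        f = t.relative_abundance()
        # mean compositions of the two classes diverge far beyond noise
        gap = np.abs(f[:, res].mean(axis=1) - f[:, ~res].mean(axis=1)).sum()
        assert gap > 0.5


class TestCorrelatedAbundances:
    def test_planted_module_covariance_is_positive_definite(self):
        from phyllokbs.synth import _module_correlation
        corr = _module_correlation(SynthSpec(seed=0))
        np.linalg.cholesky(corr)  # raises if not PD
        assert np.allclose(corr, corr.T)

    def test_module_membership_and_hubs_reported(self):
        spec = SynthSpec(seed=8, reads_per_sample=5000)
        table, module_of, hubs, restricted = gen_correlated_abundances(spec)
        assert len(module_of) == spec.n_modules * spec.module_size
        assert len(hubs) == spec.n_modules * spec.n_hubs_per_module
        assert restricted == []
        assert set(np.unique(list(module_of.values()))) == set(range(spec.n_modules))

    def test_restricted_module_concentrates_in_resistant_samples(self):
        spec = SynthSpec(seed=8, reads_per_sample=5000)
        table, module_of, hubs, restricted = gen_correlated_abundances(
            spec, restricted_module=0
        )
        assert len(restricted) == spec.restricted_n_samples
        d = design_frame(spec)
        assert all(d.loc[s, "resistance"] == "resistant" for s in restricted)
        mod0 = [i for i, t in enumerate(table.taxon_ids) if module_of.get(t) == 0]
        rel = table.relative_abundance()[mod0, :].sum(axis=0)
        inside = np.mean([rel[table.sample_ids.index(s)] for s in restricted])
        outside = np.mean(
            [r for s, r in zip(table.sample_ids, rel) if s not in restricted]
        )
        assert inside > 10 * outside


class TestMetadataYield:
    def test_noiseless_soil_free_yield_correlates_perfectly_with_kbs(self):
        yc = YieldCoefficients(b_soil=0.0, b_kbs_resistant=1.0,
                               b_kbs_susceptible=-1.0, noise_sd=0.0)
        spec = SynthSpec(seed=10, yield_coefficients=yc)
        rng = np.random.default_rng(0)
        kbs = rng.uniform(0, 0.05, spec.n_samples)
        meta = gen_metadata_yield(spec, kbs)
        d = design_frame(spec)
        res = (d["resistance"] == "resistant").to_numpy()
        y = meta.yields()
        r_res = np.corrcoef(kbs[res], y[res])[0, 1]
        r_sus = np.corrcoef(kbs[~res], y[~res])[0, 1]
        assert r_res == pytest.approx(1.0, abs=1e-12)
        assert r_sus == pytest.approx(-1.0, abs=1e-12)

    def test_yield_non_negative(self):
        spec = SynthSpec(seed=11)
        kbs = np.random.default_rng(1).uniform(0, 0.1, spec.n_samples)
        meta = gen_metadata_yield(spec, kbs)
        assert (meta.yields() >= 0).all()


class TestStudyBundle:
    def test_bundle_round_trips_through_io(self, tmp_path):
        spec = SynthSpec(seed=12, n_taxa=60, reads_per_sample=500, module_size=10)
        bundle = generate_study(spec)
        paths = write_bundle(bundle, tmp_path)
        back = read_count_table(paths["bacteria"], kingdom="bacteria")
        np.testing.assert_array_equal(back.counts, bundle.bacteria.counts)
        tree = read_tree(paths["tree_bacteria"])
        assert sorted(tree.tip_labels) == sorted(bundle.bacteria.taxon_ids)
        meta = read_metadata(paths["metadata"])
        assert meta.sample_ids == bundle.metadata.sample_ids
        tax = read_taxonomy(paths["taxonomy"])
        assert set(bundle.bacteria.taxon_ids) <= set(tax.table.index)

    def test_ground_truth_consistent_with_tables(self):
        spec = SynthSpec(seed=13, n_taxa=60, reads_per_sample=500, module_size=10)
        b = generate_study(spec)
        assert set(b.truth.kbs_taxa) <= set(b.bacteria.taxon_ids)
        assert set(b.truth.hub_ids) <= set(b.truth.module_of_taxon)
        genera = {b.taxonomy.rank(t, "genus").lower() for t in b.truth.kbs_taxa}
        assert genera <= b.truth.beneficial_genera
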