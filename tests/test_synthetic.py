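import numpy as np
import pytest

from votesig.enrichment import GeneSetCollection
from votesig.motifs import PromoterSet
from votesig.signature import PipelineConfig, call_de_table, compute_contrast, consensus, tally_votes
from votesig.synthetic import (
    SyntheticParams,
    default_planted_motif,
    generate_dataset,
    generate_genesets,
    generate_promoters,
)

SMALL = dict(n_genes=200, n_consensus_up=10, n_consensus_down=5,
             n_specific_per_contrast=3, n_subfloor_decoys=8)


class TestParamsValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_genes", 0),
            ("replicates_per_group", 1),
            ("baseline_sd", 0.0),
            ("effect_low", 1.0),
            ("gc_fraction", 1.5),
            ("consensus_breadth", 99),
        ],
    )
    def test_invariant_violations_name_the_field(self, field, value):
        params = SyntheticParams(**{**SMALL, field: value})
        with pytest.raises(ValueError, match=field):
            params.validate()

    def test_planted_genes_must_fit_in_universe(self):
        params = SyntheticParams(n_genes=10, n_consensus_up=20)
        with pytest.raises(ValueError, match="n_genes"):
            params.validate()


class TestGenerateDataset:
    def test_determinism_bit_identical(self):
        p = SyntheticParams(seed=5, **SMALL)
        m1, c1, t1 = generate_dataset(p)
        m2, c2, t2 = generate_dataset(SyntheticParams(seed=5, **SMALL))
        for a, b in zip(m1, m2):
            np.testing.assert_array_equal(a.values.to_numpy(), b.values.to_numpy())
        assert t1.per_gene_effects == t2.per_gene_effects
        assert [c.name for c in c1] == [c.name for c in c2]

    def test_seed_changes_output(self):
        a, _, _ = generate_dataset(SyntheticParams(seed=1, **SMALL))
        b, _, _ = generate_dataset(SyntheticParams(seed=2, **SMALL))
        assert not np.array_equal(a[0].values.to_numpy(), b[0].values.to_numpy())

    def test_truth_invariants(self, small_synthetic):
        params, matrices, contrasts, truth = small_synthetic
        assert not (truth.consensus_up & truth.consensus_down)
        # every up gene carries effect > 1 in at least min_breadth contrasts
        for g in truth.consensus_up:
            carried = [c.name for c in contrasts if (g, c.name) in truth.per_gene_effects]
            assert len(carried) >= params.min_breadth
            for c in carried:
                assert truth.per_gene_effects[(g, c)] >= params.effect_low > 1.0
        for g in truth.consensus_down:
            carried = [(g, c.name) for c in contrasts if (g, c.name) in truth.per_gene_effects]
            assert all(truth.per_gene_effects[k] <= -params.effect_low for k in carried)

    def test_subfloor_decoys_stay_below_the_floor(self, small_synthetic):
        params, matrices, contrasts, truth = small_synthetic
        for m, c in zip(matrices, contrasts):
            for group in ("sham", "treated"):
                means = m.values[m.samples_in_group(group)].mean(axis=1)
                assert (means[sorted(truth.subfloor)] < 5.0).all()

    def test_zero_noise_log2fc_equals_planted_effect(self, default_config):
        p = SyntheticParams(seed=3, noise_sd=0.0, n_genes=100, n_consensus_up=10,
                            n_consensus_down=0, n_specific_per_contrast=0,
                            n_subfloor_decoys=0, consensus_breadth=5)
        matrices, contrasts, truth = generate_dataset(p)
        for m, c in zip(matrices, contrasts):
            stats = compute_contrast(m, c)
            for g in truth.consensus_up:
                assert stats.loc[g, "log2fc"] == pytest.approx(truth.per_gene_effects[(g, c.name)])
                assert stats.loc[g, "log2fc"] > 1.0

    def test_zero_noise_consensus_recovers_planted_truth(self, default_config):
        p = SyntheticParams(seed=4, noise_sd=0.0, **SMALL)
        matrices, contrasts, truth = generate_dataset(p)
        calls = {c.name: call_de_table(compute_contrast(m, c), c.name, default_config)
                 for m, c in zip(matrices, contrasts)}
        up = consensus(tally_votes(calls), default_config, "up")
        assert set(up.gene_ids) == truth.consensus_up
        # decoys carry |log2FC| > 1 yet are never called in any contrast
        called = {g for df in calls.values() for g in df.index[df["direction"] != "none"]}
        assert not (truth.subfloor & called)

    def test_matrix_round_trip_through_tsv(self, tmp_path, small_synthetic):
        from votesig.expression import read_expression_table

        _, matrices, _, _ = small_synthetic
        m = matrices[0]
        m.to_tsv(tmp_path / "e.tsv", tmp_path / "g.tsv")
        back = read_expression_table(tmp_path / "e.tsv", tmp_path / "g.tsv")
        np.testing.assert_allclose(back.values.to_numpy(), m.values.to_numpy())
        assert back.group_of == m.group_of


class TestGeneratePromoters:
    def test_certain_plant_rates(self):
        p = SyntheticParams(seed=6, n_genes=30, n_consensus_up=10, n_consensus_down=0,
                            n_specific_per_contrast=0, n_subfloor_decoys=0,
                            motif_rate_target=1.0, motif_rate_background=0.0)
        _, _, truth = generate_dataset(p)
        motif = default_planted_motif()
        proms = generate_promoters(truth, p, motif)
        assert set(proms.plants) == truth.consensus_up
        consensus_site = motif.consensus()
        from votesig.motifs import reverse_complement

        for g, (pos, strand) in proms.plants.items():
            site = proms.sequence(g)[pos : pos + motif.length]
            expect = consensus_site if strand == "+" else reverse_complement(consensus_site)
            assert site == expect

    def test_gc_fraction_within_binomial_bound(self):
        # pooled GC over 100 x 1001 bases: binomial sd ~ 0.0016, so a
        # +/-0.03 band around 0.5 is > 18 sigma
        p = SyntheticParams(seed=7, n_genes=100, n_consensus_up=5, n_consensus_down=0,
                            n_specific_per_contrast=0, n_subfloor_decoys=0,
                            gc_fraction=0.5, motif_rate_target=0.0, motif_rate_background=0.0)
        _, _, truth = generate_dataset(p)
        proms = generate_promoters(truth, p)
        pooled = "".join(w.sequence for w in proms.windows.values())
        gc = (pooled.count("G") + pooled.count("C")) / len(pooled)
        assert 0.47 <= gc <= 0.53

    def test_fasta_bytes_deterministic(self, tmp_path):
        p = SyntheticParams(seed=8, n_genes=20, n_consensus_up=5, n_consensus_down=0,
                            n_specific_per_contrast=0, n_subfloor_decoys=0)
        for name in ("a.fa", "b.fa"):
            _, _, truth = generate_dataset(p)
            generate_promoters(truth, p).to_fasta(tmp_path / name)
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_motif_longer_than_promoter_rejected(self):
        p = SyntheticParams(seed=9, promoter_length=5, **SMALL)
        _, _, truth = generate_dataset(p)
        with pytest.raises(ValueError, match="promoter_length"):
            generate_promoters(truth, p)


class TestGenerateGenesets:
    @pytest.fixture
    def truth(self):
        p = SyntheticParams(seed=10, **SMALL)
        _, _, truth = generate_dataset(p)
        return truth

    def test_single_term_collection_is_the_designated_term(self, truth):
        coll = generate_genesets(truth, n_terms=1, term_size_range=(20, 20))
        assert list(coll.terms) == [truth.enriched_term]
        _, members = coll.terms[truth.enriched_term]
        assert len(members) == 20
        assert len(members & truth.consensus_up) >= 5

    def test_gmt_round_trip_deterministic(self, truth, tmp_path):
        c1 = generate_genesets(truth, seed=77)
        c1.to_gmt(tmp_path / "a.gmt")
        c2 = generate_genesets(truth, seed=77)
        c2.to_gmt(tmp_path / "b.gmt")
        assert (tmp_path / "a.gmt").read_bytes() == (tmp_path / "b.gmt").read_bytes()
        assert GeneSetCollection.from_gmt(tmp_path / "a.gmt").terms == c1.terms

    def test_term_size_range_must_fit_universe(self, truth):
        with pytest.raises(ValueError, match="term_size_range"):
            generate_genesets(truth, term_size_range=(10, 10_000))
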