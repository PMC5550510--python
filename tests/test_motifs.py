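import numpy as np
import pytest

from votesig.enrichment import hypergeom_tail
from votesig.motifs import (
    PositionWeightMatrix,
    PromoterSet,
    PromoterWindow,
    best_site_score,
    extract_windows,
    has_hit,
    load_motifs,
    max_score,
    motif_enrichment,
    pwm_log_odds,
    reverse_complement,
    write_motifs,
)

JASPAR_TEXT = """>MA0001 test_motif
A [ 10  0  2 ]
C [  0 10  2 ]
G [  0  0  4 ]
T [  0  0  2 ]
"""


def uniform_pwm(length=4):
    return PositionWeightMatrix(motif_id="uni", counts=np.full((4, length), 5.0))


def sharp_pwm(consensus="ACGTAC", motif_id="sharp", **kw):
    counts = np.full((4, len(consensus)), 0.0)
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 20.0
    return PositionWeightMatrix(motif_id=motif_id, counts=counts, **kw)


class TestLoadMotifs:
    def test_jaspar_block(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(JASPAR_TEXT)
        (motif,) = load_motifs(p)
        assert motif.length == 3
        np.testing.assert_array_equal(motif.counts[0], [10, 0, 2])

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.jaspar"
        p.write_text("")
        assert load_motifs(p) == []

    def test_malformed_block_rejected(self, tmp_path):
        p = tmp_path / "bad.jaspar"
        p.write_text(">M1 m\nA [ 1 2 ]\nC [ 1 2 ]\n")  # only 2 rows
        with pytest.raises(ValueError, match="malformed"):
            load_motifs(p)

    def test_write_read_round_trip(self, tmp_path):
        motifs = [sharp_pwm(), uniform_pwm()]
        write_motifs(motifs, tmp_path / "w.jaspar")
        back = load_motifs(tmp_path / "w.jaspar")
        assert [m.motif_id for m in back] == ["sharp", "uni"]
        np.testing.assert_allclose(back[0].counts, motifs[0].counts)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            PositionWeightMatrix(motif_id="x", counts=np.array([[-1.0], [1.0], [1.0], [1.0]]))


class TestLogOdds:
    def test_uniform_counts_score_zero(self):
        np.testing.assert_allclose(pwm_log_odds(uniform_pwm()), 0.0, atol=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        counts = rng.uniform(1, 20, size=(4, 5))
        a = PositionWeightMatrix(motif_id="a", counts=counts)
        b = PositionWeightMatrix(motif_id="b", counts=2 * counts, pseudocount=1.0)
        np.testing.assert_allclose(pwm_log_odds(a), pwm_log_odds(b), atol=0.2)

    def test_zero_pseudocount_single_base_column(self):
        counts = np.zeros((4, 1))
        counts[0, 0] = 8.0
        pwm = PositionWeightMatrix(motif_id="x", counts=counts, pseudocount=0.0)
        lo = pwm_log_odds(pwm)
        assert lo[0, 0] == pytest.approx(2.0)  # log2(1/0.25)
        assert (lo[1:, 0] == -30.0).all()  # floored, not -inf

    def test_doubling_counts_exact_with_scaled_pseudocount(self):
        counts = np.array([[3.0, 1.0], [2.0, 2.0], [1.0, 3.0], [2.0, 2.0]])
        a = PositionWeightMatrix(motif_id="a", counts=counts, pseudocount=0.0)
        b = PositionWeightMatrix(motif_id="b", counts=2 * counts, pseudocount=0.0)
        np.testing.assert_allclose(pwm_log_odds(a), pwm_log_odds(b))


class TestScanning:
    def test_consensus_scores_the_maximum(self):
        pwm = sharp_pwm("ACGTAC")
        assert best_site_score("ACGTAC", pwm) == pytest.approx(max_score(pwm))

    def test_reverse_complement_invariance(self):
        pwm = sharp_pwm("AACGTG")
        rng = np.random.default_rng(2)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=30))
            assert best_site_score(seq, pwm) == pytest.approx(
                best_site_score(reverse_complement(seq), pwm)
            )

    def test_all_n_scores_zero(self):
        assert best_site_score("N" * 12, sharp_pwm()) == 0.0

    def test_sequence_shorter_than_motif_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            best_site_score("ACG", sharp_pwm("ACGTAC"))

    def test_hit_thresholds(self):
        pwm = sharp_pwm("ACGTAC")
        assert has_hit("TTTACGTACTTT", pwm)
        assert not has_hit("TTTTTTTTTTTT", sharp_pwm("ACGTAC", score_fraction=1.0))
        permissive = sharp_pwm("ACGTAC", score_fraction=1e-9)
        assert has_hit("ACGTAC", permissive)

    def test_raising_score_fraction_never_adds_hits(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(30)]
        loose = sharp_pwm("ACGTA", score_fraction=0.5)
        tight = sharp_pwm("ACGTA", score_fraction=0.9)
        hits_loose = {s for s in seqs if has_hit(s, loose)}
        hits_tight = {s for s in seqs if has_hit(s, tight)}
        assert hits_tight <= hits_loose


class TestExtractWindows:
    @pytest.fixture
    def genome(self, tmp_path):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        fasta = tmp_path / "genome.fa"
        fasta.write_text(f">chr1\n{seq}\n")
        return fasta, seq

    def _bed(self, tmp_path, rows):
        bed = tmp_path / "tss.bed"
        bed.write_text("".join(f"{c}\t{s}\t{e}\t{n}\t0\t{st}\n" for c, s, e, n, st in rows))
        return bed

    def test_plus_strand_interior_window(self, tmp_path, genome):
        fasta, seq = genome
        bed = self._bed(tmp_path, [("chr1", 200, 201, "gA", "+")])
        ps = extract_windows(bed, fasta, window_half=50)
        w = ps.windows["gA"]
        assert len(w.sequence) == 101
        assert w.sequence == seq[150:251]
        assert not w.truncated

    def test_minus_strand_is_mirror_reverse_complement(self, tmp_path, genome):
        fasta, seq = genome
        bed = self._bed(tmp_path, [("chr1", 200, 201, "gPlus", "+"), ("chr1", 200, 201, "gMinus", "-")])
        ps = extract_windows(bed, fasta, window_half=30)
        assert ps.windows["gMinus"].sequence == reverse_complement(ps.windows["gPlus"].sequence)

    def test_edge_window_truncated_and_flagged(self, tmp_path, genome):
        fasta, seq = genome
        bed = self._bed(tmp_path, [("chr1", 10, 11, "gEdge", "+")])
        ps = extract_windows(bed, fasta, window_half=50)
        w = ps.windows["gEdge"]
        assert w.truncated
        assert w.sequence == seq[0:61]

    def test_missing_contig_rejected(self, tmp_path, genome):
        fasta, _ = genome
        bed = self._bed(tmp_path, [("chrX", 5, 6, "g", "+")])
        with pytest.raises(ValueError, match="chrX"):
            extract_windows(bed, fasta, window_half=5)


def _promoter_set(seqs):
    return PromoterSet(
        windows={
            g: PromoterWindow(gene_id=g, sequence=s, rel_start=0, rel_end=len(s) - 1)
            for g, s in seqs.items()
        }
    )


class TestMotifEnrichment:
    def test_no_hits_gives_p_one(self):
        pwm = sharp_pwm("ACGTAC", score_fraction=1.0)
        targets = _promoter_set({"t1": "TTTTTTTTTT", "t2": "TTTTTTTTTT"})
        background = _promoter_set({"b1": "TTTTTTTTTT"})
        (row,) = motif_enrichment(targets, background, [pwm])
        assert row.p_raw == 1.0

    def test_counts_feed_the_hypergeometric_tail(self):
        pwm = sharp_pwm("ACGTACGTAC", score_fraction=1.0)
        hit, miss = "TT" + "ACGTACGTAC" + "TT", "T" * 14
        targets = _promoter_set({f"t{i}": (hit if i < 9 else miss) for i in range(10)})
        background = _promoter_set({f"b{i}": (hit if i < 5 else miss) for i in range(100)})
        (row, ) = motif_enrichment(targets, background, [pwm])
        assert (row.target_with_hit, row.background_with_hit) == (9, 5)
        assert row.p_raw == pytest.approx(hypergeom_tail(9, 14, 10, 110), rel=1e-12)

    def test_enrichment_is_not_symmetric_under_set_swap(self):
        pwm = sharp_pwm("ACGTACGTAC", score_fraction=1.0)
        hit, miss = "ACGTACGTAC", "T" * 10
        a = _promoter_set({f"t{i}": (hit if i < 9 else miss) for i in range(10)})
        b = _promoter_set({f"b{i}": (hit if i < 5 else miss) for i in range(100)})
        (fwd,) = motif_enrichment(a, b, [pwm])
        (rev,) = motif_enrichment(b, a, [pwm])
        assert fwd.p_raw != pytest.approx(rev.p_raw)
        assert rev.p_raw == pytest.approx(hypergeom_tail(5, 14, 100, 110), rel=1e-12)

    def test_empty_target_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            motif_enrichment(_promoter_set({}), _promoter_set({"b": "ACGT"}), [sharp_pwm("AC")])


class TestPromoterSetFasta:
    def test_round_trip(self, tmp_path):
        ps = _promoter_set({"g1": "ACGTACGT", "g2": "TTTTACGT"})
        ps.to_fasta(tmp_path / "p.fa")
        back = PromoterSet.from_fasta(tmp_path / "p.fa")
        assert {g: w.sequence for g, w in back.windows.items()} == {
            "g1": "ACGTACGT",
            "g2": "TTTTACGT",
        }
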