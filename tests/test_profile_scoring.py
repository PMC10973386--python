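import numpy as np
import pytest

from mipscan.profile_scoring import (
    DEFAULT_SCORE_THRESHOLD,
    PSSM,
    build_pssm,
    calibrate_threshold,
    gibbs_sample,
    henikoff_weights,
    pssm_from_tsv,
    scan_pssm,
    window_scores,
)
from mipscan.synthetic import ImplantSpec, generate_background, implant

from conftest import make_record


class TestHenikoffWeights:
    def test_identical_rows_equal_weights(self):
        w = henikoff_weights(["ACD", "ACD", "ACD"])
        assert np.allclose(w, [1 / 3, 1 / 3, 1 / 3])

    def test_two_distinct_single_column(self):
        assert np.allclose(henikoff_weights(["A", "C"]), [0.5, 0.5])

    def test_hand_computed_three_rows(self):
        # rows AA, AA, CA: col1 has r=2, A-count 2, C-count 1; col2 r=1, s=3
        # raw: AA -> 1/4 + 1/3 = 7/12 ; CA -> 1/2 + 1/3 = 5/6 ; total 2
        w = henikoff_weights(["AA", "AA", "CA"])
        assert np.allclose(w, [7 / 24, 7 / 24, 10 / 24])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            henikoff_weights(["AA", "A"])

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            henikoff_weights([])


class TestBuildPssm:
    def test_background_column_scores_zero(self):
        # 20 rows, one per residue: column distribution equals uniform background
        rows = list("ACDEFGHIKLMNPQRSTVWY")
        pssm = build_pssm(rows, pseudocount_weight=1.0)
        assert np.allclose(pssm.scores, 0.0, atol=1e-12)

    def test_single_consensus_column_closed_form(self):
        pssm = build_pssm(["G"], pseudocount_weight=0.0)
        g = "ACDEFGHIKLMNPQRSTVWY".index("G")
        assert pssm.scores[0, g] == pytest.approx(np.log2(20))
        others = np.delete(pssm.scores[0], g)
        # empty cells floored, finite
        assert np.all(others == pytest.approx(np.log2(1e-9 / 0.05)))

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_pssm([])

    def test_negative_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            build_pssm(["AC"], pseudocount_weight=-0.1)

    def test_tsv_round_trip(self):
        pssm = build_pssm(["ACDG", "ACDG", "ACEG"], pseudocount_weight=0.5)
        back = pssm_from_tsv(pssm.to_tsv())
        assert np.allclose(back.scores, pssm.scores, atol=1e-6)
        assert back.pseudocount_weight == pssm.pseudocount_weight
        assert back.score_threshold == pssm.score_threshold


class TestScanPssm:
    def test_consensus_window_clears_threshold(self):
        motif = "ACDEFGHIKLMN"  # 12 distinct residues
        pssm = build_pssm([motif], pseudocount_weight=0.0)
        rec = make_record("WWWW" + motif + "WWWW")
        hits = scan_pssm(rec, pssm)
        assert len(hits) == 1
        assert hits[0].start == 5 and hits[0].end == 16
        assert hits[0].score == pytest.approx(12 * np.log2(20))
        assert hits[0].score > DEFAULT_SCORE_THRESHOLD

    def test_threshold_strictly_greater(self):
        pssm = build_pssm(["A"], pseudocount_weight=0.0, score_threshold=np.log2(20))
        rec = make_record("A")
        # the only window scores exactly log2(20) == threshold -> excluded
        assert scan_pssm(rec, pssm) == []
        assert len(scan_pssm(rec, pssm, score_threshold=np.log2(20) - 1e-9)) == 1

    def test_sequence_shorter_than_matrix(self):
        pssm = build_pssm(["ACDEFGHIKLMN"], pseudocount_weight=1.0)
        assert scan_pssm(make_record("ACD"), pssm) == []

    def test_score_additivity_against_brute_force(self):
        rng = np.random.default_rng(5)
        rows = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=8)) for _ in range(6)]
        pssm = build_pssm(rows, pseudocount_weight=1.0)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        scores = window_scores(make_record(seq), pssm)
        idx = {aa: i for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")}
        for s in range(len(seq) - 8 + 1):
            manual = sum(pssm.scores[p, idx[seq[s + p]]] for p in range(8))
            assert scores[s] == pytest.approx(manual)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(6)
        rows = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=6)) for _ in range(4)]
        pssm = build_pssm(rows, pseudocount_weight=1.0)
        rec = make_record("".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100)))
        prev: set = set()
        for thr in (10.0, 5.0, 0.0, -5.0, -np.inf):
            hits = {(h.start, h.end) for h in scan_pssm(rec, pssm, score_threshold=thr)}
            assert prev <= hits  # lowering the cutoff never removes a window
            prev = hits


def test_background_neutrality():
    """Expected window score under the background distribution is <= 0."""
    rng = np.random.default_rng(12)
    for _ in range(20):
        n = int(rng.integers(2, 8))
        rows = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=10)) for _ in range(n)]
        pssm = build_pssm(rows, pseudocount_weight=1.0)
        expected = float(np.sum(pssm.background[None, :] * pssm.scores))
        assert expected <= 1e-9


class TestGibbsSampler:
    @staticmethod
    def _implant_benchmark(gen_seed, n=20, length=100, divergence=0.0, preserve=True):
        rng = np.random.default_rng(gen_seed)
        motif = generate_background(12, seed=rng, record_id="m").residues
        seqs, starts = [], []
        for i in range(n):
            host = generate_background(length, seed=rng, record_id=f"s{i}")
            spec = ImplantSpec(consensus=motif, divergence=divergence,
                               preserve_match=preserve)
            s, t = implant(host, spec, seed=rng)
            seqs.append(s)
            starts.append(t[0].start)
        return motif, seqs, starts

    def test_recovers_implanted_motif(self):
        _, seqs, truth = self._implant_benchmark(7)
        res = gibbs_sample(seqs, motif_length=12, iterations=500, seed=1)
        correct = sum(int(a == b) for a, b in zip(res.motif_positions, truth))
        assert correct >= 18

    def test_seeded_determinism(self):
        _, seqs, _ = self._implant_benchmark(3, n=8, length=60)
        a = gibbs_sample(seqs, motif_length=12, iterations=50, seed=9)
        b = gibbs_sample(seqs, motif_length=12, iterations=50, seed=9)
        assert a.motif_positions == b.motif_positions
        assert np.array_equal(a.pssm.scores, b.pssm.scores)
        assert a.information_content == b.information_content

    def test_consensus_recovery_under_divergence(self):
        """At <=10% per-position substitution the consensus is right at >=10/12 sites."""
        motif, seqs, _ = self._implant_benchmark(21, divergence=0.1, preserve=False)
        res = gibbs_sample(seqs, motif_length=12, iterations=300, seed=4)
        agree = sum(int(a == b) for a, b in zip(res.pssm.consensus, motif))
        assert agree >= 10

    def test_too_short_sequence_rejected(self):
        seqs = [make_record("ACDEF", "a"), make_record("ACDEFGHIKLMNP", "b")]
        with pytest.raises(ValueError, match="shorter"):
            gibbs_sample(seqs, motif_length=12, iterations=10, seed=0)

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            gibbs_sample([make_record("ACDEFGHIKLMNP")], motif_length=12, seed=0)

    def test_start_positions_inside_sequences(self):
        _, seqs, _ = self._implant_benchmark(5, n=6, length=40)
        res = gibbs_sample(seqs, motif_length=12, iterations=30, seed=2)
        for s, pos in zip(seqs, res.motif_positions):
            assert 1 <= pos <= len(s.residues) - 12 + 1


def test_calibrate_threshold_orders_with_quantile():
    rng = np.random.default_rng(8)
    rows = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=12)) for _ in range(10)]
    pssm = build_pssm(rows, pseudocount_weight=1.0)
    seqs = [generate_background(150, seed=s, record_id=f"b{s}") for s in range(3)]
    lo = calibrate_threshold(pssm, seqs, quantile=0.5, n_shuffles=30, seed=1)
    hi = calibrate_threshold(pssm, seqs, quantile=0.99, n_shuffles=30, seed=1)
    assert lo <= hi
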