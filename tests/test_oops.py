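import itertools

import numpy as np
import pytest

import parsimotif as pm
from parsimotif.oops import OOPSModel, scan_sequence, sequence_log_prob
from parsimotif.seqdata import encode


def make_width1_model(theta, flank=None):
    motif = pm.MotifModel(1, 0, [pm.PCT(())], [np.asarray([theta], dtype=float)])
    return OOPSModel(motif, flank or pm.FlankingModel.uniform(0))


class TestFlanking:
    def test_homopolymer_order0(self):
        data = pm.SequenceSet(["AAAAAAAAAA"] * 5, [f"s{i}" for i in range(5)])
        model = pm.fit_flanking(data, 0)
        assert model.trans[0, 0] == pytest.approx(51 / 54)  # 50 A's + add-one over 4

    def test_uniform_synthetic_order0(self, rng):
        seqs = ["".join("ACGT"[a] for a in rng.integers(0, 4, size=200)) for _ in range(20)]
        model = pm.fit_flanking(pm.SequenceSet(seqs, [f"s{i}" for i in range(20)]), 0)
        np.testing.assert_allclose(model.trans[0], [0.25] * 4, atol=0.02)

    def test_short_sequence_high_order(self):
        model = pm.fit_flanking(pm.SequenceSet(["AC"], ["s"]), 2)
        assert model.order == 2  # trains on available lower-order prefixes
        np.testing.assert_allclose(model.trans.sum(axis=1), 1.0)

    def test_empty_segment_probability_one(self):
        model = pm.FlankingModel.uniform(2)
        assert pm.flanking_log_prob(model, "") == 0.0

    def test_uniform_order0_segment(self):
        model = pm.FlankingModel.uniform(0)
        assert pm.flanking_log_prob(model, "ACG") == pytest.approx(3 * np.log(0.25))

    def test_order1_hand_example(self):
        initial = [np.array([[0.5, 0.3, 0.1, 0.1]])]
        trans = np.array([[0.05, 0.9, 0.025, 0.025]] * 4)
        model = pm.FlankingModel(1, initial, trans)
        assert pm.flanking_log_prob(model, "AC") == pytest.approx(np.log(0.45))


class TestConditional:
    def test_no_flanks_when_l_equals_w(self, random_sites):
        motif, _ = pm.fit_motif(random_sites, 1)
        model = OOPSModel(motif, pm.FlankingModel.uniform(2))
        seq = random_sites.sites[0]
        assert pm.conditional_log_likelihood(model, seq, 1, "F") == pytest.approx(
            pm.motif_log_likelihood(motif, seq)
        )

    def test_three_factor_product(self):
        model = make_width1_model([0.3, 0.5, 0.1, 0.1])
        got = pm.conditional_log_likelihood(model, "AC", 2, "F")
        assert got == pytest.approx(np.log(0.25 * 0.5))

    def test_palindromic_window_strand_invariant(self):
        sites = pm.SiteSet(2, ["AT", "AT", "GC", "CG"])
        motif, _ = pm.fit_motif(sites, 0)
        model = OOPSModel(motif, pm.FlankingModel.uniform(0))
        # window "AT" is its own reverse complement
        f = pm.conditional_log_likelihood(model, "GATG", 2, "F")
        r = pm.conditional_log_likelihood(model, "GATG", 2, "R")
        assert f == pytest.approx(r)

    def test_sequence_shorter_than_width_errors(self, random_sites):
        motif, _ = pm.fit_motif(random_sites, 0)
        model = OOPSModel(motif, pm.FlankingModel.uniform(0))
        with pytest.raises(ValueError, match="shorter"):
            pm.conditional_log_likelihood(model, "ACG", 1, "F")


class TestJoint:
    def test_width1_strand_sum(self):
        model = make_width1_model([0.7, 0.1, 0.1, 0.1])
        # rc("A") = "T": joint = 1 * 1/2 * (0.7 + 0.1)
        assert pm.joint_log_likelihood(model, "A", 1) == pytest.approx(np.log(0.4))

    def test_equal_strand_terms(self):
        model = make_width1_model([0.25, 0.25, 0.25, 0.25])
        L = 6
        seq = "ACGTAC"
        expected = np.log(1 / L) + np.log(0.25) + (L - 1) * np.log(0.25)
        assert pm.joint_log_likelihood(model, seq, 3) == pytest.approx(expected)

    def test_scan_matches_pointwise_evaluation(self, small_benchmark):
        sites = pm.extract_sites(small_benchmark.positives, small_benchmark.truth, 8)
        motif, _ = pm.fit_motif(sites, 2)
        flank = pm.fit_flanking(small_benchmark.positives, 2)
        model = OOPSModel(motif, flank)
        for seq in small_benchmark.positives.sequences[:3]:
            cond_f, cond_r, joint = scan_sequence(model, encode(seq))
            for v in (1, 7, len(seq) - 8 + 1):
                assert cond_f[v - 1] == pytest.approx(
                    pm.conditional_log_likelihood(model, seq, v, "F")
                )
                assert cond_r[v - 1] == pytest.approx(
                    pm.conditional_log_likelihood(model, seq, v, "R")
                )
                assert joint[v - 1] == pytest.approx(pm.joint_log_likelihood(model, seq, v))

    @pytest.mark.parametrize("L,W", [(3, 1), (4, 2), (6, 2)])
    def test_oops_marginal_normalizes(self, L, W, rng):
        """Brute-force sum of the OOPS marginal over all 4^L sequences equals 1."""
        raw = rng.integers(0, 4, size=(30, W))
        sites = pm.SiteSet(W, ["".join("ACGT"[a] for a in row) for row in raw])
        motif, _ = pm.fit_motif(sites, 1)
        flank = pm.FlankingModel(0, [], np.array([[0.1, 0.2, 0.3, 0.4]]))
        model = OOPSModel(motif, flank)
        total = sum(
            np.exp(pm.oops_log_marginal(model, "".join(t)))
            for t in itertools.product("ACGT", repeat=L)
        )
        assert total == pytest.approx(1.0, abs=1e-9)


def test_flank_order2_sequence_scoring_consistency(small_benchmark):
    """Whole-sequence background score equals prefix cumulative at full length."""
    flank = pm.fit_flanking(small_benchmark.negatives, 2)
    seq = small_benchmark.negatives.sequences[0]
    manual = 0.0
    for t in range(len(seq)):
        manual += pm.flanking_log_prob(flank, seq[: t + 1]) - pm.flanking_log_prob(flank, seq[:t])
    assert sequence_log_prob(flank, seq) == pytest.approx(manual)


def test_oops_model_json_round_trip(tmp_path, random_sites):
    motif, _ = pm.fit_motif(random_sites, 1)
    data = pm.SequenceSet(random_sites.sites, [f"s{i}" for i in range(len(random_sites))])
    model = OOPSModel(motif, pm.fit_flanking(data, 2))
    path = tmp_path / "oops.json"
    model.save(path)
    back = OOPSModel.load(path)
    seq = random_sites.sites[0]
    assert pm.joint_log_likelihood(back, seq, 1) == pytest.approx(
        pm.joint_log_likelihood(model, seq, 1)
    )
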