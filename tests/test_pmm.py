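import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import parsimotif as pm
from parsimotif.pmm import fit_with_structure
from parsimotif.seqdata import SiteSet, decode


def pwm_log_likelihood(sites, thetas):
    """Independent PWM oracle: sum of per-position column log-probabilities."""
    total = 0.0
    for s in sites:
        for pos, ch in enumerate(s):
            total += np.log(thetas[pos]["ACGT".index(ch)])
    return total


class TestFsnml:
    def test_all_zero_counts_uniform(self):
        np.testing.assert_allclose(pm.fsnml_estimate([0, 0, 0, 0]), [0.25] * 4)

    def test_single_count_example(self):
        # e(1)=2 -> numerator 2*2=4, denominator 4+1+1+1=7
        np.testing.assert_allclose(pm.fsnml_estimate([1, 0, 0, 0]), [4 / 7, 1 / 7, 1 / 7, 1 / 7])

    @pytest.mark.parametrize("k", [1, 5, 1000])
    def test_symmetric_counts_uniform(self, k):
        np.testing.assert_allclose(pm.fsnml_estimate([k] * 4), [0.25] * 4, atol=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            pm.fsnml_estimate([1, -1, 0, 0])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=10**6), min_size=4, max_size=4))
    def test_strictly_positive_and_normalized(self, counts):
        theta = pm.fsnml_estimate(counts)
        assert np.all(theta > 0)
        assert theta.sum() == pytest.approx(1.0, abs=1e-12)


class TestFitPosition:
    def test_concentrated_column(self, rng):
        sites = SiteSet(2, ["AA"] * 300 + ["CA"] * 300)
        scored, theta = pm.fit_position(sites, 2, 1)
        assert np.all(theta[:, 0] > 0.99)  # column 2 is all A in every context

    def test_depth_zero_is_pwm_column(self, random_sites):
        scored, theta = pm.fit_position(random_sites, 3, 0)
        assert scored.pct.depth == 0 and theta.shape == (1, 4)
        counts = pm.context_counts(random_sites, 3, 0)[0]
        np.testing.assert_allclose(theta[0], pm.fsnml_estimate(counts))

    def test_copy_column_selects_split(self, rng):
        """When a column deterministically copies its predecessor, BIC splits."""
        first = rng.integers(0, 4, size=1000)
        sites = SiteSet(2, [decode([a, a]) for a in first])
        scored, theta = pm.fit_position(sites, 2, 1)
        assert scored.pct.n_leaves == 4
        for leaf, ctx in enumerate(scored.pct.contexts()):
            (sym,) = ctx
            assert theta[leaf, "ACGT".index(sym)] > 0.99

    def test_empty_sites_error(self):
        with pytest.raises(ValueError):
            pm.fit_position(SiteSet(2, []), 1, 0)


class TestFitMotif:
    def test_identical_sites_closed_form(self):
        n = 50
        sites = SiteSet(4, ["ACGT"] * n)
        model, score = pm.fit_motif(sites, 0)
        # per position: LL = 0 (deterministic), penalty 1.5 ln n
        assert score == pytest.approx(4 * (-1.5 * np.log(n)))
        for pos, theta in enumerate(model.thetas):
            assert theta[0, pos] > 0.95  # fsNML concentrates on the observed base

    def test_score_monotone_in_order(self, random_sites):
        scores = [pm.fit_motif(random_sites, d)[1] for d in (0, 1, 2)]
        assert scores[0] <= scores[1] + 1e-9 <= scores[2] + 2e-9

    def test_score_invariant_to_site_order(self, random_sites, rng):
        shuffled = SiteSet(random_sites.width,
                           [random_sites.sites[i] for i in rng.permutation(len(random_sites))])
        assert pm.fit_motif(random_sites, 2)[1] == pytest.approx(pm.fit_motif(shuffled, 2)[1])


class TestLikelihood:
    def test_width_one_certain(self):
        model = pm.MotifModel(1, 0, [pm.PCT(())], [np.array([[1.0, 0, 0, 0]])])
        assert pm.motif_log_likelihood(model, "A") == 0.0

    def test_uniform_model(self):
        model = pm.MotifModel(2, 0, [pm.PCT(()), pm.PCT(())],
                              [np.full((1, 4), 0.25)] * 2)
        assert pm.motif_log_likelihood(model, "AG") == pytest.approx(2 * np.log(0.25))

    def test_minimal_pct_model_equals_pwm(self, random_sites):
        """An all-minimal PMM of any order is likelihood-identical to the PWM."""
        pcts = [pm.PCT.minimal(min(2, pos - 1)) for pos in range(1, 7)]
        model, _ = fit_with_structure(random_sites, 2, pcts)
        pwm_cols = [pm.fsnml_estimate(pm.context_counts(random_sites, pos, 0)[0])
                    for pos in range(1, 7)]
        expected = pwm_log_likelihood(random_sites.sites, pwm_cols)
        assert pm.motif_log_likelihood(model, random_sites) == pytest.approx(expected)

    def test_width_mismatch_errors(self, random_sites):
        model, _ = pm.fit_motif(random_sites, 0)
        with pytest.raises(ValueError, match="width"):
            pm.motif_log_likelihood(model, "ACG")


def test_model_json_round_trip(tmp_path, random_sites):
    model, _ = pm.fit_motif(random_sites, 2)
    path = tmp_path / "model.json"
    model.save(path)
    back = pm.MotifModel.load(path)
    assert back.width == model.width and back.order == model.order
    assert back.pcts == model.pcts
    for a, b in zip(back.thetas, model.thetas):
        np.testing.assert_allclose(a, b)
    assert pm.motif_log_likelihood(back, random_sites) == pytest.approx(
        pm.motif_log_likelihood(model, random_sites)
    )
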