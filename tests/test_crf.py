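"""CRF layer against brute-force path enumeration, plus gradient checks."""
import itertools

import numpy as np
import pytest

import pharmaconer._autodiff as ad
from pharmaconer.crf import (
    NEG_INF,
    CrfParameters,
    crf_loss,
    crf_partition,
    tag_inventory,
    transition_masks,
    viterbi_decode,
)
from pharmaconer.types import TagSequence


def enumerate_scores(emissions, crf):
    """Score of every possible tag path, by direct summation."""
    n, L = emissions.shape
    scores = {}
    for path in itertools.product(range(L), repeat=n):
        s = crf.start[path[0]] + crf.stop[path[-1]]
        s += sum(emissions[i, y] for i, y in enumerate(path))
        s += sum(crf.transitions[a, b] for a, b in zip(path, path[1:]))
        scores[path] = s
    return scores


def random_instance(rng, max_n=5, max_tags=4):
    n = int(rng.integers(1, max_n + 1))
    L = int(rng.integers(2, max_tags + 1))
    emissions = rng.normal(size=(n, L))
    crf = CrfParameters(rng.normal(size=(L, L)), rng.normal(size=L),
                        rng.normal(size=L))
    return emissions, crf


class TestPartition:
    def test_uniform_single_token_closed_form(self):
        L = 7
        crf = CrfParameters(np.zeros((L, L)), np.zeros(L), np.zeros(L))
        val = crf_partition(np.zeros((1, L)), crf).value
        assert val == pytest.approx(np.log(L), abs=1e-12)

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            emissions, crf = random_instance(rng)
            scores = enumerate_scores(emissions, crf)
            brute = np.logaddexp.reduce(list(scores.values()))
            assert crf_partition(emissions, crf).value == pytest.approx(
                brute, abs=1e-6)

    def test_constant_emission_shift_moves_logz_by_n_c(self):
        rng = np.random.default_rng(5)
        emissions, crf = random_instance(rng, max_n=4)
        n = emissions.shape[0]
        base = crf_partition(emissions, crf).value
        shifted = crf_partition(emissions + 0.7, crf).value
        assert shifted == pytest.approx(base + n * 0.7, abs=1e-9)

    def test_path_posteriors_sum_to_one(self):
        rng = np.random.default_rng(7)
        emissions, crf = random_instance(rng)
        scores = enumerate_scores(emissions, crf)
        log_z = crf_partition(emissions, crf).value
        total = sum(np.exp(s - log_z) for s in scores.values())
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_rejects_nonfinite_emissions_and_empty_input(self):
        crf = CrfParameters(np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError):
            crf_partition(np.array([[np.nan, 0.0]]), crf)
        with pytest.raises(ValueError):
            crf_partition(np.zeros((0, 2)), crf)


class TestLoss:
    def test_uniform_single_token_loss_is_log_l(self):
        L = 5
        crf = CrfParameters(np.zeros((L, L)), np.zeros(L), np.zeros(L))
        loss = crf_loss(np.zeros((1, L)), crf, [2]).value
        assert loss == pytest.approx(np.log(L), abs=1e-12)

    def test_peaked_emissions_drive_loss_to_zero(self):
        L, n = 3, 4
        crf = CrfParameters(np.zeros((L, L)), np.zeros(L), np.zeros(L))
        gold = [0, 1, 2, 1]
        emissions = np.full((n, L), -50.0)
        emissions[np.arange(n), gold] = 50.0
        assert crf_loss(emissions, crf, gold).value < 1e-6

    def test_equals_negative_log_gold_posterior_from_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            emissions, crf = random_instance(rng)
            n, L = emissions.shape
            gold = tuple(int(rng.integers(L)) for _ in range(n))
            scores = enumerate_scores(emissions, crf)
            log_z = np.logaddexp.reduce(list(scores.values()))
            expected = -(scores[gold] - log_z)
            assert crf_loss(emissions, crf, list(gold)).value \
                == pytest.approx(expected, abs=1e-6)
            assert crf_loss(emissions, crf, list(gold)).value >= -1e-9

    def test_tag_outside_label_set_rejected(self):
        crf = CrfParameters(np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError):
            crf_loss(np.zeros((1, 2)), crf, [5])

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(99)
        emissions = ad.parameter(rng.normal(size=(4, 4)))
        trans = ad.parameter(rng.normal(size=(4, 4)))
        start = ad.parameter(rng.normal(size=4))
        stop = ad.parameter(rng.normal(size=4))
        gold = [0, 2, 1, 3]
        loss = crf_loss(emissions, (trans, start, stop), gold)
        loss.backward()

        def value():
            return crf_loss(
                emissions.value,
                (ad.as_tensor(trans.value), ad.as_tensor(start.value),
                 ad.as_tensor(stop.value)),
                gold).value

        eps = 1e-6
        for param in (emissions, trans, start, stop):
            it = np.nditer(param.value, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = param.value[i]
                param.value[i] = orig + eps
                up = value()
                param.value[i] = orig - eps
                down = value()
                param.value[i] = orig
                fd = (up - down) / (2 * eps)
                denom = max(abs(fd), abs(param.grad[i]), 1e-8)
                assert abs(fd - param.grad[i]) / denom < 1e-4


class TestViterbi:
    def test_zero_transitions_reduce_to_per_token_argmax(self):
        rng = np.random.default_rng(3)
        emissions = rng.normal(size=(6, 4))
        crf = CrfParameters(np.zeros((4, 4)), np.zeros(4), np.zeros(4))
        path, _ = viterbi_decode(emissions, crf)
        assert path == list(np.argmax(emissions, axis=1))

    def test_matches_enumeration_argmax(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            emissions, crf = random_instance(rng)
            scores = enumerate_scores(emissions, crf)
            best = max(scores, key=lambda p: (scores[p], [-x for x in p]))
            path, score = viterbi_decode(emissions, crf)
            assert score == pytest.approx(max(scores.values()), abs=1e-9)
            assert tuple(path) == best

    @pytest.mark.parametrize("scheme", ["BIO", "BIOES"])
    def test_masked_transitions_always_yield_valid_sequences(self, scheme):
        tags = tag_inventory(["X", "Y"], scheme)
        tm, sm, em = transition_masks(tags, scheme)
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(1, 8))
            emissions = rng.normal(size=(n, len(tags))) * 5
            crf = CrfParameters(tm + rng.normal(size=tm.shape),
                                sm + rng.normal(size=sm.shape),
                                em + rng.normal(size=em.shape))
            path, _ = viterbi_decode(emissions, crf)
            seq = TagSequence(scheme, [tags[i] for i in path])
            assert seq.is_valid(), seq.tags

    def test_mask_value_dominates_any_emission(self):
        assert NEG_INF < -1000
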