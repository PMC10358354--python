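"""Translator plumbing and the contrastive-translation loss mathematics."""

import math
import sys

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fieldsynth import (
    FeaturePatchSet,
    LossWeights,
    TranslationError,
    adversarial_loss,
    external_translator_adapter,
    get_translator,
    identity_translator,
    masked_means,
    patchnce_loss,
    patchnce_unit_loss,
    rgb_to_lab8,
    stats_transfer_translator,
    total_cut_loss,
)


def _tile(rng, side=32):
    return rng.integers(0, 256, (side, side, 3)).astype(np.uint8)


def _naive_unit_loss(q, pos, negs, tau):
    """Direct transcription of the contrastive cross-entropy, evaluated in
    extended precision with no stabilization."""
    q = np.asarray(q, dtype=np.longdouble)
    pos_term = np.exp(np.dot(q, np.asarray(pos, dtype=np.longdouble)) / tau)
    neg_terms = sum(
        np.exp(np.dot(q, np.asarray(n, dtype=np.longdouble)) / tau) for n in negs
    )
    return float(-np.log(pos_term / (pos_term + neg_terms)))


class TestTranslators:
    def test_identity_returns_same_tile(self, rng):
        t = identity_translator()
        tile = _tile(rng)
        assert np.array_equal(t(tile), tile)
        assert np.array_equal(t(t(tile)), tile)

    def test_identity_does_not_alias_input(self, rng):
        t = identity_translator()
        tile = _tile(rng)
        out = t(tile)
        out[0, 0] = 0
        assert not np.array_equal(out, tile) or tile[0, 0, 0] == 0

    def test_stats_transfer_strength_zero_is_identity(self, rng):
        t = stats_transfer_translator(strength=0.0)
        tile = _tile(rng)
        assert np.array_equal(t(tile), tile)

    def test_stats_transfer_uniform_tile_hits_reference(self):
        tile = np.full((16, 16, 3), 90, dtype=np.uint8)
        ref = (170.0, 100.0, 160.0)
        out = stats_transfer_translator(ref, strength=1.0)(tile)
        got = masked_means(rgb_to_lab8(out), np.ones((16, 16), dtype=bool))
        # exact up to the RGB round trip (<= 2 levels per channel)
        assert np.all(np.abs(got - ref) <= 2.0)

    def test_stats_transfer_interpolates_means(self, rng):
        tile = rng.integers(60, 190, (24, 24, 3)).astype(np.uint8)
        full = np.ones((24, 24), dtype=bool)
        before = masked_means(rgb_to_lab8(tile), full)
        ref = np.array([170.0, 100.0, 160.0])
        s = 0.5
        out = stats_transfer_translator(tuple(ref), strength=s)(tile)
        got = masked_means(rgb_to_lab8(out), full)
        assert np.all(np.abs(got - ((1 - s) * before + s * ref)) <= 2.5)

    def test_registry_lookup(self):
        assert get_translator("identity").name == "identity"
        with pytest.raises(KeyError):
            get_translator("nope")


class TestExternalAdapter:
    def test_copy_command_behaves_as_identity(self, rng, tmp_path):
        t = external_translator_adapter(
            f"{sys.executable} -c \"import shutil,sys; shutil.copy('{{input}}', '{{output}}')\"",
        )
        tile = _tile(rng)
        assert np.array_equal(t(tile), tile)

    def test_failure_raises_translation_error(self, rng):
        t = external_translator_adapter(f"{sys.executable} -c \"import sys; sys.exit(3)\" {{input}} {{output}}")
        with pytest.raises(TranslationError):
            t(_tile(rng))

    def test_wrong_size_output_is_contract_error(self, rng):
        code = (
            "import imageio.v3 as iio, numpy as np, sys;"
            "iio.imwrite(sys.argv[2], np.zeros((8, 8, 3), dtype=np.uint8))"
        )
        t = external_translator_adapter(f'{sys.executable} -c "{code}" {{input}} {{output}}')
        with pytest.raises(TranslationError):
            t(_tile(rng, side=16))

    def test_cache_hit_skips_reinvocation(self, rng, tmp_path):
        marker = tmp_path / "calls.txt"
        code = (
            "import shutil, sys;"
            f"open(r'{marker}', 'a').write('x');"
            "shutil.copy(sys.argv[1], sys.argv[2])"
        )
        t = external_translator_adapter(f'{sys.executable} -c "{code}" {{input}} {{output}}')
        tile = _tile(rng)
        a = t(tile)
        b = t(tile)
        assert np.array_equal(a, b)
        assert marker.read_text() == "x"  # one invocation only


class TestPatchNCE:
    @pytest.mark.parametrize("n", [1, 8, 255])
    def test_all_equal_vectors_give_log_n_plus_one(self, n):
        v = np.ones(32) / np.sqrt(32)
        ps = FeaturePatchSet(v, v, np.tile(v, (n, 1)))
        assert patchnce_unit_loss(ps) == pytest.approx(math.log(n + 1), abs=1e-9)

    def test_dominant_positive_drives_loss_to_zero(self, rng):
        # positive dot exceeds every negative dot by ~10/tau: the softmax
        # saturates and the loss vanishes
        q = np.ones(8)
        pos = np.ones(8) * (10.0 / 8.0)  # q.pos = 10
        negs = rng.normal(size=(8, 8)) * 0.01
        ps = FeaturePatchSet(q, pos, negs, temperature=0.07)
        assert patchnce_unit_loss(ps) < 1e-3

    def test_matches_naive_formula(self, rng):
        for _ in range(200):
            d = int(rng.integers(2, 12))
            q = rng.normal(size=d) * 0.5
            pos = rng.normal(size=d) * 0.5
            negs = rng.normal(size=(8, d)) * 0.5
            ps = FeaturePatchSet(q, pos, negs)
            naive = _naive_unit_loss(q, pos, negs, 0.07)
            assert patchnce_unit_loss(ps) == pytest.approx(naive, rel=1e-6)

    def test_monotone_in_dot_products(self):
        q = np.array([1.0, 0.0])
        negs = np.array([[0.5, 0.0], [0.3, 0.1]])
        base = patchnce_unit_loss(FeaturePatchSet(q, np.array([0.6, 0.0]), negs))
        better_pos = patchnce_unit_loss(FeaturePatchSet(q, np.array([0.7, 0.0]), negs))
        worse_neg = patchnce_unit_loss(
            FeaturePatchSet(q, np.array([0.6, 0.0]), negs + [[0.1, 0.0], [0.0, 0.0]])
        )
        assert better_pos < base < worse_neg

    def test_zero_temperature_rejected(self):
        v = np.ones(4)
        with pytest.raises(ValueError):
            FeaturePatchSet(v, v, v[None, :], temperature=0.0)

    def test_sum_over_layers_and_locations(self, rng):
        v = np.ones(8)
        ps = FeaturePatchSet(v, v, np.tile(v, (4, 1)))
        single = patchnce_loss([[ps]])
        assert single == pytest.approx(patchnce_unit_loss(ps))
        assert patchnce_loss([[ps, ps], [ps]]) == pytest.approx(3 * single)

    def test_nested_structure_equals_flat_sum(self, rng):
        layers = []
        flat = 0.0
        for _ in range(int(rng.integers(1, 5))):
            layer = []
            for _ in range(int(rng.integers(1, 6))):
                d = int(rng.integers(2, 6))
                ps = FeaturePatchSet(
                    rng.normal(size=d), rng.normal(size=d), rng.normal(size=(3, d))
                )
                layer.append(ps)
                flat += patchnce_unit_loss(ps)
            layers.append(layer)
        assert patchnce_loss(layers) == pytest.approx(flat)

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            patchnce_loss([])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_patchnce_nonnegative(seed):
    rng = np.random.default_rng(seed)
    d = int(rng.integers(2, 10))
    ps = FeaturePatchSet(rng.normal(size=d), rng.normal(size=d), rng.normal(size=(5, d)))
    assert patchnce_unit_loss(ps) >= 0.0


class TestAdversarialAndTotal:
    def test_maximum_entropy_discriminator(self):
        v = adversarial_loss(np.array([0.5]), np.array([0.5]))
        assert v == pytest.approx(-2 * math.log(2), abs=1e-9)

    def test_perfect_discriminator_limit(self):
        v = adversarial_loss(np.array([1.0 - 1e-9]), np.array([1e-9]))
        assert -1e-5 < v <= 0.0

    def test_matches_elementwise_log_mean(self, rng):
        dr = rng.uniform(0.01, 0.99, size=20)
        df = rng.uniform(0.01, 0.99, size=15)
        expected = np.mean([math.log(p) for p in dr]) + np.mean(
            [math.log(1 - p) for p in df]
        )
        assert adversarial_loss(dr, df) == pytest.approx(expected)

    def test_total_loss_weighting(self, rng):
        assert total_cut_loss(5.0, 2.0, 3.0, LossWeights(0, 0)) == 5.0
        assert total_cut_loss(1.0, 2.0, 3.0) == pytest.approx(6.0)
        a, b, c = rng.normal(size=3)
        lx, ly = rng.uniform(0, 2, size=2)
        got = total_cut_loss(a, b, c, LossWeights(lx, ly))
        assert got == pytest.approx(a + lx * b + ly * c)
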