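"""Meiosis, bulk selection, pooled sequencing, and the causal caller."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clumpclock import (
    EmptyPoolError,
    LocusSpec,
    SporePool,
    binom_dev_p,
    call_causal,
    cross_and_sporulate,
    select_pool,
    sequence_pool,
    subtrait_score,
)


def make_loci(n_causal, n_neutral):
    return [LocusSpec(f"causal_{i}", causal=True) for i in range(n_causal)] + [
        LocusSpec(f"neutral_{i}") for i in range(n_neutral)
    ]


class TestCrossAndSporulate:
    def test_mendelian_single_locus(self):
        pool = cross_and_sporulate(make_loci(1, 0), 10_000, seed=1)
        freq = pool.allele_freq()[0]
        assert abs(freq - 0.5) <= 3 * np.sqrt(0.25 / 10_000)

    def test_eight_locus_full_genotype_fraction(self):
        # all eight evolved alleles co-occur in (1/2)^8 of spores
        pool = cross_and_sporulate(make_loci(8, 0), 20_000, seed=2)
        full = pool.counts[pool.genotypes == 0xFF].sum() / pool.size
        p = 1 / 256
        assert abs(full - p) <= 4 * np.sqrt(p * (1 - p) / 20_000)

    def test_two_locus_classes_equifrequent(self):
        pool = cross_and_sporulate(make_loci(2, 0), 20_000, seed=3)
        assert pool.genotypes.size == 4
        fractions = pool.counts / pool.size
        assert np.all(np.abs(fractions - 0.25) <= 4 * np.sqrt(0.25 * 0.75 / 20_000))

    def test_bad_arguments_rejected(self):
        with pytest.raises(ValueError):
            cross_and_sporulate(make_loci(1, 0), 0)
        with pytest.raises(ValueError):
            cross_and_sporulate([], 10)


class TestSelectPool:
    def test_always_true_predicate_is_identity(self):
        pool = cross_and_sporulate(make_loci(2, 2), 1000, seed=4)
        out = select_pool(pool, predicate=lambda g: True)
        assert out.size == pool.size

    def test_default_predicate_fixes_causal_alleles(self):
        pool = cross_and_sporulate(make_loci(8, 0), 50_000, seed=5)
        out = select_pool(pool)
        assert np.allclose(out.allele_freq(), 1.0)

    def test_neutral_loci_stay_near_half_in_survivors(self):
        pool = cross_and_sporulate(make_loci(4, 6), 50_000, seed=6)
        out = select_pool(pool)
        neutral = out.allele_freq()[4:]
        se = np.sqrt(0.25 / out.size)
        assert np.all(np.abs(neutral - 0.5) <= 4 * se)

    def test_empty_survivors_raise(self):
        pool = cross_and_sporulate(make_loci(1, 0), 100, seed=7)
        with pytest.raises(EmptyPoolError):
            select_pool(pool, predicate=lambda g: False)


class TestSequencePool:
    def test_fixed_allele_reads_pure(self):
        pool = cross_and_sporulate(make_loci(3, 0), 5000, seed=8)
        out = select_pool(pool)
        pileup = sequence_pool(out, 80, seed=9)
        assert (pileup["alt_reads"] == pileup["depth"]).all()

    def test_half_frequency_binomial_moments(self):
        # many neutral loci at freq 1/2, depth 100: mean ~50, SD ~5
        loci = make_loci(0, 50)
        ratios = []
        for seed in range(4):
            pool = cross_and_sporulate(loci, 50_000, seed=10 + seed)
            pileup = sequence_pool(pool, 100, seed=30 + seed)
            ratios.extend((pileup["alt_reads"] / pileup["depth"]).tolist())
        ratios = np.asarray(ratios)
        assert abs(ratios.mean() - 0.5) < 0.02
        assert 0.03 < ratios.std() < 0.075

    def test_zero_depth_rejected(self):
        pool = cross_and_sporulate(make_loci(1, 0), 100, seed=12)
        with pytest.raises(ValueError):
            sequence_pool(pool, 0)


class TestBinomDevP:
    @pytest.mark.parametrize(
        "depth,alt,expected",
        [
            (1, 1, 0.5),
            (10, 10, 0.5 ** 10),
            (100, 95, 6.2616e-23),  # exact tail sum of C(100,k)/2^100, k>=95
        ],
    )
    def test_known_tails(self, depth, alt, expected):
        assert binom_dev_p(depth, alt) == pytest.approx(expected, rel=1e-4)

    def test_symmetric_under_allele_swap(self):
        for depth, alt in [(100, 95), (37, 4), (60, 30)]:
            assert binom_dev_p(depth, alt) == pytest.approx(
                binom_dev_p(depth, depth - alt), rel=1e-12
            )

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(depth=st.integers(1, 60), data=st.data())
    def test_matches_exact_rational_summation(self, depth, data):
        alt = data.draw(st.integers(0, depth))
        if alt >= depth / 2:
            ks = range(alt, depth + 1)
        else:
            ks = range(0, alt + 1)
        exact = sum(Fraction(comb(depth, k), 2 ** depth) for k in ks)
        assert binom_dev_p(depth, alt) == pytest.approx(float(exact), rel=1e-10)

    def test_stable_at_large_depth(self):
        # one-sided normal tail at z=2 for n=1e6 is ~0.0228
        assert binom_dev_p(1_000_000, 501_000) == pytest.approx(0.0228, abs=0.001)

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            binom_dev_p(0, 0)
        with pytest.raises(ValueError):
            binom_dev_p(10, 11)


class TestCallCausal:
    def test_threshold_arithmetic(self):
        import pandas as pd

        pileup = pd.DataFrame(
            {"locus": ["a", "b"], "depth": [100, 100], "alt_reads": [96, 50]}
        )
        calls = call_causal(pileup)
        assert calls.set_index("locus")["freq_hat"]["a"] == pytest.approx(0.96)
        assert bool(calls.set_index("locus")["is_causal"]["a"]) is True
        assert bool(calls.set_index("locus")["is_causal"]["b"]) is False

    def test_zero_depth_flagged_not_dropped(self):
        import pandas as pd

        pileup = pd.DataFrame(
            {"locus": ["a", "b"], "depth": [0, 50], "alt_reads": [0, 50]}
        )
        calls = call_causal(pileup)
        assert len(calls) == 2
        row = calls.set_index("locus").loc["a"]
        assert not row["callable"] and not row["is_causal"]

    def test_planted_set_recovered(self):
        loci = make_loci(3, 5)
        pool = cross_and_sporulate(loci, 2000, seed=13)
        pileup = sequence_pool(select_pool(pool), 100, seed=14)
        calls = call_causal(pileup)
        called = set(calls[calls["is_causal"]]["locus"])
        assert called == {l.name for l in loci if l.causal}

    def test_estimator_consistency_in_depth(self):
        # |freq_hat - true| shrinks like depth^(-1/2)
        loci = make_loci(0, 60)
        pool = cross_and_sporulate(loci, 50_000, seed=15)
        true = pool.allele_freq()
        mae = {}
        for depth, seed in [(10, 16), (100, 17), (1000, 18)]:
            errors = []
            for rep in range(5):
                pileup = sequence_pool(pool, depth, seed=seed + 100 * rep)
                freq_hat = pileup["alt_reads"] / pileup["depth"]
                errors.append(np.abs(freq_hat - true))
            mae[depth] = float(np.mean(errors))
        assert mae[10] > mae[100] > mae[1000]
        assert 2.0 < mae[10] / mae[100] < 5.0
        assert 2.0 < mae[100] / mae[1000] < 5.0

    def test_neutral_loci_never_cross_threshold_at_depth_100(self):
        # P(freq_hat >= 0.95 | freq=0.5, depth~100) ~ 1e-21: never observed
        loci = make_loci(0, 20)
        crossings = 0
        for seed in range(50):
            pool = cross_and_sporulate(loci, 5000, seed=100 + seed)
            pileup = sequence_pool(pool, 100, seed=200 + seed)
            calls = call_causal(pileup)
            crossings += int(calls["is_causal"].sum())
        assert crossings == 0


class TestSubtraitScore:
    def _pools(self, k_selected, n_selected):
        loci = (LocusSpec("m", causal=True),)
        start = SporePool(loci, np.array([1, 0]), np.array([500, 500]))
        selected = SporePool(
            loci, np.array([1, 0]), np.array([k_selected, n_selected - k_selected])
        )
        return start, selected

    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (190, 200, "selected_for"),
            (100, 200, "neutral"),
            (10, 200, "selected_against"),
        ],
    )
    def test_three_way_classification(self, k, n, expected):
        start, selected = self._pools(k, n)
        out = subtrait_score(start, selected)
        assert out["classification"].iloc[0] == expected

    def test_mismatched_loci_rejected(self):
        a = SporePool((LocusSpec("m"),), np.array([1]), np.array([10]))
        b = SporePool((LocusSpec("x"),), np.array([1]), np.array([10]))
        with pytest.raises(ValueError):
            subtrait_score(a, b)
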