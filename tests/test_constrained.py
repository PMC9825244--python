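from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exarch.annotations import IntervalAnnotation
from exarch.constrained import (
    ConstrainedExpectationContext,
    expected_constrained_probability,
    is_constrained,
    subsample_domains,
)


def enumerate_strict_interior_windows(L, domains, y):
    """Independent oracle: slide a y-residue window over all L-y+1 start
    positions and count windows with both endpoints strictly inside a single
    domain placed at explicit coordinates."""
    count = 0
    for s in range(1, L - y + 2):
        e = s + y - 1
        if any(a < s and e < b for a, b in domains):
            count += 1
    return Fraction(count, L - y + 1)


def random_layout(rng, L_max=500, max_domains=10):
    L = int(rng.integers(50, L_max + 1))
    domains = []
    pos = 0
    for _ in range(int(rng.integers(0, max_domains + 1))):
        gap = int(rng.integers(1, 20))
        length = int(rng.integers(3, 80))
        a = pos + gap
        b = a + length - 1
        if b > L:
            break
        domains.append((a, b))
        pos = b
    return L, domains


class TestExpectedProbability:
    def test_single_domain_hand_value(self):
        ctx = ConstrainedExpectationContext(L=100, domain_lengths=(20,))
        assert expected_constrained_probability(10, ctx, exact=True) == Fraction(9, 91)

    def test_domain_equal_to_y_plus_one_contributes_zero(self):
        ctx = ConstrainedExpectationContext(L=100, domain_lengths=(11,))
        assert expected_constrained_probability(10, ctx) == 0.0

    def test_no_domains_gives_zero(self):
        ctx = ConstrainedExpectationContext(L=100, domain_lengths=())
        assert expected_constrained_probability(10, ctx) == 0.0

    def test_y_not_smaller_than_L_rejected(self):
        ctx = ConstrainedExpectationContext(L=50, domain_lengths=(20,))
        with pytest.raises(ValueError):
            expected_constrained_probability(50, ctx)

    def test_matches_window_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 60:
            L, domains = random_layout(rng)
            y = int(rng.integers(1, 51))
            if y >= L:
                continue
            ctx = ConstrainedExpectationContext(
                L=L, domain_lengths=tuple(b - a + 1 for a, b in domains)
            )
            got = expected_constrained_probability(y, ctx, exact=True)
            want = enumerate_strict_interior_windows(L, domains, y)
            assert got == want
            checked += 1

    @given(st.integers(1, 60), st.integers(2, 60))
    @settings(max_examples=80, deadline=None)
    def test_non_increasing_in_y(self, y1, y2):
        ctx = ConstrainedExpectationContext(L=200, domain_lengths=(30, 80, 15))
        lo, hi = sorted((y1, y2))
        assert expected_constrained_probability(hi, ctx) <= expected_constrained_probability(
            lo, ctx
        ) + 1e-12


class TestIsConstrained:
    def _domains(self, *ivs):
        return IntervalAnnotation("p", "SCOP", "DOMAIN", tuple(ivs))

    @pytest.mark.parametrize(
        "span,domains,expected",
        [
            ((10, 20), [(5, 30)], True),
            ((10, 20), [(12, 30)], False),  # left boundary outside
            ((10, 20), [(1, 15), (16, 40)], False),  # needs a single domain
            ((10, 20), [(10, 20)], True),  # containment includes boundaries
        ],
    )
    def test_examples(self, span, domains, expected):
        assert is_constrained(span, self._domains(*domains)) is expected

    def test_no_domains_is_unconstrained(self):
        assert is_constrained((5, 9), None) is False

    def test_agrees_with_brute_force_on_random_layouts(self):
        rng = np.random.default_rng(6)
        for _ in range(300):
            L, domains = random_layout(rng, L_max=300, max_domains=6)
            y = int(rng.integers(1, 40))
            first = int(rng.integers(1, max(2, L - y)))
            span = (first, first + y - 1)
            ann = self._domains(*domains) if domains else None
            brute = any(a <= span[0] and span[1] <= b for a, b in domains)
            assert is_constrained(span, ann) is brute


class TestSubsampleDomains:
    def _pool(self, n):
        out = {}
        for i in range(n):
            out[f"p{i}"] = IntervalAnnotation(
                f"p{i}", "SCOP", "DOMAIN", ((10 * i + 1, 10 * i + 5),)
            )
        return out

    def test_half_keeps_exact_count(self):
        kept = subsample_domains(self._pool(10), 0.5, seed=0)
        assert sum(len(a.intervals) for a in kept.values()) == 5

    def test_fraction_one_is_identity(self):
        pool = self._pool(7)
        kept = subsample_domains(pool, 1.0, seed=0)
        assert {p: a.intervals for p, a in kept.items()} == {
            p: a.intervals for p, a in pool.items()
        }

    def test_deterministic_under_seed(self):
        pool = self._pool(12)
        a = subsample_domains(pool, 0.5, seed=42)
        b = subsample_domains(pool, 0.5, seed=42)
        assert {p: x.intervals for p, x in a.items()} == {
            p: x.intervals for p, x in b.items()
        }

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            subsample_domains(self._pool(3), 0.0)


def test_depletion_signal_declines_across_length_bins():
    """On default synthetic genomes both the observed constrained fraction
    and the observed/expected ratio decline with exon length bin (nine bins,
    negative correlation, p < 0.001); bin fractions are averaged over three
    replicate genomes to damp sampling noise in the sparse long bins."""
    import math

    from exarch.constrained import constrained_fractions_by_bin
    from exarch.simulate import (
        GeneratorConfig,
        domain_annotations,
        internal_exon_records,
        sample_genome,
    )
    from exarch.stats import correlation_t_test

    obs_reps, ratio_reps = [], []
    for seed in (0, 1, 2):
        archs = sample_genome(GeneratorConfig(n_genes=2000), seed)
        bins = constrained_fractions_by_bin(
            internal_exon_records(archs), domain_annotations(archs)
        )
        obs_reps.append([b.observed_fraction for b in bins])
        ratio_reps.append([b.ratio for b in bins])
    obs = np.mean(obs_reps, axis=0)
    ratio = np.nanmean(ratio_reps, axis=0)
    c_obs = correlation_t_test(range(9), obs)
    finite = np.isfinite(ratio)
    c_ratio = correlation_t_test(np.arange(9)[finite], ratio[finite])
    assert c_obs.r < 0 and c_obs.p < 0.001
    assert c_ratio.r < 0 and c_ratio.p < 0.001
    # the longest bins are essentially devoid of constrained exons
    assert obs[-1] <= 0.01
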