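import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from msld_sampen import (
    ClassSpec,
    MatchCounts,
    SampEnParams,
    count_template_matches,
    count_template_matches_bruteforce,
    gen_signal,
    sample_entropy,
    sample_entropy_bruteforce,
    undefined_ceiling,
)


class TestMatchCounting:
    def test_constant_series_all_pairs_match(self):
        c = count_template_matches(np.ones(10), m=2, tol=0.1)
        assert c.n_templates == 8
        assert c.b_pairs == c.a_pairs == 28  # C(8, 2)

    def test_strict_ramp_with_substep_tolerance_has_no_matches(self):
        c = count_template_matches(np.arange(1.0, 11.0), m=2, tol=0.5)
        assert (c.b_pairs, c.a_pairs) == (0, 0)

    def test_frozen_sine_fixture(self):
        # counts computed once with the exhaustive triple-loop oracle
        x = np.sin(np.arange(1, 31, dtype=float))
        expected = MatchCounts(b_pairs=16, a_pairs=12, n_templates=28)
        assert count_template_matches(x, m=2, tol=0.2) == expected
        assert count_template_matches_bruteforce(x, m=2, tol=0.2) == expected

    def test_counts_monotone_in_tolerance(self, rng):
        x = rng.standard_normal(120)
        tols = np.linspace(0.05, 2.0, 12)
        counts = [count_template_matches(x, 2, t) for t in tols]
        b = [c.b_pairs for c in counts]
        a = [c.a_pairs for c in counts]
        assert b == sorted(b)
        assert a == sorted(a)
        assert all(c.a_pairs <= c.b_pairs for c in counts)

    @pytest.mark.parametrize("bad_tol", [0.0, -1.0])
    def test_nonpositive_tolerance_rejected(self, bad_tol):
        with pytest.raises(ValueError):
            count_template_matches(np.arange(10.0), 2, bad_tol)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            count_template_matches(np.arange(3.0), 2, 0.5)

    def test_bruteforce_refuses_long_series(self):
        with pytest.raises(ValueError, match="brute-force"):
            count_template_matches_bruteforce(np.zeros(2001), 2, 0.5)


class TestSampleEntropy:
    def test_constant_series_is_perfectly_regular(self):
        assert sample_entropy(np.full(50, 3.7)) == 0.0
        assert sample_entropy_bruteforce(np.full(50, 3.7)) == 0.0

    def test_no_matches_returns_undefined_marker(self):
        params = SampEnParams(m=2, r=0.5, tolerance_mode="absolute")
        assert sample_entropy(np.arange(1.0, 11.0), params) is None

    def test_frozen_noise_value_matches_oracle(self):
        sig = gen_signal(
            ClassSpec("w", "white_noise", {"noise_sd": 1.0}), n_samples=200, seed=42
        )
        params = SampEnParams(m=2, r=0.25)
        expected = 1.9052832955250423  # frozen brute-force value
        assert sample_entropy(sig.samples, params) == pytest.approx(
            expected, abs=1e-12
        )
        assert sample_entropy_bruteforce(sig.samples, params) == pytest.approx(
            expected, abs=1e-12
        )

    def test_optimized_path_equals_bruteforce(self, rng):
        for _ in range(50):
            n = int(rng.integers(30, 150))
            x = rng.standard_normal(n)
            params = SampEnParams(
                m=int(rng.integers(1, 4)), r=float(rng.uniform(0.1, 0.5))
            )
            fast = sample_entropy(x, params)
            slow = sample_entropy_bruteforce(x, params)
            if slow is None:
                assert fast is None
            else:
                assert fast == pytest.approx(slow, abs=1e-12)

    def test_nonnegative_whenever_defined(self, rng):
        for _ in range(30):
            v = sample_entropy(rng.standard_normal(100))
            if v is not None:
                assert v >= 0

    def test_amplitude_invariance_in_relative_mode(self, rng):
        x = rng.standard_normal(200)
        base = sample_entropy(x)
        for _ in range(5):
            c = float(rng.uniform(0.01, 100))
            b = float(rng.normal(scale=50))
            assert sample_entropy(c * x + b) == base

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SampEnParams(m=0)
        with pytest.raises(ValueError):
            SampEnParams(r=0)
        with pytest.raises(ValueError):
            SampEnParams(tolerance_mode="nope")


def test_undefined_ceiling_is_max_finite_estimate():
    # one matching pair at both lengths gives -ln(1/#pairs)
    n, m = 100, 2
    assert undefined_ceiling(n, m) == pytest.approx(math.log(98 * 97 / 2))
    with pytest.raises(ValueError):
        undefined_ceiling(3, 2)


def test_complexity_ordering_noise_ar_sine():
    """White noise is the most irregular, a strongly autocorrelated AR(1)
    intermediate, and a nearly pure sinusoid the most regular; each gap is
    significant across seeded replicates."""
    params = SampEnParams(m=2, r=0.25)
    white, ar, sine = [], [], []
    n = 4096
    fs = 173.61
    t = np.arange(n) / fs
    for seed in range(20):
        rng = np.random.default_rng(seed)
        white.append(sample_entropy(rng.standard_normal(n), params))
        e = rng.standard_normal(n + 200)
        x = np.empty(n + 200)
        x[0] = e[0]
        for i in range(1, n + 200):
            x[i] = 0.95 * x[i - 1] + e[i]
        ar.append(sample_entropy(x[200:], params))
        sine.append(
            sample_entropy(np.sin(2 * np.pi * 5 * t) + 0.01 * rng.standard_normal(n), params)
        )
    assert np.mean(white) > np.mean(ar) > np.mean(sine)
    assert mannwhitneyu(white, ar, alternative="greater").pvalue < 0.01
    assert mannwhitneyu(ar, sine, alternative="greater").pvalue < 0.01
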