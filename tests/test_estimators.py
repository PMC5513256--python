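"""The eight nonparametric richness estimators against hand-computed values."""

import numpy as np
import pytest

from richsplit import (
    ABUNDANCE_ESTIMATORS,
    INCIDENCE_ESTIMATORS,
    AbundanceSample,
    IncidenceSet,
    ace,
    chao1_bc,
    chao2_bc,
    ice,
    jackknife_abundance,
    jackknife_incidence,
)

SAMPLE = AbundanceSample({"a": 1, "b": 1, "c": 1, "d": 2, "e": 2, "f": 5})


def random_sample(rng, max_species=40, max_count=30):
    s = rng.integers(2, max_species)
    return AbundanceSample(
        {f"sp{i}": int(c) for i, c in enumerate(rng.integers(1, max_count, size=s))}
    )


def random_incidence(rng, m=2, max_species=40):
    s = rng.integers(1, max_species)
    return IncidenceSet(
        m, {f"sp{i}": int(q) for i, q in enumerate(rng.integers(1, m + 1, size=s))}
    )


class TestChao1:
    def test_hand_evaluated(self):
        # s=6, n=12, f1=3, f2=2: 6 + (11/12) * 6 / 6
        assert chao1_bc(SAMPLE).estimate == pytest.approx(6 + 11.0 / 12.0)

    def test_no_singletons_no_correction(self):
        s = AbundanceSample({"a": 2, "b": 3, "c": 2})
        assert chao1_bc(s).estimate == 3.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            chao1_bc(AbundanceSample({}))

    def test_continuity_in_abundant_count(self):
        # adding an individual of an abundant species moves the estimate O(1/n)
        base = chao1_bc(SAMPLE).estimate
        bumped = chao1_bc(AbundanceSample({**dict(SAMPLE.counts), "f": 6})).estimate
        assert abs(bumped - base) < 1.0 / SAMPLE.n


class TestChao2:
    def test_hand_evaluated(self):
        inc = IncidenceSet(2, {"a": 1, "b": 1, "c": 2, "d": 2, "e": 2})
        # 5 + (1/2) * 2*1 / (2*4)
        assert chao2_bc(inc).estimate == pytest.approx(5.125)

    def test_no_uniques_no_correction(self):
        inc = IncidenceSet(3, {"a": 2, "b": 3, "c": 2})
        assert chao2_bc(inc).estimate == 3.0

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError):
            IncidenceSet(1, {"a": 1})


class TestJackknife:
    def test_abundance_hand_values(self):
        assert jackknife_abundance(SAMPLE, 1).estimate == pytest.approx(6 + 3 * 11 / 12)
        assert jackknife_abundance(SAMPLE, 2).estimate == pytest.approx(
            6 + 3 * 21 / 12 - 2 * 100 / 132
        )

    def test_incidence_hand_value(self):
        inc = IncidenceSet(2, dict(zip("abcdefgh", [1, 1, 1, 1, 2, 2, 2, 2])))
        assert jackknife_incidence(inc, 1).estimate == pytest.approx(10.0)

    def test_orders_coincide_at_two_subsamples(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            inc = random_incidence(rng, m=2)
            assert jackknife_incidence(inc, 1).estimate == pytest.approx(
                jackknife_incidence(inc, 2).estimate, abs=1e-12
            )

    def test_no_rares_no_correction(self):
        s = AbundanceSample({"a": 3, "b": 4})
        assert jackknife_abundance(s, 1).estimate == 2.0
        assert jackknife_abundance(s, 2).estimate == 2.0

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            jackknife_abundance(SAMPLE, 3)


class TestACE:
    def test_hand_evaluated(self):
        s = AbundanceSample({"a": 1, "b": 1, "c": 2, "d": 3, "e": 15})
        # S_abund=1, S_rare=4, N_rare=7, C=5/7, gamma2=max(5.6*8/42-1, 0)
        gamma2 = 5.6 * 8 / 42 - 1
        expected = 1 + 5.6 + 2.8 * gamma2
        assert ace(s).estimate == pytest.approx(expected, rel=1e-12)

    def test_all_abundant(self):
        s = AbundanceSample({"a": 20, "b": 30})
        assert ace(s).estimate == 2.0

    def test_gamma_zero_branch(self):
        # {2,2,2}: f1=0, C=1, gamma2 clamps to 0 -> S_abund + S_rare/C
        s = AbundanceSample({"a": 2, "b": 2, "c": 2})
        assert ace(s).estimate == 3.0

    def test_all_singletons_falls_back_to_chao1(self):
        s = AbundanceSample({"a": 1, "b": 1, "c": 1})
        with pytest.warns(RuntimeWarning, match="falling back"):
            res = ace(s)
        assert res.fallback
        assert res.estimate == pytest.approx(chao1_bc(s).estimate)


class TestICE:
    def test_no_uniques_gives_s_obs(self):
        inc = IncidenceSet(2, {"a": 2, "b": 2, "c": 2})
        assert ice(inc).estimate == 3.0

    def test_hand_evaluated_m2(self):
        # s=6, q1=2, q2=4: N_inf=10, C=0.8, gamma2=max(7.5*2*8/100-1,0)=0.2
        inc = IncidenceSet(2, {"a": 1, "b": 1, "c": 2, "d": 2, "e": 2, "f": 2})
        assert ice(inc).estimate == pytest.approx(6 / 0.8 + (2 / 0.8) * 0.2)

    def test_zero_coverage_falls_back_to_chao2(self):
        inc = IncidenceSet(2, {"a": 1, "b": 1})
        with pytest.warns(RuntimeWarning, match="falling back"):
            res = ice(inc)
        assert res.fallback
        assert res.estimate == pytest.approx(chao2_bc(inc).estimate)


class TestBounds:
    def test_all_estimators_at_least_s_obs_abundance(self):
        rng = np.random.default_rng(42)
        import warnings

        for _ in range(1000):
            s = random_sample(rng)
            for name, fn in ABUNDANCE_ESTIMATORS.items():
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    assert fn(s).estimate >= s.s_obs - 1e-9, name

    def test_all_estimators_at_least_s_obs_incidence(self):
        rng = np.random.default_rng(43)
        import warnings

        for _ in range(1000):
            inc = random_incidence(rng, m=int(rng.integers(2, 5)))
            for name, fn in INCIDENCE_ESTIMATORS.items():
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    assert fn(inc).estimate >= inc.s_obs - 1e-9, name


class TestOracleEquivalence:
    """Agreement with scikit-bio's independent implementations."""

    def test_chao1_matches_skbio(self):
        pytest.importorskip("skbio")
        from skbio.diversity.alpha import chao1 as skbio_chao1

        rng = np.random.default_rng(7)
        for _ in range(100):
            s = random_sample(rng)
            counts = s.count_vector()
            # scikit-bio's bias-corrected form omits the (n-1)/n factor
            ours_plain = chao1_bc(s, small_sample_correction=False).estimate
            theirs = float(skbio_chao1(counts, bias_corrected=True))
            assert ours_plain == pytest.approx(theirs, abs=1e-9)
            # and the default form applies exactly that factor to the correction
            ours = chao1_bc(s).estimate
            n = s.n
            expected = s.s_obs + (n - 1) / n * (theirs - s.s_obs)
            assert ours == pytest.approx(expected, abs=1e-9)

    def test_ace_matches_skbio(self):
        pytest.importorskip("skbio")
        from skbio.diversity.alpha import ace as skbio_ace

        rng = np.random.default_rng(8)
        checked = 0
        while checked < 100:
            s = random_sample(rng)
            counts = s.count_vector()
            rare = counts[counts <= 10]
            if rare.size and (rare == 1).all():
                continue  # skbio raises on the undefined-coverage case
            assert ace(s).estimate == pytest.approx(
                float(skbio_ace(counts)), abs=1e-9
            )
            checked += 1


class TestCouponCollectorRegime:
    def test_complete_even_sample_recovers_s_exactly(self, rng):
        """cv -> 0 and n >> S ln S: no singletons or doubletons remain."""
        from richsplit import SADParams, catch_probabilities, draw_sample

        S = 12
        asm = catch_probabilities(SADParams.create("lognormal", S, 100.0, 1e-9))
        n = int(60 * S * np.log(S))  # far beyond coupon-collector threshold
        sample = draw_sample(asm, n, seed=99)
        assert sample.s_obs == S
        assert sample.f(1) == 0 and sample.f(2) == 0
        assert chao1_bc(sample).estimate == float(S)
        assert jackknife_abundance(sample, 1).estimate == float(S)
        assert jackknife_abundance(sample, 2).estimate == float(S)
        assert ace(sample).estimate == float(S)


class TestVectorisedKernels:
    """The sweep-engine array kernels agree with the scalar estimators."""

    def test_incidence_kernels_match_scalar_at_m2(self):
        from richsplit.estimators import _chao2_vec, _ice_m2_vec, _jk1_vec, _jk2_vec

        rng = np.random.default_rng(55)
        for _ in range(200):
            s = int(rng.integers(2, 40))
            q = rng.integers(1, 3, size=s)
            inc = IncidenceSet(2, {i: int(v) for i, v in enumerate(q)})
            q1, q2 = inc.q(1), inc.q(2)
            assert float(_chao2_vec(s, 2, q1, q2)) == pytest.approx(
                chao2_bc(inc).estimate, abs=1e-12
            )
            assert float(_jk1_vec(s, 2, q1)) == pytest.approx(
                jackknife_incidence(inc, 1).estimate, abs=1e-12
            )
            assert float(_jk2_vec(s, 2, q1, q2)) == pytest.approx(
                jackknife_incidence(inc, 2).estimate, abs=1e-12
            )
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore", RuntimeWarning)
                scalar = ice(inc).estimate
            est, bad = _ice_m2_vec(np.array([s]), np.array([q1]), np.array([q2]))
            assert float(est[0]) == pytest.approx(scalar, abs=1e-9)
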