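import numpy as np
import pytest

from svyboot import (
    HTTotal,
    MethodConfig,
    ReplicateSet,
    WeightedQuantile,
    bernoulli_probs,
    bootstrap_variance,
    draw_two_stage,
    export_replicate_weights,
    first_stage_design,
    generate_population,
    mirror_match_k1,
    preston_lambdas,
    run_method,
)

from conftest import make_srswor_sample

ALL_METHODS = ["rao_wu", "mirror_match", "bwo_sitter", "bernoulli", "preston", "rwy", "chauvet"]


def _cfg(method, **kw):
    kw.setdefault("B", 200)
    if method == "chauvet":
        kw.setdefault("A_ppb", 4)
        kw.setdefault("B_ppb", 50)
    if method in ("mirror_match",):
        kw.setdefault("n_prime", 1)
        kw.setdefault("m_prime", 1)
    return MethodConfig(method=method, **kw)


class TestVarianceOfReplicates:
    def test_basic(self):
        assert bootstrap_variance(np.array([1.0, 2.0, 3.0])) == pytest.approx(1.0)
        assert bootstrap_variance(np.full(10, 7.0)) == 0.0
        perm = bootstrap_variance(np.array([3.0, 1.0, 2.0]))
        assert perm == pytest.approx(1.0)

    def test_too_few_replicates(self):
        with pytest.raises(ValueError):
            bootstrap_variance(np.array([1.0]))

    def test_grouped_mean_of_within_group_variances(self):
        reps = ReplicateSet(
            np.array([1.0, 3.0, 10.0, 10.0]),
            "chauvet",
            groups=np.array([0, 0, 1, 1]),
        )
        assert bootstrap_variance(reps) == pytest.approx((2.0 + 0.0) / 2)


@pytest.mark.parametrize("method", ALL_METHODS)
class TestCommonProperties:
    def test_constant_y_gives_zero_variance(self, method, constant_sample):
        reps = run_method(constant_sample, HTTotal(), _cfg(method, seed=1))
        assert bootstrap_variance(reps) == pytest.approx(0.0, abs=1e-16)

    def test_reproducible_given_seed(self, method, tiny_sample):
        r1 = run_method(tiny_sample, HTTotal(), _cfg(method, seed=5))
        r2 = run_method(tiny_sample, HTTotal(), _cfg(method, seed=5))
        assert np.array_equal(r1.estimates, r2.estimates)

    def test_replicate_count(self, method, tiny_sample):
        reps = run_method(tiny_sample, HTTotal(), _cfg(method, seed=2))
        expected = 200 if method != "chauvet" else 4 * 50
        assert reps.B == expected


class TestRaoWu:
    def test_requires_srswor_and_warns_on_nonsmooth(self, tiny_sample):
        with pytest.warns(UserWarning, match="non-smooth"):
            run_method(tiny_sample, WeightedQuantile(0.5), _cfg("rao_wu", seed=1))

    def test_rect_and_ragged_paths_share_distribution(self):
        # unequal m_i forces the generic path; equal m_i takes the fast one
        s_ragged = make_srswor_sample(
            N=8, M=[6, 6, 4], m=[3, 2, 2], y=[[1.0, 2.0, 4.0], [2.0, 7.0], [0.0, 5.0]]
        )
        reps = run_method(s_ragged, HTTotal(), _cfg("rao_wu", B=40_000, seed=3))
        from svyboot import var_srswor_textbook

        assert bootstrap_variance(reps) == pytest.approx(
            var_srswor_textbook(s_ragged).value, rel=0.05
        )

    def test_small_sampling_fractions_track_wr_variance(self):
        """With f1 -> 0 the rescaling reduces to the with-replacement form."""
        rng = np.random.default_rng(9)
        pop = generate_population(2000, 30.0, 0.2, seed=71)
        first = first_stage_design("srswor", pop, 50)
        s = draw_two_stage(pop, first, 3, rng)
        from svyboot import var_with_replacement

        reps = run_method(s, HTTotal(), _cfg("rao_wu", B=30_000, seed=4))
        assert bootstrap_variance(reps) == pytest.approx(
            var_with_replacement(s).value, rel=0.10
        )


class TestMirrorMatch:
    def test_k1_formula(self):
        # n=40, f1=0.2, n'=8: k1 = 40*0.8/(8*0.8) = 5 exactly
        assert mirror_match_k1(40, 0.2, 8) == pytest.approx(5.0)

    def test_invalid_n_prime(self, tiny_sample):
        with pytest.raises(ValueError):
            run_method(tiny_sample, HTTotal(), _cfg("mirror_match", n_prime=2, seed=1))

    def test_randomized_k_has_exact_expectation(self):
        from svyboot.bootstrap import _rand_round

        rng = np.random.default_rng(0)
        draws = [_rand_round(2.3, rng) for _ in range(20_000)]
        assert np.mean(draws) == pytest.approx(2.3, abs=0.01)
        assert set(draws) == {2, 3}


class TestBernoulli:
    def test_probabilities_valid_on_study_grid(self):
        for N, n in ((200, 10), (200, 40)):
            s = make_srswor_sample(
                N=N, M=[50] * n, m=[5] * n, y=[np.arange(5.0)] * n,
                pi1=[n / N] * n, p1=[1 / N] * n,
            )
            p1, p2 = bernoulli_probs(s)
            assert 0.0 <= p1 <= 1.0
            assert np.all((p2 >= 0) & (p2 <= 1))

    def test_needs_two_per_stage(self):
        s = make_srswor_sample(N=6, M=[4, 4], m=[1, 1], y=[[1.0], [2.0]])
        with pytest.raises(ValueError):
            run_method(s, HTTotal(), _cfg("bernoulli", seed=1))


class TestPreston:
    def test_lambda1_value(self):
        lam1, _ = preston_lambdas(10, 0.05, 5, [4], [0.5], [2])
        assert lam1 == pytest.approx(np.sqrt(5 * 0.95 / 5), abs=1e-9)

    def test_weights_nonnegative_and_mean_reverts_to_design(self, sample3):
        reps = run_method(sample3, HTTotal(), _cfg("preston", B=20_000, seed=6))
        W = reps.replicate_weights
        assert np.all(W >= 0)
        _, w = sample3.flat()
        assert np.allclose(W.mean(axis=0), w, rtol=0.03)

    def test_invalid_n_prime(self, sample3):
        with pytest.raises(ValueError):
            run_method(sample3, HTTotal(), _cfg("preston", n_prime=3, seed=1))

    def test_export_replicate_weights(self, sample3, tmp_path):
        import pandas as pd

        reps = run_method(sample3, HTTotal(), _cfg("preston", B=10, seed=7))
        path = tmp_path / "weights.tsv"
        export_replicate_weights(sample3, reps, path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns[:2]) == ["elem_key", "w"]
        assert df.shape == (6, 2 + 10)


class TestRwy:
    def test_scale_factor_at_default_n_prime(self, sample3):
        """n' = n-1 makes the rescaling factor sqrt(n'/(n-1)) = 1."""
        reps = run_method(sample3, HTTotal(), _cfg("rwy", B=50, seed=8))
        W = reps.replicate_weights
        n = sample3.n
        _, w = sample3.flat()
        ratio = W / w[None, :]
        # every factor is 1 + (n n_i*/n' - 1) with n_i* a multiplicity
        np_prime = n - 1
        implied = (ratio - 1.0) * np_prime / n + np_prime / n
        counts = np.rint(implied[:, ::2])  # one element per psu suffices
        assert np.all(counts >= 0)
        assert np.allclose(counts.sum(axis=1), np_prime)

    def test_weights_nonnegative(self, sample3):
        reps = run_method(sample3, HTTotal(), _cfg("rwy", B=5000, seed=9))
        assert np.all(reps.replicate_weights >= 0)

    def test_n_prime_too_large_rejected(self, sample3):
        with pytest.raises(ValueError):
            run_method(sample3, HTTotal(), _cfg("rwy", n_prime=3, seed=1))

    def test_works_under_ipps(self):
        pop = generate_population(60, 20.0, 0.1, seed=20)
        first = first_stage_design("ipps", pop, 8)
        s = draw_two_stage(pop, first, 4, np.random.default_rng(0))
        reps = run_method(s, HTTotal(), _cfg("rwy", seed=10))
        assert bootstrap_variance(reps) > 0


class TestChauvet:
    def test_full_census_gives_zero(self):
        s = make_srswor_sample(
            N=2, M=[3, 3], m=[3, 3], y=[[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
            pi1=[1.0, 1.0], p1=[0.5, 0.5],
        )
        reps = run_method(s, HTTotal(), _cfg("chauvet", seed=11))
        assert bootstrap_variance(reps) == pytest.approx(0.0, abs=1e-18)

    def test_psu_census_keeps_only_second_stage_noise(self):
        s = make_srswor_sample(
            N=2, M=[4, 4], m=[2, 2], y=[[1.0, 5.0], [2.0, 6.0]],
            pi1=[1.0, 1.0], p1=[0.5, 0.5],
        )
        reps = run_method(s, HTTotal(), _cfg("chauvet", A_ppb=2, B_ppb=4000, seed=12))
        v = bootstrap_variance(reps)
        # pure second-stage SRSWOR variance on the duplicated psus
        assert v > 0
        expected = sum(
            16 * (1 - 0.5) * np.var(np.tile(yi, 2), ddof=1) / 2 for yi in s.y
        )
        assert v == pytest.approx(expected, rel=0.10)

    def test_invalid_loop_counts(self, tiny_sample):
        with pytest.raises(ValueError):
            run_method(tiny_sample, HTTotal(), MethodConfig(method="chauvet", A_ppb=0))

    def test_outer_averaging_structure(self, tiny_sample):
        reps = run_method(tiny_sample, HTTotal(), _cfg("chauvet", A_ppb=3, B_ppb=10, seed=13))
        assert reps.groups is not None
        assert np.array_equal(np.unique(reps.groups), [0, 1, 2])
        per_group = [
            np.var(reps.estimates[reps.groups == g], ddof=1) for g in range(3)
        ]
        assert bootstrap_variance(reps) == pytest.approx(np.mean(per_group))


def test_unknown_method_rejected(tiny_sample):
    with pytest.raises(ValueError):
        run_method(tiny_sample, HTTotal(), MethodConfig(method="nope"))


def test_export_without_weights_rejected(tiny_sample, tmp_path):
    reps = run_method(tiny_sample, HTTotal(), _cfg("rao_wu", seed=1))
    with pytest.raises(ValueError):
        export_replicate_weights(tiny_sample, reps, tmp_path / "w.tsv")
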