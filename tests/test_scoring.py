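import numpy as np
import pytest

from conftest import make_screen_matrix
from esgamap import scoring
from esgamap.scoring import (attach_pvalues, compute_escores,
                             estimate_single_fitness, modal_sd, pair_table)


def multiplicative_screen(wi, wj, rng=None, noise_sd=0.0):
    w = np.outer(wi, wj)
    if rng is not None and noise_sd > 0:
        w = w * rng.lognormal(0, noise_sd, w.shape)
    return make_screen_matrix(w)


class TestEstimateSingleFitness:
    def test_exact_inversion_of_noiseless_product(self):
        rng = np.random.default_rng(0)
        wi = rng.uniform(0.4, 1.1, 30)
        wj = rng.uniform(0.4, 1.1, 40)
        fit = estimate_single_fitness(multiplicative_screen(wi, wj))
        ra = fit.array_w.to_numpy() / wj
        rq = fit.query_w.to_numpy() / wi
        assert np.ptp(ra) / np.median(ra) < 1e-9
        assert np.ptp(rq) / np.median(rq) < 1e-9
        # products are scale-free
        assert np.allclose(np.outer(fit.query_w, fit.array_w), np.outer(wi, wj))

    def test_median_beats_mean_under_planted_interactions(self):
        rng = np.random.default_rng(1)
        wi = rng.uniform(0.5, 1.1, 40)
        wj = rng.uniform(0.5, 1.1, 60)
        w = np.outer(wi, wj)
        planted = rng.random(w.shape) < 0.05
        w = w * np.where(planted, 1.5, 1.0)  # |delta| = 0.5
        screen = make_screen_matrix(w)
        fit = estimate_single_fitness(screen)
        ra = fit.array_w.to_numpy() / wj
        med_err = np.max(np.abs(ra / np.median(ra) - 1))

        mean_wj = w.mean(axis=0)  # mean-based competitor
        rm = mean_wj / wj
        mean_err = np.max(np.abs(rm / np.median(rm) - 1))
        assert med_err < mean_err

    def test_dead_array_gene_excluded(self):
        rng = np.random.default_rng(2)
        wi = rng.uniform(0.5, 1.1, 30)
        wj = rng.uniform(0.5, 1.1, 30)
        w = np.outer(wi, wj)
        w[:, 3] = 1e-4  # dead in every screen
        fit = estimate_single_fitness(make_screen_matrix(w))
        assert np.isnan(fit.array_w.iloc[3])
        assert fit.excluded.get("a3") == "dead_array_gene"

    def test_too_few_observations_excluded(self):
        rng = np.random.default_rng(3)
        w = np.outer(rng.uniform(0.5, 1, 30), rng.uniform(0.5, 1, 30))
        w[:-2, 5] = np.nan
        fit = estimate_single_fitness(make_screen_matrix(w))
        assert np.isnan(fit.array_w.iloc[5])


class TestComputeEscores:
    def test_zero_on_exact_multiplicative_matrix(self):
        rng = np.random.default_rng(4)
        screen = multiplicative_screen(rng.uniform(0.5, 1, 25),
                                       rng.uniform(0.5, 1, 25))
        fit = estimate_single_fitness(screen)
        e = compute_escores(screen, fit, sigma0=0.05)
        assert np.nanmax(np.abs(e.e)) < 1e-9

    def test_linear_in_deviation(self):
        rng = np.random.default_rng(5)
        wi = rng.uniform(0.6, 1, 25)
        wj = rng.uniform(0.6, 1, 25)
        base = np.outer(wi, wj)
        d = 0.02
        for k, mult in ((1, d), (2, 2 * d)):
            w = base.copy()
            w[0, 1] = base[0, 1] + mult
            e = compute_escores(make_screen_matrix(w, sd=np.full(base.shape, 0.05)),
                                estimate_single_fitness(make_screen_matrix(base)),
                                sigma0=0.05)
            if k == 1:
                e1 = e.e[0, 1]
            else:
                assert e.e[0, 1] == pytest.approx(2 * e1, rel=1e-6)

    def test_lethal_pair_hand_value(self):
        """Wij=0 with Wi=Wj=0.9 and a 0.05 denominator gives E = -16.2."""
        wi = np.full(25, 0.9)
        wj = np.full(25, 0.9)
        w = np.outer(wi, wj)
        w[0, 1] = 0.0
        # huge replicate counts make the moderated SEM vanish, so the
        # denominator is exactly sigma0 * Wi * Wj = 0.05
        screen = make_screen_matrix(w, sd=np.zeros(w.shape),
                                    n_obs=np.full(w.shape, 10 ** 6))
        fit = estimate_single_fitness(screen)
        e = compute_escores(screen, fit, sigma0=0.05 / 0.81)
        assert e.e[0, 1] == pytest.approx(-16.2, rel=1e-3)

    def test_sign_matches_deviation_direction(self):
        rng = np.random.default_rng(6)
        base = np.outer(rng.uniform(0.6, 1, 20), rng.uniform(0.6, 1, 20))
        w = base.copy()
        w[2, 3] *= 1.4
        w[4, 5] *= 0.6
        e = compute_escores(make_screen_matrix(w),
                            estimate_single_fitness(make_screen_matrix(base)),
                            sigma0=0.05)
        assert e.e[2, 3] > 0 > e.e[4, 5]


class TestModalSD:
    def test_mode_of_peaked_sample(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate([rng.normal(0.1, 0.005, 2000),
                               rng.uniform(0.2, 1.0, 200)])
        assert modal_sd(vals) == pytest.approx(0.1, abs=0.02)

    def test_small_sample_falls_back_to_median(self):
        assert modal_sd(np.array([0.1, 0.2, 0.3])) == pytest.approx(0.2)


class TestPValues:
    def test_refuses_small_null(self, scored_rich):
        screen, fit, e = scored_rich
        with pytest.raises(ValueError):
            attach_pvalues(e, screen, fit, null_size=5)

    def test_zero_score_has_p_one(self, scored_rich):
        _, _, e = scored_rich
        assert e.empirical_p(np.array([0.0]))[0] == pytest.approx(1.0)

    def test_small_pool_rank_formula(self, scored_rich):
        _, _, e = scored_rich
        pool = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8,
                         0.9, 1.0, 1.1, 1.2])
        saved = e.null_abs
        e.null_abs = pool
        try:
            # |E| = 0.85 -> 4 of 12 null values at least as large
            assert e.empirical_p(np.array([0.85]))[0] == pytest.approx(5 / 13)
        finally:
            e.null_abs = saved

    def test_monotone_in_magnitude(self, scored_rich):
        _, _, e = scored_rich
        p2, p3 = e.empirical_p(np.array([2.0, 3.0]))
        assert p3 <= p2

    def test_null_values_are_finite_and_pooled(self, scored_rich):
        _, _, e = scored_rich
        assert e.null_abs is not None
        assert np.all(np.isfinite(e.null_abs))
        assert len(e.null_abs) > 10_000


class TestPairTable:
    def test_orientations_merged_by_inverse_variance(self):
        e = np.full((2, 2), np.nan)
        e[0, 1] = 2.0   # q0 x a1
        e[1, 0] = 4.0   # q1 x a0
        evar = np.full((2, 2), np.nan)
        evar[0, 1] = 0.1
        evar[1, 0] = 0.3
        mat = scoring.EScoreMatrix(queries=["g1", "g2"], arrays=["g1", "g2"],
                                   e=e, evar=evar, condition="rich", sigma0=0.1)
        pairs = pair_table(mat)
        assert len(pairs) == 1
        expected = (2.0 / 0.1 + 4.0 / 0.3) / (1 / 0.1 + 1 / 0.3)
        assert pairs["E"].iloc[0] == pytest.approx(expected)

    def test_sign_conflict_flagged(self):
        e = np.full((2, 2), np.nan)
        e[0, 1] = 3.0
        e[1, 0] = -3.0
        evar = np.full((2, 2), 0.2)
        mat = scoring.EScoreMatrix(queries=["g1", "g2"], arrays=["g1", "g2"],
                                   e=e, evar=evar, condition="rich", sigma0=0.1)
        assert pair_table(mat)["sign_conflict"].iloc[0]


class TestStatisticalProperties:
    def test_planted_sign_recovered(self, small_truth, scored_rich):
        """Aggravating pairs score negative and alleviating positive."""
        _, _, e = scored_rich
        pairs = pair_table(e)
        lookup = {(a, b): v for a, b, v in zip(pairs["gene_a"], pairs["gene_b"],
                                               pairs["E"])}
        good = total = 0
        for pair, eff in small_truth.interactions.items():
            target = eff.get("rich")
            if target is None or abs(target) < 2 or pair not in lookup:
                continue
            total += 1
            good += np.sign(lookup[pair]) == np.sign(target)
        assert total > 20
        assert good / total >= 0.95

    def test_replicate_reproducibility_above_0p8(self, small_screens):
        """With 10% multiplicative noise the generator+normalization regime
        reproduces the high between-replicate agreement of real screens."""
        from esgamap import plates
        norm, _ = plates.normalize_screens(small_screens["rich"])
        _, report = plates.qc_filter(norm)
        assert report["r"].median() > 0.8
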