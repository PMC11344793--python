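"""Null-model fit, fixed-margin sampling, Poisson-binomial tails, scores and
their cosmopolitanism-binned calibration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assemblnet import null_model, synthetic
from assemblnet.errors import InvariantError
from assemblnet.io_model import OccurrenceTable
from assemblnet.null_model import (
    NullEnsemble,
    aggregation_score,
    calibrate_scores,
    cooccurrence_tail,
    fit_null_probabilities,
    pair_survival_batch,
    pair_zscore,
    sample_null_matrices,
)


def table_from(X):
    X = np.asarray(X)
    return OccurrenceTable(
        [f"g{i}" for i in range(X.shape[0])], [f"s{a}" for a in range(X.shape[1])], X
    )


class TestMarginFit:
    def test_all_ones_is_saturated(self):
        pi = fit_null_probabilities(table_from(np.ones((4, 5))))
        assert np.allclose(pi.pi, 1.0)

    def test_zero_margin_rows_and_columns(self):
        X = np.zeros((3, 4), dtype=int)
        X[0, :3] = 1
        X[1, 0] = 1
        pi = fit_null_probabilities(table_from(X))
        assert np.allclose(pi.pi[2], 0.0)  # genus never observed
        assert np.allclose(pi.pi[:, 3], 0.0)  # empty sample

    def test_random_table_margins_match(self):
        rng = np.random.default_rng(0)
        X = (rng.random((30, 40)) < 0.3).astype(int)
        X[X.sum(axis=1) == 0, 0] = 1
        table = table_from(X)
        pi = fit_null_probabilities(table)
        r = X.sum(axis=1)
        c = X.sum(axis=0)
        ok_r = r > 0
        ok_c = c > 0
        assert np.all(
            np.abs(pi.pi.sum(axis=1)[ok_r] - r[ok_r]) / r[ok_r] < 1e-4
        )
        assert np.all(
            np.abs(pi.pi.sum(axis=0)[ok_c] - c[ok_c]) / c[ok_c] < 1e-4
        )


class TestFixedMarginSampling:
    def test_empty_ensemble(self):
        t = table_from(np.eye(3, dtype=int))
        assert len(sample_null_matrices(t, n=0, seed=0)) == 0

    def test_margins_preserved_exactly(self):
        rng = np.random.default_rng(1)
        X = (rng.random((15, 25)) < 0.25).astype(int)
        t = table_from(X)
        ens = sample_null_matrices(t, n=30, seed=2)
        for m in ens.matrices:
            assert (m.sum(axis=1) == X.sum(axis=1)).all()
            assert (m.sum(axis=0) == X.sum(axis=0)).all()

    def test_two_by_two_chain_mixes(self):
        # [[1,0],[0,1]] has exactly two margin-preserving states
        t = table_from(np.eye(2, dtype=int))
        ens = sample_null_matrices(t, n=2000, seed=3)
        frac_diag = np.mean([m[0, 0] == 1 for m in ens.matrices])
        assert abs(frac_diag - 0.5) < 0.05


def enumeration_tail(probs, n_obs):
    """Exhaustive-outcome oracle for the Poisson-binomial upper tail."""
    probs = list(probs)
    total = 0.0
    for outcome in itertools.product((0, 1), repeat=len(probs)):
        if sum(outcome) >= n_obs:
            w = 1.0
            for o, p in zip(outcome, probs):
                w *= p if o else 1 - p
            total += w
    return total


class TestCooccurrenceTail:
    def test_whole_support(self):
        assert cooccurrence_tail([0.3, 0.7], 0) == 1.0

    def test_impossible_event(self):
        assert cooccurrence_tail([0.0, 0.0], 1) == 0.0

    def test_half_half(self):
        assert cooccurrence_tail([0.5, 0.5], 1) == pytest.approx(0.75, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 9))
        p = rng.random(n)
        for n_obs in range(n + 1):
            assert cooccurrence_tail(p, n_obs) == pytest.approx(
                enumeration_tail(p, n_obs), abs=1e-12
            )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_n_obs(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(1, 12)))
        tails = [cooccurrence_tail(p, k) for k in range(len(p) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))

    def test_invalid_probability_rejected(self):
        with pytest.raises(InvariantError):
            cooccurrence_tail([1.2], 0)


class TestAggregationScore:
    def test_log_identities(self):
        # tail 1 -> score 0 ; tail e^-1 -> score 1
        assert -np.log(1.0) == 0.0
        p = [0.5, 0.5]
        assert -np.log(cooccurrence_tail(p, 1)) == pytest.approx(
            -np.log(0.75), abs=1e-12
        )

    def test_score_from_table(self):
        X = np.array([[1, 0], [1, 0]])
        t = table_from(X)
        pi = null_model.ProbabilityMatrix(
            t.genus_ids, t.sample_ids, np.full((2, 2), 0.5)
        )
        # pair probs (0.25, 0.25), N=1 -> tail = 1 - 0.75^2
        expected = -np.log(1 - 0.75**2)
        assert aggregation_score(t, pi, 0, 1) == pytest.approx(expected, abs=1e-12)

    def test_nonnegative_and_monotone_in_count(self):
        rng = np.random.default_rng(7)
        p = rng.random(20) * 0.5
        tails = [max(cooccurrence_tail(p, k), 1e-300) for k in range(21)]
        scores = [-np.log(x) for x in tails]
        assert min(scores) >= 0
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_batch_survival_matches_scalar(self):
        rng = np.random.default_rng(8)
        P_u = rng.random((6, 9))
        P_v = rng.random((6, 9))
        sf = pair_survival_batch(P_u, P_v)
        for k in range(6):
            for n_obs in range(10):
                assert sf[k, n_obs] == pytest.approx(
                    cooccurrence_tail(P_u[k] * P_v[k], n_obs), abs=1e-12
                )


@pytest.fixture(scope="module")
def calibrated():
    table, ann = synthetic.generate_null_occurrences(40, 120, seed=5)
    pi = null_model.fit_environment_probabilities(table, ann)
    ens = sample_null_matrices(table, n=60, seed=6)
    cal = calibrate_scores(table, pi, ens, target_fpr=1e-3)
    return table, pi, ens, cal


class TestCalibration:
    def test_zscore_standardization(self, calibrated):
        table, pi, ens, cal = calibrated
        iu, ju = np.triu_indices(table.X.shape[0], k=1)
        sf = pair_survival_batch(pi.pi[iu], pi.pi[ju])
        mats = ens.matrices.astype(float)
        counts = np.einsum("kim,kjm->kij", mats, mats)[:, iu, ju].T.astype(int)
        S = null_model.scores_from_survival(sf, counts)
        n = table.X.sum(axis=1).astype(float)
        z = cal.zscore(S, n[iu][:, None], n[ju][:, None])
        assert abs(z.mean()) < 0.05  # standardized against itself
        frac = (z > cal.z_cutoff).mean()
        assert frac <= 1e-3

    def test_mean_plus_two_sd_gives_z_two(self, calibrated):
        *_, cal = calibrated
        b = int(cal.bin_of(10, 10))
        score = cal.bin_mean[b] + 2 * cal.bin_sd[b]
        z, _ = pair_zscore(score, 10, 10, cal)
        assert z == pytest.approx(2.0)

    def test_target_fpr_one_gives_min_cutoff(self, calibrated):
        table, pi, ens, _ = calibrated
        cal = calibrate_scores(table, pi, ens, target_fpr=1.0)
        # every null z is then significant-eligible: cutoff is the minimum
        iu, ju = np.triu_indices(table.X.shape[0], k=1)
        sf = pair_survival_batch(pi.pi[iu], pi.pi[ju])
        mats = ens.matrices.astype(float)
        counts = np.einsum("kim,kjm->kij", mats, mats)[:, iu, ju].T.astype(int)
        S = null_model.scores_from_survival(sf, counts)
        n = table.X.sum(axis=1).astype(float)
        z = cal.zscore(S, n[iu][:, None], n[ju][:, None])
        assert cal.z_cutoff == pytest.approx(z.min())

    def test_degenerate_null_scores_raise(self):
        # one occupied column per genus: no pair can ever co-occur under the
        # preserved margins, so every null score is exactly zero in every bin
        table = table_from(np.eye(6, dtype=int))
        pi = fit_null_probabilities(table)
        ens = sample_null_matrices(table, n=10, seed=0)
        with pytest.raises(InvariantError, match="degenerate"):
            calibrate_scores(table, pi, ens)

    def test_round_trip_serialization(self, calibrated, tmp_path):
        *_, cal = calibrated
        cal.save(tmp_path / "cal.json")
        back = null_model.ScoreCalibration.load(tmp_path / "cal.json")
        assert back.z_cutoff == cal.z_cutoff
        assert np.allclose(back.bin_mean, cal.bin_mean)
        assert np.allclose(back.bin_edges, cal.bin_edges)
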