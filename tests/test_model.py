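"""Ridge ES model: featurization, fitting, diagnostics, screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panenrich.model import (
    EnrichmentScoreModel,
    EnrichmentScoreResults,
    ModelError,
    decile_diagnostic,
    featurize,
    percentile_ranks,
    screen,
)
from panenrich.simulate_cdrh3 import ALLOWED_RESIDUES


def random_seqs(rng, n, length):
    return ["".join(rng.choice(list(ALLOWED_RESIDUES), size=length)) for _ in range(n)]


class TestFeaturize:
    def test_one_active_feature_per_position(self):
        assert featurize("AAA") == [(0, "A"), (1, "A"), (2, "A")]

    def test_neighbouring_sequences_share_all_but_one_feature(self):
        shared = set(featurize("ARDYG")) & set(featurize("ARDYS"))
        assert len(shared) == 4

    def test_feature_space_bound(self):
        feats = {(p, r) for p in range(9) for r in ALLOWED_RESIDUES}
        assert len(feats) == 9 * 18 <= 162

    def test_length_mismatch_errors(self):
        with pytest.raises(ModelError):
            featurize("AAA", length=4)


def ridge_normal_equations(X, y, l2):
    """Centered normal-equations oracle (intercept unpenalized)."""
    xbar, ybar = X.mean(axis=0), y.mean()
    Xc, yc = X - xbar, y - ybar
    w = np.linalg.solve(Xc.T @ Xc + l2 * np.eye(X.shape[1]), Xc.T @ yc)
    return w, ybar - xbar @ w


class TestFit:
    def test_constant_target_gives_intercept_only(self, rng):
        seqs = random_seqs(rng, 100, 9)
        res = EnrichmentScoreModel.from_records(seqs, [2.5] * 100).fit(seed=0)
        assert res.intercept == pytest.approx(2.5, abs=1e-6)
        assert max(abs(w) for w in res.weights.values()) < 1e-6

    def test_matches_normal_equations_oracle(self, rng):
        seqs = random_seqs(rng, 150, 6)
        y = rng.normal(size=150)
        res = EnrichmentScoreModel.from_records(seqs, y).fit(l2=1e-3, seed=5)
        # rebuild the training design exactly as the split defines it
        order = np.random.default_rng(5).permutation(150)
        train = order[: int(round(0.7 * 150))]
        features = sorted(res.weights)
        X = np.zeros((len(train), len(features)))
        for i, t in enumerate(train):
            for f in featurize(seqs[t]):
                X[i, features.index(f)] = 1.0
        w, b = ridge_normal_equations(X, y[train], 1e-3)
        got = np.array([res.weights[f] for f in features])
        assert np.allclose(got, w, atol=1e-8)
        assert res.intercept == pytest.approx(b, abs=1e-8)

    def test_reproducible_under_seed(self, rng):
        seqs = random_seqs(rng, 200, 9)
        y = rng.normal(size=200)
        model = EnrichmentScoreModel.from_records(seqs, y)
        r1, r2 = model.fit(seed=11), model.fit(seed=11)
        assert r1.weights == r2.weights and r1.intercept == r2.intercept
        r3 = model.fit(seed=12)
        assert r3.weights != r1.weights

    def test_recovers_planted_linear_effects(self, rng):
        # ES constructed directly as a sum of positional effects + noise
        length, n = 9, 5000
        effects = {
            (p, r): rng.normal(0, 0.3) for p in range(length) for r in ALLOWED_RESIDUES
        }
        seqs = random_seqs(rng, n, length)
        y = np.array(
            [sum(effects[f] for f in featurize(s)) for s in seqs]
        ) + rng.normal(0, 0.1, size=n)
        res = EnrichmentScoreModel.from_records(seqs, y).fit(seed=3)
        assert res.heldout_spearman > 0.9
        planted = np.array([[effects[(p, r)] for r in ALLOWED_RESIDUES] for p in range(length)])
        recovered = np.zeros_like(planted)
        for (p, r), w in res.weights.items():
            recovered[p, ALLOWED_RESIDUES.index(r)] = w
        planted -= planted.mean(axis=1, keepdims=True)
        recovered -= recovered.mean(axis=1, keepdims=True)
        assert np.abs(recovered - planted).max() < 0.05

    def test_single_residue_position_dropped(self, rng):
        seqs = ["A" + s for s in random_seqs(rng, 80, 4)]
        y = rng.normal(size=80)
        res = EnrichmentScoreModel.from_records(seqs, y).fit(seed=0)
        assert all(pos != 0 for pos, _ in res.weights)

    def test_too_few_records_errors(self):
        with pytest.raises(ModelError):
            EnrichmentScoreModel.from_records(["AAA"] * 10, [0.0] * 10).fit()

    def test_mixed_lengths_error(self):
        with pytest.raises(ModelError):
            EnrichmentScoreModel.from_records(["AAA", "AAAA"], [0.0, 0.0])


class TestDecileDiagnostic:
    def test_perfect_model_gives_decile_midpoints(self, rng):
        actual = rng.normal(size=1000)
        out = decile_diagnostic(actual, actual)
        assert np.allclose(out["mean_pred_percentile"], np.arange(5, 100, 10))

    def test_random_predictions_center_on_fifty(self, rng):
        # Monte-Carlo permutation expectation: every decile mean ~ 50
        actual = rng.normal(size=2000)
        means = np.zeros(10)
        n_rep = 20
        for _ in range(n_rep):
            out = decile_diagnostic(actual, rng.permutation(actual))
            means += out["mean_pred_percentile"].to_numpy()
        means /= n_rep
        # SE of each decile mean is ~ 29/sqrt(200*20) ~ 0.46
        assert np.abs(means - 50).max() < 2.5

    def test_matches_rank_and_average_oracle(self, rng):
        actual = rng.normal(size=1000)
        predicted = actual + rng.normal(size=1000)
        out = decile_diagnostic(actual, predicted)
        order = np.argsort(actual, kind="stable")
        pct = percentile_ranks(predicted)
        for d, idx in enumerate(np.array_split(order, 10)):
            assert out["mean_pred_percentile"].iloc[d] == pytest.approx(pct[idx].mean())
            assert out["sd_pred_percentile"].iloc[d] == pytest.approx(pct[idx].std(ddof=1))

    def test_too_few_records_error(self):
        with pytest.raises(ModelError):
            decile_diagnostic(np.arange(5), np.arange(5))


class TestScreen:
    @staticmethod
    def _results(weights, intercept, length):
        return EnrichmentScoreResults(
            length=length, weights=weights, intercept=intercept,
            l2=1e-6, split_seed=0, train_fraction=0.7,
        )

    def test_keeps_strictly_positive_predictions(self):
        res = self._results({(0, "G"): 0.1, (0, "W"): -0.2, (0, "A"): 0.0}, 0.0, 3)
        kept, summary = screen(res, ["GYY", "WYY", "AYY"])
        assert kept == ["GYY"]  # 0.1 kept; -0.2 dropped; exactly 0 dropped
        assert summary["kept_fraction"].iloc[0] == pytest.approx(1 / 3)

    def test_missing_length_model_errors(self):
        res = self._results({(0, "G"): 0.1}, 0.0, 3)
        with pytest.raises(ModelError):
            screen(res, ["GYYA"])


class TestPersistence:
    def test_json_round_trip(self, rng):
        seqs = random_seqs(rng, 100, 9)
        y = rng.normal(size=100)
        res = EnrichmentScoreModel.from_records(seqs, y).fit(seed=4)
        back = EnrichmentScoreResults.from_json(res.to_json())
        assert back.weights == res.weights
        assert back.intercept == res.intercept
        assert back.length == res.length
        assert np.allclose(back.predict(seqs[:5]), res.predict(seqs[:5]))

    def test_summary_mentions_metrics(self, rng):
        seqs = random_seqs(rng, 100, 9)
        res = EnrichmentScoreModel.from_records(seqs, rng.normal(size=100)).fit(seed=4)
        text = res.summary()
        assert "Spearman" in text and "l2" in text
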