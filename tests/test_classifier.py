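"""Pair classifier and sigmoid probability calibration."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from spps.classifier import (
    PPIDataset,
    SVMParams,
    fit_platt,
    regularized_targets,
    sample_negative_pairs,
    sigmoid_probability,
    train_svm,
)
from spps.exceptions import (
    CalibrationError,
    FingerprintMismatchError,
    UnknownProteinError,
    ValidationError,
)
from spps.features import ResidueClassMap, pair_vector, triad_vector
from spps.protein_db import ProteinDatabase, ProteinRecord


def oracle_nll(A, B, f, t):
    """Independent negative log-likelihood of the calibration sigmoid,
    written directly from the definition P = 1/(1+exp(A f + B))."""
    p = np.clip(expit(-(A * np.asarray(f) + B)), 1e-15, 1 - 1e-15)
    t = np.asarray(t)
    return float(-np.sum(t * np.log(p) + (1 - t) * np.log(1 - p)))


def grid_search_oracle(f, labels):
    """Coarse (A, B) grid + simplex polish on the independent objective."""
    t = regularized_targets(labels)
    grid_A = np.linspace(-8.0, 2.0, 41)
    grid_B = np.linspace(-3.0, 3.0, 25)
    best = min(
        ((oracle_nll(A, B, f, t), A, B) for A in grid_A for B in grid_B),
        key=lambda x: x[0],
    )
    res = minimize(
        lambda ab: oracle_nll(ab[0], ab[1], f, t),
        x0=[best[1], best[2]],
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 3000},
    )
    return res.fun, res.x


def simulate(A, B, n, seed):
    rng = np.random.default_rng(seed)
    f = rng.uniform(-3, 3, n)
    p = expit(-(A * f + B))
    y = (rng.random(n) < p).astype(int)
    return f, y


class TestFitPlatt:
    def test_symmetric_values_give_zero_intercept(self):
        # decision values symmetric about 0, labels = sign, balanced:
        # the likelihood is symmetric in B, so B must vanish
        f = np.concatenate([np.linspace(0.01, 3, 1000), -np.linspace(0.01, 3, 1000)])
        y = (f > 0).astype(int)
        fit = fit_platt(f, y)
        assert abs(fit.B) < 1e-6
        assert fit.A < 0

    def test_recovers_generating_parameters(self):
        f, y = simulate(-2.0, 0.5, 2000, seed=3)
        fit = fit_platt(f, y)
        assert fit.A == pytest.approx(-2.0, abs=0.15)
        assert fit.B == pytest.approx(0.5, abs=0.1)

    def test_matches_grid_search_oracle_nll(self):
        rng = np.random.default_rng(99)
        for _ in range(12):
            A_true = rng.uniform(-3, -0.5)
            B_true = rng.uniform(-0.5, 0.5)
            f, y = simulate(A_true, B_true, 200, seed=int(rng.integers(2**31)))
            fit = fit_platt(f, y)
            nll_oracle, _ = grid_search_oracle(f, y)
            assert fit.nll == pytest.approx(nll_oracle, abs=1e-3)

    def test_nll_not_above_initialization(self):
        f, y = simulate(-1.5, 0.2, 300, seed=7)
        fit = fit_platt(f, y)
        n_pos = int(y.sum())
        n_neg = len(y) - n_pos
        t = regularized_targets(y)
        init = oracle_nll(0.0, math.log((n_neg + 1) / (n_pos + 1)), f, t)
        assert fit.nll <= init + 1e-12

    def test_constant_decision_values_reduce_to_class_prior(self):
        y = np.array([1] * 30 + [0] * 70)
        f = np.zeros(100)
        fit = fit_platt(f, y)
        t = regularized_targets(y)
        # with f constant, the stationarity condition is mean(p) = mean(t);
        # oracle: minimize over the constant probability directly
        p_hat = sigmoid_probability(0.0, fit.A, fit.B)
        assert p_hat == pytest.approx(t.mean(), abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(CalibrationError):
            fit_platt([0.1, 0.2, 0.3], [1, 1, 1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            fit_platt([0.1, 0.2], [1])

    def test_deterministic(self):
        f, y = simulate(-2.0, 0.0, 500, seed=11)
        f1, f2 = fit_platt(f, y), fit_platt(f, y)
        assert (f1.A, f1.B, f1.nll) == (f2.A, f2.B, f2.nll)


class TestSigmoid:
    def test_midpoint(self):
        assert sigmoid_probability(0.0, A=-2.0, B=0.0) == 0.5

    def test_monotone_increasing_in_decision_value(self):
        probs = [sigmoid_probability(f, A=-1.5, B=0.3) for f in (-2, -1, 0, 1, 2)]
        direct = [1 / (1 + math.exp(-1.5 * f + 0.3)) for f in (-2, -1, 0, 1, 2)]
        assert probs == pytest.approx(direct)
        assert all(a < b for a, b in zip(probs, probs[1:]))

    def test_extreme_arguments_stay_in_unit_interval(self):
        for f in (-1e6, 1e6):
            p = sigmoid_probability(f, A=-3.0, B=1.0)
            assert 0.0 <= p <= 1.0


class TestPPIDataset:
    def test_conflicting_labels_rejected(self):
        with pytest.raises(ValidationError, match="conflicting"):
            PPIDataset([("P1", "P2", 1), ("P2", "P1", 0)])

    def test_bad_label_rejected(self):
        with pytest.raises(ValidationError):
            PPIDataset([("P1", "P2", 2)])

    def test_tsv_round_trip(self, tmp_path):
        data = PPIDataset([("P1", "P2", 1), ("P3", "P4", 0)])
        path = tmp_path / "pairs.tsv"
        data.to_tsv(path)
        assert PPIDataset.from_tsv(path).pairs == data.pairs


class TestTrainSVM:
    def test_separable_data_trains_to_perfect_accuracy(self):
        # two sequence families with disjoint triad content
        recs, pairs = [], []
        for i in range(12):
            recs.append(ProteinRecord(id=f"A{i}", sequence="ACK" * 10 + "MKV" * i))
            recs.append(ProteinRecord(id=f"B{i}", sequence="DWE" * 10 + "MKV" * i))
        for i in range(12):
            pairs.append((f"A{i}", f"B{i}", 1))
            pairs.append((f"A{i}", f"A{(i + 1) % 12}", 0))
        db = ProteinDatabase(recs)
        model = train_svm(PPIDataset(pairs), db,
                          params=SVMParams(tune=False, seed=0))
        X = np.vstack([
            pair_vector(
                triad_vector(db.sequence(a), model.class_map),
                triad_vector(db.sequence(b), model.class_map),
            ).values
            for a, b, _ in pairs
        ])
        labels = [y for _, _, y in pairs]
        assert list(model.svc.predict(X)) == labels

    def test_single_class_rejected(self, small_world):
        db, _ = small_world
        ids = [rec.id for rec in db][:4]
        with pytest.raises(ValidationError):
            train_svm(PPIDataset([(ids[0], ids[1], 1), (ids[2], ids[3], 1)]), db)

    def test_unresolvable_id_rejected(self, small_world):
        db, _ = small_world
        ids = [r.id for r in db]
        data = PPIDataset([
            (ids[0], "GHOST", 1), (ids[1], ids[2], 1),
            (ids[3], ids[4], 0), (ids[5], ids[6], 0),
        ])
        with pytest.raises(UnknownProteinError):
            train_svm(data, db)

    def test_fitted_A_negative_on_learnable_data(self, small_model):
        assert small_model.platt_A < 0

    def test_probability_in_unit_interval(self, small_world, small_model):
        db, data = small_world
        for a, b, _ in data.pairs[:50]:
            p = small_model.predict_probability(db.sequence(a), db.sequence(b))
            assert 0.0 <= p <= 1.0

    def test_symmetrized_prediction_is_order_invariant(self, small_world, small_model):
        db, data = small_world
        for a, b, _ in data.pairs[:20]:
            sa, sb = db.sequence(a), db.sequence(b)
            assert small_model.predict_probability(sa, sb) == pytest.approx(
                small_model.predict_probability(sb, sa), abs=1e-15
            )

    def test_training_invariant_to_row_order(self, small_world):
        db, data = small_world
        params = SVMParams(tune=False, seed=5)
        m1 = train_svm(data, db, params=params)
        reordered = PPIDataset(list(reversed(data.pairs)))
        m2 = train_svm(reordered, db, params=params)
        probe = data.pairs[:10]
        for a, b, _ in probe:
            p1 = m1.predict_probability(db.sequence(a), db.sequence(b))
            p2 = m2.predict_probability(db.sequence(a), db.sequence(b))
            assert p1 == pytest.approx(p2, abs=5e-3)

    def test_save_load_identical_predictions(self, small_world, small_model, tmp_path):
        db, data = small_world
        path = tmp_path / "m.model"
        small_model.save(path)
        loaded = type(small_model).load(path)
        for a, b, _ in data.pairs[:30]:
            sa, sb = db.sequence(a), db.sequence(b)
            assert loaded.predict_probability(sa, sb) == small_model.predict_probability(sa, sb)

    def test_fingerprint_mismatch_refused(self, small_model):
        other = dict(small_model.class_map.mapping)
        other["A"], other["C"] = other["C"], other["A"]
        with pytest.raises(FingerprintMismatchError):
            small_model.check_fingerprint(ResidueClassMap(mapping=other))

    def test_same_seed_reproduces_model(self, small_world):
        db, data = small_world
        params = SVMParams(tune=False, seed=77)
        m1 = train_svm(data, db, params=params)
        m2 = train_svm(data, db, params=params)
        assert m1.platt_A == m2.platt_A and m1.platt_B == m2.platt_B
        a, b, _ = data.pairs[0]
        sa, sb = db.sequence(a), db.sequence(b)
        assert m1.predict_probability(sa, sb) == m2.predict_probability(sa, sb)


class TestNegativeSampling:
    def test_ratio_and_disjointness(self):
        ids = [f"P{i}" for i in range(30)]
        positives = [(f"P{i}", f"P{i+1}") for i in range(0, 20, 2)]
        negs = sample_negative_pairs(positives, ids, ratio=2.0, seed=4)
        assert len(negs) == 2 * len(positives)
        pos_set = {frozenset(p) for p in positives}
        neg_keys = [frozenset((a, b)) for a, b, _ in negs]
        assert not (pos_set & set(neg_keys))
        assert len(set(neg_keys)) == len(neg_keys)

    def test_impossible_request_rejected(self):
        with pytest.raises(ValidationError):
            sample_negative_pairs([("P0", "P1")], ["P0", "P1"], ratio=5.0, seed=0)
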