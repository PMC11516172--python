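import numpy as np
import pandas as pd
import pytest

from pyroscape.grid_io import GridValidationError
from pyroscape.pseudo_absence import (DomainModel, EnvelopeModel, ModelFitError,
                                      NoveltyModel, combine_presence_only,
                                      evaluate_binary_auc, sample_pseudo_absences,
                                      two_step_pseudo_absence)
from pyroscape.synthetic_landscape import sample_presences
from pyroscape.preprocess import thin_points
from conftest import make_grid, points_at_cells


def brute_force_auc(scores, labels):
    """Exhaustive pairwise Mann-Whitney count, ties 1/2."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestEnvelope:
    def test_training_presences_score_one_at_full_trim(self):
        rng = np.random.default_rng(0)
        feats = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        model = EnvelopeModel.fit(feats)
        assert model.score(feats).all()

    def test_cell_above_max_scores_zero(self):
        feats = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0]})
        model = EnvelopeModel.fit(feats)
        assert model.score(pd.DataFrame({"a": [5.1]}))[0] == 0
        assert model.score(pd.DataFrame({"a": [3.0]}))[0] == 1

    def test_trimmed_envelope_excludes_about_ten_percent_of_training(self):
        rng = np.random.default_rng(1)
        feats = pd.DataFrame({"a": rng.uniform(0, 1, 100)})
        model = EnvelopeModel.fit(feats, trim=(5.0, 95.0))
        frac_out = 1.0 - model.score(feats).mean()
        assert frac_out == pytest.approx(0.10, abs=0.03)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ModelFitError):
            EnvelopeModel.fit(pd.DataFrame({"a": [1.0, 2.0]}))


class TestDomain:
    def test_identical_cell_has_similarity_one(self):
        feats = pd.DataFrame({"a": [0.0, 2.0, 4.0, 6.0, 10.0]})
        model = DomainModel.fit(feats, theta=0.95)
        assert model.score(feats.iloc[[2]]).all()

    def test_hand_computed_gower_similarity(self):
        # one variable with range 10; cell 6 units from the closest presence
        feats = pd.DataFrame({"a": [0.0, 1.0, 2.0, 5.0, 10.0]})
        model = DomainModel.fit(feats, theta=0.95)
        sim = model.similarity(pd.DataFrame({"a": [16.0]}))
        assert sim[0] == pytest.approx(0.4, abs=1e-12)
        assert model.score(pd.DataFrame({"a": [16.0]}))[0] == 0

    def test_theta_zero_rejected(self):
        feats = pd.DataFrame({"a": np.arange(5.0)})
        with pytest.raises(ModelFitError):
            DomainModel.fit(feats, theta=0.0)

    def test_all_zero_range_variables_rejected(self):
        feats = pd.DataFrame({"a": np.ones(6)})
        with pytest.raises(ModelFitError):
            DomainModel.fit(feats)


class TestNovelty:
    @pytest.fixture
    def gaussian_cloud(self):
        rng = np.random.default_rng(2)
        return pd.DataFrame(rng.normal(0, 1, size=(200, 2)), columns=["a", "b"])

    def test_query_at_training_mean_is_inlier(self, gaussian_cloud):
        model = NoveltyModel.fit(gaussian_cloud)
        assert model.score(pd.DataFrame({"a": [0.0], "b": [0.0]}))[0] == 1

    def test_far_query_is_outlier(self, gaussian_cloud):
        model = NoveltyModel.fit(gaussian_cloud)
        assert model.score(pd.DataFrame({"a": [10.0], "b": [10.0]}))[0] == 0

    def test_refit_is_deterministic(self, gaussian_cloud):
        rng = np.random.default_rng(3)
        query = pd.DataFrame(rng.normal(0, 2, size=(50, 2)), columns=["a", "b"])
        s1 = NoveltyModel.fit(gaussian_cloud).score(query)
        s2 = NoveltyModel.fit(gaussian_cloud).score(query)
        np.testing.assert_array_equal(s1, s2)

    def test_constant_feature_rejected(self):
        feats = pd.DataFrame({"a": np.ones(20), "b": np.arange(20.0)})
        with pytest.raises(ModelFitError):
            NoveltyModel.fit(feats)


class TestBinaryAuc:
    def test_perfect_separation(self):
        assert evaluate_binary_auc([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert evaluate_binary_auc([1, 1, 1, 1], [1, 1, 0, 0]) == 0.5

    def test_hand_counted_mixed_case(self):
        # positives (1,1,0), negatives (0,0,1,0): concordant pairs 8.5 of 12
        value = evaluate_binary_auc([1, 1, 0, 0, 0, 1, 0], [1, 1, 1, 0, 0, 0, 0])
        assert value == pytest.approx(8.5 / 12, abs=1e-12)

    def test_one_class_empty_is_error(self):
        with pytest.raises(GridValidationError):
            evaluate_binary_auc([1, 0], [1, 1])

    def test_agrees_with_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = rng.integers(2, 13)
            labels = np.zeros(n, int)
            labels[: rng.integers(1, n)] = 1
            rng.shuffle(labels)
            if labels.all() or not labels.any():
                continue
            scores = rng.integers(0, 4, n).astype(float)
            assert evaluate_binary_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)


class TestCombine:
    def _member(self, values, auc_value, tag="m"):
        return (tag, make_grid(np.asarray(values, dtype=np.int8)), auc_value)

    def test_gate_excludes_low_auc_member(self):
        ones = np.ones((2, 2))
        zeros = np.zeros((2, 2))
        ens = combine_presence_only(
            [self._member(ones, 0.9, "a"), self._member(ones, 0.85, "b"),
             self._member(zeros, 0.6, "c")])
        assert ens.passing == ["a", "b"]
        assert (ens.combined.values == 1).all()

    def test_tie_votes_one(self):
        a = np.array([[1, 0], [0, 0]])
        b = np.array([[0, 0], [0, 0]])
        a[0, 1] = 1
        b[0, 1] = 0
        ens = combine_presence_only(
            [self._member(a, 0.9, "a"), self._member(b, 0.85, "b")])
        # cell (0,1): votes (1, 0) -> tie -> 1
        assert ens.combined.values[0, 1] == 1

    def test_unanimous_zero_cell_lands_in_zero_region(self):
        a = np.array([[1, 0], [0, 0]])
        ens = combine_presence_only(
            [self._member(a, 0.9, "a"), self._member(a, 0.85, "b")])
        assert ens.zero_region.values[1, 1] == 1
        assert ens.zero_region.values[0, 0] == 0

    def test_no_passing_member_is_informative_error(self):
        with pytest.raises(ModelFitError, match="gate"):
            combine_presence_only([self._member(np.ones((2, 2)), 0.7)])


class TestSampling:
    def test_count_is_multiplier_times_presences(self):
        zero = make_grid(np.ones((30, 30), dtype=np.int8))
        out = sample_pseudo_absences(zero, n_presence=100, seed=0)
        assert len(out) == 200
        assert (out.table["label"] == "pseudo_absence").all()

    def test_exactly_enough_cells_selects_all(self):
        vals = np.zeros((20, 20), dtype=np.int8)
        vals.ravel()[:200] = 1
        zero = make_grid(vals)
        out = sample_pseudo_absences(zero, n_presence=100, seed=1)
        assert len(out) == 200
        r, c = zero.cell_of(out.table["x"].to_numpy(), out.table["y"].to_numpy())
        assert set(zip(r, c)) == set(zip(*np.nonzero(vals)))

    def test_same_seed_reproduces_sample(self):
        zero = make_grid(np.ones((30, 30), dtype=np.int8))
        a = sample_pseudo_absences(zero, 50, seed=9)
        b = sample_pseudo_absences(zero, 50, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_shortfall_reported(self):
        vals = np.zeros((10, 10), dtype=np.int8)
        vals.ravel()[:50] = 1
        with pytest.raises(GridValidationError, match="shortfall"):
            sample_pseudo_absences(make_grid(vals), n_presence=100, seed=0)

    def test_presence_cells_never_drawn(self):
        zero = make_grid(np.ones((10, 10), dtype=np.int8))
        presences = points_at_cells(zero, [0, 1], [0, 1])
        out = sample_pseudo_absences(zero, 20, seed=3, presence_points=presences)
        r, c = zero.cell_of(out.table["x"].to_numpy(), out.table["y"].to_numpy())
        assert (0, 0) not in set(zip(r, c))
        assert (1, 1) not in set(zip(r, c))


class TestTwoStep:
    def test_contract_on_synthetic_landscape(self, small_landscape):
        stacks, _, truth = small_landscape
        presences = thin_points(
            sample_presences(truth, 120, "spring", seed=11), 300.0)
        ensemble, pseudo = two_step_pseudo_absence(stacks["spring"], presences, seed=5)
        assert len(pseudo) == 2 * len(presences)
        grid = ensemble.combined
        pr, pc = grid.cell_of(presences.table["x"].to_numpy(),
                              presences.table["y"].to_numpy())
        ar, ac = grid.cell_of(pseudo.table["x"].to_numpy(),
                              pseudo.table["y"].to_numpy())
        # disjoint from presence cells and from the ensemble-positive region
        assert set(zip(ar, ac)).isdisjoint(set(zip(pr, pc)))
        assert (grid.values[ar, ac] == 0).all()

    def test_zero_region_depleted_in_true_risk(self):
        """The candidate pseudo-absence zone has lower mean true risk than
        the landscape, across 20 generator seeds."""
        from pyroscape.synthetic_landscape import LandscapeSpec, make_landscape

        hits = 0
        for seed in range(20):
            spec = LandscapeSpec(shape=(64, 64), seed=seed)
            stacks, _, truth = make_landscape(spec)
            pres = thin_points(sample_presences(truth, 150, "spring", seed=seed + 50),
                               300.0)
            try:
                ens, _ = two_step_pseudo_absence(stacks["spring"], pres, seed=seed)
            except ModelFitError:
                continue
            risk = truth.risk_surface["spring"].values
            zero = ens.zero_region.values.astype(bool)
            if risk[zero].mean() < risk.mean():
                hits += 1
        assert hits >= 18
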