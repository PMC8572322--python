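"""Model-diagnostic battery: splits, Andersen LR, Wald, item fit, GOF data."""

import numpy as np
import pytest

import raschmon as rm
from raschmon.diagnostics import (
    andersen_lr_test,
    goodness_of_fit_plotdata,
    item_fit,
    split_sample,
    wald_tests,
)
from raschmon.errors import DegenerateSplitError


def _matrix_with_scores(scores, k=6):
    resp = np.array([[1] * r + [0] * (k - r) for r in scores])
    return rm.ResponseMatrix(
        [f"R{i}" for i in range(len(scores))], [f"V{i+1}" for i in range(k)], resp
    )


def _duplicated(matrix):
    """Two identical copies of every respondent plus labels separating them."""
    resp = np.vstack([matrix.responses, matrix.responses])
    ids = [f"{r}a" for r in matrix.respondent_ids] + [
        f"{r}b" for r in matrix.respondent_ids
    ]
    labels = np.array([0] * matrix.n_persons + [1] * matrix.n_persons)
    return rm.ResponseMatrix(ids, matrix.item_codes, resp), labels


class TestSplitSample:
    def test_median_split_even_scores(self):
        m = _matrix_with_scores([1, 2, 3, 4])
        low, high, tag = split_sample(m)
        assert tag == "median raw score"
        assert sorted(low.raw_scores) == [1, 2]
        assert sorted(high.raw_scores) == [3, 4]

    def test_ties_go_to_the_low_group(self):
        m = _matrix_with_scores([1, 2, 2, 5])
        low, high, _ = split_sample(m)
        assert sorted(low.raw_scores) == [1, 2, 2]
        assert sorted(high.raw_scores) == [5]

    def test_equal_scores_degenerate(self):
        with pytest.raises(DegenerateSplitError):
            split_sample(_matrix_with_scores([3, 3, 3, 3]))

    def test_explicit_labels(self):
        m = _matrix_with_scores([1, 2, 3, 4])
        low, high, tag = split_sample(m, np.array([0, 1, 0, 1]))
        assert tag == "explicit labels"
        assert sorted(low.raw_scores) == [1, 3]


class TestAndersen:
    def test_df_contract_on_25_item_cohort(self, simulated_cohort):
        res = andersen_lr_test(simulated_cohort.matrix)
        assert res.df == 24
        assert res.lr >= 0.0
        assert 0.0 <= res.p_value <= 1.0

    def test_identical_subgroups_give_zero_lr(self, simulated_cohort):
        dup, labels = _duplicated(simulated_cohort.matrix)
        res = andersen_lr_test(dup, labels)
        assert res.lr == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_invariant_to_subgroup_relabeling(self, simulated_cohort):
        m = simulated_cohort.matrix
        labels = (np.arange(m.n_persons) % 2).astype(int)
        a = andersen_lr_test(m, labels)
        b = andersen_lr_test(m, 1 - labels)
        assert a.lr == pytest.approx(b.lr, abs=1e-8)

    def test_detects_strong_dif(self, default_bank):
        shift = np.zeros(25)
        shift[0] = 1.5
        sim = rm.simulate_responses(
            rm.SimulationConfig(
                n_persons=2000, item_difficulties=default_bank,
                seed=17, dif_shift=shift,
            )
        )
        res = andersen_lr_test(sim.matrix)
        assert res.p_value < 0.001


class TestWald:
    def test_identical_subgroups_give_zero_z(self, simulated_cohort):
        dup, labels = _duplicated(simulated_cohort.matrix)
        res = wald_tests(dup, labels)
        assert np.allclose(res.table["z"], 0.0, atol=1e-5)

    def test_antisymmetric_under_subgroup_swap(self, simulated_cohort):
        m = simulated_cohort.matrix
        labels = (np.arange(m.n_persons) % 2).astype(int)
        a = wald_tests(m, labels)
        b = wald_tests(m, 1 - labels)
        np.testing.assert_allclose(
            a.table["z"].to_numpy(), -b.table["z"].to_numpy(), atol=1e-8
        )

    def test_flags_a_shifted_item(self, default_bank):
        shift = np.zeros(25)
        shift[3] = 1.5
        sim = rm.simulate_responses(
            rm.SimulationConfig(
                n_persons=4000, item_difficulties=default_bank,
                seed=19, dif_shift=shift,
            )
        )
        res = wald_tests(sim.matrix)
        t = res.table.set_index("item_code")
        assert t.loc["V4", "p_value"] < 0.05
        assert t.loc["V4", "z"] ** 2 == t["z"].pow(2).max()

    def test_bonferroni_column_optional(self, simulated_cohort):
        plain = wald_tests(simulated_cohort.matrix)
        assert "p_bonferroni" not in plain.table
        corrected = wald_tests(simulated_cohort.matrix, bonferroni=True)
        assert np.all(
            corrected.table["p_bonferroni"] >= corrected.table["p_value"] - 1e-15
        )


class TestItemFit:
    def test_calibration_near_one_under_the_model(self, default_bank):
        sim = rm.simulate_responses(
            rm.SimulationConfig(n_persons=3000, item_difficulties=default_bank, seed=23)
        )
        items = rm.fit_cml(sim.matrix)
        persons = rm.estimate_person_parameters(sim.matrix, items)
        res = item_fit(sim.matrix, items, persons)
        assert np.all(res.table[["infit_msq", "outfit_msq"]] >= 0)
        assert 0.9 < res.table["infit_msq"].mean() < 1.1

    def test_random_response_item_shows_worst_outfit(self):
        """An item answered at random, independent of ability, is flagged by
        the largest outfit mean square."""
        bank = np.linspace(-1.5, 1.5, 9)
        sim = rm.simulate_responses(
            rm.SimulationConfig(n_persons=800, item_difficulties=bank, seed=29)
        )
        resp = sim.matrix.responses.copy()
        rng = np.random.default_rng(30)
        resp[:, 4] = rng.integers(0, 2, size=800)  # noise item
        noisy = rm.ResponseMatrix(
            sim.matrix.respondent_ids, sim.matrix.item_codes, resp
        )
        items = rm.fit_cml(noisy)
        persons = rm.estimate_person_parameters(noisy, items)
        res = item_fit(noisy, items, persons)
        t = res.table.set_index("item_code")
        assert t.loc["V5", "outfit_msq"] > 1.0
        assert t["outfit_msq"].idxmax() == "V5"


class TestGoodnessOfFit:
    def test_identical_subgroups_fall_on_the_identity_line(self, simulated_cohort):
        dup, labels = _duplicated(simulated_cohort.matrix)
        table = goodness_of_fit_plotdata(dup, labels)
        np.testing.assert_allclose(table["beta_low"], table["beta_high"], atol=1e-6)

    def test_row_count_and_ellipse_scaling(self, simulated_cohort):
        table = goodness_of_fit_plotdata(simulated_cohort.matrix)
        assert len(table) == 25
        ratio = table["ellipse_half_low"] / table["se_low"]
        np.testing.assert_allclose(ratio, np.sqrt(5.991464), rtol=1e-4)
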