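"""Indicator matrix, chi-square subtype tests, SAM and the four-group split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from subtypenet._utils import BASAL, LUMINAL, DataConsistencyError
from subtypenet.groups import (
    assign_direction,
    build_indicator_matrix,
    chi_square_subtype,
    partition_groups,
    sam_statistics,
    subtype_cna_tests,
)
from conftest import two_group_labels


def textbook_chi2(table):
    """Sum (O-E)^2/E with zero-columns dropped (independent oracle)."""
    t = np.asarray(table, float)
    t = t[:, t.sum(axis=0) > 0]
    e = np.outer(t.sum(1), t.sum(0)) / t.sum()
    return float(((t - e) ** 2 / e).sum())


class TestIndicatorMatrix:
    def test_hand_input_exact_and_canonical_order(self):
        labels = two_group_labels(1, 1)
        per_sample = {
            "L0": pd.Series({"g1": 1, "g2": 0, "g3": -1}),
            "B0": pd.Series({"g1": 0, "g2": 0, "g3": 1}),
        }
        gsm = build_indicator_matrix(per_sample, labels)
        assert list(gsm.states.columns) == ["B0", "L0"]  # sorted
        assert gsm.states.loc["g3", "B0"] == 1
        # input dict order must not matter
        gsm2 = build_indicator_matrix(
            dict(reversed(list(per_sample.items()))), labels)
        pd.testing.assert_frame_equal(gsm.states, gsm2.states)

    def test_genes_missing_in_any_sample_dropped(self):
        labels = two_group_labels(1, 1)
        gsm = build_indicator_matrix({
            "L0": pd.Series({"g1": 1.0, "g2": np.nan}),
            "B0": pd.Series({"g1": 0.0, "g2": 1.0}),
        }, labels)
        assert list(gsm.states.index) == ["g1"]

    def test_round_trip_tsv(self, tmp_path):
        from subtypenet import io
        labels = two_group_labels(2, 2)
        states = pd.DataFrame(
            np.array([[1, 0, -1, 0], [0, 0, 1, 1]]),
            index=["g1", "g2"], columns=labels.index)
        io.write_states(states, tmp_path / "s.tsv")
        back = io.read_states(tmp_path / "s.tsv")
        pd.testing.assert_frame_equal(back.rename_axis(None), states)


class TestChiSquare:
    def test_identical_distributions_give_null_result(self):
        chi2, p, df, degenerate = chi_square_subtype([[10, 30, 12],
                                                      [10, 30, 12]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert not degenerate

    def test_matches_textbook_formula(self, rng):
        for _ in range(200):
            tab = rng.integers(0, 40, size=(2, 3))
            tab[:, 1] += 1  # keep both rows occupied
            chi2, p, df, degenerate = chi_square_subtype(tab)
            if degenerate:
                continue
            assert chi2 == pytest.approx(textbook_chi2(tab), rel=1e-12)

    def test_single_occupied_column_is_degenerate(self):
        chi2, p, df, degenerate = chi_square_subtype([[0, 12, 0], [0, 9, 0]])
        assert degenerate and p == 1.0 and chi2 == 0.0

    def test_empty_subtype_row_rejected(self):
        with pytest.raises(DataConsistencyError):
            chi_square_subtype([[0, 0, 0], [5, 5, 5]])

    @given(st.permutations([0, 1, 2]), st.booleans())
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_row_and_column_permutation(self, cperm, flip):
        tab = np.array([[10, 30, 12], [25, 10, 5]])
        t2 = tab[::-1] if flip else tab
        t2 = t2[:, list(cperm)]
        assert chi_square_subtype(t2)[0] == \
            pytest.approx(chi_square_subtype(tab)[0], rel=1e-12)

    def test_asymptotic_p_close_to_permutation_p(self, rng):
        """Label-permutation null computed exactly via MV hypergeometric."""
        for _ in range(5):
            tab = np.array([rng.multinomial(52, [0.2, 0.6, 0.2]),
                            rng.multinomial(40, [0.35, 0.5, 0.15])])
            chi2, p_asym, _, _ = chi_square_subtype(tab)
            colors = tab.sum(axis=0)
            draws = rng.multivariate_hypergeometric(colors, 52, size=20000)
            n = tab.sum()
            e_l = colors * 52 / n
            e_b = colors * 40 / n
            rest = colors[None, :] - draws
            with np.errstate(divide="ignore", invalid="ignore"):
                null = np.where(e_l > 0, (draws - e_l) ** 2 / e_l, 0).sum(1) \
                    + np.where(e_b > 0, (rest - e_b) ** 2 / e_b, 0).sum(1)
            p_perm = float((null >= chi2 - 1e-9).mean())
            assert abs(p_asym - p_perm) < 0.03


class TestDirection:
    def test_clear_luminal_gain(self):
        # luminal: 30 gains of 52; basal: 2 gains of 40, losses rare
        tab = np.array([[3, 19, 30], [4, 34, 2]])
        assert assign_direction(tab) == (LUMINAL, 1)

    def test_symmetric_table_tie_breaks_deterministically(self):
        tab = np.array([[10, 20, 10], [10, 20, 10]])
        assert assign_direction(tab) == assign_direction(tab)
        assert assign_direction(tab)[1] == 1  # gain preferred on ties

    def test_direction_matches_planted_truth(self, tiny_dataset):
        truth = tiny_dataset.truth
        gsm = build_indicator_matrix(
            {s: truth.true_states[s] for s in truth.true_states.columns},
            tiny_dataset.labels)
        cna = subtype_cna_tests(gsm)
        hits = 0
        planted = truth.subtype_specific_genes
        for gene, group in planted.items():
            dom = LUMINAL if group.startswith("luminalA") else BASAL
            state = 1 if group.endswith("gain") else -1
            row = cna.loc[gene]
            hits += (row["dominant_subtype"] == dom
                     and row["dominant_state"] == state)
        assert hits / len(planted) >= 0.95


class TestSAM:
    def test_equal_group_means_give_zero_d(self):
        labels = two_group_labels(3, 3)
        x = pd.DataFrame([[1.0, 2.0, 3.0, 3.0, 2.0, 1.0]], index=["f"],
                         columns=labels.index)
        res = sam_statistics(x, labels, n_perm=50, seed=0)
        assert res.loc["f", "d"] == pytest.approx(0.0)

    def test_constant_feature_handled_by_s0(self, rng):
        labels = two_group_labels(5, 5)
        x = pd.DataFrame(rng.standard_normal((20, 10)), columns=labels.index)
        x.iloc[0] = 1.0  # zero variance
        res = sam_statistics(x, labels, n_perm=50, seed=0)
        assert np.isfinite(res["d"]).all()

    def test_planted_shift_detected_with_high_power(self, rng):
        labels = two_group_labels(20, 20)
        x = rng.standard_normal((300, 40))
        x[:30, :20] += 2.0  # 2-SD shift in the first 30 features
        df = pd.DataFrame(x, columns=labels.index)
        res = sam_statistics(df, labels, n_perm=200, seed=1)
        hits = ((res["p_perm"][:30] < 0.05) & (res["q"][:30] < 0.1)).mean()
        assert hits >= 0.9


class TestPartition:
    @staticmethod
    def _cna_row(subtype, state, p=0.001):
        return {"chi2": 30.0, "p": p, "df": 2, "degenerate": False,
                "dominant_subtype": subtype, "dominant_state": state}

    @staticmethod
    def _de_row(direction, p=0.001, q=0.01):
        return {"d": 3.0 * direction, "s": 1.0, "p_perm": p, "q": q,
                "direction": direction}

    def test_concordant_genes_split_into_four_disjoint_groups(self):
        cna = pd.DataFrame({
            "lg": self._cna_row(LUMINAL, 1),
            "ll": self._cna_row(LUMINAL, -1),
            "bg": self._cna_row(BASAL, 1),
            "bl": self._cna_row(BASAL, -1),
        }).T
        de = pd.DataFrame({
            "lg": self._de_row(+1), "ll": self._de_row(-1),
            "bg": self._de_row(-1), "bl": self._de_row(+1),
        }).T
        out = partition_groups(cna, de)
        assert out.loc["lg", "group"] == "luminalA_gain"
        assert out.loc["ll", "group"] == "luminalA_loss"
        assert out.loc["bg", "group"] == "basal_gain"
        assert out.loc["bl", "group"] == "basal_loss"
        assert out["group"].value_counts().max() == 1

    def test_discordant_or_nonsignificant_genes_excluded(self):
        cna = pd.DataFrame({
            "discordant": self._cna_row(LUMINAL, 1),
            "weak_cna": self._cna_row(LUMINAL, 1, p=0.2),
            "weak_de": self._cna_row(LUMINAL, 1),
        }).T
        de = pd.DataFrame({
            "discordant": self._de_row(-1),  # gained but underexpressed
            "weak_cna": self._de_row(+1),
            "weak_de": self._de_row(+1, p=0.3),
        }).T
        assert partition_groups(cna, de).empty

    def test_null_simulation_passes_both_filters_rarely(self, rng):
        """Under a full null the two-filter pass rate stays below 1%."""
        labels = two_group_labels(26, 20)
        n_genes = 400
        states = pd.DataFrame(
            (rng.random((n_genes, 46)) < 0.05).astype(int)
            * rng.choice([-1, 1], size=(n_genes, 46)),
            index=[f"g{i}" for i in range(n_genes)], columns=labels.index)
        gsm = build_indicator_matrix(
            {s: states[s] for s in states.columns}, labels)
        cna = subtype_cna_tests(gsm)
        expr = pd.DataFrame(rng.standard_normal((n_genes, 46)),
                            index=states.index, columns=labels.index)
        de = sam_statistics(expr, labels, n_perm=100, seed=2)
        out = partition_groups(cna, de)
        assert len(out) / n_genes < 0.01
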