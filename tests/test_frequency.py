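"""Identification-frequency statistics: matrix building, ratios, exact tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from conftest import toy_labels
from evfrac.frequency import (
    MarkerPanel,
    PresenceMatrix,
    build_presence_matrix,
    compute_frequencies,
    fisher_differential,
    load_default_marker_panels,
    mann_whitney,
    marker_panel_report,
    partition_by_ratio,
)


def matrix_from_counts(k_sev, k_lev, n_sev, n_lev, name="P"):
    """Presence matrix realising given identification counts for one protein."""
    ids = [f"s{i}" for i in range(n_sev)] + [f"l{i}" for i in range(n_lev)]
    labels = pd.Series(["SEV"] * n_sev + ["LEV"] * n_lev, index=ids)
    cells = pd.DataFrame(
        {name: [i < k_sev for i in range(n_sev)] + [i < k_lev for i in range(n_lev)]},
        index=ids,
    )
    return PresenceMatrix(cells=cells, labels=labels)


class TestBuildMatrix:
    def test_duplicates_collapse(self):
        ident = pd.DataFrame(
            {"dataset_id": ["d1", "d1", "d2"], "protein_id": ["P", "P", "Q"]}
        )
        m = build_presence_matrix(ident, toy_labels())
        assert m.cells.shape == (2, 2)
        assert m.cells.loc["d1", "P"] and m.cells.loc["d2", "Q"]
        assert not m.cells.loc["d1", "Q"] and not m.cells.loc["d2", "P"]

    def test_excluded_only_input_rejected(self):
        ident = pd.DataFrame({"dataset_id": ["dx"], "protein_id": ["P"]})
        labels = pd.DataFrame(
            {"dataset_id": ["dx"], "label": ["EXCLUDED"], "reason": ["PELLET_BETWEEN_WINDOWS"]}
        )
        with pytest.raises(ValueError, match="no labelled"):
            build_presence_matrix(ident, labels)

    def test_unlabeled_dataset_rejected(self):
        ident = pd.DataFrame({"dataset_id": ["mystery"], "protein_id": ["P"]})
        with pytest.raises(ValueError, match="mystery"):
            build_presence_matrix(ident, toy_labels())

    def test_synthetic_dimensions_match_truth(self, study, study_stats):
        m = study_stats["matrix"]
        kept = study.dataset_truth.query("label != 'EXCLUDED'")
        assert m.cells.shape[0] == len(kept)
        identified = study.identifications[
            study.identifications["dataset_id"].isin(kept["dataset_id"])
        ]["protein_id"].nunique()
        assert m.cells.shape[1] == identified


class TestFrequencies:
    def test_smoothed_ratio_hand_example(self):
        stats = compute_frequencies(matrix_from_counts(3, 0, 10, 10))
        row = stats.loc["P"]
        assert row["f_sev"] == pytest.approx(0.3)
        assert row["f_lev"] == 0.0
        assert row["log2_ratio"] == pytest.approx(math.log2(7), abs=1e-12)
        assert np.isnan(row["log2_ratio_raw"])

    def test_ubiquitous_protein_has_zero_ratio(self):
        row = compute_frequencies(matrix_from_counts(10, 10, 10, 10)).loc["P"]
        assert row["log2_ratio"] == 0.0 and row["log2_ratio_raw"] == 0.0

    def test_single_fraction_matrix_rejected(self):
        ids = ["s0", "s1"]
        m = PresenceMatrix(
            cells=pd.DataFrame({"P": [True, True]}, index=ids),
            labels=pd.Series(["SEV", "SEV"], index=ids),
        )
        with pytest.raises(ValueError, match="both fractions"):
            compute_frequencies(m)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        k_sev=st.integers(0, 12),
        k_lev=st.integers(0, 12),
        n=st.integers(5, 12),
    )
    def test_label_swap_negates_ratio(self, k_sev, k_lev, n):
        k_sev, k_lev = min(k_sev, n), min(k_lev, n)
        a = compute_frequencies(matrix_from_counts(k_sev, k_lev, n, n)).loc["P"]
        b = compute_frequencies(matrix_from_counts(k_lev, k_sev, n, n)).loc["P"]
        assert a["log2_ratio"] == pytest.approx(-b["log2_ratio"], abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        k_sev=st.integers(5, 30),
        k_lev=st.integers(5, 30),
        n=st.integers(30, 60),
    )
    def test_raw_and_smoothed_agree_at_decent_counts(self, k_sev, k_lev, n):
        """Smoothing bias is bounded by log2(1 + 0.5/min(k)); < 0.05 once k >= 20."""
        row = compute_frequencies(matrix_from_counts(k_sev, k_lev, n, n)).loc["P"]
        diff = abs(row["log2_ratio"] - row["log2_ratio_raw"])
        assert diff <= math.log2(1 + 0.5 / min(k_sev, k_lev)) + 1e-12
        if min(k_sev, k_lev) >= 20:
            assert diff < 0.05

    def test_class_frequency_within_binomial_envelope(self, study, study_stats):
        """Mean flEV of ECTO-class proteins sits in the exact binomial 99% band of 0.6."""
        from scipy.stats import binom

        stats = study_stats["stats"]
        ecto = study.protein_class.reindex(stats.index) == "ECTO"
        n_lev = int(stats["n_lev"].iloc[0])
        lo, hi = binom.ppf([0.005, 0.995], n_lev, 0.6) / n_lev
        mean_f = stats.loc[ecto, "f_lev"].mean()
        assert lo <= mean_f <= hi


class TestFisher:
    def test_disjoint_2x2_table(self):
        stats = fisher_differential(compute_frequencies(matrix_from_counts(2, 0, 2, 2)))
        assert stats.loc["P", "fisher_p"] == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_rows_give_p_one(self):
        stats = fisher_differential(compute_frequencies(matrix_from_counts(5, 5, 10, 10)))
        assert stats.loc["P", "fisher_p"] == pytest.approx(1.0)

    def test_q_at_least_p(self, study_stats):
        stats = study_stats["stats"]
        assert (stats["fisher_q"] >= stats["fisher_p"] - 1e-12).all()


def brute_force_mwu_p(x, y):
    """Independent enumeration oracle: rank-based U over all group assignments."""
    x, y = list(x), list(y)
    pooled = np.array(x + y, dtype=float)
    n, m = len(x), len(y)
    ranks = rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    mu = n * m / 2
    hits = total = 0
    for idx in itertools.combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return u_obs, hits / total


class TestMannWhitney:
    @pytest.mark.parametrize(
        "x, y, u_exp, p_exp",
        [
            ([1, 2], [3, 4], 0.0, 1 / 3),
            ([0, 0, 1], [2, 3, 3], 0.0, 0.1),
        ],
    )
    def test_enumerated_toys(self, x, y, u_exp, p_exp):
        u, p = mann_whitney(x, y)
        assert u == u_exp
        assert p == pytest.approx(p_exp, abs=1e-12)

    def test_identical_samples_give_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        x=st.lists(st.integers(0, 6), min_size=2, max_size=5),
        y=st.lists(st.integers(10, 16), min_size=2, max_size=5),
    )
    def test_exact_path_matches_enumeration_oracle(self, x, y):
        u_impl, p_impl = mann_whitney(x, y)
        u_ref, p_ref = brute_force_mwu_p(x, y)
        assert u_impl == pytest.approx(u_ref)
        assert p_impl == pytest.approx(p_ref, abs=1e-12)


class TestMarkerPanels:
    def test_bundled_fixture_has_twenty_symbols(self):
        panels = load_default_marker_panels()
        members = {m for p in panels for m in p.members}
        assert len(panels) == 2 and len(members) == 20
        assert {"CD63", "CD9", "TSG101"} <= members
        assert {"ACTB", "ARF6", "ANXA1"} <= members

    def test_report_flags_missing_members(self, study_stats):
        stats = study_stats["stats"]
        present = list(stats.index[:3])
        panel = MarkerPanel("toy", "EXOSOME", tuple(present + ["NOT_A_PROTEIN"]))
        report, tests = marker_panel_report(stats, [panel])
        assert report["missing"].sum() == 1
        assert tests.loc[0, "n_present"] == 3

    def test_no_overlap_rejected(self, study_stats):
        panel = MarkerPanel("toy", "EXOSOME", ("NOPE1", "NOPE2"))
        with pytest.raises(ValueError, match="no overlap"):
            marker_panel_report(study_stats["stats"], [panel])

    def test_synthetic_exo_panel_separates_fractions(self, study, study_stats):
        """A panel of EXO-class proteins shows clearly unequal fsEV vs flEV."""
        stats = study_stats["stats"]
        truth = study.protein_class.reindex(stats.index)
        exo = tuple(stats.index[truth == "EXO"][:10])
        bg = tuple(stats.index[truth == "BACKGROUND"][:10])
        _, tests = marker_panel_report(
            stats, [MarkerPanel("exo", "EXOSOME", exo), MarkerPanel("bg", "ECTOSOME", bg)]
        )
        assert tests.set_index("panel").loc["exo", "p"] < 0.01
        exo_med = stats.loc[list(exo), "log2_ratio"].abs().median()
        bg_med = stats.loc[list(bg), "log2_ratio"].abs().median()
        assert bg_med < exo_med


class TestPartition:
    def test_boundaries(self):
        stats = pd.DataFrame(
            {"log2_ratio": [0.0, 0.1, 0.11, -0.1, -0.11, 2.807]},
            index=list("ABCDEF"),
        )
        part = partition_by_ratio(stats)
        assert part.tolist() == [
            "BALANCED", "BALANCED", "SEV_ENRICHED",
            "BALANCED", "LEV_ENRICHED", "SEV_ENRICHED",
        ]

    def test_invalid_theta(self, study_stats):
        with pytest.raises(ValueError):
            partition_by_ratio(study_stats["stats"], theta=0.0)

    def test_partition_is_exhaustive(self, study_stats):
        part = study_stats["partition"]
        assert part.notna().all()
        assert part.value_counts().sum() == len(study_stats["stats"])

    def test_exo_class_lands_sev_enriched(self, study, study_stats):
        truth = study.protein_class.reindex(study_stats["stats"].index)
        exo_part = study_stats["partition"][truth == "EXO"]
        assert (exo_part == "SEV_ENRICHED").mean() >= 0.90
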