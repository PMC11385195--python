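"""Target scoring, standardization, target calls, and guide assignment."""

import itertools
import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irimap import (
    DifferentialTable,
    TargetScoreMatrix,
    assign_guides,
    call_targets,
    collapse_umis_hamming1,
    compute_target_score,
    cpm_filter,
    perturbation_scores,
    standardize_columns,
    two_group_scores,
)
from irimap.errors import ConfigError, DomainError


def _table(rows, modality="eclip"):
    return DifferentialTable(
        pd.DataFrame(rows, columns=["rbp", "feature", "p_value", "log2fc"]), modality
    )


class TestComputeTargetScore:
    @pytest.mark.parametrize(
        "p,lfc,expected",
        [
            (0.01, 2.0, 2.0),
            (1.0, -5.0, 0.0),
            (0.001, -0.5, -3.0),
            (0.1, 0.0, 0.0),
        ],
    )
    def test_signed_log10_examples(self, p, lfc, expected):
        assert compute_target_score(p, lfc) == pytest.approx(expected)

    def test_domain_error_outside_unit_interval(self):
        for bad in (0.0, -0.1, 1.0001):
            with pytest.raises(DomainError):
                compute_target_score(bad, 1.0)

    @settings(max_examples=50, deadline=None)
    @given(
        p=st.floats(1e-12, 1.0),
        q=st.floats(1e-12, 1.0),
        lfc=st.floats(0.01, 10),
    )
    def test_odd_in_sign_and_increasing_in_significance(self, p, q, lfc):
        assert compute_target_score(p, lfc) == pytest.approx(-compute_target_score(p, -lfc))
        lo, hi = max(p, q), min(p, q)
        assert compute_target_score(hi, lfc) >= compute_target_score(lo, lfc)


class TestStandardize:
    def test_column_closed_form(self):
        m = TargetScoreMatrix(
            pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=["a", "b", "c"]), "eclip"
        )
        z = standardize_columns(m)
        assert np.allclose(z.values["f"], [-1.22474487, 0.0, 1.22474487])

    def test_constant_column_maps_to_zero(self):
        m = TargetScoreMatrix(
            pd.DataFrame({"f": [5.0, 5.0, 5.0], "g": [0.0, 1.0, 2.0]}, index=list("abc")),
            "eclip",
        )
        z = standardize_columns(m)
        assert np.allclose(z.values["f"], 0.0)

    def test_idempotent_on_non_constant_columns(self, rng):
        m = TargetScoreMatrix(
            pd.DataFrame(rng.standard_normal((6, 4)), index=list("abcdef")), "bioid"
        )
        once = standardize_columns(m)
        twice = standardize_columns(once)
        assert np.allclose(once.values, twice.values)
        assert np.allclose(once.values.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(once.values.std(axis=0, ddof=0), 1.0)

    def test_single_row_rejected(self):
        m = TargetScoreMatrix(pd.DataFrame({"f": [1.0]}, index=["a"]), "eclip")
        with pytest.raises(DomainError):
            standardize_columns(m)


class TestCpmFilter:
    def _counts(self, genes):
        # 3 samples, equal library size 1e6 so cpm == count
        df = pd.DataFrame(genes, index=["s1", "s2", "s3"])
        df["filler"] = 1_000_000 - df.sum(axis=1)
        return df

    def test_kept_and_dropped_genes(self):
        counts = self._counts({"g1": [3, 3, 0], "g2": [3, 0, 0]})
        kept = cpm_filter(counts, min_cpm=2, min_samples=2)
        assert "g1" in kept and "g2" not in kept

    def test_min_samples_zero_keeps_everything(self):
        counts = self._counts({"g1": [0, 0, 0], "g2": [1, 0, 0]})
        kept = cpm_filter(counts, min_cpm=2, min_samples=0)
        assert set(kept) >= {"g1", "g2"}

    def test_zero_total_sample_named(self):
        counts = pd.DataFrame({"g1": [5, 0]}, index=["ok", "empty"])
        with pytest.raises(DomainError, match="empty"):
            cpm_filter(counts)


class TestCallTargets:
    def test_single_feature_bh_is_identity(self):
        calls = call_targets(_table([("A", "f", 0.01, 1.0)]), 0.05, 0.5)
        assert calls["A"] == frozenset({"f"})

    def test_lfc_filter_blocks_significant_feature(self):
        calls = call_targets(_table([("A", "f", 0.01, 0.4)]), 0.05, 0.5)
        assert calls["A"] == frozenset()

    def test_uniform_grid_matches_brute_force_bh(self):
        # p = k/20: the brute-force step-up adjusts every value to 1, so no
        # feature can pass any usual FDR level despite p_(1) = 0.05.
        rows = [("A", f"f{k}", k / 20, 1.0) for k in range(1, 21)]
        expected = _brute_force_bh([k / 20 for k in range(1, 21)], 0.05)
        assert expected == set()
        assert call_targets(_table(rows), 0.05, 0.5)["A"] == frozenset()

    def test_matches_brute_force_bh_on_random_pvalues(self, rng):
        p = rng.uniform(size=40) ** 3
        rows = [("A", f"f{i}", float(pi), 1.0) for i, pi in enumerate(p)]
        expected = {f"f{i}" for i in _brute_force_bh(list(p), 0.05)}
        assert call_targets(_table(rows), 0.05, 0.5)["A"] == frozenset(expected)

    def test_monotone_in_fdr_and_antimonotone_in_lfc(self, rng):
        rows = [
            ("A", f"f{i}", float(p), float(l))
            for i, (p, l) in enumerate(zip(rng.uniform(size=60) ** 2, rng.normal(1, 1, 60)))
        ]
        t = _table(rows)
        loose = call_targets(t, 0.2, 0.5)["A"]
        tight = call_targets(t, 0.01, 0.5)["A"]
        assert tight <= loose
        low_lfc = call_targets(t, 0.05, 0.1)["A"]
        high_lfc = call_targets(t, 0.05, 1.5)["A"]
        assert high_lfc <= low_lfc

    def test_empty_table_gives_empty_calls(self):
        empty = DifferentialTable(
            pd.DataFrame(columns=["rbp", "feature", "p_value", "log2fc"]), "eclip"
        )
        assert call_targets(empty) == {}


def _brute_force_bh(pvalues, alpha):
    """Step-up BH by definition: indices of rejected hypotheses."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    k_max = 0
    for rank, i in enumerate(order, start=1):
        if pvalues[i] <= rank * alpha / m:
            k_max = rank
    return set(order[:k_max])


class TestGuideAssignment:
    def test_five_umis_one_guide_assigned(self):
        rows = pd.DataFrame(
            [("AAAACCCC", u, "g1") for u in ["AAAAAA", "CCCCCC", "GGGGGG", "TTTTTT", "ACGTAC"]],
            columns=["cell_barcode", "umi", "guide"],
        )
        assert assign_guides(rows) == {"AAAACCCC": "g1"}

    def test_eighty_percent_exactly_is_unassigned(self):
        umis = ["AAATTT", "CCCGGG", "GGGCCC", "TTTAAA", "ACACAC",
                "GTGTGT", "CACACA", "TGTGTG", "AACCGG", "TTGGCC"]
        rows = [("AAAACCCC", u, "g1") for u in umis[:8]]
        rows += [("AAAACCCC", u, "g2") for u in umis[8:]]
        df = pd.DataFrame(rows, columns=["cell_barcode", "umi", "guide"])
        assert assign_guides(df) == {"AAAACCCC": None}

    def test_four_umis_unassigned(self):
        rows = pd.DataFrame(
            [("AAAACCCC", u, "g1") for u in ["AAAAAA", "CCCCCC", "GGGGGG", "TTTTTT"]],
            columns=["cell_barcode", "umi", "guide"],
        )
        assert assign_guides(rows) == {"AAAACCCC": None}

    def test_hamming1_pair_counts_as_one_umi(self):
        counts = collapse_umis_hamming1({"AAAA": Counter({"g": 2}), "AAAT": Counter({"g": 1})})
        assert len(counts) == 1
        assert counts["AAAA"]["g"] == 3

    def test_malformed_barcode_rows_rejected(self):
        rows = pd.DataFrame(
            [("AAAA-BAD", "AAAAAA", "g1")] +
            [("AAAACCCC", u, "g1") for u in ["AAAAAA", "CCCCCC", "GGGGGG", "TTTTTT", "ACGTAC"]],
            columns=["cell_barcode", "umi", "guide"],
        )
        assert assign_guides(rows) == {"AAAACCCC": "g1"}

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_hamming_collapse_is_order_independent(self, seed):
        rng = np.random.default_rng(seed)
        umis = ["".join(rng.choice(list("ACGT"), 4)) for _ in range(12)]
        reads = {u: Counter({"g": int(rng.integers(1, 5))}) for u in set(umis)}
        base = collapse_umis_hamming1(reads)
        shuffled_keys = list(reads)
        rng.shuffle(shuffled_keys)
        shuffled = {u: reads[u] for u in shuffled_keys}
        assert set(collapse_umis_hamming1(shuffled)) == set(base)


class TestPerturbationScores:
    def test_welch_t_matches_hand_computation(self):
        # KD (1,2,3) vs control (4,5,6): equal variances s^2=1, n=3 each
        kd = np.array([[1.0], [2.0], [3.0]])
        ctrl = np.array([[4.0], [5.0], [6.0]])
        p, ts = two_group_scores(kd, ctrl)
        se = math.sqrt(1 / 3 + 1 / 3)
        t_stat = (2.0 - 5.0) / se
        from scipy import stats as sps

        df = (1 / 3 + 1 / 3) ** 2 / ((1 / 3) ** 2 / 2 + (1 / 3) ** 2 / 2)
        expected_p = 2 * sps.t.sf(abs(t_stat), df)
        assert p[0] == pytest.approx(expected_p)
        assert ts[0] == pytest.approx(-(-math.log10(expected_p)))

    def test_silenced_gene_gets_large_negative_ts(self, rng):
        counts = pd.DataFrame(
            {
                "gene": np.concatenate([rng.poisson(50, 20), np.zeros(20, dtype=int)]),
                "other": rng.poisson(10, 40),
            },
            index=[f"c{i}" for i in range(40)],
        )
        assignment = {f"c{i}": ("nt" if i < 20 else "kd") for i in range(40)}
        ts = perturbation_scores(counts, assignment, "nt")
        assert ts.values.loc["kd", "gene"] < -5

    def test_null_groups_give_uniform_pvalues(self):
        from scipy import stats as sps

        rng = np.random.default_rng(0)
        case = rng.normal(0, 1, size=(30, 1500))
        ctrl = rng.normal(0, 1, size=(30, 1500))
        p, _ = two_group_scores(case, ctrl)
        assert sps.kstest(p, "uniform").pvalue > 0.01

    def test_insufficient_control_cells_raise(self):
        counts = pd.DataFrame({"g": [1, 2, 3]}, index=["a", "b", "c"])
        with pytest.raises(ConfigError):
            perturbation_scores(counts, {"a": "nt", "b": "kd", "c": "kd"}, "nt")
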