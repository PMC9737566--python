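"""CV, Kruskal-Wallis (with brute-force and permutation oracles),
the step-down letter procedure, and the summary tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from seedshape.stats import (SeedGroupComparison, campbell_skillings,
                             coefficient_of_variation, kruskal_wallis,
                             kruskal_wallis_exact, summarize)


def brute_force_h(groups):
    """Independent midrank H oracle: explicit sorting, textbook formula."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    n = len(pooled)
    start, h = 0, 0.0
    for g in groups:
        h += ranks[start:start + len(g)].sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - ((counts**3 - counts).sum() / (n**3 - n))
    return h / tie if tie > 0 else 0.0


class TestCV:
    def test_formula(self):
        assert coefficient_of_variation([2, 4, 4, 4, 5, 5, 7, 9]) == \
            pytest.approx(42.7618, abs=1e-3)

    def test_mean50_sd5(self):
        # values constructed to have mean 50, sample SD 5
        assert coefficient_of_variation([45, 50, 55]) == \
            pytest.approx(10.0, abs=1e-12)

    def test_constant_list(self):
        assert coefficient_of_variation([3.2, 3.2, 3.2]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([1.0])
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


class TestKruskalWallis:
    def test_hand_oracle(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(3.857142857, abs=1e-3)
        assert 0 < p < 0.05

    def test_identical_groups(self):
        assert kruskal_wallis([[1, 1, 1], [1, 1], [1]]) == (0.0, 1.0)

    def test_tie_correction_bounded(self):
        h, _ = kruskal_wallis([[1, 1, 1], [1, 1, 2]])
        assert np.isfinite(h)
        assert h == pytest.approx(brute_force_h([[1, 1, 1], [1, 1, 2]]),
                                  abs=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            k = rng.integers(2, 5)
            groups = [rng.integers(0, 6, rng.integers(1, 9)).tolist()
                      for _ in range(k)]
            if all(v == groups[0][0] for g in groups for v in g):
                continue
            h, _ = kruskal_wallis(groups)
            assert h == pytest.approx(brute_force_h(groups), abs=1e-9)

    def test_exact_permutation_validates_chi2_roughly(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(0, 1, 4).tolist(),
                  rng.normal(0, 1, 4).tolist(),
                  rng.normal(0, 1, 4).tolist()]
        h, p_exact = kruskal_wallis_exact(groups)
        _, p_chi2 = kruskal_wallis(groups)
        assert abs(p_exact - p_chi2) < 0.12

    def test_exact_rejects_large_n(self):
        with pytest.raises(ValueError, match="exact"):
            kruskal_wallis_exact([list(range(10)), list(range(10))])


class TestCampbellSkillings:
    def test_well_separated_singletons(self):
        comp = campbell_skillings({
            "low": list(range(1, 11)),
            "mid": list(range(101, 111)),
            "high": list(range(201, 211)),
        })
        assert comp.subsets == [("low",), ("mid",), ("high",)]
        assert comp.letters == {"low": "a", "mid": "b", "high": "c"}

    def test_identical_groups_share_letter(self):
        rng = np.random.default_rng(7)  # seed with accepting omnibus
        comp = campbell_skillings({g: rng.normal(0, 1, 20) for g in "wxyz"})
        assert not comp.significant
        assert len(comp.subsets) == 1
        assert set(comp.letters.values()) == {"a"}

    def test_k2_reduces_to_single_kw(self):
        a, b = [1, 3, 5, 7], [2, 4, 6, 8]
        comp = campbell_skillings({"a": a, "b": b})
        h, p = kruskal_wallis([a, b])
        assert comp.h == pytest.approx(h)
        assert comp.p == pytest.approx(p)

    def test_letters_reconstruct_subsets(self):
        rng = np.random.default_rng(21)
        comp = campbell_skillings({
            "g1": rng.normal(0, 1, 15), "g2": rng.normal(0.5, 1, 15),
            "g3": rng.normal(1.0, 1, 15), "g4": rng.normal(5.0, 1, 15),
        })
        # shared letter <-> co-membership in some homogeneous subset
        for a in comp.groups:
            for b in comp.groups:
                share = bool(set(comp.letters[a]) & set(comp.letters[b]))
                together = any(a in s and b in s for s in comp.subsets)
                assert share == together

    def test_subsets_contiguous_in_rank_order(self):
        rng = np.random.default_rng(2)
        comp = campbell_skillings({
            f"g{i}": rng.normal(i * 0.6, 1, 12) for i in range(5)})
        pos = {g: i for i, g in enumerate(comp.groups)}
        for s in comp.subsets:
            idx = sorted(pos[g] for g in s)
            assert idx == list(range(idx[0], idx[-1] + 1))

    def test_no_split_without_omnibus_rejection(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            comp = campbell_skillings(
                {g: rng.normal(0, 1, 10) for g in "abcd"})
            if not comp.significant:
                assert len(comp.subsets) == 1

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="empty"):
            campbell_skillings({"a": [1, 2], "b": []})


class TestSummarize:
    def test_single_species_min_equals_max(self):
        df = pd.DataFrame({
            "species": ["sp"] * 3, "view": ["lateral"] * 3,
            "A": [1.0, 1.2, 1.4], "C": [0.9, 0.8, 0.7],
        })
        out = summarize(df, view="lateral")
        assert out.loc["A", "min"] == out.loc["A", "max"] == \
            pytest.approx(1.2)
        assert out.loc["A", "min_species"] == "sp"

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame())

    def test_unknown_view_errors(self):
        df = pd.DataFrame({"species": ["s"], "view": ["lateral"], "A": [1.0]})
        with pytest.raises(ValueError, match="no rows"):
            summarize(df, view="dorsal")


class TestModelResults:
    def test_fit_produces_consistent_tables(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({
            "group": np.repeat(["x", "y", "z"], 15),
            "C": np.concatenate([rng.normal(0.5, 0.05, 15),
                                 rng.normal(0.7, 0.05, 15),
                                 rng.normal(0.9, 0.05, 15)]),
            "S": rng.normal(0.95, 0.01, 45),
        })
        res = SeedGroupComparison(df, descriptors=["C", "S"]).fit()
        tidy = res.tidy()
        assert set(tidy["descriptor"]) == {"C", "S"}
        assert res.comparisons["C"].significant
        assert "S" in res.excluded or res.comparisons["S"].significant
        assert "alpha" in res.summary()
        js = res.to_json_dict()
        assert js["C"]["letters"] == res.letters("C")

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            SeedGroupComparison(pd.DataFrame())
        with pytest.raises(ValueError):
            SeedGroupComparison(pd.DataFrame({"C": [1.0]}))
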