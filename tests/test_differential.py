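"""Per-site pooled-variance t-test, composite calling rule, protein
ranking and domain mapping, each checked against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from redoxome import differential
from redoxome.differential import (
    call_increased_oxidation,
    map_sites_to_domains,
    rank_proteins,
)
from redoxome.errors import (
    AnnotationError,
    EmptyResultError,
    InsufficientReplicatesError,
)
from redoxome.io import DomainAnnotation, DomainInterval


class TestTestSite:
    def test_worked_example_pooled_t_on_four_df(self):
        delta, rel, p = differential.test_site([10, 11, 12], [13, 14, 15])
        assert delta == pytest.approx(3.0)
        assert rel == pytest.approx(3 / 11)
        # t = 3 / sqrt(2/3) = 3.6742 on 4 df
        assert p == pytest.approx(0.0213116411, abs=1e-9)

    def test_identical_groups_give_p_one(self):
        delta, rel, p = differential.test_site([5, 6, 7], [5, 6, 7])
        assert delta == 0.0 and p == 1.0

    def test_zero_variance_different_means_give_p_zero(self):
        _, _, p = differential.test_site([5, 5], [9, 9])
        assert p == 0.0

    def test_zero_control_mean_gives_infinite_relative_increase(self):
        _, rel, _ = differential.test_site([0, 0], [2, 4])
        assert rel == math.inf

    def test_both_groups_zero_give_zero_relative_increase(self):
        _, rel, p = differential.test_site([0, 0], [0, 0])
        assert rel == 0.0 and p == 1.0

    def test_single_replicate_rejected(self):
        with pytest.raises(InsufficientReplicatesError):
            differential.test_site([1.0], [2.0, 3.0])

    def test_agrees_with_scipy_students_t_on_random_sites(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.normal(10, 2, size=rng.integers(3, 9))
            b = rng.normal(11, 2, size=rng.integers(3, 9))
            delta, _, p = differential.test_site(a, b)
            ref = stats.ttest_ind(b, a, equal_var=True)
            assert delta == pytest.approx(b.mean() - a.mean(), rel=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)


def _random_results(n, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "delta_abs": rng.normal(0, 10, n),
            "rel_increase": rng.normal(0.3, 0.3, n),
            "p_value": rng.uniform(size=n),
        },
        index=pd.Index([f"P{i:03d}:10" for i in range(n)], name="site_id"),
    )


def naive_calls(df, alpha, rel_min, top_frac):
    """Brute-force reimplementation of the three-criterion rule."""
    order = sorted(df.index, key=lambda s: (-df.at[s, "delta_abs"], s))
    top = set(order[: math.ceil(top_frac * len(df))])
    return {
        s
        for s in df.index
        if df.at[s, "p_value"] < alpha
        and df.at[s, "rel_increase"] >= rel_min
        and s in top
    }


class TestCalling:
    def test_top_set_size_is_ceiling_of_fraction(self):
        out = call_increased_oxidation(_random_results(100, 0))
        assert out["in_top_set"].sum() == 15

    def test_composite_criteria(self):
        df = pd.DataFrame(
            {
                "delta_abs": [50.0, 49.0, 1.0],
                "rel_increase": [0.30, 0.20, 0.40],
                "p_value": [0.04, 0.04, 0.01],
            },
            index=pd.Index(["A:1", "B:1", "C:1"], name="site_id"),
        )
        out = call_increased_oxidation(df, top_frac=0.5)
        # top set = {A:1, B:1}; A passes all three, B fails rel_min,
        # C passes p and rel but is outside the top set
        assert list(out.loc[["A:1", "B:1", "C:1"], "called"]) == [True, False, False]

    def test_matches_naive_reimplementation_exactly(self):
        df = _random_results(50, seed=3)
        out = call_increased_oxidation(df, alpha=0.05, rel_min=0.25, top_frac=0.15)
        assert set(out.index[out["called"]]) == naive_calls(df, 0.05, 0.25, 0.15)

    @pytest.mark.parametrize(
        "loose", [{"alpha": 0.2}, {"rel_min": 0.1}, {"top_frac": 0.4}]
    )
    def test_loosening_any_criterion_never_shrinks_call_set(self, loose):
        df = _random_results(200, seed=5)
        strict = dict(alpha=0.05, rel_min=0.25, top_frac=0.15)
        base = call_increased_oxidation(df, **strict)
        wide = call_increased_oxidation(df, **{**strict, **loose})
        assert set(base.index[base["called"]]) <= set(wide.index[wide["called"]])

    def test_boundary_ties_broken_by_site_id(self):
        df = pd.DataFrame(
            {
                "delta_abs": [5.0, 5.0, 5.0, 1.0],
                "rel_increase": [1.0] * 4,
                "p_value": [0.01] * 4,
            },
            index=pd.Index(["B:1", "A:1", "C:1", "D:1"], name="site_id"),
        )
        out = call_increased_oxidation(df, top_frac=0.5)  # top 2 of 4
        assert set(out.index[out["in_top_set"]]) == {"A:1", "B:1"}

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyResultError):
            call_increased_oxidation(_random_results(0, 0))


class TestProteinRanking:
    def _results(self, counts):
        rows = []
        for acc, n in counts.items():
            for i in range(n):
                rows.append({"site_id": f"{acc}:{i + 1}", "called": True})
        return pd.DataFrame(rows).set_index("site_id")

    def test_sort_by_count_then_accession(self):
        ranks = rank_proteins(self._results({"B": 2, "A": 10, "C": 2}))
        assert list(ranks.protein_accession) == ["A", "B", "C"]
        assert list(ranks["rank"]) == [1, 2, 3]
        assert list(ranks.n_called_sites) == [10, 2, 2]

    def test_no_called_sites_gives_empty_ranking(self):
        df = pd.DataFrame(
            {"called": [False]}, index=pd.Index(["A:1"], name="site_id")
        )
        assert len(rank_proteins(df)) == 0


class TestDomainMapping:
    def _annot(self):
        return DomainAnnotation(
            [
                DomainInterval("P1", "ketosynthase", 40, 60),
                DomainInterval("P1", "thioesterase", 61, 90),
            ]
        )

    def test_site_inside_interval_gets_its_label(self):
        df, counts = map_sites_to_domains(["P1:50"], self._annot())
        assert df.domain_label.tolist() == ["ketosynthase"]
        assert counts["ketosynthase"] == 1

    def test_interval_ends_are_inclusive(self):
        df, _ = map_sites_to_domains(["P1:60", "P1:61"], self._annot())
        assert df.domain_label.tolist() == ["ketosynthase", "thioesterase"]

    def test_uncovered_site_is_unannotated(self):
        df, _ = map_sites_to_domains(["P1:95"], self._annot())
        assert df.domain_label.tolist() == ["unannotated"]

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(AnnotationError):
            DomainAnnotation(
                [
                    DomainInterval("P1", "a", 40, 60),
                    DomainInterval("P1", "b", 55, 70),
                ]
            )
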