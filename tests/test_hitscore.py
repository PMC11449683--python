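import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acidep import (
    AnnEntry,
    ConfigError,
    DataError,
    PrognosticAnnotation,
    StageAnnotation,
    filter_by_hit_rate,
    gene_hit_rate,
    hit_matrix,
    is_hit,
    is_inverted_hit,
    rank_tumors,
    score_tumor,
    stage_concordance,
)


UNFAV = AnnEntry("unfavorable", True)
FAV = AnnEntry("favorable", True)
NONE = AnnEntry("none", False)


class TestHitPredicates:
    def test_induced_unfavorable_significant_is_hit(self):
        assert is_hit("induced", UNFAV)

    def test_reduced_favorable_significant_is_hit(self):
        assert is_hit("reduced", FAV)

    def test_discordant_direction_is_not_strict_hit(self):
        assert not is_hit("induced", FAV)
        assert not is_hit("reduced", UNFAV)

    def test_insignificant_entry_is_not_hit(self):
        assert not is_hit("induced", AnnEntry("unfavorable", False))

    def test_missing_entry_is_not_hit(self):
        assert not is_hit("induced", None)

    def test_inversion_within_tolerance(self):
        assert is_inverted_hit("induced", AnnEntry("favorable", True, 0.10), 0.20)

    def test_inversion_outside_tolerance(self):
        assert not is_inverted_hit("induced", AnnEntry("favorable", True, 0.30), 0.20)

    def test_zero_tolerance_needs_zero_magnitude(self):
        assert not is_inverted_hit("induced", AnnEntry("favorable", True, 0.01), 0.0)
        assert is_inverted_hit("induced", AnnEntry("favorable", True, 0.0), 0.0)

    def test_missing_magnitude_counts_false(self):
        assert not is_inverted_hit("induced", AnnEntry("favorable", True, None), 0.2)

    def test_concordant_entry_is_not_inverted(self):
        assert not is_inverted_hit("induced", AnnEntry("unfavorable", True, 0.1), 0.2)


def build_annotation(spec: dict[tuple[str, str], AnnEntry]) -> PrognosticAnnotation:
    return PrognosticAnnotation(dict(spec))


class TestScoreTumor:
    def test_enumerated_mixed_tallies(self):
        # 5 induced genes: 3 unfavorable-sig, 1 favorable-sig mag 0.1, 1 none
        ann = build_annotation({
            ("g1", "t"): UNFAV, ("g2", "t"): UNFAV, ("g3", "t"): UNFAV,
            ("g4", "t"): AnnEntry("favorable", True, 0.1),
            ("g5", "t"): NONE,
        })
        res = score_tumor([f"g{i}" for i in range(1, 6)], [], ann, "t", tol=0.2)
        assert res.hits_induced_strict == 3
        assert res.hits_induced_tolerant == 4
        assert res.total_strict == 3 and res.total_tolerant == 4

    def test_saturation_on_fully_concordant_lists(self):
        induced = [f"i{k}" for k in range(100)]
        reduced = [f"r{k}" for k in range(100)]
        ann = build_annotation(
            {(g, "t"): UNFAV for g in induced} | {(g, "t"): FAV for g in reduced}
        )
        res = score_tumor(induced, reduced, ann, "t")
        assert res.total_strict == 200
        assert res.dominance == "balanced"

    def test_empty_lists_give_zero_result(self):
        res = score_tumor([], [], build_annotation({}), "t")
        assert res.total_strict == res.total_tolerant == 0

    def test_unannotated_tumor_gives_zero_and_missing(self):
        ann = build_annotation({("g1", "other"): UNFAV})
        res = score_tumor(["g1"], [], ann, "t")
        assert res.total_strict == 0 and res.n_missing == 1

    def test_dominance_typing(self):
        ann = build_annotation({
            ("i1", "t"): UNFAV, ("i2", "t"): UNFAV, ("r1", "t"): FAV,
        })
        res = score_tumor(["i1", "i2"], ["r1", "r2"], ann, "t")
        assert res.dominance == "induced_type"
        ann2 = build_annotation({
            ("i1", "t"): UNFAV, ("r1", "t"): FAV, ("r2", "t"): FAV,
        })
        flipped = score_tumor(["i1"], ["r1", "r2"], ann2, "t")
        assert flipped.dominance == "reduced_type"

    def test_dominance_margin_widens_balanced_band(self):
        ann = build_annotation({
            ("i1", "t"): UNFAV, ("i2", "t"): UNFAV, ("r1", "t"): FAV,
        })
        res = score_tumor(["i1", "i2"], ["r1"], ann, "t", dominance_margin=1)
        assert res.dominance == "balanced"

    @settings(max_examples=100, deadline=None)
    @given(
        tol1=st.floats(0, 1), tol2=st.floats(0, 1),
        mags=st.lists(st.floats(0, 1), min_size=1, max_size=20),
    )
    def test_tolerant_tally_monotone_in_tol(self, tol1, tol2, mags):
        lo, hi = sorted([tol1, tol2])
        induced = [f"g{i}" for i in range(len(mags))]
        ann = build_annotation({
            (g, "t"): AnnEntry("favorable", True, m) for g, m in zip(induced, mags)
        })
        res_lo = score_tumor(induced, [], ann, "t", tol=lo)
        res_hi = score_tumor(induced, [], ann, "t", tol=hi)
        assert res_lo.total_tolerant <= res_hi.total_tolerant
        assert res_lo.total_tolerant >= res_lo.total_strict

    @settings(max_examples=50, deadline=None)
    @given(st.lists(
        st.tuples(
            st.sampled_from(["unfavorable", "favorable", "none"]),
            st.booleans(),
            st.one_of(st.none(), st.floats(0, 1)),
        ),
        min_size=1, max_size=30,
    ))
    def test_role_direction_flip_symmetry(self, entry_specs):
        genes = [f"g{i}" for i in range(len(entry_specs))]
        flip = {"unfavorable": "favorable", "favorable": "unfavorable", "none": "none"}

        def entry(direction, sig, mag):
            sig = sig and direction != "none"
            return AnnEntry(direction, sig, mag)

        ann = build_annotation({
            (g, "t"): entry(d, s, m) for g, (d, s, m) in zip(genes, entry_specs)
        })
        ann_flipped = build_annotation({
            (g, "t"): entry(flip[d], s, m) for g, (d, s, m) in zip(genes, entry_specs)
        })
        as_induced = score_tumor(genes, [], ann, "t")
        as_reduced = score_tumor([], genes, ann_flipped, "t")
        assert as_induced.hits_induced_strict == as_reduced.hits_reduced_strict
        assert as_induced.hits_induced_tolerant == as_reduced.hits_reduced_tolerant


class TestRankingAndRates:
    def _results(self):
        ann = build_annotation(
            {("g1", "tA"): UNFAV, ("g2", "tA"): UNFAV, ("g1", "tB"): UNFAV}
            | {("g1", "tC"): NONE, ("g2", "tC"): NONE}
        )
        return [
            score_tumor(["g1", "g2"], [], ann, t) for t in ("tA", "tB", "tC")
        ]

    def test_ranking_descends_by_strict_total(self):
        df = rank_tumors(self._results())
        assert list(df["tumor_type"]) == ["tA", "tB", "tC"]
        assert list(df["total_strict"]) == [2, 1, 0]

    def test_tied_totals_order_by_name(self):
        ann = build_annotation({("g1", "tB"): UNFAV, ("g1", "tA"): UNFAV})
        results = [score_tumor(["g1"], [], ann, t) for t in ("tB", "tA")]
        assert list(rank_tumors(results)["tumor_type"]) == ["tA", "tB"]

    def test_empty_results_is_error(self):
        with pytest.raises(DataError):
            rank_tumors([])

    def test_gene_hit_rate_boundaries(self):
        results = self._results()
        assert gene_hit_rate("g1", results) == pytest.approx(2 / 3)
        assert gene_hit_rate("g2", results) == pytest.approx(1 / 3)
        assert gene_hit_rate("gX", results) == 0.0

    def test_filter_keeps_boundary_rate(self):
        results = self._results()
        # g1 hit in 2/3 tumors, g2 in 1/3; min_rate 1/3 keeps both (>=)
        assert filter_by_hit_rate(["g1", "g2"], results, min_rate=2 / 3) == ["g1"]
        assert filter_by_hit_rate(["g1", "g2"], results, min_rate=1 / 3) == ["g1", "g2"]

    def test_hit_matrix_statuses(self):
        results = self._results()
        hm = hit_matrix(results)
        assert hm.loc[("induced", "g1"), "tA"] == "hit"
        assert hm.loc[("induced", "g2"), "tB"] == "missing"
        assert hm.loc[("induced", "g2"), "tC"] == "miss"


class TestStageConcordance:
    def _stage_ann(self, gene, concordant_tumors, total=7):
        entries = {}
        for i in range(total):
            trend = "late_stage_high" if i < concordant_tumors else "none"
            entries[(gene, f"t{i}")] = (trend, i < concordant_tumors)
        return StageAnnotation(entries)

    def test_four_of_seven(self):
        ann = self._stage_ann("PRRX2", 4)
        df = stage_concordance(["PRRX2"], ann, {"PRRX2": "induced"})
        assert df.loc["PRRX2", "concordant"] == 4
        assert df.loc["PRRX2", "evaluated"] == 7

    def test_no_significant_trends(self):
        ann = self._stage_ann("g", 0)
        df = stage_concordance(["g"], ann, {"g": "induced"})
        assert df.loc["g", "concordant"] == 0 and df.loc["g", "evaluated"] == 7

    def test_all_concordant(self):
        ann = self._stage_ann("g", 7)
        df = stage_concordance(["g"], ann, {"g": "induced"})
        assert df.loc["g", "concordant"] == 7

    def test_reduced_role_needs_low_trend(self):
        ann = StageAnnotation({("g", "t0"): ("late_stage_low", True)})
        df = stage_concordance(["g"], ann, {"g": "reduced"})
        assert df.loc["g", "concordant"] == 1
        df2 = stage_concordance(["g"], ann, {"g": "induced"})
        assert df2.loc["g", "concordant"] == 0

    def test_unannotated_gene_gets_zero_of_zero(self):
        ann = self._stage_ann("other", 3)
        df = stage_concordance(["g"], ann, {"g": "induced"})
        assert df.loc["g", "evaluated"] == 0

    def test_missing_role_is_error(self):
        with pytest.raises(ConfigError):
            stage_concordance(["g"], StageAnnotation({}), {})


class TestAnnotationIO:
    def test_prognostic_round_trip(self, tmp_path):
        ann = build_annotation({
            ("g1", "breast"): AnnEntry("unfavorable", True, 0.3),
            ("g2", "lung"): NONE,
        })
        ann.to_table(tmp_path / "ann.tsv")
        back = PrognosticAnnotation.from_table(tmp_path / "ann.tsv")
        assert back.get("g1", "breast") == AnnEntry("unfavorable", True, 0.3)
        assert back.get("g2", "lung") == NONE

    def test_stage_round_trip(self, tmp_path):
        ann = StageAnnotation({("g1", "breast"): ("late_stage_high", True)})
        ann.to_table(tmp_path / "st.tsv")
        back = StageAnnotation.from_table(tmp_path / "st.tsv")
        assert back.get("g1", "breast") == ("late_stage_high", True)
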