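"""Survey model and importance-value computation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phyloresist import (
    FormatError,
    ValidationError,
    importance_values,
    read_survey,
    stage_mean_iv,
    write_survey,
)
from phyloresist.survey import PlotSurvey, SpeciesRecord

from conftest import make_plot, rec


class TestRecordValidation:
    def test_subplot_hits_cannot_exceed_total(self):
        with pytest.raises(ValidationError):
            rec("x", hits=6, n_subplots=5)

    def test_zero_count_rejected(self):
        with pytest.raises(ValidationError):
            rec("x", count=0)

    def test_negative_dominance_rejected(self):
        with pytest.raises(ValidationError):
            rec("x", dominance=-1)

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValidationError):
            make_plot("p1", "XX", 0.5, [])

    def test_duplicate_species_layer_rejected(self):
        with pytest.raises(ValidationError):
            make_plot("p1", "BF", 0.0, [rec("a"), rec("a")])

    def test_same_species_in_two_layers_is_allowed(self):
        p = make_plot("p1", "BF", 0.0, [rec("a", "tree"), rec("a", "shrub")])
        assert len(p.records) == 2


class TestImportanceValues:
    def test_monoculture_iv_is_100(self):
        p = make_plot("p1", "MB", 1.0, [rec("bamboo", "tree", count=50, dominance=900.0)])
        (iv,) = importance_values(p, "tree")
        assert iv.iv == pytest.approx(100.0)
        assert iv.rel_density == iv.rel_dominance == iv.rel_frequency == 100.0

    def test_two_identical_species_split_evenly(self):
        p = make_plot(
            "p1", "BF", 0.0,
            [rec("a", count=4, dominance=10, hits=2), rec("b", count=4, dominance=10, hits=2)],
        )
        for iv in importance_values(p, "shrub"):
            assert iv.iv == pytest.approx(50.0)

    def test_hand_computed_two_species_example(self):
        # counts 3/1, dominance 10/10, hits 2/2 and 1/2: relD 75/25,
        # relDom 50/50, freq 1.0/0.5 -> relF 200/3 and 100/3
        p = make_plot(
            "p1", "BF", 0.0,
            [
                rec("a", count=3, dominance=10, hits=2, n_subplots=2),
                rec("b", count=1, dominance=10, hits=1, n_subplots=2),
            ],
        )
        iv_a, iv_b = importance_values(p, "shrub")
        assert iv_a.iv == pytest.approx(575.0 / 9.0)
        assert iv_b.iv == pytest.approx(325.0 / 9.0)
        assert iv_a.rel_frequency == pytest.approx(200.0 / 3.0)

    def test_empty_layer_returns_empty_list(self):
        p = make_plot("p1", "BF", 0.0, [rec("a", "tree")])
        assert importance_values(p, "herb") == []

    def test_zero_total_dominance_is_degenerate(self):
        p = make_plot("p1", "BF", 0.0, [rec("a", dominance=0.0), rec("b", dominance=0.0)])
        with pytest.raises(ValidationError):
            importance_values(p, "shrub")

    def test_components_and_iv_each_sum_to_100(self, default_dataset):
        surveys, _, _ = default_dataset
        for plot in surveys:
            for layer in ("tree", "shrub", "herb"):
                ivs = importance_values(plot, layer)
                if not ivs:
                    continue
                for attr in ("rel_density", "rel_dominance", "rel_frequency", "iv"):
                    assert sum(getattr(v, attr) for v in ivs) == pytest.approx(
                        100.0, abs=1e-9
                    )

    def test_record_order_does_not_matter(self):
        records = [
            rec("a", count=3, dominance=5, hits=2),
            rec("b", count=7, dominance=1, hits=4),
            rec("c", count=2, dominance=9, hits=1),
        ]
        base = importance_values(make_plot("p", "BF", 0.0, records), "shrub")
        for perm in itertools.permutations(records):
            ivs = importance_values(make_plot("p", "BF", 0.0, list(perm)), "shrub")
            assert ivs == base

    @given(scale=st.floats(min_value=0.01, max_value=1000.0))
    @settings(max_examples=25, deadline=None)
    def test_dominance_scale_invariance(self, scale):
        records = [rec("a", dominance=3.0), rec("b", dominance=9.0)]
        scaled = [
            rec("a", dominance=3.0 * scale), rec("b", dominance=9.0 * scale)
        ]
        base = importance_values(make_plot("p", "BF", 0.0, records), "shrub")
        after = importance_values(make_plot("p", "BF", 0.0, scaled), "shrub")
        for v0, v1 in zip(base, after):
            assert v1.rel_dominance == pytest.approx(v0.rel_dominance)


class TestReadWrite:
    def test_round_trip_single_plot(self, tmp_path):
        p = make_plot(
            "p1", "LM", 0.3,
            [rec("a", "tree", count=3, dominance=50.0), rec("b", "tree", count=2, dominance=30.0)],
        )
        path = tmp_path / "s.csv"
        write_survey([p], path)
        (back,) = read_survey(path)
        assert back.plot_id == "p1"
        assert len(back.layer_records("tree")) == 2

    def test_generator_output_round_trips(self, default_dataset, tmp_path):
        surveys, _, _ = default_dataset
        spath, cpath = tmp_path / "s.csv", tmp_path / "c.csv"
        write_survey(surveys, spath, cpath)
        back = read_survey(spath, cpath)
        assert len(back) == 16
        assert sorted(s.stage for s in back).count("BF") == 4
        by_id = {s.plot_id: s for s in surveys}
        for b in back:
            orig = by_id[b.plot_id]
            assert b.stage == orig.stage
            assert b.invader_cover == pytest.approx(orig.invader_cover)
            assert b.soil == pytest.approx(orig.soil)
            assert sorted((r.species, r.layer, r.count) for r in b.records) == sorted(
                (r.species, r.layer, r.count) for r in orig.records
            )

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("plot_id,stage,layer,species,count\np,BF,tree,a,1\n")
        with pytest.raises(FormatError, match="dominance"):
            read_survey(path)

    def test_bad_stage_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "plot_id,stage,layer,species,count,dominance,subplot_hits,n_subplots\n"
            "p,XX,tree,a,1,1.0,1,1\n"
        )
        with pytest.raises(ValidationError):
            read_survey(path)

    def test_duplicate_row_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "plot_id,stage,layer,species,count,dominance,subplot_hits,n_subplots\n"
            "p,BF,tree,a,1,1.0,1,1\np,BF,tree,a,2,1.0,1,1\n"
        )
        with pytest.raises(ValidationError):
            read_survey(path)


class TestStageMeans:
    def _plots(self):
        plots = []
        for i, stage in enumerate(["BF"] * 2 + ["LM"] * 2):
            recs = [rec("a", count=2, dominance=4.0)]
            if stage == "BF":
                recs.append(rec("b", count=2, dominance=4.0))
            plots.append(make_plot(f"p{i}", stage, 0.0 if stage == "BF" else 0.3, recs))
        return plots

    def test_absent_species_contribute_zero(self):
        means = stage_mean_iv(self._plots(), "shrub")
        # b is absent from both LM plots -> mean 0 there
        assert means.loc["b", "LM"] == 0.0
        # in BF, a and b are identical -> both 50
        assert means.loc["b", "BF"] == pytest.approx(50.0)
        # a is alone in LM -> 100
        assert means.loc["a", "LM"] == pytest.approx(100.0)

    def test_means_match_plotwise_enumeration(self, default_dataset):
        surveys, _, _ = default_dataset
        means = stage_mean_iv(surveys, "herb")
        from phyloresist import iv_table

        per_plot = iv_table(surveys, "herb")
        bf_plots = [s.plot_id for s in surveys if s.stage == "BF"]
        sp = means.index[0]
        manual = np.mean([per_plot.loc[p].get(sp, 0.0) for p in bf_plots])
        assert means.loc[sp, "BF"] == pytest.approx(manual)

    def test_rows_sorted_by_overall_mean(self, default_dataset):
        surveys, _, _ = default_dataset
        means = stage_mean_iv(surveys, "shrub")
        overall = means.mean(axis=1).to_numpy()
        assert np.all(np.diff(overall) <= 1e-12)

    def test_unknown_layer_rejected(self):
        with pytest.raises(ValidationError):
            stage_mean_iv(self._plots(), "canopy")
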