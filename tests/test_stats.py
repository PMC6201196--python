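"""Repeat-level aggregation and ANOVA/post-hoc machinery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from nucleomorph import (
    RepeatSummary,
    compare_groups,
    condition_contrast,
    render_report,
    summarize_repeat,
    summarize_table,
)
from nucleomorph.stats import LABEL_COLUMNS, summaries_frame


def _nucleus_rows(n, cr, line="l0", cond="monolayer", rep=1, field="f0", labels=()):
    rows = []
    for i in range(n):
        row = {
            "line_id": line,
            "condition": cond,
            "repeat_id": rep,
            "field_id": field,
            "contour_ratio": cr,
            "major_axis_um": 15.0,
            "touches_border": False,
        }
        for c in LABEL_COLUMNS:
            row[c] = c.removeprefix("label_") in labels
        rows.append(row)
    return rows


def _summary(line, cond, rep, value, n=50):
    return RepeatSummary(
        line_id=line, condition=cond, repeat_id=rep, n_nuclei=n,
        means={"contour_ratio": value}, proportions={"elongated": value},
    )


class TestSummarizeRepeat:
    def test_weighted_mean_of_fields(self):
        # fields of 10 and 30 nuclei with mean CRs 0.8 and 0.9 -> 0.875
        rows = _nucleus_rows(10, 0.8, field="f0") + _nucleus_rows(30, 0.9, field="f1")
        s = summarize_repeat(pd.DataFrame(rows), "l0", "monolayer", 1)
        assert s.means["contour_ratio"] == pytest.approx(0.875)
        assert s.n_nuclei == 40

    def test_all_normal_proportions(self):
        s = summarize_repeat(pd.DataFrame(_nucleus_rows(20, 0.9)), "l0", "m", 1)
        assert s.proportions["normal"] == 1.0
        for name in ("elongated", "blebs", "strings", "jellybean", "severely_deformed"):
            assert s.proportions[name] == 0.0

    def test_multilabel_double_counting(self):
        rows = _nucleus_rows(5, 0.7, labels=("blebs", "elongated"))
        rows += _nucleus_rows(5, 0.9)
        s = summarize_repeat(pd.DataFrame(rows), "l0", "m", 1)
        # class proportions sum past 1 while normal + any_abnormal == 1
        assert s.proportions["blebs"] + s.proportions["elongated"] == pytest.approx(1.0)
        assert s.proportions["normal"] + s.proportions["any_abnormal"] == pytest.approx(1.0)

    def test_border_nuclei_excluded(self):
        rows = _nucleus_rows(10, 0.8)
        border = _nucleus_rows(5, 0.2)
        for r in border:
            r["touches_border"] = True
        s = summarize_repeat(pd.DataFrame(rows + border), "l0", "m", 1)
        assert s.n_nuclei == 10
        assert s.means["contour_ratio"] == pytest.approx(0.8)

    def test_empty_repeat_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            s = summarize_repeat(pd.DataFrame(columns=["touches_border"]), "l0", "m", 1)
        assert s is None

    def test_proportion_recovery_within_binomial_ci(self, mixed_field):
        # recovered abnormal fraction within the exact binomial CI of the draw
        from nucleomorph import analyze_field

        spec, field, truth = mixed_field
        df = analyze_field(field)
        df["line_id"], df["condition"], df["repeat_id"] = "l0", "m", 1
        s = summarize_table(df)[0]
        k = int((~truth.table["is_normal"]).sum())
        n = len(truth.table)
        lo, hi = sp_stats.beta.ppf([0.025, 0.975], [k, k + 1], [n - k + 1, n - k])
        lo = 0.0 if k == 0 else lo
        assert lo <= s.proportions["any_abnormal"] <= hi

    def test_split_field_invariance(self):
        # splitting a field into sub-fields does not change the repeat mean
        rows = _nucleus_rows(12, 0.8, field="f0") + _nucleus_rows(24, 0.95, field="f0")
        merged = summarize_repeat(pd.DataFrame(rows), "l0", "m", 1)
        for i, r in enumerate(rows):
            r["field_id"] = f"f{i % 5}"
        split = summarize_repeat(pd.DataFrame(rows), "l0", "m", 1)
        assert split.means["contour_ratio"] == pytest.approx(
            merged.means["contour_ratio"]
        )

    def test_deformed_pooling_identity(self):
        rows = (
            _nucleus_rows(3, 0.7, labels=("jellybean",))
            + _nucleus_rows(4, 0.7, labels=("severely_deformed",))
            + _nucleus_rows(2, 0.7, labels=("jellybean", "severely_deformed"))
            + _nucleus_rows(11, 0.9)
        )
        df = pd.DataFrame(rows)
        s = summarize_repeat(df, "l0", "m", 1)
        n = len(df)
        n_jelly = int(df["label_jellybean"].sum())
        n_severe = int(df["label_severely_deformed"].sum())
        n_both = int((df["label_jellybean"] & df["label_severely_deformed"]).sum())
        assert s.proportions["deformed"] * n == pytest.approx(
            n_jelly + n_severe - n_both
        )


class TestCompareGroups:
    def test_degenerate_separation(self):
        summaries = [
            _summary(line, "m", r, v)
            for line, v in zip("abcde", (0.1, 0.3, 0.5, 0.7, 0.9))
            for r, v in [(1, v), (2, v), (3, v)]
        ]
        comp = compare_groups(summaries, "contour_ratio", design="one_way")
        assert comp.anova_table.loc["C(line_id)", "PR(>F)"] < 1e-10
        assert (comp.posthoc["p_adj"] < 0.05).all()

    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(300):
            summaries = [
                _summary(line, "m", r, rng.normal(0.8, 0.02))
                for line in ("a", "b")
                for r in (1, 2, 3)
            ]
            comp = compare_groups(summaries, "contour_ratio", design="one_way")
            pvals.append(float(comp.anova_table.loc["C(line_id)", "PR(>F)"]))
        _, p = sp_stats.kstest(pvals, "uniform")
        assert p > 0.01

    def test_needs_two_groups_and_two_repeats(self):
        with pytest.raises(ValueError):
            compare_groups([_summary("a", "m", 1, 0.8)], "contour_ratio")
        with pytest.raises(ValueError):
            compare_groups(
                [_summary("a", "m", 1, 0.8), _summary("b", "m", 1, 0.9)],
                "contour_ratio",
            )

    def test_missing_metric_errors(self):
        summaries = [_summary("a", "m", r, 0.8) for r in (1, 2, 3)]
        summaries += [_summary("b", "m", r, 0.9) for r in (1, 2, 3)]
        with pytest.raises(ValueError, match="metric"):
            compare_groups(summaries, "no_such_metric")

    def test_two_way_empty_cell_named(self):
        summaries = [
            _summary("a", "monolayer", r, 0.8) for r in (1, 2, 3)
        ] + [
            _summary("a", "construct3d", r, 0.7) for r in (1, 2, 3)
        ] + [
            _summary("b", "monolayer", r, 0.85) for r in (1, 2, 3)
        ]
        with pytest.raises(ValueError, match="construct3d"):
            compare_groups(summaries, "contour_ratio", design="two_way")

    def test_unknown_design_rejected(self):
        summaries = [
            _summary(g, "m", r, 0.8) for g in "ab" for r in (1, 2, 3)
        ]
        with pytest.raises(ValueError, match="design"):
            compare_groups(summaries, "contour_ratio", design="three_way")

    def test_repeated_design_runs(self):
        rng = np.random.default_rng(0)
        summaries = [
            _summary(g, c, r, rng.normal(0.8, 0.02))
            for g in "ab"
            for c in ("monolayer", "construct3d")
            for r in (1, 2, 3)
        ]
        comp = compare_groups(summaries, "contour_ratio", design="two_way_repeated")
        assert "C(repeat_id)" in comp.anova_table.index


class TestConditionContrast:
    def test_requires_both_conditions_per_line(self):
        summaries = [_summary("a", "monolayer", r, 0.8) for r in (1, 2, 3)]
        summaries += [_summary("b", "monolayer", r, 0.8) for r in (1, 2, 3)]
        summaries += [_summary("b", "construct3d", r, 0.7) for r in (1, 2, 3)]
        with pytest.raises(ValueError, match="lacks"):
            condition_contrast(summaries, "contour_ratio")

    def test_detects_condition_effect_in_affected_line_only(self):
        rng = np.random.default_rng(3)
        summaries = []
        for line, shift in (("a", 0.25), ("b", 0.0)):
            for cond in ("monolayer", "construct3d"):
                for r in (1, 2, 3):
                    mu = 0.10 + (shift if cond == "construct3d" else 0.0)
                    summaries.append(
                        _summary(line, cond, r, rng.normal(mu, 0.02))
                    )
        comp = condition_contrast(summaries, "elongated")
        sidak = comp.posthoc[comp.posthoc["method"] == "sidak"].set_index("group")
        assert sidak.loc["a", "p_adj"] < 0.05
        assert sidak.loc["b", "p_adj"] >= 0.05

    def test_sidak_adjustment_monotone(self):
        # adjusted p never smaller than raw two-sided p would be
        rng = np.random.default_rng(9)
        summaries = [
            _summary(g, c, r, rng.normal(0.8, 0.05))
            for g in "abcd"
            for c in ("monolayer", "construct3d")
            for r in (1, 2, 3)
        ]
        comp = condition_contrast(summaries, "contour_ratio")
        sidak = comp.posthoc[comp.posthoc["method"] == "sidak"]
        assert (sidak["p_adj"] <= 1.0).all() and (sidak["p_adj"] >= 0.0).all()


class TestRenderReport:
    def test_empty_input(self, tmp_path):
        written = render_report(pd.DataFrame(), [], tmp_path / "r")
        assert (tmp_path / "r" / "stats.json").exists()
        assert (tmp_path / "r" / "contrasts.csv").exists()
        assert written["figures"] == []

    def test_single_group_no_posthoc_content(self, tmp_path):
        df = pd.DataFrame(_nucleus_rows(10, 0.8))
        written = render_report(df, [], tmp_path / "r")
        contrasts = pd.read_csv(written["contrasts"])
        assert len(contrasts) == 0

    def test_full_battery_all_sections(self, tmp_path):
        rng = np.random.default_rng(1)
        rows = []
        for line in ("a", "b"):
            for rep in (1, 2, 3):
                rows += _nucleus_rows(
                    10, float(rng.normal(0.8, 0.02)), line=line, rep=rep
                )
        df = pd.DataFrame(rows)
        summaries = summarize_table(df)
        comp = compare_groups(summaries, "contour_ratio")
        written = render_report(df, [comp], tmp_path / "r")
        assert written["figures"]
        import json

        stats = json.loads((tmp_path / "r" / "stats.json").read_text())
        assert stats[0]["metric"] == "contour_ratio"
        contrasts = pd.read_csv(written["contrasts"])
        assert {"contrast", "estimate", "p_adj", "method"} <= set(contrasts.columns)


class TestSummariesFrame:
    def test_frame_columns(self):
        s = [_summary("a", "m", 1, 0.5)]
        df = summaries_frame(s, "contour_ratio")
        assert set(df.columns) == {"line_id", "condition", "repeat_id", "value", "n_nuclei"}
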