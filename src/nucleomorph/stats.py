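"""Repeat-level aggregation and group comparisons.

Statistics run on repeat-level means, never nucleus-level values: each
experimental repeat contributes one number per metric (the nucleus-count
weighted mean over its fields), and ANOVA + post-hoc contrasts operate on
those repeat means.  Tukey's HSD adjusts between-group (cell line)
contrasts; Sidak's step adjusts within-line condition contrasts.

Shape-label proportions are multi-label: a nucleus with k abnormality
labels contributes to k class tallies, so abnormal-class proportions may
sum to more than 1, while normal + any-abnormal always equals 1.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.libqsturng import psturng

from .types import SHAPE_LABELS

logger = logging.getLogger(__name__)

LABEL_COLUMNS = [f"label_{name}" for name in SHAPE_LABELS]
FLAG_COLUMNS = ["has_honeycomb", "has_foci", "has_capping", "has_emerin_foci"]
MEAN_COLUMNS = ["contour_ratio", "major_axis_um", "peripheral_ratio_lamin_ac"]


@dataclass
class RepeatSummary:
    line_id: str
    condition: str
    repeat_id: int
    n_nuclei: int
    means: dict = dc_field(default_factory=dict)
    proportions: dict = dc_field(default_factory=dict)

    def value(self, metric: str) -> float:
        if metric in self.means:
            return self.means[metric]
        if metric in self.proportions:
            return self.proportions[metric]
        raise KeyError(metric)


@dataclass
class GroupComparison:
    design: str
    metric: str
    anova_table: pd.DataFrame
    posthoc: pd.DataFrame  # columns: contrast, group, estimate, p_adj, method
    alpha: float = 0.05

    @property
    def significant_contrasts(self) -> pd.DataFrame:
        return self.posthoc[self.posthoc["p_adj"] < self.alpha]


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def summarize_repeat(
    per_nucleus: pd.DataFrame,
    line_id: str,
    condition: str,
    repeat_id: int,
) -> Optional[RepeatSummary]:
    """Aggregate one repeat's per-nucleus table to a single summary row.

    Pools all non-border nuclei across the repeat's fields, which equals the
    nucleus-count-weighted mean of per-field values.  Returns ``None`` (with
    a warning) for a repeat with zero usable nuclei.
    """
    df = per_nucleus
    if "touches_border" in df.columns:
        df = df[~df["touches_border"].astype(bool)]
    if len(df) == 0:
        logger.warning(
            "repeat %s/%s/%s has no usable nuclei; excluded",
            line_id, condition, repeat_id,
        )
        return None
    means = {
        col: float(df[col].mean())
        for col in MEAN_COLUMNS
        if col in df.columns and df[col].notna().any()
    }
    proportions = {}
    for col in LABEL_COLUMNS + FLAG_COLUMNS + ["in_myotube"]:
        if col in df.columns:
            proportions[col.removeprefix("label_")] = float(
                df[col].astype(bool).mean()
            )
    if all(c in df.columns for c in LABEL_COLUMNS):
        any_abnormal = df[LABEL_COLUMNS].astype(bool).any(axis=1)
        proportions["normal"] = float((~any_abnormal).mean())
        proportions["any_abnormal"] = float(any_abnormal.mean())
        # reporting-time pooling of the two deformation sub-labels
        proportions["deformed"] = float(
            (df["label_jellybean"].astype(bool) | df["label_severely_deformed"].astype(bool)).mean()
        )
    return RepeatSummary(
        line_id=str(line_id),
        condition=str(condition),
        repeat_id=int(repeat_id),
        n_nuclei=int(len(df)),
        means=means,
        proportions=proportions,
    )


def summarize_table(per_nucleus: pd.DataFrame) -> list[RepeatSummary]:
    """Group a pooled per-nucleus table by (line, condition, repeat)."""
    required = {"line_id", "condition", "repeat_id"}
    missing = required - set(per_nucleus.columns)
    if missing:
        raise ValueError(f"per-nucleus table lacks columns: {sorted(missing)}")
    out = []
    for (line, cond, rep), sub in per_nucleus.groupby(
        ["line_id", "condition", "repeat_id"]
    ):
        s = summarize_repeat(sub, line, cond, rep)
        if s is not None:
            out.append(s)
    return out


def summaries_frame(summaries: Sequence[RepeatSummary], metric: str) -> pd.DataFrame:
    rows = []
    for s in summaries:
        try:
            v = s.value(metric)
        except KeyError:
            continue
        rows.append(
            {
                "line_id": s.line_id,
                "condition": s.condition,
                "repeat_id": s.repeat_id,
                "value": v,
                "n_nuclei": s.n_nuclei,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def _tukey_posthoc(df: pd.DataFrame, mse: float, dfe: float) -> pd.DataFrame:
    """Tukey HSD pairwise contrasts on group (line) means of repeat values."""
    groups = sorted(df["line_id"].unique())
    k = len(groups)
    rows = []
    for a, b in itertools.combinations(groups, 2):
        va = df.loc[df["line_id"] == a, "value"]
        vb = df.loc[df["line_id"] == b, "value"]
        diff = float(vb.mean() - va.mean())
        se = np.sqrt(mse / 2.0 * (1.0 / len(va) + 1.0 / len(vb)))
        q = abs(diff) / se if se > 0 else np.inf
        p = float(np.atleast_1d(psturng(q, k, dfe))[0]) if np.isfinite(q) else 0.0
        rows.append(
            {
                "contrast": f"{a} vs {b}",
                "group": "between_lines",
                "estimate": diff,
                "p_adj": min(1.0, p),
                "method": "tukey",
            }
        )
    return pd.DataFrame(rows)


def _sidak_within_line(df: pd.DataFrame, mse: float, dfe: float) -> pd.DataFrame:
    """Condition contrasts within each line, Sidak-adjusted across lines."""
    lines = sorted(df["line_id"].unique())
    conds = sorted(df["condition"].unique())
    if len(conds) != 2:
        raise ValueError("within-line condition contrasts require exactly 2 conditions")
    m = len(lines)
    rows = []
    for line in lines:
        sub = df[df["line_id"] == line]
        v0 = sub.loc[sub["condition"] == conds[0], "value"]
        v1 = sub.loc[sub["condition"] == conds[1], "value"]
        diff = float(v1.mean() - v0.mean())
        se = np.sqrt(mse * (1.0 / len(v0) + 1.0 / len(v1)))
        if se > 0:
            t = diff / se
            p = 2.0 * sp_stats.t.sf(abs(t), dfe)
        else:
            p = 0.0 if diff != 0 else 1.0
        p_adj = 1.0 - (1.0 - min(p, 1.0)) ** m
        rows.append(
            {
                "contrast": f"{line}: {conds[1]} vs {conds[0]}",
                "group": line,
                "estimate": diff,
                "p_adj": float(min(1.0, p_adj)),
                "method": "sidak",
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    summaries: Sequence[RepeatSummary],
    metric: str,
    design: str = "one_way",
    alpha: float = 0.05,
) -> GroupComparison:
    """ANOVA over repeat-level values with the design's post-hoc contrasts.

    ``one_way``: groups are lines; Tukey HSD pairwise contrasts.
    ``two_way``: line × condition factorial; Tukey between lines plus
    Sidak-adjusted within-line condition contrasts.
    ``two_way_repeated``: as ``two_way`` with repeat as a blocking factor.
    """
    df = summaries_frame(summaries, metric)
    if df.empty:
        raise ValueError(f"no summaries carry metric {metric!r}")
    n_groups = df["line_id"].nunique()
    if n_groups < 2:
        raise ValueError("need >= 2 groups")
    if (df.groupby(["line_id", "condition"]).size() < 2).any():
        raise ValueError("need >= 2 repeats per group cell")

    if design == "one_way":
        model = ols("value ~ C(line_id)", data=df).fit()
        table = anova_lm(model, typ=2)
        mse = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
        dfe = float(table.loc["Residual", "df"])
        posthoc = _tukey_posthoc(df, mse, dfe)
    elif design in ("two_way", "two_way_repeated"):
        cells = df.groupby(["line_id", "condition"]).size()
        full = df["line_id"].nunique() * df["condition"].nunique()
        if len(cells) != full:
            present = set(cells.index)
            missing = [
                (l, c)
                for l in df["line_id"].unique()
                for c in df["condition"].unique()
                if (l, c) not in present
            ]
            raise ValueError(f"two-way design has empty cells: {missing}")
        formula = "value ~ C(line_id) * C(condition)"
        if design == "two_way_repeated":
            formula += " + C(repeat_id)"
        model = ols(formula, data=df).fit()
        table = anova_lm(model, typ=2)
        mse = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
        dfe = float(table.loc["Residual", "df"])
        posthoc = pd.concat(
            [_tukey_posthoc(df, mse, dfe), _sidak_within_line(df, mse, dfe)],
            ignore_index=True,
        )
    else:
        raise ValueError(f"unknown design {design!r}")
    return GroupComparison(
        design=design, metric=metric, anova_table=table, posthoc=posthoc, alpha=alpha
    )


def condition_contrast(
    summaries: Sequence[RepeatSummary],
    metric: str,
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-way (line × condition) ANOVA with Sidak within-line contrasts.

    This is the machinery behind comparisons of the same lines cultured as
    2D monolayers vs 3D constructs; requires both conditions for each line.
    """
    df = summaries_frame(summaries, metric)
    for line, sub in df.groupby("line_id"):
        if sub["condition"].nunique() < 2:
            raise ValueError(f"line {line!r} lacks one of the two conditions")
    return compare_groups(summaries, metric, design="two_way", alpha=alpha)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def render_report(
    per_nucleus: "pd.DataFrame",
    comparisons: Sequence[GroupComparison],
    out_dir,
) -> dict:
    """Write box plots, a stats JSON and a contrasts CSV to ``out_dir``.

    Box plots show pooled per-nucleus distributions with whiskers at the
    minimum/maximum and '+' at the mean, overlaid with repeat means.
    Deterministic for fixed input.  Returns the paths written.
    """
    import json as _json
    from pathlib import Path as _Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = _Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict = {"figures": []}

    plot_metrics = [
        m for m in ("contour_ratio", "major_axis_um", "peripheral_ratio_lamin_ac")
        if m in per_nucleus.columns
    ]
    has_groups = "line_id" in per_nucleus.columns and len(per_nucleus) > 0
    for metric in plot_metrics if has_groups else []:
        fig, ax = plt.subplots(figsize=(6, 4))
        groups = sorted(per_nucleus["line_id"].unique())
        data = [
            per_nucleus.loc[per_nucleus["line_id"] == g, metric].dropna()
            for g in groups
        ]
        ax.boxplot(
            data,
            tick_labels=groups,
            whis=(0, 100),
            showmeans=True,
            meanprops={"marker": "+", "markeredgecolor": "black"},
        )
        ax.set_ylabel(metric)
        fig.tight_layout()
        p = out / f"box_{metric}.svg"
        fig.savefig(p)
        plt.close(fig)
        written["figures"].append(str(p))

    stats_obj = []
    contrast_rows = []
    for comp in comparisons:
        stats_obj.append(
            {
                "metric": comp.metric,
                "design": comp.design,
                "alpha": comp.alpha,
                "anova": _json.loads(comp.anova_table.to_json()),
            }
        )
        t = comp.posthoc.copy()
        t.insert(0, "metric", comp.metric)
        contrast_rows.append(t)
    stats_path = out / "stats.json"
    stats_path.write_text(_json.dumps(stats_obj, indent=2))
    written["stats"] = str(stats_path)
    contrasts_path = out / "contrasts.csv"
    if contrast_rows:
        pd.concat(contrast_rows, ignore_index=True).to_csv(contrasts_path, index=False)
    else:
        pd.DataFrame(
            columns=["metric", "contrast", "group", "estimate", "p_adj", "method"]
        ).to_csv(contrasts_path, index=False)
    written["contrasts"] = str(contrasts_path)
    return written
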