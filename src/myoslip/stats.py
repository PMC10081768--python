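"""Stage binning, replicate-aware (superplot) aggregation and tests.

Slippage measurements are hierarchical: many legs per cell, two cells per
embryo, several embryos (biological replicates) per condition.  Statistics
respect that nesting: means are taken leg -> cell -> embryo -> condition and
confidence intervals and tests operate on replicate (embryo) means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats as sps

VALUE_COLUMNS = ("v_myo", "v_mem", "slippage")

MEASUREMENT_NAMES = {
    "v_myo": "Myosin velocity",
    "v_mem": "Membrane movement",
    "slippage": "Slippage",
}


@dataclass
class StageBinning:
    """Early/late windows on the minutes-post-MSxx-birth clock.

    Early is the closed interval [early_lo, early_hi] (default [3, 7] min),
    late is t >= late_lo (default 13 min); times in between are excluded.
    """

    early_lo: float = 3.0
    early_hi: float = 7.0
    late_lo: float = 13.0

    def __post_init__(self) -> None:
        if not (self.early_lo < self.early_hi < self.late_lo):
            raise ValueError(
                f"stage windows must satisfy early_lo < early_hi < late_lo, got "
                f"{self.early_lo}, {self.early_hi}, {self.late_lo}")


@dataclass
class GadCount:
    """Scored gastrulation-defective embryos for one condition."""

    label: str
    n_gad: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError(f"{self.label}: n_total must be > 0, got {self.n_total}")
        if not (0 <= self.n_gad <= self.n_total):
            raise ValueError(f"{self.label}: need 0 <= n_gad <= n_total, got "
                             f"{self.n_gad}/{self.n_total}")

    @property
    def percent(self) -> float:
        """Percentage Gad, rounded half-up to one decimal."""
        pct = Decimal(100 * self.n_gad) / Decimal(self.n_total)
        return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def bin_stage(time_post_msxx: float, binning: StageBinning | None = None) -> str:
    """'early', 'late' or 'excluded' for a time in minutes post MSxx birth."""
    if binning is None:
        binning = StageBinning()
    t = float(time_post_msxx)
    if not np.isfinite(t):
        raise ValueError(f"time_post_msxx must be finite, got {t}")
    if binning.early_lo <= t <= binning.early_hi:
        return "early"
    if t >= binning.late_lo:
        return "late"
    return "excluded"


def _ci_halfwidth(values: np.ndarray, level: float = 0.95) -> float:
    n = len(values)
    if n < 2:
        return float("nan")
    t_crit = sps.t.ppf(0.5 + level / 2.0, n - 1)
    return float(t_crit * np.std(values, ddof=1) / np.sqrt(n))


def aggregate(records: pd.DataFrame, value_cols=VALUE_COLUMNS) -> dict[str, pd.DataFrame]:
    """Hierarchical means of leg-level records.

    Returns {'cell', 'embryo', 'condition'} DataFrames: cell means of legs,
    embryo (replicate) means of cells, condition means of embryos with 95%
    confidence intervals computed at the replicate level.  Flagged records
    and excluded-stage records are dropped; a group with no valid records is
    simply absent from the output (missing, not zero).
    """
    df = records.copy()
    if "condition" not in df.columns:
        df["condition"] = "all"
    if "flag" in df.columns:
        df = df[df["flag"].fillna("") == ""]
    df = df[df["stage"].isin(["early", "late"])]
    df = df.dropna(subset=list(value_cols))
    if df.empty:
        empty = pd.DataFrame()
        return {"cell": empty, "embryo": empty, "condition": empty}

    cols = list(value_cols)
    cell = (df.groupby(["condition", "embryo", "cell", "stage"], as_index=False)[cols]
            .mean())
    embryo = (cell.groupby(["condition", "embryo", "stage"], as_index=False)[cols]
              .mean())

    rows = []
    for (cond, stage), grp in embryo.groupby(["condition", "stage"]):
        row = {"condition": cond, "stage": stage, "n_replicates": len(grp)}
        for c in cols:
            v = grp[c].to_numpy()
            row[c] = v.mean()
            row[f"{c}_ci95"] = _ci_halfwidth(v)
        rows.append(row)
    condition = pd.DataFrame(rows)
    return {"cell": cell, "embryo": embryo, "condition": condition}


def welch_t(group_a, group_b) -> tuple[float, float]:
    """Welch's unequal-variance t-test (two-sided).

    The statistic and Welch–Satterthwaite degrees of freedom are computed
    from the closed forms; p is the two-sided tail of Student's t.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_t needs n >= 2 in each group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("welch_t: both groups have zero variance and unequal means")
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def paired_t(pairs) -> tuple[float, float]:
    """Paired t-test (two-sided): one-sample t on the within-pair differences.

    ``pairs`` is a sequence of (first, second) per replicate; incomplete
    pairs (NaN in either member) are excluded with a warning.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (first, second) tuples")
    complete = np.isfinite(arr).all(axis=1)
    if not complete.all():
        warnings.warn(f"paired_t: excluded {int((~complete).sum())} incomplete pair(s)")
    arr = arr[complete]
    if len(arr) < 2:
        raise ValueError("paired_t needs >= 2 complete pairs")
    d = arr[:, 0] - arr[:, 1]
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        raise ValueError("paired_t: zero variance of nonzero differences")
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), float(p)


def gad_stats(counts: list[GadCount], comparisons: list[tuple[str, str]] | None = None,
              method: str = "gof", continuity_correction: bool = False) -> dict:
    """Gastrulation-defective percentages and chi-square comparisons.

    The default comparison is a chi-square goodness-of-fit test of the
    first condition's observed (Gad, non-Gad) counts against the
    proportions expected from the second condition (1 degree of freedom);
    ``method="contingency"`` uses the 2x2 contingency chi-square instead.
    Returns ``{"percent": {label: pct}, "comparisons": DataFrame}``.
    """
    if method not in ("gof", "contingency"):
        raise ValueError("method must be 'gof' or 'contingency'")
    by_label = {c.label: c for c in counts}
    if len(by_label) != len(counts):
        raise ValueError("duplicate condition labels in counts")
    percent = {c.label: c.percent for c in counts}
    rows = []
    for la, lb in comparisons or []:
        ca, cb = by_label[la], by_label[lb]
        if method == "gof":
            p_exp = cb.n_gad / cb.n_total
            chi2, p = sps.chisquare(
                [ca.n_gad, ca.n_total - ca.n_gad],
                f_exp=[ca.n_total * p_exp, ca.n_total * (1.0 - p_exp)])
        else:
            table = np.array([[ca.n_gad, ca.n_total - ca.n_gad],
                              [cb.n_gad, cb.n_total - cb.n_gad]])
            chi2, p, _, _ = sps.chi2_contingency(table, correction=continuity_correction)
        rows.append({"a": la, "b": lb, "chi2": float(chi2), "p": float(p)})
    return {"percent": percent, "comparisons": pd.DataFrame(rows)}


def stage_report(records: pd.DataFrame, control: str | None = None,
                 value_cols=VALUE_COLUMNS) -> pd.DataFrame:
    """Early/late summary, one row per (condition, measurement).

    Columns: replicate-level early and late means, their difference, 95% CI
    half-widths, Welch p vs the control condition per stage (when a control
    is named and distinct), paired early-vs-late p across replicates
    measured at both stages, and replicate counts.
    """
    agg = aggregate(records, value_cols)
    embryo, condition = agg["embryo"], agg["condition"]
    if condition.empty:
        return pd.DataFrame()
    rows = []
    for cond in condition["condition"].unique():
        for c in value_cols:
            row = {"condition": cond, "measurement": MEASUREMENT_NAMES.get(c, c)}
            sub = condition[condition["condition"] == cond]
            for stage in ("early", "late"):
                s = sub[sub["stage"] == stage]
                row[f"mean_{stage}"] = s[c].iloc[0] if len(s) else float("nan")
                row[f"ci95_{stage}"] = s[f"{c}_ci95"].iloc[0] if len(s) else float("nan")
                row[f"n_{stage}"] = int(s["n_replicates"].iloc[0]) if len(s) else 0
            row["mean_difference"] = row["mean_early"] - row["mean_late"]

            emb = embryo[embryo["condition"] == cond].pivot(
                index="embryo", columns="stage", values=c)
            if {"early", "late"} <= set(emb.columns):
                both = emb.dropna(subset=["early", "late"])
                if len(both) >= 2:
                    _, row["p_early_vs_late"] = paired_t(
                        both[["early", "late"]].to_numpy())
                else:
                    row["p_early_vs_late"] = float("nan")
            else:
                row["p_early_vs_late"] = float("nan")

            if control is not None and cond != control:
                for stage in ("early", "late"):
                    mine = embryo[(embryo["condition"] == cond)
                                  & (embryo["stage"] == stage)][c].to_numpy()
                    ctrl = embryo[(embryo["condition"] == control)
                                  & (embryo["stage"] == stage)][c].to_numpy()
                    key = f"p_{stage}_vs_control"
                    row[key] = (welch_t(mine, ctrl)[1]
                                if len(mine) >= 2 and len(ctrl) >= 2 else float("nan"))
            rows.append(row)
    return pd.DataFrame(rows)


def superplot_export(records: pd.DataFrame, csv_path=None, fig_path=None,
                     value: str = "slippage"):
    """Tidy superplot table and (optionally) the figure.

    The CSV stacks three levels of the hierarchy: every leg-level point,
    each replicate (embryo) mean, and each condition mean with its 95% CI,
    distinguished by a ``level`` column.  The figure shows leg-level points
    as small semi-transparent dots, replicate means as larger dots, the
    condition mean as a bar with 95% CI, and early-late pairing lines per
    replicate.  Output ordering is fixed so re-runs are byte-identical.
    """
    agg = aggregate(records, (value,))
    df = records.copy()
    if "condition" not in df.columns:
        df["condition"] = "all"
    if "flag" in df.columns:
        df = df[df["flag"].fillna("") == ""]
    df = df[df["stage"].isin(["early", "late"])].dropna(subset=[value])

    leg_rows = df[["condition", "embryo", "stage", value]].copy()
    leg_rows.insert(0, "level", "leg")
    rep_rows = agg["embryo"][["condition", "embryo", "stage", value]].copy()
    rep_rows.insert(0, "level", "replicate")
    cond = agg["condition"].copy()
    cond_rows = cond[["condition", "stage", value, f"{value}_ci95"]].copy()
    cond_rows.insert(0, "level", "condition")
    cond_rows.insert(2, "embryo", "")
    cond_rows = cond_rows.rename(columns={f"{value}_ci95": "ci95"})
    table = pd.concat([leg_rows, rep_rows, cond_rows], ignore_index=True)
    table = table.sort_values(
        ["level", "condition", "stage", "embryo", value],
        kind="stable").reset_index(drop=True)
    if csv_path is not None:
        table.to_csv(csv_path, index=False)

    if fig_path is not None:
        _superplot_figure(df, agg, value, fig_path)
    return table


def _superplot_figure(df, agg, value, fig_path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conditions = sorted(df["condition"].unique())
    stages = ["early", "late"]
    fig, ax = plt.subplots(figsize=(2.2 + 1.6 * len(conditions), 4.0))
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    palette = plt.get_cmap("tab10")
    for ci, cond in enumerate(conditions):
        for si, stage in enumerate(stages):
            x0 = ci * (len(stages) + 0.6) + si
            pts = df[(df["condition"] == cond) & (df["stage"] == stage)][value]
            ax.scatter(x0 + rng.uniform(-0.18, 0.18, len(pts)), pts, s=6, alpha=0.25,
                       color="gray", linewidths=0)
            reps = agg["embryo"]
            reps = reps[(reps["condition"] == cond) & (reps["stage"] == stage)]
            for ri, (_, r) in enumerate(reps.iterrows()):
                ax.scatter(x0, r[value], s=55, color=palette(ri % 10),
                           edgecolor="black", zorder=3)
            conds = agg["condition"]
            row = conds[(conds["condition"] == cond) & (conds["stage"] == stage)]
            if len(row):
                m, ci95 = row[value].iloc[0], row[f"{value}_ci95"].iloc[0]
                ax.hlines(m, x0 - 0.3, x0 + 0.3, color="black", zorder=4)
                if np.isfinite(ci95):
                    ax.errorbar(x0, m, yerr=ci95, color="black", capsize=4, zorder=4)
        # pairing lines between stages per replicate
        reps = agg["embryo"]
        piv = reps[reps["condition"] == cond].pivot(index="embryo", columns="stage",
                                                    values=value)
        if {"early", "late"} <= set(piv.columns):
            for ri, (_, r) in enumerate(piv.dropna().iterrows()):
                x0 = ci * (len(stages) + 0.6)
                ax.plot([x0, x0 + 1], [r["early"], r["late"]],
                        color=palette(ri % 10), alpha=0.6, lw=1)
    ax.set_xticks([ci * (len(stages) + 0.6) + si
                   for ci in range(len(conditions)) for si in range(2)])
    ax.set_xticklabels([f"{c}\n{s}" for c in conditions for s in stages], fontsize=8)
    ax.set_ylabel(f"{MEASUREMENT_NAMES.get(value, value)} (µm/min)")
    fig.tight_layout()
    fig.savefig(fig_path, dpi=150)
    plt.close(fig)
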