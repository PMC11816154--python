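"""Cohort summaries and NSCLC-vs-SCLC comparisons.

Every variable is reported both ways — mean +/- SD and median (Q1-Q3) — and
compared with the two-sided Mann-Whitney U test at alpha = 0.05 per
variable, without multiplicity adjustment (a Benjamini-Hochberg column is
emitted additionally but does not drive the significance flag).  Quartiles
use linear interpolation (the type-7 convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panels import CHAR_ANTIGENS
from .gating import REPORTED_POPULATIONS

ALPHA = 0.05

ANALYZER_VARIABLES = ("NE-SSC", "NE-SFL", "NE-FSC", "LY-X", "LY-Y")

#: the full comparison schema: 10 population percentages, the two event
#: counts and the analyzer WBC, 16 antigens x {percent, GMF}, 5 positional
#: parameters
def comparison_variables() -> list[str]:
    out = [f"{p}_pct" for p in REPORTED_POPULATIONS]
    out += ["tumor_events", "all_cells_events", "WBC_per_ul"]
    for a in CHAR_ANTIGENS:
        out += [f"{a}_pct", f"{a}_gmf"]
    out += list(ANALYZER_VARIABLES)
    return out


@dataclass(frozen=True)
class SummaryRow:
    variable: str
    group: str
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("quartiles must bracket the median")


def summarize(values, variable: str = "", group: str = "") -> SummaryRow:
    """Mean/SD (n-1 denominator) plus type-7 median and quartiles."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("cannot summarize an empty value list")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return SummaryRow(variable, group, int(values.size), float(values.mean()),
                      sd, float(med), float(q1), float(q3))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with the min-U convention.

    The p-value is exact (full enumeration) for tie-free samples with
    n1*n2 <= 400, otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = x.size * y.size <= 400
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    u = min(float(res.statistic), x.size * y.size - float(res.statistic))
    return u, float(res.pvalue)


def compare_groups(nsclc: pd.DataFrame, sclc: pd.DataFrame,
                   variables: list[str] | None = None) -> pd.DataFrame:
    """Per-variable NSCLC-vs-SCLC comparison table.

    Both inputs are per-sample data frames (one row per patient).  Missing
    variables or groups with < 2 usable values yield a row with a reason
    code instead of a test result.
    """
    variables = variables if variables is not None else comparison_variables()
    rows = []
    for var in variables:
        row: dict = {"variable": var, "reason": ""}
        ok = True
        for label, df in (("NSCLC", nsclc), ("SCLC", sclc)):
            if var not in df.columns:
                row["reason"] = f"variable missing in {label}"
                ok = False
                continue
            vals = np.asarray(df[var], dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size < 2:
                row["reason"] = f"fewer than 2 usable values in {label}"
                ok = False
                continue
            s = summarize(vals, var, label)
            row.update({f"{label}_n": s.n, f"{label}_mean": s.mean,
                        f"{label}_sd": s.sd, f"{label}_median": s.median,
                        f"{label}_q1": s.q1, f"{label}_q3": s.q3})
        if ok:
            xv = np.asarray(nsclc[var], dtype=float)
            yv = np.asarray(sclc[var], dtype=float)
            u, p = mann_whitney_u(xv[~np.isnan(xv)], yv[~np.isnan(yv)])
            row["U"] = u
            row["p_value"] = p
            row["significant"] = bool(p < ALPHA)
        else:
            row["U"] = np.nan
            row["p_value"] = np.nan
            row["significant"] = False
        rows.append(row)
    table = pd.DataFrame(rows)
    tested = table["p_value"].notna()
    table["p_bh"] = np.nan
    if tested.any():
        table.loc[tested, "p_bh"] = _benjamini_hochberg(
            table.loc[tested, "p_value"].to_numpy())
    return table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def format_comparison_markdown(table: pd.DataFrame, title: str = "") -> str:
    """Human-readable medians (Q1-Q3) report, one line per variable."""
    lines = []
    if title:
        lines += [f"## {title}", ""]
    lines.append("| Variable | NSCLC median (Q1-Q3) | SCLC median (Q1-Q3) "
                 "| U | p | sig |")
    lines.append("|---|---|---|---|---|---|")
    for _, r in table.iterrows():
        if np.isnan(r.get("p_value", np.nan)):
            lines.append(f"| {r['variable']} | - | - | - | - | {r['reason']} |")
            continue
        def fmt(g):
            return (f"{r[f'{g}_median']:.1f} "
                    f"({r[f'{g}_q1']:.1f}-{r[f'{g}_q3']:.1f})")
        star = "*" if r["significant"] else ""
        lines.append(f"| {r['variable']} | {fmt('NSCLC')} | {fmt('SCLC')} | "
                     f"{r['U']:.1f} | {r['p_value']:.4g} | {star} |")
    return "\n".join(lines) + "\n"
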