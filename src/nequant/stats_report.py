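"""Group-comparison statistics and tidy reporting.

Two-group comparisons use Student's t test (Welch's unequal-variance form
by default for unpaired designs, or the paired form); three or more groups
use one-way ANOVA followed by Holm-adjusted pairwise t tests, or the
Kruskal-Wallis test for non-normal data. Significance stars follow the
convention *P < 0.05, **P < 0.01, ***P < 0.001. Normality is never tested
automatically — the caller chooses the parametric or rank-based design.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

DESIGNS = ("t_unpaired", "t_paired", "anova_holm", "kruskal")


def holm_adjust(pvalues) -> np.ndarray:
    """Holm (step-down Bonferroni) multiplicity adjustment.

    Sort the m raw p-values ascending, multiply the i-th (1-based) by
    (m - i + 1), enforce monotone non-decreasing adjusted values along the
    sorted order, cap at 1, and return them in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1D sequence of p-values")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = p[order] * (m - np.arange(m))
    adjusted = np.minimum(np.maximum.accumulate(adjusted), 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _describe(x: np.ndarray) -> str:
    sem = x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else float("nan")
    return f"{x.mean():.6g} ± {sem:.3g}"


def compare_groups(samples: dict[str, np.ndarray], design: str = "t_unpaired",
                   equal_var: bool = False) -> pd.DataFrame:
    """Run the chosen group comparison and return a tidy result table.

    ``samples`` maps group label to 1D data. Designs: ``t_unpaired``
    (two groups, Welch by default), ``t_paired`` (two equal-length groups),
    ``anova_holm`` (one-way ANOVA plus Holm-adjusted pairwise t tests),
    ``kruskal``. Columns: test_name, groups, statistic, p_raw, p_adjusted,
    n_per_group, effect_summary, stars.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; choose from {DESIGNS}")
    groups = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    min_n = 3 if design == "anova_holm" else 2
    for name, x in groups.items():
        if len(x) < min_n:
            raise ValueError(f"group {name!r} has n={len(x)} < {min_n}")
    if all(np.ptp(x) == 0 for x in groups.values()):
        raise ValueError("degenerate test: zero within-group variance in all groups")

    names = list(groups)
    rows = []

    def _row(test, pair, stat, p, p_adj=None):
        ns = {g: len(groups[g]) for g in pair}
        rows.append({
            "test_name": test,
            "groups": " vs ".join(pair),
            "statistic": float(stat),
            "p_raw": float(p),
            "p_adjusted": float(p_adj) if p_adj is not None else float(p),
            "n_per_group": ns,
            "effect_summary": "; ".join(f"{g}: {_describe(groups[g])}" for g in pair),
            "stars": significance_stars(p_adj if p_adj is not None else p),
        })

    if design in ("t_unpaired", "t_paired"):
        if len(groups) != 2:
            raise ValueError("t test designs take exactly two groups")
        a, b = (groups[n] for n in names)
        if design == "t_paired":
            if len(a) != len(b):
                raise ValueError("paired design needs equal-length groups")
            res = sps.ttest_rel(a, b)
            label = "paired t (two-tailed)"
        else:
            res = sps.ttest_ind(a, b, equal_var=equal_var)
            label = ("Student t (two-tailed)" if equal_var
                     else "Welch t (two-tailed)")
        stat, p = res.statistic, res.pvalue
        if np.isnan(stat) and np.array_equal(a, b):
            # identical groups: define the null result instead of NaN
            stat, p = 0.0, 1.0
        _row(label, names, stat, p)

    elif design == "kruskal":
        stat, p = sps.kruskal(*groups.values())
        _row("Kruskal-Wallis", names, stat, p)

    else:  # anova_holm
        stat, p = sps.f_oneway(*groups.values())
        _row("one-way ANOVA", names, stat, p)
        pairs = list(combinations(names, 2))
        raw = []
        for g1, g2 in pairs:
            t, pr = sps.ttest_ind(groups[g1], groups[g2], equal_var=equal_var)
            raw.append((t, pr))
        adj = holm_adjust([pr for _, pr in raw])
        for (g1, g2), (t, pr), pa in zip(pairs, raw, adj):
            _row("pairwise t + Holm", (g1, g2), t, pr, pa)

    return pd.DataFrame(rows)


def write_report(results: pd.DataFrame, csv_path, md_path=None,
                 exclusions: list[str] | None = None) -> None:
    """Emit the result table as CSV and, optionally, a markdown run report."""
    results.to_csv(csv_path, index=False)
    if md_path is None:
        return
    lines = ["# Group comparison report", ""]
    for _, r in results.iterrows():
        lines.append(f"- **{r.test_name}** [{r.groups}]: statistic = "
                     f"{r.statistic:.4g}, p = {r.p_raw:.3g} "
                     f"(adjusted {r.p_adjusted:.3g}) {r.stars}")
        lines.append(f"  - {r.effect_summary}")
    if exclusions:
        lines += ["", "## Exclusions", ""] + [f"- {e}" for e in exclusions]
    with open(md_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
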