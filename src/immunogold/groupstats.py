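"""Group comparisons: two-way ANOVA with Bonferroni-adjusted pairwise tests.

Densities are compared across genotype x compartment with a two-way ANOVA
(Type II sums of squares when the design is unbalanced) followed by
per-compartment two-sample t tests with Bonferroni adjustment
(``p_adj = min(1, m * p_raw)``).  Significance stars follow the convention
``*`` for p < 0.05 and ``****`` for p < 0.0001.  The experimental unit is
the animal; profile-level tests are available as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

ALPHA_STAR = 0.05
ALPHA_FOUR_STAR = 1e-4


def stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < ALPHA_FOUR_STAR:
        return "****"
    if p < ALPHA_STAR:
        return "*"
    return "ns"


@dataclass
class ComparisonResult:
    factors: tuple[str, str]
    anova_table: pd.DataFrame
    f_stats: dict[str, float]
    p_values: dict[str, float]
    balanced: bool
    ss_type: int
    zero_variance: bool = False
    pairwise: Optional[pd.DataFrame] = None
    notes: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"Two-way ANOVA ({self.factors[0]} x {self.factors[1]}, "
            f"Type {'II' if self.ss_type == 2 else 'I'} SS, "
            f"{'balanced' if self.balanced else 'unbalanced'})"
        ]
        for term, f in self.f_stats.items():
            lines.append(
                f"  {term}: F = {f:.4g}, p = {self.p_values[term]:.4g} "
                f"{stars(self.p_values[term])}"
            )
        if self.pairwise is not None:
            lines.append("Bonferroni pairwise comparisons:")
            for row in self.pairwise.itertuples():
                lines.append(
                    f"  {row.compartment}: p_adj = {row.p_adj:.4g} {row.stars}"
                )
        return "\n".join(lines)


def two_way_anova(
    table: pd.DataFrame,
    value: str = "density_per_um2",
    factor_a: str = "genotype",
    factor_b: str = "compartment",
) -> ComparisonResult:
    """Two-way fixed-effects ANOVA on a long-format table.

    Requires at least two levels per factor and at least two observations
    per cell; all-identical responses are flagged as zero variance (F is
    undefined).
    """
    for f in (factor_a, factor_b):
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than two levels")
    counts = table.groupby([factor_a, factor_b], observed=True)[value].count()
    balanced = counts.nunique() == 1
    ss_type = 2 if not balanced else 1

    if np.allclose(table[value].var(ddof=0), 0.0):
        terms = [factor_a, factor_b, f"{factor_a}:{factor_b}"]
        return ComparisonResult(
            factors=(factor_a, factor_b),
            anova_table=pd.DataFrame(),
            f_stats={t: float("nan") for t in terms},
            p_values={t: float("nan") for t in terms},
            balanced=bool(balanced),
            ss_type=ss_type,
            zero_variance=True,
            notes=["all responses identical; F undefined"],
        )

    data = table.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    model = ols("_y ~ C(_a) * C(_b)", data=data).fit()
    aov = sm.stats.anova_lm(model, typ=ss_type)
    key_map = {
        "C(_a)": factor_a,
        "C(_b)": factor_b,
        "C(_a):C(_b)": f"{factor_a}:{factor_b}",
    }
    f_stats = {key_map[k]: float(aov.loc[k, "F"]) for k in key_map}
    p_values = {key_map[k]: float(aov.loc[k, "PR(>F)"]) for k in key_map}
    aov = aov.rename(index=key_map)
    return ComparisonResult(
        factors=(factor_a, factor_b),
        anova_table=aov,
        f_stats=f_stats,
        p_values=p_values,
        balanced=bool(balanced),
        ss_type=ss_type,
    )


def bonferroni_pairwise(
    table: pd.DataFrame,
    value: str = "density_per_um2",
    group: str = "genotype",
    within: str = "compartment",
    m: Optional[int] = None,
) -> pd.DataFrame:
    """Per-compartment two-sample t tests with Bonferroni adjustment.

    ``m`` defaults to the number of compartments compared (11 for the
    gradient tables).  Adjusted p is ``min(1, m * p_raw)`` and is never
    below the raw p.
    """
    groups = sorted(table[group].unique())
    if len(groups) != 2:
        raise ValueError("pairwise comparison needs exactly two groups")
    compartments = list(dict.fromkeys(table[within]))
    if m is None:
        m = len(compartments)
    rows = []
    for comp in compartments:
        sub = table[table[within] == comp]
        a = sub.loc[sub[group] == groups[0], value].to_numpy(float)
        b = sub.loc[sub[group] == groups[1], value].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            t, p = float("nan"), float("nan")
        else:
            t, p = stats.ttest_ind(a, b)
        p_adj = min(1.0, m * p) if not np.isnan(p) else float("nan")
        rows.append(
            {
                "compartment": comp,
                "mean_" + str(groups[0]): float(a.mean()) if len(a) else float("nan"),
                "mean_" + str(groups[1]): float(b.mean()) if len(b) else float("nan"),
                "t": float(t),
                "p_raw": float(p),
                "p_adj": float(p_adj),
                "m": m,
                "stars": stars(p_adj),
            }
        )
    return pd.DataFrame(rows)


def summarize_condition(
    values,
    unit: str = "immunoparticles/µm²",
    n_label: str = "animals",
) -> str:
    """Report-table string: ``"mean ± SEM unit, n = k label"``.

    With a single observation the SEM is undefined and left blank.
    """
    vals = np.asarray(list(values), float)
    if len(vals) == 0:
        raise ValueError("no values to summarise")
    mean = vals.mean()
    if len(vals) >= 2:
        sem = np.std(vals, ddof=1) / np.sqrt(len(vals))
        return f"{mean:.2f} ± {sem:.2f} {unit}, n = {len(vals)} {n_label}"
    return f"{mean:.2f} ± -- {unit}, n = 1 {n_label}"
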