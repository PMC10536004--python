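"""Factorial comparison of kinetic parameters across catechin structure.

The four catechins form a complete 2×2 layout of two structural
attributes — gallation (EGCG, ECG) and B-ring trihydroxylation (EGCG,
EGC).  Subject-level kinetic responses are analyzed by fixed-effects
two-way ANOVA with interaction, followed by Tukey's HSD across the four
catechin cells summarized as a compact letter display (cells sharing a
letter are not significantly different at the family-wise level).
An exploratory three-way ANOVA adds sex as a factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .model import CATECHINS, DOSES

ALPHA = 0.05


@dataclass
class FactorialResult:
    response: str
    anova_table: pd.DataFrame  # F and p for gallation, hydroxylation, interaction
    cell_means: pd.DataFrame  # per-catechin mean ± SEM and letter group
    tukey_pvalues: pd.DataFrame  # adjusted pairwise p-values (catechin × catechin)
    degenerate: bool = False  # zero-variance response

    @property
    def p_gallation(self) -> float:
        return float(self.anova_table.loc["gallated", "PR(>F)"])

    @property
    def p_hydroxylation(self) -> float:
        return float(self.anova_table.loc["trihydroxylated", "PR(>F)"])

    @property
    def p_interaction(self) -> float:
        return float(self.anova_table.loc["gallated:trihydroxylated", "PR(>F)"])

    def letters(self) -> dict[str, str]:
        return dict(zip(self.cell_means.catechin, self.cell_means.letters))


def _attach_factors(values: pd.DataFrame) -> pd.DataFrame:
    df = values.copy()
    df["gallated"] = df["catechin"].map(lambda c: DOSES[c].gallated)
    df["trihydroxylated"] = df["catechin"].map(lambda c: DOSES[c].b_ring_hydroxyls == 3)
    return df


def compact_letter_display(
    groups: list[str], means: dict[str, float], different: dict[frozenset, bool]
) -> dict[str, str]:
    """Assign letters so two groups share a letter iff not significantly different.

    Insert-and-absorb algorithm: start with one letter covering all
    groups; for each significantly different pair split every covering
    letter in two; drop letters whose group set is contained in another;
    name letters a, b, c… in descending order of the best mean they cover.
    """
    sets: list[set[str]] = [set(groups)]
    for pair, diff in different.items():
        if not diff:
            continue
        a, b = sorted(pair)
        for s in list(sets):
            if a in s and b in s:
                sets.remove(s)
                sets.extend([s - {a}, s - {b}])
        # absorb subsets
        sets = [s for s in sets if s and not any(s < t for t in sets)]
        # deduplicate
        uniq = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    sets.sort(key=lambda s: -max(means[g] for g in s))
    labels = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(labels, sets):
        for g in s:
            out[g] += letter
    return {g: "".join(sorted(v)) for g, v in out.items()}


def factorial_anova(
    values: pd.DataFrame, response_name: str = "value", alpha: float = ALPHA
) -> FactorialResult:
    """Two-way gallation × hydroxylation ANOVA with Tukey post-hoc letters.

    ``values`` is tidy with columns [subject_id, catechin, value]; each
    catechin occupies one cell of the 2×2 layout and every cell needs at
    least two subjects.
    """
    required = {"subject_id", "catechin", "value"}
    if not required <= set(values.columns):
        raise ValueError(f"values must have columns {sorted(required)}")
    present = set(values["catechin"].unique())
    missing = set(CATECHINS) - present
    if missing:
        raise ValueError(f"incomplete factorial layout; missing cells: {sorted(missing)}")
    counts = values.groupby("catechin").size()
    if (counts < 2).any():
        raise ValueError("need at least 2 subjects per catechin cell")

    df = _attach_factors(values)
    degenerate = bool(np.isclose(df.groupby("catechin")["value"].var().max(), 0.0))

    model = smf.ols("value ~ C(gallated) * C(trihydroxylated)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={
            "C(gallated)": "gallated",
            "C(trihydroxylated)": "trihydroxylated",
            "C(gallated):C(trihydroxylated)": "gallated:trihydroxylated",
        }
    )

    tk = pairwise_tukeyhsd(df["value"].to_numpy(), df["catechin"].to_numpy(), alpha=alpha)
    tk_df = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    pmat = pd.DataFrame(np.ones((4, 4)), index=list(CATECHINS), columns=list(CATECHINS))
    different: dict[frozenset, bool] = {}
    for _, row in tk_df.iterrows():
        g1, g2, p = str(row["group1"]), str(row["group2"]), float(row["p-adj"])
        pmat.loc[g1, g2] = pmat.loc[g2, g1] = p
        different[frozenset((g1, g2))] = (p <= alpha) and not degenerate

    means = df.groupby("catechin")["value"].agg(["mean", "sem", "count"]).reset_index()
    letter_map = compact_letter_display(
        list(means.catechin), dict(zip(means.catechin, means["mean"])), different
    )
    means["letters"] = means["catechin"].map(letter_map)
    means = means.set_index("catechin").loc[list(CATECHINS)].reset_index()

    return FactorialResult(
        response=response_name,
        anova_table=table,
        cell_means=means,
        tukey_pvalues=pmat,
        degenerate=degenerate,
    )


def exploratory_sex_anova(
    values: pd.DataFrame, sex_labels: dict[str, str], alpha: float = ALPHA
) -> pd.DataFrame:
    """Three-way sex × gallation × hydroxylation ANOVA table.

    Returns the ANOVA table with an extra boolean column
    ``significant`` (p ≤ alpha); raises for a single-sex cohort.
    """
    df = _attach_factors(values)
    df["sex"] = df["subject_id"].map(sex_labels)
    if df["sex"].isna().any():
        raise ValueError("missing sex label for some subjects")
    if df["sex"].nunique() < 2:
        raise ValueError("sex factor needs both levels present")
    counts = df.groupby(["catechin", "sex"]).size()
    if (counts < 2).any():
        raise ValueError("need at least 2 subjects per catechin × sex cell")
    model = smf.ols("value ~ C(sex) * C(gallated) * C(trihydroxylated)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table["significant"] = table["PR(>F)"] <= alpha
    return table


def plot_factorial(result: FactorialResult, ax=None):
    """Grouped bar chart of cell means ± SEM with Tukey letter annotations."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    m = result.cell_means
    x = np.arange(len(m))
    ax.bar(x, m["mean"], yerr=m["sem"], capsize=3, color="#4c8a64")
    for xi, (mu, sem, letter) in enumerate(zip(m["mean"], m["sem"], m["letters"])):
        ax.text(xi, mu + sem, letter, ha="center", va="bottom")
    ax.set_xticks(x, m["catechin"])
    ax.set_ylabel(result.response)
    return ax
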