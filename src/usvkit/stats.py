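"""Genotype x sex cohort statistics for USV count tables.

The inferential core is a fixed-effects two-way (genotype x sex) analysis
of variance with interaction, applied per outcome (total calls and each of
the ten syllable-type counts), followed by Tukey-Kramer post-hoc
comparisons of the four genotype x sex cell means and mean +/- SEM group
summaries.

Because the cohort design is unbalanced (e.g. 13/26/7/9 pups per cell),
main effects are tested with Type III (marginal) sums of squares under
sum-to-zero factor coding: the SS of a term is the increase in residual SS
when that term's column is dropped from the full model

    y = mu + a*g + b*s + c*(g*s) + e,   g, s in {-1, +1}.

Type I (sequential) and Type II decompositions are available for
sensitivity analyses; on balanced data all three coincide.

The module follows the model/results idiom: build a :class:`CohortAnova`
from a cohort table, ``fit()`` it, and read estimates, the ANOVA table,
Tukey-Kramer pairs and a ``summary()`` text report off the results object.
:func:`run_full_analysis` iterates the model over all outcomes and derives
the cohort-level counts of interest (how many syllable types show a
significant genotype effect; how many of those are male-specific).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .taxonomy import CALL_TYPES

TERMS = ("genotype", "sex", "genotype:sex")
CELLS = (("WT", "F"), ("WT", "M"), ("KO", "F"), ("KO", "M"))


def _require_full_design(table: pd.DataFrame) -> None:
    for g, s in CELLS:
        if not ((table["genotype"] == g) & (table["sex"] == s)).any():
            raise ValueError(f"empty design cell: genotype={g}, sex={s}")


def _design_matrix(table: pd.DataFrame) -> np.ndarray:
    g = np.where(table["genotype"].to_numpy() == "WT", 1.0, -1.0)
    s = np.where(table["sex"].to_numpy() == "F", 1.0, -1.0)
    return np.column_stack([np.ones(len(table)), g, s, g * s])


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(resid @ resid)


@dataclass(frozen=True)
class AnovaResult:
    """Per-term SS/df/F/p plus the residual line for one outcome."""

    outcome: str
    ss: dict[str, float]
    df: dict[str, int]
    f: dict[str, float]
    p: dict[str, float]
    ss_resid: float
    df_resid: int
    ss_type: str = "III"

    @property
    def mse(self) -> float:
        return self.ss_resid / self.df_resid

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "outcome": self.outcome, "term": t, "SS": self.ss[t],
                "df": self.df[t], "F": self.f[t], "p": self.p[t],
            }
            for t in TERMS
        ]
        rows.append(
            {
                "outcome": self.outcome, "term": "residual",
                "SS": self.ss_resid, "df": self.df_resid,
                "F": np.nan, "p": np.nan,
            }
        )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TukeyResult:
    """Tukey-Kramer comparisons of the four genotype x sex cell means."""

    outcome: str
    pairs: pd.DataFrame  # columns: group1, group2, mean_diff, q, p_adj

    def p_for(self, cell1: tuple[str, str], cell2: tuple[str, str]) -> float:
        a, b = "-".join(cell1), "-".join(cell2)
        m = self.pairs[
            ((self.pairs["group1"] == a) & (self.pairs["group2"] == b))
            | ((self.pairs["group1"] == b) & (self.pairs["group2"] == a))
        ]
        if m.empty:
            raise KeyError(f"no comparison {a} vs {b}")
        return float(m["p_adj"].iloc[0])


def two_way_anova(
    table: pd.DataFrame, outcome: str, ss_type: str = "III"
) -> AnovaResult:
    """Two-way genotype x sex ANOVA with interaction for one outcome.

    Type III (default): each term's SS is the residual-SS increase when
    its column is dropped from the full sum-to-zero-coded model — the
    marginal decomposition appropriate for unbalanced designs. Type I is
    sequential in the order genotype, sex, interaction; Type II drops each
    main effect from the main-effects model.

    Raises ``ValueError`` on an empty design cell (named in the message)
    or zero residual variance.
    """
    _require_full_design(table)
    y = table[outcome].to_numpy(dtype=float)
    X = _design_matrix(table)
    n = len(y)
    df_resid = n - 4
    if df_resid < 1:
        raise ValueError("residual df < 1: need more than 4 observations")
    rss_full = _rss(X, y)
    if rss_full <= 1e-12 * max(1.0, float(y @ y)):
        raise ValueError("zero residual variance: F statistics undefined")

    cols = {"genotype": 1, "sex": 2, "genotype:sex": 3}
    ss: dict[str, float] = {}
    if ss_type == "III":
        for term, j in cols.items():
            ss[term] = _rss(np.delete(X, j, axis=1), y) - rss_full
    elif ss_type == "I":
        prev = _rss(X[:, :1], y)
        for term, j in cols.items():
            cur = _rss(X[:, : j + 1], y)
            ss[term] = prev - cur
            prev = cur
    elif ss_type == "II":
        main = X[:, :3]
        rss_main = _rss(main, y)
        ss["genotype"] = _rss(np.delete(main, 1, axis=1), y) - rss_main
        ss["sex"] = _rss(np.delete(main, 2, axis=1), y) - rss_main
        ss["genotype:sex"] = rss_main - rss_full
    else:
        raise ValueError(f"unknown SS type {ss_type!r}")

    mse = rss_full / df_resid
    ss = {t: max(0.0, v) for t, v in ss.items()}
    f = {t: ss[t] / mse for t in TERMS}
    p = {t: float(sps.f.sf(f[t], 1, df_resid)) for t in TERMS}
    return AnovaResult(
        outcome=outcome,
        ss=ss, df={t: 1 for t in TERMS}, f=f, p=p,
        ss_resid=rss_full, df_resid=df_resid, ss_type=ss_type,
    )


def tukey_posthoc(table: pd.DataFrame, outcome: str) -> TukeyResult:
    """Tukey-Kramer comparisons of all six pairs of the four cells.

    Uses the full-model residual mean square and df; unequal cell sizes
    are handled by the Kramer harmonic adjustment

        SE(i,j) = sqrt(MSE/2 * (1/n_i + 1/n_j)),   q = |mean_i - mean_j|/SE,

    with adjusted p from the studentized-range distribution (k = 4 groups).
    """
    anova = two_way_anova(table, outcome)
    mse, dfr = anova.mse, anova.df_resid
    stats = {}
    for g, s in CELLS:
        sub = table[(table["genotype"] == g) & (table["sex"] == s)][outcome]
        stats["-".join((g, s))] = (float(sub.mean()), len(sub))
    rows = []
    for (name1, (m1, n1)), (name2, (m2, n2)) in combinations(stats.items(), 2):
        se = np.sqrt(mse / 2.0 * (1.0 / n1 + 1.0 / n2))
        diff = m1 - m2
        q = abs(diff) / se if se > 0 else np.inf
        p_adj = float(sps.studentized_range.sf(q, len(CELLS), dfr))
        rows.append(
            {
                "group1": name1, "group2": name2,
                "mean_diff": diff, "q": q, "p_adj": min(1.0, p_adj),
            }
        )
    return TukeyResult(outcome=outcome, pairs=pd.DataFrame(rows))


def summarize_groups(
    table: pd.DataFrame, outcomes: list[str] | None = None
) -> pd.DataFrame:
    """Per-cell n, mean and SEM (sd/sqrt(n); missing when n == 1)."""
    if outcomes is None:
        outcomes = _default_outcomes(table)
    rows = []
    for g, s in CELLS:
        sub = table[(table["genotype"] == g) & (table["sex"] == s)]
        if sub.empty:
            continue
        for outc in outcomes:
            v = sub[outc].to_numpy(dtype=float)
            sem = float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan
            rows.append(
                {
                    "genotype": g, "sex": s, "outcome": outc,
                    "n": len(v), "mean": float(v.mean()), "sem": sem,
                }
            )
    return pd.DataFrame(rows)


def _default_outcomes(table: pd.DataFrame) -> list[str]:
    type_cols = [ct.value for ct in CALL_TYPES if ct.value in table.columns]
    base = ["total_calls"] if "total_calls" in table.columns else []
    return base + type_cols


# ---------------------------------------------------------------------------
# Model / results objects


class CohortAnova:
    """Two-way genotype x sex ANOVA model for one cohort outcome.

    Parameters
    ----------
    table : DataFrame with ``genotype`` (WT/KO), ``sex`` (M/F) and the
        outcome column.
    outcome : name of the count column to analyse.
    ss_type : "III" (default, marginal), "II" or "I".

    ``fit()`` returns a :class:`CohortAnovaResults`.
    """

    def __init__(self, table: pd.DataFrame, outcome: str, ss_type: str = "III"):
        _require_full_design(table)
        self.table = table
        self.outcome = outcome
        self.ss_type = ss_type

    @classmethod
    def from_dataframe(
        cls, table: pd.DataFrame, outcome: str, ss_type: str = "III"
    ) -> "CohortAnova":
        return cls(table, outcome, ss_type)

    def fit(self) -> "CohortAnovaResults":
        anova = two_way_anova(self.table, self.outcome, self.ss_type)
        tukey = tukey_posthoc(self.table, self.outcome)
        summary = summarize_groups(self.table, [self.outcome])
        return CohortAnovaResults(self, anova, tukey, summary)


@dataclass(frozen=True)
class CohortAnovaResults:
    """Fitted two-way ANOVA: term tests, post-hoc pairs, cell summaries."""

    model: CohortAnova
    anova: AnovaResult
    tukey: TukeyResult
    group_summary: pd.DataFrame

    def significant_terms(self, alpha: float = 0.05) -> list[str]:
        return [t for t in TERMS if self.anova.p[t] < alpha]

    def summary(self) -> str:
        lines = [
            f"Two-way ANOVA (Type {self.anova.ss_type} SS) — outcome: "
            f"{self.anova.outcome}",
            f"{'term':<14}{'SS':>12}{'df':>5}{'F':>10}{'p':>10}",
        ]
        for t in TERMS:
            lines.append(
                f"{t:<14}{self.anova.ss[t]:>12.4f}{self.anova.df[t]:>5d}"
                f"{self.anova.f[t]:>10.4f}{self.anova.p[t]:>10.4g}"
            )
        lines.append(
            f"{'residual':<14}{self.anova.ss_resid:>12.4f}"
            f"{self.anova.df_resid:>5d}{'':>10}{'':>10}"
        )
        lines.append("")
        lines.append("Group means (mean ± SEM):")
        for _, r in self.group_summary.iterrows():
            lines.append(
                f"  {r['genotype']}-{r['sex']}: n={r['n']:.0f}, "
                f"{r['mean']:.2f} ± {r['sem']:.2f}"
            )
        lines.append("")
        lines.append("Tukey–Kramer pairwise comparisons:")
        for _, r in self.tukey.pairs.iterrows():
            lines.append(
                f"  {r['group1']} vs {r['group2']}: diff={r['mean_diff']:+.2f}, "
                f"q={r['q']:.3f}, p_adj={r['p_adj']:.4g}"
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class CohortReport:
    """Full per-outcome analysis of one cohort table."""

    results: dict[str, CohortAnovaResults]
    alpha: float
    n_genotype_significant: int
    genotype_significant_types: list[str]
    n_male_specific: int
    male_specific_types: list[str]

    def anova_frame(self) -> pd.DataFrame:
        return pd.concat(
            [r.anova.to_frame() for r in self.results.values()],
            ignore_index=True,
        )

    def tukey_frame(self) -> pd.DataFrame:
        frames = []
        for outc, r in self.results.items():
            f = r.tukey.pairs.copy()
            f.insert(0, "outcome", outc)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def summary_frame(self) -> pd.DataFrame:
        return pd.concat(
            [r.group_summary for r in self.results.values()], ignore_index=True
        )


def run_full_analysis(
    table: pd.DataFrame, alpha: float = 0.05, ss_type: str = "III"
) -> CohortReport:
    """ANOVA + Tukey + summaries for total calls and every syllable type.

    Also derives the two cohort-level counts of interest:

    * the number of syllable types with a significant genotype main effect
      at ``alpha``;
    * among those, the number whose male WT-vs-KO Tukey contrast is
      significant while the female contrast is not (male-specific types).

    Deterministic given the input table. No correction is applied across
    the 11 outcomes (each outcome is reported at face-value alpha).
    """
    outcomes = _default_outcomes(table)
    results: dict[str, CohortAnovaResults] = {}
    for outc in outcomes:
        results[outc] = CohortAnova(table, outc, ss_type=ss_type).fit()

    type_names = [ct.value for ct in CALL_TYPES if ct.value in table.columns]
    sig_types = [
        t for t in type_names if results[t].anova.p["genotype"] < alpha
    ]
    male_specific = []
    for t in sig_types:
        tk = results[t].tukey
        p_male = tk.p_for(("WT", "M"), ("KO", "M"))
        p_female = tk.p_for(("WT", "F"), ("KO", "F"))
        if p_male < alpha and p_female >= alpha:
            male_specific.append(t)

    return CohortReport(
        results=results,
        alpha=alpha,
        n_genotype_significant=len(sig_types),
        genotype_significant_types=sig_types,
        n_male_specific=len(male_specific),
        male_specific_types=male_specific,
    )


def plot_group_means(
    report: CohortReport, path: str, outcomes: list[str] | None = None
) -> None:
    """Bar plot of cell means ± SEM with genotype-significance marks."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    outcomes = outcomes or list(report.results)
    fig, axes = plt.subplots(
        1, len(outcomes), figsize=(2.2 * len(outcomes) + 1, 3.2), squeeze=False
    )
    for ax, outc in zip(axes[0], outcomes):
        res = report.results[outc]
        summ = res.group_summary.set_index(
            res.group_summary["genotype"] + "-" + res.group_summary["sex"]
        )
        names = ["WT-F", "WT-M", "KO-F", "KO-M"]
        means = [summ.loc[nm, "mean"] for nm in names]
        sems = [summ.loc[nm, "sem"] for nm in names]
        ax.bar(names, means, yerr=sems, capsize=3,
               color=["#888", "#888", "#c44", "#c44"])
        title = outc
        if res.anova.p["genotype"] < report.alpha:
            title += " #"
        ax.set_title(title, fontsize=9)
        ax.tick_params(axis="x", rotation=60, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
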