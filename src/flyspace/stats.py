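"""Normality-gated group comparisons for behavioral replicate tables.

The comparison design mirrors common practice in fly behavioral work:
check each group for Gaussianity (Shapiro–Wilk), run a factorial ANOVA
(Type II sums of squares, so mildly unbalanced designs are handled) when
the data pass, and otherwise fall back to a Kruskal–Wallis rank test with
Dunn's pairwise post hoc comparisons under Holm multiplicity control.
Welch's t-test (Satterthwaite degrees of freedom) covers the two-group
unequal-variance case.

ANOVA fitting is delegated to statsmodels and the elementary tests to
scipy; the module's own contract is the gating logic, design handling and
the result schema.  Dunn's z statistics (tie-corrected) are computed here
directly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Design",
    "ComparisonResult",
    "DegenerateDataWarning",
    "normality_gate",
    "factorial_anova",
    "kruskal_dunn",
    "welch_t",
    "compare",
]


class DegenerateDataWarning(UserWarning):
    """A group was too small or constant for the normality test."""


@dataclass(frozen=True)
class Design:
    """Factorial comparison design.

    ``factors`` are the grouping columns (e.g. genotype, age class, sex,
    housing, protein isoform); the model includes all main effects and
    interactions up to ``len(factors)``-way.
    """

    response: str
    factors: tuple[str, ...]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError("need at least one factor")
        if len(self.factors) > 3:
            raise ValueError("designs beyond three-way are not supported")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class ComparisonResult:
    """Output contract of the comparison stage.

    ``terms`` holds one row per tested term (F/H/t statistic, degrees of
    freedom, p-value); ``posthoc`` the pairwise table with raw and adjusted
    p-values where a post hoc was run; ``normality`` the per-group
    Shapiro–Wilk diagnostics when gating was applied.
    """

    test: str
    terms: pd.DataFrame
    posthoc: pd.DataFrame | None = None
    normality: pd.DataFrame | None = None
    alpha: float = 0.05
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Gate
# ---------------------------------------------------------------------------

def normality_gate(
    groups: list[np.ndarray],
    alpha: float = 0.05,
    return_diagnostics: bool = False,
):
    """Choose "anova" or "rank" from per-group Shapiro–Wilk tests.

    Any group rejecting Gaussianity at ``alpha`` routes the analysis to the
    rank test.  Groups that are constant-valued or smaller than three
    observations cannot be tested and force the rank path with a warning.
    """
    rows = []
    choice = "anova"
    for i, g in enumerate(groups):
        g = np.asarray(g, dtype=float)
        if len(g) < 3:
            warnings.warn(
                f"group {i} has {len(g)} < 3 values; normality untestable, "
                "using the rank path",
                DegenerateDataWarning,
                stacklevel=2,
            )
            rows.append((i, len(g), np.nan, np.nan, False))
            choice = "rank"
            continue
        if np.ptp(g) == 0:
            warnings.warn(
                f"group {i} is constant-valued; normality untestable, "
                "using the rank path",
                DegenerateDataWarning,
                stacklevel=2,
            )
            rows.append((i, len(g), np.nan, np.nan, False))
            choice = "rank"
            continue
        w, p = sps.shapiro(g)
        passed = p >= alpha
        rows.append((i, len(g), w, p, passed))
        if not passed:
            choice = "rank"
    diag = pd.DataFrame(rows, columns=["group", "n", "W", "p", "gaussian"])
    return (choice, diag) if return_diagnostics else choice


# ---------------------------------------------------------------------------
# Parametric branch
# ---------------------------------------------------------------------------

def _check_estimable(table: pd.DataFrame, design: Design) -> None:
    cells = table.groupby(list(design.factors), observed=True).size()
    full_cells = int(np.prod([table[f].nunique() for f in design.factors]))
    if len(cells) < full_cells:
        raise ValueError(
            "design has empty cells; the "
            f"{':'.join(design.factors)} interaction is inestimable"
        )
    n_params = full_cells
    if len(table) <= n_params and len(design.factors) > 1:
        raise ValueError(
            "zero residual degrees of freedom: the "
            f"{':'.join(design.factors)} interaction is inestimable "
            "(need > 1 replicate in at least one cell)"
        )
    if len(table) <= n_params:
        raise ValueError("zero residual degrees of freedom: need replication")


def factorial_anova(table: pd.DataFrame, design: Design) -> ComparisonResult:
    """Fit a full factorial ANOVA with Type II sums of squares.

    Handles unbalanced (unequal cell count) designs; reports each main
    effect and every interaction up to the design order.
    """
    for col in (design.response, *design.factors):
        if col not in table.columns:
            raise ValueError(f"column '{col}' not in table")
    _check_estimable(table, design)
    rhs = " * ".join(f"C({f})" for f in design.factors)
    model = smf.ols(f"{design.response} ~ {rhs}", data=table).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.drop(index="Residual", errors="ignore")
    df_resid = float(model.df_resid)
    terms = pd.DataFrame(
        {
            "term": [_clean_term(t) for t in aov.index],
            "statistic": aov["F"].to_numpy(),
            "df": aov["df"].to_numpy(),
            "df_resid": df_resid,
            "p": aov["PR(>F)"].to_numpy(),
        }
    )
    return ComparisonResult(test="anova", terms=terms, alpha=design.alpha)


def _clean_term(term: str) -> str:
    return term.replace("C(", "").replace(")", "")


# ---------------------------------------------------------------------------
# Rank branch
# ---------------------------------------------------------------------------

def _dunn_posthoc(groups: dict, adjust: str = "holm") -> pd.DataFrame:
    """Tie-corrected Dunn pairwise z tests on pooled ranks."""
    names = list(groups)
    values = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction term sum(t^3 - t) / (12 (N - 1))
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    splits = np.cumsum([len(v) for v in values])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = {k: r.mean() for k, r in zip(names, group_ranks)}
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append((a, b, z, p))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    out["p_adj"] = multipletests(out["p"], method=adjust)[1] if len(out) else []
    return out


def kruskal_dunn(
    groups: dict,
    alpha: float = 0.05,
    adjust: str = "holm",
) -> ComparisonResult:
    """Kruskal–Wallis H (tie-corrected) with Dunn's post hoc pairwise tests.

    ``groups`` maps group label to its replicate values.  All-identical
    observations give H = 0, p = 1 by convention.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    values = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(len(v) < 2 for v in values):
        raise ValueError("need >= 2 values per group")
    pooled = np.concatenate(values)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*values)
    terms = pd.DataFrame(
        {"term": ["groups"], "statistic": [h], "df": [len(groups) - 1],
         "df_resid": [np.nan], "p": [p]}
    )
    posthoc = _dunn_posthoc(groups, adjust=adjust) if len(groups) > 2 else None
    return ComparisonResult(test="kruskal", terms=terms, posthoc=posthoc, alpha=alpha)


def welch_t(a: np.ndarray, b: np.ndarray, alpha: float = 0.05) -> ComparisonResult:
    """Welch's unequal-variance t-test with Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    if va + vb == 0:
        df = len(a) + len(b) - 2.0
        t, p = 0.0, 1.0
    else:
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    terms = pd.DataFrame(
        {"term": ["difference"], "statistic": [float(t)], "df": [float(df)],
         "df_resid": [np.nan], "p": [float(p)]}
    )
    return ComparisonResult(test="welch", terms=terms, alpha=alpha)


# ---------------------------------------------------------------------------
# Gated procedure
# ---------------------------------------------------------------------------

def compare(
    table: pd.DataFrame,
    design: Design,
    gate: str = "auto",
) -> ComparisonResult:
    """Run the full gated comparison on a tidy replicate table.

    With ``gate="auto"`` each factor-combination cell is Shapiro–Wilk
    tested; a rejection (or an untestable cell) routes the analysis to
    Kruskal–Wallis over the crossed groups, otherwise to the factorial
    ANOVA.  ``gate="anova"`` or ``gate="rank"`` forces a branch.
    """
    if gate not in ("auto", "anova", "rank"):
        raise ValueError("gate must be 'auto', 'anova' or 'rank'")
    grouped = {
        key: sub[design.response].to_numpy()
        for key, sub in table.groupby(list(design.factors), observed=True)
    }
    diag = None
    if gate == "auto":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateDataWarning)
            gate, diag = normality_gate(
                list(grouped.values()), alpha=design.alpha, return_diagnostics=True
            )
        diag["group"] = list(grouped.keys())
    if gate == "anova":
        result = factorial_anova(table, design)
    else:
        named = {
            "/".join(map(str, np.atleast_1d(k))): v for k, v in grouped.items()
        }
        result = kruskal_dunn(named, alpha=design.alpha)
    result.normality = diag
    return result
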