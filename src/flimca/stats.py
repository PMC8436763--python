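"""Nested nonparametric statistics on bouton-record tables.

The statistical unit is the individual bouton; boutons are nested in
cells (1-4 per cell). The branch-order question is addressed twice, as
in the source protocol: a conservative Kruskal-Wallis one-way ANOVA on
branch order alone, and a two-way ANOVA with branch order and cell
identity as factors (no interaction; Type II sums of squares, because
the nesting leaves the design unbalanced). Pharmacology and
somatic-voltage effects use the paired baseline-effect comparison with a
Shapiro-Wilk normality gate on the paired differences: normality
rejected at alpha = .05 selects the Wilcoxon signed-rank test (Pratt
zero handling), otherwise the paired t-test. All p-values are reported
raw (no multiplicity correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, PairingError

__all__ = [
    "StatResult",
    "BranchOrderResult",
    "branch_order_analysis",
    "paired_condition_test",
    "percent_change",
]

RESPONSE_COLUMNS = {"ca0": "ca0_nM", "delta": "delta_nM"}


@dataclass
class StatResult:
    """One hypothesis-test outcome with its provenance."""

    test: str
    statistic: float
    df: Optional[float]
    p_value: float
    n: tuple
    normality_gate: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ConfigurationError(f"invalid p-value {self.p_value}")


@dataclass
class BranchOrderResult:
    """Kruskal-Wallis plus two-way ANOVA results for one response."""

    kruskal: StatResult
    anova_order: StatResult
    anova_cell: StatResult


def _response_column(records: pd.DataFrame, response: str) -> str:
    col = RESPONSE_COLUMNS.get(response, response)
    if col not in records.columns:
        raise ConfigurationError(f"no column {col!r} in the record table")
    return col


def branch_order_analysis(records: pd.DataFrame,
                          response: str = "delta",
                          include_anova: bool = True) -> BranchOrderResult:
    """Branch-order effect on a response, with and without the cell factor.

    ``response`` is ``"ca0"``, ``"delta"`` or a column name. Rows with a
    missing response are dropped; branch-order levels with fewer than two
    observations are dropped with a warning. Requires at least two levels
    and cell ids. ``include_anova=False`` skips the two-way ANOVA (e.g.
    for rank-test power simulations) and returns NaN placeholders for it.
    """
    col = _response_column(records, response)
    df = records.dropna(subset=[col]).copy()
    counts = df.groupby("branch_order")[col].count()
    thin = counts[counts < 2].index.tolist()
    if thin:
        warnings.warn(
            f"dropping branch-order level(s) {thin} with < 2 observations",
            stacklevel=2,
        )
        df = df[~df["branch_order"].isin(thin)]
    groups = [g[col].to_numpy() for _, g in df.groupby("branch_order")]
    if len(groups) < 2:
        raise ConfigurationError("need >= 2 branch-order levels")
    ns = tuple(len(g) for g in groups)

    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        # all observations identical: no rank variation, treat as no effect
        kw = StatResult("kruskal-wallis", 0.0, float(len(groups) - 1), 1.0, ns)
    else:
        h, p = sps.kruskal(*groups)
        kw = StatResult("kruskal-wallis", float(h), float(len(groups) - 1),
                        float(p), ns)

    if not include_anova:
        na = StatResult("two-way-anova:skipped", np.nan, None, np.nan, ns)
        return BranchOrderResult(kw, na, na)

    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    dd = pd.DataFrame(
        {
            "resp": df[col].to_numpy(),
            "order": pd.Categorical(df["branch_order"]),
            "cell": pd.Categorical(df["cell_id"]),
        }
    )
    model = smf.ols("resp ~ C(order) + C(cell)", data=dd).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank warnings on tiny designs
        tab = anova_lm(model, typ=2)
    f_order = tab.loc["C(order)"]
    f_cell = tab.loc["C(cell)"]
    an_order = StatResult(
        "two-way-anova:branch_order",
        float(f_order["F"]),
        float(f_order["df"]),
        float(f_order["PR(>F)"]),
        ns,
    )
    an_cell = StatResult(
        "two-way-anova:cell",
        float(f_cell["F"]),
        float(f_cell["df"]),
        float(f_cell["PR(>F)"]),
        (int(dd["cell"].nunique()),),
    )
    return BranchOrderResult(kw, an_order, an_cell)


def _paired_arrays(before, after, value: Optional[str]):
    if isinstance(before, pd.DataFrame):
        if value is None:
            raise ConfigurationError("give the value column for DataFrames")
        b = before.dropna(subset=[value]).set_index("bouton_id")[value]
        a = after.dropna(subset=[value]).set_index("bouton_id")[value]
        common = b.index.intersection(a.index)
        if len(common) == 0 or len(common) < min(len(b), len(a)):
            missing = set(b.index).symmetric_difference(a.index)
            if len(common) == 0:
                raise PairingError(f"no matching bouton ids ({missing})")
        return b.loc[common].to_numpy(float), a.loc[common].to_numpy(float)
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise PairingError("before/after arrays must have equal length")
    return b, a


def paired_condition_test(
    before,
    after,
    value: Optional[str] = None,
    alpha_gate: float = 0.05,
) -> StatResult:
    """Paired baseline-effect comparison with a normality gate.

    ``before`` and ``after`` are either record DataFrames (matched on
    ``bouton_id``, with ``value`` naming the response column) or
    position-paired arrays. A Shapiro-Wilk test on the paired differences
    chooses the test: rejection at ``alpha_gate`` selects the Wilcoxon
    signed-rank test (Pratt treatment of zero differences), otherwise the
    paired t-test. Needs n >= 5 pairs.
    """
    b, a = _paired_arrays(before, after, value)
    n = len(b)
    if n < 5:
        raise ConfigurationError(f"need >= 5 pairs, got {n}")
    diff = a - b
    if np.all(diff == diff[0]):
        # constant differences: the gate is undefined; report degenerately
        p = 1.0 if diff[0] == 0 else 0.0
        return StatResult(
            "degenerate-constant-differences", 0.0, None, p, (n,),
            normality_gate="skipped (constant differences)",
        )
    sw_stat, sw_p = sps.shapiro(diff)
    if sw_p < alpha_gate:
        res = sps.wilcoxon(b, a, zero_method="pratt")
        return StatResult(
            "wilcoxon-signed-rank",
            float(res.statistic),
            None,
            float(res.pvalue),
            (n,),
            normality_gate=(
                f"shapiro-wilk p={sw_p:.3g} < {alpha_gate}: normality "
                "rejected, nonparametric test"
            ),
        )
    t = sps.ttest_rel(a, b)
    return StatResult(
        "paired-t",
        float(t.statistic),
        float(n - 1),
        float(t.pvalue),
        (n,),
        normality_gate=(
            f"shapiro-wilk p={sw_p:.3g} >= {alpha_gate}: normality retained"
        ),
    )


def percent_change(mean_before: float, mean_after: float) -> float:
    """Percent drop from baseline: 100 * (1 - after / before)."""
    if mean_before <= 0:
        raise ConfigurationError("mean_before must be > 0")
    return 100.0 * (1.0 - mean_after / mean_before)
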