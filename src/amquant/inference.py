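"""Nonparametric inference and plot annotation for colonization data.

The omnibus test is Kruskal–Wallis (tie-corrected, chi-square
approximation).  Pairwise comparisons use the rank-based Fisher-LSD
criterion: a t statistic on group mean ranks with the pooled rank variance
deflated by (N - 1 - H)/(N - k) and N - k degrees of freedom, as
conventional in agricultural statistics.  Every variable is tested
independently, and p-value adjustment is applied within the pairwise family
of one variable.

All routines here are deterministic; no randomness is involved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InferenceError, SchemaError
from .summaries import collapse_technical
from .tabular_io import Dataset

#: Supported p-value adjustment methods ("fdr" is an alias of "BH").
ADJUST_METHODS = ("none", "holm", "hommel", "hochberg", "bonferroni",
                  "BH", "BY", "fdr")

_SM_METHOD = {"holm": "holm", "hommel": "hommel", "hochberg": "simes-hochberg",
              "bonferroni": "bonferroni", "bh": "fdr_bh", "by": "fdr_by",
              "fdr": "fdr_bh"}


@dataclass(frozen=True)
class TestResult:
    """Kruskal–Wallis omnibus outcome."""

    H: float
    df: int
    p: float


@dataclass
class ComparisonTable:
    """Pairwise adjusted p-values, one row per sample pair per variable.

    ``data`` columns: sample_1, sample_2, variable, p_raw, p_adj.
    """

    data: pd.DataFrame
    method: str
    samples: list[str]
    variables: list[str]
    omnibus: dict[str, TestResult] = field(default_factory=dict)

    def wide(self) -> pd.DataFrame:
        """Pivot to one row per pair with one adjusted-p column per variable."""
        pairs = list(dict.fromkeys(zip(self.data["sample_1"],
                                       self.data["sample_2"])))
        rows = []
        for s1, s2 in pairs:
            row = {"sample_1": s1, "sample_2": s2}
            block = self.data[(self.data["sample_1"] == s1)
                              & (self.data["sample_2"] == s2)]
            for v in self.variables:
                cell = block.loc[block["variable"] == v, "p_adj"]
                row[v] = float(cell.iloc[0]) if len(cell) else float("nan")
            rows.append(row)
        if not rows:
            return pd.DataFrame(columns=["sample_1", "sample_2", *self.variables])
        return pd.DataFrame(rows)

    def variable_rows(self, variable: str) -> pd.DataFrame:
        return self.data[self.data["variable"] == variable]


@dataclass
class AnnotationSet:
    """Plot annotation marks: letters or asterisks per (variable, sample)."""

    style: str  # "asterisks" or "letters"
    marks: dict[str, dict[str, str]]  # variable -> sample -> mark
    alpha: float
    method: str


def rank_midties(values: Sequence[float]) -> np.ndarray:
    """Rank values 1..N, assigning tied values the mean of the spanned ranks."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InferenceError("cannot rank an empty sequence")
    if not np.all(np.isfinite(values)):
        raise InferenceError("cannot rank non-finite values")
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=float)
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _tie_correction(values: np.ndarray) -> float:
    """1 - sum(t^3 - t)/(N^3 - N) over tie groups; 0 when all values equal."""
    N = values.size
    _, counts = np.unique(values, return_counts=True)
    return 1.0 - float(np.sum(counts**3 - counts)) / (N**3 - N)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal–Wallis test with chi-square p-value.

    When every observation is identical the statistic is defined as 0 and
    p = 1.
    """
    if len(groups) < 2:
        raise InferenceError("Kruskal-Wallis needs at least 2 groups")
    sizes = [len(g) for g in groups]
    if min(sizes) < 1:
        raise InferenceError("every group needs at least one observation")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    N = pooled.size
    if N < 3:
        raise InferenceError("Kruskal-Wallis needs at least 3 observations")
    k = len(groups)
    ranks = rank_midties(pooled)
    correction = _tie_correction(pooled)
    if correction <= 0.0:  # all observations identical
        return TestResult(0.0, k - 1, 1.0)
    H = 12.0 / (N * (N + 1)) * sum(
        n_i * np.mean(r_i)**2
        for n_i, r_i in zip(sizes, np.split(ranks, np.cumsum(sizes)[:-1]))
    ) - 3.0 * (N + 1)
    H /= correction
    H = max(H, 0.0)
    p = float(stats.chi2.sf(H, k - 1))
    return TestResult(float(H), k - 1, p)


def pairwise_lsd_on_ranks(groups: Sequence[Sequence[float]],
                          labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Rank-based Fisher-LSD pairwise comparisons after Kruskal–Wallis.

    For each pair (i, j) the statistic is
    ``t = |Rbar_i - Rbar_j| / sqrt(S2 * (N-1-H)/(N-k) * (1/n_i + 1/n_j))``
    with ``S2`` the ddof-1 variance of the pooled (tie-respecting) ranks,
    referred to a t distribution with N - k degrees of freedom (two-sided).

    Returns a DataFrame with columns sample_1, sample_2, p.
    """
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    omnibus = kruskal_wallis(groups)
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    N, k = pooled.size, len(groups)
    if N - k <= 0:
        raise InferenceError("no residual degrees of freedom for the post hoc "
                             "test (need N > number of groups)")
    ranks = rank_midties(pooled)
    mean_ranks = [np.mean(r) for r in np.split(ranks, np.cumsum(sizes)[:-1])]
    S2 = float(np.var(ranks, ddof=1))
    deflation = max((N - 1 - omnibus.H) / (N - k), 0.0)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(S2 * deflation * (1.0 / sizes[i] + 1.0 / sizes[j]))
        diff = abs(mean_ranks[i] - mean_ranks[j])
        if se == 0.0:
            p = 1.0 if diff == 0.0 else 0.0
        else:
            p = 2.0 * float(stats.t.sf(diff / se, N - k))
        rows.append({"sample_1": labels[i], "sample_2": labels[j],
                     "p": min(p, 1.0)})
    return pd.DataFrame(rows)


def adjust_pvalues(p: Sequence[float], method: str = "none") -> np.ndarray:
    """Adjust a vector of p-values for multiple testing.

    Supported methods: none, holm, hommel, hochberg, bonferroni, BH, BY and
    fdr (alias of BH).  Input order is preserved and results are clipped to
    [0, 1].
    """
    key = str(method).strip().lower()
    valid = {m.lower() for m in ADJUST_METHODS}
    if key not in valid:
        raise InferenceError(f"unknown adjustment method {method!r}; "
                             f"valid methods: {list(ADJUST_METHODS)}")
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise InferenceError("p-values must lie in [0, 1]")
    if key == "none":
        return p.copy()
    adjusted = multipletests(p, method=_SM_METHOD[key])[1]
    return np.clip(adjusted, 0.0, 1.0)


def _replicate_values(ds: Dataset) -> tuple[pd.DataFrame, list[str]]:
    table = collapse_technical(ds)
    variables = [v for v in table.columns
                 if v not in ("Samples", "Replicates", "trt")]
    return table, variables


def pairwise_tests(ds: Dataset, method: str = "none") -> ComparisonTable:
    """Per-variable pairwise rank-LSD comparisons across all sample pairs.

    Technical replicates are collapsed first (grid) or pooled into indices
    (trouvelot); each variable is tested independently and the adjustment is
    applied within that variable's pairwise family.
    """
    if len(ds.sample_order) < 2:
        raise InferenceError("statistical comparison needs at least 2 samples")
    adjust_pvalues([], method)  # validate the method name up front
    table, variables = _replicate_values(ds)
    samples = list(ds.sample_order)
    groups_by_sample = {s: table[table["Samples"] == s] for s in samples}
    rows = []
    omnibus = {}
    for v in variables:
        groups = [groups_by_sample[s][v].to_numpy(dtype=float) for s in samples]
        omnibus[v] = kruskal_wallis(groups)
        lsd = pairwise_lsd_on_ranks(groups, samples)
        adj = adjust_pvalues(lsd["p"].to_numpy(), method)
        for (_, row), p_adj in zip(lsd.iterrows(), adj):
            rows.append({"sample_1": row["sample_1"], "sample_2": row["sample_2"],
                         "variable": v, "p_raw": float(row["p"]),
                         "p_adj": float(p_adj)})
    data = pd.DataFrame(rows, columns=["sample_1", "sample_2", "variable",
                                       "p_raw", "p_adj"])
    return ComparisonTable(data, method, samples, variables, omnibus)


def oneway_tests(ds: Dataset, method: str = "none") -> ComparisonTable:
    """One-way analysis: identical to :func:`pairwise_tests` (the omnibus
    Kruskal–Wallis results are always attached as ``.omnibus``)."""
    return pairwise_tests(ds, method)


def compact_letter_display(rows: pd.DataFrame, alpha: float,
                           sample_order: Sequence[str]) -> dict[str, str]:
    """Assign compact letters so that two samples share a letter iff their
    adjusted p-value is >= alpha (insert-and-absorb algorithm).

    ``rows`` must contain columns sample_1, sample_2 and p_adj (or p) and
    cover every unordered pair of ``sample_order``.
    """
    samples = list(sample_order)
    pcol = "p_adj" if "p_adj" in rows.columns else "p"
    pmat: dict[frozenset, float] = {}
    for _, row in rows.iterrows():
        pmat[frozenset((row["sample_1"], row["sample_2"]))] = float(row[pcol])
    expected = {frozenset(pair) for pair in itertools.combinations(samples, 2)}
    missing = expected - set(pmat)
    if missing:
        raise InferenceError(
            f"incomplete pair coverage for letter display: missing "
            f"{sorted(tuple(sorted(m)) for m in missing)}")

    columns: list[set[str]] = [set(samples)]
    order = {s: i for i, s in enumerate(samples)}
    for s1, s2 in itertools.combinations(samples, 2):
        if pmat[frozenset((s1, s2))] >= alpha:
            continue  # not significant: may share
        new_columns: list[set[str]] = []
        for col in columns:
            if s1 in col and s2 in col:
                new_columns.append(col - {s1})
                new_columns.append(col - {s2})
            else:
                new_columns.append(col)
        # absorb: drop empty columns, proper subsets and duplicates
        columns = []
        for col in new_columns:
            if not col or any(col < other for other in new_columns):
                continue
            if col not in columns:
                columns.append(col)
    unique = sorted(columns, key=lambda col: (min(order[s] for s in col),
                                              sorted(order[s] for s in col)))
    letters = "abcdefghijklmnopqrstuvwxyz"
    if len(unique) > len(letters):
        raise InferenceError("more letter groups than available letters")
    assigned: dict[str, list[str]] = {s: [] for s in samples}
    for letter, col in zip(letters, unique):
        for s in col:
            assigned[s].append(letter)
    return {s: "".join(sorted(assigned[s])) for s in samples}


def asterisks_vs_control(rows: pd.DataFrame, control: str,
                         alpha: float = 0.05) -> dict[str, str]:
    """Mark each sample with "*" iff its adjusted p against the control is
    below alpha; the control itself is never marked."""
    pcol = "p_adj" if "p_adj" in rows.columns else "p"
    samples: list[str] = []
    pvals: dict[str, float] = {}
    for _, row in rows.iterrows():
        s1, s2 = row["sample_1"], row["sample_2"]
        for s in (s1, s2):
            if s not in samples:
                samples.append(s)
        if control in (s1, s2):
            other = s2 if s1 == control else s1
            pvals[other] = float(row[pcol])
    if control not in samples:
        raise InferenceError(f"control {control!r} absent from the comparisons")
    marks = {control: ""}
    for s in samples:
        if s == control:
            continue
        if s not in pvals:
            raise InferenceError(f"no comparison between control and {s!r}")
        marks[s] = "*" if pvals[s] < alpha else ""
    return marks


def annotations(ds: Dataset, style: str, method: str = "none",
                alpha: float = 0.05) -> AnnotationSet:
    """Compute per-variable plot annotation marks (letters or asterisks)."""
    if style not in ("asterisks", "letters"):
        raise InferenceError(f"unknown annotation style {style!r}; "
                             "expected 'asterisks' or 'letters'")
    cmp = pairwise_tests(ds, method)
    marks: dict[str, dict[str, str]] = {}
    for v in cmp.variables:
        rows = cmp.variable_rows(v)
        if style == "letters":
            marks[v] = compact_letter_display(rows, alpha, ds.sample_order)
        else:
            marks[v] = asterisks_vs_control(rows, ds.control, alpha)
    return AnnotationSet(style, marks, alpha, method)


@dataclass
class AnovaTable:
    """Two-way ANOVA decomposition plus residual diagnostics for one variable.

    ``table`` rows: the sample factor, trt, their interaction and Residual,
    with sequential (Type I) sums of squares.  ``qq_theoretical`` /
    ``qq_sample`` are paired normal Q-Q coordinates sorted by sample
    quantile.
    """

    table: pd.DataFrame
    fitted: np.ndarray
    residuals: np.ndarray
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray


def twoway_anova(ds: Dataset) -> dict[str, AnovaTable]:
    """Parametric two-way ANOVA (sample x trt, with interaction) per variable.

    Requires the dataset to carry a ``trt`` factor column; sums of squares
    are sequential in the order sample, trt, sample:trt.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if not ds.has_trt:
        raise SchemaError("two-way ANOVA requires a 'trt' factor column")
    table, variables = _replicate_values(ds)
    for factor in ("Samples", "trt"):
        if table[factor].nunique() < 2:
            raise InferenceError(f"factor {factor!r} needs at least 2 levels")
    out: dict[str, AnovaTable] = {}
    for v in variables:
        df = table[["Samples", "trt", v]].rename(columns={v: "value"})
        model = smf.ols("value ~ C(Samples) * C(trt)", data=df).fit()
        if model.df_resid <= 0:
            raise InferenceError("no residual degrees of freedom for two-way "
                                 "ANOVA (need replication within cells)")
        with np.errstate(divide="ignore", invalid="ignore"):
            aov = sm.stats.anova_lm(model, typ=1)
        aov = aov.rename(index={"C(Samples)": "Samples", "C(trt)": "trt",
                                "C(Samples):C(trt)": "Samples:trt"})
        if "mean_sq" not in aov.columns:
            aov.insert(2, "mean_sq", aov["sum_sq"] / aov["df"])
        aov = aov.rename(columns={"PR(>F)": "p"})
        residuals = np.asarray(model.resid)
        fitted = np.asarray(model.fittedvalues)
        (osm, osr), _ = stats.probplot(residuals, dist="norm")
        out[v] = AnovaTable(aov, fitted, residuals, osm, osr)
    return out
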