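"""GO-term overrepresentation and expression/evolution statistics.

Covers the comparative layer of the analysis: selecting tau-extreme gene
sets, one-sided hypergeometric (Fisher) overrepresentation of GO terms
with multiple-testing adjustment, Pearson/Spearman correlations between
expression breadth, expression level, gene length and omega (dN/dS), group
comparisons (Kruskal-Wallis / one-way ANOVA) of omega and tau across
tissues of maximal expression, and the per-tissue summary table with
bootstrap confidence intervals.

GO terms are treated as flat labels (no ancestor propagation), matching
how term lists exported per gene are consumed by simple overrepresentation
scans.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests


class CorrelationResult(NamedTuple):
    r: float
    df: int
    p_value: float
    n: int
    method: str


class GroupCompareResult(NamedTuple):
    statistic: float
    df: tuple[int, ...]
    p_value: float
    method: str


def select_tau_extreme_sets(
    tau: pd.Series | pd.DataFrame, k: int = 500
) -> tuple[list[str], list[str]]:
    """The k most and k least tissue-specific genes.

    ``tau`` may be the tau table (with a ``tau`` column) or a Series of
    tau values indexed by gene id; withheld (NaN) values are ignored.
    Ties at either boundary are broken by gene id so the selection is
    deterministic; the two sets are disjoint whenever 2k <= n.
    """
    if isinstance(tau, pd.DataFrame):
        tau = tau["tau"]
    tau = tau.dropna()
    if len(tau) < 2 * k:
        raise ValueError(
            f"need at least {2 * k} unfiltered genes, have {len(tau)}"
        )
    frame = tau.rename("tau").rename_axis("gene_id").reset_index()
    frame = frame.sort_values(["tau", "gene_id"], kind="mergesort")
    low = frame["gene_id"].head(k).tolist()
    high = frame["gene_id"].tail(k).tolist()
    return high, low


def _terms_of(annotations, gene: str) -> set[str]:
    val = annotations.get(gene, set())
    if isinstance(val, str):
        return {t for t in val.split(";") if t}
    return set(val)


def go_overrepresentation(
    gene_set: Iterable[str],
    universe: Iterable[str],
    annotations: Mapping[str, set[str] | str] | pd.Series,
    alpha: float = 0.05,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation of GO terms.

    For each term annotating the universe, the raw p-value is
    ``P[X >= set_count]`` with ``X ~ Hypergeom(universe_size,
    universe_count, set_size)`` — the probability that a random gene set
    of the same size contains at least as many term-annotated genes.
    P-values are adjusted across terms (Benjamini-Hochberg by default,
    ``method='bonferroni'`` available) and terms with adjusted p < alpha
    are flagged significant.

    ``annotations`` maps gene id to a term set (or a semicolon-joined
    string, as in the annotation TSV).  The universe is typically the
    detected genes; ``gene_set`` must be a subset of it.
    """
    gene_set = set(gene_set)
    universe = set(universe)
    if not gene_set <= universe:
        extra = sorted(gene_set - universe)[:5]
        raise ValueError(f"gene set not a subset of the universe (e.g. {extra})")
    if isinstance(annotations, pd.Series):
        annotations = annotations.to_dict()

    term_universe: dict[str, int] = {}
    term_set: dict[str, int] = {}
    for gene in universe:
        for term in _terms_of(annotations, gene):
            term_universe[term] = term_universe.get(term, 0) + 1
            if gene in gene_set:
                term_set[term] = term_set.get(term, 0) + 1

    m, n = len(universe), len(gene_set)
    rows = []
    for term, big_k in sorted(term_universe.items()):
        k = term_set.get(term, 0)
        p = float(min(1.0, _st.hypergeom.sf(k - 1, m, big_k, n)))
        rows.append((term, k, n, big_k, m, p))
    result = pd.DataFrame(
        rows,
        columns=[
            "term_id", "set_count", "set_size",
            "universe_count", "universe_size", "p_raw",
        ],
    )
    if len(result):
        adjusted = multipletests(result["p_raw"], method=method)[1]
        result["p_adjusted"] = np.minimum(
            1.0, np.maximum(adjusted, result["p_raw"])
        )
        result["significant"] = result["p_adjusted"] < alpha
        result = result.sort_values(
            ["p_adjusted", "p_raw", "term_id"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        result["p_adjusted"] = []
        result["significant"] = []
    return result


_TRANSFORMS = {
    "none": lambda v: v,
    "log": np.log10,
    "log1p": np.log1p,
}


def correlate(
    x, y, method: str = "pearson", transform: str | tuple[str, str] = "none"
) -> CorrelationResult:
    """Correlation between two paired variables.

    ``method`` is 'pearson' or 'spearman' (average ranks on ties);
    ``transform`` ('none' | 'log' | 'log1p') is applied to both variables,
    or per-variable when given as a pair.  Pairs with missing values are
    dropped; df = n - 2.
    """
    if isinstance(transform, str):
        tx = ty = transform
    else:
        tx, ty = transform
    x = np.asarray(pd.Series(x), dtype=float)
    y = np.asarray(pd.Series(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = _TRANSFORMS[tx](x[ok]), _TRANSFORMS[ty](y[ok])
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "pearson":
        r, p = _st.pearsonr(x, y)
    elif method == "spearman":
        r, p = _st.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return CorrelationResult(float(r), int(x.size - 2), float(p), int(x.size), method)


def group_compare(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    method: str = "kruskal",
) -> GroupCompareResult:
    """Compare a variable across groups (e.g. tissues of maximal expression).

    'kruskal': tie-corrected Kruskal-Wallis H, df = (k - 1,).
    'anova': one-way ANOVA F, df = (k - 1, n - k).
    Requires >= 2 groups with >= 2 values each.
    """
    if isinstance(groups, Mapping):
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(arrays)
    n = sum(a.size for a in arrays)
    if method == "kruskal":
        flat = np.concatenate(arrays)
        if np.all(flat == flat[0]):  # scipy rejects all-identical data
            return GroupCompareResult(0.0, (k - 1,), 1.0, method)
        h, p = _st.kruskal(*arrays)
        return GroupCompareResult(float(h), (k - 1,), float(p), method)
    if method == "anova":
        f, p = _st.f_oneway(*arrays)
        if np.isnan(f):  # zero variance everywhere
            f, p = 0.0, 1.0
        return GroupCompareResult(float(f), (k - 1, n - k), float(p), method)
    raise ValueError("method must be 'kruskal' or 'anova'")


def _bootstrap_ci(
    values: np.ndarray,
    rng: np.random.Generator,
    n_boot: int,
    level: float = 0.95,
) -> tuple[float, float]:
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def summarize_by_max_tissue(
    tau_table: pd.DataFrame,
    gene_records: pd.DataFrame,
    counts: pd.DataFrame | None = None,
    n_boot: int = 10_000,
    ci_method: str = "bootstrap",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-tissue summary of omega and tau for genes with maximal
    expression in that tissue.

    Columns: ``n_max`` (genes whose highest read count is in the tissue),
    ``n_unique`` (genes expressed exclusively there; requires ``counts``),
    mean omega and mean tau with 95% CIs.  CIs are nonparametric bootstrap
    percentile intervals by default (omega is heavily right-skewed, so a
    normal-theory interval would be misleading); ``ci_method='t'`` gives
    the classical t-interval.  CIs are NA for groups with fewer than 3
    genes.
    """
    merged = tau_table.join(gene_records[["omega"]], how="inner")
    merged = merged[merged["max_tissue"].notna()]
    rng = np.random.default_rng([int(seed), 41])
    rows = []
    tissues = [c for c in (counts.columns if counts is not None else
                           pd.unique(merged["max_tissue"]))]
    for tissue in tissues:
        sub = merged[merged["max_tissue"] == tissue]
        n_max = len(sub)
        if counts is not None and n_max:
            sub_counts = counts.loc[sub.index]
            only_here = (sub_counts.drop(columns=tissue).sum(axis=1) == 0) & (
                sub_counts[tissue] > 0
            )
            n_unique = int(only_here.sum())
        else:
            n_unique = 0 if counts is not None else np.nan
        row = {"tissue": tissue, "n_max": n_max, "n_unique": n_unique}
        for var in ("omega", "tau"):
            vals = sub[var].dropna().to_numpy(float)
            row[f"mean_{var}"] = vals.mean() if vals.size else np.nan
            if vals.size >= 3:
                if ci_method == "bootstrap":
                    lo, hi = _bootstrap_ci(vals, rng, n_boot)
                elif ci_method == "t":
                    sem = _st.sem(vals)
                    lo, hi = _st.t.interval(0.95, vals.size - 1, vals.mean(), sem)
                else:
                    raise ValueError("ci_method must be 'bootstrap' or 't'")
            else:
                lo = hi = np.nan
            row[f"{var}_ci_low"], row[f"{var}_ci_high"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows).set_index("tissue")
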