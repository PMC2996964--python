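"""The tau index of tissue specificity of gene expression.

For a gene with expression measured in N >= 2 tissues, let ``x_i`` be the
log2 of its TPM in tissue i after flooring tissues with *no detected
expression* (TPM exactly 0) at ``floor_tpm`` (default 2 TPM).  Then

    tau = sum_i (1 - x_i / x_max) / (N - 1),      x_max = max_i x_i.

tau is 0 for a gene expressed equally in every tissue (housekeeping-like)
and approaches 1 for a gene expressed in a single tissue.  The floor keeps
the log transform defined for undetected tissues and damps the specificity
attributed to absences at shallow sequencing depth.

Conventions implemented here (pinned by the bundled MHC worked example in
:mod:`tissuespec.datasets`):

* log base 2;
* the floor applies to zero TPM only — a small positive TPM enters
  unfloored;
* tau estimates from fewer than four reads in total are withheld
  (reported as missing), because at 3 reads or fewer the profile is pure
  sampling noise;
* the tissue of maximal expression is the argmax of *read counts* (not
  TPM), subject to the same four-read minimum.

tau values are only comparable at a fixed tissue count N; results carry N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .quantify import compute_tpm

#: Marker used when rendering a withheld (read-filtered) tau.
FILTERED_MARKER = "-"


def compute_tau(tpm_profile, floor_tpm: float = 2.0) -> float:
    """Compute tau for one expression profile (TPM per tissue).

    Parameters
    ----------
    tpm_profile
        Non-negative TPM values, one per tissue (N >= 2).
    floor_tpm
        Value substituted for tissues with TPM exactly 0.

    Returns
    -------
    tau in [0, 1].  0 iff all floored log-TPM values are equal.

    Notes
    -----
    The result is clipped into [0, 1]: with positive TPM below 1 (possible
    only at library sizes beyond the regime this floor convention was
    designed for) a log term can turn negative and push the raw sum above
    1.
    """
    x = np.asarray(tpm_profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau requires a 1-D profile over at least 2 tissues")
    if (x < 0).any() or np.isnan(x).any():
        raise ValueError("TPM values must be non-negative and finite")
    return float(compute_tau_matrix(x[None, :], floor_tpm=floor_tpm)[0])


def compute_tau_matrix(tpm: np.ndarray, floor_tpm: float = 2.0) -> np.ndarray:
    """Vectorised tau over the rows of a (profiles x tissues) TPM array."""
    x = np.array(tpm, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("expected a 2-D array with >= 2 tissue columns")
    if (x < 0).any() or np.isnan(x).any():
        raise ValueError("TPM values must be non-negative and finite")
    x[x == 0] = floor_tpm
    lx = np.log2(x)
    xmax = lx.max(axis=1)
    n = x.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = (1.0 - lx / xmax[:, None]).sum(axis=1) / (n - 1)
    # all-equal rows (including xmax == 0 exactly) are uniform: tau = 0
    uniform = np.all(lx == lx[:, [0]], axis=1)
    tau[uniform] = 0.0
    return np.clip(tau, 0.0, 1.0)


def assign_max_tissue(
    counts, min_reads: int = 4, tissue_order=None
) -> tuple[str | None, bool]:
    """Tissue of maximal expression for one profile of read counts.

    Returns ``(tissue, tie)``: the tissue with the highest read count, or
    ``None`` if fewer than ``min_reads`` reads in total.  Ties are broken
    by the first tissue in ``tissue_order`` (default: input order) and
    flagged with ``tie=True``.
    """
    counts = pd.Series(counts)
    if tissue_order is not None:
        counts = counts.reindex(tissue_order)
    total = counts.sum()
    if total < min_reads:
        return None, False
    top = counts.max()
    winners = counts.index[counts == top]
    return winners[0], len(winners) > 1


def filter_low_reads(
    counts: pd.DataFrame,
    library_sizes,
    min_reads: int = 4,
    floor_tpm: float = 2.0,
    tpm: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Compute the tau table with the minimum-read filter applied.

    Parameters
    ----------
    counts
        Entity (gene or contig) x library integer read counts.
    library_sizes
        Total reads per library, used to convert counts to TPM unless a
        precomputed ``tpm`` table is given.
    min_reads
        Profiles with fewer total reads get no tau and no max tissue
        (withheld; "fewer than four reads" and "3 or fewer reads" are the
        same rule at the default).
    floor_tpm
        Zero-TPM floor passed to the tau computation.
    tpm
        Optional TPM table aligned with ``counts``; by default recomputed
        from the counts, which reproduces published tau values exactly
        where a printed TPM table has been rounded.

    Returns
    -------
    DataFrame indexed like ``counts`` with columns ``tau`` (float, NaN
    when withheld), ``total_reads``, ``max_tissue`` (None when withheld),
    ``max_tie`` and ``n_tissues``.
    """
    if tpm is None:
        tpm = compute_tpm(counts, library_sizes)
    taus = compute_tau_matrix(tpm.to_numpy(float), floor_tpm=floor_tpm)
    totals = counts.sum(axis=1)
    keep = totals >= min_reads

    arr = counts.to_numpy()
    max_idx = arr.argmax(axis=1)
    tie = (arr == arr.max(axis=1, keepdims=True)).sum(axis=1) > 1
    tissues = np.asarray(counts.columns, dtype=object)

    out = pd.DataFrame(
        {
            "tau": np.where(keep, taus, np.nan),
            "total_reads": totals.astype(int),
            "max_tissue": np.where(keep, tissues[max_idx], None),
            "max_tie": np.where(keep, tie, False),
            "n_tissues": counts.shape[1],
        },
        index=counts.index,
    )
    out.index.name = counts.index.name or "entity_id"
    return out


def render_tau(tau: float, decimals: int = 3) -> str:
    """Format a tau value for reports; NaN renders as the filtered marker."""
    if tau is None or (isinstance(tau, float) and np.isnan(tau)):
        return FILTERED_MARKER
    return f"{tau:.{decimals}f}"


@dataclass
class TauDistributionSummary:
    """Histogram and percentile view of a tau distribution."""

    bin_edges: np.ndarray
    bin_counts: np.ndarray
    values: np.ndarray
    bimodality_coefficient: float

    def percentile_of(self, tau: float) -> float:
        """Percentile rank (0-100) of a tau value within the distribution."""
        return float(_st.percentileofscore(self.values, tau, kind="weak"))


def tau_distribution_summary(
    taus, n_bins: int = 20
) -> TauDistributionSummary:
    """Summarise a collection of (unfiltered) tau values.

    The bimodality coefficient is Sarle's ``(g1^2 + 1) / (g2 + 3(n-1)^2 /
    ((n-2)(n-3)))`` (skewness g1, excess kurtosis g2); values above ~5/9
    suggest a bimodal or heavily skewed distribution.  For n <= 3 the
    coefficient is NaN.
    """
    values = np.asarray(pd.Series(taus).dropna(), dtype=float)
    if values.size == 0:
        raise ValueError("no unfiltered tau values to summarise")
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    n = values.size
    if n > 3 and values.std() > 0:
        g1 = _st.skew(values, bias=False)
        g2 = _st.kurtosis(values, bias=False)
        bc = (g1**2 + 1) / (g2 + 3 * (n - 1) ** 2 / ((n - 2) * (n - 3)))
    else:
        bc = float("nan")
    return TauDistributionSummary(edges, counts, values, float(bc))
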