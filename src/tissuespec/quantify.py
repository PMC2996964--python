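"""Gene-level quantification of digital expression counts.

Contig-level read counts are aggregated to gene level via contig-to-gene
assignments, then normalised to transcripts per million (TPM).

TPM here is the EST/454-era *count-proportion* TPM:

    tpm[g, t] = counts[g, t] / library_size[t] * 1e6

There is **no transcript-length correction** — this is the tag-counting
normalisation of classic digital-expression studies, not the modern
length-normalised RNA-seq TPM.  With short 454 contigs the read count is a
direct (if 3'-biased) tag count per gene, so the proportion of a library's
reads is the natural expression measure.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

#: Row label under which reads from contigs with no gene assignment are
#: pooled, so that per-library totals stay conserved and reportable.
UNANNOTATED_ID = "__unannotated__"


def _as_library_sizes(library_sizes, columns) -> pd.Series:
    sizes = pd.Series(library_sizes)
    if not sizes.index.equals(pd.Index(columns)):
        # allow positional specification (list/tuple/array)
        if len(sizes) != len(columns):
            raise ValueError(
                f"{len(sizes)} library sizes for {len(columns)} libraries"
            )
        if not set(columns).issubset(set(sizes.index)):
            sizes.index = columns
        else:
            sizes = sizes.reindex(columns)
    if (sizes <= 0).any() or sizes.isna().any():
        raise ValueError("library sizes must be positive")
    return sizes.astype(float)


def aggregate_contigs_to_genes(
    contig_counts: pd.DataFrame,
    assignments: Mapping[str, str],
    keep_unannotated: bool = True,
) -> pd.DataFrame:
    """Sum contig read counts to gene level.

    Parameters
    ----------
    contig_counts
        Contig x library integer count table (contig ids as index).
    assignments
        Mapping of contig id -> gene id (e.g. from best-BLAST-hit
        assignment).  Every key must be present in ``contig_counts``.
    keep_unannotated
        If true (default), counts of contigs absent from ``assignments``
        are summed into a single :data:`UNANNOTATED_ID` row so that total
        reads are conserved; if false the row is dropped.

    Returns
    -------
    Gene x library count table.  Total reads are conserved exactly when
    ``keep_unannotated`` is true.
    """
    unknown = set(assignments) - set(contig_counts.index)
    if unknown:
        raise KeyError(
            f"assignments reference contigs absent from the count table: "
            f"{sorted(unknown)[:5]}{'...' if len(unknown) > 5 else ''}"
        )
    gene_of = pd.Series(
        [assignments.get(c, UNANNOTATED_ID) for c in contig_counts.index],
        index=contig_counts.index,
    )
    gene_counts = contig_counts.groupby(gene_of).sum()
    gene_counts.index.name = "gene_id"
    if not keep_unannotated and UNANNOTATED_ID in gene_counts.index:
        gene_counts = gene_counts.drop(index=UNANNOTATED_ID)
    return gene_counts


def compute_tpm(counts: pd.DataFrame, library_sizes) -> pd.DataFrame:
    """Normalise a gene (or contig) x library count table to TPM.

    ``tpm = counts / library_size * 1e6`` per library.  Zero counts give
    TPM 0; the zero-floor used by the tau index is *not* applied here (it
    belongs to the specificity computation only).
    """
    sizes = _as_library_sizes(library_sizes, counts.columns)
    if (np.asarray(counts) < 0).any():
        raise ValueError("negative read counts")
    return counts.div(sizes, axis=1) * 1e6


def infer_counts_from_tpm(tpm: pd.DataFrame, library_sizes) -> pd.DataFrame:
    """Recover integer read counts from a count-proportion TPM table.

    Rounds ``tpm * library_size / 1e6`` to the nearest integer (half away
    from zero), which inverts :func:`compute_tpm` for tables printed to
    limited precision.  Needed to apply the minimum-read filter to
    published TPM tables.
    """
    sizes = _as_library_sizes(library_sizes, tpm.columns)
    if (np.asarray(tpm) < 0).any():
        raise ValueError("negative TPM")
    raw = tpm.mul(sizes, axis=1) / 1e6
    return np.floor(raw + 0.5).astype(np.int64)
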