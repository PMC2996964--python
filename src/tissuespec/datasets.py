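"""Bundled reference data: zebra finch MHC-region expression profiles.

The dataset below is the published seven-library digital-expression profile
of ten MHC-region genes in the zebra finch (*Taeniopygia guttata*): six
tissue cDNA libraries sequenced on the 454 GS20 platform (embryo, liver,
muscle, skin, spleen, testes) plus a brain EST library.  Values are
transcripts per million (TPM) in the count-proportion sense — reads assigned
to the gene divided by library size, times 10^6 — printed to one decimal.

These profiles are the canonical worked example for the tau
tissue-specificity index with the EST-era conventions implemented in
:mod:`tissuespec.tau` (zero TPM floored at 2, log2 transform, profiles with
fewer than four reads withheld).
"""

from __future__ import annotations

import pandas as pd

#: Library labels for the seven-library MHC analysis, in column order.
MHC_TISSUES: tuple[str, ...] = (
    "brain_est",
    "embryo",
    "liver",
    "muscle",
    "skin",
    "spleen",
    "testes",
)

#: Total reads per library for the seven-library MHC analysis.
MHC_LIBRARY_SIZES: dict[str, int] = {
    "brain_est": 92_040,
    "embryo": 323_897,
    "liver": 392_890,
    "muscle": 325_646,
    "skin": 252_349,
    "spleen": 287_902,
    "testes": 299_755,
}

#: The six 454 tissue libraries used for the genome-wide analyses
#: (brain EST excluded).
TISSUES_454: tuple[str, ...] = MHC_TISSUES[1:]

_MHC_TPM_ROWS: dict[str, tuple[float, ...]] = {
    "TUBB": (21.7, 3.1, 0.0, 0.0, 0.0, 0.0, 0.0),
    "TRIM7.2": (97.8, 0.0, 0.0, 3.1, 0.0, 0.0, 0.0),
    "TRIM39": (0.0, 0.0, 2.5, 0.0, 4.0, 6.9, 3.3),
    "TRIM27": (10.9, 3.1, 0.0, 0.0, 0.0, 0.0, 0.0),
    "Ii": (76.1, 182.2, 323.2, 887.5, 241.7, 4060.4, 250.2),
    "ClassI": (130.4, 6.2, 106.9, 18.4, 31.7, 1695.0, 110.1),
    "CIITA": (0.0, 0.0, 0.0, 0.0, 0.0, 10.4, 0.0),
    "CD1A": (0.0, 0.0, 2.5, 0.0, 0.0, 55.6, 0.0),
    "BRD2": (21.7, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    "B2M": (10.9, 0.0, 45.8, 9.2, 27.7, 896.1, 43.4),
}


def mhc_expression_tpm() -> pd.DataFrame:
    """Return the MHC gene x library TPM table (genes as rows).

    TPM values are as printed (one decimal).  To recover integer read
    counts — needed for the minimum-read filter — use
    :func:`tissuespec.quantify.infer_counts_from_tpm` with
    :func:`mhc_library_sizes`.
    """
    return pd.DataFrame.from_dict(
        _MHC_TPM_ROWS, orient="index", columns=list(MHC_TISSUES)
    ).rename_axis(index="gene_id")


def mhc_library_sizes() -> pd.Series:
    """Library sizes (total reads) aligned to the columns of
    :func:`mhc_expression_tpm`."""
    return pd.Series(MHC_LIBRARY_SIZES, name="library_size")
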