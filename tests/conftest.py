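import pytest

import tissuespec as ts
from tissuespec import datasets


@pytest.fixture(scope="session")
def small_study() -> ts.SyntheticStudy:
    """A complete simulated study, small but with contaminants and decoys."""
    config = ts.SimulationConfig(n_genes=400, seed=11, contaminant_fraction=0.01)
    return ts.simulate_study(config)


@pytest.fixture(scope="session")
def mhc():
    """(TPM table, library sizes) for the bundled MHC worked example."""
    return datasets.mhc_expression_tpm(), datasets.mhc_library_sizes()


@pytest.fixture(scope="session")
def mhc_tau_table(mhc):
    """Tau table for the MHC example via the count-exact route (TPM ->
    integer counts -> exact TPM -> tau), the route that reproduces the
    published values at full precision."""
    tpm, sizes = mhc
    counts = ts.infer_counts_from_tpm(tpm, sizes)
    exact_tpm = ts.compute_tpm(counts, sizes)
    return ts.filter_low_reads(counts, sizes, tpm=exact_tpm)
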