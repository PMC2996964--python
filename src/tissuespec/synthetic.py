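"""Synthetic multi-tissue digital-expression studies with ground truth.

Emulates the count structure of a 454/EST digital-expression experiment:
a catalog of genes with Dirichlet tissue profiles and log-normal
abundances; per-library read counts drawn multinomially so that column
sums equal the configured library sizes exactly; genes fragmented into
contigs with conserved read totals; a small fraction of contaminant
contigs (foreign-taxon transcripts that look ordinary in the count table
and are only identifiable through their alignment hits); and a tabular
alignment file linking every non-contaminant contig to its true gene,
with decoy hits above the e-value cutoff.

Ground truth (true tissue proportions, expected TPM, true tau, simulated
omega) is retained for parameter-recovery tests.  True tau is computed by
the same routine as estimated tau (:func:`tissuespec.tau.compute_tau_matrix`)
applied to the noise-free expected TPM, so the generator and the
specificity module can never drift apart.

The default configuration mirrors the regime of a two-run-per-tissue GS20
study: six tissue libraries of ~0.25-0.4 M reads, heavily skewed per-gene
depths, tissue profiles spanning housekeeping-like (tau ~ 0.15) to
single-tissue (tau > 0.8) via a two-component Dirichlet mixture, and a
contaminant rate of a few per ten thousand contigs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _st

from .tau import compute_tau_matrix

#: Default library sizes: the six 454 tissue libraries of the reference
#: study design (embryo, liver, muscle, skin, spleen, testes).
DEFAULT_LIBRARY_SIZES = (323_897, 392_890, 325_646, 252_349, 287_902, 299_755)
DEFAULT_TISSUES = ("embryo", "liver", "muscle", "skin", "spleen", "testes")

#: Synthetic GO terms planted preferentially in high-tau genes (and, for
#: the LOW set, in low-tau genes); used by enrichment recovery tests.
PLANTED_HIGH_TAU_TERMS = ("GO:SYN0001", "GO:SYN0002", "GO:SYN0003")
PLANTED_LOW_TAU_TERMS = ("GO:SYN0004", "GO:SYN0005")
N_BACKGROUND_TERMS = 25

_TRUE_HIT_EVALUE = 1e-50
_DECOY_MIN_LOG10_EVALUE = -9.5  # decoys sit strictly above the 1e-10 cutoff


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic digital-expression study.

    ``profile_concentration`` is the Dirichlet alpha of the
    tissue-specific component; ``profile_concentration_broad`` (optional)
    adds a second, flatter component drawn with probability
    ``broad_fraction``, giving the bimodal specificity structure typical
    of real tissue panels.  ``omega_coupling`` is the slope linking true
    tau to log-scale simulated omega (dN/dS), so the
    specificity-vs-constraint relationship is recoverable by construction.
    """

    n_genes: int = 2000
    n_tissues: int = 6
    library_sizes: tuple[int, ...] = DEFAULT_LIBRARY_SIZES
    tissue_names: tuple[str, ...] | None = None
    profile_concentration: float = 0.35
    profile_concentration_broad: float | None = 5.0
    broad_fraction: float = 0.4
    profile_zero_threshold: float = 0.02
    mean_expression_dispersion: float = 1.6
    contigs_per_gene_mean: float = 2.0
    contaminant_fraction: float = 0.0005
    omega_coupling: float = 1.0
    omega_log_intercept: float = -2.2
    omega_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_tissues <= 0:
            raise ValueError("n_genes and n_tissues must be positive")
        if len(self.library_sizes) != self.n_tissues:
            raise ValueError("library_sizes length must equal n_tissues")
        if any(s <= 0 for s in self.library_sizes):
            raise ValueError("library sizes must be positive")
        if self.profile_concentration <= 0:
            raise ValueError("profile_concentration must be positive")
        if (
            self.profile_concentration_broad is not None
            and self.profile_concentration_broad <= 0
        ):
            raise ValueError("profile_concentration_broad must be positive")
        if not 0 <= self.broad_fraction <= 1:
            raise ValueError("broad_fraction must be in [0, 1]")
        if not 0 <= self.profile_zero_threshold < 1:
            raise ValueError("profile_zero_threshold must be in [0, 1)")
        if self.mean_expression_dispersion <= 0:
            raise ValueError("mean_expression_dispersion must be positive")
        if self.contigs_per_gene_mean < 0:
            raise ValueError("contigs_per_gene_mean must be non-negative")
        if not 0 <= self.contaminant_fraction < 1:
            raise ValueError("contaminant_fraction must be in [0, 1)")

    @property
    def tissues(self) -> tuple[str, ...]:
        if self.tissue_names is not None:
            if len(self.tissue_names) != self.n_tissues:
                raise ValueError("tissue_names length must equal n_tissues")
            return tuple(self.tissue_names)
        if self.n_tissues == len(DEFAULT_TISSUES):
            return DEFAULT_TISSUES
        return tuple(f"tissue_{i + 1}" for i in range(self.n_tissues))

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-scoped deterministic generator (seed is never global)."""
        return np.random.default_rng([int(self.seed), int(stage)])


@dataclass
class SimulationTruth:
    """Ground truth of a synthetic study.

    ``genes`` holds per-gene scalars (transcript length, relative
    abundance, omega, true tau, GO terms); ``proportions`` the true tissue
    proportion vectors (rows sum to 1); ``expected_tpm`` the noise-free
    TPM implied by abundances and proportions.
    """

    genes: pd.DataFrame
    proportions: pd.DataFrame
    expected_tpm: pd.DataFrame
    tissues: tuple[str, ...]

    @property
    def annotation(self) -> pd.DataFrame:
        """Annotation table (gene_id, length_bp, omega, go_terms) in the
        shape the analysis consumes, standing in for a BioMart export."""
        return self.genes[["length_bp", "omega", "go_terms"]].copy()


def generate_gene_catalog(config: SimulationConfig) -> SimulationTruth:
    """Draw the gene catalog: profiles, abundances, omega, GO terms.

    Tissue proportions come from a (optionally two-component) symmetric
    Dirichlet; abundances are log-normal with sigma
    ``mean_expression_dispersion``; omega is
    ``exp(intercept + omega_coupling * (true_tau - 0.5) + noise) - 0.02``
    clipped at 0, so transformed omega correlates positively with true tau
    for positive coupling.  Planted GO terms are assigned with probability
    increasing (or decreasing) in the gene's tau rank.
    """
    rng = config.rng(0)
    n, t = config.n_genes, config.n_tissues
    gene_ids = [f"gene_{i:05d}" for i in range(n)]

    lengths = np.clip(
        rng.lognormal(mean=np.log(1200.0), sigma=0.5, size=n), 200, 15000
    ).astype(int)

    alpha = np.full(n, config.profile_concentration)
    if config.profile_concentration_broad is not None and config.broad_fraction > 0:
        broad = rng.random(n) < config.broad_fraction
        alpha[broad] = config.profile_concentration_broad
    # gamma construction == Dirichlet(alpha_g * 1_t) row-wise
    g = rng.gamma(shape=alpha[:, None], scale=1.0, size=(n, t))
    # guard against all-zero rows at tiny alpha (numerically possible)
    dead = g.sum(axis=1) == 0
    if dead.any():
        g[dead, rng.integers(0, t, size=int(dead.sum()))] = 1.0
    proportions = g / g.sum(axis=1, keepdims=True)
    # Detection-limit sparsification: a gene is genuinely OFF in tissues
    # holding a negligible share of its expression.  Exact zeros are what
    # the zero-TPM floor convention presumes; without them "true tau"
    # would hinge on log terms of arbitrarily small proportions.
    if config.profile_zero_threshold > 0:
        proportions[proportions < config.profile_zero_threshold] = 0.0
        proportions /= proportions.sum(axis=1, keepdims=True)

    abundance = rng.lognormal(mean=0.0, sigma=config.mean_expression_dispersion, size=n)

    weights = abundance[:, None] * proportions
    colsum = weights.sum(axis=0, keepdims=True)
    # a library in which no gene has mass degenerates to uniform allocation
    with np.errstate(invalid="ignore", divide="ignore"):
        expected_tpm = np.where(colsum > 0, weights / colsum, 1.0 / n) * 1e6
    true_tau = compute_tau_matrix(expected_tpm)

    noise = rng.normal(0.0, config.omega_noise_sd, size=n)
    omega = np.clip(
        np.exp(
            config.omega_log_intercept
            + config.omega_coupling * (true_tau - 0.5)
            + noise
        )
        - 0.02,
        0.0,
        None,
    )

    go_terms = _assign_go_terms(rng, true_tau)

    tissues = config.tissues
    genes = pd.DataFrame(
        {
            "length_bp": lengths,
            "abundance": abundance,
            "omega": omega,
            "true_tau": true_tau,
            "go_terms": go_terms,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return SimulationTruth(
        genes=genes,
        proportions=pd.DataFrame(proportions, index=genes.index, columns=tissues),
        expected_tpm=pd.DataFrame(expected_tpm, index=genes.index, columns=tissues),
        tissues=tissues,
    )


def _assign_go_terms(rng: np.random.Generator, true_tau: np.ndarray) -> list[str]:
    n = true_tau.size
    background = [f"GO:BG{i:04d}" for i in range(N_BACKGROUND_TERMS)]
    tau_rank = _st.rankdata(true_tau) / n  # in (0, 1]
    terms_per_gene: list[set[str]] = [set() for _ in range(n)]
    n_bg = rng.poisson(3.0, size=n)
    for i in range(n):
        k = min(int(n_bg[i]), N_BACKGROUND_TERMS)
        if k:
            terms_per_gene[i].update(
                rng.choice(background, size=k, replace=False)
            )
    for term in PLANTED_HIGH_TAU_TERMS:
        hit = rng.random(n) < 0.02 + 0.35 * tau_rank**2
        for i in np.flatnonzero(hit):
            terms_per_gene[i].add(term)
    for term in PLANTED_LOW_TAU_TERMS:
        hit = rng.random(n) < 0.02 + 0.35 * (1 - tau_rank) ** 2
        for i in np.flatnonzero(hit):
            terms_per_gene[i].add(term)
    return [";".join(sorted(s)) for s in terms_per_gene]


def simulate_read_counts(
    truth: SimulationTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Gene x library read counts: per library, one multinomial draw of
    ``library_size`` reads with probabilities proportional to
    abundance x tissue proportion.  Column sums equal the configured
    library sizes exactly."""
    if list(truth.expected_tpm.columns) != list(config.tissues):
        raise ValueError("truth and config tissue panels disagree")
    rng = config.rng(1)
    probs = truth.expected_tpm.to_numpy() / 1e6
    counts = np.empty_like(probs, dtype=np.int64)
    for j, size in enumerate(config.library_sizes):
        counts[:, j] = rng.multinomial(int(size), probs[:, j] / probs[:, j].sum())
    return pd.DataFrame(counts, index=truth.genes.index, columns=truth.tissues)


def fragment_into_contigs(
    gene_counts: pd.DataFrame,
    truth: SimulationTruth,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, str], list[str]]:
    """Split each expressed gene's reads among one or more contigs.

    The number of contigs per gene is ``max(1, Poisson(contigs_per_gene_mean))``
    (so the mean -> 0 limit yields exactly one contig per expressed gene);
    reads are apportioned per tissue by a multinomial over random contig
    weights, conserving per-gene, per-tissue totals exactly.  Contig
    lengths are the segment lengths between random breakpoints of the
    transcript, hence never exceed the transcript length.

    A ``contaminant_fraction`` of additional contigs is appended whose
    reads concentrate in one random tissue; they carry no entry in the
    contig-to-gene truth map and are indistinguishable in the count table.

    Returns ``(contig_table, contig_to_gene, contaminant_ids)`` where
    ``contig_table`` has a ``length`` column followed by per-library
    counts.
    """
    if (gene_counts.to_numpy() < 0).any():
        raise ValueError("negative gene counts")
    rng = config.rng(2)
    tissues = list(gene_counts.columns)
    lengths_bp = truth.genes["length_bp"]

    rows: list[np.ndarray] = []
    contig_lengths: list[int] = []
    contig_gene: list[str] = []
    counts_arr = gene_counts.to_numpy(np.int64)
    n_contigs_per_gene = np.maximum(
        1, rng.poisson(config.contigs_per_gene_mean, size=len(gene_counts))
    )
    for i, gene in enumerate(gene_counts.index):
        c = counts_arr[i]
        if c.sum() == 0:
            continue
        k = int(n_contigs_per_gene[i])
        length = int(lengths_bp.loc[gene])
        if k > 1:
            weights = rng.dirichlet(np.ones(k))
            split = rng.multinomial(c, weights)  # (n_tissues, k)
            breaks = np.sort(rng.integers(1, length, size=k - 1))
            seg = np.diff(np.concatenate([[0], breaks, [length]]))
        else:
            split = c[:, None]
            seg = np.array([length])
        for j in range(k):
            rows.append(split[:, j])
            contig_lengths.append(max(int(seg[j]), 1))
            contig_gene.append(gene)

    n_real = len(rows)
    n_cont = int(round(config.contaminant_fraction / (1 - config.contaminant_fraction) * n_real))
    contaminant_flags = [False] * n_real
    for _ in range(n_cont):
        reads = max(4, int(rng.lognormal(4.0, 1.5)))
        tissue_idx = rng.integers(0, len(tissues))
        c = np.zeros(len(tissues), dtype=np.int64)
        c[tissue_idx] = reads
        rows.append(c)
        contig_lengths.append(int(np.clip(rng.lognormal(np.log(300), 0.5), 41, 3000)))
        contig_gene.append("")
        contaminant_flags.append(True)

    order = rng.permutation(len(rows))
    ids = [f"contig_{i:06d}" for i in range(len(rows))]
    table = pd.DataFrame(
        np.array(rows)[order],
        index=pd.Index(ids, name="contig_id"),
        columns=tissues,
    )
    table.insert(0, "length", np.array(contig_lengths)[order])
    genes_in_order = np.array(contig_gene, dtype=object)[order]
    flags_in_order = np.array(contaminant_flags)[order]
    contig_to_gene = {
        cid: g for cid, g, f in zip(ids, genes_in_order, flags_in_order) if not f
    }
    contaminant_ids = [cid for cid, f in zip(ids, flags_in_order) if f]
    return table, contig_to_gene, contaminant_ids


def build_alignments(
    contig_table: pd.DataFrame,
    contig_to_gene: dict[str, str],
    contaminant_ids: list[str],
    truth: SimulationTruth,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[str]]:
    """Synthetic 12-column tabular alignments for the fixture bundle.

    Every non-contaminant contig hits its true gene at e-value 1e-50;
    ~20% of contigs get additional decoy hits to random other genes, all
    strictly above the 1e-10 cutoff, so best-hit assignment recovers the
    truth map with 100% accuracy by construction.  Contaminant contigs hit
    foreign-taxon subjects (returned as the contaminant subject list)
    below the cutoff.
    """
    rng = config.rng(3)
    gene_ids = list(truth.genes.index)
    contaminant_subjects = [f"planaria_scaffold_{i:03d}" for i in range(max(1, len(contaminant_ids)))]
    records: list[tuple] = []

    def _row(q, s, length, evalue):
        pident = float(np.round(rng.uniform(95, 100), 2))
        sstart = int(rng.integers(1, 500))
        return (
            q, s, pident, int(length), int(rng.integers(0, 5)), 0,
            1, int(length), sstart, sstart + int(length) - 1,
            float(evalue), float(np.round(1.9 * length, 1)),
        )

    for cid in contig_table.index:
        length = int(contig_table.loc[cid, "length"])
        if cid in contig_to_gene:
            records.append(_row(cid, contig_to_gene[cid], length, _TRUE_HIT_EVALUE))
        else:
            subj = contaminant_subjects[rng.integers(0, len(contaminant_subjects))]
            records.append(_row(cid, subj, length, 1e-45))
        if rng.random() < 0.2:
            for _ in range(int(rng.integers(1, 3))):
                decoy_gene = gene_ids[rng.integers(0, len(gene_ids))]
                exponent = rng.uniform(_DECOY_MIN_LOG10_EVALUE, 0.0)
                records.append(
                    _row(cid, decoy_gene, max(30, length // 2), 10.0**exponent)
                )
    frame = pd.DataFrame(
        records,
        columns=[
            "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore",
        ],
    )
    return frame, contaminant_subjects


@dataclass
class SyntheticStudy:
    """A complete simulated study plus its ground truth."""

    config: SimulationConfig
    truth: SimulationTruth
    gene_counts: pd.DataFrame
    contig_table: pd.DataFrame
    contig_to_gene: dict[str, str]
    contaminant_ids: list[str]
    alignments: pd.DataFrame
    contaminant_subjects: list[str]

    @property
    def contig_counts(self) -> pd.DataFrame:
        """Per-library contig counts (the ``length`` column dropped)."""
        return self.contig_table.drop(columns="length")


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Run the full generative chain: catalog -> counts -> contigs -> alignments."""
    truth = generate_gene_catalog(config)
    gene_counts = simulate_read_counts(truth, config)
    contig_table, contig_to_gene, contaminant_ids = fragment_into_contigs(
        gene_counts, truth, config
    )
    alignments, contaminant_subjects = build_alignments(
        contig_table, contig_to_gene, contaminant_ids, truth, config
    )
    return SyntheticStudy(
        config=config,
        truth=truth,
        gene_counts=gene_counts,
        contig_table=contig_table,
        contig_to_gene=contig_to_gene,
        contaminant_ids=contaminant_ids,
        alignments=alignments,
        contaminant_subjects=contaminant_subjects,
    )


def write_fixture_bundle(study: SyntheticStudy, out_dir) -> dict[str, Path]:
    """Write the study as plain-text fixtures that round-trip through the
    package's readers.

    Files: contig count TSV (contig_id, length, one column per library),
    annotation TSV (gene_id, length_bp, omega, go_terms), 12-column
    tabular alignment file (no header), gene-level truth TSV, contig-to-
    gene truth map TSV, contaminant subject list, and library sizes TSV.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out}: {exc}") from exc
    paths = {
        "contig_counts": out / "contig_counts.tsv",
        "annotation": out / "annotation.tsv",
        "alignments": out / "alignments.tsv",
        "truth_genes": out / "truth_genes.tsv",
        "truth_map": out / "contig_to_gene.tsv",
        "contaminant_subjects": out / "contaminant_subjects.txt",
        "library_sizes": out / "library_sizes.tsv",
        "gene_counts": out / "gene_counts.tsv",
    }
    study.contig_table.to_csv(paths["contig_counts"], sep="\t")
    study.truth.annotation.to_csv(paths["annotation"], sep="\t")
    study.alignments.to_csv(paths["alignments"], sep="\t", header=False, index=False)
    truth_wide = study.truth.genes.join(
        study.truth.proportions.add_prefix("prop_")
    )
    truth_wide.to_csv(paths["truth_genes"], sep="\t")
    pd.Series(study.contig_to_gene, name="gene_id").rename_axis(
        "contig_id"
    ).to_csv(paths["truth_map"], sep="\t")
    paths["contaminant_subjects"].write_text(
        "\n".join(study.contaminant_subjects) + "\n"
    )
    pd.Series(
        dict(zip(study.config.tissues, study.config.library_sizes)),
        name="library_size",
    ).rename_axis("library").to_csv(paths["library_sizes"], sep="\t")
    study.gene_counts.to_csv(paths["gene_counts"], sep="\t")
    return paths


def read_fixture_bundle(out_dir) -> dict[str, pd.DataFrame | pd.Series]:
    """Read back a fixture bundle written by :func:`write_fixture_bundle`."""
    out = Path(out_dir)
    return {
        "contig_counts": pd.read_csv(out / "contig_counts.tsv", sep="\t", index_col=0),
        "annotation": pd.read_csv(out / "annotation.tsv", sep="\t", index_col=0),
        "truth_genes": pd.read_csv(out / "truth_genes.tsv", sep="\t", index_col=0),
        "truth_map": pd.read_csv(out / "contig_to_gene.tsv", sep="\t", index_col=0)["gene_id"],
        "contaminant_subjects": [
            s for s in (out / "contaminant_subjects.txt").read_text().splitlines() if s
        ],
        "library_sizes": pd.read_csv(out / "library_sizes.tsv", sep="\t", index_col=0)["library_size"],
        "gene_counts": pd.read_csv(out / "gene_counts.tsv", sep="\t", index_col=0),
    }


def simulate_coupled_contigs(
    n_contigs: int,
    coupling: float,
    library_sizes,
    seed: int,
    depth_range: tuple[int, int] = (4, 2000),
    specificity_beta: tuple[float, float] = (1.2, 1.2),
) -> pd.DataFrame:
    """Contig count table with a planted depth-specificity coupling.

    A Gaussian copula ties log total reads to an underlying specificity
    score s in (0, 1): ``coupling`` is the copula correlation (negative
    values make deep contigs less tissue-specific, the relationship the
    sampling-bias null is tested against).  Each contig's tissue profile
    is ``(1 - s) * uniform + s * one_hot(random tissue)`` and its counts
    are one multinomial draw of its total, so shallow totals genuinely
    produce sparse profiles.

    Totals are log-uniform over ``depth_range``; the marginal of s is
    Beta(``specificity_beta``).  With ``coupling = 0`` specificity is
    independent of depth (the null regime).
    """
    if not -1 < coupling < 1:
        raise ValueError("coupling must be in (-1, 1)")
    rng = np.random.default_rng([int(seed), 17])
    sizes = np.asarray(library_sizes, dtype=float)
    t = sizes.size
    cov = np.array([[1.0, coupling], [coupling, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_contigs)
    u, v = _st.norm.cdf(z[:, 0]), _st.norm.cdf(z[:, 1])
    lo, hi = depth_range
    totals = np.rint(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))).astype(int)
    totals = np.clip(totals, lo, hi)
    s = _st.beta.ppf(v, *specificity_beta)
    top = rng.integers(0, t, size=n_contigs)
    profiles = np.full((n_contigs, t), (1.0 / t))
    profiles *= (1.0 - s)[:, None]
    profiles[np.arange(n_contigs), top] += s
    counts = rng.multinomial(totals, profiles)
    return pd.DataFrame(
        counts,
        index=pd.Index([f"contig_{i:06d}" for i in range(n_contigs)], name="contig_id"),
        columns=[f"tissue_{j + 1}" for j in range(t)] if not isinstance(
            library_sizes, (pd.Series, dict)
        ) else list(pd.Series(library_sizes).index),
    )
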