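"""Synthetic metagenome generator with known subspecies structure.

Emulates, at desk scale, a benchmark in which metagenomes are composed of
mixtures of genomes from known within-species clades: each subspecies is
abstracted to a consensus haplotype (a 0/1 alt-allele pattern over SNV
positions), samples draw their true allele frequencies from a mixture of
consensus haplotypes plus truncated-Gaussian jitter, and read counts are
binomial at Poisson-distributed site coverage.  The generator returns the
resulting SNV table, correlated gene abundances, and the ground truth
needed to score recovery.

The model is deliberately non-evolutionary: no coalescent, no linkage
decay, no sequencing-error model.  It preserves exactly the statistical
structure the subspecies method exploits — distinct near-fixed allele
patterns per subspecies — and nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .snv_core import SNVTable

BASES = np.array(["A", "C", "G", "T"])


class FeasibilityError(ValueError):
    """Requested divergence cannot be realized for k_true and n_snvs."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    divergence is the fraction of SNV positions at which the cluster
    consensus alleles differ (i.e. are not identical across all clusters);
    at each such position a random subset of clusters carries the alternate
    allele, so any two clusters differ at the full divergence fraction for
    k_true = 2 and at roughly half to two-thirds of it for k_true >= 3
    (simultaneous pairwise separation above 2/3 is combinatorially
    impossible for three or more binary haplotypes).
    """

    k_true: int = 3
    n_samples: int = 60
    n_snvs: int = 200
    divergence: float = 0.8
    within_noise: float = 0.05
    coverage_mean: float = 50.0
    mixture_mode: str = "pure"  # "pure" | "mixed"
    mixture_dirichlet_alpha: float = 1.0
    gene_count: int = 100
    assoc_gene_fraction: float = 0.2
    gene_noise_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 1.0 and 0.0 <= self.within_noise <= 1.0):
            raise ValueError("divergence and within_noise must be in [0, 1]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.mixture_mode not in ("pure", "mixed"):
            raise ValueError("mixture_mode must be 'pure' or 'mixed'")


@dataclass
class GroundTruth:
    """True per-sample mixture proportions (and dominant cluster), the
    consensus alleles per cluster, and per-gene association labels."""

    proportions: pd.DataFrame      # samples x clusters (1-based ids), rows sum to 1
    cluster: pd.Series             # dominant cluster per sample (1-based)
    consensus: np.ndarray          # (k_true, n_snvs) of 0/1
    gene_cluster: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))
    # gene_cluster: gene id -> associated cluster (0 = independent)


def simulate_haplotypes(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Draw k_true consensus haplotypes over n_snvs positions.

    round(divergence * n_snvs) positions are discriminating: a uniformly
    random subset of clusters (size uniform in 1..k_true-1) carries allele
    1 there while the rest carry 0.  Including single-carrier and
    single-non-carrier patterns guarantees every cluster owns distinctive
    alleles for genotyping.  Remaining positions share one allele across
    clusters.  A rejection check verifies every cluster pair differs at no
    less than three quarters of the construction's expected pairwise
    difference (several standard deviations below it, so resampling is
    rare).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    k, m = cfg.k_true, cfg.n_snvs
    n_disc = int(round(cfg.divergence * m))
    if k >= 2 and cfg.divergence > 0 and n_disc == 0:
        raise FeasibilityError(
            f"divergence {cfg.divergence} with n_snvs={m} yields no "
            "discriminating positions"
        )
    if k >= 2:
        # P(a given pair differs at a discriminating position)
        sizes = np.arange(1, k)
        p_diff = float(np.mean(2 * sizes * (k - sizes) / (k * (k - 1))))
        min_pair_diff = 0.75 * p_diff * n_disc
    else:
        min_pair_diff = 0.0
    for _attempt in range(100):
        consensus = np.zeros((k, m), dtype=np.int8)
        shared = rng.integers(0, 2, size=m).astype(np.int8)
        consensus[:] = shared
        disc_pos = rng.choice(m, size=n_disc, replace=False)
        for p in disc_pos:
            size = int(rng.integers(1, k)) if k > 2 else 1
            carriers = rng.choice(k, size=size, replace=False)
            pattern = np.zeros(k, dtype=np.int8)
            pattern[carriers] = 1
            consensus[:, p] = pattern
        if k < 2:
            break
        diffs = np.array(
            [
                (consensus[a] != consensus[b]).sum()
                for a in range(k)
                for b in range(a + 1, k)
            ]
        )
        if (diffs >= min_pair_diff).all():
            break
    else:
        raise FeasibilityError(
            f"could not realize divergence {cfg.divergence} for k_true={k}, "
            f"n_snvs={m} after 100 attempts"
        )
    truth = GroundTruth(
        proportions=pd.DataFrame(),
        cluster=pd.Series(dtype=int),
        consensus=consensus,
    )
    return consensus, truth


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(n)]


def simulate_samples(
    consensus: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    truth: GroundTruth | None = None,
    proportions: np.ndarray | None = None,
) -> tuple[SNVTable, GroundTruth]:
    """Draw per-sample allele counts from the consensus haplotypes.

    True frequency = mixture-weighted consensus + truncated Gaussian jitter
    (sd = within_noise), clipped to [0, 1]; site coverage is
    Poisson(coverage_mean) and alt counts Binomial(coverage, f).  In
    ``pure`` mode cluster membership is balanced then shuffled; in
    ``mixed`` mode proportions are Dirichlet(alpha); an explicit
    (n_samples x k) ``proportions`` matrix overrides both.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    k, m = consensus.shape
    n = cfg.n_samples
    samples = _sample_ids(n)
    clusters = np.arange(1, k + 1)

    if proportions is not None:
        props = np.asarray(proportions, dtype=float)
        if props.shape != (n, k):
            raise ValueError(f"proportions must have shape ({n}, {k})")
        if not np.allclose(props.sum(axis=1), 1.0):
            raise ValueError("mixture proportions must sum to 1 per sample")
    elif cfg.mixture_mode == "pure":
        membership = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
        rng.shuffle(membership)
        props = np.zeros((n, k))
        props[np.arange(n), membership] = 1.0
    else:
        props = rng.dirichlet(np.full(k, cfg.mixture_dirichlet_alpha), size=n)

    f_true = props @ consensus.astype(float)  # (n, m)
    if cfg.within_noise > 0:
        f_true = f_true + rng.normal(0.0, cfg.within_noise, size=f_true.shape)
    f_true = np.clip(f_true, 0.0, 1.0)

    cov = rng.poisson(cfg.coverage_mean, size=(n, m))
    alt = rng.binomial(cov, f_true)
    ref = cov - alt

    ref_base_idx = rng.integers(0, 4, size=m)
    alt_base_idx = (ref_base_idx + rng.integers(1, 4, size=m)) % 4
    snvs = pd.DataFrame(
        {
            "contig": "contig_1",
            "pos": np.arange(1, m + 1),
            "ref": BASES[ref_base_idx],
            "alt": BASES[alt_base_idx],
        }
    )
    table = SNVTable(
        species_id="sim_species",
        snvs=snvs,
        ref_count=ref.T.astype(np.int64),
        alt_count=alt.T.astype(np.int64),
        coverage=cov.T.astype(np.int64),
        sample_ids=samples,
    )
    out = truth if truth is not None else GroundTruth(
        pd.DataFrame(), pd.Series(dtype=int), consensus
    )
    out.proportions = pd.DataFrame(props, index=samples, columns=clusters)
    out.cluster = pd.Series(
        clusters[np.argmax(props, axis=1)], index=samples, name="cluster"
    )
    return table, out


def simulate_genes(
    truth: GroundTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Gene x sample abundance table with a known associated fraction.

    Associated genes follow their cluster's true abundance times a
    per-gene scale, plus additive lognormal noise scaled by
    ``gene_noise_scale`` (0 gives an exact monotone relationship);
    independent genes are pure lognormal draws.  Labels are recorded in
    ``truth.gene_cluster`` (0 = independent).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if truth.proportions.empty:
        raise ValueError("ground truth lacks per-sample cluster abundances")
    samples = list(truth.proportions.index)
    clusters = list(truth.proportions.columns)
    n_assoc = int(round(cfg.assoc_gene_fraction * cfg.gene_count))
    gene_ids = [f"gene_{i + 1:04d}" for i in range(cfg.gene_count)]
    abund = np.empty((cfg.gene_count, len(samples)))
    labels = np.zeros(cfg.gene_count, dtype=int)
    for g in range(cfg.gene_count):
        if g < n_assoc:
            c = clusters[g % len(clusters)]
            labels[g] = c
            scale = rng.uniform(1.0, 5.0)
            noise = cfg.gene_noise_scale * rng.lognormal(0.0, 0.5, size=len(samples))
            abund[g] = scale * truth.proportions[c].to_numpy() + noise
        else:
            abund[g] = rng.lognormal(0.0, 1.0, size=len(samples))
    truth.gene_cluster = pd.Series(labels, index=gene_ids, name="gene_cluster")
    return pd.DataFrame(abund, index=gene_ids, columns=samples)


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[SNVTable, pd.DataFrame, GroundTruth]:
    """One call for the full generator: SNV table, gene abundances, truth."""
    rng = np.random.default_rng(cfg.seed)
    consensus, truth = simulate_haplotypes(cfg, rng)
    table, truth = simulate_samples(consensus, cfg, rng, truth)
    genes = simulate_genes(truth, cfg, rng)
    return table, genes, truth


# ---------------------------------------------------------------------------
# Neutral coding-gene simulation (pN/pS calibration)
# ---------------------------------------------------------------------------

def simulate_neutral_genes(
    n_genes: int = 100,
    n_codons: int = 300,
    n_snvs_per_gene: int = 50,
    seed: int = 0,
) -> tuple[dict[str, str], list, SNVTable]:
    """Random CDS genes with SNVs placed uniformly over positions.

    Each gene is a contig of ``n_codons`` random stop-free codons carrying
    ``n_snvs_per_gene`` SNVs at distinct uniformly random positions with a
    uniformly random alternate base.  Under this placement the expected
    nonsynonymous/synonymous split matches the Nei-Gojobori site counts, so
    pN/pS is ~1 by construction.  Returns (reference dict, gene models,
    SNVTable) ready for the selection estimator.
    """
    from .gene_selection import GeneModel, translate_codon

    rng = np.random.default_rng(seed)
    codons = [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if translate_codon(a + b + c) != "*"
    ]
    ref: dict[str, str] = {}
    genes = []
    rows = []
    for g in range(n_genes):
        contig = f"gene_contig_{g + 1:03d}"
        seq = "".join(rng.choice(codons) for _ in range(n_codons))
        ref[contig] = seq
        length = 3 * n_codons
        genes.append(GeneModel(f"gene_{g + 1:03d}", contig, 1, length, "+"))
        pos = rng.choice(length, size=n_snvs_per_gene, replace=False)
        for p in np.sort(pos):
            ref_base = seq[p]
            alt = "ACGT"[("ACGT".index(ref_base) + int(rng.integers(1, 4))) % 4]
            rows.append((contig, int(p) + 1, ref_base, alt))
    snvs = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    n = len(snvs)
    counts = np.full((n, 2), 10, dtype=np.int64)
    table = SNVTable("neutral_sim", snvs, counts, counts,
                     2 * counts, ["S001", "S002"])
    return ref, genes, table


# ---------------------------------------------------------------------------
# mpileup emission (for end-to-end exercises of the pileup parser)
# ---------------------------------------------------------------------------

def snv_table_to_mpileup(
    t: SNVTable, rng: np.random.Generator | None = None
) -> str:
    """Render an SNVTable as samtools-mpileup-style text.

    Reference reads appear as '.'/',' and alt reads as upper/lowercase alt
    letters in shuffled order, with occasional read-start/end markers;
    qualities are constant.  Parsing the result reproduces the table's
    ref/alt counts.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    lines = []
    for i in range(t.n_snvs):
        contig = t.snvs["contig"].iat[i]
        pos = int(t.snvs["pos"].iat[i])
        ref = t.snvs["ref"].iat[i]
        alt = t.snvs["alt"].iat[i]
        fields = [contig, str(pos), ref]
        for j in range(len(t.sample_ids)):
            nref = int(t.ref_count[i, j])
            nalt = int(t.alt_count[i, j])
            nother = int(t.coverage[i, j]) - nref - nalt
            symbols = (
                [rng.choice([".", ","]) for _ in range(nref)]
                + [alt if rng.random() < 0.5 else alt.lower() for _ in range(nalt)]
                + ["N" for _ in range(max(nother, 0))]
            )
            rng.shuffle(symbols)
            if symbols and rng.random() < 0.3:
                symbols[0] = "^I" + symbols[0]
            if symbols and rng.random() < 0.3:
                symbols[-1] = symbols[-1] + "$"
            cov = nref + nalt + max(nother, 0)
            bases = "".join(symbols) if symbols else "*"
            fields += [str(cov), bases, "I" * cov if cov else "*"]
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def write_truth(truth: GroundTruth, path) -> None:
    df = truth.proportions.copy()
    df.columns = [f"prop_cluster_{c}" for c in df.columns]
    df["cluster"] = truth.cluster
    df.to_csv(path, sep="\t", index_label="sample")
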