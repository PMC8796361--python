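"""Subspecies-specific genes and purifying-selection estimates.

Two independent analyses:

* **Gene association** — Spearman rank correlation between each gene's
  abundance and each subspecies' abundance across shared samples, with
  Benjamini-Hochberg FDR across all gene x cluster tests of the species.
  Spearman is used because metagenomic abundances are compositional and
  heavy-tailed; rank correlation is invariant to monotone scaling.
* **pN/pS** — per-gene ratio of observed-per-site nonsynonymous to
  synonymous polymorphism.  Expected site counts follow the Nei-Gojobori
  equal-rates convention: each codon position contributes the fraction of
  its three possible substitutions that are nonsynonymous.  Values below 1
  indicate purifying selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .snv_core import SNVTable

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# standard genetic code (NCBI tables 1 and 11 translate all codons
# identically; start codons are treated as ordinary codons)
from Bio.Data import CodonTable as _BioCodonTable

_tab = _BioCodonTable.unambiguous_dna_by_id[11]
_CODON_TABLE = dict(_tab.forward_table)
_CODON_TABLE.update({stop: "*" for stop in _tab.stop_codons})
del _tab


def translate_codon(codon: str) -> str:
    """One-letter amino acid, '*' for stop; None for ambiguous codons."""
    return _CODON_TABLE.get(codon.upper())


# ---------------------------------------------------------------------------
# Gene-subspecies association
# ---------------------------------------------------------------------------

def gene_association(
    ga: pd.DataFrame,
    subspecies_abundance: pd.DataFrame,
    min_assoc_samples: int = 10,
) -> pd.DataFrame:
    """Correlate gene abundances with subspecies abundances.

    ``ga``: genes x samples abundance table (non-negative, any consistent
    unit).  ``subspecies_abundance``: samples x clusters (the raw view of a
    SubspeciesProfile).  Returns a frame with columns gene_id, cluster,
    rho, p_value, q_value, n_samples, sorted by q then \\|rho\\| descending.
    Genes with a constant abundance vector over the shared samples are
    skipped (correlation undefined) with a logged reason.
    """
    if (ga.to_numpy(dtype=float) < 0).any():
        raise ValueError("gene abundances must be non-negative")
    rows = []
    for cluster in subspecies_abundance.columns:
        ab = subspecies_abundance[cluster].dropna()
        shared = [s for s in ga.columns if s in ab.index]
        if len(shared) < min_assoc_samples:
            logger.info(
                "cluster %s: only %d shared samples (< %d); association skipped",
                cluster, len(shared), min_assoc_samples,
            )
            continue
        y = ab.loc[shared].to_numpy(dtype=float)
        for gene_id, gvals in ga[shared].iterrows():
            x = gvals.to_numpy(dtype=float)
            if np.all(x == x[0]):
                logger.info(
                    "gene %s: constant abundance over shared samples; skipped",
                    gene_id,
                )
                continue
            rho, p = stats.spearmanr(x, y)
            rows.append((gene_id, cluster, float(rho), float(p), len(shared)))
    res = pd.DataFrame(
        rows, columns=["gene_id", "cluster", "rho", "p_value", "n_samples"]
    )
    if len(res):
        res["q_value"] = multipletests(res["p_value"], method="fdr_bh")[1]
        res["abs_rho"] = res["rho"].abs()
        res = (
            res.sort_values(["q_value", "abs_rho"], ascending=[True, False],
                            kind="stable")
            .drop(columns="abs_rho")
            .reset_index(drop=True)
        )
    else:
        res["q_value"] = pd.Series(dtype=float)
    return res[["gene_id", "cluster", "rho", "p_value", "q_value", "n_samples"]]


# ---------------------------------------------------------------------------
# pN/pS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A CDS on a reference contig; 1-based inclusive coordinates."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'
    phase: int = 0


def read_gff3_cds(path) -> list[GeneModel]:
    """Read CDS features from a GFF3 file (ID or Parent attribute names the gene)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9 or f[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("Parent") or f"{f[0]}:{f[3]}-{f[4]}"
            phase = int(f[7]) if f[7] not in (".", "") else 0
            genes.append(GeneModel(gene_id, f[0], int(f[3]), int(f[4]), f[6], phase))
    return genes


def _revcomp(seq: str) -> str:
    return "".join(COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


def nei_gojobori_sites(cds: str) -> tuple[float, float]:
    """Expected nonsynonymous and synonymous site counts of a CDS.

    Each of the 3 positions of each codon contributes n/3 nonsynonymous
    sites, where n of its three possible substitutions change the amino
    acid (stops counted as distinct).  n_sites + s_sites = length exactly.
    Codons containing ambiguous bases are excluded from the totals.
    """
    n_sites = s_sites = 0.0
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3].upper()
        aa = translate_codon(codon)
        if aa is None:
            continue
        for pos in range(3):
            nonsyn = 0
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                mutant = codon[:pos] + b + codon[pos + 1 :]
                if translate_codon(mutant) != aa:
                    nonsyn += 1
            n_sites += nonsyn / 3.0
            s_sites += (3 - nonsyn) / 3.0
    return n_sites, s_sites


def classify_snv(cds: str, offset: int, alt: str) -> str | None:
    """'syn' or 'nonsyn' for substituting ``alt`` at CDS offset (0-based);
    None when the codon is ambiguous or alt equals the reference base."""
    codon_start = offset - offset % 3
    codon = cds[codon_start : codon_start + 3].upper()
    if len(codon) < 3:
        return None
    aa = translate_codon(codon)
    if aa is None or alt.upper() not in "ACGT":
        return None
    pos = offset % 3
    if codon[pos] == alt.upper():
        return None
    mutant = codon[:pos] + alt.upper() + codon[pos + 1 :]
    return "syn" if translate_codon(mutant) == aa else "nonsyn"


def pnps(
    t: SNVTable,
    genes: list[GeneModel],
    ref: dict[str, str],
    pc: float = 0.5,
) -> pd.DataFrame:
    """Per-gene pN/pS from observed SNVs.

    Each SNV row of the table (presence in any sample) falling inside a CDS
    is classified synonymous/nonsynonymous by substituting the alt allele
    into the reference codon, with strand applied.  pN/pS =
    ((n_obs + pc) / n_sites) / ((s_obs + pc) / s_sites) with pseudocount
    ``pc``.  Genes whose CDS length is not a multiple of 3, with nonzero
    phase, or on a missing contig are skipped with a logged reason.
    """
    snvs = t.snvs
    rows = []
    for g in genes:
        if g.contig not in ref:
            logger.warning("gene %s: contig %s absent from reference; skipped",
                           g.gene_id, g.contig)
            continue
        if g.phase != 0:
            logger.warning("gene %s: nonzero phase %d; skipped", g.gene_id, g.phase)
            continue
        seq = ref[g.contig][g.start - 1 : g.end].upper()
        if len(seq) % 3 != 0:
            logger.warning("gene %s: CDS length %d not a multiple of 3; skipped",
                           g.gene_id, len(seq))
            continue
        cds = _revcomp(seq) if g.strand == "-" else seq
        n_sites, s_sites = nei_gojobori_sites(cds)
        if n_sites == 0 or s_sites == 0:
            logger.warning("gene %s: degenerate site counts; skipped", g.gene_id)
            continue
        inside = snvs[
            (snvs["contig"] == g.contig)
            & (snvs["pos"] >= g.start)
            & (snvs["pos"] <= g.end)
        ]
        n_obs = s_obs = 0
        for _, row in inside.iterrows():
            if g.strand == "-":
                offset = g.end - int(row["pos"])
                alt = COMPLEMENT.get(row["alt"].upper(), "N")
            else:
                offset = int(row["pos"]) - g.start
                alt = row["alt"].upper()
            kind = classify_snv(cds, offset, alt)
            if kind == "syn":
                s_obs += 1
            elif kind == "nonsyn":
                n_obs += 1
        ratio = ((n_obs + pc) / n_sites) / ((s_obs + pc) / s_sites)
        rows.append((g.gene_id, n_obs, s_obs, n_sites, s_sites, ratio))
    return pd.DataFrame(
        rows, columns=["gene_id", "n_obs", "s_obs", "n_sites", "s_sites", "pnps"]
    )


def read_fasta(path) -> dict[str, str]:
    """Reference sequences as a {contig: sequence} dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
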