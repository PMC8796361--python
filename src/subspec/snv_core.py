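"""Core SNV handling: pileup parsing, SNV calling, filtering, frequencies.

The entry point of the pipeline is a per-species set of allele counts at
genomic positions across metagenomic samples.  Counts come either from a
``samtools mpileup`` text stream (one coverage/bases/qualities triple per
sample) or from a precomputed SNV table in the package's TSV dialect.  From
these, SNVs are called with simple count/frequency thresholds, filtered for
coverage and prevalence, and converted to the alt-allele frequency matrix
("SNV profile") that all downstream analyses consume.

Coordinates are 1-based inclusive throughout, matching mpileup and VCF.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
OTHER = 4  # index for non-ACGT observations (N, ambiguity codes)


class PileupParseError(ValueError):
    """Raised when an mpileup line cannot be interpreted."""


class NoSamplesPassError(RuntimeError):
    """All samples were removed by the mean-coverage filter.

    Distinct from an empty input: the table had samples, none passed.
    """


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for SNV calling and filtering.

    min_coverage_per_site : reads required at a site for it to count as
        observed in a sample (also the calling coverage floor).
    min_sample_prevalence : fraction of retained samples in which an SNV
        must be observed (coverage >= min_coverage_per_site) to be kept.
    min_allele_count : alt reads required in >=1 sample to call an SNV.
    min_allele_freq : alt read fraction required in that same sample.
    min_mean_coverage_per_sample : mean coverage over SNV positions below
        which a sample is dropped entirely.
    """

    min_coverage_per_site: int = 5
    min_sample_prevalence: float = 0.5
    min_allele_count: int = 4
    min_allele_freq: float = 0.01
    min_mean_coverage_per_sample: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_sample_prevalence <= 1.0:
            raise ValueError("min_sample_prevalence must be in [0, 1]")
        if not 0.0 <= self.min_allele_freq <= 1.0:
            raise ValueError("min_allele_freq must be in [0, 1]")
        if self.min_coverage_per_site < 0 or self.min_allele_count < 0:
            raise ValueError("count thresholds must be >= 0")
        if self.min_mean_coverage_per_sample < 0:
            raise ValueError("min_mean_coverage_per_sample must be >= 0")


@dataclass
class PileupMatrix:
    """Per-position base counts for one species across samples.

    ``counts`` has shape (n_positions, n_samples, 5): A, C, G, T, other.
    """

    species_id: str
    positions: pd.DataFrame  # columns: contig, pos, ref
    counts: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.positions), len(self.sample_ids), 5):
            raise ValueError("counts shape does not match positions/samples")
        if (self.counts < 0).any():
            raise ValueError("negative base counts")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        for _, grp in self.positions.groupby("contig", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("positions must be strictly increasing within contig")

    @property
    def coverage(self) -> np.ndarray:
        """Total base count per position x sample (includes 'other')."""
        return self.counts.sum(axis=2)


@dataclass
class SNVTable:
    """Called SNVs with per-sample ref/alt counts and site coverage.

    One row per (position, alt allele); multi-allelic sites span rows.
    ``coverage`` is the total base count at the site, so
    ref_count + alt_count <= coverage.
    """

    species_id: str
    snvs: pd.DataFrame  # columns: contig, pos, ref, alt
    ref_count: np.ndarray  # (n_snvs, n_samples)
    alt_count: np.ndarray
    coverage: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        n, s = len(self.snvs), len(self.sample_ids)
        for arr in (self.ref_count, self.alt_count, self.coverage):
            if arr.shape != (n, s):
                raise ValueError("count matrix shape mismatch")
        if ((self.ref_count + self.alt_count) > self.coverage).any():
            raise ValueError("ref_count + alt_count exceeds coverage")
        if (self.snvs["ref"] == self.snvs["alt"]).any():
            raise ValueError("alt allele equals ref allele")

    @property
    def n_snvs(self) -> int:
        return len(self.snvs)

    @property
    def snv_ids(self) -> pd.Index:
        s = self.snvs
        return pd.Index(
            s["contig"].astype(str)
            + ":"
            + s["pos"].astype(str)
            + ":"
            + s["ref"]
            + ">"
            + s["alt"]
        )

    def subset(self, snv_mask=None, sample_mask=None) -> "SNVTable":
        snv_mask = np.ones(self.n_snvs, bool) if snv_mask is None else np.asarray(snv_mask)
        sample_mask = (
            np.ones(len(self.sample_ids), bool) if sample_mask is None else np.asarray(sample_mask)
        )
        return SNVTable(
            species_id=self.species_id,
            snvs=self.snvs.loc[snv_mask].reset_index(drop=True),
            ref_count=self.ref_count[np.ix_(snv_mask, sample_mask)],
            alt_count=self.alt_count[np.ix_(snv_mask, sample_mask)],
            coverage=self.coverage[np.ix_(snv_mask, sample_mask)],
            sample_ids=[s for s, m in zip(self.sample_ids, sample_mask) if m],
        )


# ---------------------------------------------------------------------------
# mpileup parsing
# ---------------------------------------------------------------------------

def _count_bases(bases: str, ref: str, line_no: int) -> np.ndarray:
    """Walk one mpileup base string and tally A/C/G/T/other counts.

    '.' and ',' count toward the reference base; ACGT (either case) toward
    that base; '^' consumes the following mapping-quality character; '$',
    '*', '<' and '>' are skipped; '+N'/'-N' indel segments consume N bases.
    """
    counts = np.zeros(5, dtype=np.int64)
    ref_idx = _BASE_INDEX.get(ref.upper(), OTHER)
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # '^' plus mapping quality char
            continue
        if c in "$*<>":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(f"line {line_no}: indel without length after '{c}'")
            i = j + int(bases[i + 1 : j])
            continue
        if c in ".,":
            counts[ref_idx] += 1
        else:
            counts[_BASE_INDEX.get(c.upper(), OTHER)] += 1
        i += 1
    return counts


def parse_mpileup(stream, sample_ids: list[str], species_id: str = "species") -> PileupMatrix:
    """Parse a default-format ``samtools mpileup`` text stream.

    ``stream`` may be a file-like object, a path, or a string of lines.
    Each line must carry one (coverage, bases, qualities) triple per entry
    in ``sample_ids``.  Base qualities are parsed but not used.
    """
    if isinstance(stream, str) and "\n" in stream:
        stream = io.StringIO(stream)
    elif isinstance(stream, str):
        stream = open(stream)

    n_samples = len(sample_ids)
    contigs, positions, refs = [], [], []
    rows = []
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 3 + 3 * n_samples:
            raise PileupParseError(
                f"line {line_no}: expected {3 + 3 * n_samples} columns for "
                f"{n_samples} samples, got {len(fields)}"
            )
        contig, pos, ref = fields[0], int(fields[1]), fields[2]
        if ref.upper() not in "ACGTN" or len(ref) != 1:
            raise PileupParseError(f"line {line_no}: unknown reference base {ref!r}")
        row = np.zeros((n_samples, 5), dtype=np.int64)
        for s in range(n_samples):
            cov = int(fields[3 + 3 * s])
            bases = fields[4 + 3 * s]
            if cov == 0 and bases in ("*", ""):
                continue
            row[s] = _count_bases(bases, ref, line_no)
        contigs.append(contig)
        positions.append(pos)
        refs.append(ref.upper())
        rows.append(row)

    pos_df = pd.DataFrame({"contig": contigs, "pos": positions, "ref": refs})
    counts = np.stack(rows) if rows else np.zeros((0, n_samples, 5), dtype=np.int64)
    return PileupMatrix(species_id, pos_df, counts, list(sample_ids))


# ---------------------------------------------------------------------------
# SNV calling
# ---------------------------------------------------------------------------

def call_snvs(pm: PileupMatrix, fp: FilterParams | None = None) -> SNVTable:
    """Call SNVs from a pileup: a (position, alt) pair becomes an SNV row iff
    in at least one sample the alt count and alt frequency meet the calling
    thresholds at a site with sufficient coverage.
    """
    fp = fp or FilterParams()
    if len(pm.positions) == 0:
        raise ValueError("empty pileup")
    cov = pm.coverage  # (n_pos, n_samples)
    covered = cov >= fp.min_coverage_per_site
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(cov > 0, pm.counts.transpose(2, 0, 1) / cov, 0.0)  # (5, pos, samp)

    snv_rows = []
    counts_per_row = []
    refs = pm.positions["ref"].to_numpy()
    for bi, base in enumerate(BASES):
        is_alt = refs != base
        passes = (
            (pm.counts[:, :, bi] >= fp.min_allele_count)
            & (freq[bi] >= fp.min_allele_freq)
            & covered
        )
        hit = is_alt & passes.any(axis=1)
        for pi in np.nonzero(hit)[0]:
            ref = refs[pi]
            ref_bi = _BASE_INDEX.get(ref, None)
            ref_cnt = (
                pm.counts[pi, :, ref_bi]
                if ref_bi is not None
                else np.zeros(len(pm.sample_ids), dtype=np.int64)
            )
            snv_rows.append(
                (pm.positions["contig"].iat[pi], int(pm.positions["pos"].iat[pi]), ref, base)
            )
            counts_per_row.append((ref_cnt, pm.counts[pi, :, bi], cov[pi]))

    if snv_rows:
        snvs = pd.DataFrame(snv_rows, columns=["contig", "pos", "ref", "alt"])
        order = snvs.sort_values(["contig", "pos", "alt"], kind="stable").index.to_numpy()
        snvs = snvs.iloc[order].reset_index(drop=True)
        ref_count = np.stack([counts_per_row[i][0] for i in order])
        alt_count = np.stack([counts_per_row[i][1] for i in order])
        coverage = np.stack([counts_per_row[i][2] for i in order])
    else:
        snvs = pd.DataFrame(columns=["contig", "pos", "ref", "alt"])
        n_s = len(pm.sample_ids)
        ref_count = alt_count = coverage = np.zeros((0, n_s), dtype=np.int64)

    return SNVTable(pm.species_id, snvs, ref_count, alt_count, coverage, list(pm.sample_ids))


def filter_snvs(t: SNVTable, fp: FilterParams | None = None) -> SNVTable:
    """Apply sample- and SNV-level filters until a fixed point.

    Samples with mean coverage over SNV positions below
    ``min_mean_coverage_per_sample`` are dropped; SNVs observed (coverage >=
    min_coverage_per_site) in fewer than ``min_sample_prevalence`` of the
    retained samples are dropped.  The two steps interact (dropping SNVs
    changes sample means), so they are iterated to a fixed point, which makes
    the operation idempotent and deterministic.
    """
    fp = fp or FilterParams()
    had_samples = len(t.sample_ids) > 0
    cur = t
    while True:
        if len(cur.sample_ids) == 0:
            if had_samples:
                raise NoSamplesPassError(
                    f"{t.species_id}: no samples pass the mean-coverage filter"
                )
            return cur
        if cur.n_snvs == 0:
            return cur
        mean_cov = cur.coverage.mean(axis=0)
        keep_samples = mean_cov >= fp.min_mean_coverage_per_sample
        if not keep_samples.any():
            raise NoSamplesPassError(
                f"{t.species_id}: no samples pass the mean-coverage filter"
            )
        step = cur.subset(sample_mask=keep_samples)
        observed = step.coverage >= fp.min_coverage_per_site
        prevalence = observed.mean(axis=1)
        keep_snvs = prevalence >= fp.min_sample_prevalence
        nxt = step.subset(snv_mask=keep_snvs)
        if nxt.n_snvs == cur.n_snvs and len(nxt.sample_ids) == len(cur.sample_ids):
            return nxt
        cur = nxt


def to_freq_matrix(t: SNVTable, fp: FilterParams | None = None) -> pd.DataFrame:
    """Alt-allele frequency matrix (SNV x sample), the per-species SNV profile.

    f = alt / (ref + alt) where site coverage >= min_coverage_per_site; NaN
    otherwise, and NaN when ref + alt = 0 at a covered site (all reads were
    other alleles).
    """
    fp = fp or FilterParams()
    denom = (t.ref_count + t.alt_count).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(denom > 0, t.alt_count / denom, np.nan)
    f = np.where(t.coverage >= fp.min_coverage_per_site, f, np.nan)
    return pd.DataFrame(f, index=t.snv_ids, columns=t.sample_ids)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def write_snv_table(t: SNVTable, path) -> None:
    """Write an SNVTable to TSV: species, contig, pos, ref, alt, then
    <sample>.ref_count, <sample>.alt_count, <sample>.coverage per sample."""
    df = t.snvs.copy()
    df.insert(0, "species", t.species_id)
    per_sample = {}
    for j, s in enumerate(t.sample_ids):
        per_sample[f"{s}.ref_count"] = t.ref_count[:, j]
        per_sample[f"{s}.alt_count"] = t.alt_count[:, j]
        per_sample[f"{s}.coverage"] = t.coverage[:, j]
    df = pd.concat([df, pd.DataFrame(per_sample, index=df.index)], axis=1)
    df.to_csv(path, sep="\t", index=False)


def read_snv_table(path) -> SNVTable:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str, "alt": str})
    fixed = ["species", "contig", "pos", "ref", "alt"]
    sample_cols = [c for c in df.columns if c not in fixed]
    sample_ids = []
    for c in sample_cols:
        if c.endswith(".ref_count"):
            sample_ids.append(c[: -len(".ref_count")])
    species = str(df["species"].iloc[0]) if len(df) else "species"
    n = len(df)
    ref_count = np.zeros((n, len(sample_ids)), dtype=np.int64)
    alt_count = np.zeros_like(ref_count)
    coverage = np.zeros_like(ref_count)
    for j, s in enumerate(sample_ids):
        ref_count[:, j] = df[f"{s}.ref_count"].to_numpy()
        alt_count[:, j] = df[f"{s}.alt_count"].to_numpy()
        coverage[:, j] = df[f"{s}.coverage"].to_numpy()
    return SNVTable(
        species, df[["contig", "pos", "ref", "alt"]].reset_index(drop=True),
        ref_count, alt_count, coverage, sample_ids,
    )


def write_freq_matrix(fm: pd.DataFrame, path) -> None:
    """FreqMatrix TSV: rows = SNV ids 'contig:pos:ref>alt', NA = missing."""
    fm.to_csv(path, sep="\t", index_label="snv_id", na_rep="NA")


def read_freq_matrix(path) -> pd.DataFrame:
    fm = pd.read_csv(path, sep="\t", index_col="snv_id", na_values=["NA"])
    fm.index.name = None
    return fm
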