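"""Config-driven pipeline orchestration and report generation.

Runs the full per-species chain — SNV calling/filtering, SNV-profile
dissimilarities, discovery-subset selection, prediction-strength
clustering, genotyping-allele extraction, subspecies profiling, gene
association and pN/pS — writing one artifact directory per species, then
summarizes all species in a plain-text table and an HTML report.  Species
are independent; they can be processed serially or in a thread pool with
byte-identical outputs, and a failure in one species never aborts the
others.
"""

from __future__ import annotations

import base64
import html
import io
import logging
import zlib
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dissimilarity, gene_selection, snv_core, subpop
from .snv_core import FilterParams, NoSamplesPassError
from .subpop import (
    DiscoveryParams,
    GenotypeParams,
    InsufficientDiscoverySamplesError,
)

logger = logging.getLogger(__name__)

OUTCOMES = (
    "subspecies_detected",
    "single_population",
    "insufficient_discovery_samples",
    "no_samples_pass_filters",
    "failed",
)


@dataclass
class SpeciesInput:
    species_id: str
    snv_table: str | None = None
    mpileup: str | None = None
    samples: list[str] = field(default_factory=list)
    gene_abundance: str | None = None
    gff: str | None = None
    fasta: str | None = None


@dataclass
class RunConfig:
    """Validated pipeline configuration (one YAML file, CLI-overridable)."""

    species: list[SpeciesInput]
    out_dir: str
    seed: int = 0
    threads: int = 1
    species_include: list[str] | None = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    discovery_params: DiscoveryParams = field(default_factory=DiscoveryParams)
    genotype_params: GenotypeParams = field(default_factory=GenotypeParams)
    metric: str = "mean_abs"
    min_shared: int = 100
    k_max: int = 10
    ps_threshold: float = 0.8
    n_iterations: int = 100
    train_fraction: float = 0.5
    min_discovery_size: int = 20
    min_markers_observed: int = 5
    profile_agg: str = "median"
    min_assoc_samples: int = 10
    pnps_pseudocount: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        species = [SpeciesInput(**s) for s in raw.pop("species", [])]
        fp = FilterParams(**raw.pop("filter", {}))
        dp = DiscoveryParams(**raw.pop("discovery", {}))
        gp = GenotypeParams(**raw.pop("genotyping", {}))
        cfg = cls(species=species, filter_params=fp, discovery_params=dp,
                  genotype_params=gp, **raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.species:
            raise ValueError("config lists no species")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0 <= self.ps_threshold <= 1:
            raise ValueError("ps_threshold must be in [0, 1]")
        if self.metric not in dissimilarity.METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.profile_agg not in ("median", "mean"):
            raise ValueError("profile_agg must be 'median' or 'mean'")
        for sp in self.species:
            if not sp.snv_table and not sp.mpileup:
                raise ValueError(f"{sp.species_id}: needs snv_table or mpileup")
            for p in (sp.snv_table, sp.mpileup, sp.gene_abundance, sp.gff, sp.fasta):
                if p and not Path(p).exists():
                    raise FileNotFoundError(f"{sp.species_id}: missing input {p}")


@dataclass
class SpeciesReport:
    species_id: str
    outcome: str
    n_samples: int = 0
    n_snvs: int = 0
    n_discovery: int = 0
    k_selected: int | None = None
    ps_per_k: pd.DataFrame | None = None
    cluster_sizes: dict = field(default_factory=dict)
    marker_counts: dict = field(default_factory=dict)
    top_genes: pd.DataFrame | None = None
    pnps_summary: dict = field(default_factory=dict)
    message: str = ""


def _species_seed(global_seed: int, species_id: str) -> int:
    """Stable per-species seed, independent of species order."""
    ss = np.random.SeedSequence([global_seed, zlib.crc32(species_id.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def run_species(sp: SpeciesInput, cfg: RunConfig) -> SpeciesReport:
    out = Path(cfg.out_dir) / sp.species_id
    out.mkdir(parents=True, exist_ok=True)
    seed = _species_seed(cfg.seed, sp.species_id)

    if sp.snv_table:
        table = snv_core.read_snv_table(sp.snv_table)
    else:
        pm = snv_core.parse_mpileup(sp.mpileup, sp.samples, sp.species_id)
        table = snv_core.call_snvs(pm, cfg.filter_params)
    logger.info("%s: %d SNVs x %d samples in", sp.species_id, table.n_snvs,
                len(table.sample_ids))
    try:
        table = snv_core.filter_snvs(table, cfg.filter_params)
    except NoSamplesPassError as exc:
        logger.warning("%s: %s", sp.species_id, exc)
        return SpeciesReport(sp.species_id, "no_samples_pass_filters",
                             message=str(exc))
    logger.info("%s: %d SNVs x %d samples after filtering", sp.species_id,
                table.n_snvs, len(table.sample_ids))
    snv_core.write_snv_table(table, out / "snv_filtered.tsv")
    fm = snv_core.to_freq_matrix(table, cfg.filter_params)
    snv_core.write_freq_matrix(fm, out / "freq.tsv")

    report = SpeciesReport(sp.species_id, "subspecies_detected",
                           n_samples=len(table.sample_ids), n_snvs=table.n_snvs)
    # pN/pS needs only the filtered table plus annotations, so it runs
    # regardless of whether clustering is possible for this sample set
    if sp.gff and sp.fasta:
        genes = gene_selection.read_gff3_cds(sp.gff)
        ref = gene_selection.read_fasta(sp.fasta)
        sel = gene_selection.pnps(table, genes, ref, cfg.pnps_pseudocount)
        sel.to_csv(out / "pnps.tsv", sep="\t", index=False)
        if len(sel):
            report.pnps_summary = {
                "n_genes": int(len(sel)),
                "median_pnps": float(sel["pnps"].median()),
            }

    dm = dissimilarity.pairwise_dissimilarity(fm, cfg.metric, cfg.min_shared)
    dissimilarity.write_dist_matrix(dm, out / "dist.tsv", out / "n_shared.tsv")

    disc = subpop.select_discovery_subset(fm, cfg.discovery_params)
    disc.scores.to_csv(out / "discovery.tsv", sep="\t", index_label="sample")
    report.n_discovery = len(disc.subset)
    if disc.empty:
        logger.warning("%s: no metagenomes meet the discovery subset criteria",
                       sp.species_id)
        report.outcome = "insufficient_discovery_samples"
        report.message = "no metagenomes meet the discovery subset criteria"
        return report
    sub_dm, isolated = dm.restrict(disc.subset).drop_isolated()
    if isolated:
        logger.warning("%s: %d discovery samples isolated (shared SNVs below "
                       "min_shared with all others): %s", sp.species_id,
                       len(isolated), ",".join(isolated))
    try:
        cr = subpop.choose_k(
            sub_dm, cfg.k_max, cfg.ps_threshold, cfg.n_iterations,
            cfg.train_fraction, seed, cfg.min_discovery_size,
        )
    except InsufficientDiscoverySamplesError as exc:
        logger.warning("%s: %s", sp.species_id, exc)
        report.outcome = "insufficient_discovery_samples"
        report.message = str(exc)
        return report
    subpop.write_cluster_result(cr, out / "clusters.tsv", out / "ps_per_k.tsv")
    report.k_selected = cr.k_selected
    report.ps_per_k = cr.ps_per_k
    report.cluster_sizes = cr.assignments.value_counts().sort_index().to_dict()

    if cr.k_selected < 2:
        report.outcome = "single_population"
    else:
        gs = subpop.genotype_alleles(fm, cr, cfg.genotype_params)
        subpop.write_genotype_alleles(gs, out / "genotyping_alleles.tsv")
        report.marker_counts = (
            gs.markers["cluster"].value_counts().sort_index().to_dict()
            if len(gs.markers) else {}
        )
        prof = subpop.profile_subspecies(fm, gs, cfg.min_markers_observed,
                                         cfg.profile_agg)
        subpop.write_subspecies_profile(prof, out / "subspecies_abundance.tsv")

        if sp.gene_abundance:
            ga = pd.read_csv(sp.gene_abundance, sep="\t", index_col=0)
            assoc = gene_selection.gene_association(ga, prof.raw,
                                                    cfg.min_assoc_samples)
            assoc.to_csv(out / "gene_assoc.tsv", sep="\t", index=False)
            report.top_genes = assoc.head(10)

    return report


def run_pipeline(cfg: RunConfig) -> list[SpeciesReport]:
    """Run all configured species (optionally in a thread pool) and write
    summary.txt / report.html alongside the per-species artifacts."""
    cfg.validate()
    species = [
        sp for sp in cfg.species
        if cfg.species_include is None or sp.species_id in cfg.species_include
    ]

    def safe_run(sp: SpeciesInput) -> SpeciesReport:
        try:
            return run_species(sp, cfg)
        except Exception as exc:  # isolate per-species failures
            logger.exception("%s: failed", sp.species_id)
            return SpeciesReport(sp.species_id, "failed", message=str(exc))

    if cfg.threads > 1:
        with ThreadPoolExecutor(max_workers=cfg.threads) as pool:
            reports = list(pool.map(safe_run, species))
    else:
        reports = [safe_run(sp) for sp in species]
    reports.sort(key=lambda r: r.species_id)
    write_report(reports, cfg.out_dir)
    return reports


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _ps_plot_data_uri(ps_per_k: pd.DataFrame, threshold: float) -> str:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.errorbar(ps_per_k["k"], ps_per_k["mean_ps"], yerr=ps_per_k["sd_ps"],
                marker="o", capsize=3)
    ax.axhline(threshold, color="red", linestyle="--", linewidth=1)
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("prediction strength")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=90)
    plt.close(fig)
    return "data:image/png;base64," + base64.b64encode(buf.getvalue()).decode()


def _df_to_html(df: pd.DataFrame, max_rows: int = 20) -> str:
    shown = df.head(max_rows)
    head = "".join(f"<th>{html.escape(str(c))}</th>" for c in shown.columns)
    rows = []
    for _, r in shown.iterrows():
        cells = "".join(
            f"<td>{html.escape(f'{v:.4g}' if isinstance(v, float) else str(v))}</td>"
            for v in r
        )
        rows.append(f"<tr>{cells}</tr>")
    return (
        f"<table><thead><tr>{head}</tr></thead><tbody>{''.join(rows)}</tbody></table>"
    )


def write_report(reports: list[SpeciesReport], out_dir,
                 ps_threshold: float = 0.8) -> None:
    """Plain-text outcome table plus an HTML report with per-species
    sections; every number is read from / identical to the TSV artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    lines = [
        f"{'species':<24}{'outcome':<34}{'k':>3}  {'n_discovery':>11}  cluster_sizes"
    ]
    for r in reports:
        sizes = ",".join(str(v) for _, v in sorted(r.cluster_sizes.items())) or "-"
        k = str(r.k_selected) if r.k_selected is not None else "-"
        lines.append(
            f"{r.species_id:<24}{r.outcome:<34}{k:>3}  {r.n_discovery:>11}  {sizes}"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")

    sections = []
    for r in reports:
        parts = [f"<h2>{html.escape(r.species_id)}</h2>"]
        parts.append(
            f"<p>Outcome: <strong>{html.escape(r.outcome)}</strong>"
            + (f" — {html.escape(r.message)}" if r.message else "")
            + "</p>"
        )
        parts.append(
            f"<p>{r.n_snvs} SNVs across {r.n_samples} samples; "
            f"{r.n_discovery} discovery samples.</p>"
        )
        if r.ps_per_k is not None:
            parts.append(f"<p>Selected k = {r.k_selected}</p>")
            parts.append(
                f'<img src="{_ps_plot_data_uri(r.ps_per_k, ps_threshold)}" '
                f'alt="prediction strength per k" />'
            )
            parts.append(_df_to_html(r.ps_per_k))
        if r.cluster_sizes:
            parts.append("<h3>Cluster sizes</h3>")
            parts.append(_df_to_html(pd.DataFrame(
                {"cluster": list(r.cluster_sizes), "n_samples": list(r.cluster_sizes.values())}
            )))
        if r.marker_counts:
            parts.append("<h3>Genotyping markers per cluster</h3>")
            parts.append(_df_to_html(pd.DataFrame(
                {"cluster": list(r.marker_counts), "n_markers": list(r.marker_counts.values())}
            )))
        parts.append("<h3>Gene associations</h3>")
        if r.top_genes is not None and len(r.top_genes):
            parts.append(_df_to_html(r.top_genes))
        else:
            parts.append("<p>not run</p>")
        parts.append("<h3>Purifying selection (pN/pS)</h3>")
        if r.pnps_summary:
            parts.append(
                f"<p>{r.pnps_summary['n_genes']} genes; median pN/pS = "
                f"{r.pnps_summary['median_pnps']:.4g}</p>"
            )
        else:
            parts.append("<p>not run</p>")
        sections.append("\n".join(parts))

    doc = (
        "<!DOCTYPE html>\n"
        '<html><head><meta charset="utf-8" />'
        "<title>Subspecies report</title>"
        "<style>table{border-collapse:collapse}td,th{border:1px solid #999;"
        "padding:2px 6px}</style></head><body>\n"
        "<h1>Subspecies detection report</h1>\n"
        + "\n".join(sections)
        + "\n</body></html>\n"
    )
    (out / "report.html").write_text(doc)
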