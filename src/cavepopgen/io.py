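"""Format readers/writers, configuration and the end-to-end pipeline.

VCF 4.2 is read through cyvcf2 and GFF3 through gffutils; coordinates are
converted to the internal 0-based half-open convention at these
boundaries only (the frequency panel keeps 1-based VCF positions).  TSV
outputs are tab-separated with a mandatory header and '.' for missing.
Every stochastic stage consumes a stage-specific child seed derived from
the master seed, so stages are independently reproducible.
"""

from __future__ import annotations

import logging
import os
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .panel import AlleleFrequencyPanel, GeneModel, GenotypeMatrix, Population
from .popstats import AncestryTracts

logger = logging.getLogger(__name__)

MISSING = "."


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from the master seed."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_sample_map(path: str) -> dict[str, Population]:
    """sample -> Population from a TSV with sample/pop/ecotype/lineage."""
    df = pd.read_csv(path, sep="\t")
    return {
        row["sample"]: Population(row["pop"], row["ecotype"], int(row["lineage"]))
        for _, row in df.iterrows()
    }


def read_vcf_genotypes(path: str, pop_map: dict[str, Population]) -> GenotypeMatrix:
    """Read per-sample diploid calls (all records, multi-allelic included)."""
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in pop_map]
    if unknown:
        raise ValueError(f"samples absent from population map: {unknown}")
    chroms, poss, n_alt, rows = [], [], [], []
    for i, var in enumerate(vcf):
        if var.REF is None or len(var.REF) != 1 or \
                any(len(a) != 1 for a in var.ALT):
            raise ValueError(f"malformed or non-SNP record at line ~{i + 1}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        n_alt.append(len(var.ALT))
        gt = np.asarray(var.genotypes)[:, :2]
        dos = np.where((gt < 0).any(axis=1), -1, (gt > 0).sum(axis=1))
        rows.append(dos.astype(np.int8))
    if not rows:
        raise ValueError(f"no records in {path}")
    pops = list(dict.fromkeys(pop_map[s] for s in samples))
    return GenotypeMatrix(
        samples=samples,
        sample_pop=[pop_map[s].name for s in samples],
        populations=pops,
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        dosage=np.stack(rows, axis=1),
        n_alt_alleles=np.asarray(n_alt, dtype=np.int64),
    )


def read_vcf_to_panel(path: str, pop_map: dict[str, Population]) -> AlleleFrequencyPanel:
    """Per-population alternate-allele frequencies from a VCF.

    Multi-allelic records are dropped (with a logged count); haploid
    observation counts cover non-missing calls only; populations with
    fewer than two called haplotypes at a site get a missing frequency.
    """
    gm = read_vcf_genotypes(path, pop_map)
    keep = np.flatnonzero(gm.n_alt_alleles == 1)
    dropped = gm.n_sites - keep.size
    if dropped:
        logger.info("%d multi-allelic records dropped", dropped)
    k = len(gm.populations)
    freq = np.full((k, keep.size), np.nan)
    n = np.zeros((k, keep.size), dtype=np.int64)
    for i, pop in enumerate(gm.populations):
        rows = gm.pop_sample_indices(pop.name)
        sub = gm.dosage[np.ix_(rows, keep)]
        called = sub >= 0
        n_hap = 2 * called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        ok = n_hap >= 2
        freq[i, ok] = alt[ok] / n_hap[ok]
        n[i] = n_hap
    return AlleleFrequencyPanel(
        populations=list(gm.populations),
        chrom=gm.chrom[keep], pos=gm.pos[keep], freq=freq, n=n,
    )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff(path: str) -> list[GeneModel]:
    """Gene models (with CDS/UTR sub-features) from a GFF3 file.

    transcript_length is the exon-length sum of the longest transcript,
    cds_length the CDS-length sum; coordinates convert from 1-based
    inclusive to 0-based half-open here.  Children extending past their
    gene get clamped with a warning.
    """
    import gffutils

    db = gffutils.create_db(path, ":memory:", keep_order=True,
                            merge_strategy="create_unique")
    genes = []
    for g in db.features_of_type("gene"):
        start, end = g.start - 1, g.end
        cds, utr5, utr3 = [], [], []
        best_len, best_exons = 0, 0
        isoforms = 0
        for t in db.children(g, featuretype=("mRNA", "transcript")):
            isoforms += 1
            exons = list(db.children(t, featuretype="exon"))
            tlen = sum(e.end - e.start + 1 for e in exons)
            if tlen >= best_len:
                best_len, best_exons = tlen, len(exons)
        for feat, bucket in (("CDS", cds), ("five_prime_UTR", utr5),
                             ("three_prime_UTR", utr3)):
            for f in db.children(g, featuretype=feat):
                s, e = f.start - 1, f.end
                if s < start or e > end:
                    logger.warning("%s: %s child outside gene span; clamping",
                                   g.id, feat)
                    s, e = max(s, start), min(e, end)
                bucket.append((s, e))
        genes.append(GeneModel(
            gene_id=g.id, chrom=g.seqid, start=start, end=end,
            strand=g.strand if g.strand in "+-" else "+",
            transcript_length=best_len,
            cds_length=sum(e - s for s, e in cds),
            exon_count=best_exons,
            isoform_count=max(isoforms, 1),
            cds=sorted(cds), utr5=sorted(utr5), utr3=sorted(utr3),
        ))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def attach_go_terms(genes: list[GeneModel], go_table: pd.DataFrame) -> None:
    """Attach GO term names (column ``go_name``) to genes in place."""
    by_gene = go_table.groupby("gene")["go_name"].apply(list)
    for g in genes:
        g.go_terms = list(by_gene.get(g.gene_id, []))


# ---------------------------------------------------------------------------
# flat tables
# ---------------------------------------------------------------------------

def read_bed(path: str) -> list[tuple[str, int, int]]:
    """BED intervals (0-based half-open) as (chrom, start, end) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            c, s, e = line.split("\t")[:3]
            out.append((c, int(s), int(e)))
    return out


def read_sweep_table(path: str, populations: dict[str, Population] | None = None):
    from .candidates import SweepCallTable

    return SweepCallTable(pd.read_csv(path, sep="\t"), populations)


def read_design(path: str):
    """Replicate design TSV with surface / cave / lineage columns."""
    from .reuse_scan import ReplicateDesign

    df = pd.read_csv(path, sep="\t")
    return ReplicateDesign([(r["surface"], r["cave"], int(r["lineage"]))
                            for _, r in df.iterrows()])


def read_keyword_table(path: str) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["category"], []).append(row["keyword"])
    return out


def read_tracts(path: str, genome_length: int,
                recombination_rate: float = 1.16e-8) -> AncestryTracts:
    """Ancestry tract TSV with individual / source / length_bp columns."""
    df = pd.read_csv(path, sep="\t")
    tracts: dict[str, list[tuple[str, int]]] = {}
    for _, row in df.iterrows():
        tracts.setdefault(row["individual"], []).append(
            (row["source"], int(row["length_bp"])))
    return AncestryTracts(tracts, genome_length, recombination_rate)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Paths and parameters of the end-to-end run; YAML round-trippable."""

    outdir: str = "pipeline_out"
    vcf: str = ""
    samples: str = ""
    gff: str = ""
    qtl_bed: str = ""
    sweep_table: str = ""
    design: str = ""
    motif_table: str = ""
    go_table: str = ""
    keyword_table: str = ""
    window_bp: int = 50_000
    sweep_window_bp: int = 5_000
    scan_window_snps: int = 50
    scan_n_perm: int = 10_000
    qtl_n_perm: int = 5_000
    neutral_thin_bp: int = 50_000
    alpha: float = 0.01
    flank: int = 10_000
    ne: int = 100_000
    rec_rate: float = 1.16e-8
    mu: float = 3.5e-9
    dmc_max_genes: int = 25
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("window_bp", "sweep_window_bp", "scan_window_snps",
                     "scan_n_perm", "qtl_n_perm", "flank", "ne"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write its report under config.outdir.

    Stages: genotype filters -> windowed statistics -> sweep-table
    intersections -> eigen reuse scan -> composite-likelihood mode fits on
    candidate genes -> enrichment / TFBS-loss / gene-length statistics.
    Any stage failure aborts with the stage name attached.
    """
    from . import candidates as cand
    from . import convergence as conv
    from . import popstats, reuse_scan

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {"seed": config.seed}
    stage = "load"
    try:
        pop_map = read_sample_map(config.samples)
        genotypes = read_vcf_genotypes(config.vcf, pop_map)
        genes = read_gff(config.gff)
        qtl = read_bed(config.qtl_bed)
        pops = {p.name: p for p in genotypes.populations}
        sweeps = read_sweep_table(config.sweep_table, pops)
        design = read_design(config.design)
        keywords = read_keyword_table(config.keyword_table)
        go_table = pd.read_csv(config.go_table, sep="\t")
        attach_go_terms(genes, go_table)
        motifs = pd.read_csv(config.motif_table, sep="\t")

        stage = "filters"
        panel, filt = popstats.apply_site_filters(genotypes)
        report["filters"] = {
            "input_sites": filt.input_sites, "retained": filt.retained,
            "removed_non_biallelic": filt.removed_non_biallelic,
            "removed_missingness": filt.removed_missingness,
            "removed_maf": filt.removed_maf,
            "removed_all_heterozygous": filt.removed_all_heterozygous,
        }

        stage = "stats"
        wstats = popstats.windowed_stats(panel, config.window_bp)
        write_tsv(wstats, os.path.join(config.outdir, "windowed_stats.tsv"))

        stage = "sweep_intersections"
        cave_pops = [p.name for p in genotypes.populations if p.ecotype == "cave"]
        surf_pops = [p.name for p in genotypes.populations if p.ecotype == "surface"]
        overlap_set = cand.overlapping_sweeps(sweeps, genes, cave_pops, surf_pops)
        fractions_cave = [cand.sweep_fraction(sweeps, p) for p in cave_pops]
        fractions_surf = [cand.sweep_fraction(sweeps, p) for p in surf_pops]
        report["overlapping_sweep_genes"] = sorted(overlap_set)
        if len(fractions_cave) >= 2 and len(fractions_surf) >= 2:
            w, p = popstats.compare_sweep_fractions(fractions_cave, fractions_surf)
            report["sweep_fraction_test"] = {"W": w, "p": p}

        stage = "reuse_scan"
        null = reuse_scan.null_distribution(
            panel, design, n_perm=config.scan_n_perm,
            seed=stage_seed(config.seed, "reuse_scan"),
            window_snps=config.scan_window_snps, alpha=config.alpha)
        windows = reuse_scan.scan_panel(panel, design, null,
                                        window_snps=config.scan_window_snps)
        gene_labels = reuse_scan.windows_to_genes(windows, genes)
        write_tsv(gene_labels, os.path.join(config.outdir, "reuse_genes.tsv"))
        report["reuse_counts"] = dict(
            gene_labels["classification"].value_counts()) if len(gene_labels) \
            else {}

        stage = "convergence_modes"
        F = conv.estimate_neutral_F(panel, _intergenic_mask(panel, genes),
                                    thin_bp=config.neutral_thin_bp)
        candidates_for_dmc = [g for g in genes
                              if g.gene_id in overlap_set][: config.dmc_max_genes]
        spec_set = conv.default_model_specs(
            tuple(cave_pops[:3]), ne=config.ne, rec_rate=config.rec_rate)
        dmc_results = []
        for g in candidates_for_dmc:
            res = conv.fit_gene(panel, g, spec_set, F, flank=config.flank)
            if res is not None:
                dmc_results.append(res)
        if dmc_results:
            summary = conv.summarize_mode_assignments(dmc_results)
            write_tsv(summary, os.path.join(config.outdir, "mode_summary.tsv"))
            report["mode_summary"] = summary.to_dict("records")

        stage = "enrichment"
        categories = cand.assign_phenotype_categories(genes, keywords)
        report["phenotype_categories"] = {g: sorted(c)
                                          for g, c in sorted(categories.items())}
        qtl_test = cand.qtl_overlap_permutation(
            overlap_set, genes, qtl, n_perm=config.qtl_n_perm,
            seed=stage_seed(config.seed, "qtl_permutation"))
        report["qtl_permutation"] = qtl_test
        if overlap_set:
            cand_len = [g.transcript_length for g in genes if g.gene_id in overlap_set]
            all_len = [g.transcript_length for g in genes]
            if len(cand_len) >= 2 and np.var(cand_len) + np.var(all_len) > 0:
                t, df_, p = cand.length_comparison(cand_len, all_len)
                report["transcript_length_test"] = {"t": t, "df": df_, "p": p}
        losses = cand.tfbs_loss_filter(motifs, surf_pops, cave_pops)
        write_tsv(losses, os.path.join(config.outdir, "tfbs_losses.tsv"))
        report["tfbs_losses"] = int(len(losses))
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = _to_plain(report)
    with open(os.path.join(config.outdir, "report.yaml"), "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=True, default_flow_style=False)
    return report


def _to_plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {_to_plain(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _intergenic_mask(panel: AlleleFrequencyPanel, genes: list[GeneModel]) -> np.ndarray:
    mask = np.ones(panel.n_sites, dtype=bool)
    for g in genes:
        mask &= ~((panel.chrom == g.chrom) & (panel.pos - 1 >= g.start)
                  & (panel.pos - 1 < g.end))
    return mask
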