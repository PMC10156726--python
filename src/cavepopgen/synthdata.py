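"""Synthetic multi-population SNP panels with implanted convergent sweeps.

The generator emulates the sampling design of a two-lineage cave/surface
system: an ancestral population splits into two lineages, each lineage
carries one surface population and one or more independently colonized
cave populations.  Shared drift along internal branches induces the
within-lineage allele-frequency covariance that every downstream scan
assumes; sweeps of known mode (independent mutation, standing variation,
migration) are implanted by deterministic frequency surgery so that truth
labels are exact.

Nothing here is a model of how the real data arose (the study it mirrors
is observational); the forms are stand-ins chosen to reproduce the
qualitative structure the inference stack keys on, and are documented as
such in docs/methods.md.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .panel import AlleleFrequencyPanel, Population

SCENARIOS = ("neutral", "independent", "standing", "migration")

#: final frequency of the beneficial allele after a sweep; kept just below
#: fixation so implanted sites remain polymorphic and pass MAF filters
SWEEP_EPSILON = 0.01


@dataclass
class DemographyConfig:
    """Population-tree and sampling parameters for the neutral simulator.

    Branch lengths are in generations, effective sizes are diploid counts.
    Rates follow the study system: recombination 1.16 cM/Mb and mutation
    3.5e-9 per bp per generation.
    """

    ancestral_ne: int = 10_000
    branch_ne: int = 10_000
    t_root_lineage: int = 500
    t_lineage_surface: int = 200
    t_lineage_cave: int = 200
    caves_per_lineage: tuple[int, int] = (1, 2)
    surfaces_per_lineage: tuple[int, int] = (1, 1)
    sample_size: int = 10  # diploid individuals per population
    snp_count: int = 20_000
    chrom_length: int = 10_000_000
    chrom: str = "chr1"
    recombination_rate: float = 1.16e-8  # Morgans per bp (1.16 cM/Mb)
    mutation_rate: float = 3.5e-9  # per bp per generation
    exact_wf: bool = False  # generation-by-generation binomial drift
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ancestral_ne", "branch_ne", "sample_size", "snp_count", "chrom_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("t_root_lineage", "t_lineage_surface", "t_lineage_cave"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.recombination_rate < 0 or self.mutation_rate < 0:
            raise ValueError("rates must be >= 0")
        if not any(self.caves_per_lineage):
            raise ValueError("at least one cave population is required")

    def populations(self) -> list[Population]:
        pops: list[Population] = []
        for lineage in (1, 2):
            for i in range(self.surfaces_per_lineage[lineage - 1]):
                pops.append(Population(f"L{lineage}_surface{i + 1}", "surface", lineage))
            for i in range(self.caves_per_lineage[lineage - 1]):
                pops.append(Population(f"L{lineage}_cave{i + 1}", "cave", lineage))
        return pops


@dataclass
class ScenarioTruth:
    """Ground truth for one implanted region."""

    region_id: str
    scenario: str
    selected_position: int
    region_start: int
    region_end: int
    selected_pops: tuple[str, ...] = ()
    s: float = 0.0
    t_standing: float = 0.0
    g: float = 0.0
    source_pop: str | None = None
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario != "neutral":
            if not (self.region_start <= self.selected_position < self.region_end):
                raise ValueError("selected_position must lie inside the region")
            if not self.selected_pops:
                raise ValueError("non-neutral scenario requires selected_pops")
        if self.scenario == "migration" and self.source_pop is None:
            raise ValueError("migration scenario requires source_pop")
        if self.scenario == "standing" and self.t_standing < 0:
            raise ValueError("t_standing must be >= 0")


def _drift(freq: np.ndarray, t: float, ne: int, rng: np.random.Generator,
           exact: bool) -> np.ndarray:
    """One branch of Wright-Fisher drift applied to a frequency vector.

    Default is a single variance-matched Gaussian step (var = x(1-x)t/2Ne,
    truncated to [0,1]); ``exact`` switches to generation-by-generation
    binomial sampling of 2Ne gametes.
    """
    if t == 0:
        return freq.copy()
    if exact:
        x = freq.copy()
        for _ in range(int(round(t))):
            x = rng.binomial(2 * ne, x) / (2 * ne)
        return x
    sd = np.sqrt(freq * (1.0 - freq) * t / (2.0 * ne))
    return np.clip(freq + rng.normal(0.0, 1.0, freq.shape) * sd, 0.0, 1.0)


def simulate_neutral_panel(
    config: DemographyConfig,
    rng: np.random.Generator | None = None,
    draw_haplotypes: bool = True,
) -> tuple[AlleleFrequencyPanel, dict[str, np.ndarray]]:
    """Simulate a neutral panel down the two-lineage population tree.

    Per SNP the ancestral frequency is uniform on [0.05, 0.95]; it drifts
    along root->lineage and lineage->population branches.  Haplotypes are
    independent Bernoulli draws given the population frequency (no linkage
    outside implanted sweeps).

    Returns the panel and a dict mapping population name to a
    (2 * sample_size, snp_count) int8 haplotype matrix.
    """
    if config.snp_count <= 0:
        raise ValueError("snp_count must be > 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.snp_count
    positions = np.sort(
        rng.choice(np.arange(1, config.chrom_length + 1), size=m, replace=False)
    )
    ancestral = rng.uniform(0.05, 0.95, m)

    lineage_freq = {
        lineage: _drift(ancestral, config.t_root_lineage, config.branch_ne, rng,
                        config.exact_wf)
        for lineage in (1, 2)
    }
    pops = config.populations()
    freq = np.empty((len(pops), m))
    for i, pop in enumerate(pops):
        t = (config.t_lineage_surface if pop.ecotype == "surface"
             else config.t_lineage_cave)
        freq[i] = _drift(lineage_freq[pop.lineage], t, config.branch_ne, rng,
                         config.exact_wf)

    n_hap = 2 * config.sample_size
    n = np.full((len(pops), m), n_hap, dtype=np.int64)
    panel = AlleleFrequencyPanel(
        populations=pops,
        chrom=np.full(m, config.chrom, dtype=object),
        pos=positions,
        freq=freq,
        n=n,
    )
    haplotypes: dict[str, np.ndarray] = {}
    if draw_haplotypes:
        for i, pop in enumerate(pops):
            haplotypes[pop.name] = (
                rng.random((n_hap, m)) < freq[i]
            ).astype(np.int8)
    return panel, haplotypes


def sweep_duration(s: float, ne: int) -> float:
    """Approximate sojourn time of a hard sweep, log(4*Ne*s)/s generations."""
    if s <= 0:
        raise ValueError("selection coefficient must be > 0")
    return np.log(4.0 * ne * s) / s


def hitchhiking_retention(r_morgans: np.ndarray | float, s: float, ne: int) -> np.ndarray:
    """Probability a flanking site rides the sweeping haplotype: exp(-r*tau)."""
    tau = sweep_duration(s, ne)
    return np.exp(-np.asarray(r_morgans, dtype=float) * tau)


def implant_sweep(
    panel: AlleleFrequencyPanel,
    truth: ScenarioTruth,
    config: DemographyConfig,
    return_record: bool = False,
):
    """Implant a convergent sweep of known mode by frequency surgery.

    The beneficial (alternate) allele is set to 1 - epsilon at the selected
    site in every selected population.  Each flanking SNP within the truth
    region, at recombination distance r Morgans, is replaced by the allele
    state of the sweeping haplotype with probability y(r) = exp(-r * tau),
    tau = log(4*Ne*s)/s.  Haplotype-origin sharing encodes the mode:

    - independent: each selected population draws its own haplotype;
    - migration: one haplotype (drawn at the source population's pre-sweep
      frequencies) is shared by all selected populations;
    - standing: one shared haplotype, but each replacement survives
      t_standing generations of recombination only with probability
      exp(-r * t_standing), otherwise an independent draw is used.

    Unselected populations are untouched.  Returns a new panel; with
    ``return_record`` also a dict pop -> replaced site-index array
    (including the selected site) used for truth-derived sweep tables.
    """
    out = panel.copy()
    record: dict[str, np.ndarray] = {}
    if truth.scenario == "neutral":
        return (out, record) if return_record else out
    if truth.s <= 0:
        raise ValueError("non-neutral scenario requires s > 0")
    missing = set(truth.selected_pops) - set(panel.pop_names)
    if missing:
        raise ValueError(f"selected populations not in panel: {missing}")

    rng = np.random.default_rng(truth.seed)
    on_chrom = panel.chrom == truth.chrom
    in_region = on_chrom & (panel.pos >= truth.region_start) & (panel.pos < truth.region_end)
    region_idx = np.flatnonzero(in_region)
    if region_idx.size == 0:
        raise ValueError(f"region {truth.region_id}: no SNPs inside")
    sel_site = region_idx[np.argmin(np.abs(panel.pos[region_idx] - truth.selected_position))]

    r = np.abs(panel.pos[region_idx] - panel.pos[sel_site]) * config.recombination_rate
    y = hitchhiking_retention(r, truth.s, config.branch_ne)

    sel_rows = [panel.pop_index(p) for p in truth.selected_pops]
    pre = panel.freq[np.ix_(sel_rows, region_idx)]

    # one shared haplotype for allele-reuse modes, drawn at the origin's
    # pre-sweep frequencies; the standing "origin" is the mean background
    # across selected populations (proxy for the ancestral standing state)
    if truth.scenario == "migration":
        src = panel.pop_index(truth.source_pop)
        origin_freq = panel.freq[src, region_idx]
    else:
        origin_freq = np.nanmean(pre, axis=0)
    shared_hap = (rng.random(region_idx.size) < origin_freq).astype(float)

    for row_i, (prow, name) in enumerate(zip(sel_rows, truth.selected_pops)):
        own_hap = (rng.random(region_idx.size) < pre[row_i]).astype(float)
        if truth.scenario == "independent":
            hap = own_hap
        elif truth.scenario == "migration":
            hap = shared_hap
        else:  # standing: shared state survives recombination with exp(-r*t)
            survives = rng.random(region_idx.size) < np.exp(-r * truth.t_standing)
            hap = np.where(survives, shared_hap, own_hap)
        replace = rng.random(region_idx.size) < y
        replace[region_idx == sel_site] = True  # y(0) = 1 by construction
        new = out.freq[prow, region_idx]
        new = np.where(replace, hap, new)
        out.freq[prow, region_idx] = new
        out.freq[prow, sel_site] = 1.0 - SWEEP_EPSILON
        record[name] = region_idx[replace]
    return (out, record) if return_record else out


# ---------------------------------------------------------------------------
# fixture emission: every downstream input format plus truth labels
# ---------------------------------------------------------------------------

SWEEP_TABLE_HEADER = "chrom\tstart\tend\tpop\tclass"

#: phenotype-category keywords used for the GO fixture; mirrors the kind of
#: keyword list used to bin candidate genes by cave-derived trait
DEFAULT_KEYWORDS: dict[str, list[str]] = {
    "pigmentation": ["pigment", "melanosome", "melanin"],
    "vision": ["eye", "retina", "light", "photoreceptor"],
    "sleep": ["sleep", "circadian"],
    "metabolism": ["lipid", "insulin", "metabolic"],
    "mechanosensory": ["neuromast", "lateral line", "otolith"],
}

_GO_VOCAB = [
    ("GO:0032438", "melanosome organization"),
    ("GO:0048592", "eye morphogenesis"),
    ("GO:0060041", "retina development"),
    ("GO:0030431", "sleep"),
    ("GO:0007623", "circadian rhythm"),
    ("GO:0006629", "lipid metabolic process"),
    ("GO:0032868", "response to insulin"),
    ("GO:0048884", "neuromast development"),
    ("GO:0048840", "otolith development"),
    ("GO:0009416", "response to light stimulus"),
    ("GO:0008152", "metabolic process"),
    ("GO:0007275", "multicellular organism development"),
    ("GO:0016020", "membrane"),
    ("GO:0005634", "nucleus"),
]


def tile_genes(config: DemographyConfig) -> list[dict]:
    """10-kb gene models every 50 kb, alternating strand, with UTR/CDS parts.

    Sub-feature layout per gene (coordinates 0-based, relative to start):
    5'UTR 500 bp, CDS exon 3000 bp, intron 2000 bp, CDS exon 4000 bp,
    3'UTR 500 bp.
    """
    genes = []
    i = 0
    start = 20_000
    while start + 10_000 <= config.chrom_length:
        strand = "+" if i % 2 == 0 else "-"
        genes.append({
            "gene_id": f"gene{i + 1:04d}",
            "chrom": config.chrom,
            "start": start,
            "end": start + 10_000,
            "strand": strand,
        })
        i += 1
        start += 50_000
    return genes


def qtl_intervals(config: DemographyConfig) -> list[tuple[str, int, int]]:
    """Three QTL intervals covering ~25% of the chromosome (BED semantics)."""
    L = config.chrom_length
    return [
        (config.chrom, int(0.05 * L), int(0.13 * L)),
        (config.chrom, int(0.40 * L), int(0.48 * L)),
        (config.chrom, int(0.70 * L), int(0.79 * L)),
    ]


def truth_sweep_table(
    panel: AlleleFrequencyPanel,
    truths: Sequence[ScenarioTruth],
    config: DemographyConfig,
    records: dict[str, dict[str, np.ndarray]] | None = None,
    window_bp: int = 5_000,
):
    """Per-population 5-kb sweep classifications derived from truth.

    A window with >=1 replaced SNP in a selected population is ``hard`` if
    the hitchhiking retention y at the window center exceeds 0.9, else
    ``soft``; windows immediately adjacent to sweep windows get the matching
    linked label; everything else is ``neutral``.
    """
    import pandas as pd

    n_win = int(np.ceil(config.chrom_length / window_bp))
    rows = []
    for pop in panel.pop_names:
        classes = np.array(["neutral"] * n_win, dtype=object)
        for truth in truths:
            if truth.scenario == "neutral" or pop not in truth.selected_pops:
                continue
            if records is not None and truth.region_id in records:
                replaced = records[truth.region_id].get(pop, np.array([], dtype=int))
                win_idx = np.unique(panel.pos[replaced] // window_bp)
            else:  # fall back to the expected hitchhiking footprint
                lo = truth.region_start
                hi = truth.region_end
                sites = np.flatnonzero(
                    (panel.chrom == truth.chrom)
                    & (panel.pos >= lo) & (panel.pos < hi)
                )
                r = np.abs(panel.pos[sites] - truth.selected_position) * config.recombination_rate
                y = hitchhiking_retention(r, truth.s, config.branch_ne)
                win_idx = np.unique(panel.pos[sites[y > 0.5]] // window_bp)
            win_idx = win_idx[win_idx < n_win]
            centers = win_idx * window_bp + window_bp // 2
            rc = np.abs(centers - truth.selected_position) * config.recombination_rate
            yc = hitchhiking_retention(rc, truth.s, config.branch_ne)
            for w, yy in zip(win_idx, yc):
                classes[w] = "hard" if yy > 0.9 else "soft"
            for w, yy in zip(win_idx, yc):
                link = "hardLinked" if yy > 0.9 else "softLinked"
                for adj in (w - 1, w + 1):
                    if 0 <= adj < n_win and classes[adj] == "neutral":
                        classes[adj] = link
        for w in range(n_win):
            rows.append({
                "chrom": config.chrom,
                "start": w * window_bp,
                "end": min((w + 1) * window_bp, config.chrom_length),
                "pop": pop,
                "class": classes[w],
            })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "pop", "class"])


def write_vcf(path: str, panel: AlleleFrequencyPanel, sample_size: int,
              rng: np.random.Generator) -> dict[str, list[str]]:
    """Write a VCF 4.2 with diploid GTs drawn binomially from pop frequencies.

    Returns the sample -> population map implied by the emitted columns.
    """
    samples = []
    sample_pop = {}
    for pop in panel.populations:
        names = [f"{pop.name}_ind{j + 1}" for j in range(sample_size)]
        samples.extend(names)
        sample_pop[pop.name] = names
    # genotype = alt-allele dosage per individual, Binomial(2, p)
    dosages = np.empty((len(samples), panel.n_sites), dtype=np.int8)
    row = 0
    for i, pop in enumerate(panel.populations):
        p = np.nan_to_num(panel.freq[i], nan=0.0)
        dosages[row:row + sample_size] = rng.binomial(2, p, (sample_size, panel.n_sites))
        row += sample_size
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(panel.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j in range(panel.n_sites):
            gts = "\t".join(gt_map[int(d)] for d in dosages[:, j])
            fh.write(f"{panel.chrom[j]}\t{panel.pos[j]}\tsnp{j + 1}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")
    return sample_pop


def write_gff3(path: str, genes: Iterable[dict]) -> None:
    """Emit tiled gene models as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            c, s, e, st, gid = g["chrom"], g["start"], g["end"], g["strand"], g["gene_id"]
            # 0-based half-open -> 1-based inclusive
            fh.write(f"{c}\tsynth\tgene\t{s + 1}\t{e}\t.\t{st}\t.\tID={gid}\n")
            mid = f"{gid}.t1"
            fh.write(f"{c}\tsynth\tmRNA\t{s + 1}\t{e}\t.\t{st}\t.\tID={mid};Parent={gid}\n")
            # layout: UTR5 500 | CDS 3000 | intron 2000 | CDS 4000 | UTR3 500
            parts = [("five_prime_UTR", 0, 500), ("CDS", 500, 3500),
                     ("CDS", 5500, 9500), ("three_prime_UTR", 9500, 10000)]
            if st == "-":
                parts = [("three_prime_UTR", 0, 500), ("CDS", 500, 3500),
                         ("CDS", 5500, 9500), ("five_prime_UTR", 9500, 10000)]
            exons = [(0, 3500), (5500, 10000)]
            for k, (a, b) in enumerate(exons):
                fh.write(f"{c}\tsynth\texon\t{s + a + 1}\t{s + b}\t.\t{st}\t.\t"
                         f"ID={mid}.exon{k + 1};Parent={mid}\n")
            for kind, a, b in parts:
                fh.write(f"{c}\tsynth\t{kind}\t{s + a + 1}\t{s + b}\t.\t{st}\t"
                         f"{0 if kind == 'CDS' else '.'}\tParent={mid}\n")


def emit_fixture_set(
    panel: AlleleFrequencyPanel,
    truths: Sequence[ScenarioTruth],
    outdir: str,
    config: DemographyConfig,
    records: dict[str, dict[str, np.ndarray]] | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Write the full downstream input set plus truth labels.

    Emits: panel VCF, GFF3 gene models, QTL BED, truth-derived sweep-call
    table, motif presence table, GO annotation + keyword tables, sample
    map, and the scenario-truth TSV.  Returns a name -> path dict.
    """
    import pandas as pd

    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = {k: os.path.join(outdir, v) for k, v in {
        "vcf": "panel.vcf", "gff": "genes.gff3", "qtl": "qtl.bed",
        "sweeps": "sweep_calls.tsv", "motifs": "motif_presence.tsv",
        "go": "go_annotations.tsv", "keywords": "keywords.tsv",
        "truth": "truth.tsv", "samples": "samples.tsv",
        "readme": "README.txt",
    }.items()}
    with open(paths["readme"], "w") as fh:
        fh.write(
            "Synthetic fixture set.\n\n"
            "All files here are generated, not observed: the frequency panel\n"
            "comes from a Wright-Fisher stand-in (Gaussian drift steps down a\n"
            "two-lineage tree), sweeps are implanted by deterministic\n"
            "frequency surgery, and the sweep-call, motif and GO tables are\n"
            "derived from the implanted truth in truth.tsv. The generative\n"
            "formulas are stand-ins chosen for controllability, documented in\n"
            "the package's docs/methods.md; they are not a model of any real\n"
            f"dataset. Generator seed: {seed}.\n")

    sample_pop = write_vcf(paths["vcf"], panel, config.sample_size, rng)
    with open(paths["samples"], "w") as fh:
        fh.write("sample\tpop\tecotype\tlineage\n")
        for pop in panel.populations:
            for s in sample_pop[pop.name]:
                fh.write(f"{s}\t{pop.name}\t{pop.ecotype}\t{pop.lineage}\n")

    genes = tile_genes(config)
    write_gff3(paths["gff"], genes)

    with open(paths["qtl"], "w") as fh:
        for c, s, e in qtl_intervals(config):
            fh.write(f"{c}\t{s}\t{e}\n")

    sweep_df = truth_sweep_table(panel, truths, config, records)
    sweep_df.to_csv(paths["sweeps"], sep="\t", index=False)

    # GO annotations: 0-3 terms per gene from a small vocabulary
    go_rows = []
    for g in genes:
        k = rng.integers(0, 4)
        for t in rng.choice(len(_GO_VOCAB), size=k, replace=False):
            go_id, go_name = _GO_VOCAB[int(t)]
            go_rows.append({"gene": g["gene_id"], "go_id": go_id, "go_name": go_name})
    pd.DataFrame(go_rows, columns=["gene", "go_id", "go_name"]).to_csv(
        paths["go"], sep="\t", index=False)

    with open(paths["keywords"], "w") as fh:
        fh.write("category\tkeyword\n")
        for cat, kws in DEFAULT_KEYWORDS.items():
            for kw in kws:
                fh.write(f"{cat}\t{kw}\n")

    # motif presence: high baseline presence; convergent losses implanted in
    # cave populations for genes overlapping swept regions
    swept_spans = [(t.region_start, t.region_end) for t in truths
                   if t.scenario != "neutral"]
    motif_rows = []
    motifs = [f"MA{100 + i}" for i in range(5)]
    for g in genes[: min(len(genes), 40)]:  # keep the fixture small
        in_sweep = any(g["start"] < e and s < g["end"] for s, e in swept_spans)
        for flank in ("upstream", "downstream"):
            for motif in motifs:
                lost = in_sweep and motif in motifs[:2]
                for pop in panel.populations:
                    p_present = 0.9
                    if lost and pop.ecotype == "cave":
                        p_present = 0.05
                    for s in sample_pop[pop.name]:
                        motif_rows.append({
                            "motif": motif, "gene": g["gene_id"], "flank": flank,
                            "pop": pop.name, "genome": s,
                            "present": int(rng.random() < p_present),
                        })
    pd.DataFrame(motif_rows, columns=["motif", "gene", "flank", "pop",
                                      "genome", "present"]).to_csv(
        paths["motifs"], sep="\t", index=False)

    with open(paths["truth"], "w") as fh:
        _write_truth(fh, truths)
    return paths


def _write_truth(fh, truths) -> None:
    fh.write("region_id\tchrom\tregion_start\tregion_end\tscenario\t"
             "selected_position\ts\tt_standing\tg\tsource_pop\tselected_pops\tseed\n")
    for t in truths:
        fh.write(
            f"{t.region_id}\t{t.chrom}\t{t.region_start}\t{t.region_end}\t"
            f"{t.scenario}\t{t.selected_position}\t{t.s}\t{t.t_standing}\t"
            f"{t.g}\t{t.source_pop or '.'}\t{','.join(t.selected_pops) or '.'}\t{t.seed}\n")


# ---------------------------------------------------------------------------
# recovery harnesses: fixed study conditions for parameter-recovery and
# calibration experiments (shared by the test suite and acceptance script)
# ---------------------------------------------------------------------------

#: selection strength and standing time of implanted recovery sweeps
RECOVERY_S = 0.1
RECOVERY_T_STANDING = 500.0
RECOVERY_G = 1e-3


def make_convergence_region(mode: str, seed: int):
    """One 300-kb region with a 100-kb candidate gene swept under ``mode``.

    The gene plus 10-kb flanks gives the composite-likelihood fit a span
    wide enough for the between-population sharing decay to express
    itself (survival of the shared standing background falls to ~0.5 at
    the span edge for t_st = 500).  SNP density is 5 per kb.  Returns
    (panel, gene, truth, config); ``mode`` may be ``neutral``.
    """
    from .panel import GeneModel

    config = DemographyConfig(snp_count=1500, chrom_length=300_000, seed=seed)
    panel, _ = simulate_neutral_panel(config, draw_haplotypes=False)
    caves = tuple(p.name for p in panel.populations if p.ecotype == "cave")
    gene = GeneModel("candidate", config.chrom, 100_000, 200_000, "+")
    truth = ScenarioTruth(
        region_id=f"{mode}_{seed}", scenario=mode, selected_position=150_000,
        region_start=0, region_end=config.chrom_length,
        selected_pops=caves if mode != "neutral" else (),
        s=RECOVERY_S if mode != "neutral" else 0.0,
        t_standing=RECOVERY_T_STANDING if mode == "standing" else 0.0,
        g=RECOVERY_G if mode == "standing" else 0.0,
        source_pop=caves[0] if mode == "migration" else None,
        chrom=config.chrom, seed=seed + 1)
    if mode != "neutral":
        panel = implant_sweep(panel, truth, config)
    return panel, gene, truth, config


SEVEN_CAVE_CONFIG = dict(caves_per_lineage=(3, 4))


def make_reuse_region(kind: str, seed: int):
    """One 200-kb region for the eigen scan: 2 surfaces + 7 caves.

    ``kind``: ``allele`` implants one haplotype shared by all seven caves
    (allele reuse), ``locus`` implants one shared haplotype per lineage
    drawn independently (locus reuse), ``neutral`` implants nothing.
    The selected site sits at 100 kb.
    """
    config = DemographyConfig(snp_count=400, chrom_length=200_000, seed=seed,
                              **SEVEN_CAVE_CONFIG)
    panel, _ = simulate_neutral_panel(config, draw_haplotypes=False)
    caves = {lin: [p.name for p in panel.populations
                   if p.ecotype == "cave" and p.lineage == lin]
             for lin in (1, 2)}
    if kind == "allele":
        truth = ScenarioTruth(
            "allele", "migration", 100_000, 0, config.chrom_length,
            selected_pops=tuple(caves[1] + caves[2]), s=RECOVERY_S,
            source_pop=caves[1][0], chrom=config.chrom, seed=seed + 1)
        panel = implant_sweep(panel, truth, config)
    elif kind == "locus":
        for lin in (1, 2):
            truth = ScenarioTruth(
                f"locus_L{lin}", "migration", 100_000, 0, config.chrom_length,
                selected_pops=tuple(caves[lin]), s=RECOVERY_S,
                source_pop=caves[lin][0], chrom=config.chrom, seed=seed + lin)
            panel = implant_sweep(panel, truth, config)
    elif kind != "neutral":
        raise ValueError(f"unknown region kind {kind!r}")
    return panel, config


def seven_cave_design(panel: AlleleFrequencyPanel):
    """Replicate design pairing each cave with its lineage's surface."""
    from .reuse_scan import ReplicateDesign

    surfaces = {p.lineage: p.name for p in panel.populations
                if p.ecotype == "surface"}
    return ReplicateDesign([
        (surfaces[p.lineage], p.name, p.lineage)
        for p in panel.populations if p.ecotype == "cave"
    ])
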