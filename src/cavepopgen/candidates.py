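"""Sweep-intersection logic and downstream candidate-gene statistics.

Consumes per-population 5-kb sweep-classification tables (diploS/HIC-style
labels: neutral / hard / soft / hardLinked / softLinked / skipped) plus
gene models, QTL intervals, GO annotations and motif-presence tables, and
produces the candidate gene sets and the enrichment / comparison tests
run on them.  A "sweep" always means a hard or soft call; linked and
skipped calls are never evidence of selection, and skipped windows are
evidence-neutral in the surface veto.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import GeneModel, Population, overlaps

SWEEP_CLASSES = ("neutral", "hard", "soft", "hardLinked", "softLinked", "skipped")
SWEPT = frozenset({"hard", "soft"})
SURFACE_OK = frozenset({"neutral", "hardLinked", "softLinked"})


@dataclass
class SweepCallTable:
    """Per-population 5-kb window sweep classifications.

    ``calls`` has columns chrom / start / end / pop / class with 0-based
    half-open window coordinates tiling each chromosome.
    """

    calls: pd.DataFrame
    populations: dict[str, Population] | None = None  # name -> metadata

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "pop", "class"}
        if not required.issubset(self.calls.columns):
            raise ValueError(f"sweep table needs columns {sorted(required)}")
        bad = set(self.calls["class"]) - set(SWEEP_CLASSES)
        if bad:
            raise ValueError(f"unknown sweep classes: {bad}")
        for (pop, chrom), grp in self.calls.groupby(["pop", "chrom"]):
            g = grp.sort_values("start")
            if (g["end"].to_numpy()[:-1] > g["start"].to_numpy()[1:]).any():
                raise ValueError(f"{pop}/{chrom}: overlapping windows")

    def pop_names(self) -> list[str]:
        return sorted(self.calls["pop"].unique())

    def classes_over(self, pop: str, chrom: str, start: int, end: int) -> np.ndarray:
        """Classes of the windows overlapping [start, end) for one population."""
        sub = self.calls[(self.calls["pop"] == pop) & (self.calls["chrom"] == chrom)]
        hit = (sub["start"].to_numpy() < end) & (sub["end"].to_numpy() > start)
        return sub["class"].to_numpy()[hit]

    def lineage_of(self, pop: str) -> int | None:
        if self.populations and pop in self.populations:
            return self.populations[pop].lineage
        return None


# ---------------------------------------------------------------------------
# intersection logic
# ---------------------------------------------------------------------------

def cave_adaptive_genes(
    sweeps: SweepCallTable,
    genes: list[GeneModel],
    cave_pop: str,
    surface_pop: str,
) -> set[str]:
    """Genes swept in a cave population and clean in its lineage's surface.

    A gene qualifies when at least one window overlapping its span
    (UTR + CDS + introns) is hard or soft in the cave population AND every
    non-skipped window overlapping the span in the surface population is
    neutral or linked.  Cross-lineage pairings are rejected.
    """
    cl, sl = sweeps.lineage_of(cave_pop), sweeps.lineage_of(surface_pop)
    if cl is not None and sl is not None and cl != sl:
        raise ValueError(f"{cave_pop} and {surface_pop} are not in the same lineage")
    out = set()
    for gene in genes:
        cave = sweeps.classes_over(cave_pop, gene.chrom, gene.start, gene.end)
        if not any(c in SWEPT for c in cave):
            continue
        surf = [c for c in sweeps.classes_over(surface_pop, gene.chrom,
                                               gene.start, gene.end)
                if c != "skipped"]
        if all(c in SURFACE_OK for c in surf):
            out.add(gene.gene_id)
    return out


def overlapping_sweeps(
    sweeps: SweepCallTable,
    genes: list[GeneModel],
    cave_pops: list[str],
    surface_pops: list[str],
) -> set[str]:
    """Genes swept in every listed cave and clean in every listed surface.

    The cave-adaptive condition must hold simultaneously for each cave
    against each surface, so the result is contained in every pairwise
    cave-adaptive set.
    """
    out: set[str] | None = None
    for cave in cave_pops:
        for surf in surface_pops:
            pair = _cave_adaptive_no_lineage_check(sweeps, genes, cave, surf)
            out = pair if out is None else (out & pair)
    return out or set()


def _cave_adaptive_no_lineage_check(sweeps, genes, cave_pop, surface_pop):
    # overlapping-sweeps intersections deliberately cross lineages
    out = set()
    for gene in genes:
        cave = sweeps.classes_over(cave_pop, gene.chrom, gene.start, gene.end)
        if not any(c in SWEPT for c in cave):
            continue
        surf = [c for c in sweeps.classes_over(surface_pop, gene.chrom,
                                               gene.start, gene.end)
                if c != "skipped"]
        if all(c in SURFACE_OK for c in surf):
            out.add(gene.gene_id)
    return out


def sweep_fraction(sweeps: SweepCallTable, pop: str) -> float:
    """Fraction of a population's classified windows carrying a sweep call."""
    sub = sweeps.calls[sweeps.calls["pop"] == pop]
    cls = sub["class"].to_numpy()
    usable = cls != "skipped"
    if not usable.any():
        return np.nan
    return float(np.isin(cls[usable], list(SWEPT)).mean())


# ---------------------------------------------------------------------------
# phenotype categories
# ---------------------------------------------------------------------------

def assign_phenotype_categories(
    genes: list[GeneModel],
    keyword_table: dict[str, list[str]],
) -> dict[str, set[str]]:
    """Map gene -> phenotype categories by GO-name keyword substrings.

    A gene joins every category one of whose keywords substring-matches
    (case-insensitively) any of its GO term names; multi-assignment is
    allowed and genes without GO terms stay unassigned.
    """
    if not keyword_table:
        raise ValueError("empty keyword table")
    out: dict[str, set[str]] = {}
    for gene in genes:
        cats = set()
        terms = [t.lower() for t in gene.go_terms]
        for category, keywords in keyword_table.items():
            if any(kw.lower() in term for kw in keywords for term in terms):
                cats.add(category)
        if cats:
            out[gene.gene_id] = cats
    return out


# ---------------------------------------------------------------------------
# enrichment and comparison statistics
# ---------------------------------------------------------------------------

def qtl_overlap_permutation(
    gene_set: set[str],
    all_genes: list[GeneModel],
    qtl_intervals: list[tuple[str, int, int]],
    n_perm: int = 5_000,
    seed: int = 0,
) -> dict:
    """One-sided permutation test of gene-set overlap with QTL intervals.

    ``observed`` counts set genes overlapping any QTL interval; the null
    re-draws equally sized gene sets without replacement from
    ``all_genes``.  p = (1 + #{null >= observed}) / (n_perm + 1).  When
    the null is degenerate (sd = 0), Z is reported missing.
    """
    universe = [g.gene_id for g in all_genes]
    if not gene_set <= set(universe):
        raise ValueError("gene set must be a subset of the gene universe")
    hits = np.array([
        any(g.chrom == c and overlaps(g.start, g.end, s, e)
            for c, s, e in qtl_intervals)
        for g in all_genes
    ])
    in_set = np.array([g in gene_set for g in universe])
    observed = int(np.sum(hits & in_set))
    m = int(in_set.sum())
    if m == 0 or not qtl_intervals:
        return {"observed": observed, "null_mean": 0.0, "null_sd": 0.0,
                "z": np.nan, "p": 1.0, "n_perm": n_perm}
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=np.int64)
    n_genes = len(universe)
    for b in range(n_perm):
        null[b] = hits[rng.choice(n_genes, size=m, replace=False)].sum()
    mean, sd = float(null.mean()), float(null.std(ddof=0))
    z = (observed - mean) / sd if sd > 0 else np.nan
    if sd == 0:
        # degenerate null (e.g. QTL covering the whole genome): every
        # permutation ties the observation; report the resolution floor
        p = 1.0 / (n_perm + 1.0)
    else:
        p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return {"observed": observed, "null_mean": mean, "null_sd": sd,
            "z": z, "p": float(p), "n_perm": n_perm}


def fisher_enrichment(k_set: int, n_set: int, k_bg: int, n_bg: int):
    """Fisher's exact test of feature enrichment in a gene set vs background.

    The 2x2 table is {k_set, n_set-k_set; k_bg-k_set, (n_bg-n_set)-(k_bg-k_set)};
    the set must be a subset of the background.  Returns (odds_ratio, p).
    """
    a = k_set
    b = n_set - k_set
    c = k_bg - k_set
    d = (n_bg - n_set) - (k_bg - k_set)
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell: gene set is not a subset of background")
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def length_comparison(
    candidate_values,
    genome_values,
) -> tuple[float, float, float]:
    """Welch two-sided t-test, candidate minus genome sign convention.

    Used for transcript length, CDS length, exon count and isoform count.
    Returns (t, df, p) with the Welch-Satterthwaite fractional df.
    """
    x = np.asarray(candidate_values, dtype=float)
    y = np.asarray(genome_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two genes per group")
    if np.var(x) == 0 and np.var(y) == 0:
        raise ValueError("zero variance in both groups")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def sweep_age_by_category(
    ages: dict[str, np.ndarray],
) -> tuple[float, int, float]:
    """Kruskal-Wallis comparison of sweep-age distributions across categories.

    Midrank tie correction; chi-square p on (n_categories - 1) df.
    Returns (H, df, p).
    """
    groups = [np.asarray(v, dtype=float) for v in ages.values()]
    if len(groups) < 2:
        raise ValueError("need at least two categories")
    if any(g.size < 2 for g in groups):
        raise ValueError("every category needs at least two ages")
    res = sps.kruskal(*groups)
    return float(res.statistic), len(groups) - 1, float(res.pvalue)


# ---------------------------------------------------------------------------
# convergent TFBS loss
# ---------------------------------------------------------------------------

@dataclass
class MotifPresenceTable:
    """Motif presence flags per genome, gene flank and population.

    ``table`` columns: motif, gene, flank (upstream/downstream), pop,
    genome, present (0/1).  Every genome must belong to exactly one
    population.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"motif", "gene", "flank", "pop", "genome", "present"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"motif table needs columns {sorted(required)}")
        if not self.table["present"].isin([0, 1, True, False]).all():
            raise ValueError("presence flags must be boolean")
        pops_per_genome = self.table.groupby("genome")["pop"].nunique()
        if (pops_per_genome > 1).any():
            raise ValueError("each genome must belong to exactly one population")


def tfbs_loss_filter(
    table: pd.DataFrame | MotifPresenceTable,
    surface_pops: list[str],
    cave_pops: list[str],
    surface_min: float = 0.80,
    cave_max: float = 0.20,
) -> pd.DataFrame:
    """Motifs convergently lost in caves: present in >= 80% of genomes in
    every surface population and < 20% in every cave population.

    ``table`` columns: motif, gene, flank, pop, genome, present.  Boundary
    semantics are exact: a surface fraction of exactly 0.80 passes, a cave
    fraction of exactly 0.20 fails.
    """
    if isinstance(table, MotifPresenceTable):
        table = table.table
    if not surface_pops or not cave_pops:
        raise ValueError("need at least one surface and one cave population")
    sizes = table.groupby("pop")["genome"].nunique()
    for pop in list(surface_pops) + list(cave_pops):
        if sizes.get(pop, 0) == 0:
            raise ValueError(f"population {pop} has zero genomes in the table")
    frac = (table.groupby(["gene", "flank", "motif", "pop"])["present"]
            .mean().unstack("pop"))
    surf_ok = np.all([frac[p] >= surface_min for p in surface_pops], axis=0)
    cave_ok = np.all([frac[p] < cave_max for p in cave_pops], axis=0)
    losses = frac.index.to_frame(index=False)[surf_ok & cave_ok]
    return losses.reset_index(drop=True)[["gene", "flank", "motif"]]


# ---------------------------------------------------------------------------
# count summaries
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


def summarize_category_counts(
    per_pop_counts: dict[str, int],
    annotation_total: int | None = None,
) -> dict:
    """Per-population counts with their mean and annotation fraction.

    The mean is rounded to the nearest integer and fractions to the
    nearest whole percent, halves away from zero.
    """
    counts = dict(per_pop_counts)
    mean = _round_half_away(float(np.mean(list(counts.values())))) if counts else 0
    out = {"counts": counts, "mean": mean}
    if annotation_total:
        out["percent_of_annotation"] = {
            pop: _round_half_away(100.0 * c / annotation_total)
            for pop, c in counts.items()
        }
        out["mean_percent_of_annotation"] = _round_half_away(
            100.0 * float(np.mean(list(counts.values()))) / annotation_total)
    return out
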