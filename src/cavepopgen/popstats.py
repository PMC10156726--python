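"""Site filters and population-genetic summary statistics.

Per-site pi / Dxy / Fst, their 50-kb windowed and per-gene aggregates, the
two dating relations (Dxy = 2*mu*T for allele split times and
T_admix = 1/(L_M * p_B) for admixture onset from ancestry-tract lengths),
the frequency-based ABBA-BABA D statistic with a block jackknife, and the
cave-versus-surface comparison of genome fractions under selection.

Fst uses the Hudson (1992) estimator with sample-size correction and
ratio-of-sums aggregation across windows.  Missing frequencies are
excluded pairwise per statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import AlleleFrequencyPanel, GeneModel, GenotypeMatrix, Population


# ---------------------------------------------------------------------------
# site filter cascade
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Counts of sites removed by each rule, in application order."""

    input_sites: int = 0
    removed_non_biallelic: int = 0
    removed_missingness: int = 0
    removed_maf: int = 0
    removed_all_heterozygous: int = 0
    retained: int = 0
    snps_retained: int = 0

    @property
    def removed_total(self) -> int:
        return (self.removed_non_biallelic + self.removed_missingness
                + self.removed_maf + self.removed_all_heterozygous)

    def check_conservation(self) -> None:
        if self.removed_total + self.retained != self.input_sites:
            raise AssertionError("filter report does not conserve site count")


def apply_site_filters(
    genotypes: GenotypeMatrix,
    max_missing: float = 0.20,
    min_maf: float = 0.01,
) -> tuple[AlleleFrequencyPanel, FilterReport]:
    """Apply the genotyping filter cascade and build a frequency panel.

    Rules in order: retain biallelic SNPs only; remove sites with more than
    ``max_missing`` missing data within any single population; remove
    variants with pooled minor allele frequency below ``min_maf``; remove
    sites where every genotyped sample in some population is heterozygous
    (collapsed-paralog signature).  Each site is counted once, under the
    first rule that removes it.
    """
    if genotypes.n_sites == 0:
        raise ValueError("empty genotype table")
    report = FilterReport(input_sites=genotypes.n_sites)
    dos = genotypes.dosage
    miss = dos < 0

    alive = genotypes.n_alt_alleles == 1
    report.removed_non_biallelic = int(np.sum(~alive))

    pop_rows = {p.name: genotypes.pop_sample_indices(p.name)
                for p in genotypes.populations}
    fail_missing = np.zeros(genotypes.n_sites, dtype=bool)
    for rows in pop_rows.values():
        if rows.size == 0:
            continue
        frac = miss[rows].mean(axis=0)
        fail_missing |= frac > max_missing
    newly = alive & fail_missing
    report.removed_missingness = int(np.sum(newly))
    alive &= ~fail_missing

    # pooled MAF across all retained samples
    called = ~miss
    alt = np.where(called, dos, 0).sum(axis=0)
    tot = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    maf = np.minimum(p, 1.0 - p)
    fail_maf = ~(maf >= min_maf)  # NaN (no calls) fails too
    newly = alive & fail_maf
    report.removed_maf = int(np.sum(newly))
    alive &= ~fail_maf

    fail_het = np.zeros(genotypes.n_sites, dtype=bool)
    for rows in pop_rows.values():
        if rows.size == 0:
            continue
        sub = dos[rows]
        called_sub = sub >= 0
        n_called = called_sub.sum(axis=0)
        n_het = (sub == 1).sum(axis=0)
        fail_het |= (n_called > 0) & (n_het == n_called)
    newly = alive & fail_het
    report.removed_all_heterozygous = int(np.sum(newly))
    alive &= ~fail_het

    keep = np.flatnonzero(alive)
    report.retained = keep.size
    report.snps_retained = keep.size
    report.check_conservation()

    k = len(genotypes.populations)
    freq = np.full((k, keep.size), np.nan)
    n = np.zeros((k, keep.size), dtype=np.int64)
    for i, pop in enumerate(genotypes.populations):
        rows = pop_rows[pop.name]
        sub = dos[np.ix_(rows, keep)]
        called_sub = sub >= 0
        n_hap = 2 * called_sub.sum(axis=0)
        alt = np.where(called_sub, sub, 0).sum(axis=0)
        ok = n_hap >= 2
        freq[i, ok] = alt[ok] / n_hap[ok]
        n[i] = n_hap
    panel = AlleleFrequencyPanel(
        populations=list(genotypes.populations),
        chrom=genotypes.chrom[keep],
        pos=genotypes.pos[keep],
        freq=freq,
        n=n,
    )
    return panel, report


# ---------------------------------------------------------------------------
# per-site statistics
# ---------------------------------------------------------------------------

def site_pi(p, n):
    """Nucleotide diversity at a site: 2p(1-p) * n/(n-1)."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 2):
        raise ValueError("site_pi requires n >= 2")
    return 2.0 * p * (1.0 - p) * n / (n - 1.0)


def site_dxy(p1, p2):
    """Absolute divergence at a site: p1(1-p2) + p2(1-p1)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return p1 * (1.0 - p2) + p2 * (1.0 - p1)


def _fst_components(p1, n1, p2, n2):
    """Hudson-estimator numerator and denominator per site."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    num = ((p1 - p2) ** 2
           - p1 * (1.0 - p1) / (n1 - 1.0)
           - p2 * (1.0 - p2) / (n2 - 1.0))
    den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    return num, den


def site_fst(p1, n1, p2, n2):
    """Hudson Fst at one site; NaN where the denominator is zero."""
    if np.any(np.asarray(n1) < 2) or np.any(np.asarray(n2) < 2):
        raise ValueError("site_fst requires n >= 2 in both populations")
    num, den = _fst_components(p1, n1, p2, n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# windowed and per-gene aggregation
# ---------------------------------------------------------------------------

def _window_index(chrom: np.ndarray, pos: np.ndarray, window_bp: int):
    """Assign each site to a (chrom, window_start) bin; windows tile from 0.

    Positions are 1-based, so site pos belongs to window (pos-1)//window_bp.
    """
    starts = (pos - 1) // window_bp * window_bp
    return list(zip(chrom.tolist(), starts.tolist())), starts


def windowed_stats(panel: AlleleFrequencyPanel, window_bp: int = 50_000) -> pd.DataFrame:
    """Mean pi, Dxy, and ratio-of-sums Fst in non-overlapping windows.

    One row per (chrom, window, statistic, unit); ``unit`` is a population
    for pi and a ``popA|popB`` pair for Dxy/Fst.  Empty combinations are
    reported with missing values.
    """
    keys, starts = _window_index(panel.chrom, panel.pos, window_bp)
    df_sites = pd.DataFrame({"chrom": panel.chrom, "wstart": starts})
    groups = df_sites.groupby(["chrom", "wstart"], sort=True).indices

    rows = []
    names = panel.pop_names
    for (chrom, wstart), idx in groups.items():
        idx = np.asarray(idx)
        wend = wstart + window_bp
        for i, name in enumerate(names):
            p = panel.freq[i, idx]
            n = panel.n[i, idx]
            ok = ~np.isnan(p)
            val = float(np.mean(site_pi(p[ok], n[ok]))) if ok.any() else np.nan
            rows.append((chrom, wstart, wend, "pi", name, val, int(ok.sum())))
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pi_, pj = panel.freq[i, idx], panel.freq[j, idx]
                ok = ~np.isnan(pi_) & ~np.isnan(pj)
                pair = f"{names[i]}|{names[j]}"
                if ok.any():
                    dxy = float(np.mean(site_dxy(pi_[ok], pj[ok])))
                    num, den = _fst_components(pi_[ok], panel.n[i, idx][ok],
                                               pj[ok], panel.n[j, idx][ok])
                    dsum = float(np.sum(den))
                    fst = float(np.sum(num) / dsum) if dsum > 0 else np.nan
                else:
                    dxy = fst = np.nan
                rows.append((chrom, wstart, wend, "dxy", pair, dxy, int(ok.sum())))
                rows.append((chrom, wstart, wend, "fst", pair, fst, int(ok.sum())))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "stat",
                                       "unit", "value", "n_sites"])


def gene_stats(panel: AlleleFrequencyPanel, genes: list[GeneModel]) -> pd.DataFrame:
    """Min / max / mean of per-site statistics over SNPs inside each gene span.

    Operates on sites directly (never on window averages).  Genes without
    SNPs get missing-value rows.
    """
    names = panel.pop_names
    rows = []
    for gene in genes:
        on = (panel.chrom == gene.chrom) & (panel.pos - 1 >= gene.start) \
            & (panel.pos - 1 < gene.end)
        idx = np.flatnonzero(on)

        def emit(stat, unit, vals):
            if vals.size:
                rows.append((gene.gene_id, stat, unit, float(np.min(vals)),
                             float(np.max(vals)), float(np.mean(vals)), vals.size))
            else:
                rows.append((gene.gene_id, stat, unit, np.nan, np.nan, np.nan, 0))

        for i, name in enumerate(names):
            p = panel.freq[i, idx]
            n = panel.n[i, idx]
            ok = ~np.isnan(p)
            emit("pi", name, site_pi(p[ok], n[ok]) if ok.any() else np.array([]))
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pi_, pj = panel.freq[i, idx], panel.freq[j, idx]
                ok = ~np.isnan(pi_) & ~np.isnan(pj)
                pair = f"{names[i]}|{names[j]}"
                emit("dxy", pair, site_dxy(pi_[ok], pj[ok]) if ok.any() else np.array([]))
                vals = site_fst(pi_[ok], panel.n[i, idx][ok], pj[ok],
                                panel.n[j, idx][ok]) if ok.any() else np.array([])
                vals = np.asarray(vals)
                emit("fst", pair, vals[~np.isnan(vals)] if vals.size else vals)
    return pd.DataFrame(rows, columns=["gene", "stat", "unit", "min",
                                       "max", "mean", "n_sites"])


# ---------------------------------------------------------------------------
# dating
# ---------------------------------------------------------------------------

def tmrca_from_dxy(dxy: float, mu: float = 3.5e-9) -> float:
    """Split time in generations from absolute divergence: T = Dxy / (2*mu)."""
    if mu <= 0:
        raise ValueError("mutation rate must be > 0")
    return float(dxy) / (2.0 * mu)


@dataclass
class AncestryTracts:
    """Per-individual local-ancestry tracts for admixture dating.

    ``tracts`` maps individual -> list of (source, length_bp) with source
    in {"minor", "major"}.
    """

    tracts: dict[str, list[tuple[str, int]]]
    genome_length: int
    recombination_rate: float = 1.16e-8  # Morgans per bp

    def __post_init__(self) -> None:
        for ind, tr in self.tracts.items():
            total = 0
            for source, length in tr:
                if source not in ("minor", "major"):
                    raise ValueError(f"{ind}: unknown tract source {source!r}")
                if length <= 0:
                    raise ValueError(f"{ind}: tract lengths must be > 0")
                total += length
            if total > self.genome_length:
                raise ValueError(f"{ind}: tract lengths exceed genome length")

    def minor_tract_lengths_morgans(self) -> np.ndarray:
        out = [length * self.recombination_rate
               for tr in self.tracts.values()
               for source, length in tr if source == "minor"]
        return np.asarray(out, dtype=float)

    def major_fraction(self) -> float:
        major = sum(length for tr in self.tracts.values()
                    for source, length in tr if source == "major")
        total = sum(length for tr in self.tracts.values() for _, length in tr)
        return major / total if total else np.nan


def admixture_time(tracts: AncestryTracts) -> float:
    """Generations since admixture onset: T = 1 / (L_M * p_B).

    L_M is the mean minor-parent tract length in Morgans and p_B the
    major-parent genome fraction (the probability a recombination event
    falls on major-parent background).
    """
    lm = tracts.minor_tract_lengths_morgans()
    if lm.size == 0:
        raise ValueError("at least one minor-parent tract is required")
    L_M = float(np.mean(lm))
    p_B = tracts.major_fraction()
    if L_M <= 0:
        raise ValueError("mean minor tract length must be > 0")
    if not 0.0 < p_B < 1.0:
        raise ValueError("major-parent fraction must be strictly between 0 and 1")
    return 1.0 / (L_M * p_B)


# ---------------------------------------------------------------------------
# introgression: frequency-based ABBA-BABA
# ---------------------------------------------------------------------------

def patterson_d(p1, p2, p3, p4, block_snps: int = 500):
    """Patterson's D from four aligned allele-frequency vectors.

    ABBA and BABA site weights use the outgroup (P4) to polarize:
    ABBA = (1-p1) p2 p3 (1-p4), BABA = p1 (1-p2) p3 (1-p4).
    D = sum(ABBA - BABA) / sum(ABBA + BABA); the standard error comes from
    a block jackknife over ``block_snps``-SNP blocks.

    Returns (D, SE, Z); D is NaN when the denominator is zero.
    """
    p1, p2, p3, p4 = (np.asarray(x, dtype=float) for x in (p1, p2, p3, p4))
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    num = np.nansum(abba - baba)
    den = np.nansum(abba + baba)
    if den == 0:
        return np.nan, np.nan, np.nan
    d = num / den

    m = p1.size
    n_blocks = int(np.ceil(m / block_snps))
    if n_blocks < 2:
        return float(d), np.nan, np.nan
    d_jack = []
    for b in range(n_blocks):
        sl = slice(b * block_snps, min((b + 1) * block_snps, m))
        nb = num - np.nansum(abba[sl] - baba[sl])
        db = den - np.nansum(abba[sl] + baba[sl])
        d_jack.append(nb / db if db != 0 else d)
    d_jack = np.asarray(d_jack)
    se = float(np.sqrt((n_blocks - 1) / n_blocks
                       * np.sum((d_jack - np.mean(d_jack)) ** 2)))
    z = float(d / se) if se > 0 else np.nan
    return float(d), se, z


# ---------------------------------------------------------------------------
# genome-fraction comparison
# ---------------------------------------------------------------------------

def compare_sweep_fractions(fractions_cave, fractions_surface):
    """One-sided rank-sum test that cave sweep fractions exceed surface ones.

    Returns (W, p) with W the Mann-Whitney U of the cave sample (the
    statistic R reports as W).  Exact null distribution for small groups
    without ties; midranks otherwise.
    """
    cave = np.asarray(fractions_cave, dtype=float)
    surf = np.asarray(fractions_surface, dtype=float)
    if cave.size < 2 or surf.size < 2:
        raise ValueError("need at least two values per group")
    has_ties = np.unique(np.concatenate([cave, surf])).size < cave.size + surf.size
    method = "asymptotic" if has_ties else (
        "exact" if max(cave.size, surf.size) <= 10 else "auto")
    res = sps.mannwhitneyu(cave, surf, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)
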