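"""Eigenanalysis of allele-frequency change across replicate pairs.

Each replicate surface->cave comparison contributes one allele-frequency
change vector per window of 50 SNPs.  The spectrum of the k x k
cross-product of unit-normalized change vectors separates reuse patterns:
one dominant eigenvalue with same-sign loadings means every cave moved the
same alleles the same way (allele reuse); a spectrum split along lineage
lines means each lineage moved its own alleles at the same locus (locus
reuse).  Significance is empirical, against null pseudo-windows of 50
SNPs resampled genome-wide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import AlleleFrequencyPanel, GeneModel, overlaps

logger = logging.getLogger(__name__)

CLASSIFICATIONS = ("none", "allele_reuse", "locus_reuse", "antiparallel", "divergent")

#: loadings closer to zero than this are treated as sign-neutral
LOADING_TOL = 0.05


@dataclass
class ReplicateDesign:
    """Ordered surface->cave replicate pairs with lineage labels."""

    pairs: list[tuple[str, str, int]]  # (surface_pop, cave_pop, lineage)

    def __post_init__(self) -> None:
        if len(self.pairs) < 2:
            raise ValueError("need at least two replicate pairs")

    @property
    def k(self) -> int:
        return len(self.pairs)

    @property
    def lineages(self) -> np.ndarray:
        return np.asarray([lin for _, _, lin in self.pairs])

    def validate_against(self, panel: AlleleFrequencyPanel) -> None:
        names = set(panel.pop_names)
        for surf, cave, _ in self.pairs:
            if surf not in names or cave not in names:
                raise ValueError(f"design pair ({surf}, {cave}) not in panel")


@dataclass
class EigenWindowResult:
    """Eigen decomposition of one 50-SNP window plus its classification."""

    chrom: str
    start: int  # bp span of the window, 1-based inclusive endpoints
    end: int
    snp_count: int
    eigenvalues: np.ndarray  # descending
    loadings: np.ndarray  # column j = eigenvector j, rows = replicates
    p_values: np.ndarray  # cumulative empirical p per eigenvector index
    classification: str = "none"
    usable: bool = True


def change_vectors(panel: AlleleFrequencyPanel, design: ReplicateDesign) -> np.ndarray:
    """Raw (k, m) matrix of cave-minus-surface frequency change per pair."""
    design.validate_against(panel)
    rows = []
    for surf, cave, _ in design.pairs:
        rows.append(panel.freq[panel.pop_index(cave)]
                    - panel.freq[panel.pop_index(surf)])
    return np.vstack(rows)


def af_change_matrix(
    panel: AlleleFrequencyPanel,
    design: ReplicateDesign,
    window_sites: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-normalized allele-frequency-change matrix for one window.

    Row j is the cave-minus-surface frequency difference of replicate j
    over the window's SNPs, scaled to unit Euclidean norm.  Returns
    (A, kept_rows); rows with zero norm are dropped and reported missing
    from ``kept_rows`` (the caller flags the window).
    """
    window_sites = np.asarray(window_sites)
    sub = panel.take_sites(window_sites)
    if np.isnan([sub.freq[sub.pop_index(p)]
                 for pair in design.pairs for p in pair[:2]]).any():
        raise ValueError("window has undefined frequencies in design populations")
    A = change_vectors(sub, design)
    norms = np.linalg.norm(A, axis=1)
    kept = np.flatnonzero(norms > 0)
    if kept.size < design.k:
        logger.warning("window: %d replicate rows with zero change dropped",
                       design.k - kept.size)
    A = A[kept] / norms[kept, None]
    return A, kept


def eigen_scan(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen decomposition of C = A A^T with a deterministic sign convention.

    Returns eigenvalues in descending order and the loading matrix whose
    column j is eigenvector j, oriented so its largest-magnitude loading
    is positive.
    """
    C = A @ A.T
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    for j in range(vecs.shape[1]):
        pivot = np.argmax(np.abs(vecs[:, j]))
        if vecs[pivot, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vals, vecs


@dataclass
class NullDistribution:
    """Empirical null of cumulative eigenvalue sums from pseudo-windows."""

    cumulative: np.ndarray  # (n_perm, k) cumulative eigenvalue sums
    q99: np.ndarray  # per eigenvector index m (0-based): 99th percentile
    n_perm: int

    def empirical_p(self, m_index: int, value: float) -> float:
        """P(null cumulative sum at index >= value), add-one corrected."""
        null = self.cumulative[:, m_index]
        return (1.0 + np.sum(null >= value)) / (self.n_perm + 1.0)


def null_distribution(
    panel: AlleleFrequencyPanel,
    design: ReplicateDesign,
    n_perm: int = 10_000,
    seed: int = 0,
    window_snps: int = 50,
    alpha: float = 0.01,
) -> NullDistribution:
    """Null eigenvalue distributions from random genome-wide pseudo-windows.

    Each permutation samples ``window_snps`` SNPs uniformly at random
    (same sites across replicates, independently per permutation), builds
    the normalized change matrix and records cumulative eigenvalue sums
    for m = 1..k.
    """
    D = change_vectors(panel, design)
    valid = np.flatnonzero(~np.isnan(D).any(axis=0))
    if valid.size < window_snps:
        raise ValueError("not enough defined SNPs to build pseudo-windows")
    rng = np.random.default_rng(seed)
    replace = False
    if valid.size < 10 * n_perm:
        warnings.warn("fewer than 10 * n_perm candidate SNPs; sampling "
                      "pseudo-windows with replacement", stacklevel=2)
        replace = True
    if replace:
        idx = rng.choice(valid, size=(n_perm, window_snps), replace=True)
    else:
        idx = np.empty((n_perm, window_snps), dtype=np.int64)
        for b in range(n_perm):
            idx[b] = rng.choice(valid, size=window_snps, replace=False)
    W = D.T[idx]  # (n_perm, window_snps, k)
    W = np.swapaxes(W, 1, 2)  # (n_perm, k, window_snps)
    norms = np.linalg.norm(W, axis=2, keepdims=True)
    norms[norms == 0] = 1.0
    W = W / norms
    C = W @ np.swapaxes(W, 1, 2)
    vals = np.linalg.eigvalsh(C)[:, ::-1]  # descending
    cum = np.cumsum(vals, axis=1)
    q99 = np.quantile(cum, 1.0 - alpha, axis=0)
    return NullDistribution(cumulative=cum, q99=q99, n_perm=n_perm)


def _sign_categories(loadings: np.ndarray, tol: float = LOADING_TOL) -> np.ndarray:
    cats = np.where(loadings > tol, 1, np.where(loadings < -tol, -1, 0))
    return cats


def _partitions_by_lineage(cats: np.ndarray, lineages: np.ndarray) -> bool:
    """True when each lineage is internally uniform and lineages differ."""
    groups = [cats[lineages == lin] for lin in np.unique(lineages)]
    if len(groups) < 2:
        return False
    reps = []
    for g in groups:
        if g.size == 0 or not np.all(g == g[0]):
            return False
        reps.append(g[0])
    return len(set(reps)) == len(reps)


def classify_window(
    result: EigenWindowResult,
    null: NullDistribution,
    design: ReplicateDesign,
    joint_ev2: bool = True,
    tol: float = LOADING_TOL,
) -> str:
    """Classify a window's reuse pattern from its spectrum and loadings.

    allele_reuse: leading eigenvalue significant and every eigenvector-1
    loading clearly nonzero with a common sign.  locus_reuse: the
    (joint or marginal) eigenvector-2 statistic significant and the sign
    structure of eigenvector 2 (or a sign split of eigenvector 1)
    partitions replicates by lineage.  antiparallel: eigenvector-1
    significant with mixed signs not aligned with lineage.  divergent:
    eigenvector-2 significance without a lineage partition.  Precedence:
    allele_reuse > locus_reuse > antiparallel > divergent.
    """
    lam = result.eigenvalues
    sig1 = lam[0] > null.q99[0]
    stat2 = lam[0] + lam[1] if joint_ev2 else lam[1]
    thresh2 = null.q99[1] if joint_ev2 else np.quantile(
        null.cumulative[:, 1] - null.cumulative[:, 0], 0.99)
    sig2 = lam.size >= 2 and stat2 > thresh2
    # marginal guard: a locus-reuse call additionally requires eigenvalue 2
    # itself (not just the cumulative sum) to be extreme, so that a strong
    # one-axis signal with coherent cross-lineage leakage on eigenvector 1
    # cannot be demoted to, or mistaken for, a two-axis pattern
    lam2_q99 = np.quantile(null.cumulative[:, 1] - null.cumulative[:, 0], 0.99)
    sig2_marginal = lam.size >= 2 and lam[1] > lam2_q99

    lineages = design.lineages
    if result.loadings.shape[0] != lineages.size:
        logger.warning("replicate rows dropped; locus-reuse call unavailable")
        lineages = None

    cats1 = _sign_categories(result.loadings[:, 0], tol)
    locus = False
    if lineages is not None and sig2 and sig2_marginal:
        cats2 = _sign_categories(result.loadings[:, 1], tol) \
            if result.loadings.shape[1] >= 2 else None
        locus = (cats2 is not None and _partitions_by_lineage(cats2, lineages)) \
            or _partitions_by_lineage(cats1, lineages)
    if sig1 and np.all(cats1 != 0) and np.unique(cats1).size == 1 and not locus:
        return "allele_reuse"
    if locus:
        return "locus_reuse"
    if sig1 and np.unique(cats1).size > 1:
        if lineages is None or not _partitions_by_lineage(cats1, lineages):
            return "antiparallel"
    if sig2:
        return "divergent"
    return "none"


def scan_panel(
    panel: AlleleFrequencyPanel,
    design: ReplicateDesign,
    null: NullDistribution,
    window_snps: int = 50,
    joint_ev2: bool = True,
) -> list[EigenWindowResult]:
    """Non-overlapping 50-SNP windows across the panel, classified.

    Windows advance in steps of ``window_snps`` eligible SNPs (defined in
    every design population); chromosome-end remainders are skipped.
    """
    D = change_vectors(panel, design)
    results = []
    for chrom in dict.fromkeys(panel.chrom):
        on = np.flatnonzero((panel.chrom == chrom) & ~np.isnan(D).any(axis=0))
        n_win = on.size // window_snps
        if on.size % window_snps:
            logger.info("%s: %d trailing SNPs skipped", chrom,
                        on.size % window_snps)
        for w in range(n_win):
            sites = on[w * window_snps:(w + 1) * window_snps]
            A, kept = af_change_matrix(panel, design, sites)
            res = EigenWindowResult(
                chrom=str(chrom),
                start=int(panel.pos[sites[0]]),
                end=int(panel.pos[sites[-1]]),
                snp_count=window_snps,
                eigenvalues=np.zeros(design.k),
                loadings=np.zeros((design.k, design.k)),
                p_values=np.ones(design.k),
            )
            if kept.size == 0:
                res.usable = False
                results.append(res)
                continue
            vals, vecs = eigen_scan(A)
            res.eigenvalues = vals
            res.loadings = vecs
            cum = np.cumsum(vals)
            res.p_values = np.array([
                null.empirical_p(m, cum[m]) for m in range(vals.size)])
            if kept.size == design.k:
                res.classification = classify_window(res, null, design, joint_ev2)
            else:
                res.usable = False
            results.append(res)
    return results


def windows_to_genes(
    results: list[EigenWindowResult],
    genes: list[GeneModel],
) -> pd.DataFrame:
    """Genes overlapped by significant reuse windows, once per label.

    A gene may carry both the allele_reuse and locus_reuse labels when
    different windows over its span classify differently.
    """
    rows = []
    for gene in genes:
        labels = set()
        for res in results:
            if res.classification not in ("allele_reuse", "locus_reuse"):
                continue
            # window bp span (1-based inclusive) vs gene (0-based half-open)
            if res.chrom == gene.chrom and overlaps(
                    res.start - 1, res.end, gene.start, gene.end):
                labels.add(res.classification)
        for label in sorted(labels):
            rows.append({"gene": gene.gene_id, "classification": label})
    return pd.DataFrame(rows, columns=["gene", "classification"])
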