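"""Composite-likelihood discrimination of modes of repeated adaptation.

Around a candidate gene, allele frequencies in k populations are modeled
as multivariate normal with mean zero (after per-site standardization)
and a covariance that is the neutral, shared-drift coancestry matrix F
plus sweep-induced inflation terms that decay with recombination distance
r from a proposed selected site.  The decay of coancestry *between*
selected populations is what separates the modes:

- independent mutation: within-population inflation only; between-pair
  coancestry never increases above its neutral value;
- migration: one haplotype spreads among selected populations, so pairs
  share the swept background wherever both retained it (prob y(r)^2),
  with an establishment lag when migration is weak;
- standing variation: the shared background predates selection by t_st
  generations, during which recombination (rate r per generation) and
  coalescence on the low-frequency standing background (frequency g)
  erode the sharing: exp(-2 r t_st) / (1 + 4 Ne g r).

Two mixed models restrict the between-pair sharing to a designated
subgroup (same-lineage caves) and treat the remaining selected
population as an independent origin.  Composite likelihoods multiply
per-site densities as if sites were independent; they rank models, they
do not give calibrated uncertainty.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import AlleleFrequencyPanel, GeneModel

logger = logging.getLogger(__name__)

MODELS = ("neutral", "independent", "standing", "migration",
          "mixed_migration", "mixed_standing")

DEFAULT_NE = 100_000
DEFAULT_REC = 1.16e-8  # Morgans per bp
MAX_GENE_SPAN = 400_000  # genes longer than this are skipped

#: live-parameter count per model, used to break exact likelihood ties
#: toward the simpler model
_N_LIVE = {"neutral": 0, "migration": 2, "mixed_migration": 2,
           "independent": 2, "standing": 3, "mixed_standing": 3}


def default_grids(ne: int = DEFAULT_NE) -> dict[str, np.ndarray]:
    """Default parameter grids for the composite-likelihood search."""
    return {
        "s": np.array([1e-4, 1e-3, 1e-2, 1e-1]),
        "t_st": np.array([5.0, 10.0, 25.0, 50.0, 100.0, 500.0, 1000.0]),
        "g": np.array([1.0 / (2 * ne), 1e-3, 1e-2, 1e-1]),
        "m": np.array([1e-5, 1e-4, 1e-3, 1e-2]),
    }


@dataclass
class NeutralCovariance:
    """k x k coancestry of standardized frequencies at thinned neutral sites."""

    populations: list[str]
    F: np.ndarray
    n_sites: int
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if not np.allclose(self.F, self.F.T):
            raise ValueError("F must be symmetric")
        if np.min(np.linalg.eigvalsh(self.F)) < -1e-8:
            raise ValueError("F must be positive semi-definite")


@dataclass
class DmcModelSpec:
    """One convergence model plus the grids of its live parameters."""

    model: str
    selected_pops: tuple[str, ...]
    source_pop: str | None = None  # migration source
    subgroup: tuple[str, ...] = ()  # shared-origin subgroup of mixed models
    grids: dict[str, np.ndarray] = field(default_factory=default_grids)
    ne: int = DEFAULT_NE
    rec_rate: float = DEFAULT_REC
    n_proposed_sites: int = 50

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.ne <= 0 or self.rec_rate <= 0:
            raise ValueError("ne and rec_rate must be > 0")
        for name in self.live_params():
            if len(np.atleast_1d(self.grids[name])) == 0:
                raise ValueError(f"model {self.model}: empty grid for {name}")
        if self.model.startswith("mixed") and len(self.subgroup) < 2:
            raise ValueError("mixed models need a shared subgroup of >= 2 pops")

    def live_params(self) -> tuple[str, ...]:
        return {
            "neutral": (),
            "independent": ("s", "t_st"),
            "standing": ("s", "t_st", "g"),
            "migration": ("s", "m"),
            "mixed_migration": ("s", "m"),
            "mixed_standing": ("s", "t_st", "g"),
        }[self.model]

    def param_combinations(self):
        names = self.live_params()
        if not names:
            yield {}
            return
        for combo in itertools.product(*(np.atleast_1d(self.grids[n]) for n in names)):
            yield dict(zip(names, (float(v) for v in combo)))


def default_model_specs(
    selected_pops: tuple[str, ...],
    source_pop: str | None = None,
    subgroup: tuple[str, ...] = (),
    ne: int = DEFAULT_NE,
    rec_rate: float = DEFAULT_REC,
    grids: dict[str, np.ndarray] | None = None,
) -> list[DmcModelSpec]:
    """The six-model set: neutral, three pure modes, two mixed models."""
    grids = grids or default_grids(ne)
    source = source_pop or selected_pops[0]
    sub = tuple(subgroup) or tuple(selected_pops[:2])
    common = dict(selected_pops=tuple(selected_pops), grids=grids,
                  ne=ne, rec_rate=rec_rate)
    return [
        DmcModelSpec(model="neutral", **common),
        DmcModelSpec(model="independent", **common),
        DmcModelSpec(model="standing", **common),
        DmcModelSpec(model="migration", source_pop=source, **common),
        DmcModelSpec(model="mixed_migration", source_pop=sub[0], subgroup=sub, **common),
        DmcModelSpec(model="mixed_standing", subgroup=sub, **common),
    ]


# ---------------------------------------------------------------------------
# neutral coancestry
# ---------------------------------------------------------------------------

def standardize_freqs(freq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize per site: (p_i - pbar) / sqrt(pbar (1 - pbar)).

    pbar is the unweighted across-population mean.  Returns (X, keep)
    where ``keep`` flags sites with defined frequencies everywhere and
    pbar(1-pbar) > 0; X has shape (k, n_kept).
    """
    freq = np.asarray(freq, dtype=float)
    keep = ~np.isnan(freq).any(axis=0)
    pbar = np.mean(freq, axis=0)
    var = pbar * (1.0 - pbar)
    keep &= var > 0
    X = (freq[:, keep] - pbar[keep]) / np.sqrt(var[keep])
    return X, keep


def estimate_neutral_F(
    panel: AlleleFrequencyPanel,
    intergenic_mask: np.ndarray | None = None,
    thin_bp: int = 50_000,
    epsilon: float = 1e-6,
) -> NeutralCovariance:
    """Neutral coancestry from thinned putatively neutral sites.

    ``intergenic_mask`` flags sites outside genes; thinning keeps the
    first eligible site in each ``thin_bp`` bin per chromosome.  The
    returned F gets ``epsilon`` added to its diagonal.
    """
    eligible = np.ones(panel.n_sites, dtype=bool) if intergenic_mask is None \
        else np.asarray(intergenic_mask, dtype=bool)
    keep_idx = []
    for chrom in dict.fromkeys(panel.chrom):
        on = np.flatnonzero((panel.chrom == chrom) & eligible)
        if on.size == 0:
            continue
        bins = (panel.pos[on] - 1) // thin_bp
        first = np.concatenate([[True], np.diff(bins) > 0])
        keep_idx.append(on[first])
    idx = np.concatenate(keep_idx) if keep_idx else np.array([], dtype=int)
    X, kept = standardize_freqs(panel.freq[:, idx])
    if X.shape[1] < 100:
        raise ValueError(f"only {X.shape[1]} neutral sites after thinning; "
                         "need at least 100")
    F = (X @ X.T) / X.shape[1] + epsilon * np.eye(panel.n_pops)
    return NeutralCovariance(populations=panel.pop_names, F=F,
                             n_sites=int(X.shape[1]), epsilon=epsilon)


# ---------------------------------------------------------------------------
# sweep kernels
# ---------------------------------------------------------------------------

def sweep_retention(r_bp, s: float, ne: int = DEFAULT_NE,
                    rec_rate: float = DEFAULT_REC):
    """Probability a neutral lineage rides the beneficial background.

    y = exp(-r * tau) with r = r_bp * rec_rate Morgans and sweep duration
    tau = log(4 Ne s)/s generations.
    """
    if s <= 0:
        raise ValueError("selection coefficient must be > 0")
    r = np.asarray(r_bp, dtype=float) * rec_rate
    tau = np.log(4.0 * ne * s) / s
    y = np.exp(-r * tau)
    return y if y.ndim else float(y)


def _between_share(model: str, r_morgans, params: dict, ne: int, s: float):
    """Fraction of the y^2 between-pair inflation retained under the model."""
    r = np.asarray(r_morgans, dtype=float)
    if model in ("migration", "mixed_migration"):
        # establishment lag of the migrant allele; negligible once the
        # number of migrant copies 2*Ne*m reaches one per generation
        lag = max(0.0, np.log(1.0 / (2.0 * ne * params["m"]))) / s
        return np.exp(-r * lag)
    if model in ("standing", "mixed_standing"):
        decay = np.exp(-2.0 * r * params["t_st"])
        coal = 1.0 / (1.0 + 4.0 * ne * params["g"] * r)
        return decay * coal
    return np.zeros_like(r)


def model_covariance(
    spec: DmcModelSpec,
    params: dict,
    r_bp: float,
    F: np.ndarray | NeutralCovariance,
    populations: list[str] | None = None,
) -> np.ndarray:
    """Model covariance at recombination distance ``r_bp`` from the site.

    The model is a mixture: with probability y = exp(-r*tau) a selected
    population's standardized frequency is the (unit-variance) state of
    the swept haplotype, otherwise its neutral value.  Hence, with S the
    selected set,

    - C_ii = (1-y) F_ii + y                       for i in S,
    - C_ij = (1-y)^2 F_ij + y^2 * share(r)        for sharing pairs in S,
    - C_ij = (1-y)^2 F_ij                         for non-sharing pairs in S,
    - C_ij = (1-y) F_ij                           for i in S, j not in S,

    where ``share`` is the mode-specific between-population retention of
    the common haplotype (1 for established migration, eroded by
    exp(-2 r t_st)/(1 + 4 Ne g r) for standing variation, 0 for
    independent origins).  This is the second-moment structure of an
    explicit generative mixture, so C is positive semi-definite for every
    parameter value, and C -> F in the no-sweep limit y -> 0.  Between
    selected pairs coancestry never increases under the independent model
    and is maximal under established migration.  The neutral model
    returns F unchanged.
    """
    if isinstance(F, NeutralCovariance):
        populations = F.populations
        F = F.F
    if populations is None:
        raise ValueError("population order required when F is a bare matrix")
    C = np.array(F, dtype=float, copy=True)
    if spec.model == "neutral":
        return C
    for name in spec.live_params():
        grid = np.atleast_1d(spec.grids[name])
        if not np.any(np.isclose(grid, params[name])):
            raise ValueError(f"parameter {name}={params[name]} is off-grid")
    s = params["s"]
    y = sweep_retention(r_bp, s, spec.ne, spec.rec_rate)
    sel = [populations.index(p) for p in spec.selected_pops]
    unsel = [i for i in range(len(populations)) if i not in sel]
    share_pops = spec.subgroup if spec.model.startswith("mixed") else spec.selected_pops
    if spec.model == "independent":
        share_pops = ()
    share_idx = {populations.index(p) for p in share_pops}
    r_m = r_bp * spec.rec_rate
    share = _between_share(spec.model, r_m, params, spec.ne, s)
    for i in sel:
        C[i, i] = (1.0 - y) * F[i, i] + y
        for j in unsel:
            C[i, j] = C[j, i] = (1.0 - y) * F[i, j]
    for a in range(len(sel)):
        for b in range(a + 1, len(sel)):
            i, j = sel[a], sel[b]
            C[i, j] = (1.0 - y) ** 2 * F[i, j]
            if i in share_idx and j in share_idx:
                C[i, j] += y * y * share
            C[j, i] = C[i, j]
    return C


# ---------------------------------------------------------------------------
# composite likelihood
# ---------------------------------------------------------------------------

def _project_vec(X: np.ndarray) -> np.ndarray:
    """Drop the last population coordinate (standardized vectors sum to 0)."""
    return X[..., :-1]


def _project_cov(C: np.ndarray) -> np.ndarray:
    return C[..., :-1, :-1]


def _chol_loglik(X: np.ndarray, C: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    """Gaussian log density of rows of X under stacked covariances C.

    X: (n, d); C: (n, d, d) or (d, d).  Singular covariances are
    regularized by adding ``epsilon`` to the diagonal, with a log record.
    """
    d = X.shape[-1]
    C = np.broadcast_to(C, (X.shape[0], d, d)) if C.ndim == 2 else C
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        logger.info("singular model covariance; epsilon-regularizing")
        L = np.linalg.cholesky(C + epsilon * np.eye(d))
    z = np.linalg.solve(L, X[..., None])[..., 0]
    logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=-2, axis2=-1)), axis=-1)
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + np.sum(z * z, axis=-1))


def composite_loglik(
    window_freqs: np.ndarray,
    positions: np.ndarray,
    proposed_site: float,
    spec: DmcModelSpec,
    params: dict,
    F: NeutralCovariance,
) -> float:
    """Sum over SNPs of the log MVN density under the model covariance.

    Frequencies are standardized per site; the model covariance is
    evaluated at each SNP's distance from the proposed selected site;
    sites are treated as independent (composite likelihood).  One
    population coordinate is dropped before evaluating the density
    because standardized vectors are sum-constrained.
    """
    window_freqs = np.asarray(window_freqs, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("no SNPs in window")
    X, keep = standardize_freqs(window_freqs)
    positions = positions[keep]
    C = np.stack([
        model_covariance(spec, params, abs(pos - proposed_site), F)
        for pos in positions
    ])
    return float(np.sum(_chol_loglik(_project_vec(X.T), _project_cov(C))))


# ---------------------------------------------------------------------------
# per-gene grid search
# ---------------------------------------------------------------------------

@dataclass
class DmcGeneResult:
    """Best convergence model for one candidate gene."""

    gene_id: str
    span: tuple[int, int]  # analysis span incl. flanks, 0-based half-open
    model_logliks: dict[str, float]
    best_model: str
    mcle: dict[str, float]
    best_site: float  # bp position of the best proposed site
    site_class: str = ""
    n_snps: int = 0
    model_mcle: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        best = max(self.model_logliks.values())
        if not np.isclose(self.model_logliks[self.best_model], best):
            raise ValueError("best_model must attain the maximum log-likelihood")


def proposed_sites(span_start: float, span_end: float, n: int = 50) -> np.ndarray:
    """n evenly spaced proposed selected sites across the analysis span."""
    return np.linspace(span_start, span_end, n)


def _binned_distances(dist: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Quantile-bin a distance matrix; returns (bin_index, bin_mean_r_bp)."""
    flat = dist.ravel()
    edges = np.quantile(flat, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(edges)
    idx = np.searchsorted(edges, flat).reshape(dist.shape)
    n_eff = edges.size + 1
    reps = np.array([flat[idx.ravel() == b].mean() if np.any(idx.ravel() == b)
                     else 0.0 for b in range(n_eff)])
    return idx, reps


def fit_gene(
    panel: AlleleFrequencyPanel,
    gene: GeneModel,
    spec_set: list[DmcModelSpec],
    F: NeutralCovariance,
    flank: int = 10_000,
    n_sites: int = 50,
    r_bins: int | None = 48,
) -> DmcGeneResult | None:
    """Grid search over models x parameters x proposed sites for one gene.

    The analysis span is the gene plus ``flank`` bp on each side.  For
    every model the maximum composite log-likelihood over its parameter
    grid and the ``n_sites`` evenly spaced proposed sites is recorded;
    the best model is the overall argmax, with exact ties broken toward
    the model with fewer live parameters.  ``r_bins`` trades likelihood
    precision for speed by evaluating the covariance on quantile-binned
    SNP-site distances; ``None`` uses exact distances.

    Returns None (with a log record) for genes without SNPs in span or
    longer than 400 kbp.
    """
    if gene.length() > MAX_GENE_SPAN:
        logger.warning("gene %s skipped: span %d bp exceeds %d",
                       gene.gene_id, gene.length(), MAX_GENE_SPAN)
        return None
    lo, hi = gene.start - flank, gene.end + flank
    on = (panel.chrom == gene.chrom) & (panel.pos - 1 >= lo) & (panel.pos - 1 < hi)
    idx = np.flatnonzero(on)
    X, keep = standardize_freqs(panel.freq[:, idx])
    pos = (panel.pos[idx] - 1)[keep].astype(float)
    if pos.size == 0:
        logger.warning("gene %s skipped: no usable SNPs in span", gene.gene_id)
        return None
    sites = proposed_sites(lo, hi, n_sites)
    dist = np.abs(pos[None, :] - sites[:, None])  # (n_sites, n_snps)
    Xp = _project_vec(X.T)  # (n_snps, k-1)
    d = Xp.shape[1]
    # per-site-per-bin scatter matrices let each parameter combination be
    # scored with a handful of small inversions instead of one per SNP
    if r_bins is not None:
        bin_idx, bin_rep = _binned_distances(dist, r_bins)
        n_bins = bin_rep.size
        scat = np.zeros((n_sites, n_bins, d, d))
        counts = np.zeros((n_sites, n_bins))
        outer = Xp[:, :, None] * Xp[:, None, :]
        for b in range(n_bins):
            mask = bin_idx == b  # (n_sites, n_snps)
            counts[:, b] = mask.sum(axis=1)
            scat[:, b] = np.einsum("sj,jab->sab", mask.astype(float), outer)

    model_logliks: dict[str, float] = {}
    model_best: dict[str, tuple[float, dict, float]] = {}
    for spec in spec_set:
        best_ll, best_params, best_site = -np.inf, {}, sites[0]
        for params in spec.param_combinations():
            if spec.model == "neutral":
                ll_sites = np.full(n_sites, float(np.sum(
                    _chol_loglik(Xp, _project_cov(F.F)))))
            elif r_bins is not None:
                C = np.stack([
                    _project_cov(model_covariance(spec, params, float(r), F))
                    for r in bin_rep
                ])
                Cinv = np.linalg.inv(C)
                sign, logdet = np.linalg.slogdet(C)
                quad = np.einsum("bij,sbij->sb", Cinv, scat)
                ll_sites = -0.5 * (
                    counts @ (d * np.log(2 * np.pi) + logdet) + quad.sum(axis=1))
            else:
                ll_sites = np.array([
                    float(np.sum(_chol_loglik(Xp, _project_cov(np.stack([
                        model_covariance(spec, params, float(r), F)
                        for r in dist[si]
                    ])))))
                    for si in range(n_sites)
                ])
            si = int(np.argmax(ll_sites))
            if ll_sites[si] > best_ll:
                best_ll, best_params, best_site = float(ll_sites[si]), params, float(sites[si])
        model_logliks[spec.model] = best_ll
        model_best[spec.model] = (best_ll, best_params, best_site)

    best_model = sorted(
        model_logliks,
        key=lambda mdl: (-model_logliks[mdl], _N_LIVE[mdl], MODELS.index(mdl)),
    )[0]
    ll, params, site = model_best[best_model]
    result = DmcGeneResult(
        gene_id=gene.gene_id,
        span=(lo, hi),
        model_logliks=model_logliks,
        best_model=best_model,
        mcle=params,
        best_site=site,
        n_snps=int(pos.size),
        model_mcle={m: dict(v[1]) for m, v in model_best.items()},
    )
    result.site_class = classify_selected_site(site, gene, flank)
    return result


def classify_selected_site(position: float, gene: GeneModel,
                           flank: int = 10_000) -> str:
    """Classify a selected-site position against the gene's annotation.

    Inside the gene span: CDS > UTR5/UTR3 > intron.  Outside, within the
    flanks: upstream10k / downstream10k, oriented by strand.
    """
    pos = float(position)
    if gene.start <= pos < gene.end:
        for s, e in gene.cds:
            if s <= pos < e:
                return "CDS"
        for s, e in gene.utr5:
            if s <= pos < e:
                return "UTR5"
        for s, e in gene.utr3:
            if s <= pos < e:
                return "UTR3"
        return "intron"
    if gene.start - flank <= pos < gene.start:
        return "upstream10k" if gene.strand == "+" else "downstream10k"
    if gene.end <= pos <= gene.end + flank:
        return "downstream10k" if gene.strand == "+" else "upstream10k"
    raise ValueError(f"position {pos} outside span + flanks of {gene.gene_id}")


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


def summarize_mode_assignments(results) -> pd.DataFrame:
    """Counts and whole-percent shares of best-model assignments.

    ``results`` is either an iterable of DmcGeneResult or a mapping
    model -> count.  Percentages are computed on the assigned total and
    rounded to the nearest whole percent, halves away from zero.
    """
    if isinstance(results, dict):
        counts = dict(results)
    else:
        counts = {}
        for r in results:
            counts[r.best_model] = counts.get(r.best_model, 0) + 1
    if not counts:
        raise ValueError("no results to summarize")
    total = sum(counts.values())
    rows = [{"model": m, "count": c,
             "percent": round_half_away(100.0 * c / total)}
            for m, c in counts.items()]
    return pd.DataFrame(rows, columns=["model", "count", "percent"])
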