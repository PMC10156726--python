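"""Core data containers shared across the pipeline.

The panel abstraction is an allele-frequency matrix over populations and
SNP sites.  Each population carries an ecotype (cave or surface) and a
lineage label; every scan in the package is a function of this container.
Coordinates are stored 1-based (VCF/GFF convention) on the panel itself;
interval logic elsewhere converts to 0-based half-open at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

ECOTYPES = ("cave", "surface")


@dataclass(frozen=True)
class Population:
    """A sampled population with its ecotype and lineage membership."""

    name: str
    ecotype: str
    lineage: int

    def __post_init__(self) -> None:
        if self.ecotype not in ECOTYPES:
            raise ValueError(f"ecotype must be one of {ECOTYPES}, got {self.ecotype!r}")


@dataclass
class AlleleFrequencyPanel:
    """Populations x sites matrix of alternate-allele frequencies.

    Attributes
    ----------
    populations:
        Ordered population labels; row order of ``freq`` and ``n``.
    chrom:
        Chromosome name per site (length m).
    pos:
        1-based position per site, strictly increasing within chromosome.
    freq:
        (k, m) float array of alternate-allele frequencies in [0, 1];
        ``nan`` marks missing.
    n:
        (k, m) int array of haploid observation counts backing each
        frequency; wherever ``freq`` is defined, ``n >= 2``.
    """

    populations: list[Population]
    chrom: np.ndarray
    pos: np.ndarray
    freq: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.freq = np.asarray(self.freq, dtype=float)
        self.n = np.asarray(self.n, dtype=np.int64)
        k, m = self.freq.shape
        if len(self.populations) != k:
            raise ValueError("freq row count does not match population count")
        if self.pos.shape != (m,) or self.chrom.shape != (m,):
            raise ValueError("site arrays do not match freq column count")
        if self.n.shape != (k, m):
            raise ValueError("n shape does not match freq shape")
        defined = ~np.isnan(self.freq)
        if np.any((self.freq[defined] < 0) | (self.freq[defined] > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        if np.any(self.n[defined] < 2):
            raise ValueError("defined frequencies require n >= 2")
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_pops(self) -> int:
        return len(self.populations)

    @property
    def n_sites(self) -> int:
        return self.pos.size

    @property
    def pop_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def pop_index(self, name: str) -> int:
        for i, p in enumerate(self.populations):
            if p.name == name:
                return i
        raise KeyError(f"population {name!r} not in panel")

    def copy(self) -> "AlleleFrequencyPanel":
        return AlleleFrequencyPanel(
            populations=list(self.populations),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            freq=self.freq.copy(),
            n=self.n.copy(),
        )

    def take_sites(self, idx: np.ndarray) -> "AlleleFrequencyPanel":
        """Sub-panel restricted to site indices ``idx`` (order preserved)."""
        return AlleleFrequencyPanel(
            populations=list(self.populations),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            freq=self.freq[:, idx],
            n=self.n[:, idx],
        )


@dataclass
class GenotypeMatrix:
    """Per-sample diploid calls, the substrate of the site-filter cascade.

    ``dosage`` holds alternate-allele counts per call: 0, 1, 2, or -1 for
    missing.  ``n_alt_alleles`` records how many distinct ALT alleles the
    source record carried, so the biallelic rule can be applied before any
    frequency is ever formed.
    """

    samples: list[str]
    sample_pop: list[str]  # population label per sample, aligned with samples
    populations: list[Population]
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray  # (n_samples, m) int8
    n_alt_alleles: np.ndarray  # (m,) int

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.n_alt_alleles = np.asarray(self.n_alt_alleles, dtype=np.int64)
        s, m = self.dosage.shape
        if len(self.samples) != s or len(self.sample_pop) != s:
            raise ValueError("sample metadata does not match dosage rows")
        if self.pos.shape != (m,) or self.n_alt_alleles.shape != (m,):
            raise ValueError("site arrays do not match dosage columns")
        known = {p.name for p in self.populations}
        missing = set(self.sample_pop) - known
        if missing:
            raise ValueError(f"samples assigned to unknown populations: {missing}")

    @property
    def n_sites(self) -> int:
        return self.pos.size

    def pop_sample_indices(self, pop: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.sample_pop, dtype=object) == pop)


@dataclass
class GeneModel:
    """A gene with the sub-feature detail the site classifier needs.

    Spans are 0-based half-open.  ``transcript_length`` is the exon length
    sum of the longest transcript (UTR + CDS), ``cds_length`` excludes
    introns and UTRs.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcript_length: int = 0
    cds_length: int = 0
    exon_count: int = 0
    isoform_count: int = 1
    go_terms: list[str] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: empty span")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        for kind in (self.cds, self.utr5, self.utr3):
            for s, e in kind:
                if s < self.start or e > self.end:
                    raise ValueError(
                        f"gene {self.gene_id}: sub-feature [{s},{e}) outside span"
                    )

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def length(self) -> int:
        return self.end - self.start


def overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """Half-open interval overlap."""
    return a_start < b_end and b_start < a_end
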