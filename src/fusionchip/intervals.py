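"""Genomic interval arithmetic and strand-aware peak annotation.

Coordinates are 0-based, half-open throughout.  A ChIP-seq peak carries a
*mode* (position of maximal signal); peak boundaries are conventionally
redefined to a fixed halfwidth around the mode before any downstream
analysis.  Peaks are annotated against gene models with a fixed category
priority: TSS +/-1 kb, then the -1..-5 kb and -5..-10 kb upstream windows,
then coding exon, UTR, intron, and finally intergenic.  "Intergenic" means
outside every gene territory, where a territory runs from 10 kb upstream of
the TSS (in transcription direction) to the 3' end of the transcript.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "AnnotationCategory",
    "AnnotationConfig",
    "Annotation",
    "PeakAnnotator",
    "overlaps",
    "redefine_boundaries",
    "assign_category",
    "nearest_tss",
    "sample_random_intervals",
    "sample_matched_random_peaks",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome; strand in {+,-,.}."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff a and b share at least one base (half-open convention)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak: an unstranded interval plus the signal mode."""

    name: str
    interval: GenomicInterval
    mode: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.mode < self.interval.end):
            raise ValueError(
                f"peak {self.name}: mode {self.mode} outside "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.score < 0:
            raise ValueError(f"peak {self.name}: negative score")

    @property
    def center(self) -> int:
        return (self.interval.start + self.interval.end) // 2


def redefine_boundaries(
    peak: Peak, halfwidth: int = 150, chrom_length: int | None = None
) -> Peak:
    """Return the peak with boundaries [mode - halfwidth, mode + halfwidth).

    The interval is clipped to chromosome bounds when ``chrom_length`` is
    given.  The mode must lie on the chromosome.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    if chrom_length is not None and not (0 <= peak.mode < chrom_length):
        raise ValueError(
            f"peak {peak.name}: mode {peak.mode} outside chromosome "
            f"of length {chrom_length}"
        )
    start = max(0, peak.mode - halfwidth)
    end = peak.mode + halfwidth
    if chrom_length is not None:
        end = min(end, chrom_length)
    iv = GenomicInterval(peak.interval.chrom, start, end)
    return replace(peak, interval=iv)


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene model anchored at the TSS.

    ``exons`` are sorted, disjoint (start, end) pairs within the transcript
    span.  The CDS bounds delimit coding sequence; exon parts outside the
    CDS are UTR.  A gene with ``cds_start == cds_end`` is non-coding and its
    exons count as exonic (not UTR) for annotation.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid span")
        prev = self.start
        for s, e in self.exons:
            if s < prev or e <= s or e > self.end:
                raise ValueError(
                    f"gene {self.gene_id}: exons not sorted/disjoint/in-span"
                )
            prev = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, in genomic order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return tuple(out)

    def introns_by_rank(self) -> tuple[tuple[int, int], ...]:
        """Introns ordered 1..n in transcription direction."""
        iv = self.introns
        return iv if self.strand == "+" else tuple(reversed(iv))

    def _cds(self) -> tuple[int, int] | None:
        if self.cds_start is None or self.cds_end is None:
            return None
        if self.cds_start >= self.cds_end:
            return None
        return (self.cds_start, self.cds_end)

    @property
    def coding_exons(self) -> tuple[tuple[int, int], ...]:
        """Exon segments inside the CDS; whole exons when non-coding."""
        cds = self._cds()
        if cds is None:
            return self.exons
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, cds[0]), min(e, cds[1])
            if s2 < e2:
                out.append((s2, e2))
        return tuple(out)

    @property
    def utrs(self) -> tuple[tuple[int, int], ...]:
        """Exon segments outside the CDS (both 5' and 3' UTR)."""
        cds = self._cds()
        if cds is None:
            return ()
        out = []
        for s, e in self.exons:
            if s < cds[0]:
                out.append((s, min(e, cds[0])))
            if e > cds[1]:
                out.append((max(s, cds[1]), e))
        return tuple(out)

    def rel_window(self, r0: int, r1: int) -> tuple[int, int]:
        """Genomic interval of transcription-direction offsets [r0, r1).

        Offset 0 is the TSS base; negative offsets are upstream.
        """
        if self.strand == "+":
            return (self.tss + r0, self.tss + r1)
        return (self.tss - r1 + 1, self.tss - r0 + 1)

    def territory(self, upstream: int = 10_000) -> tuple[int, int]:
        """Span from ``upstream`` bp upstream of the TSS to the 3' end."""
        if self.strand == "+":
            return (self.tss - upstream, self.end)
        return (self.start, self.tss + upstream + 1)


class AnnotationCategory(enum.IntEnum):
    """Peak annotation categories in priority order (lowest wins)."""

    TSS_1KB = 0
    UP_1_5KB = 1
    UP_5_10KB = 2
    EXON = 3
    UTR = 4
    INTRON = 5
    INTERGENIC = 6

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class AnnotationConfig:
    tss_window: int = 1000
    upstream_near: int = 5000
    upstream_far: int = 10_000

    def __post_init__(self) -> None:
        if not (0 < self.tss_window < self.upstream_near < self.upstream_far):
            raise ValueError("require 0 < tss_window < upstream_near < upstream_far")


@dataclass(frozen=True)
class Annotation:
    category: AnnotationCategory
    intron_index: int | None = None
    gene_id: str | None = None


def _gene_regions(
    gene: GeneModel, cfg: AnnotationConfig
) -> dict[AnnotationCategory, tuple[tuple[int, int], ...]]:
    w, near, far = cfg.tss_window, cfg.upstream_near, cfg.upstream_far
    return {
        AnnotationCategory.TSS_1KB: (gene.rel_window(-w, w),),
        AnnotationCategory.UP_1_5KB: (gene.rel_window(-near, -w),),
        AnnotationCategory.UP_5_10KB: (gene.rel_window(-far, -near),),
        AnnotationCategory.EXON: gene.coding_exons,
        AnnotationCategory.UTR: gene.utrs,
        AnnotationCategory.INTRON: gene.introns,
    }


def _seg_overlaps(start: int, end: int, seg: tuple[int, int]) -> bool:
    return start < seg[1] and seg[0] < end


class PeakAnnotator:
    """Annotates peaks against a set of gene models with category priority.

    Candidate genes per peak are found through an interval tree over gene
    territories (10 kb upstream of TSS to transcript 3' end); a peak
    overlapping no territory is intergenic by definition.
    """

    def __init__(
        self, genes: Sequence[GeneModel], cfg: AnnotationConfig | None = None
    ):
        self.cfg = cfg or AnnotationConfig()
        self.genes = list(genes)
        self._regions = {g.gene_id: _gene_regions(g, self.cfg) for g in self.genes}
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            t0, t1 = g.territory(self.cfg.upstream_far)
            # category regions can poke past the territory (a TSS window
            # reaches 1 kb downstream of the TSS even for a shorter gene),
            # and they take precedence over the intergenic fallthrough
            for segs in self._regions[g.gene_id].values():
                for s, e in segs:
                    t0, t1 = min(t0, s), max(t1, e)
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            tree.addi(max(0, t0), t1, g)

    def annotate(self, peak: Peak) -> Annotation:
        iv = peak.interval
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return Annotation(AnnotationCategory.INTERGENIC)
        candidates = [hit.data for hit in tree.overlap(iv.start, iv.end)]
        if not candidates:
            return Annotation(AnnotationCategory.INTERGENIC)
        for cat in AnnotationCategory:
            if cat is AnnotationCategory.INTERGENIC:
                break
            matching = [
                g
                for g in candidates
                if any(
                    _seg_overlaps(iv.start, iv.end, seg)
                    for seg in self._regions[g.gene_id][cat]
                )
            ]
            if not matching:
                continue
            # closest-TSS transcript resolves which gene reports the hit;
            # ties break on gene_id for determinism
            gene = min(matching, key=lambda g: (abs(g.tss - peak.mode), g.gene_id))
            idx = None
            if cat is AnnotationCategory.INTRON:
                for k, seg in enumerate(gene.introns_by_rank(), start=1):
                    if _seg_overlaps(iv.start, iv.end, seg):
                        idx = k
                        break
            return Annotation(cat, intron_index=idx, gene_id=gene.gene_id)
        return Annotation(AnnotationCategory.INTERGENIC)

    def annotate_peaks(self, peaks: Iterable[Peak]):
        """Annotate many peaks; returns a pandas DataFrame."""
        import pandas as pd

        rows = []
        for p in peaks:
            a = self.annotate(p)
            rows.append(
                (p.name, a.category.name, a.intron_index, a.gene_id)
            )
        return pd.DataFrame(
            rows, columns=["name", "category", "intron_index", "gene_id"]
        )


def assign_category(
    peak: Peak, genes: Sequence[GeneModel], cfg: AnnotationConfig | None = None
) -> Annotation:
    """One-shot annotation of a single peak (see :class:`PeakAnnotator`)."""
    return PeakAnnotator(genes, cfg).annotate(peak)


_UNASSIGNED = None


def nearest_tss(peak: Peak, genes: Sequence[GeneModel]) -> str | None:
    """Gene with the TSS nearest the peak mode on the same chromosome.

    Ties break to the lexicographically smallest gene_id.  Returns None
    when the chromosome carries no gene (cross-chromosome assignment is
    disallowed).
    """
    best: tuple[int, str] | None = None
    for g in genes:
        if g.chrom != peak.interval.chrom:
            continue
        key = (abs(g.tss - peak.mode), g.gene_id)
        if best is None or key < best:
            best = key
    return best[1] if best is not None else _UNASSIGNED


def _as_rng(rng: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_random_intervals(
    genome: Mapping[str, int],
    n: int,
    width: int,
    rng: int | np.random.Generator | None = None,
) -> list[GenomicInterval]:
    """Sample n uniform intervals of fixed width, chromosomes length-weighted.

    Start positions are uniform over valid starts; a chromosome's weight is
    its number of valid starts.  Deterministic given a seed.
    """
    if n <= 0:
        return []
    chroms = [c for c, L in genome.items() if L >= width]
    if not chroms:
        raise ValueError(f"no chromosome can hold width {width}")
    weights = np.array([genome[c] - width + 1 for c in chroms], dtype=float)
    gen = _as_rng(rng)
    picks = gen.choice(len(chroms), size=n, p=weights / weights.sum())
    out = []
    for i in picks:
        c = chroms[i]
        s = int(gen.integers(0, genome[c] - width + 1))
        out.append(GenomicInterval(c, s, s + width))
    return out


def sample_matched_random_peaks(
    genome: Mapping[str, int],
    peaks: Sequence[Peak],
    rng: int | np.random.Generator | None = None,
) -> list[Peak]:
    """Random peaks width-matched one-to-one to an observed peak set.

    Each random peak keeps its template's width; the mode is placed at the
    template's mode offset within the interval.
    """
    gen = _as_rng(rng)
    out = []
    for k, p in enumerate(peaks):
        w = p.interval.width
        iv = sample_random_intervals(genome, 1, w, gen)[0]
        mode = iv.start + (p.mode - p.interval.start)
        out.append(Peak(f"rand_{k}", iv, mode))
    return out
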