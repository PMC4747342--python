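"""Cistrome-level summaries: annotation enrichment versus random peaks,
dual-motif co-occurrence, spatial motif profiles, and motif-conditioned
peak-set overlap tests.

These are the descriptive statistics used to characterize a transcription
factor's binding-site set: where peaks fall relative to genes compared with
a length-matched random background, how often two motifs co-occur within
peaks, whether motif positions concentrate at peak centers (a hallmark of
direct binding), and whether a second motif is enriched in the subset of
another factor's peaks that the studied factor also binds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import (
    AnnotationCategory,
    AnnotationConfig,
    GeneModel,
    GenomicInterval,
    Peak,
    PeakAnnotator,
    sample_matched_random_peaks,
    sample_random_intervals,
)
from .motifs import PWM, MotifHit, peaks_with_hits, scan_peaks
from .stats import ContingencyTable2x2

__all__ = [
    "CategoryEnrichment",
    "AnnotationEnrichmentResult",
    "CooccurrencePartition",
    "SpatialProfile",
    "annotation_enrichment",
    "motif_cooccurrence",
    "spatial_profile",
    "motif_conditioned_overlap_test",
]


@dataclass(frozen=True)
class CategoryEnrichment:
    category: str
    observed_count: int
    random_mean_count: float

    @property
    def ratio(self) -> float:
        """Observed/random fold ratio; NaN when the random mean is zero."""
        if self.random_mean_count == 0:
            return float("nan")
        return self.observed_count / self.random_mean_count


@dataclass
class AnnotationEnrichmentResult:
    categories: list[CategoryEnrichment]
    intron_breakdown: pd.DataFrame  # columns: intron_index, observed, random_mean
    n_peaks: int
    n_replicates: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "category": ce.category,
                    "observed": ce.observed_count,
                    "random_mean": ce.random_mean_count,
                    "ratio": ce.ratio,
                }
                for ce in self.categories
            ]
        )


def _category_counts(ann: pd.DataFrame) -> pd.Series:
    cats = [c.name for c in AnnotationCategory]
    return ann["category"].value_counts().reindex(cats, fill_value=0)


def annotation_enrichment(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    genome_sizes: Mapping[str, int],
    cfg: AnnotationConfig | None = None,
    n_replicates: int = 10,
    rng: int | np.random.Generator | None = None,
) -> AnnotationEnrichmentResult:
    """Fold enrichment of peak annotation categories versus random peaks.

    ``n_replicates`` random peak sets, each size- and width-matched to the
    observed set, form the background; the per-category ratio is observed
    count over mean random count.  An intron-rank breakdown (first intron,
    second intron, ...) is reported alongside.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    annotator = PeakAnnotator(genes, cfg)
    obs = annotator.annotate_peaks(peaks)
    obs_counts = _category_counts(obs)
    obs_introns = (
        obs.loc[obs["category"] == "INTRON", "intron_index"]
        .value_counts()
        .sort_index()
    )

    rand_counts = []
    rand_introns: list[pd.Series] = []
    for _ in range(n_replicates):
        rpeaks = sample_matched_random_peaks(genome_sizes, peaks, gen)
        rann = annotator.annotate_peaks(rpeaks)
        rand_counts.append(_category_counts(rann))
        rand_introns.append(
            rann.loc[rann["category"] == "INTRON", "intron_index"].value_counts()
        )
    rand_mean = pd.concat(rand_counts, axis=1).mean(axis=1)

    cats = [
        CategoryEnrichment(cat, int(obs_counts[cat]), float(rand_mean[cat]))
        for cat in obs_counts.index
    ]
    all_idx = sorted(
        set(obs_introns.index)
        | {i for s in rand_introns for i in s.index}
    )
    rim = (
        pd.concat(rand_introns, axis=1).reindex(all_idx).fillna(0).mean(axis=1)
        if rand_introns and all_idx
        else pd.Series(dtype=float)
    )
    intron_df = pd.DataFrame(
        {
            "intron_index": all_idx,
            "observed": [int(obs_introns.get(i, 0)) for i in all_idx],
            "random_mean": [float(rim.get(i, 0.0)) for i in all_idx],
        }
    )
    return AnnotationEnrichmentResult(
        categories=cats,
        intron_breakdown=intron_df,
        n_peaks=len(peaks),
        n_replicates=n_replicates,
    )


@dataclass(frozen=True)
class CooccurrencePartition:
    """Partition of a peak set by presence/absence of two motifs."""

    n_both: int
    n_first_only: int
    n_second_only: int
    n_neither: int

    @property
    def total(self) -> int:
        return self.n_both + self.n_first_only + self.n_second_only + self.n_neither

    @property
    def frac_any(self) -> float:
        """Fraction of peaks containing either motif."""
        return (self.total - self.n_neither) / self.total if self.total else 0.0

    @property
    def frac_second_given_first(self) -> float:
        """P(second motif | first motif) over peaks."""
        denom = self.n_both + self.n_first_only
        return self.n_both / denom if denom else float("nan")


def motif_cooccurrence(
    peaks: Sequence[Peak],
    hits_first: Iterable[MotifHit],
    hits_second: Iterable[MotifHit],
) -> CooccurrencePartition:
    """Exact presence/absence partition of peaks by two motif hit lists.

    Multiplicity is ignored: a peak either contains a motif or it does not.
    """
    names = {p.name for p in peaks}
    set1 = peaks_with_hits(hits_first)
    set2 = peaks_with_hits(hits_second)
    unknown = (set1 | set2) - names
    if unknown:
        raise ValueError(f"hits reference unknown peaks: {sorted(unknown)[:5]}")
    n_both = len(set1 & set2)
    return CooccurrencePartition(
        n_both=n_both,
        n_first_only=len(set1) - n_both,
        n_second_only=len(set2) - n_both,
        n_neither=len(names) - len(set1 | set2),
    )


@dataclass
class SpatialProfile:
    """Per-bin density of motif-hit starts relative to peak centers.

    ``observed_density`` is pooled hit counts per bin divided by the number
    of peaks; ``null_density`` is built identically from random fixed-width
    regions and is expected to be flat.
    """

    bin_edges: np.ndarray
    observed_density: np.ndarray
    null_density: np.ndarray
    n_peaks: int
    n_null: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "observed_density": self.observed_density,
                "null_density": self.null_density,
            }
        )


def spatial_profile(
    peaks: Sequence[Peak],
    pwm: PWM,
    genome: Mapping[str, str],
    genome_sizes: Mapping[str, int] | None = None,
    null_n: int = 1000,
    null_width: int = 300,
    bin_width: int = 10,
    halfwidth: int = 150,
    p_threshold: float = 1e-4,
    rng: int | np.random.Generator | None = None,
    hits: Sequence[MotifHit] | None = None,
) -> SpatialProfile:
    """Motif-position profile around peak centers with a random-region null.

    ``peaks`` should be pre-filtered to those of interest (typically peaks
    containing the motif, or both motifs under study).  Pass ``hits`` to
    reuse an existing scan of the same peaks.
    """
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    edges = np.arange(-halfwidth, halfwidth + bin_width, bin_width)
    if len(peaks) == 0:
        z = np.zeros(len(edges) - 1)
        return SpatialProfile(edges, z, z.copy(), 0, 0)
    if hits is None:
        hits = scan_peaks(peaks, genome, pwm, p_threshold=p_threshold)
    obs_offsets = np.array([h.offset for h in hits], dtype=float)
    obs_counts, _ = np.histogram(obs_offsets, bins=edges)

    if genome_sizes is None:
        genome_sizes = {c: len(s) for c, s in genome.items()}
    null_ivs = sample_random_intervals(genome_sizes, null_n, null_width, gen)
    null_peaks = [
        Peak(f"null_{i}", iv, iv.start + null_width // 2)
        for i, iv in enumerate(null_ivs)
    ]
    null_hits = scan_peaks(null_peaks, genome, pwm, p_threshold=p_threshold)
    null_offsets = np.array([h.offset for h in null_hits], dtype=float)
    null_counts, _ = np.histogram(null_offsets, bins=edges)

    return SpatialProfile(
        bin_edges=edges,
        observed_density=obs_counts / len(peaks),
        null_density=null_counts / max(null_n, 1),
        n_peaks=len(peaks),
        n_null=null_n,
    )


def _build_tree(peaks: Sequence[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end
        )
    return trees


def motif_conditioned_overlap_test(
    peaks_a_with_motif: Sequence[Peak],
    peaks_b: Sequence[Peak],
    motif2_peak_names: set[str] | Iterable[MotifHit],
) -> ContingencyTable2x2:
    """2x2 association of (overlaps peak set B) x (contains second motif).

    ``peaks_a_with_motif`` must already be filtered for the first motif's
    presence.  Overlap means >= 1 shared bp with any peak in ``peaks_b``.
    Returns the table with odds ratio and two-sided Fisher exact p.
    """
    if len(peaks_a_with_motif) == 0:
        raise ValueError("peaks_a_with_motif is empty")
    if not isinstance(motif2_peak_names, set):
        motif2_peak_names = peaks_with_hits(motif2_peak_names)
    trees = _build_tree(peaks_b)
    a = b = c = d = 0
    for p in peaks_a_with_motif:
        tree = trees.get(p.interval.chrom)
        ov = bool(tree is not None and tree.overlap(p.interval.start, p.interval.end))
        has2 = p.name in motif2_peak_names
        if ov and has2:
            a += 1
        elif ov:
            b += 1
        elif has2:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)
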