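"""Synthetic study generator with planted ground truth.

Emulates the structure of a dual-DNA-binding-domain fusion-factor study:
a small multi-chromosome genome with strand-aware gene models; a peak set
with controllable annotation-category bias; two motifs (a paired-domain
PAX8-like motif and a DR1 PPARG-like motif) planted into peak sequences at
controllable rates and offsets; four pairwise differential-expression
comparisons with planted gene-set-level directional effects (the
vehicle-control comparison is pure null); and a two-species homolog map
with controllable binding-overlap fractions.

Every draw comes from one seeded integer-state generator, so outputs are
byte-identical across runs with the same configuration.  Truth tables
record every planted feature so each pipeline stage can be checked against
its expected output exactly or in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .de import HomologMap
from .enrich import GeneSet
from .intervals import (
    AnnotationCategory,
    AnnotationConfig,
    GeneModel,
    GenomicInterval,
    Peak,
)
from .motifs import ALPHABET, PWM, encode

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "default_pwms",
    "simulate_genome_and_genes",
    "category_position_masks",
    "eligible_peak_starts",
    "expected_random_category_shares",
    "simulate_peaks_and_motifs",
    "simulate_gene_sets",
    "simulate_de_tables",
    "simulate_homolog_binding",
    "simulate_study",
    "codes_to_seq",
]

COMPARISONS = ("ppfp_vs_ev", "ppfp_pio_vs_ev_pio", "ppfp_pio_vs_ppfp", "ev_pio_vs_ev")

# gene-set-level effects emulating the study design: the fusion factor
# perturbs sets with and without ligand, the ligand reverses one set
# (set0000, the oxidative-stress-like set), and the vehicle comparison
# ("ev_pio_vs_ev") carries no signal at all.
DEFAULT_EFFECTS: dict[str, tuple[tuple[str, str], ...]] = {
    "ppfp_vs_ev": (("set0000", "induced"), ("set0001", "induced"), ("set0002", "repressed")),
    "ppfp_pio_vs_ev_pio": (("set0000", "induced"), ("set0001", "induced"), ("set0002", "repressed")),
    "ppfp_pio_vs_ppfp": (("set0000", "repressed"), ("set0003", "induced")),
    "ev_pio_vs_ev": (),
}


@dataclass
class SimulationConfig:
    """Defaults define the study conditions; see the methods note."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 2_400_000,
            "chr2": 1_800_000,
            "chr3": 1_200_000,
            "chr4": 600_000,
        }
    )
    base_freqs: tuple[float, float, float, float] = (0.29, 0.21, 0.21, 0.29)
    # gene models
    n_genes: int = 300
    mean_introns: float = 3.0
    exon_len_range: tuple[int, int] = (80, 400)
    intron_len_range: tuple[int, int] = (500, 3000)
    cds_inset_range: tuple[int, int] = (80, 250)
    intergene_gap_range: tuple[int, int] = (1000, 8000)
    # peaks
    n_peaks: int = 2000
    peak_halfwidth: int = 150
    category_weights: dict[str, float] = field(
        default_factory=lambda: {
            "TSS_1KB": 0.25,
            "UP_1_5KB": 0.06,
            "UP_5_10KB": 0.04,
            "EXON": 0.04,
            "UTR": 0.02,
            "INTRON": 0.19,
            "INTERGENIC": 0.40,
        }
    )
    # motif planting: peak classes both / first(PAX8) only / second(PPARG)
    # only, chosen so 65% of peaks contain a motif and half of the
    # PAX8-motif peaks also contain a PPARG motif
    rate_both: float = 0.20
    rate_first_only: float = 0.20
    rate_second_only: float = 0.25
    offset_mode: str = "centered"  # or "uniform"
    offset_sd: float = 20.0
    plant_mode: str = "pwm"  # or "consensus"
    # gene sets
    n_sets: int = 500
    set_size_range: tuple[int, int] = (5, 60)
    # differential expression
    de_effect_z: float = 3.5
    de_lfc_scale: float = 0.5
    # homolog-mapped binding overlap
    n_homologs_b1: int = 1500
    n_homologs_b2: int = 1500
    frac_bound_b1: float = 0.34
    frac_bound_b2: float = 0.25
    frac_unmapped_b: float = 0.10

    def __post_init__(self) -> None:
        w = self.category_weights
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("category weights must sum to 1")
        rates = (self.rate_both, self.rate_first_only, self.rate_second_only)
        if any(not 0 <= r <= 1 for r in rates) or sum(rates) > 1:
            raise ValueError("motif plant rates must be probabilities summing to <= 1")


def default_pwms() -> tuple[PWM, PWM]:
    """Stand-in probability matrices for the two motifs.

    Sharp, information-rich columns (dominant base probability 0.98) model
    a paired-domain PAX8-like site (12 bp) and a DR1-type nuclear-receptor
    PPARG-like site (13 bp).  Real matrices can be supplied in MEME minimal
    format instead.
    """

    def from_consensus(name: str, consensus: str, dominant: float = 0.98) -> PWM:
        w = len(consensus)
        probs = np.full((w, 4), (1 - dominant) / 3)
        for i, b in enumerate(consensus):
            probs[i, ALPHABET.index(b)] = dominant
        return PWM(name, probs)

    pax8 = from_consensus("PAX8", "GTCATGCTTGAC")
    pparg = from_consensus("PPARG", "AGGTCAAAGGTCA")
    return pax8, pparg


def codes_to_seq(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def _as_rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def simulate_genome_and_genes(
    cfg: SimulationConfig, rng=None
) -> tuple[dict[str, np.ndarray], list[GeneModel]]:
    """I.i.d. background genome plus non-overlapping strand-aware gene models.

    Returns the genome as mutable uint8 code arrays (A=0..T=3) so motif
    instances can be written in later, and the gene models.  Raises when
    the requested gene count cannot be placed without overlap.
    """
    gen = _as_rng(rng if rng is not None else cfg.seed)
    genome = {
        c: gen.choice(4, size=L, p=np.asarray(cfg.base_freqs)).astype(np.uint8)
        for c, L in cfg.chrom_lengths.items()
    }
    chroms = list(cfg.chrom_lengths)
    cursors = {c: 2000 for c in chroms}
    genes: list[GeneModel] = []
    ci = 0
    tries = 0
    while len(genes) < cfg.n_genes:
        if tries > cfg.n_genes * len(chroms) * 4:
            raise ValueError(
                "cannot place genes without overlap; reduce n_genes or "
                "enlarge chrom_lengths"
            )
        tries += 1
        c = chroms[ci % len(chroms)]
        ci += 1
        n_introns = gen.poisson(cfg.mean_introns)
        exon_lens = gen.integers(*cfg.exon_len_range, size=n_introns + 1)
        intron_lens = gen.integers(*cfg.intron_len_range, size=n_introns)
        gap = int(gen.integers(*cfg.intergene_gap_range))
        start = cursors[c] + gap
        pos = start
        exons = []
        for k, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if k < n_introns:
                pos += int(intron_lens[k])
        end = pos
        if end + 2000 > cfg.chrom_lengths[c]:
            continue  # chromosome full; try the next one
        inset5 = int(gen.integers(*cfg.cds_inset_range))
        inset3 = int(gen.integers(*cfg.cds_inset_range))
        total_exonic = int(exon_lens.sum())
        inset5 = min(inset5, max(total_exonic // 4, 1))
        inset3 = min(inset3, max(total_exonic // 4, 1))
        cds_start = _exonic_to_genomic(exons, inset5)
        cds_end = _exonic_to_genomic(exons, total_exonic - inset3)
        strand = "+" if gen.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"gene{len(genes):04d}",
                chrom=c,
                strand=strand,
                start=start,
                end=end,
                exons=tuple(exons),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
        cursors[c] = end
    return genome, genes


def _exonic_to_genomic(exons: Sequence[tuple[int, int]], offset: int) -> int:
    """Genomic coordinate of the given cumulative exonic offset."""
    left = offset
    for s, e in exons:
        if left < e - s:
            return s + left
        left -= e - s
    return exons[-1][1]


def category_position_masks(
    genes: Sequence[GeneModel],
    chrom_lengths: Mapping[str, int],
    cfg: AnnotationConfig | None = None,
) -> dict[str, np.ndarray]:
    """Per-position annotation category codes (priority-resolved).

    Position code = the highest-priority category of any region covering
    that base; intergenic elsewhere.  A peak's annotation category equals
    the minimum code over the bases it covers.
    """
    acfg = cfg or AnnotationConfig()
    masks = {
        c: np.full(L, AnnotationCategory.INTERGENIC.value, dtype=np.uint8)
        for c, L in chrom_lengths.items()
    }
    # paint lowest priority first so higher priority overwrites
    order = [
        AnnotationCategory.INTRON,
        AnnotationCategory.UTR,
        AnnotationCategory.EXON,
        AnnotationCategory.UP_5_10KB,
        AnnotationCategory.UP_1_5KB,
        AnnotationCategory.TSS_1KB,
    ]
    from .intervals import _gene_regions

    for cat in order:
        for g in genes:
            m = masks[g.chrom]
            for s, e in _gene_regions(g, acfg)[cat]:
                s, e = max(s, 0), min(e, len(m))
                if s < e:
                    m[s:e] = cat.value
    return masks


def _windowed_min(codes: np.ndarray, width: int) -> np.ndarray:
    n = len(codes) - width + 1
    out = codes[:n].copy()
    for k in range(1, width):
        np.minimum(out, codes[k : k + n], out=out)
    return out


def eligible_peak_starts(
    masks: Mapping[str, np.ndarray], width: int
) -> dict[int, list[tuple[str, np.ndarray]]]:
    """Start positions where a width-bp peak annotates as each category."""
    out: dict[int, list[tuple[str, np.ndarray]]] = {c.value: [] for c in AnnotationCategory}
    for chrom, codes in masks.items():
        wmin = _windowed_min(codes, width)
        for cat in AnnotationCategory:
            starts = np.nonzero(wmin == cat.value)[0]
            if len(starts):
                out[cat.value].append((chrom, starts))
    return out


def expected_random_category_shares(
    masks: Mapping[str, np.ndarray], width: int
) -> dict[str, float]:
    """Exact category distribution of a uniform random width-bp interval.

    This is the closed-form expectation against which planted annotation
    bias can be compared: share(c) = (number of start positions whose
    interval annotates c) / (total start positions), chromosomes pooled.
    """
    counts = {c.name: 0 for c in AnnotationCategory}
    total = 0
    for chrom, codes in masks.items():
        wmin = _windowed_min(codes, width)
        total += len(wmin)
        vals, cnts = np.unique(wmin, return_counts=True)
        for v, n in zip(vals, cnts):
            counts[AnnotationCategory(v).name] += int(n)
    return {k: v / total for k, v in counts.items()}


def _sample_site(pwm: PWM, mode: str, gen: np.random.Generator) -> np.ndarray:
    if mode == "consensus":
        return encode(pwm.consensus)
    cols = [gen.choice(4, p=pwm.probs[i]) for i in range(pwm.width)]
    return np.array(cols, dtype=np.uint8)


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1].astype(np.uint8)


def simulate_peaks_and_motifs(
    cfg: SimulationConfig,
    genome: dict[str, np.ndarray],
    genes: Sequence[GeneModel],
    pwm_first: PWM | None = None,
    pwm_second: PWM | None = None,
    rng=None,
) -> tuple[list[Peak], pd.DataFrame]:
    """Place peaks per category weights and write motif instances into them.

    Peaks are non-overlapping, width 2*halfwidth, mode at center.  Each
    peak's motif class (both / first only / second only / neither) is drawn
    from the configured rates; planted sites are sampled from the PWM (or
    its consensus), written into the genome on a random strand at an offset
    from the peak center that is Gaussian (sd ``offset_sd``) or uniform.

    Returns the peaks and a truth table with one row per peak carrying the
    intended annotation category and one row per planted site.
    """
    gen = _as_rng(rng if rng is not None else cfg.seed + 1)
    if pwm_first is None or pwm_second is None:
        pax8, pparg = default_pwms()
        pwm_first = pwm_first or pax8
        pwm_second = pwm_second or pparg
    width = 2 * cfg.peak_halfwidth
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    masks = category_position_masks(genes, chrom_lengths)
    pools = eligible_peak_starts(masks, width)
    cats = list(cfg.category_weights)
    weights = np.array([cfg.category_weights[c] for c in cats])
    for c in cats:
        if cfg.category_weights[c] > 0 and not pools[AnnotationCategory[c].value]:
            raise ValueError(f"category {c} has zero genomic capacity at width {width}")

    import bisect

    occ_starts: dict[str, list[int]] = {c: [] for c in genome}
    occ_ends: dict[str, list[int]] = {c: [] for c in genome}

    def free(chrom: str, s: int, e: int) -> bool:
        ends = occ_ends[chrom]
        i = bisect.bisect_right(ends, s)
        return i >= len(ends) or occ_starts[chrom][i] >= e

    def occupy(chrom: str, s: int, e: int) -> None:
        i = bisect.bisect_left(occ_starts[chrom], s)
        occ_starts[chrom].insert(i, s)
        occ_ends[chrom].insert(i, e)

    peaks: list[Peak] = []
    truth_rows = []
    cat_draws = gen.choice(len(cats), size=cfg.n_peaks, p=weights)
    for i in range(cfg.n_peaks):
        cat = cats[int(cat_draws[i])]
        pool = pools[AnnotationCategory[cat].value]
        sizes = np.array([len(starts) for _, starts in pool], dtype=float)
        placed = False
        for _ in range(200):
            j = int(gen.choice(len(pool), p=sizes / sizes.sum()))
            chrom, starts = pool[j]
            s = int(starts[int(gen.integers(0, len(starts)))])
            if free(chrom, s, s + width):
                placed = True
                break
        if not placed:
            # rejection saturated: sample uniformly from the remaining
            # free starts of this category
            remaining = [
                (chrom, starts[np.fromiter(
                    (free(chrom, int(x), int(x) + width) for x in starts),
                    bool, len(starts),
                )])
                for chrom, starts in pool
            ]
            counts = np.array([len(st) for _, st in remaining], dtype=float)
            if counts.sum() == 0:
                raise ValueError(
                    f"cannot place peak {i} in category {cat} without "
                    "overlap; reduce n_peaks or category weight"
                )
            j = int(gen.choice(len(remaining), p=counts / counts.sum()))
            chrom, starts = remaining[j]
            s = int(starts[int(gen.integers(0, len(starts)))])
        occupy(chrom, s, s + width)
        name = f"peak{i:04d}"
        mode = s + cfg.peak_halfwidth
        peaks.append(Peak(name, GenomicInterval(chrom, s, s + width), mode))

        u = gen.random()
        plant_first = u < cfg.rate_both + cfg.rate_first_only
        plant_second = u < cfg.rate_both or (
            cfg.rate_both + cfg.rate_first_only
            <= u
            < cfg.rate_both + cfg.rate_first_only + cfg.rate_second_only
        )
        planted: list[tuple[str, int, int]] = []  # (motif, off, width)
        for motif_name, pwm, do in (
            (pwm_first.name, pwm_first, plant_first),
            (pwm_second.name, pwm_second, plant_second),
        ):
            if not do:
                continue
            off = _draw_offset(cfg, pwm.width, planted, gen)
            site = _sample_site(pwm, cfg.plant_mode, gen)
            strand = "+" if gen.random() < 0.5 else "-"
            written = site if strand == "+" else _revcomp_codes(site)
            pos = mode + off
            genome[chrom][pos : pos + pwm.width] = written
            planted.append((motif_name, off, pwm.width))
            truth_rows.append(
                {
                    "peak": name,
                    "record": "plant",
                    "category": cat,
                    "motif": motif_name,
                    "offset": off,
                    "strand": strand,
                    "site": codes_to_seq(site),
                }
            )
        if not planted:
            truth_rows.append(
                {
                    "peak": name,
                    "record": "peak",
                    "category": cat,
                    "motif": "",
                    "offset": 0,
                    "strand": ".",
                    "site": "",
                }
            )
    truth = pd.DataFrame(truth_rows)
    return peaks, truth


def _draw_offset(
    cfg: SimulationConfig,
    width: int,
    placed: list[tuple[str, int, int]],
    gen: np.random.Generator,
) -> int:
    lo, hi = -cfg.peak_halfwidth, cfg.peak_halfwidth - width
    for _ in range(200):
        if cfg.offset_mode == "centered":
            off = int(np.clip(round(gen.normal(-width / 2, cfg.offset_sd)), lo, hi))
        else:
            off = int(gen.integers(lo, hi + 1))
        if all(off + width <= o or o + w <= off for _, o, w in placed):
            return off
    raise ValueError("cannot place non-overlapping motif instances in peak")


def simulate_gene_sets(
    cfg: SimulationConfig, gene_ids: Sequence[str], rng=None
) -> list[GeneSet]:
    """Random gene sets drawn from the gene universe."""
    gen = _as_rng(rng if rng is not None else cfg.seed + 2)
    ids = np.asarray(gene_ids)
    lo, hi = cfg.set_size_range
    hi = min(hi, len(ids))
    out = []
    for i in range(cfg.n_sets):
        size = int(gen.integers(lo, hi + 1))
        members = gen.choice(ids, size=size, replace=False)
        out.append(GeneSet(f"set{i:04d}", f"synthetic set {i}", frozenset(members)))
    return out


def simulate_de_tables(
    cfg: SimulationConfig,
    gene_ids: Sequence[str],
    sets: Sequence[GeneSet],
    effects: Mapping[str, Iterable[tuple[str, str]]] | None = None,
    rng=None,
) -> dict[str, pd.DataFrame]:
    """Per-comparison DE tables with planted directional set effects.

    Null genes carry z ~ N(0,1); genes in a planted set get a shifted z
    (+/- ``de_effect_z``).  p = two-sided normal tail of z, log2fc =
    z * ``de_lfc_scale``, FDR = BH within each table.  Comparisons without
    effects (the vehicle control by default) are pure null.
    """
    from .enrich import bh_fdr

    gen = _as_rng(rng if rng is not None else cfg.seed + 3)
    if effects is None:
        effects = DEFAULT_EFFECTS
    sets_by_id = {s.set_id: s for s in sets}
    for comp, eff in effects.items():
        for sid, direction in eff:
            if sid not in sets_by_id:
                raise ValueError(f"effect on unknown set {sid} in {comp}")
            if direction not in ("induced", "repressed"):
                raise ValueError(f"bad direction {direction}")
    ids = list(gene_ids)
    tables = {}
    for comp in effects:
        z = gen.normal(0.0, 1.0, size=len(ids))
        shift = np.zeros(len(ids))
        for sid, direction in effects[comp]:
            members = sets_by_id[sid].genes
            sign = 1.0 if direction == "induced" else -1.0
            in_set = np.fromiter((g in members for g in ids), bool, len(ids))
            shift[in_set] += sign * cfg.de_effect_z
        z = z + shift
        p = 2 * sps.norm.sf(np.abs(z))
        p = np.clip(p, 1e-300, 1.0)
        tables[comp] = pd.DataFrame(
            {
                "gene_id": ids,
                "log2fc": z * cfg.de_lfc_scale,
                "pvalue": p,
                "fdr": bh_fdr(p),
            }
        )
    return tables


def simulate_homolog_binding(
    cfg: SimulationConfig, rng=None
) -> tuple[HomologMap, set[str], set[str], set[str]]:
    """Two-species homolog map with planted binding-overlap fractions.

    Species-B genes in two bound sets (think adipocyte- and
    macrophage-specific reference cistromes) map to species-A genes; each
    B gene's A homolog is bound with the configured per-set probability.
    Returns (map, bound_a, bound_b1, bound_b2).
    """
    gen = _as_rng(rng if rng is not None else cfg.seed + 4)
    n = cfg.n_homologs_b1 + cfg.n_homologs_b2
    b_genes = [f"mg{i:05d}" for i in range(n)]
    a_genes = [f"rg{i:05d}" for i in range(n)]
    pairs = []
    bound_a: set[str] = set()
    b1: set[str] = set()
    b2: set[str] = set()
    for i, (bg, ag) in enumerate(zip(b_genes, a_genes)):
        in_b1 = i < cfg.n_homologs_b1
        (b1 if in_b1 else b2).add(bg)
        if gen.random() < cfg.frac_unmapped_b:
            continue  # no homolog for this B gene
        pairs.append((ag, bg))
        frac = cfg.frac_bound_b1 if in_b1 else cfg.frac_bound_b2
        if gen.random() < frac:
            bound_a.add(ag)
    return HomologMap(pairs), bound_a, b1, b2


@dataclass
class SimulatedStudy:
    """All inputs of one synthetic end-to-end run, plus ground truth."""

    cfg: SimulationConfig
    genome: dict[str, str]
    genome_sizes: dict[str, int]
    genes: list[GeneModel]
    peaks: list[Peak]
    truth: pd.DataFrame
    pwm_first: PWM
    pwm_second: PWM
    sets: list[GeneSet]
    de_tables: dict[str, pd.DataFrame]
    effects: dict[str, tuple[tuple[str, str], ...]]
    hmap: HomologMap
    bound_a: set[str]
    bound_b1: set[str]
    bound_b2: set[str]


def simulate_study(cfg: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate one complete synthetic study from a single seed."""
    cfg = cfg or SimulationConfig()
    gen = np.random.default_rng(cfg.seed)
    genome_codes, genes = simulate_genome_and_genes(cfg, gen)
    pax8, pparg = default_pwms()
    peaks, truth = simulate_peaks_and_motifs(cfg, genome_codes, genes, pax8, pparg, gen)
    sets = simulate_gene_sets(cfg, [g.gene_id for g in genes], gen)
    de_tables = simulate_de_tables(cfg, [g.gene_id for g in genes], sets, None, gen)
    hmap, bound_a, b1, b2 = simulate_homolog_binding(cfg, gen)
    genome = {c: codes_to_seq(a) for c, a in genome_codes.items()}
    return SimulatedStudy(
        cfg=cfg,
        genome=genome,
        genome_sizes={c: len(s) for c, s in genome.items()},
        genes=genes,
        peaks=peaks,
        truth=truth,
        pwm_first=pax8,
        pwm_second=pparg,
        sets=sets,
        de_tables=de_tables,
        effects=dict(DEFAULT_EFFECTS),
        hmap=hmap,
        bound_a=bound_a,
        bound_b1=b1,
        bound_b2=b2,
    )
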