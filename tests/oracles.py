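"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: position sets instead of interval
arithmetic, per-window python loops instead of vectorized scans, explicit
hypergeometric enumeration instead of library Fisher tests.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps

PRIORITY = ["TSS_1KB", "UP_1_5KB", "UP_5_10KB", "EXON", "UTR", "INTRON", "INTERGENIC"]


def oracle_gene_region_positions(gene, cfg):
    """Per-category genomic position sets for one gene, derived from scratch."""
    w, near, far = cfg.tss_window, cfg.upstream_near, cfg.upstream_far
    t = gene.tss
    if gene.strand == "+":
        tssw = range(t - w, t + w)
        up15 = range(t - near, t - w)
        up510 = range(t - far, t - near)
    else:
        tssw = range(t - w + 1, t + w + 1)
        up15 = range(t + w + 1, t + near + 1)
        up510 = range(t + near + 1, t + far + 1)
    exonic = set()
    for s, e in gene.exons:
        exonic |= set(range(s, e))
    if gene.cds_start is not None and gene.cds_start < gene.cds_end:
        cds = set(range(gene.cds_start, gene.cds_end))
        coding = exonic & cds
        utr = exonic - cds
    else:
        coding, utr = exonic, set()
    intron = set(range(gene.start, gene.end)) - exonic
    return {
        "TSS_1KB": set(tssw),
        "UP_1_5KB": set(up15),
        "UP_5_10KB": set(up510),
        "EXON": coding,
        "UTR": utr,
        "INTRON": intron,
    }


def oracle_assign_category(peak, genes, cfg) -> str:
    """Exhaustive per-region membership check applied in priority order."""
    ppos = set(range(peak.interval.start, peak.interval.end))
    for cat in PRIORITY[:-1]:
        for g in genes:
            if g.chrom != peak.interval.chrom:
                continue
            if ppos & oracle_gene_region_positions(g, cfg)[cat]:
                return cat
    return "INTERGENIC"


def oracle_score_bits(seq: str, probs: np.ndarray, background: np.ndarray) -> float:
    """Per-position log2-odds product computed by an explicit loop."""
    total = 0.0
    lookup = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i, base in enumerate(seq):
        if base not in lookup:
            return float("-inf")
        j = lookup[base]
        total += math.log2(probs[i][j] / background[j])
    return total


def oracle_revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


def oracle_enumerate_null(probs: np.ndarray, background: np.ndarray, granularity: float):
    """Exact null by enumerating all 4^w sequences; returns {int_score: tail_p}.

    Scores are rounded per column to ``granularity`` bits, matching the
    scanning contract, but the distribution itself comes from enumeration
    rather than dynamic programming.
    """
    import itertools

    w = len(probs)
    tail: dict[int, float] = {}
    pmf: dict[int, float] = {}
    for combo in itertools.product(range(4), repeat=w):
        s = sum(round(math.log2(probs[i][j] / background[j]) / granularity) for i, j in enumerate(combo))
        prob = math.prod(background[j] for j in combo)
        pmf[s] = pmf.get(s, 0.0) + prob
    acc = 0.0
    for s in sorted(pmf, reverse=True):
        acc += pmf[s]
        tail[s] = acc
    return tail


def oracle_scan_hits(peaks, genome, probs, background, granularity, p_threshold):
    """Brute-force both-strand window scan; returns {(peak, offset, strand)}."""
    tail = oracle_enumerate_null(probs, background, granularity)
    scores = sorted(tail)
    w = len(probs)
    hits = set()
    for peak in peaks:
        seq = genome[peak.interval.chrom][peak.interval.start : peak.interval.end]
        center = len(seq) // 2
        for start in range(len(seq) - w + 1):
            window = seq[start : start + w]
            for strand in "+-":
                target = window if strand == "+" else oracle_revcomp(window)
                if "N" in target:
                    continue
                s = sum(
                    round(math.log2(probs[i]["ACGT".index(b)] / background["ACGT".index(b)]) / granularity)
                    for i, b in enumerate(target)
                )
                # tail lookup: p of the smallest enumerated score >= s
                p = 1.0
                for sc in scores:
                    if sc >= s:
                        p = tail[sc]
                        break
                else:
                    p = 0.0
                if p < p_threshold:
                    hits.add((peak.name, start - center, strand))
    return hits


def oracle_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct hypergeometric tail enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = sps.hypergeom(n, col1, row1)
    p_obs = rv.pmf(a)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = rv.pmf(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)
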