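"""Position-weight-matrix scanning with exact null p-values.

A PWM is a per-position nucleotide probability model; windows are scored as
log2 odds against a 0-order background.  The null distribution of the score
of a random width-mer is computed exactly by dynamic programming over
discretized column scores, giving each observed score an exceedance
p-value P(S >= s).  An occurrence ("hit") is any window on either strand
whose p-value falls below the threshold (default 1e-4, the conventional
scanning default).

The background used for scanning is the mononucleotide composition of the
scanned genome, symmetrized across strands (A/T and C/G averaged) so that
scanning a reverse-complemented genome yields identical per-peak calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import Peak

__all__ = [
    "PWM",
    "MotifHit",
    "ScoreDistribution",
    "pwm_from_counts",
    "score_window",
    "score_pvalue_table",
    "scan_peaks",
    "genome_background",
    "encode",
    "revcomp",
]

ALPHABET = "ACGT"
_CODE = {b: i for i, b in enumerate(ALPHABET)}
_COMP = str.maketrans("ACGTN", "TGCAN")
UNIFORM = np.full(4, 0.25)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to int8 codes (A=0..T=3, anything else 4)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


@dataclass(frozen=True)
class PWM:
    """Probability matrix over ACGT columns with an explicit background."""

    name: str
    probs: np.ndarray  # (width, 4), rows sum to 1
    background: np.ndarray = field(default_factory=lambda: UNIFORM.copy())

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] < 1:
            raise ValueError("probs must be a width x 4 matrix")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9) or np.any(bg <= 0):
            raise ValueError("background must be a positive probability vector")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @cached_property
    def log_odds(self) -> np.ndarray:
        """log2(p/bg) matrix; -inf where a probability is zero."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / self.background)

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def with_background(self, background: np.ndarray) -> "PWM":
        return PWM(self.name, self.probs, background)

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.probs[::-1, ::-1].copy(), self.background[::-1].copy())


def pwm_from_counts(
    name: str,
    counts: np.ndarray,
    pseudocount: float = 0.1,
    background: np.ndarray | None = None,
) -> PWM:
    """Build a PWM from a count matrix with background-weighted pseudocounts.

    probs[i, j] = (counts[i, j] + pseudocount * bg[j]) / (colsum_i + pseudocount)
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] < 1:
        raise ValueError("counts must be a width x 4 matrix")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    bg = UNIFORM.copy() if background is None else np.asarray(background, float)
    colsums = counts.sum(axis=1, keepdims=True)
    if pseudocount == 0 and np.any(colsums == 0):
        raise ValueError("all-zero column with zero pseudocount")
    probs = (counts + pseudocount * bg) / (colsums + pseudocount)
    return PWM(name, probs, bg)


def score_window(pwm: PWM, seq: str) -> float:
    """Log-odds score (bits) of one window; -inf if it contains non-ACGT."""
    if len(seq) != pwm.width:
        raise ValueError(f"window length {len(seq)} != PWM width {pwm.width}")
    codes = encode(seq)
    if np.any(codes > 3):
        return float("-inf")
    return float(pwm.log_odds[np.arange(pwm.width), codes].sum())


class ScoreDistribution:
    """Exact null distribution of discretized PWM scores under the background.

    Column log-odds are rounded to integer multiples of ``granularity``
    bits; the distribution of the integer sum is built by exact dynamic
    programming (convolution over columns).  ``pvalue`` returns
    P(S >= s) for a window's discretized score.
    """

    def __init__(self, pwm: PWM, granularity: float = 1e-3):
        if granularity <= 0:
            raise ValueError("granularity must be positive")
        lo = pwm.log_odds
        if not np.all(np.isfinite(lo)):
            raise ValueError(
                "PWM has zero probabilities; use a pseudocount before "
                "building a score distribution"
            )
        self.granularity = float(granularity)
        self.scaled = np.round(lo / granularity).astype(np.int64)  # (w, 4)
        offset = int(-self.scaled.min(axis=1).sum())
        span = int((self.scaled.max(axis=1) - self.scaled.min(axis=1)).sum())
        pmf = np.zeros(span + 1)
        pmf[0] = 1.0
        pos = 0  # current pmf occupies [pos, pos+len) relative to min-sum
        cur_len = 1
        bg = pwm.background
        for i in range(pwm.width):
            col = self.scaled[i] - self.scaled[i].min()
            new = np.zeros(cur_len + col.max())
            for j in range(4):
                new[col[j] : col[j] + cur_len] += bg[j] * pmf[:cur_len]
            cur_len = len(new)
            pmf = new
        self._min_int = int(self.scaled.min(axis=1).sum())
        self._pmf = pmf
        # survival[k] = P(S_int >= min_int + k)
        self._surv = pmf[::-1].cumsum()[::-1]

    @property
    def min_score(self) -> float:
        return self._min_int * self.granularity

    def discretize(self, score: float) -> int:
        return int(np.round(score / self.granularity))

    def pvalue_int(self, s_int: int) -> float:
        k = s_int - self._min_int
        if k <= 0:
            return 1.0
        if k >= len(self._surv):
            return 0.0
        return float(self._surv[k])

    def pvalue(self, score: float) -> float:
        """Exceedance probability of a (bits) score under the null."""
        if score == float("-inf"):
            return 1.0
        return self.pvalue_int(self.discretize(score))

    def score_threshold(self, p_threshold: float) -> float:
        """Smallest achievable score with p-value below ``p_threshold``."""
        idx = np.nonzero(self._surv < p_threshold)[0]
        if len(idx) == 0:
            return float("inf")
        return (self._min_int + int(idx[0])) * self.granularity


def score_pvalue_table(pwm: PWM, granularity: float = 1e-3) -> ScoreDistribution:
    """Exact score -> p-value map for a PWM (see :class:`ScoreDistribution`)."""
    return ScoreDistribution(pwm, granularity)


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence within a peak.

    ``offset`` is the hit start (forward-strand coordinate) relative to the
    peak center; ``strand`` is the strand of the matching orientation.
    """

    peak_name: str
    offset: int
    strand: str
    score: float
    pvalue: float


def genome_background(genome: Mapping[str, str], symmetrize: bool = True) -> np.ndarray:
    """Mononucleotide frequencies of a genome; strand-symmetrized by default."""
    counts = np.zeros(4)
    for seq in genome.values():
        codes = encode(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        return UNIFORM.copy()
    freqs = counts / counts.sum()
    if symmetrize:
        freqs = (freqs + freqs[::-1]) / 2.0
    return freqs


def _window_scores_int(codes: np.ndarray, scaled: np.ndarray) -> np.ndarray:
    """Discretized score of every window; int64, INT_MIN-ish where N present."""
    w = scaled.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    pad = np.concatenate(
        [scaled, np.full((w, 1), np.iinfo(np.int32).min, dtype=np.int64)], axis=1
    )
    win = np.lib.stride_tricks.sliding_window_view(codes, w)
    return pad[np.arange(w), win].sum(axis=1)


def scan_peaks(
    peaks: Sequence[Peak],
    genome: Mapping[str, str],
    pwm: PWM,
    p_threshold: float = 1e-4,
    background: np.ndarray | None = None,
    granularity: float = 1e-3,
) -> list[MotifHit]:
    """Scan peak sequences on both strands for motif occurrences.

    Every window whose exact null p-value is below ``p_threshold`` is
    reported.  The scanning background defaults to the strand-symmetrized
    mononucleotide composition of ``genome``.
    """
    if background is None:
        background = genome_background(genome)
    fwd = pwm.with_background(background)
    dist = ScoreDistribution(fwd, granularity)
    # reverse-complement scores come from the flipped integer matrix, so both
    # strands share one exact null table (background is strand-symmetric)
    strand_mats = (("+", dist.scaled), ("-", dist.scaled[::-1, ::-1]))
    hits: list[MotifHit] = []
    for peak in peaks:
        iv = peak.interval
        seq = genome.get(iv.chrom)
        if seq is None or iv.end > len(seq):
            raise ValueError(f"peak {peak.name} outside FASTA bounds")
        codes = encode(seq[iv.start : iv.end])
        center = iv.width // 2
        for strand, scaled in strand_mats:
            sints = _window_scores_int(codes, scaled)
            for j in np.nonzero(sints > np.iinfo(np.int32).min // 2)[0]:
                p = dist.pvalue_int(int(sints[j]))
                if p < p_threshold:
                    hits.append(
                        MotifHit(
                            peak_name=peak.name,
                            offset=int(j) - center,
                            strand=strand,
                            score=float(sints[j]) * granularity,
                            pvalue=p,
                        )
                    )
    return hits


def peaks_with_hits(hits: Iterable[MotifHit]) -> set[str]:
    """Names of peaks containing at least one occurrence."""
    return {h.peak_name for h in hits}
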