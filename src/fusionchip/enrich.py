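"""Gene-set enrichment engines.

Two logistic-regression engines are provided:

* :func:`lrpath_directional` — directional enrichment of expression
  results.  Gene-set membership (0/1) is regressed on the signed evidence
  statistic sign(log2fc) * (-ln p) across the whole tested universe; a
  positive slope means members concentrate among significantly induced
  genes ("induced" set), a negative slope among repressed genes.

* :func:`chipenrich` — binary peak-presence enrichment with an empirical
  adjustment for gene locus length.  Whether a gene's locus contains a peak
  is regressed on set membership plus a natural cubic spline in
  log10(locus length); locus length (10 kb upstream of TSS to the 3' end)
  strongly confounds naive peak-presence tests because long genes collect
  peaks by chance.

Both engines Wald-test the membership/slope coefficient, control FDR by
Benjamini-Hochberg across tested sets, and apply the standard size filter
(5 to 500 genes after intersection with the tested universe).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError
from scipy import stats as sps

from .intervals import AnnotationConfig, GeneModel, Peak
from .motifs import MotifHit, peaks_with_hits
from .stats import firth_logit

__all__ = [
    "GeneSet",
    "GeneLocus",
    "EnrichmentResult",
    "bh_fdr",
    "lrpath_directional",
    "chipenrich",
    "gene_loci",
    "assign_peaks_to_genes",
    "stratified_enrichment",
    "StratifiedEnrichment",
]

MIN_SET_SIZE = 5
MAX_SET_SIZE = 500


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneLocus:
    """A gene's peak-assignment summary for peak-presence enrichment."""

    gene_id: str
    locus_length: int
    n_peaks: int

    def __post_init__(self) -> None:
        if self.locus_length <= 0:
            raise ValueError(f"{self.gene_id}: locus_length must be positive")
        if self.n_peaks < 0:
            raise ValueError(f"{self.gene_id}: negative peak count")

    @property
    def has_peak(self) -> bool:
        return self.n_peaks >= 1


@dataclass
class EnrichmentResult:
    set_id: str
    description: str
    n_genes_tested: int
    coefficient: float
    direction: str  # induced / repressed / enriched / depleted
    pvalue: float
    qvalue: float | None = None
    note: str = ""


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _finalize(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    if results:
        q = bh_fdr([r.pvalue for r in results])
        for r, qi in zip(results, q):
            r.qvalue = float(qi)
    return results


def _eligible_sets(
    sets: Iterable[GeneSet],
    universe: set[str],
    min_size: int,
    max_size: int,
) -> list[tuple[GeneSet, set[str]]]:
    out = []
    for gs in sets:
        members = gs.genes & universe
        if min_size <= len(members) <= max_size:
            out.append((gs, members))
    return out


def lrpath_directional(
    records: pd.DataFrame,
    sets: Sequence[GeneSet],
    min_size: int = MIN_SET_SIZE,
    max_size: int = MAX_SET_SIZE,
) -> list[EnrichmentResult]:
    """Directional logistic-regression enrichment of expression results.

    ``records`` needs columns gene_id, log2fc, pvalue.  For each eligible
    set, membership is regressed on sign(log2fc)*(-ln p); the slope's
    two-sided Wald p and sign give significance and direction.  q-values
    are BH over all tested sets.
    """
    for col in ("gene_id", "log2fc", "pvalue"):
        if col not in records.columns:
            raise ValueError(f"records missing column {col}")
    if records["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in records")
    genes = records["gene_id"].to_numpy()
    p = records["pvalue"].to_numpy(float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("pvalue must be in (0, 1]")
    x = np.sign(records["log2fc"].to_numpy(float)) * (-np.log(p))
    universe = set(genes)
    X = sm.add_constant(x)
    results: list[EnrichmentResult] = []
    for gs, members in _eligible_sets(sets, universe, min_size, max_size):
        y = np.isin(genes, list(members)).astype(float)
        if y.sum() == 0 or y.sum() == len(y):
            continue  # degenerate: all genes in or out of the set
        if np.ptp(x) == 0:
            # no evidence spread: slope is undefined, report a null result
            results.append(
                EnrichmentResult(
                    gs.set_id, gs.description, int(y.sum()), 0.0, "induced", 1.0,
                    note="constant evidence statistic",
                )
            )
            continue
        coef, pval, note = _logit_coef_p(X, y, col=1)
        results.append(
            EnrichmentResult(
                set_id=gs.set_id,
                description=gs.description,
                n_genes_tested=int(y.sum()),
                coefficient=coef,
                direction="induced" if coef >= 0 else "repressed",
                pvalue=pval,
                note=note,
            )
        )
    return _finalize(results)


def _logit_coef_p(X: np.ndarray, y: np.ndarray, col: int) -> tuple[float, float, str]:
    """Wald coefficient test for one logistic-regression column.

    Falls back to a Firth-penalized fit when the ML fit separates or fails
    to converge; the fallback is flagged in the returned note.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            coef = float(fit.params[col])
            se = float(fit.bse[col])
            ok = np.isfinite(se) and se > 0 and abs(coef) < 15 and se < 100
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
            ok = False
    if ok:
        z = coef / se
        return coef, float(2 * sps.norm.sf(abs(z))), ""
    beta, se_f = firth_logit(X, y)
    if not np.isfinite(se_f[col]) or se_f[col] <= 0:
        return float(beta[col]), 1.0, "firth_fallback_degenerate"
    z = beta[col] / se_f[col]
    return float(beta[col]), float(2 * sps.norm.sf(abs(z))), "firth_fallback"


def _spline_basis(log_len: np.ndarray, df: int) -> np.ndarray:
    """Natural cubic spline basis on log10 locus length, knots at quantiles."""
    if np.ptp(log_len) == 0:
        return np.zeros((len(log_len), 0))
    return np.asarray(patsy.dmatrix(
        "cr(x, df=df) - 1", {"x": log_len, "df": df}, return_type="matrix"
    ))


def chipenrich(
    loci: Sequence[GeneLocus],
    sets: Sequence[GeneSet],
    spline_df: int = 10,
    min_size: int = MIN_SET_SIZE,
    max_size: int = MAX_SET_SIZE,
) -> list[EnrichmentResult]:
    """Peak-presence gene-set enrichment with locus-length adjustment.

    For each eligible set, fits has_peak ~ membership + spline(log10 locus
    length) and Wald-tests the membership coefficient.  With all locus
    lengths equal the spline drops out and the model reduces to a plain
    logistic membership test.
    """
    ids = [l.gene_id for l in loci]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id in loci")
    genes = np.array(ids)
    haspeak = np.array([float(l.has_peak) for l in loci])
    log_len = np.log10(np.array([l.locus_length for l in loci], dtype=float))
    basis = _spline_basis(log_len, spline_df)
    universe = set(ids)
    results: list[EnrichmentResult] = []
    for gs, members in _eligible_sets(sets, universe, min_size, max_size):
        y_member = np.isin(genes, list(members)).astype(float)
        # the natural-spline basis spans the constant, so it doubles as the
        # intercept; a plain intercept stands in when lengths are all equal
        if basis.shape[1]:
            X = np.column_stack([y_member, basis])
        else:
            X = np.column_stack([y_member, np.ones(len(genes))])
        if haspeak.sum() == 0 or haspeak.sum() == len(haspeak):
            continue  # degenerate outcome
        coef, pval, note = _logit_coef_p(X, haspeak, col=0)
        results.append(
            EnrichmentResult(
                set_id=gs.set_id,
                description=gs.description,
                n_genes_tested=int(y_member.sum()),
                coefficient=coef,
                direction="enriched" if coef >= 0 else "depleted",
                pvalue=pval,
                note=note,
            )
        )
    return _finalize(results)


def gene_loci(
    genes: Sequence[GeneModel],
    peak_gene_ids: Iterable[str],
    cfg: AnnotationConfig | None = None,
) -> list[GeneLocus]:
    """Build GeneLocus records from gene models and assigned peak gene ids.

    Locus length spans from ``upstream_far`` bp upstream of the TSS to the
    transcript 3' end.
    """
    cfg = cfg or AnnotationConfig()
    counts: dict[str, int] = {}
    for g in peak_gene_ids:
        counts[g] = counts.get(g, 0) + 1
    out = []
    for g in genes:
        t0, t1 = g.territory(cfg.upstream_far)
        out.append(
            GeneLocus(g.gene_id, max(t1 - max(t0, 0), 1), counts.get(g.gene_id, 0))
        )
    return out


def assign_peaks_to_genes(
    peaks: Sequence[Peak], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Nearest-TSS assignment with signed transcription-direction distance.

    Returns a frame (peak, gene_id, distance) where distance is the peak
    mode's offset from the assigned TSS in transcription direction
    (negative = upstream).  Peaks on chromosomes without genes are dropped.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for p in peaks:
        cands = by_chrom.get(p.interval.chrom)
        if not cands:
            continue
        g = min(cands, key=lambda g: (abs(g.tss - p.mode), g.gene_id))
        rel = p.mode - g.tss if g.strand == "+" else g.tss - p.mode
        rows.append((p.name, g.gene_id, int(rel)))
    return pd.DataFrame(rows, columns=["peak", "gene_id", "distance"])


@dataclass
class StratifiedEnrichment:
    """Per-stratum peak-presence enrichment plus a joint ChIP/RNA report."""

    strata: dict[tuple[str, str], list[EnrichmentResult]]
    joint: pd.DataFrame
    skipped: list[tuple[str, str]] = field(default_factory=list)


def stratified_enrichment(
    peaks: Sequence[Peak],
    motif_hits: Mapping[str, Iterable[MotifHit]],
    genes: Sequence[GeneModel],
    sets: Sequence[GeneSet],
    rna_results: Sequence[EnrichmentResult] | None = None,
    near_tss_bp: int = 10_000,
    q_cut: float = 0.05,
    spline_df: int = 10,
    cfg: AnnotationConfig | None = None,
) -> StratifiedEnrichment:
    """Peak-group enrichment stratified by motif content and TSS distance.

    Peaks are assigned to the nearest-TSS gene, then split into strata by
    (motif name) x (zone), where "near" means within ``near_tss_bp`` of the
    TSS on either side and "far" means more than ``near_tss_bp`` upstream in
    transcription direction.  Each stratum gets its own locus-length-adjusted
    enrichment run; the joint report marks sets that are both peak-enriched
    (q <= q_cut) and significant in a supplied expression-enrichment run.
    """
    assign = assign_peaks_to_genes(peaks, genes)
    assign = assign.set_index("peak")
    strata: dict[tuple[str, str], list[EnrichmentResult]] = {}
    skipped: list[tuple[str, str]] = []
    for motif, hits in motif_hits.items():
        with_motif = peaks_with_hits(hits)
        for zone in ("near", "far"):
            sel = []
            for pname in with_motif:
                if pname not in assign.index:
                    continue
                d = int(assign.loc[pname, "distance"])
                in_near = abs(d) <= near_tss_bp
                in_far = d < -near_tss_bp
                if (zone == "near" and in_near) or (zone == "far" and in_far):
                    sel.append(pname)
            if not sel:
                skipped.append((motif, zone))
                continue
            gene_hits = assign.loc[sel, "gene_id"].tolist()
            loci = gene_loci(genes, gene_hits, cfg)
            strata[(motif, zone)] = chipenrich(
                loci, sets, spline_df=spline_df
            )
    rna_by_id = (
        {r.set_id: r for r in rna_results} if rna_results is not None else {}
    )
    rows = []
    for (motif, zone), res in strata.items():
        for r in res:
            if r.qvalue is None or r.qvalue > q_cut:
                continue
            rna = rna_by_id.get(r.set_id)
            rows.append(
                {
                    "motif": motif,
                    "zone": zone,
                    "set_id": r.set_id,
                    "chip_q": r.qvalue,
                    "rna_q": rna.qvalue if rna else np.nan,
                    "rna_direction": (
                        rna.direction
                        if rna and rna.qvalue is not None and rna.qvalue <= q_cut
                        else ""
                    ),
                }
            )
    joint = pd.DataFrame(
        rows, columns=["motif", "zone", "set_id", "chip_q", "rna_q", "rna_direction"]
    )
    return StratifiedEnrichment(strata=strata, joint=joint, skipped=skipped)
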