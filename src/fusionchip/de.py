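"""Differential-expression classification and ChIP/RNA integration.

Consumes per-comparison differential-expression tables (gene, log2 fold
change, p-value, FDR) produced upstream, classifies genes as induced (UP),
repressed (DOWN) or unchanged (NC) at stated cutoffs, and supplies the
cross-comparison analyses: multi-comparison Venn regions, direction
concordance between two perturbations, sign-reversal summaries,
opposite-direction gene-set detection, homolog-mapped binding overlap
between two reference cistromes, and external-gene-list overlap fractions.

Fold-change cutoffs are linear: a gene passes ``fc_cut`` when
2**|log2fc| > fc_cut, symmetrically for induction and repression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import ContingencyTable2x2, fisher_exact_2xc

__all__ = [
    "DEClassification",
    "HomologMap",
    "classify_de",
    "venn_comparisons",
    "concordance_analysis",
    "ConcordanceResult",
    "reversal_analysis",
    "ReversalResult",
    "opposite_direction_genesets",
    "homolog_binding_overlap",
    "HomologOverlapResult",
    "cross_study_overlap",
]

REQUIRED_DE_COLUMNS = ("gene_id", "log2fc", "pvalue", "fdr")


def _check_de_frame(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_DE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")
    if records["gene_id"].duplicated().any():
        dups = records.loc[records["gene_id"].duplicated(), "gene_id"].head().tolist()
        raise ValueError(f"duplicate gene_id in DE table: {dups}")
    if not np.all(np.isfinite(records["log2fc"])):
        raise ValueError("log2fc must be finite")
    return records


@dataclass
class DEClassification:
    """Per-gene UP/DOWN/NC calls at stated FDR and fold-change cutoffs."""

    calls: pd.Series  # index gene_id, values in {"UP","DOWN","NC"}
    fdr_cut: float
    fc_cut: float

    @property
    def genes(self) -> pd.Index:
        return self.calls.index

    @property
    def de_genes(self) -> set[str]:
        return set(self.calls.index[self.calls != "NC"])

    @property
    def up_genes(self) -> set[str]:
        return set(self.calls.index[self.calls == "UP"])

    @property
    def down_genes(self) -> set[str]:
        return set(self.calls.index[self.calls == "DOWN"])

    def counts(self) -> dict[str, int]:
        vc = self.calls.value_counts()
        return {k: int(vc.get(k, 0)) for k in ("UP", "DOWN", "NC")}


def classify_de(
    records: pd.DataFrame, fdr_cut: float = 0.05, fc_cut: float = 2.0
) -> DEClassification:
    """Classify genes as UP/DOWN/NC.

    UP: fdr < fdr_cut, 2**|log2fc| > fc_cut and log2fc > 0; DOWN symmetric;
    otherwise NC.  One record per gene is required.
    """
    records = _check_de_frame(records)
    lfc = records["log2fc"].to_numpy(float)
    passes = (records["fdr"].to_numpy(float) < fdr_cut) & (
        np.exp2(np.abs(lfc)) > fc_cut
    )
    calls = np.where(passes & (lfc > 0), "UP", np.where(passes & (lfc < 0), "DOWN", "NC"))
    return DEClassification(
        calls=pd.Series(calls, index=pd.Index(records["gene_id"], name="gene_id")),
        fdr_cut=fdr_cut,
        fc_cut=fc_cut,
    )


def venn_comparisons(
    classifications: Mapping[str, DEClassification],
) -> dict[tuple[str, ...], int]:
    """Exclusive region counts of DE (UP or DOWN) gene sets across 2-3 runs.

    Keys are sorted tuples of comparison names; the value for key S is the
    number of genes DE in exactly the comparisons in S.  All classifications
    must share one gene universe.
    """
    names = sorted(classifications)
    if not 2 <= len(names) <= 3:
        raise ValueError("venn_comparisons expects 2 or 3 classifications")
    universes = [frozenset(classifications[n].genes) for n in names]
    if len(set(universes)) != 1:
        raise ValueError("classifications use different gene universes")
    de_sets = {n: classifications[n].de_genes for n in names}
    regions: dict[tuple[str, ...], int] = {}
    import itertools

    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(de_sets[n] for n in combo))
            outside = set.union(
                *(de_sets[n] for n in names if n not in combo), set()
            )
            regions[combo] = len(inside - outside)
    return regions


@dataclass
class ConcordanceResult:
    """Direction concordance of two perturbations over the first one's DE genes.

    ``table`` is the 2x3 count matrix (rows: first-run UP/DOWN; columns:
    second-run UP/DOWN/NC); ``fisher_p`` is the exact conditional test on
    that full table.  ``doubly_changed`` is the 2x2 restricted to genes
    changed in both runs, with its own Fisher odds ratio/p.
    """

    table: pd.DataFrame
    row_percent: pd.DataFrame
    fisher_p: float
    doubly_changed: ContingencyTable2x2 | None

    @property
    def frac_discordant(self) -> float:
        """Among doubly-changed genes, fraction with opposite directions."""
        t = self.doubly_changed
        if t is None:
            return float("nan")
        disc = t.b + t.c
        tot = t.a + t.b + t.c + t.d
        return disc / tot if tot else float("nan")


def concordance_analysis(
    class_a: DEClassification, class_b: DEClassification
) -> ConcordanceResult:
    """Cross-tabulate run-A DE genes by their run-B calls and test association.

    Rows cover the genes DE in run A (its UP and DOWN sets); columns are the
    run-B calls (UP/DOWN/NC, with genes absent from run B counted NC).  The
    headline p-value is the exact conditional test on the full 2x3 table;
    the 2x2 of doubly-changed genes is reported with its own Fisher test.
    """
    rows = {}
    bcalls = class_b.calls
    for a_dir, genes in (("UP", class_a.up_genes), ("DOWN", class_a.down_genes)):
        sub = bcalls.reindex(sorted(genes)).fillna("NC")
        vc = sub.value_counts()
        rows[a_dir] = [int(vc.get(k, 0)) for k in ("UP", "DOWN", "NC")]
    table = pd.DataFrame(rows, index=["UP", "DOWN", "NC"]).T
    totals = table.sum(axis=1)
    with np.errstate(invalid="ignore"):
        row_pct = table.div(totals, axis=0) * 100.0
    p23 = fisher_exact_2xc(table.to_numpy())
    dd = None
    if (table.loc["UP", ["UP", "DOWN"]].sum() > 0) and (
        table.loc["DOWN", ["UP", "DOWN"]].sum() > 0
    ):
        dd = ContingencyTable2x2(
            int(table.loc["UP", "UP"]),
            int(table.loc["UP", "DOWN"]),
            int(table.loc["DOWN", "UP"]),
            int(table.loc["DOWN", "DOWN"]),
        )
    return ConcordanceResult(
        table=table, row_percent=row_pct, fisher_p=p23, doubly_changed=dd
    )


@dataclass(frozen=True)
class ReversalResult:
    n_shared: int
    n_same_direction: int
    n_opposite: int

    @property
    def frac_same(self) -> float:
        return self.n_same_direction / self.n_shared if self.n_shared else float("nan")

    @property
    def frac_opposite(self) -> float:
        return self.n_opposite / self.n_shared if self.n_shared else float("nan")


def reversal_analysis(
    class_a: DEClassification, class_b: DEClassification
) -> ReversalResult:
    """Among genes DE in both runs, count matching vs opposite directions."""
    shared = class_a.de_genes & class_b.de_genes
    same = sum(1 for g in shared if class_a.calls[g] == class_b.calls[g])
    return ReversalResult(
        n_shared=len(shared), n_same_direction=same, n_opposite=len(shared) - same
    )


def opposite_direction_genesets(
    enrich_a: Sequence, enrich_b: Sequence, q_cut: float = 0.05
) -> list[str]:
    """Gene sets significant in both enrichment runs with opposite directions.

    Both runs must have tested the same gene-set collection.  Directions are
    read from each result's ``direction`` attribute.
    """
    ids_a = {r.set_id for r in enrich_a}
    ids_b = {r.set_id for r in enrich_b}
    if ids_a != ids_b:
        raise ValueError("enrichment runs tested different gene-set collections")
    dir_a = {r.set_id: r.direction for r in enrich_a if r.qvalue is not None and r.qvalue <= q_cut}
    dir_b = {r.set_id: r.direction for r in enrich_b if r.qvalue is not None and r.qvalue <= q_cut}
    out = [
        sid
        for sid in sorted(dir_a.keys() & dir_b.keys())
        if dir_a[sid] != dir_b[sid]
    ]
    return out


class HomologMap:
    """Many-to-many homolog pairs between two species' gene identifiers."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self.a_to_b: dict[str, set[str]] = {}
        self.b_to_a: dict[str, set[str]] = {}
        for a, b in pairs:
            if a == b:
                raise ValueError(f"self-pair in homolog map: {a}")
            self.a_to_b.setdefault(a, set()).add(b)
            self.b_to_a.setdefault(b, set()).add(a)

    def __len__(self) -> int:
        return sum(len(v) for v in self.a_to_b.values())

    def one_to_one(self) -> "HomologMap":
        """Subset of pairs where both partners map uniquely."""
        return HomologMap(
            (a, next(iter(bs)))
            for a, bs in self.a_to_b.items()
            if len(bs) == 1 and len(self.b_to_a[next(iter(bs))]) == 1
        )


@dataclass
class HomologOverlapResult:
    prop_b1: float
    prop_b2: float
    table: ContingencyTable2x2
    n_b1: int
    n_b2: int

    @property
    def pvalue(self) -> float:
        return self.table.fisher_p


def homolog_binding_overlap(
    bound_a: set[str],
    bound_b1: set[str],
    bound_b2: set[str],
    hmap: HomologMap,
) -> HomologOverlapResult:
    """Compare species-A binding rates among homologs of two species-B sets.

    A species-B gene counts as "bound in A" when any of its A homologs is in
    ``bound_a`` (any-homolog semantics).  Proportions are reported over all
    mapped members of each set; the two-sided Fisher test uses the
    b1-exclusive versus b2-exclusive homologs to keep the 2x2 cells disjoint.
    """
    mapped1 = {b for b in bound_b1 if b in hmap.b_to_a}
    mapped2 = {b for b in bound_b2 if b in hmap.b_to_a}
    if not mapped1 or not mapped2:
        raise ValueError("a species-B set has no mapped homologs")

    def bound(b: str) -> bool:
        return bool(hmap.b_to_a[b] & bound_a)

    prop1 = sum(bound(b) for b in mapped1) / len(mapped1)
    prop2 = sum(bound(b) for b in mapped2) / len(mapped2)
    excl1 = mapped1 - mapped2
    excl2 = mapped2 - mapped1
    a = sum(bound(b) for b in excl1)
    c = sum(bound(b) for b in excl2)
    table = ContingencyTable2x2(a, len(excl1) - a, c, len(excl2) - c)
    return HomologOverlapResult(
        prop_b1=prop1, prop_b2=prop2, table=table, n_b1=len(mapped1), n_b2=len(mapped2)
    )


def cross_study_overlap(
    gene_list: Sequence[str],
    de_class: DEClassification,
    peak_genes: set[str],
    hmap: HomologMap,
) -> dict[str, float]:
    """Overlap of an external (species-B) gene list with DE and bound genes.

    The list is mapped through homologs first; fractions are over mapped
    genes.  A gene overlaps when any homolog is DE (resp. has a peak).
    """
    mapped = [g for g in gene_list if g in hmap.b_to_a]
    n = len(mapped)
    if n == 0:
        return {"n_mapped": 0, "frac_de": 0.0, "frac_peak": 0.0}
    de = de_class.de_genes
    n_de = sum(1 for g in mapped if hmap.b_to_a[g] & de)
    n_pk = sum(1 for g in mapped if hmap.b_to_a[g] & peak_genes)
    return {"n_mapped": n, "frac_de": n_de / n, "frac_peak": n_pk / n}
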