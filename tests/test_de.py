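import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fusionchip.de import (
    DEClassification,
    HomologMap,
    classify_de,
    concordance_analysis,
    cross_study_overlap,
    homolog_binding_overlap,
    opposite_direction_genesets,
    reversal_analysis,
    venn_comparisons,
)
from fusionchip.enrich import EnrichmentResult
from fusionchip.stats import fisher_exact_2xc


def de_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "pvalue", "fdr"])


def calls(mapping):
    return DEClassification(
        pd.Series(mapping, name="call").rename_axis("gene_id"), 0.05, 2.0
    )


# classifications reproducing the reference 2x3 concordance table of the
# PAX8-knockdown versus fusion-factor comparison: 175 induced / 121
# repressed genes on side A; side B calls fill the cells
# [[32, 62, 81], [47, 24, 50]]
TABLE2 = {"UP": (32, 62, 81), "DOWN": (47, 24, 50)}


def table2_classifications():
    a, b = {}, {}
    k = 0
    for a_dir, row in TABLE2.items():
        for b_call, n in zip(("UP", "DOWN", "NC"), row):
            for _ in range(n):
                g = f"g{k:04d}"
                a[g] = a_dir
                b[g] = b_call
                k += 1
    return calls(a), calls(b)


class TestClassifyDe:
    def test_clear_induction(self):
        cls = classify_de(de_frame([("g", 2.0, 1e-4, 0.01)]), 0.05, 2.0)
        assert cls.calls["g"] == "UP"

    def test_fold_change_below_cut_is_nc(self):
        # 2**0.5 = 1.41 < 2 despite the small FDR
        cls = classify_de(de_frame([("g", 0.5, 1e-4, 0.01)]), 0.05, 2.0)
        assert cls.calls["g"] == "NC"

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            classify_de(de_frame([("g", 1, 0.5, 0.5), ("g", 2, 0.5, 0.5)]))

    def test_planted_boundary_counts_exact(self):
        rows = []
        for i in range(100):  # just past both cuts -> UP
            rows.append((f"u{i}", 1.001, 1e-4, 0.049))
        for i in range(150):  # DOWN
            rows.append((f"d{i}", -1.001, 1e-4, 0.049))
        for i in range(80):  # exactly at the cut: excluded (strict)
            rows.append((f"n{i}", 1.0, 1e-4, 0.049))
        for i in range(70):  # fdr at the cut: excluded
            rows.append((f"m{i}", 1.5, 1e-4, 0.05))
        counts = classify_de(de_frame(rows), 0.05, 2.0).counts()
        assert (counts["UP"], counts["DOWN"], counts["NC"]) == (100, 150, 150)

    def test_threshold_monotone(self, rng):
        rows = [
            (f"g{i}", float(rng.normal(0, 1.5)), 0.5, float(rng.uniform(0, 1)))
            for i in range(300)
        ]
        df = de_frame(rows)
        loose = classify_de(df, 0.1, 1.5).de_genes
        assert classify_de(df, 0.05, 1.5).de_genes <= loose
        assert classify_de(df, 0.1, 2.0).de_genes <= loose

    def test_row_order_invariant(self, rng):
        rows = [
            (f"g{i}", float(rng.normal()), 0.5, float(rng.uniform()))
            for i in range(100)
        ]
        df = de_frame(rows)
        shuffled = df.sample(frac=1, random_state=1)
        a = classify_de(df).calls.sort_index()
        b = classify_de(shuffled).calls.sort_index()
        assert a.equals(b)


class TestVenn:
    def test_identical_classifications_concentrate(self):
        c = calls({"a": "UP", "b": "DOWN", "c": "NC"})
        regions = venn_comparisons({"x": c, "y": c})
        assert regions[("x", "y")] == 2
        assert regions[("x",)] == regions[("y",)] == 0

    def test_disjoint_sets(self):
        cx = calls({"a": "UP", "b": "NC"})
        cy = calls({"a": "NC", "b": "UP"})
        regions = venn_comparisons({"x": cx, "y": cy})
        assert regions[("x", "y")] == 0
        assert regions[("x",)] == regions[("y",)] == 1

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError):
            venn_comparisons({"x": calls({"a": "UP"}), "y": calls({"b": "UP"})})

    def test_three_way_matches_set_algebra(self, rng):
        genes = [f"g{i}" for i in range(200)]
        cls = {}
        for name in ("A", "B", "C"):
            cls[name] = calls(
                {g: ("UP" if rng.random() < 0.3 else "NC") for g in genes}
            )
        regions = venn_comparisons(cls)
        de = {n: cls[n].de_genes for n in cls}
        for r in range(1, 4):
            for combo in itertools.combinations(sorted(cls), r):
                inside = set.intersection(*(de[n] for n in combo))
                for n in cls:
                    if n not in combo:
                        inside -= de[n]
                assert regions[combo] == len(inside)


class TestConcordance:
    def test_reference_table_reproduced(self):
        ca, cb = table2_classifications()
        res = concordance_analysis(ca, cb)
        assert res.table.loc["UP"].tolist() == [32, 62, 81]
        assert res.table.loc["DOWN"].tolist() == [47, 24, 50]

    def test_exact_2x3_p_matches_r_reference(self):
        """Exact conditional test on the full 2x3 table; reference value
        computed with R's fisher.test (1.4732e-4)."""
        ca, cb = table2_classifications()
        res = concordance_analysis(ca, cb)
        assert res.fisher_p == pytest.approx(1.473245e-4, rel=1e-4)

    def test_doubly_changed_2x2(self):
        ca, cb = table2_classifications()
        res = concordance_analysis(ca, cb)
        t = res.doubly_changed
        assert (t.a, t.b, t.c, t.d) == (32, 62, 47, 24)
        assert t.fisher_p == pytest.approx(7.28121e-5, rel=1e-4)

    def test_perfect_concordance_rejects_hard(self):
        ca = calls({f"u{i}": "UP" for i in range(50)} | {f"d{i}": "DOWN" for i in range(50)})
        cb = ca
        res = concordance_analysis(ca, cb)
        assert res.fisher_p < 1e-6
        assert res.doubly_changed.odds_ratio == float("inf") or res.doubly_changed.odds_ratio > 1

    def test_2xc_reduces_to_fisher_2x2(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 60, size=4))
            table = [[a, b], [c, d]]
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            assert fisher_exact_2xc(table) == pytest.approx(
                sps.fisher_exact(table)[1], rel=1e-7
            )


class TestReversal:
    def test_identical_all_same_direction(self):
        c = calls({"a": "UP", "b": "DOWN", "c": "NC"})
        res = reversal_analysis(c, c)
        assert res.n_shared == 2 and res.frac_same == 1.0

    def test_sign_flip_all_opposite(self):
        c = calls({"a": "UP", "b": "DOWN"})
        flipped = calls({"a": "DOWN", "b": "UP"})
        res = reversal_analysis(c, flipped)
        assert res.frac_opposite == 1.0

    def test_planted_80_20_split(self):
        a, b = {}, {}
        for i in range(80):
            a[f"s{i}"], b[f"s{i}"] = "UP", "UP"
        for i in range(20):
            a[f"o{i}"], b[f"o{i}"] = "UP", "DOWN"
        res = reversal_analysis(calls(a), calls(b))
        assert (res.n_shared, res.n_same_direction, res.n_opposite) == (100, 80, 20)


def enr(set_id, direction, q):
    return EnrichmentResult(set_id, "", 10, 1.0 if direction == "induced" else -1.0,
                            direction, 0.001, q)


class TestOppositeDirectionSets:
    def test_no_shared_significant_sets(self):
        a = [enr("s1", "induced", 0.01), enr("s2", "induced", 0.9)]
        b = [enr("s1", "induced", 0.01), enr("s2", "repressed", 0.9)]
        assert opposite_direction_genesets(a, b) == []

    def test_planted_reversal_found(self):
        a = [enr("s1", "induced", 0.01), enr("s2", "induced", 0.01)]
        b = [enr("s1", "repressed", 0.01), enr("s2", "induced", 0.01)]
        assert opposite_direction_genesets(a, b) == ["s1"]

    def test_mismatched_collections_rejected(self):
        with pytest.raises(ValueError):
            opposite_direction_genesets([enr("s1", "induced", 0.5)], [enr("s2", "induced", 0.5)])


class TestHomologOverlap:
    def make_map(self, n):
        return HomologMap((f"a{i}", f"b{i}") for i in range(n))

    def test_all_bound_gives_unit_proportions(self):
        hmap = self.make_map(40)
        res = homolog_binding_overlap(
            {f"a{i}" for i in range(40)},
            {f"b{i}" for i in range(20)},
            {f"b{i}" for i in range(20, 40)},
            hmap,
        )
        assert res.prop_b1 == 1.0 and res.prop_b2 == 1.0

    def test_power_at_planted_difference(self, rng):
        """0.34 vs 0.25 at n=1500 per set rejects at alpha=0.01 in most
        replicates."""
        hmap = self.make_map(3000)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            bound_a = {
                f"a{i}" for i in range(3000)
                if rng.random() < (0.34 if i < 1500 else 0.25)
            }
            res = homolog_binding_overlap(
                bound_a,
                {f"b{i}" for i in range(1500)},
                {f"b{i}" for i in range(1500, 3000)},
                hmap,
            )
            hits += res.pvalue < 0.01
        assert hits / n_rep >= 0.9

    def test_null_calibration(self, rng):
        hmap = self.make_map(1200)
        pvals = []
        for _ in range(300):
            bound_a = {f"a{i}" for i in range(1200) if rng.random() < 0.3}
            res = homolog_binding_overlap(
                bound_a,
                {f"b{i}" for i in range(600)},
                {f"b{i}" for i in range(600, 1200)},
                hmap,
            )
            pvals.append(res.pvalue)
        pvals = np.array(pvals)
        # the exact test is conservative: rejection rates stay at or below
        # nominal (plus Monte-Carlo slack) at every level
        for alpha in (0.01, 0.05, 0.2):
            se = np.sqrt(alpha * (1 - alpha) / len(pvals))
            assert np.mean(pvals < alpha) <= alpha + 3 * se
        assert pvals.mean() > 0.45

    def test_empty_mapped_sets_rejected(self):
        with pytest.raises(ValueError):
            homolog_binding_overlap(set(), {"bX"}, {"bY"}, self.make_map(5))

    def test_many_to_many_any_homolog_semantics(self):
        hmap = HomologMap([("a1", "b1"), ("a2", "b1")])
        res = homolog_binding_overlap({"a2"}, {"b1"}, {"b1", "bz"}, hmap)
        assert res.prop_b1 == 1.0

    def test_one_to_one_subset(self):
        hmap = HomologMap([("a1", "b1"), ("a2", "b1"), ("a3", "b3")])
        strict = hmap.one_to_one()
        assert set(strict.a_to_b) == {"a3"}


class TestCrossStudyOverlap:
    def test_subset_of_de_genes(self):
        hmap = HomologMap([(f"a{i}", f"b{i}") for i in range(10)])
        cls = calls({f"a{i}": "UP" for i in range(10)})
        res = cross_study_overlap([f"b{i}" for i in range(10)], cls, set(), hmap)
        assert res["frac_de"] == 1.0 and res["frac_peak"] == 0.0

    def test_planted_fractions_recovered(self):
        n = 100
        hmap = HomologMap([(f"a{i}", f"b{i}") for i in range(n)])
        cls = calls({f"a{i}": ("UP" if i < 31 else "NC") for i in range(n)})
        peak_genes = {f"a{i}" for i in range(22)}
        res = cross_study_overlap([f"b{i}" for i in range(n)], cls, peak_genes, hmap)
        assert res["frac_de"] == pytest.approx(0.31)
        assert res["frac_peak"] == pytest.approx(0.22)
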