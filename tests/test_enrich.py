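import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from fusionchip.enrich import (
    GeneLocus,
    GeneSet,
    assign_peaks_to_genes,
    bh_fdr,
    chipenrich,
    gene_loci,
    lrpath_directional,
    stratified_enrichment,
)
from fusionchip.intervals import GeneModel, GenomicInterval, Peak
from fusionchip.motifs import MotifHit


def de_frame(genes, log2fc, pvalue):
    return pd.DataFrame({"gene_id": genes, "log2fc": log2fc, "pvalue": pvalue})


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.05]) == pytest.approx([0.05])

    def test_hand_computed_step_up(self):
        # all four share q = max-rank minimum: m*p/rank = 0.04 for each
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_empty(self):
        assert len(bh_fdr([])) == 0

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=30))
    def test_monotone_and_order_preserving(self, ps):
        q = bh_fdr(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)
        # permuting input permutes output identically
        perm = np.random.default_rng(0).permutation(len(ps))
        q2 = bh_fdr([ps[i] for i in perm])
        assert np.allclose(np.asarray(q)[perm], q2)


class TestLrpathDirectional:
    def planted(self, rng, n=400, members=50, strength=6.0):
        genes = [f"g{i}" for i in range(n)]
        p = rng.uniform(1e-8, 1, size=n) ** 1  # null-ish
        lfc = rng.normal(0, 1, size=n)
        z = rng.normal(strength, 1, size=members)
        from scipy import stats as sps

        p[:members] = np.clip(2 * sps.norm.sf(np.abs(z)), 1e-300, 1)
        lfc[:members] = np.abs(lfc[:members]) + 0.5
        sets = [GeneSet("planted", "", frozenset(genes[:members])),
                GeneSet("random", "", frozenset(genes[200:250]))]
        return de_frame(genes, lfc, p), sets

    def test_no_signal_gives_null_result(self):
        genes = [f"g{i}" for i in range(50)]
        df = de_frame(genes, [1.0] * 50, [0.5] * 50)
        res = lrpath_directional(df, [GeneSet("s", "", frozenset(genes[:10]))])
        assert res[0].pvalue == pytest.approx(1.0)
        assert res[0].coefficient == 0.0

    def test_planted_induced_set_recovered(self, rng):
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            df, sets = self.planted(rng)
            res = {r.set_id: r for r in lrpath_directional(df, sets)}
            ok = (
                res["planted"].qvalue <= 0.05
                and res["planted"].direction == "induced"
            )
            hits += ok
        assert hits / n_rep >= 0.95

    def test_antisymmetry_under_sign_flip(self, rng):
        df, sets = self.planted(rng)
        res = lrpath_directional(df, sets)
        flipped_df = df.assign(log2fc=-df["log2fc"])
        res_f = lrpath_directional(flipped_df, sets)
        for r, rf in zip(res, res_f):
            assert r.pvalue == pytest.approx(rf.pvalue, rel=1e-9)
            assert r.direction != rf.direction
            assert r.coefficient == pytest.approx(-rf.coefficient, rel=1e-6)

    def test_size_filters(self):
        genes = [f"g{i}" for i in range(600)]
        rng = np.random.default_rng(0)
        df = de_frame(genes, rng.normal(size=600), rng.uniform(0.01, 1, 600))
        sets = [
            GeneSet("too_big", "", frozenset(genes[:501])),
            GeneSet("too_small", "", frozenset(genes[:4])),
            GeneSet("ok", "", frozenset(genes[:50])),
        ]
        res = lrpath_directional(df, sets)
        assert [r.set_id for r in res] == ["ok"]


def loci_frame(lengths, haspeak):
    return [
        GeneLocus(f"g{i}", int(L), int(h))
        for i, (L, h) in enumerate(zip(lengths, haspeak))
    ]


class TestChipenrich:
    def test_equal_lengths_reduce_to_plain_logit(self, rng):
        n = 400
        haspeak = (rng.random(n) < 0.3).astype(int)
        member = rng.random(n) < 0.2
        genes = [f"g{i}" for i in range(n)]
        loci = loci_frame(np.full(n, 25_000), haspeak)
        gs = GeneSet("s", "", frozenset(np.array(genes)[member]))
        res = chipenrich(loci, [gs], spline_df=10)[0]
        X = sm.add_constant(member.astype(float))
        ref = sm.GLM(haspeak.astype(float), X, family=sm.families.Binomial()).fit()
        assert res.coefficient == pytest.approx(float(ref.params[1]), abs=1e-6)

    def test_separation_falls_back_to_penalized_fit(self):
        # every peak-bearing gene is in the set: ML fit separates
        lengths = np.full(60, 10_000)
        haspeak = np.array([1] * 10 + [0] * 50)
        loci = loci_frame(lengths, haspeak)
        gs = GeneSet("s", "", frozenset(f"g{i}" for i in range(10)))
        res = chipenrich(loci, [gs], spline_df=5)[0]
        assert res.note == "firth_fallback"
        assert 0 < res.pvalue <= 1 and np.isfinite(res.coefficient)

    def test_set_size_filter_applies(self, rng):
        n = 600
        loci = loci_frame(rng.integers(5000, 50_000, n), rng.random(n) < 0.3)
        big = GeneSet("big", "", frozenset(f"g{i}" for i in range(501)))
        ok = GeneSet("ok", "", frozenset(f"g{i}" for i in range(40)))
        res = chipenrich(loci, [big, ok])
        assert [r.set_id for r in res] == ["ok"]

    def test_length_confounder_removed(self, rng):
        """Peak presence driven purely by locus length must not look like
        enrichment of a long-gene set once the spline adjusts for length."""
        from fusionchip.stats import ContingencyTable2x2

        n = 500
        n_rep = 120
        naive_rej = adj_rej = 0
        for _ in range(n_rep):
            log_len = rng.normal(4.3, 0.45, size=n)
            p_peak = 1 / (1 + np.exp(-(-2.0 + 1.6 * (log_len - 4.3))))
            haspeak = rng.random(n) < p_peak
            top = np.argsort(log_len)[-50:]
            gs = GeneSet("long", "", frozenset(f"g{i}" for i in top))
            loci = loci_frame(np.round(10 ** log_len), haspeak)
            a = int(haspeak[top].sum())
            rest = np.ones(n, bool)
            rest[top] = False
            c = int(haspeak[rest].sum())
            naive_p = ContingencyTable2x2(a, 50 - a, c, int(rest.sum()) - c).fisher_p
            naive_rej += naive_p < 0.05
            res = chipenrich(loci, [gs], spline_df=10)[0]
            adj_rej += res.pvalue < 0.05
        assert naive_rej / n_rep > 0.4
        assert adj_rej / n_rep < 0.15


def make_gene(gid, chrom, tss, strand="+"):
    if strand == "+":
        exons = ((tss, tss + 200), (tss + 1200, tss + 1500))
        return GeneModel(gid, chrom, strand, tss, tss + 1500, exons,
                         tss + 50, tss + 1400)
    exons = ((tss - 1500 + 1, tss - 1200 + 1), (tss - 200 + 1, tss + 1))
    return GeneModel(gid, chrom, strand, tss - 1500 + 1, tss + 1, exons,
                     tss - 1400 + 1, tss - 50 + 1)


def peak_at(name, chrom, pos):
    return Peak(name, GenomicInterval(chrom, pos - 150, pos + 150), pos)


class TestAssignPeaksToGenes:
    def test_signed_distance_is_strand_aware(self):
        gp = make_gene("gp", "c", 100_000, "+")
        gm = make_gene("gm", "c2", 100_000, "-")
        ap = assign_peaks_to_genes([peak_at("p1", "c", 95_000)], [gp])
        assert ap.loc[0, "distance"] == -5000  # upstream of + gene
        am = assign_peaks_to_genes([peak_at("p2", "c2", 105_000)], [gm])
        assert am.loc[0, "distance"] == -5000  # upstream of - gene

    def test_peaks_without_genes_dropped(self):
        out = assign_peaks_to_genes([peak_at("p", "cX", 1000)], [make_gene("g", "c", 5000)])
        assert out.empty


class TestStratifiedEnrichment:
    def build_scenario(self, rng):
        """Near-TSS motif peaks target an 'induced' set, far-upstream motif
        peaks a 'repressed' set."""
        genes, peaks, hits = [], [], []
        near_set, far_set, bg = [], [], []
        pos = 60_000
        for i in range(180):
            gid = f"g{i:03d}"
            genes.append(make_gene(gid, "c", pos, "+"))
            if i < 60:  # peak 2 kb from TSS, carries the motif
                pk = peak_at(f"pk{i}", "c", pos + 2000)
                peaks.append(pk)
                hits.append(MotifHit(pk.name, 0, "+", 12.0, 1e-6))
                near_set.append(gid)
            elif i < 120:  # peak 15 kb upstream, carries the motif
                pk = peak_at(f"pk{i}", "c", pos - 15_000)
                peaks.append(pk)
                hits.append(MotifHit(pk.name, 0, "+", 12.0, 1e-6))
                far_set.append(gid)
            else:
                bg.append(gid)
            pos += 40_000
        sets = [
            GeneSet("near_targets", "", frozenset(near_set)),
            GeneSet("far_targets", "", frozenset(far_set)),
            GeneSet("background", "", frozenset(bg[:50])),
        ]
        rna = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in genes],
                "log2fc": [
                    1.5 if g.gene_id in near_set
                    else (-1.5 if g.gene_id in far_set else float(rng.normal(0, 0.3)))
                    for g in genes
                ],
                "pvalue": [
                    1e-8 if (g.gene_id in near_set or g.gene_id in far_set)
                    else float(rng.uniform(0.05, 1))
                    for g in genes
                ],
            }
        )
        return genes, peaks, hits, sets, rna

    def test_planted_near_far_dichotomy_recovered(self, rng):
        genes, peaks, hits, sets, rna = self.build_scenario(rng)
        from fusionchip.enrich import lrpath_directional

        rna_res = lrpath_directional(rna, sets)
        res = stratified_enrichment(
            peaks, {"PAX8": hits}, genes, sets, rna_results=rna_res, spline_df=4
        )
        near = {r.set_id: r for r in res.strata[("PAX8", "near")]}
        far = {r.set_id: r for r in res.strata[("PAX8", "far")]}
        assert near["near_targets"].qvalue <= 0.05
        assert near["near_targets"].coefficient > 0
        assert far["far_targets"].qvalue <= 0.05
        assert not (near["far_targets"].qvalue <= 0.05 and near["far_targets"].coefficient > 0)
        joint = res.joint
        row = joint[(joint.zone == "near") & (joint.set_id == "near_targets")]
        assert row["rna_direction"].iloc[0] == "induced"
        row = joint[(joint.zone == "far") & (joint.set_id == "far_targets")]
        assert row["rna_direction"].iloc[0] == "repressed"

    def test_empty_stratum_skipped(self, rng):
        genes, peaks, hits, sets, _ = self.build_scenario(rng)
        near_only = [h for h in hits if int(h.peak_name[2:]) < 60]
        res = stratified_enrichment(peaks, {"PAX8": near_only}, genes, sets, spline_df=4)
        assert ("PAX8", "far") in res.skipped


class TestGeneLoci:
    def test_locus_length_spans_upstream_to_3prime(self):
        g = make_gene("g", "c", 100_000, "+")
        locus = gene_loci([g], ["g", "g"])[0]
        assert locus.locus_length == 10_000 + 1500
        assert locus.n_peaks == 2 and locus.has_peak
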