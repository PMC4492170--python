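"""Region definitions, per-gene summaries, TE and TSS analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methylex as mx
from methylex.io_formats import ValidationError
from tests.conftest import make_track


class TestDefineRegions:
    def test_plus_strand_layout(self):
        gene = mx.GeneRecord("g", "c", "+", [(5000, 7000)])
        r = mx.define_regions(gene, chromosome_length=10_000)
        assert r.upstream == (4000, 5000)
        assert r.body == (5000, 7000)
        assert r.downstream == (7000, 8000)
        assert r.first500 == (5000, 5500)

    def test_minus_strand_mirror(self):
        gene = mx.GeneRecord("g", "c", "-", [(5000, 7000)])
        r = mx.define_regions(gene, chromosome_length=10_000)
        assert r.upstream == (7000, 8000)       # 5' flank in gene orientation
        assert r.downstream == (4000, 5000)
        assert r.first500 == (6500, 7000)

    def test_truncation_at_contig_edges(self):
        gene = mx.GeneRecord("g", "c", "+", [(300, 900)])
        r = mx.define_regions(gene, chromosome_length=1000)
        assert r.upstream == (0, 300)
        assert r.downstream == (900, 1000)

    def test_short_gene_first500_is_whole_body(self):
        gene = mx.GeneRecord("g", "c", "+", [(100, 400)])
        r = mx.define_regions(gene, chromosome_length=10_000)
        assert r.first500 == (100, 400)


class TestRegionMethylation:
    def test_body_pooled_percent(self):
        gene = mx.GeneRecord("g1", "c", "+", [(1000, 2000)])
        rows = [("c", 1000 + i * 100, "+", "CG", m, u)
                for i, (m, u) in enumerate([(1, 1), (2, 0), (0, 2), (1, 1)])]
        track = make_track(rows, genome={"c": "A" * 4000})
        table = mx.region_methylation(track, [gene])
        assert table.loc["g1", "m_cg"] == 50.0

    def test_architecture_fields(self):
        gene = mx.GeneRecord("g1", "c", "+", [(100, 900)])
        track = make_track([("c", 100, "+", "CG", 1, 1)], genome={"c": "A" * 2000})
        table = mx.region_methylation(track, [gene])
        assert table.loc["g1", "l_exon"] == 800
        assert table.loc["g1", "l_intron"] == 0
        assert table.loc["g1", "n_exon"] == 1

    def test_chromosome_mismatch_rejected(self):
        gene = mx.GeneRecord("g1", "chrX", "+", [(0, 100)])
        track = make_track([("chr1", 0, "+", "CG", 1, 1)])
        with pytest.raises(ValidationError, match="chrX"):
            mx.region_methylation(track, [gene])

    def test_values_match_brute_force_for_random_genes(self, bundle,
                                                       bundle_track,
                                                       bundle_regions, rng):
        genes = {g.gene_id: g for g in bundle.genes}
        sample = rng.choice(list(genes), size=50, replace=False)
        for gid in sample:
            g = genes[gid]
            regions = mx.define_regions(
                g, chromosome_length=bundle_track.chromosome_length(g.chromosome))
            for region, prefix in [("upstream", "u"), ("body", "m"),
                                   ("downstream", "d")]:
                lo, hi = regions.interval(region)
                raw = bundle_track.data
                sub = raw[(raw["chromosome"] == g.chromosome)
                          & (raw["position"] >= lo) & (raw["position"] < hi)]
                for ctx in mx.CONTEXTS:
                    s = sub[sub["context"] == ctx]
                    total = (s["count_methylated"] + s["count_unmethylated"]).sum()
                    expected = (100.0 * s["count_methylated"].sum() / total
                                if total else np.nan)
                    got = bundle_regions.loc[gid, f"{prefix}_{ctx.lower()}"]
                    if np.isnan(expected):
                        assert np.isnan(got)
                    else:
                        assert got == pytest.approx(expected, abs=1e-9)

    def test_first500_plus_rest_pools_to_body(self, bundle, bundle_track,
                                              bundle_regions):
        """Count conservation: the body value equals the count-weighted
        combination of the first-500bp and rest-of-body values."""
        for g in bundle.genes[:25]:
            regions = mx.define_regions(
                g, chromosome_length=bundle_track.chromosome_length(g.chromosome))
            body = bundle_track.query(g.chromosome, *regions.body)
            first = bundle_track.query(g.chromosome, *regions.first500)
            for ctx in mx.CONTEXTS:
                b = body[body["context"] == ctx]
                f = first[first["context"] == ctx]
                bm = b["count_methylated"].sum()
                bt = bm + b["count_unmethylated"].sum()
                fm = f["count_methylated"].sum()
                ft = fm + f["count_unmethylated"].sum()
                if bt == 0:
                    continue
                key = ctx.lower()
                assert bundle_regions.loc[g.gene_id, f"m_{key}"] == \
                    pytest.approx(100.0 * bm / bt, abs=1e-9)
                if ft:
                    assert bundle_regions.loc[g.gene_id, f"first500_{key}"] == \
                        pytest.approx(100.0 * fm / ft, abs=1e-9)
                rest_m, rest_t = bm - fm, bt - ft
                recombined = (fm + rest_m) / bt * 100.0
                assert recombined == pytest.approx(
                    bundle_regions.loc[g.gene_id, f"m_{key}"], abs=1e-9)


class TestTEMethylation:
    def _track(self):
        rows = [("c", 10, "+", "CG", 1, 1), ("c", 220, "+", "CG", 3, 1),
                ("c", 500, "+", "CG", 5, 0)]
        return make_track(rows, genome={"c": "A" * 1000})

    def test_short_repeats_excluded(self):
        reps = pd.DataFrame({"chromosome": ["c", "c"], "start": [0, 200],
                             "end": [80, 400], "family": ["f1", "f1"]})
        per_repeat, per_family = mx.te_methylation(self._track(), reps)
        assert len(per_repeat) == 1
        assert per_repeat.iloc[0]["start"] == 200

    def test_family_pooling(self):
        reps = pd.DataFrame({"chromosome": ["c", "c"], "start": [0, 200],
                             "end": [150, 400], "family": ["f1", "f1"]})
        _, per_family = mx.te_methylation(self._track(), reps)
        # copies pool to (1+3) methylated of (2+4) total reads
        assert per_family.iloc[0]["copies"] == 2
        assert per_family.iloc[0]["pct_cg"] == pytest.approx(100 * 4 / 6)

    def test_family_aggregate_equals_pooled_member_counts(self, bundle,
                                                          bundle_track):
        per_repeat, per_family = mx.te_methylation(bundle_track, bundle.repeats)
        fam = per_family.set_index("family")
        lengths = bundle.repeats["end"] - bundle.repeats["start"]
        kept = bundle.repeats[lengths >= 100]
        for family, group in kept.groupby("family"):
            meth = tot = 0
            for _, rep in group.iterrows():
                sub = bundle_track.query(rep["chromosome"], rep["start"], rep["end"])
                s = sub[sub["context"] == "CG"]
                meth += s["count_methylated"].sum()
                tot += (s["count_methylated"] + s["count_unmethylated"]).sum()
            if tot:
                assert fam.loc[family, "pct_cg"] == pytest.approx(
                    100.0 * meth / tot, abs=1e-9)


class TestTSSProfile:
    def test_uniform_track_gives_flat_profile(self):
        rows = [("c", p, "+", "CG", 1, 1) for p in range(0, 6000, 53)]
        gene = mx.GeneRecord("g", "c", "+", [(3000, 5000)])
        track = make_track(rows, genome={"c": "A" * 7000})
        profile = mx.tss_profile(track, [gene])
        covered = profile.data.dropna(subset=["percent"])
        assert (covered["percent"] == 50.0).all()

    def test_minus_strand_profile_mirrors_plus(self):
        """The same asymmetric layout on opposite strands gives the same
        oriented profile."""
        n = 10_000
        plus_rows = [("c", p, "+", "CG", (1 if p >= 5000 else 0), 1)
                     for p in range(3000, 7000, 41)]
        plus = make_track(plus_rows, genome={"c": "A" * n})
        gene_plus = mx.GeneRecord("g", "c", "+", [(5000, 7000)])
        # mirrored layout: methylated sites where position < 5000
        minus_rows = [("c", p, "+", "CG", (1 if p < 5000 else 0), 1)
                      for p in range(3000, 7000, 41)]
        minus = make_track(minus_rows, genome={"c": "A" * n})
        gene_minus = mx.GeneRecord("g", "c", "-", [(3000, 5000)])
        p1 = mx.tss_profile(plus, [gene_plus], flank=1000)
        p2 = mx.tss_profile(minus, [gene_minus], flank=1000)
        a = p1.data[p1.data.context == "CG"]["percent"].to_numpy()
        b = p2.data[p2.data.context == "CG"]["percent"].to_numpy()
        np.testing.assert_allclose(a, b, atol=2.0, equal_nan=True)

    def test_synthetic_dip_minimum_in_first_500bp(self, bundle, bundle_track):
        """The generator's first-500bp CG target sits below the up-stream
        target, so the profile minimum must land inside [0, 500)."""
        profile = mx.tss_profile(bundle_track, bundle.genes, flank=1500)
        cg = profile.data[profile.data.context == "CG"].dropna(subset=["percent"])
        best = cg.loc[cg["percent"].idxmin(), "offset"]
        assert 0 <= best < 500

    def test_requires_genes(self, bundle_track):
        with pytest.raises(ValidationError):
            mx.tss_profile(bundle_track, [])


class TestRegionContrast:
    def test_identical_proportions_not_significant(self):
        rows = ([("c", 900 + i, "+", "CG", 1, 1) for i in range(50)]
                + [("c", 1000 + i, "+", "CG", 1, 1) for i in range(50)])
        gene = mx.GeneRecord("g", "c", "+", [(1000, 3000)])
        track = make_track(rows, genome={"c": "A" * 5000})
        result = mx.region_contrast(track, [gene], "first500", "upstream", "CG")
        assert result.difference == 0.0
        assert result.pvalue == pytest.approx(1.0)

    def test_extreme_difference_significant(self):
        rows = ([("c", 500 + i, "+", "CG", 9, 1) for i in range(100)]
                + [("c", 1000 + i, "+", "CG", 1, 9) for i in range(100)])
        gene = mx.GeneRecord("g", "c", "+", [(1000, 3000)])
        track = make_track(rows, genome={"c": "A" * 5000})
        result = mx.region_contrast(track, [gene], "upstream", "first500", "CG")
        assert result.difference == pytest.approx(80.0)
        assert result.pvalue < 1e-10

    def test_statistic_matches_closed_form_two_proportion_z(self):
        # 50/100 vs 60/100 by hand: pooled p = 0.55
        rows = ([("c", 900, "+", "CG", 50, 50)]
                + [("c", 1100, "+", "CG", 60, 40)])
        gene = mx.GeneRecord("g", "c", "+", [(1000, 3000)])
        track = make_track(rows, genome={"c": "A" * 5000})
        result = mx.region_contrast(track, [gene], "upstream", "first500", "CG")
        pool = 0.55
        z_hand = (0.5 - 0.6) / np.sqrt(pool * (1 - pool) * (2 / 100))
        assert result.statistic == pytest.approx(z_hand)
        assert result.pvalue == pytest.approx(2 * stats.norm.sf(abs(z_hand)))

    def test_zero_coverage_region_rejected(self):
        track = make_track([("c", 1100, "+", "CG", 1, 1)],
                           genome={"c": "A" * 5000})
        gene = mx.GeneRecord("g", "c", "+", [(1000, 3000)])
        with pytest.raises(ValidationError):
            mx.region_contrast(track, [gene], "upstream", "first500", "CG")


class TestCorrelations:
    def test_duplicated_column_has_unit_correlation(self, rng):
        base = rng.random(30) * 100
        table = pd.DataFrame({m: rng.random(30) * 100
                              for m in mx.METHYLATION_MEASURES})
        table["m_cg"] = base
        table["u_cg"] = base
        r, n, p = mx.methylation_correlations(table)
        assert r.loc["m_cg", "u_cg"] == pytest.approx(1.0)
        assert (np.diag(r) == 1.0).all()

    def test_matches_hand_computed_pearson(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        table = pd.DataFrame({m: x for m in mx.METHYLATION_MEASURES})
        table["m_chg"] = y
        r, n, p = mx.methylation_correlations(table)
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        assert r.loc["m_cg", "m_chg"] == pytest.approx(r_hand, abs=1e-12)
        assert n.loc["m_cg", "m_chg"] == 5

    def test_zero_variance_measure_gives_nan(self, rng):
        table = pd.DataFrame({m: rng.random(20) for m in mx.METHYLATION_MEASURES})
        table["d_chh"] = 7.0
        r, n, p = mx.methylation_correlations(table)
        assert np.isnan(r.loc["d_chh", "m_cg"])

    def test_too_few_complete_rows_rejected(self):
        table = pd.DataFrame({m: [1.0, np.nan] for m in mx.METHYLATION_MEASURES})
        with pytest.raises(ValidationError):
            mx.methylation_correlations(table)


class TestChromosomeAnova:
    def _table(self, rng, n_per=60, n_chrom=5, shift=None):
        n = n_per * n_chrom
        table = pd.DataFrame({
            "m_cg": rng.normal(56, 10, n), "m_chg": rng.normal(4, 1, n),
            "m_chh": rng.normal(1.2, 0.3, n),
            "expression": rng.lognormal(2, 1, n),
            "chromosome": np.repeat([f"chr{i}" for i in range(n_chrom)], n_per),
        })
        if shift is not None:
            table.loc[table["chromosome"] == "chr0", "m_cg"] += shift
        return table

    def test_null_f_near_one(self, rng):
        f_values = [mx.chromosome_anova(self._table(rng)).loc["m_cg", "F"]
                    for _ in range(40)]
        # E[F] = df2/(df2-2) ~ 1.007 under the null
        assert np.mean(f_values) == pytest.approx(1.0, abs=0.25)

    def test_shifted_chromosome_detected(self, rng):
        out = mx.chromosome_anova(self._table(rng, shift=50.0))
        assert out.loc["m_cg", "F"] > 50
        assert out.loc["m_cg", "pvalue"] < 1e-6

    def test_two_groups_reduce_to_t_squared(self, rng):
        table = self._table(rng, n_per=40, n_chrom=2)
        out = mx.chromosome_anova(table)
        a = table[table["chromosome"] == "chr0"]["m_cg"]
        b = table[table["chromosome"] == "chr1"]["m_cg"]
        t, _ = stats.ttest_ind(a, b)
        assert out.loc["m_cg", "F"] == pytest.approx(t ** 2, rel=1e-10)

    def test_single_chromosome_rejected(self, rng):
        table = self._table(rng, n_chrom=1)
        with pytest.raises(ValidationError):
            mx.chromosome_anova(table)
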