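"""LD intervals, gene funnel stages, haplotype tests and utilization."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ricegwas.candidates import (
    classify_snp_location,
    expression_filter,
    filter_transposons,
    genes_in_interval,
    genes_with_significant_snps,
    haplotype_analysis,
    haplotype_utilization,
    local_ld_interval,
    screen_candidates,
    LdInterval,
    HaplotypeGroup,
    HaplotypeResult,
)
from ricegwas.containers import GeneModel, GenotypeMatrix
from ricegwas.qtl import QTL


def make_gene(gid="G1", chrom="Chr1", strand="+", start=10_000, end=16_000,
              gene_class="gene", exons=None, utr5=None, utr3=None):
    if exons is None:
        exons = [(start, start + 1000), (start + 3000, end)]
    return GeneModel(gene_id=gid, chrom=chrom, strand=strand, start=start,
                     end=end, gene_class=gene_class, exons=exons,
                     utr5=utr5 or [], utr3=utr3 or [])


def make_qtl(member_pos, lead_pos, population="Full", chrom="Chr1"):
    member_pos = np.asarray(member_pos)
    scores = np.full(member_pos.size, 5.0)
    scores[member_pos == lead_pos] = 9.0
    return QTL(name="qTFC-Full-1-1", population=population, chrom=chrom,
               member_pos=member_pos, member_neg_log10_p=scores,
               lead_pos=lead_pos, lead_neg_log10_p=9.0)


def ld_matrix(blocks, n=80, seed=0):
    """Genotypes where SNPs in one block are near-copies of a template."""
    rng = np.random.default_rng(seed)
    cols, pos = [], []
    p = 1
    for size, flip_rate in blocks:
        template = 2.0 * (rng.random(n) < 0.5)
        for _ in range(size):
            col = template.copy()
            flip = rng.random(n) < flip_rate
            col[flip] = 2.0 - col[flip]
            cols.append(col)
            pos.append(p)
            p += 1000
    return GenotypeMatrix(
        accessions=[f"A{i}" for i in range(n)],
        chrom=np.array(["Chr1"] * len(cols)),
        pos=np.array(pos), ref=np.array(["A"] * len(cols)),
        alt=np.array(["T"] * len(cols)),
        dosages=np.column_stack(cols))


class TestLocalLdInterval:
    def test_only_lead_gives_degenerate_interval(self):
        G = ld_matrix([(1, 0.0)])
        q = make_qtl([1], 1)
        iv = local_ld_interval(q, G)
        assert (iv.left, iv.right, iv.length) == (1, 1, 0)

    def test_run_breaks_at_first_unlinked_snp(self):
        # 11 SNPs: 10 tightly linked to the lead, the 11th independent
        G = ld_matrix([(11, 0.02)], seed=1)
        # make SNP 11 independent of the block
        rng = np.random.default_rng(9)
        G.dosages[:, 10] = 2.0 * (rng.random(80) < 0.5)
        q = make_qtl(G.pos, int(G.pos[0]))
        iv = local_ld_interval(q, G, r2_min=0.6)
        assert iv.right == G.pos[9]
        assert iv.left == G.pos[0]

    def test_interval_always_contains_lead(self):
        G = ld_matrix([(5, 0.05), (5, 0.05)], seed=2)
        q = make_qtl(G.pos, int(G.pos[7]))
        iv = local_ld_interval(q, G, r2_min=0.6)
        assert iv.left <= q.lead_pos <= iv.right

    def test_published_endpoint_arithmetic_265kb(self):
        iv = LdInterval(qtl_name="q", chrom="Chr9", lead_pos=14_300_000,
                        member_pos=np.array([14_210_097, 14_475_412]),
                        r2_to_lead=np.array([1.0, 1.0]),
                        left=14_210_097, right=14_475_412)
        assert iv.length_kb == 265

    def test_monomorphic_lead_rejected(self):
        G = ld_matrix([(3, 0.0)])
        G.dosages[:, 0] = 0.0
        q = make_qtl(G.pos, int(G.pos[0]))
        with pytest.raises(ValueError, match="monomorphic"):
            local_ld_interval(q, G)


class TestGenesInInterval:
    def test_intergenic_gap_is_empty(self):
        genes = [make_gene(start=1000, end=2000, exons=[(1000, 2000)])]
        assert genes_in_interval(genes, "Chr1", (5000, 6000)) == []

    def test_abutting_gene_excluded(self):
        g = make_gene(start=1000, end=2000, exons=[(1000, 2000)])
        assert genes_in_interval([g], "Chr1", (2000, 3000)) == []
        assert genes_in_interval([g], "Chr1", (1999, 3000)) == [g]

    def test_matches_loop_oracle(self, rng):
        genes = [make_gene(gid=f"G{i}", start=s, end=s + 500,
                           exons=[(s, s + 500)])
                 for i, s in enumerate(rng.choice(100_000, 50, replace=False))]
        left, right = 20_000, 60_000
        got = {g.gene_id for g in genes_in_interval(genes, "Chr1",
                                                    (left, right))}
        expected = {g.gene_id for g in genes
                    if max(g.start, left) < min(g.end, right)}
        assert got == expected


class TestFilterTransposons:
    def test_all_transposons_removed(self):
        genes = [make_gene(gid=f"T{i}", gene_class="transposon")
                 for i in range(4)]
        assert filter_transposons(genes) == []

    def test_21_of_22_retained(self):
        genes = [make_gene(gid=f"G{i}", start=1000 * i + 1000,
                           end=1000 * i + 1500,
                           exons=[(1000 * i + 1000, 1000 * i + 1500)])
                 for i in range(22)]
        genes[5].gene_class = "transposon"
        out = filter_transposons(genes)
        assert len(out) == 21
        assert all(g.gene_class == "gene" for g in out)

    def test_idempotent_and_hypothetical_flag(self):
        genes = [make_gene(gid="A"), make_gene(gid="B",
                                               gene_class="hypothetical")]
        once = filter_transposons(genes)
        assert filter_transposons(once) == once
        keep_hyp = filter_transposons(genes, exclude_hypothetical=False)
        assert len(keep_hyp) == 2


class TestClassifySnpLocation:
    @pytest.fixture
    def gene(self):
        return GeneModel(
            gene_id="G", chrom="Chr1", strand="+", start=10_000, end=20_000,
            gene_class="gene",
            exons=[(10_000, 12_000), (15_000, 20_000)],
            utr5=[(10_000, 10_200)], utr3=[(19_800, 20_000)])

    @pytest.mark.parametrize("pos,expected", [
        (11_000, "exon"),
        (13_000, "intron"),
        (10_100, "5'UTR"),
        (19_900, "3'UTR"),
        (9_500, "promoter"),
        (7_999, "outside"),
        (25_000, "outside"),
    ])
    def test_region_classes(self, gene, pos, expected):
        assert classify_snp_location(pos, gene) == expected

    def test_minus_strand_promoter_is_downstream_of_span(self):
        g = GeneModel(gene_id="G", chrom="Chr1", strand="-", start=10_000,
                      end=20_000, gene_class="gene",
                      exons=[(10_000, 20_000)])
        assert classify_snp_location(21_000, g) == "promoter"
        assert classify_snp_location(9_500, g) == "outside"

    def test_matches_interval_membership_oracle(self, gene, rng):
        for pos in rng.integers(7_000, 23_000, size=500):
            got = classify_snp_location(int(pos), gene)
            in_utr5 = any(s <= pos <= e for s, e in gene.utr5)
            in_utr3 = any(s <= pos <= e for s, e in gene.utr3)
            in_exon = any(s <= pos <= e for s, e in gene.exons)
            in_span = gene.start <= pos <= gene.end
            in_prom = gene.start - 2000 <= pos < gene.start
            if in_utr5:
                expected = "5'UTR"
            elif in_utr3:
                expected = "3'UTR"
            elif in_exon:
                expected = "exon"
            elif in_span:
                expected = "intron"
            elif in_prom:
                expected = "promoter"
            else:
                expected = "outside"
            assert got == expected


class TestGenesWithSignificantSnps:
    def test_no_significant_snps_empty(self):
        assert genes_with_significant_snps([make_gene()], np.array([])) == {}

    def test_planted_13_of_21_retained(self, rng):
        genes, sig = [], []
        for i in range(21):
            s = 100_000 * (i + 1)
            g = make_gene(gid=f"G{i}", start=s, end=s + 5000,
                          exons=[(s, s + 5000)])
            genes.append(g)
            if i < 13:
                sig.append(s + 2500)  # inside the gene body
            else:
                sig.append(s + 50_000)  # intergenic
        hits = genes_with_significant_snps(genes, np.array(sig))
        assert set(hits) == {f"G{i}" for i in range(13)}
        assert all(c == ["exon"] for c in hits.values())

    def test_invariant_to_snp_order(self, rng):
        g = make_gene()
        sig = np.array([11_500, 9_000, 15_500])
        h1 = genes_with_significant_snps([g], sig)
        h2 = genes_with_significant_snps([g], sig[::-1])
        assert h1 == h2


class TestExpressionFilter:
    def expr_frame(self, levels):
        rows = []
        for gid, lv in levels.items():
            for tissue in ("ovary", "embryo", "endosperm"):
                rows.append((gid, tissue, 7, lv))
        return pd.DataFrame(rows, columns=["gene_id", "tissue", "timepoint",
                                           "level"])

    def test_all_zero_gene_excluded(self):
        genes = [make_gene(gid="Z")]
        kept, classes = expression_filter(genes, self.expr_frame({"Z": 0.0}))
        assert kept == [] and classes["Z"] == "none"

    def test_high_gene_retained(self):
        genes = [make_gene(gid="H")]
        kept, classes = expression_filter(genes, self.expr_frame({"H": 50.0}))
        assert kept == genes and classes["H"] == "high"

    def test_13_reduce_to_3(self):
        levels = {f"G{i}": 0.0 for i in range(13)}
        levels["G0"], levels["G1"] = 60.0, 40.0  # high
        levels["G2"] = 10.0                       # moderate
        levels["G3"], levels["G4"] = 2.0, 3.0     # low -> excluded
        genes = [make_gene(gid=f"G{i}", start=1000 + 10_000 * i,
                           end=6000 + 10_000 * i,
                           exons=[(1000 + 10_000 * i, 6000 + 10_000 * i)])
                 for i in range(13)]
        kept, classes = expression_filter(genes, self.expr_frame(levels))
        assert {g.gene_id for g in kept} == {"G0", "G1", "G2"}
        assert classes["G2"] == "moderate" and classes["G3"] == "low"

    def test_unmeasured_gene_retained_with_warning(self):
        genes = [make_gene(gid="U")]
        with pytest.warns(UserWarning, match="absent"):
            kept, classes = expression_filter(genes, self.expr_frame({}))
        assert kept == genes and classes["U"] == "unmeasured"


class TestHaplotypeAnalysis:
    def build_panel(self, dosage_col, n=60):
        pos = np.array([12_000])
        return GenotypeMatrix(
            accessions=[f"A{i}" for i in range(n)],
            chrom=np.array(["Chr1"]), pos=pos,
            ref=np.array(["A"]), alt=np.array(["T"]),
            dosages=np.asarray(dosage_col, dtype=float).reshape(n, 1))

    def pheno_frame(self, values, subpop="japonica"):
        return pd.DataFrame({
            "accession": [f"A{i}" for i in range(len(values))],
            "mean_tfc": values,
            "subpop": subpop,
        })

    def test_single_haplotype_not_significant(self):
        G = self.build_panel([0.0] * 60)
        res = haplotype_analysis(make_gene(), np.array([12_000]), G,
                                 self.pheno_frame(np.linspace(100, 200, 60)))
        assert len(res.groups) == 1
        assert not res.significant and len(res.tests) == 0

    def test_t_statistic_matches_textbook_formula(self):
        # 30 vs 30 accessions with a clear mean shift
        dos = [0.0] * 30 + [2.0] * 30
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(120, 10, 30),
                               rng.normal(160, 10, 30)])
        G = self.build_panel(dos)
        res = haplotype_analysis(make_gene(), np.array([12_000]), G,
                                 self.pheno_frame(vals), min_group_n=5)
        t_ref, p_ref = stats.ttest_ind(vals[:30], vals[30:])
        (row,) = res.tests.itertuples(index=False)
        assert abs(row.t) == pytest.approx(abs(t_ref), rel=1e-10)
        assert row.p == pytest.approx(p_ref, rel=1e-10)
        assert res.significant

    def test_small_groups_dropped(self):
        dos = [0.0] * 55 + [2.0] * 5
        G = self.build_panel(dos)
        res = haplotype_analysis(make_gene(), np.array([12_000]), G,
                                 self.pheno_frame(np.linspace(90, 430, 60)),
                                 min_group_n=10)
        assert len(res.groups) == 1

    def test_heterozygous_calls_excluded(self):
        dos = [0.0] * 30 + [1.0] * 30
        G = self.build_panel(dos)
        res = haplotype_analysis(make_gene(), np.array([12_000]), G,
                                 self.pheno_frame(np.linspace(90, 430, 60)),
                                 min_group_n=5)
        assert sum(g.n for g in res.groups) == 30

    def test_planted_effect_detected_with_power(self):
        # haplotype split of one phenotypic SD: detected in >= 90% of seeds
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            dos = np.repeat([0.0, 2.0], 125)
            vals = np.where(dos == 2.0, 150.0, 130.0) + rng.normal(0, 20, 250)
            G = self.build_panel(dos, n=250)
            res = haplotype_analysis(make_gene(), np.array([12_000]), G,
                                     self.pheno_frame(vals))
            hits += res.significant
        assert hits >= 18


class TestHaplotypeUtilization:
    def make_result(self, hap1_ids, hap2_ids):
        g1 = HaplotypeGroup("G", (1,), "A", hap1_ids, {})
        g2 = HaplotypeGroup("G", (1,), "B", hap2_ids, {})
        return HaplotypeResult("G", [g1, g2], pd.DataFrame(), False)

    def test_toy_32_and_9_percent(self):
        # 25 landraces of which 8 carry Hap1; 11 improved of which 1 does
        land = [f"L{i}" for i in range(25)]
        imp = [f"I{i}" for i in range(11)]
        hap1 = land[:8] + imp[:1]
        hap2 = land[8:] + imp[1:]
        res = self.make_result(hap1, hap2)
        meta = pd.DataFrame({
            "accession": land + imp,
            "improvement_status": ["landrace"] * 25 + ["improved"] * 11,
        })
        out = haplotype_utilization(res, meta)
        get = lambda h, c: out.loc[(out.haplotype == h) &
                                   (out.category == c), "percent"].iloc[0]
        assert get("Hap1", "landrace") == 32.0
        assert get("Hap1", "improved") == 9.0

    def test_single_haplotype_everywhere_100_percent(self):
        ids = [f"A{i}" for i in range(10)]
        res = HaplotypeResult(
            "G", [HaplotypeGroup("G", (1,), "A", ids, {})],
            pd.DataFrame(), False)
        meta = pd.DataFrame({"accession": ids,
                             "improvement_status": ["landrace"] * 6
                             + ["improved"] * 4})
        out = haplotype_utilization(res, meta)
        assert (out["percent"] == 100.0).all()

    def test_percentages_sum_to_100_per_category(self):
        land = [f"L{i}" for i in range(17)]
        res = self.make_result(land[:5], land[5:])
        meta = pd.DataFrame({"accession": land,
                             "improvement_status": ["landrace"] * 17})
        out = haplotype_utilization(res, meta)
        total = out.groupby("category")["percent"].sum()
        assert ((total - 100.0).abs() <= 1.0).all()


class TestScreenCandidates:
    def test_all_transposon_annotation_yields_no_candidates(self):
        G = ld_matrix([(6, 0.02)], seed=3)
        q = make_qtl(G.pos, int(G.pos[2]))
        genes = [make_gene(gid=f"T{i}", gene_class="transposon",
                           start=1000 * i + 500, end=1000 * i + 900,
                           exons=[(1000 * i + 500, 1000 * i + 900)])
                 for i in range(3)]
        pheno = pd.DataFrame({
            "accession": G.accessions,
            "mean_tfc": np.linspace(90, 430, G.n_accessions),
            "subpop": "japonica"})
        expr = pd.DataFrame(columns=["gene_id", "tissue", "timepoint",
                                     "level"])
        rep = screen_candidates(q, G, G.pos, genes, expr, pheno)
        assert (rep["verdict"] != "candidate").all()
        assert (rep["first_fail"] == "transposon").all()

    def test_funnel_stage_counts_non_increasing(self, causal_panel):
        from ricegwas.simdata import simulate_annotation, simulate_expression
        cfg, G, labels, pheno, _ = causal_panel
        from ricegwas.structure import filter_snps, kinship, pca
        from ricegwas import gwas, qtl as qtl_mod
        Gq, _ = filter_snps(G)
        y = pheno["mean_tfc"].to_numpy()
        K = kinship(Gq)
        Q = pca(Gq, 3).coordinates
        assoc = gwas.associate(Gq, y, Q, K)
        sig = qtl_mod.significant_snps(assoc, 4.0)
        qtls = qtl_mod.call_qtls(sig)
        assert qtls, "expected at least one QTL around the planted SNP"
        target = max(qtls, key=lambda q: q.lead_neg_log10_p)
        genes = simulate_annotation(cfg, gene_density=20, seed=50)
        expr = simulate_expression(genes, seed=51)
        sig_pos = sig.loc[sig["chrom"] == target.chrom,
                          "pos"].to_numpy(dtype=np.int64)
        rep = screen_candidates(target, Gq, sig_pos, genes, expr, pheno)
        order = ["transposon", "sig_snp", "expression", "haplotype", ""]
        counts = rep["first_fail"].value_counts()
        survivors = [len(rep)]
        for stage in order[:-1]:
            survivors.append(survivors[-1] - counts.get(stage, 0))
        assert all(a >= b for a, b in zip(survivors, survivors[1:]))
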