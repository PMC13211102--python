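"""Gene overlap, codon-level effect classification, prioritization, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from scipy import stats as sps

from bsakit import (
    CandidateRegion,
    GeneModel,
    classify_effect,
    classify_variants,
    genes_in_regions,
    hypergeometric_enrichment,
    prioritize_candidates,
    read_gff3,
    reference_sequences,
    simulate_companion_tables,
    write_gff3,
)

from conftest import make_variant


@pytest.fixture(scope="module")
def toy_reference():
    rng = np.random.default_rng(123)
    seq = list("ACGT"[i] for i in rng.integers(0, 4, 200))
    # plus-strand CDS exon 1 starts with codons AAA CCC GGG TTT ACG
    seq[20:35] = list("AAACCCGGGTTTACG")
    seq[50:65] = list("ATGAAACCCGGGTTT")
    return {"c": "".join(seq)}


@pytest.fixture(scope="module")
def plus_gene():
    return GeneModel("gp", "c", 10, 100, "+", ((20, 35, 0), (50, 65, 0)))


@pytest.fixture(scope="module")
def minus_gene():
    return GeneModel("gm", "c", 110, 190, "-", ((120, 135, 0), (150, 165, 0)))


def snp(pos, ref, alt, chrom="c"):
    return make_variant(chrom=chrom, pos=pos, ref=ref, alt=alt)


class TestClassifyEffect:
    def test_synonymous_codon(self, toy_reference, plus_gene):
        # AAA -> AAG, both Lys (third codon base at 0-based 22)
        eff = classify_effect(snp(23, "A", "G"), plus_gene, toy_reference)
        assert eff.effect == "synonymous"

    def test_nonsynonymous_codon(self, toy_reference, plus_gene):
        # AAA -> GAA, Lys -> Glu
        eff = classify_effect(snp(21, "A", "G"), plus_gene, toy_reference)
        assert eff.effect == "nonsynonymous"

    def test_intronic_snp_noncoding(self, toy_reference, plus_gene):
        eff = classify_effect(snp(41, toy_reference["c"][40], "A" if toy_reference["c"][40] != "A" else "C"),
                              plus_gene, toy_reference)
        assert eff.effect == "noncoding"

    def test_intergenic(self, toy_reference, plus_gene):
        base = toy_reference["c"][5]
        eff = classify_effect(snp(6, base, "A" if base != "A" else "C"), None, toy_reference)
        assert eff.effect == "intergenic" and eff.gene_id is None

    def test_frameshift_and_inframe_deletions(self, toy_reference, plus_gene):
        s = toy_reference["c"]
        two_bp = make_variant(chrom="c", pos=22, ref=s[21:24], alt=s[21])
        three_bp = make_variant(chrom="c", pos=22, ref=s[21:25], alt=s[21])
        assert classify_effect(two_bp, plus_gene, toy_reference).effect == "frameshift"
        assert classify_effect(three_bp, plus_gene, toy_reference).effect == "inframe_indel"

    def test_insertion_frameshift(self, toy_reference, plus_gene):
        s = toy_reference["c"]
        ins = make_variant(chrom="c", pos=22, ref=s[21], alt=s[21] + "AT")
        assert classify_effect(ins, plus_gene, toy_reference).effect == "frameshift"

    def test_indel_spanning_cds_boundary_is_noncoding(self, toy_reference, plus_gene):
        s = toy_reference["c"]
        # deletion removing bases 34..37 (0-based): crosses the exon1 end at 35
        v = make_variant(chrom="c", pos=34, ref=s[33:38], alt=s[33])
        assert classify_effect(v, plus_gene, toy_reference).effect == "noncoding"

    def test_ref_mismatch_raises(self, toy_reference, plus_gene):
        wrong = "C" if toy_reference["c"][20] != "C" else "G"
        with pytest.raises(ValueError, match="c:21"):
            classify_effect(snp(21, wrong, "A"), plus_gene, toy_reference)

    def test_minus_strand_uses_complement(self, toy_reference, minus_gene):
        """On the minus strand the mRNA codon change is evaluated on the
        reverse complement; the genomic alt base must be complemented."""
        seq = toy_reference["c"]
        # the last base of the plus-order CDS (0-based 164) is the first mRNA base
        pos0 = 164
        ref_base = seq[pos0]
        alt_base = "A" if ref_base != "A" else "G"
        eff = classify_effect(snp(pos0 + 1, ref_base, alt_base), minus_gene, toy_reference)
        # oracle: full spliced translation before/after
        plus = seq[120:135] + seq[150:165]
        mrna_before = str(Seq(plus).reverse_complement())
        mutated = seq[:pos0] + alt_base + seq[pos0 + 1 :]
        mrna_after = str(Seq(mutated[120:135] + mutated[150:165]).reverse_complement())
        same = Seq(mrna_before).translate() == Seq(mrna_after).translate()
        assert eff.effect == ("synonymous" if same else "nonsynonymous")

    def test_strand_symmetry_under_genome_mirroring(self, toy_reference, plus_gene):
        """Mirroring the chromosome (reverse complement) and flipping the
        gene to the minus strand leaves every SNP's effect class unchanged."""
        seq = toy_reference["c"]
        L = len(seq)
        mirrored = {"c": str(Seq(seq).reverse_complement())}
        mgene = GeneModel(
            "gp_m", "c", L - plus_gene.end, L - plus_gene.start, "-",
            tuple((L - e, L - s, ph) for s, e, ph in reversed(plus_gene.cds_segments)),
        )
        for pos0 in range(20, 35):
            ref_base = seq[pos0]
            alt_base = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref_base]
            fwd = classify_effect(snp(pos0 + 1, ref_base, alt_base), plus_gene, toy_reference)
            mpos0 = L - 1 - pos0
            mref = str(Seq(ref_base).complement())
            malt = str(Seq(alt_base).complement())
            rev = classify_effect(snp(mpos0 + 1, mref, malt), mgene, mirrored)
            assert fwd.effect == rev.effect


def test_classification_matches_whole_cds_translation_oracle(small_config, small_sim):
    """On ~1000 random simulated SNPs, the codon-level classifier agrees with
    a brute-force oracle that translates the entire CDS before and after."""
    _, truth = small_sim
    reference = reference_sequences(small_config)
    comp = simulate_companion_tables(small_config, truth)
    genes = comp.genes
    rng = np.random.default_rng(99)
    seq = reference["chr1"]

    variants, expected = [], []
    for _ in range(1000):
        g = genes[rng.integers(0, len(genes))]
        pos0 = int(rng.integers(g.start, g.end))
        ref_base = seq[pos0]
        alt_base = "ACGT"[(("ACGT".index(ref_base)) + int(rng.integers(1, 4))) % 4]
        variants.append(make_variant(chrom="chr1", pos=pos0 + 1, ref=ref_base, alt=alt_base))

        in_cds = any(s <= pos0 < e for s, e, _ in g.cds_segments)
        if not in_cds:
            expected.append("noncoding")
            continue
        plus = "".join(seq[s:e] for s, e, _ in g.cds_segments)
        mutated = seq[:pos0] + alt_base + seq[pos0 + 1 :]
        plus_mut = "".join(mutated[s:e] for s, e, _ in g.cds_segments)
        if g.strand == "-":
            plus, plus_mut = (str(Seq(x).reverse_complement()) for x in (plus, plus_mut))
        same = Seq(plus).translate() == Seq(plus_mut).translate()
        expected.append("synonymous" if same else "nonsynonymous")

    table = classify_variants(variants, genes, reference)
    assert list(table["effect"]) == expected
    assert (table["gene_id"].notna()).all()


def test_gff3_roundtrip(tmp_path, small_config, small_sim):
    _, truth = small_sim
    comp = simulate_companion_tables(small_config, truth)
    p = tmp_path / "genes.gff3"
    write_gff3(comp.genes[:20], str(p))
    back = read_gff3(str(p))
    assert back == sorted(comp.genes[:20], key=lambda g: (g.chrom, g.start, g.gene_id))


class TestGenesInRegions:
    regions = [CandidateRegion("chr1", 0, 1_000_000)]

    def test_gene_inside(self):
        genes = [GeneModel("a", "chr1", 10_000, 12_000, "+")]
        assert genes_in_regions(self.regions, genes) == ["a"]

    def test_gene_straddling_boundary_included(self):
        genes = [GeneModel("a", "chr1", 999_000, 1_002_000, "+")]
        assert genes_in_regions(self.regions, genes) == ["a"]
        assert genes_in_regions(self.regions, genes, containment=True) == []

    def test_gene_on_other_chromosome_excluded(self):
        genes = [GeneModel("a", "chr2", 10, 100, "+")]
        assert genes_in_regions(self.regions, genes) == []

    def test_gene_reported_once(self):
        regions = [CandidateRegion("chr1", 0, 100), CandidateRegion("chr1", 200, 300)]
        genes = [GeneModel("a", "chr1", 50, 250, "+")]
        assert genes_in_regions(regions, genes) == ["a"]


class TestPrioritize:
    def _effects(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "variant_type",
                                           "gene_id", "effect"])

    def test_sort_contract_and_primary_flags(self):
        parents = self._effects([
            ("c", 1, "A", "G", "SNP", "g_nonsyn", "nonsynonymous"),
            ("c", 2, "A", "G", "SNP", "g_nonsyn", "nonsynonymous"),
            ("c", 3, "AT", "A", "InDel", "g_frameshift", "frameshift"),
            ("c", 4, "A", "G", "SNP", "g_silent", "synonymous"),
        ])
        out = prioritize_candidates(["g_nonsyn", "g_frameshift", "g_silent"],
                                    {"parents": parents})
        assert list(out["gene_id"]) == ["g_frameshift", "g_nonsyn", "g_silent"]
        assert list(out["primary"]) == [True, True, False]

    def test_counts_match_bruteforce_recount(self, rng):
        genes = [f"g{i}" for i in range(20)]
        rows = [
            ("c", i, "A", "G", "SNP", genes[rng.integers(0, 20)],
             ["synonymous", "nonsynonymous", "frameshift", "noncoding"][rng.integers(0, 4)])
            for i in range(300)
        ]
        eff = {"parents": self._effects(rows[:200]), "bulks": self._effects(rows[200:])}
        out = prioritize_candidates(genes, eff).set_index("gene_id")
        for label, table in eff.items():
            for g in genes:
                sub = table[table["gene_id"] == g]
                assert out.loc[g, f"nonsyn_{label}"] == (sub["effect"] == "nonsynonymous").sum()
                assert out.loc[g, f"frameshift_{label}"] == (sub["effect"] == "frameshift").sum()


class TestEnrichment:
    def _map(self, pairs):
        return pd.DataFrame(pairs, columns=["gene_id", "term_id"])

    def test_exact_extreme_case(self):
        """All 5 candidates carry the term held by 5 of 20 background genes:
        p = 1 / C(20,5) = 1/15504."""
        bg = [f"g{i}" for i in range(20)]
        cand = bg[:5]
        tm = self._map([(g, "T") for g in bg[:5]])
        res = hypergeometric_enrichment(cand, bg, tm)
        assert res["p_value"].iloc[0] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_candidates_equal_background_gives_p_one(self):
        bg = [f"g{i}" for i in range(10)]
        tm = self._map([(g, "T") for g in bg[:4]] + [(g, "U") for g in bg[4:]])
        res = hypergeometric_enrichment(bg, bg, tm)
        assert np.allclose(res["p_value"], 1.0)

    def test_zero_overlap_gives_p_one(self):
        bg = [f"g{i}" for i in range(10)]
        tm = self._map([("g9", "T")])
        res = hypergeometric_enrichment(bg[:3], bg, tm)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_candidate_outside_background_errors(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(["x"], ["a", "b"], self._map([("a", "T")]))

    def test_fdr_preserves_p_ordering(self):
        bg = [f"g{i}" for i in range(50)]
        rngl = np.random.default_rng(5)
        tm = self._map([(bg[rngl.integers(0, 50)], f"T{j}") for j in range(200)])
        res = hypergeometric_enrichment(bg[:10], bg, tm)
        assert (res["fdr"] >= res["p_value"] - 1e-12).all()
        assert res["p_value"].is_monotonic_increasing

    def test_p_values_uniform_under_random_candidates(self):
        """Upper-tail hypergeometric p-values are calibrated under random
        candidate draws: after smoothing the discrete lattice with the
        standard randomization p* = P[X > k] + U*P[X = k], the p-values are
        exactly uniform, so the KS test should not reject."""
        rngl = np.random.default_rng(17)
        bg = [f"g{i}" for i in range(2000)]
        tm = self._map([(g, "T") for g in bg[:1000]])
        pvals = []
        for _ in range(1000):
            cand = rngl.choice(bg, size=200, replace=False)
            row = hypergeometric_enrichment(cand, bg, tm).iloc[0]
            pmf = sps.hypergeom.pmf(row["k"], row["N"], row["K"], row["n"])
            pvals.append(row["p_value"] - rngl.uniform() * pmf)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01
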