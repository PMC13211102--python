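"""Gene models, coding-effect classification, prioritization and enrichment.

Candidate regions are overlapped with gene models (any-overlap rule: a gene
is a candidate if it shares at least 1 bp with a region; ``containment=True``
restores the strict located-within reading). Variants are classified at the
codon level: SNPs inside CDS are synonymous or nonsynonymous (stop gains and
losses fold into nonsynonymous), coding InDels are frameshift when the net
length change is not a multiple of 3 and in-frame otherwise, and everything
else is noncoding (inside a gene) or intergenic. Genes carrying at least one
nonsynonymous or frameshift variant are flagged as primary candidates.

Enrichment of candidate gene sets against user-supplied gene-to-term maps
uses the upper-tail hypergeometric test with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import gffutils
from Bio.Seq import Seq
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .regions import CandidateRegion
from .variants import VariantRecord

logger = logging.getLogger(__name__)

EFFECTS = (
    "synonymous",
    "nonsynonymous",
    "frameshift",
    "inframe_indel",
    "noncoding",
    "intergenic",
)


@dataclass(frozen=True)
class GeneModel:
    """A gene with an ordered set of CDS segments (0-based half-open).

    ``cds_segments`` are (start, end, phase) tuples in genomic order; for
    minus-strand genes the transcription order is the reverse.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_segments: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        prev_end = self.start
        total = 0
        for s, e, _ in self.cds_segments:
            if s < prev_end or e > self.end:
                raise ValueError(f"{self.gene_id}: CDS segments overlap or exceed gene bounds")
            total += e - s
            prev_end = e
        if self.cds_segments and total < 3:
            raise ValueError(f"{self.gene_id}: total CDS length must be >= 3")


@dataclass(frozen=True)
class VariantEffect:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str | None
    effect: str


def read_gff3(path: str) -> list[GeneModel]:
    """Read gene models from GFF3. Only the first mRNA per gene is used."""
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        mrnas = sorted(db.children(g, featuretype="mRNA"), key=lambda f: f.id)
        parent = mrnas[0] if mrnas else g
        cds = sorted(db.children(parent, featuretype="CDS"), key=lambda f: f.start)
        segs = tuple(
            (c.start - 1, c.end, int(c.frame) if c.frame not in (None, ".") else 0)
            for c in cds
        )
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand if g.strand in "+-" else "+",
                cds_segments=segs,
            )
        )
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))


def genes_in_regions(
    regions: list[CandidateRegion],
    genes: list[GeneModel],
    containment: bool = False,
) -> list[str]:
    """Gene ids overlapping any region by >= 1 bp (each reported once).

    With ``containment=True`` a gene must lie entirely within one region.
    """
    by_chrom: dict[str, list[CandidateRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    out: list[str] = []
    seen = set()
    for g in genes:
        for r in by_chrom.get(g.chrom, ()):
            hit = (
                (r.start <= g.start and g.end <= r.end)
                if containment
                else (g.start < r.end and r.start < g.end)
            )
            if hit and g.gene_id not in seen:
                seen.add(g.gene_id)
                out.append(g.gene_id)
                break
    return out


def _spliced_cds(gene: GeneModel, seq: str) -> str:
    """mRNA-orientation CDS sequence from a chromosome sequence."""
    plus = "".join(seq[s:e] for s, e, _ in gene.cds_segments)
    return plus if gene.strand == "+" else str(Seq(plus).reverse_complement())


def _cds_offset(gene: GeneModel, pos0: int) -> int | None:
    """Offset of genomic position ``pos0`` within the mRNA-orientation CDS."""
    off = 0
    hit = None
    for s, e, _ in gene.cds_segments:
        if s <= pos0 < e:
            hit = off + (pos0 - s)
        off += e - s
    if hit is None:
        return None
    return hit if gene.strand == "+" else off - 1 - hit


def _first_phase(gene: GeneModel) -> int:
    if not gene.cds_segments:
        return 0
    seg = gene.cds_segments[0] if gene.strand == "+" else gene.cds_segments[-1]
    return seg[2]


def classify_effect(
    variant: VariantRecord,
    gene: GeneModel | None,
    reference: Mapping[str, str],
) -> VariantEffect:
    """Codon-level effect of one variant on one gene model.

    Raises ``ValueError`` if the variant REF allele disagrees with the
    reference sequence. InDels whose changed bases straddle a CDS boundary
    are conservatively classified noncoding with a warning (documented
    limitation).
    """
    seq = reference[variant.chrom]
    pos0 = variant.pos - 1
    if seq[pos0 : pos0 + len(variant.ref)].upper() != variant.ref.upper():
        raise ValueError(
            f"REF allele mismatch at {variant.chrom}:{variant.pos} "
            f"(VCF {variant.ref!r} vs reference {seq[pos0:pos0 + len(variant.ref)]!r})"
        )

    def make(effect: str, gene_id: str | None) -> VariantEffect:
        return VariantEffect(
            variant.chrom, variant.pos, variant.ref, variant.alt, gene_id, effect
        )

    span_end = pos0 + len(variant.ref)
    if gene is None or gene.chrom != variant.chrom or span_end <= gene.start or pos0 >= gene.end:
        return make("intergenic", None)

    if variant.variant_type == "SNP":
        off = _cds_offset(gene, pos0)
        if off is None:
            return make("noncoding", gene.gene_id)
        phase = _first_phase(gene)
        if off < phase:
            return make("noncoding", gene.gene_id)
        cds = _spliced_cds(gene, seq)
        alt_base = variant.alt if gene.strand == "+" else str(Seq(variant.alt).complement())
        codon_start = phase + 3 * ((off - phase) // 3)
        codon = cds[codon_start : codon_start + 3]
        if len(codon) < 3:
            return make("noncoding", gene.gene_id)
        within = off - codon_start
        alt_codon = codon[:within] + alt_base + codon[within + 1 :]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(alt_codon).translate())
        return make("synonymous" if aa_ref == aa_alt else "nonsynonymous", gene.gene_id)

    # InDel: changed interval is the anchor-excluded REF span for deletions,
    # or the insertion point (between pos0 and pos0+1) for insertions.
    if len(variant.ref) > len(variant.alt):
        lo, hi = pos0 + 1, pos0 + len(variant.ref)
    else:
        lo, hi = pos0, pos0 + 1
    in_cds = [(s, e) for s, e, _ in gene.cds_segments if lo < e and s < hi]
    if not in_cds:
        return make("noncoding", gene.gene_id)
    s, e = in_cds[0]
    fully_inside = len(in_cds) == 1 and s <= lo and hi <= e
    if not fully_inside:
        logger.warning(
            "InDel at %s:%d spans a CDS boundary; classified noncoding",
            variant.chrom, variant.pos,
        )
        return make("noncoding", gene.gene_id)
    shift = abs(len(variant.ref) - len(variant.alt)) % 3
    return make("frameshift" if shift != 0 else "inframe_indel", gene.gene_id)


def classify_variants(
    variants: Iterable[VariantRecord],
    genes: list[GeneModel],
    reference: Mapping[str, str],
) -> pd.DataFrame:
    """Effect table for a variant set.

    Each variant is assigned to the first overlapping gene (by start, then
    id) or classified intergenic. Columns: chrom, pos, ref, alt,
    variant_type, gene_id, effect.
    """
    trees: dict[str, IntervalTree] = {}
    gene_by_key: dict[tuple, GeneModel] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
        gene_by_key[(g.chrom, g.gene_id)] = g
    rows = []
    for v in variants:
        tree = trees.get(v.chrom)
        gene = None
        if tree is not None:
            hits = sorted(tree.overlap(v.pos - 1, v.pos - 1 + len(v.ref)),
                          key=lambda iv: (iv.begin, iv.data))
            if hits:
                gene = gene_by_key[(v.chrom, hits[0].data)]
        eff = classify_effect(v, gene, reference)
        rows.append(
            (v.chrom, v.pos, v.ref, v.alt, v.variant_type, eff.gene_id, eff.effect)
        )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "variant_type", "gene_id", "effect"]
    )


HIGH_IMPACT = ("nonsynonymous", "frameshift")


def prioritize_candidates(
    candidate_genes: Iterable[str],
    effects_by_set: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Per-gene high-impact variant counts across contrast sets.

    ``effects_by_set`` maps a set label (e.g. ``"parents"``, ``"bulks"``) to
    an effect table from :func:`classify_variants`. Genes with at least one
    nonsynonymous or frameshift variant in any set are flagged ``primary``;
    the table is sorted by (frameshift count, nonsynonymous count)
    descending, then gene id.
    """
    genes = sorted(set(candidate_genes))
    out = pd.DataFrame({"gene_id": genes}).set_index("gene_id")
    for label, eff in effects_by_set.items():
        sub = eff[eff["gene_id"].isin(genes)]
        for effect, short in (("nonsynonymous", "nonsyn"), ("frameshift", "frameshift")):
            counts = sub[sub["effect"] == effect].groupby("gene_id").size()
            out[f"{short}_{label}"] = counts.reindex(genes).fillna(0).astype(int)
    nonsyn_cols = [c for c in out.columns if c.startswith("nonsyn_")]
    fs_cols = [c for c in out.columns if c.startswith("frameshift_")]
    out["nonsyn_total"] = out[nonsyn_cols].sum(axis=1) if nonsyn_cols else 0
    out["frameshift_total"] = out[fs_cols].sum(axis=1) if fs_cols else 0
    out["primary"] = (out["nonsyn_total"] + out["frameshift_total"]) > 0
    out = out.reset_index().sort_values(
        ["frameshift_total", "nonsyn_total", "gene_id"],
        ascending=[False, False, True],
        kind="stable",
        ignore_index=True,
    )
    return out


def hypergeometric_enrichment(
    candidate_genes: Iterable[str],
    background_genes: Iterable[str],
    term_map: pd.DataFrame,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric term enrichment with BH-FDR.

    ``term_map`` is a two-column table (gene_id, term_id). For each term:
    N = background size, K = background genes with the term, n = candidate
    size, k = candidate genes with the term, and
    p = P[X >= k], X ~ Hypergeometric(N, K, n).
    """
    cand = set(candidate_genes)
    bg = set(background_genes)
    if not cand <= bg:
        missing = sorted(cand - bg)[:5]
        raise ValueError(f"candidate genes absent from background: {missing}...")
    tm = term_map[term_map["gene_id"].isin(bg)]
    N, n = len(bg), len(cand)
    rows = []
    for term, grp in tm.groupby("term_id", sort=True):
        term_genes = set(grp["gene_id"])
        K = len(term_genes)
        k = len(term_genes & cand)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, p))
    df = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p_value"])
    if len(df):
        df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["fdr"] = []
    df["significant"] = df["fdr"] < fdr_alpha
    return df.sort_values(["p_value", "term_id"], kind="stable", ignore_index=True)
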