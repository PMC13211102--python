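"""Variant records and VCF input/output.

A :class:`VariantRecord` is one biallelic site with the GATK-style quality
annotations used for hard filtering (QUAL, QD, MQ, FS) and per-sample
genotype/allele-depth calls for the four samples of a BSA-seq design:
the two parents and the two phenotypic bulks.

Sample *roles* are the keys ``parent_wt``, ``parent_mut``, ``bulk_low`` and
``bulk_high``; the mapping from VCF sample names to roles is supplied when
reading (see :func:`read_vcf`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from cyvcf2 import VCF

ROLES = ("parent_wt", "parent_mut", "bulk_low", "bulk_high")

#: Default VCF sample names emitted by the simulator, keyed by role.
DEFAULT_SAMPLE_NAMES = {
    "parent_wt": "HN48_CK",
    "parent_mut": "LSD914_CK",
    "bulk_low": "MSN_F",
    "bulk_high": "MSN_M",
}


@dataclass(frozen=True)
class SampleCall:
    """Genotype and allele depths for one sample at one site.

    ``genotype`` is a pair of allele indices (0 = REF, 1 = ALT) or ``None``
    when the call is missing.
    """

    genotype: tuple[int, int] | None
    ref_depth: int
    alt_depth: int

    @property
    def total_depth(self) -> int:
        return self.ref_depth + self.alt_depth

    def is_hom(self, allele: int) -> bool:
        return self.genotype is not None and self.genotype == (allele, allele)


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float | None = None
    qd: float | None = None
    mq: float | None = None
    fs: float | None = None
    n_alt_alleles: int = 1
    samples: dict[str, SampleCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"1-based position must be >= 1, got {self.pos}")

    @property
    def variant_type(self) -> str:
        """``"SNP"`` iff both alleles have length 1, else ``"InDel"``."""
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "InDel"

    @property
    def is_biallelic(self) -> bool:
        return self.n_alt_alleles == 1


def read_vcf(
    path: str,
    sample_roles: dict[str, str] | None = None,
) -> list[VariantRecord]:
    """Read a VCF into :class:`VariantRecord` objects.

    Parameters
    ----------
    path:
        VCF file (plain or bgzipped).
    sample_roles:
        Mapping role -> sample name in the VCF. Defaults to the simulator's
        sample names (:data:`DEFAULT_SAMPLE_NAMES`). Roles whose sample is
        absent raise ``KeyError``.
    """
    roles = dict(DEFAULT_SAMPLE_NAMES if sample_roles is None else sample_roles)
    vcf = VCF(path)
    name_to_col = {name: i for i, name in enumerate(vcf.samples)}
    role_cols = {}
    for role, name in roles.items():
        if name not in name_to_col:
            raise KeyError(f"sample {name!r} (role {role}) not found in {path}")
        role_cols[role] = name_to_col[name]

    records: list[VariantRecord] = []
    for v in vcf:
        ad = v.format("AD")
        calls: dict[str, SampleCall] = {}
        for role, col in role_cols.items():
            g = v.genotypes[col]
            alleles = tuple(a for a in g[:-1])
            genotype = None if any(a < 0 for a in alleles) else (alleles[0], alleles[1])
            if ad is not None:
                rd = int(ad[col][0]) if ad[col][0] >= 0 else 0
                alt_d = int(ad[col][1]) if len(ad[col]) > 1 and ad[col][1] >= 0 else 0
            else:
                rd = alt_d = 0
            calls[role] = SampleCall(genotype=genotype, ref_depth=rd, alt_depth=alt_d)

        def _info(key: str) -> float | None:
            val = v.INFO.get(key)
            return None if val is None else float(val)

        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=v.ALT[0] if v.ALT else "*",
                qual=None if v.QUAL is None else float(v.QUAL),
                qd=_info("QD"),
                mq=_info("MQ"),
                fs=_info("FS"),
                n_alt_alleles=len(v.ALT),
                samples=calls,
            )
        )
    return records


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled Fisher strand bias">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref,alt)">
"""


def _fmt_sample(call: SampleCall | None) -> str:
    if call is None:
        return "./.:.,."
    if call.genotype is None:
        gt = "./."
    else:
        gt = f"{call.genotype[0]}/{call.genotype[1]}"
    return f"{gt}:{call.ref_depth},{call.alt_depth}"


def write_vcf(
    records: list[VariantRecord],
    path: str,
    contigs: dict[str, int] | None = None,
    sample_names: dict[str, str] | None = None,
) -> None:
    """Write records as a VCF v4.2 text file (GT and AD FORMAT fields).

    Output is byte-deterministic: no date or command line is embedded, so two
    writes of identical records produce identical files.
    """
    names = dict(DEFAULT_SAMPLE_NAMES if sample_names is None else sample_names)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        cols = "\t".join(names[r] for r in ROLES)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for rec in records:
            info_parts = []
            for key, val in (("QD", rec.qd), ("MQ", rec.mq), ("FS", rec.fs)):
                if val is not None:
                    info_parts.append(f"{key}={val:.2f}")
            info = ";".join(info_parts) if info_parts else "."
            qual = "." if rec.qual is None else f"{rec.qual:.2f}"
            fields = [
                rec.chrom,
                str(rec.pos),
                ".",
                rec.ref,
                rec.alt,
                qual,
                ".",
                info,
                "GT:AD",
            ]
            fields.extend(_fmt_sample(rec.samples.get(r)) for r in ROLES)
            fh.write("\t".join(fields) + "\n")
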