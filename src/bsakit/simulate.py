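"""Forward simulation of an F2 bulk-segregant experiment.

The generator emulates the design of a BSA-seq study of a quantitative
trait (main stem node number in soybean): an F2 population from a biparental
cross between a wild-type line and a mutant line, truncation-selected extreme
bulks, and short-read allele-count sampling of the two bulks and the two
parents at ~30x depth.

Model summary
-------------
* Markers segregate 1:2:1 under Mendelian F2 expectations. Gametes are built
  by a Markov walk along each chromosome with Haldane recombination (no
  interference) at a fixed cM/Mb rate.
* Phenotype = baseline + sum of additive QTL effects x dosage + N(0, env_sd).
* Bulks are the top and bottom ``bulk_size`` individuals by phenotype
  (truncation selection; ties broken by individual id for reproducibility).
* Per site and bulk, total depth ~ NegativeBinomial(mean, dispersion)
  (dispersion -> infinity recovers Poisson) and mutant-allele reads ~
  Binomial(depth, f') where f' is the bulk's true mutant-allele frequency
  perturbed by the per-read error rate.
* Parents are emitted error-free and homozygous for opposite alleles, which
  is exactly the "informative site" configuration the downstream filter
  selects. The mutant parent always carries the ALT allele, so the SNP-index
  counts ALT reads.

The default genome is a single 20 Mb chromosome standing in for the whole
genome at desk scale; its recombination rate (120 cM/Mb) preserves the
~2400 cM genetic length of the full soybean map under the physical
compression, which is what keeps genome-wide outlier thresholds meaningful
on the toy genome. See docs/methods.md for the reasoning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .effects import GeneModel
from .variants import VariantRecord, SampleCall

DEFAULT_CONTRASTS = ("L.V2", "L.R2", "L.R4", "S.V2", "S.R2", "S.R4")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated F2 bulk-segregant experiment.

    Defaults describe the study design being emulated: 322 F2 individuals,
    extreme bulks of 32, ~30x bulk depth, one additive QTL whose effect
    (3.05 nodes per allele) reproduces the parental means 17.98 vs 24.08.
    """

    chromosomes: tuple[tuple[str, int], ...] = (("chr18", 20_000_000),)
    marker_density: float = 100.0  # markers per Mb
    qtls: tuple[tuple[str, int, float], ...] = (("chr18", 12_300_000, 3.05),)
    trait_baseline: float = 17.98
    env_sd: float = 1.0
    population_size: int = 322
    bulk_size: int = 32
    mean_depth: float = 30.0
    depth_dispersion: float = 10.0  # NB dispersion; np.inf -> Poisson
    error_rate: float = 0.002  # per-read allele-flip probability
    recomb_rate_cm_per_mb: float = 120.0
    indel_fraction: float = 0.0  # fraction of markers emitted as InDels
    parent_depth: float = 40.0
    seed: int = 1

    def __post_init__(self) -> None:
        chrom_names = {name for name, _ in self.chromosomes}
        if len(chrom_names) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for chrom, pos, _ in self.qtls:
            lengths = dict(self.chromosomes)
            if chrom not in lengths:
                raise ValueError(f"QTL chromosome {chrom!r} not declared")
            if not (1 <= pos <= lengths[chrom]):
                raise ValueError(f"QTL position {pos} outside {chrom}")
        if self.bulk_size > self.population_size // 2:
            raise ValueError("bulk_size must be <= population_size / 2")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.env_sd < 0:
            raise ValueError("env_sd must be >= 0")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.n_markers() == 0:
            raise ValueError("configuration yields zero markers")

    def n_markers(self) -> int:
        return sum(
            int(round(self.marker_density * length / 1e6))
            for _, length in self.chromosomes
        )

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "chromosomes" in raw:
            raw["chromosomes"] = tuple((str(c), int(l)) for c, l in raw["chromosomes"])
        if "qtls" in raw:
            raw["qtls"] = tuple((str(c), int(p), float(e)) for c, p, e in raw["qtls"])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        raw = asdict(self)
        raw["chromosomes"] = [list(c) for c in self.chromosomes]
        raw["qtls"] = [list(q) for q in self.qtls]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class SimTruth:
    """Ground truth emitted by :func:`simulate_f2` for recovery tests."""

    qtls: tuple[tuple[str, int, float], ...]
    phenotypes: np.ndarray  # one trait value per F2 individual
    bulk_low_ids: np.ndarray
    bulk_high_ids: np.ndarray
    #: per-site true mutant-allele frequency in each bulk before read sampling
    true_allele_freq: pd.DataFrame  # columns: chrom, pos, freq_low, freq_high
    #: genotype dosage (count of mutant-parent alleles) per individual x locus
    dosages: dict[str, np.ndarray]
    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        low, high = set(self.bulk_low_ids), set(self.bulk_high_ids)
        if low & high:
            raise ValueError("bulk id sets must be disjoint")
        f = self.true_allele_freq
        if ((f[["freq_low", "freq_high"]] < 0) | (f[["freq_low", "freq_high"]] > 1)).any().any():
            raise ValueError("true allele frequencies must lie in [0, 1]")


def reference_sequences(config: SimulationConfig) -> dict[str, str]:
    """Deterministic random reference genome for the configured chromosomes.

    Regenerable independently of :func:`simulate_f2` (same seed stream), so
    variant REF alleles always match this sequence.
    """
    seqs = {}
    for k, (chrom, length) in enumerate(config.chromosomes):
        rng = np.random.default_rng([config.seed, 10_000 + k])
        seqs[chrom] = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
    return seqs


def _haldane_r(d_cm: np.ndarray) -> np.ndarray:
    """Recombination fraction from genetic distance in cM (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def _simulate_dosages(
    rng: np.random.Generator, n_ind: int, pos: np.ndarray, rate_cm_per_mb: float
) -> np.ndarray:
    """F2 genotype dosages (0/1/2 mutant alleles) for one chromosome."""
    m = len(pos)
    n_gam = 2 * n_ind
    first = rng.integers(0, 2, size=(n_gam, 1), dtype=np.int8)
    if m > 1:
        r = _haldane_r(np.diff(pos) / 1e6 * rate_cm_per_mb)
        switch = (rng.random((n_gam, m - 1)) < r).astype(np.int8)
        steps = np.concatenate([first, switch], axis=1)
    else:
        steps = first
    origin = np.cumsum(steps, axis=1, dtype=np.int64) % 2
    return (origin[0::2] + origin[1::2]).astype(np.int8)


def _draw_depths(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    if np.isinf(dispersion):
        return rng.poisson(mean, size=size)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_f2(config: SimulationConfig) -> tuple[list[VariantRecord], SimTruth]:
    """Simulate the full BSA-seq experiment for ``config``.

    Returns the four-sample variant table (two parents, two bulks) and the
    ground truth (phenotypes, bulk memberships, true bulk allele
    frequencies). Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    refs = reference_sequences(config)
    n = config.population_size

    positions: dict[str, np.ndarray] = {}
    dosages: dict[str, np.ndarray] = {}
    qtl_by_chrom: dict[str, list[tuple[int, float]]] = {}
    for chrom, pos, eff in config.qtls:
        qtl_by_chrom.setdefault(chrom, []).append((pos, eff))

    genetic = np.zeros(n)
    for chrom, length in config.chromosomes:
        n_mark = int(round(config.marker_density * length / 1e6))
        # leave room at the 3' end for short deletion alleles
        pos = rng.choice(np.arange(1, length - 3), size=min(n_mark, length - 4), replace=False)
        qtl_pos = np.array([p for p, _ in qtl_by_chrom.get(chrom, [])], dtype=int)
        pos = np.union1d(pos, qtl_pos)
        positions[chrom] = pos
        dos = _simulate_dosages(rng, n, pos.astype(float), config.recomb_rate_cm_per_mb)
        dosages[chrom] = dos
        for p, eff in qtl_by_chrom.get(chrom, []):
            genetic = genetic + eff * dos[:, np.searchsorted(pos, p)]

    phenotypes = config.trait_baseline + genetic + rng.normal(0.0, config.env_sd, size=n)

    order = np.argsort(phenotypes, kind="stable")  # ties broken by individual id
    bulk_low = np.sort(order[: config.bulk_size])
    bulk_high = np.sort(order[-config.bulk_size :])

    records: list[VariantRecord] = []
    freq_rows = []
    for chrom, length in config.chromosomes:
        pos = positions[chrom]
        dos = dosages[chrom]
        seq = refs[chrom]
        m = len(pos)

        f_low = dos[bulk_low].mean(axis=0) / 2.0
        f_high = dos[bulk_high].mean(axis=0) / 2.0

        depth_low = _draw_depths(rng, config.mean_depth, config.depth_dispersion, m)
        depth_high = _draw_depths(rng, config.mean_depth, config.depth_dispersion, m)
        e = config.error_rate
        alt_low = rng.binomial(depth_low, f_low * (1 - e) + (1 - f_low) * e)
        alt_high = rng.binomial(depth_high, f_high * (1 - e) + (1 - f_high) * e)

        is_indel = rng.random(m) < config.indel_fraction
        ins = rng.random(m) < 0.5
        indel_len = rng.integers(1, 4, size=m)
        alt_off = rng.integers(1, 4, size=m)  # SNP: offset to a different base
        ins_seq = rng.integers(0, 4, size=(m, 3))

        qual = rng.uniform(100, 1000, size=m)
        qd = rng.uniform(20, 35, size=m)
        mqv = np.clip(rng.normal(60, 2, size=m), 40, None)
        fsv = rng.exponential(2.0, size=m)
        p_depth_wt = rng.poisson(config.parent_depth, size=m)
        p_depth_mut = rng.poisson(config.parent_depth, size=m)

        for j in range(m):
            p = int(pos[j])
            base = seq[p - 1]
            if is_indel[j]:
                if ins[j]:
                    ref_a = base
                    alt_a = base + "".join(
                        _BASES[ins_seq[j, : indel_len[j]]].astype(str)
                    )
                else:
                    ref_a = seq[p - 1 : p + indel_len[j]]
                    alt_a = base
            else:
                ref_a = base
                alt_a = _BASES[(np.searchsorted(_BASES, base.encode()) + alt_off[j]) % 4].decode()

            dl, dh = int(depth_low[j]), int(depth_high[j])
            al, ah = int(alt_low[j]), int(alt_high[j])
            samples = {
                "parent_wt": SampleCall((0, 0), int(p_depth_wt[j]), 0),
                "parent_mut": SampleCall((1, 1), 0, int(p_depth_mut[j])),
                "bulk_low": SampleCall(_pool_gt(al, dl), dl - al, al),
                "bulk_high": SampleCall(_pool_gt(ah, dh), dh - ah, ah),
            }
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=p,
                    ref=ref_a,
                    alt=alt_a,
                    qual=float(qual[j]),
                    qd=float(qd[j]),
                    mq=float(mqv[j]),
                    fs=float(fsv[j]),
                    samples=samples,
                )
            )
            freq_rows.append((chrom, p, f_low[j], f_high[j]))

    truth = SimTruth(
        qtls=config.qtls,
        phenotypes=phenotypes,
        bulk_low_ids=bulk_low,
        bulk_high_ids=bulk_high,
        true_allele_freq=pd.DataFrame(
            freq_rows, columns=["chrom", "pos", "freq_low", "freq_high"]
        ),
        dosages=dosages,
        positions=positions,
    )
    return records, truth


def _pool_gt(alt_reads: int, depth: int) -> tuple[int, int] | None:
    """Nominal pooled-sample genotype call from allele counts."""
    if depth == 0:
        return None
    if alt_reads == 0:
        return (0, 0)
    if alt_reads == depth:
        return (1, 1)
    return (0, 1)


@dataclass
class CompanionTables:
    """Gene models plus DE and metabolite tables with planted ground truth."""

    genes: list[GeneModel]
    de_table: pd.DataFrame  # feature_id, contrast, log2fc, fdr
    metabolites: pd.DataFrame  # compound, abundance_wt, abundance_mut, detected_*
    planted_down_genes: list[str]
    exclusive_compound: str


def simulate_companion_tables(
    config: SimulationConfig,
    truth: SimTruth,
    *,
    gene_spacing: int = 20_000,
    n_planted_down: int = 3,
    plant_radius: int = 100_000,
    contrasts: tuple[str, ...] = DEFAULT_CONTRASTS,
    n_metabolites: int = 24,
) -> CompanionTables:
    """Companion gene models, DE table and metabolite table for a simulation.

    Gene models tile the simulated chromosomes every ``gene_spacing`` bp.
    ``n_planted_down`` genes nearest a QTL (within ``plant_radius``) are
    planted as consistently down-regulated in the mutant across *all*
    contrasts (log2FC <= -1, FDR < 0.01); all other gene x contrast cells are
    drawn from a null-plus-sporadic-DE mixture. The metabolite table contains
    two-line abundances including one compound detected only in the mutant
    line (and one detected in neither line, to exercise the error path).
    """
    if not contrasts:
        raise ValueError("at least one contrast must be declared")
    rng = np.random.default_rng([config.seed, 77])

    genes: list[GeneModel] = []
    for chrom, length in config.chromosomes:
        i = 0
        for slot in range(0, length - gene_spacing, gene_spacing):
            start = slot + 2_000
            end = start + 5_000
            strand = "+" if i % 2 == 0 else "-"
            cds = ((start + 500, start + 1_400, 0), (start + 2_000, start + 2_900, 0))
            genes.append(
                GeneModel(
                    gene_id=f"gene_{chrom}_{start:08d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    cds_segments=cds,
                )
            )
            i += 1

    # plant consistently-down genes nearest a QTL
    planted: list[str] = []
    for chrom, qpos, _ in truth.qtls:
        near = [
            g for g in genes
            if g.chrom == chrom and g.start < qpos + plant_radius and g.end > qpos - plant_radius
        ]
        near.sort(key=lambda g: abs((g.start + g.end) // 2 - qpos))
        planted.extend(g.gene_id for g in near[: n_planted_down - len(planted)])
        if len(planted) >= n_planted_down:
            break
    if len(planted) < n_planted_down:
        raise ValueError("not enough genes near QTLs to plant; increase plant_radius")

    planted_set = set(planted)
    rows = []
    for g in genes:
        for c in contrasts:
            if g.gene_id in planted_set:
                log2fc = -rng.uniform(1.5, 3.0)
                fdr = rng.uniform(1e-6, 1e-3)
            elif rng.random() < 0.15:  # sporadic DE in one contrast
                log2fc = rng.choice([-1.0, 1.0]) * rng.uniform(1.0, 4.0)
                fdr = rng.uniform(1e-5, 0.009)
            else:
                log2fc = rng.normal(0.0, 0.6)
                fdr = rng.uniform(0.02, 1.0)
            rows.append((g.gene_id, c, float(log2fc), float(fdr)))
    de_table = pd.DataFrame(rows, columns=["feature_id", "contrast", "log2fc", "fdr"])

    comp_rows = []
    for k in range(n_metabolites):
        wt = float(rng.lognormal(3.0, 1.0))
        ratio = float(rng.uniform(0.6, 1.6))
        comp_rows.append((f"compound_{k:02d}", wt, wt * ratio, True, True))
    # planted differential compounds (boundary-safe margins)
    wt = float(rng.lognormal(3.0, 0.5))
    comp_rows.append(("compound_up_mut", wt, wt * 2.5, True, True))
    comp_rows.append(("compound_down_mut", wt, wt * 0.33, True, True))
    comp_rows.append(("cis_zeatin_like", 0.0, float(rng.lognormal(2.0, 0.5)), False, True))
    comp_rows.append(("compound_lost_mut", float(rng.lognormal(2.0, 0.5)), 0.0, True, False))
    comp_rows.append(("compound_undetected", 0.0, 0.0, False, False))
    metabolites = pd.DataFrame(
        comp_rows,
        columns=["compound", "abundance_wt", "abundance_mut", "detected_wt", "detected_mut"],
    )

    return CompanionTables(
        genes=genes,
        de_table=de_table,
        metabolites=metabolites,
        planted_down_genes=sorted(planted),
        exclusive_compound="cis_zeatin_like",
    )


def write_gff3(genes: list[GeneModel], path: str) -> None:
    """Write gene models (gene/mRNA/CDS) as GFF3; 1-based closed coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};Name={g.gene_id}"
            fh.write(
                f"{g.chrom}\tbsakit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tbsakit\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e, phase) in enumerate(g.cds_segments):
                fh.write(
                    f"{g.chrom}\tbsakit\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"ID={mrna}.cds{i};Parent={mrna}\n"
                )


def write_fasta(seqs: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_phenotypes(truth: SimTruth, path: str) -> None:
    n = len(truth.phenotypes)
    bulk = np.array(["-"] * n, dtype=object)
    bulk[truth.bulk_low_ids] = "low"
    bulk[truth.bulk_high_ids] = "high"
    pd.DataFrame(
        {"individual": np.arange(n), "phenotype": truth.phenotypes, "bulk": bulk}
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")
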