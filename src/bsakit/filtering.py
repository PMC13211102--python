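"""Hard-quality and informativeness filters for BSA-seq variant tables.

Two stages, applied in order:

1. :func:`apply_hard_filters` — GATK-style site-quality filter keeping only
   biallelic sites with QUAL >= 30, QD >= 2.0, MQ >= 40 and FS <= 60.0
   (boundaries inclusive as written). Sites missing a required annotation
   are dropped and counted, not raised.
2. :func:`select_informative_sites` — keeps sites where the two parents are
   called homozygous for opposite alleles (so bulk reads can be polarized by
   parental origin) and both bulks have total depth >= 4.

Both return a :class:`FilterResult` carrying the retained records (input
order preserved) and an audit of per-rule drop counts; the two audits
together reconcile input minus output exactly.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple

import pandas as pd

from .variants import VariantRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    min_qual: float = 30.0
    min_qd: float = 2.0
    min_mq: float = 40.0
    max_fs: float = 60.0
    require_biallelic: bool = True
    min_bulk_depth: int = 4

    def __post_init__(self) -> None:
        for name in ("min_qual", "min_qd", "min_mq", "max_fs", "min_bulk_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class FilterResult(NamedTuple):
    variants: list[VariantRecord]
    dropped: Counter  # reason -> count

    def audit_table(self) -> pd.DataFrame:
        rows = sorted(self.dropped.items()) + [("retained", len(self.variants))]
        return pd.DataFrame(rows, columns=["rule", "n_sites"])


def apply_hard_filters(
    variants: list[VariantRecord], config: FilterConfig = FilterConfig()
) -> FilterResult:
    """Site-quality hard filter. A site is dropped on its *first* failing rule."""
    kept: list[VariantRecord] = []
    dropped: Counter = Counter()
    for v in variants:
        if config.require_biallelic and not v.is_biallelic:
            dropped["not_biallelic"] += 1
            continue
        if v.qual is None or v.qd is None or v.mq is None or v.fs is None:
            dropped["missing_annotation"] += 1
            continue
        if v.qual < config.min_qual:
            dropped["low_qual"] += 1
            continue
        if v.qd < config.min_qd:
            dropped["low_qd"] += 1
            continue
        if v.mq < config.min_mq:
            dropped["low_mq"] += 1
            continue
        if v.fs > config.max_fs:
            dropped["high_fs"] += 1
            continue
        kept.append(v)
    if dropped:
        logger.info("hard filters dropped %d/%d sites: %s", sum(dropped.values()), len(variants), dict(dropped))
    return FilterResult(kept, dropped)


def select_informative_sites(
    variants: list[VariantRecord], config: FilterConfig = FilterConfig()
) -> FilterResult:
    """Keep parent-polymorphic sites with adequate bulk coverage.

    Parent polymorphism is read strictly as homozygous-opposite (0/0 vs 1/1
    in either orientation); heterozygous or missing parent calls drop the
    site. Depth >= ``min_bulk_depth`` is required of the total (ref+alt)
    depth in *both* bulks.
    """
    kept: list[VariantRecord] = []
    dropped: Counter = Counter()
    for v in variants:
        pw = v.samples.get("parent_wt")
        pm = v.samples.get("parent_mut")
        if pw is None or pm is None or pw.genotype is None or pm.genotype is None:
            dropped["missing_parent_genotype"] += 1
            continue
        opposite = (pw.is_hom(0) and pm.is_hom(1)) or (pw.is_hom(1) and pm.is_hom(0))
        if not opposite:
            dropped["parents_not_opposite_hom"] += 1
            continue
        bl = v.samples.get("bulk_low")
        bh = v.samples.get("bulk_high")
        if bl is None or bh is None:
            dropped["missing_bulk"] += 1
            continue
        if bl.total_depth < config.min_bulk_depth or bh.total_depth < config.min_bulk_depth:
            dropped["low_bulk_depth"] += 1
            continue
        kept.append(v)
    if dropped:
        logger.info("informative-site filter dropped %d/%d sites: %s", sum(dropped.values()), len(variants), dict(dropped))
    return FilterResult(kept, dropped)


def filter_variants(
    variants: list[VariantRecord], config: FilterConfig = FilterConfig()
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Run both stages; returns retained variants and a combined audit table."""
    hard = apply_hard_filters(variants, config)
    info = select_informative_sites(hard.variants, config)
    audit = pd.concat(
        [
            hard.audit_table().assign(stage="hard_filter"),
            info.audit_table().assign(stage="informative"),
        ],
        ignore_index=True,
    )[["stage", "rule", "n_sites"]]
    return info.variants, audit
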