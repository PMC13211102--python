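"""End-to-end association pipeline: filter -> indices -> windows -> thresholds -> regions.

:func:`associate` runs both statistics (delta-index with its simulated-null
permutation threshold; ED with median + 3 SD) separately per variant type
and combines the resulting region sets (base-pair intersection by default,
i.e. the strict all-methods-and-types reading).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filtering import FilterConfig, filter_variants
from .regions import CandidateRegion, call_regions, combine_region_sets
from .stats import (
    DEFAULT_STEP,
    DEFAULT_WINDOW,
    ThresholdSet,
    WindowProfile,
    compute_indices,
    delta_threshold_permutation,
    ed_threshold,
    smooth_profile,
)
from .variants import VariantRecord

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    sites: pd.DataFrame
    profiles: dict[tuple[str, str], WindowProfile]  # (variant_type, method)
    thresholds: dict[tuple[str, str], ThresholdSet]
    regions: dict[tuple[str, str], list[CandidateRegion]]
    combined: list[CandidateRegion]
    audit: pd.DataFrame | None = None


def associate(
    variants: list[VariantRecord],
    chrom_lengths: dict[str, int],
    *,
    bulk_size: int | None = None,
    filter_config: FilterConfig | None = FilterConfig(),
    window_size: int = DEFAULT_WINDOW,
    step_size: int = DEFAULT_STEP,
    min_variants: int = 10,
    n_permutations: int = 1000,
    delta_level: float = 0.95,
    delta_scope: str = "site",
    ed_k: float = 3.0,
    ed_power: float = 1.0,
    variant_types: tuple[str, ...] = ("SNP", "InDel"),
    combine: str = "intersect",
    max_gap_windows: int = 0,
    seed: int = 0,
) -> AssociationResult:
    """Run the full BSA association on a four-sample variant table.

    ``filter_config=None`` skips filtering (inputs already filtered).
    ``bulk_size`` feeds the delta-index null; ``None`` falls back to read
    sampling only. Variant types with no sites are skipped with a warning
    rather than forcing an empty intersection. Deterministic given ``seed``.
    """
    audit = None
    if filter_config is not None:
        variants, audit = filter_variants(variants, filter_config)
    sites = compute_indices(variants, ed_power=ed_power)

    rng = np.random.default_rng(seed)
    profiles: dict[tuple[str, str], WindowProfile] = {}
    thresholds: dict[tuple[str, str], ThresholdSet] = {}
    regions: dict[tuple[str, str], list[CandidateRegion]] = {}
    sets: list[list[CandidateRegion]] = []
    for vt in variant_types:
        sub = sites[sites["variant_type"] == vt]
        perm_seed = int(rng.integers(0, 2**31 - 1))
        if sub.empty:
            logger.warning("no %s sites; excluded from combination", vt)
            continue
        common = dict(
            window_size=window_size, step_size=step_size, min_variants=min_variants
        )
        prof_d = smooth_profile(sub, chrom_lengths, stat="abs_delta", **common)
        thr_d = delta_threshold_permutation(
            sub,
            chrom_lengths,
            n_permutations=n_permutations,
            bulk_size=bulk_size,
            scope=delta_scope,
            seed=perm_seed,
            **common,
        )
        reg_d = call_regions(
            prof_d, thr_d, level=delta_level, variant_type=vt,
            max_gap_windows=max_gap_windows,
        )
        prof_e = smooth_profile(sub, chrom_lengths, stat="ed", **common)
        thr_e = ed_threshold(prof_e, k=ed_k)
        reg_e = call_regions(
            prof_e, thr_e, variant_type=vt, max_gap_windows=max_gap_windows
        )
        profiles[(vt, "delta")], profiles[(vt, "ed")] = prof_d, prof_e
        thresholds[(vt, "delta")], thresholds[(vt, "ed")] = thr_d, thr_e
        regions[(vt, "delta")], regions[(vt, "ed")] = reg_d, reg_e
        sets.extend([reg_d, reg_e])

    combined = combine_region_sets(sets, mode=combine) if sets else []
    return AssociationResult(
        sites=sites,
        profiles=profiles,
        thresholds=thresholds,
        regions=regions,
        combined=combined,
        audit=audit,
    )
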