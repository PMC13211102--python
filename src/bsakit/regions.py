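"""Candidate-region calling and interval algebra over half-open regions.

Thresholded window profiles become candidate regions (maximal runs of
consecutive significant windows, merged to disjoint intervals); region sets
from the two methods (delta-index, ED) and two variant types (SNP, InDel)
are combined by base-pair-level intersection (default) or union. All
coordinates are 0-based half-open.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .stats import ThresholdSet, WindowProfile


@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    start: int  # 0-based half-open
    end: int
    source_method: str = "unknown"  # delta | ed | combined
    variant_type: str = "unknown"  # SNP | InDel | combined
    peak_value: float = float("nan")

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"region start must be < end ({self.chrom}:{self.start}-{self.end})")

    @property
    def span(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether the 1-based position ``pos`` falls inside this region."""
        return chrom == self.chrom and self.start <= pos - 1 < self.end


def _check_disjoint_sorted(regions: list[CandidateRegion]) -> None:
    for a, b in zip(regions, regions[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError("region set must be disjoint and sorted")
        if a.chrom == b.chrom and b.start < a.start:
            raise ValueError("region set must be sorted")


def call_regions(
    profile: WindowProfile,
    threshold: "ThresholdSet | float | np.ndarray",
    level: float = 0.95,
    source_method: str | None = None,
    variant_type: str = "unknown",
    max_gap_windows: int = 0,
) -> list[CandidateRegion]:
    """Regions where the smoothed statistic exceeds its threshold.

    Maximal runs of consecutive unmasked windows with ``stat_mean >
    threshold`` span one region from the first window's start to the last
    window's end. Up to ``max_gap_windows`` consecutive non-significant
    windows may be bridged (default 0: no gap bridging). Because windows
    overlap when step < window, physically overlapping run-spans are merged,
    keeping the output disjoint and sorted.

    ``threshold`` may be a scalar, an array aligned with ``profile.windows``,
    or a :class:`ThresholdSet` (resolved at confidence ``level`` for the
    delta method).
    """
    win = profile.windows
    if isinstance(threshold, ThresholdSet):
        thr = threshold.threshold_for(profile, level)
        if source_method is None:
            source_method = threshold.method
    elif isinstance(threshold, numbers.Real):
        thr = np.full(len(win), float(threshold))
    else:
        thr = np.asarray(threshold, dtype=float)
        if thr.shape != (len(win),):
            raise ValueError("threshold array must align with profile windows")
    if source_method is None:
        source_method = "unknown"

    stat = win["stat_mean"].to_numpy()
    with np.errstate(invalid="ignore"):
        above = (~win["masked"].to_numpy()) & ~np.isnan(thr) & (stat > thr)

    regions: list[CandidateRegion] = []
    for chrom, grp in win.assign(_above=above).groupby("chrom", sort=False):
        grp = grp.sort_values("start", kind="stable")
        run: list[int] = []  # positional indices into grp
        gap = 0
        rows = grp.reset_index(drop=True)
        sig = rows["_above"].to_numpy()
        for i in range(len(rows)):
            if sig[i]:
                run.append(i)
                gap = 0
            elif run:
                gap += 1
                if gap > max_gap_windows:
                    regions.append(_run_to_region(rows, run, chrom, source_method, variant_type))
                    run, gap = [], 0
        if run:
            regions.append(_run_to_region(rows, run, chrom, source_method, variant_type))

    return _merge_overlapping(regions)


def _run_to_region(rows, run, chrom, source_method, variant_type) -> CandidateRegion:
    first, last = run[0], run[-1]
    peak = float(np.nanmax(rows.loc[run, "stat_mean"].to_numpy()))
    return CandidateRegion(
        chrom=chrom,
        start=int(rows.loc[first, "start"]),
        end=int(rows.loc[last, "end"]),
        source_method=source_method,
        variant_type=variant_type,
        peak_value=peak,
    )


def _merge_overlapping(regions: list[CandidateRegion]) -> list[CandidateRegion]:
    regions = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    out: list[CandidateRegion] = []
    for r in regions:
        if out and out[-1].chrom == r.chrom and r.start <= out[-1].end:
            prev = out[-1]
            peak = np.nanmax([prev.peak_value, r.peak_value])
            out[-1] = replace(prev, end=max(prev.end, r.end), peak_value=float(peak))
        else:
            out.append(r)
    return out


def combine_region_sets(
    sets: list[list[CandidateRegion]],
    mode: str = "intersect",
    min_overlap_bp: int = 1,
    source_method: str = "combined",
    variant_type: str = "combined",
) -> list[CandidateRegion]:
    """Base-pair-level intersection or union of region sets.

    ``intersect`` keeps only bases present in *every* input set (pieces
    shorter than ``min_overlap_bp`` are discarded); ``union`` merges all.
    Output is disjoint and sorted. An empty *list of sets* is an error; an
    empty set within the list makes the intersection empty.
    """
    if not sets:
        raise ValueError("combine_region_sets requires at least one region set")
    if mode not in ("intersect", "union"):
        raise ValueError("mode must be 'intersect' or 'union'")
    for s in sets:
        _check_disjoint_sorted(sorted(s, key=lambda r: (r.chrom, r.start)))

    def tag(ivs: list[tuple[str, int, int]]) -> list[CandidateRegion]:
        return [
            CandidateRegion(c, s, e, source_method, variant_type)
            for c, s, e in ivs
            if e - s >= (min_overlap_bp if mode == "intersect" else 1)
        ]

    ivs = [(r.chrom, r.start, r.end) for r in sets[0]]
    if mode == "union":
        allr = sorted(
            ((r.chrom, r.start, r.end) for s in sets for r in s),
            key=lambda t: (t[0], t[1]),
        )
        merged: list[tuple[str, int, int]] = []
        for c, s, e in allr:
            if merged and merged[-1][0] == c and s <= merged[-1][2]:
                merged[-1] = (c, merged[-1][1], max(merged[-1][2], e))
            else:
                merged.append((c, s, e))
        return tag(merged)

    for other in sets[1:]:
        oiv = sorted(((r.chrom, r.start, r.end) for r in other), key=lambda t: (t[0], t[1]))
        ivs = _intersect_two(ivs, oiv)
    return tag(ivs)


def _intersect_two(a, b):
    out = []
    for c1, s1, e1 in a:
        for c2, s2, e2 in b:
            if c1 != c2:
                continue
            s, e = max(s1, s2), min(e1, e2)
            if s < e:
                out.append((c1, s, e))
    return sorted(out, key=lambda t: (t[0], t[1]))


@dataclass
class RegionSummary:
    n_regions: int
    total_bp: int
    total_mb: float  # Mb = 1e6 bp, 2 decimals
    largest: CandidateRegion | None
    per_chrom: pd.DataFrame  # chrom, n_regions, span_bp, span_mb, share_pct


def summarize_regions(regions: list[CandidateRegion]) -> RegionSummary:
    """Counts, spans (Mb, 2 decimals) and per-chromosome shares of total span."""
    cols = ["chrom", "n_regions", "span_bp", "span_mb", "share_pct"]
    if not regions:
        return RegionSummary(0, 0, 0.0, None, pd.DataFrame(columns=cols))
    total = sum(r.span for r in regions)
    largest = max(regions, key=lambda r: (r.span, r.chrom, -r.start))
    rows = []
    for chrom in sorted({r.chrom for r in regions}):
        sub = [r for r in regions if r.chrom == chrom]
        span = sum(r.span for r in sub)
        rows.append(
            (chrom, len(sub), span, round(span / 1e6, 2), round(span / total * 100, 2))
        )
    return RegionSummary(
        n_regions=len(regions),
        total_bp=total,
        total_mb=round(total / 1e6, 2),
        largest=largest,
        per_chrom=pd.DataFrame(rows, columns=cols),
    )


def write_bed(regions: list[CandidateRegion], path: str) -> None:
    """BED (0-based half-open) with name = method:type and score = peak."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
            name = f"{r.source_method}:{r.variant_type}"
            score = "0" if np.isnan(r.peak_value) else f"{r.peak_value:.4f}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score}\n")


def read_bed(path: str) -> list[CandidateRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            method, _, vtype = f[3].partition(":") if len(f) > 3 else ("unknown", "", "unknown")
            regions.append(
                CandidateRegion(f[0], int(f[1]), int(f[2]), method or "unknown", vtype or "unknown")
            )
    return sorted(regions, key=lambda r: (r.chrom, r.start))
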