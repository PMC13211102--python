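"""Per-site association statistics, sliding-window smoothing and thresholds.

Statistics
----------
For each informative site, the *SNP-index* (InDel-index for indels) of a bulk
is the fraction of its reads carrying the mutant-parent allele. The
*delta-index* is ``index_high - index_low`` (signed; thresholding uses the
absolute value). The *Euclidean distance* (ED) between the bulks'
allele-frequency vectors over the two alleles is

    ed = sqrt((f_high - f_low)^2 + ((1 - f_high) - (1 - f_low))^2)

which for biallelic sites equals ``sqrt(2) * |delta|``; an optional exponent
(``ed_power``, commonly 4-5 in practice, default 1) sharpens peaks.

Smoothing uses overlapping sliding windows (default 1 Mb window, 100 kb
step); a window's value is the arithmetic mean (optionally median) of the
per-site statistic, and windows with fewer than ``min_variants`` sites are
masked.

Thresholds
----------
* delta-index: a depth-aware simulated null. Under H0 (no locus-trait
  association) each bulk's allele frequency at a site is the sampling
  outcome of drawing ``bulk_size`` F2 individuals (frequency ~
  Binomial(2*bulk_size, 1/2) / (2*bulk_size)) followed by read sampling
  (Binomial(observed depth, frequency)). With ``bulk_size=None`` the
  bulk-composition stage is skipped and the null is read sampling at p=0.5
  only. Per-site null quantiles at the requested confidence levels are
  averaged within each window to give the windowed threshold track
  (``scope="site"``, default); ``scope="window"`` instead pools windowed
  null means across iterations and thresholds at their global quantile.
* ED: genome-wide ``median + k * SD`` (k=3) of the unmasked window values,
  with the sample SD (n-1 denominator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import VariantRecord

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 1_000_000
DEFAULT_STEP = 100_000
DEFAULT_LEVELS = (0.90, 0.95, 0.99)


def compute_indices(
    variants: list[VariantRecord], ed_power: float = 1.0
) -> pd.DataFrame:
    """Per-site SNP/InDel-index, delta-index and ED statistics.

    The index is polarized to count the *mutant-parent* allele, so a locus
    selected in the high bulk drives ``index_high`` toward 1. Sites whose
    mutant parent is not homozygous, or with zero depth in a bulk, are
    skipped with a logged count.

    Returns a DataFrame sorted by (chrom, pos) with columns: chrom, pos,
    variant_type, depth_low, depth_high, index_low, index_high, delta,
    abs_delta, ed.
    """
    rows = []
    skipped = 0
    for v in variants:
        pm = v.samples.get("parent_mut")
        bl = v.samples.get("bulk_low")
        bh = v.samples.get("bulk_high")
        if pm is None or bl is None or bh is None:
            skipped += 1
            continue
        if pm.is_hom(1):
            mut_low, mut_high = bl.alt_depth, bh.alt_depth
        elif pm.is_hom(0):
            mut_low, mut_high = bl.ref_depth, bh.ref_depth
        else:
            skipped += 1
            continue
        dl, dh = bl.total_depth, bh.total_depth
        if dl == 0 or dh == 0:
            skipped += 1
            continue
        il, ih = mut_low / dl, mut_high / dh
        delta = ih - il
        ed = float(np.hypot(ih - il, (1 - ih) - (1 - il))) ** ed_power
        rows.append((v.chrom, v.pos, v.variant_type, dl, dh, il, ih, delta, abs(delta), ed))
    if skipped:
        logger.info("compute_indices skipped %d sites (unpolarizable or zero depth)", skipped)
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "variant_type", "depth_low", "depth_high",
            "index_low", "index_high", "delta", "abs_delta", "ed",
        ],
    )
    return df.sort_values(["chrom", "pos"], kind="stable", ignore_index=True)


def _window_frame(
    chrom_lengths: dict[str, int], window_size: int, step_size: int
) -> pd.DataFrame:
    rows = [
        (chrom, start, min(start + window_size, length))
        for chrom, length in chrom_lengths.items()
        for start in range(0, length, step_size)
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass
class WindowProfile:
    """Sliding-window smoothed statistic track.

    ``windows`` columns: chrom, start, end (0-based half-open), stat_mean,
    n_variants, masked. Masked windows (fewer than ``min_variants`` sites)
    carry ``stat_mean = NaN`` and never seed candidate regions.
    """

    windows: pd.DataFrame
    stat: str
    window_size: int
    step_size: int
    min_variants: int

    @property
    def unmasked(self) -> pd.DataFrame:
        return self.windows[~self.windows["masked"]]


def smooth_profile(
    sites: pd.DataFrame,
    chrom_lengths: dict[str, int],
    stat: str = "abs_delta",
    window_size: int = DEFAULT_WINDOW,
    step_size: int = DEFAULT_STEP,
    min_variants: int = 10,
    agg: str = "mean",
) -> WindowProfile:
    """Smooth the per-site column ``stat`` over sliding windows.

    A site at 1-based position ``pos`` belongs to window [start, end) iff
    ``start <= pos - 1 < end``.
    """
    if window_size < step_size:
        raise ValueError("window_size must be >= step_size")
    if agg not in ("mean", "median"):
        raise ValueError("agg must be 'mean' or 'median'")

    win = _window_frame(chrom_lengths, window_size, step_size)
    means = np.full(len(win), np.nan)
    counts = np.zeros(len(win), dtype=int)
    for chrom, grp in sites.groupby("chrom", sort=False):
        sel = win["chrom"] == chrom
        if not sel.any():
            continue
        pos0 = np.sort(grp["pos"].to_numpy()) - 1
        vals = grp.sort_values("pos", kind="stable")[stat].to_numpy()
        lo = np.searchsorted(pos0, win.loc[sel, "start"].to_numpy(), side="left")
        hi = np.searchsorted(pos0, win.loc[sel, "end"].to_numpy(), side="left")
        counts[sel.to_numpy()] = hi - lo
        if agg == "mean":
            cs = np.concatenate([[0.0], np.cumsum(vals)])
            with np.errstate(invalid="ignore"):
                means[sel.to_numpy()] = np.where(hi > lo, (cs[hi] - cs[lo]) / np.maximum(hi - lo, 1), np.nan)
        else:
            m = np.full(hi.shape, np.nan)
            for i, (a, b) in enumerate(zip(lo, hi)):
                if b > a:
                    m[i] = np.median(vals[a:b])
            means[sel.to_numpy()] = m

    win["stat_mean"] = means
    win["n_variants"] = counts
    win["masked"] = counts < min_variants
    win.loc[win["masked"], "stat_mean"] = np.nan
    return WindowProfile(win, stat, window_size, step_size, min_variants)


@dataclass
class ThresholdSet:
    """Significance thresholds for one statistic.

    For the delta-index, ``delta_thresholds`` maps confidence level to the
    genome-global pooled per-site null quantile, and ``window_thresholds``
    (when ``scope="site"``) carries a per-window threshold column ``q{level}``
    per level. For ED, ``ed_threshold = median + k*SD`` of the window track.
    """

    method: str  # "delta" | "ed"
    delta_thresholds: dict[float, float] | None = None
    window_thresholds: pd.DataFrame | None = None
    ed_threshold: float | None = None
    ed_median: float | None = None
    ed_sd: float | None = None
    k: float | None = None
    n_permutations: int | None = None
    scope: str | None = None

    def threshold_for(self, profile: WindowProfile, level: float = 0.95) -> np.ndarray:
        """Per-window threshold array aligned with ``profile.windows``."""
        if self.method == "ed":
            return np.full(len(profile.windows), self.ed_threshold)
        if self.window_thresholds is not None:
            col = f"q{level:g}"
            if col not in self.window_thresholds.columns:
                raise KeyError(f"level {level} not in threshold set")
            merged = profile.windows[["chrom", "start"]].merge(
                self.window_thresholds[["chrom", "start", col]],
                on=["chrom", "start"],
                how="left",
            )
            return merged[col].to_numpy()
        if self.delta_thresholds is None or level not in self.delta_thresholds:
            raise KeyError(f"level {level} not in threshold set")
        return np.full(len(profile.windows), self.delta_thresholds[level])


def _null_delta_draws(
    rng: np.random.Generator,
    depth_low: np.ndarray,
    depth_high: np.ndarray,
    n_permutations: int,
    bulk_size: int | None,
) -> np.ndarray:
    """|delta-index| draws under H0; shape (n_permutations, n_sites)."""
    shape = (n_permutations, len(depth_low))
    if bulk_size is None:
        p_low = p_high = 0.5
    else:
        m = 2 * bulk_size
        p_low = rng.binomial(m, 0.5, size=shape) / m
        p_high = rng.binomial(m, 0.5, size=shape) / m
    x_low = rng.binomial(depth_low, p_low, size=shape)
    x_high = rng.binomial(depth_high, p_high, size=shape)
    return np.abs(x_high / depth_high - x_low / depth_low)


def site_null_delta_quantiles(
    depth_low: int,
    depth_high: int,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    n_draws: int = 100_000,
    bulk_size: int | None = None,
    seed: int = 0,
) -> dict[float, float]:
    """Sampled null quantiles of |delta-index| for one site's depths."""
    rng = np.random.default_rng(seed)
    draws = _null_delta_draws(
        rng, np.array([depth_low]), np.array([depth_high]), n_draws, bulk_size
    )[:, 0]
    return {lv: float(np.quantile(draws, lv)) for lv in levels}


def delta_threshold_permutation(
    sites: pd.DataFrame,
    chrom_lengths: dict[str, int] | None = None,
    *,
    window_size: int = DEFAULT_WINDOW,
    step_size: int = DEFAULT_STEP,
    min_variants: int = 10,
    n_permutations: int = 1000,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    bulk_size: int | None = None,
    scope: str = "site",
    seed: int = 0,
) -> ThresholdSet:
    """Simulated-null significance thresholds for the windowed |delta-index|.

    See the module docstring for the null model. Deterministic given
    ``seed``. ``chrom_lengths`` defaults to the max observed position per
    chromosome.
    """
    if scope not in ("site", "window"):
        raise ValueError("scope must be 'site' or 'window'")
    if n_permutations < 100:
        logger.warning(
            "n_permutations=%d is small; thresholds will be noisy", n_permutations
        )
    sites = sites[(sites["depth_low"] > 0) & (sites["depth_high"] > 0)]
    sites = sites.sort_values(["chrom", "pos"], kind="stable", ignore_index=True)
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(g["pos"].max()) for c, g in sites.groupby("chrom", sort=False)
        }
    rng = np.random.default_rng(seed)
    d_low = sites["depth_low"].to_numpy()
    d_high = sites["depth_high"].to_numpy()
    draws = _null_delta_draws(rng, d_low, d_high, n_permutations, bulk_size)

    global_thr = {lv: float(np.quantile(draws, lv)) for lv in levels}
    win = _window_frame(chrom_lengths, window_size, step_size)
    window_thr: pd.DataFrame | None = None

    if scope == "site":
        site_q = np.quantile(draws, levels, axis=0)  # (n_levels, n_sites)
        cols = {}
        for li, lv in enumerate(levels):
            prof = smooth_profile(
                sites.assign(_q=site_q[li]),
                chrom_lengths,
                stat="_q",
                window_size=window_size,
                step_size=step_size,
                min_variants=min_variants,
            )
            cols[f"q{lv:g}"] = prof.windows["stat_mean"].to_numpy()
        window_thr = win.assign(**cols)
    else:
        # alternative scope: pool windowed null means across iterations
        pooled = []
        for chrom, grp_idx in sites.groupby("chrom", sort=False).groups.items():
            idx = np.asarray(grp_idx)
            pos0 = sites.loc[idx, "pos"].to_numpy() - 1
            sub = draws[:, idx]
            cs = np.concatenate(
                [np.zeros((n_permutations, 1)), np.cumsum(sub, axis=1)], axis=1
            )
            wsel = win["chrom"] == chrom
            lo = np.searchsorted(pos0, win.loc[wsel, "start"].to_numpy())
            hi = np.searchsorted(pos0, win.loc[wsel, "end"].to_numpy())
            ok = (hi - lo) >= min_variants
            if ok.any():
                means = (cs[:, hi[ok]] - cs[:, lo[ok]]) / (hi - lo)[ok]
                pooled.append(means.ravel())
        if pooled:
            pool = np.concatenate(pooled)
            global_thr = {lv: float(np.quantile(pool, lv)) for lv in levels}

    return ThresholdSet(
        method="delta",
        delta_thresholds=global_thr,
        window_thresholds=window_thr,
        n_permutations=n_permutations,
        scope=scope,
    )


def ed_threshold(profile: WindowProfile, k: float = 3.0) -> ThresholdSet:
    """Genome-wide ED threshold: median + k * sample SD of unmasked windows."""
    vals = profile.unmasked["stat_mean"].to_numpy()
    if len(vals) < 2:
        raise ValueError("ed_threshold requires >= 2 unmasked windows")
    med = float(np.median(vals))
    sd = float(np.std(vals, ddof=1))
    return ThresholdSet(
        method="ed", ed_threshold=med + k * sd, ed_median=med, ed_sd=sd, k=k
    )
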