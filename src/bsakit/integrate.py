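"""Overlay of candidate genes with differential expression and hormone calls.

DEG calling follows the printed rule exactly: FDR strictly below the cutoff
(default 0.01) and |log2FC| >= the cutoff (default 1, boundary inclusive).
Fold changes are oriented mutant/wild-type throughout, so a compound or gene
"down in the mutant" maps to FC <= 0.5 / negative log2FC.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .effects import GeneModel
from .regions import CandidateRegion

logger = logging.getLogger(__name__)

DEFAULT_CONTRASTS = ("L.V2", "L.R2", "L.R4", "S.V2", "S.R2", "S.R4")


def flag_degs(
    expression: pd.DataFrame,
    fdr_max: float = 0.01,
    min_abs_log2fc: float = 1.0,
    feature_to_gene: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Differentially expressed features: fdr < fdr_max AND |log2fc| >= cutoff.

    ``expression`` columns: feature_id, contrast, log2fc, fdr. Records with a
    missing fdr are skipped with a logged count. ``feature_to_gene``
    optionally collapses transcript ids onto gene ids (transcript-level
    tables are handled by the same operations through this map).
    """
    df = expression.copy()
    missing = df["fdr"].isna()
    if missing.any():
        logger.info("flag_degs skipped %d records with missing fdr", int(missing.sum()))
        df = df[~missing]
    keep = (df["fdr"] < fdr_max) & (df["log2fc"].abs() >= min_abs_log2fc)
    out = df[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    if feature_to_gene is not None:
        out["feature_id"] = out["feature_id"].map(lambda f: feature_to_gene.get(f, f))
    return out.reset_index(drop=True)


def overlap_candidates_with_degs(
    candidate_genes: Iterable[str],
    degs: pd.DataFrame,
    contrasts: tuple[str, ...] = DEFAULT_CONTRASTS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-contrast up/down counts and the gene x contrast direction matrix.

    Returns ``(counts, matrix)``: counts has one row per contrast with
    columns n_up / n_down over candidate genes; matrix is indexed by all
    candidate genes (sorted) with one column per contrast holding "up",
    "down" or NaN (gene not DE in that contrast).
    """
    genes = sorted(set(candidate_genes))
    sub = degs[degs["feature_id"].isin(genes)]
    matrix = pd.DataFrame(index=pd.Index(genes, name="gene_id"),
                          columns=list(contrasts), dtype=object)
    rows = []
    for c in contrasts:
        dc = sub[sub["contrast"] == c]
        dirs = dc.set_index("feature_id")["direction"]
        dup = dirs.index[dirs.index.duplicated()]
        if len(dup):
            dirs = dirs[~dirs.index.duplicated(keep="first")]
        matrix.loc[dirs.index, c] = dirs
        rows.append((c, int((dirs == "up").sum()), int((dirs == "down").sum())))
    counts = pd.DataFrame(rows, columns=["contrast", "n_up", "n_down"])
    return counts, matrix


def consistent_genes(
    matrix: pd.DataFrame, require_same_direction: bool = True
) -> list[str]:
    """Genes DE in *all* contrasts, optionally with one direction throughout."""
    if matrix.shape[1] == 0:
        raise ValueError("no contrasts declared")
    de_all = matrix.notna().all(axis=1)
    if require_same_direction:
        same = matrix.nunique(axis=1, dropna=True) == 1
        de_all &= same
    return sorted(matrix.index[de_all])


def differential_metabolites(
    abundances: pd.DataFrame,
    fc_high: float = 2.0,
    fc_low: float = 0.5,
) -> pd.DataFrame:
    """Differential compound calls from two-line abundances.

    ``abundances`` columns: compound, abundance_wt, abundance_mut and
    optional detected_wt / detected_mut flags (inferred from abundance > 0
    when absent). Fold change is mutant/wild-type; compounds with FC >=
    fc_high or <= fc_low are differential (boundaries inclusive), compounds
    detected in exactly one line are "exclusive" (direction toward the
    detecting line) and count as differential, and compounds detected in
    neither line are excluded with a log entry.
    """
    df = abundances.copy()
    if "detected_wt" not in df.columns:
        df["detected_wt"] = df["abundance_wt"] > 0
    if "detected_mut" not in df.columns:
        df["detected_mut"] = df["abundance_mut"] > 0

    undetected = ~df["detected_wt"] & ~df["detected_mut"]
    if undetected.any():
        logger.info(
            "differential_metabolites excluded %d compounds undetected in both lines: %s",
            int(undetected.sum()), list(df.loc[undetected, "compound"]),
        )
        df = df[~undetected]

    rows = []
    for _, r in df.iterrows():
        if r["detected_wt"] and r["detected_mut"]:
            fc = r["abundance_mut"] / r["abundance_wt"]
            if fc >= fc_high:
                status, direction, diff = "differential", "up", True
            elif fc <= fc_low:
                status, direction, diff = "differential", "down", True
            else:
                status, direction, diff = "not_differential", None, False
        elif r["detected_mut"]:
            fc, status, direction, diff = np.nan, "exclusive", "up", True
        else:
            fc, status, direction, diff = np.nan, "exclusive", "down", True
        rows.append((r["compound"], fc, status, direction, diff))
    return pd.DataFrame(
        rows, columns=["compound", "fold_change", "status", "direction", "differential"]
    )


def final_report(
    regions: list[CandidateRegion],
    priority: pd.DataFrame,
    matrix: pd.DataFrame,
    gene_models: list[GeneModel] | None = None,
    metabolites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Ranked candidate-gene report synthesizing all pipeline stages.

    One row per candidate gene (the index of ``matrix``): the containing
    region, high-impact variant counts from ``priority``
    (:func:`bsakit.effects.prioritize_candidates`), the DE consistency score
    (contrasts DE / total contrasts), the consistent direction, and the rank.
    Ranking is deterministic: consistency desc, frameshift count desc,
    nonsynonymous count desc, gene id. Differential-metabolite calls, if
    given, are attached as ``report.attrs["n_differential_metabolites"]``.
    """
    genes = list(matrix.index)
    n_contrasts = matrix.shape[1]
    rep = pd.DataFrame({"gene_id": genes}).set_index("gene_id")

    region_str = pd.Series("", index=rep.index, dtype=object)
    if gene_models is not None:
        models = {g.gene_id: g for g in gene_models}
        for gid in genes:
            g = models.get(gid)
            if g is None:
                continue
            for r in regions:
                if r.chrom == g.chrom and g.start < r.end and r.start < g.end:
                    region_str[gid] = f"{r.chrom}:{r.start}-{r.end}"
                    break
    rep["region"] = region_str

    pri = priority.set_index("gene_id") if len(priority) else pd.DataFrame()
    for col in ("nonsyn_total", "frameshift_total"):
        vals = pri[col] if col in pri.columns else pd.Series(dtype=int)
        rep[col] = vals.reindex(rep.index).fillna(0).astype(int)

    n_de = matrix.notna().sum(axis=1)
    rep["n_contrasts_de"] = n_de
    rep["consistency"] = (n_de / n_contrasts).round(4)

    def _direction(row) -> str:
        vals = set(row.dropna())
        if not vals:
            return ""
        return vals.pop() if len(vals) == 1 else "mixed"

    rep["direction"] = matrix.apply(_direction, axis=1)

    rep = rep.reset_index().sort_values(
        ["consistency", "frameshift_total", "nonsyn_total", "gene_id"],
        ascending=[False, False, False, True],
        kind="stable",
        ignore_index=True,
    )
    rep["rank"] = np.arange(1, len(rep) + 1)
    if metabolites is not None:
        rep.attrs["n_differential_metabolites"] = int(metabolites["differential"].sum())
    return rep
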