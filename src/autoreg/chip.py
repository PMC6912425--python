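"""Peak-to-gene annotation, occupancy analytics and differential binding.

Peaks are assigned to the gene whose TSS is closest to the peak midpoint
(ties broken by the lexicographically smaller gene id).  The signed
distance is strand-aware: negative means the midpoint lies upstream of
the TSS.  Genomic regions collapse to four categories with precedence
Promoter > 5UTR > 3UTR > other, where the promoter window is +/- 3 kb
around the TSS (midpoint containment).

Occupancy is the sum of size-factor-normalised reads-in-peaks per gene
(optionally split by region); the region split conserves gene totals
exactly.  Differential peak binding reuses the NB Wald machinery with a
0.5 log2 fold-change label threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from autoreg.diffexp import DesignSpec, nb_wald_test, run_contrasts, size_factors
from autoreg.errors import ValidationError

logger = logging.getLogger(__name__)

PROMOTER_HALFWIDTH = 3000
REGIONS = ("Promoter", "5UTR", "3UTR", "other")


def assign_nearest_gene(peaks: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Assign each peak to the gene with the nearest TSS (by midpoint).

    Adds ``assigned_gene`` and ``distance_to_tss`` columns.  Peaks on
    chromosomes without genes stay unassigned (empty gene, NaN distance)
    with a log notice.
    """
    out = peaks.copy()
    out["assigned_gene"] = ""
    out["distance_to_tss"] = np.nan
    mid = (out["start"].to_numpy() + out["end"].to_numpy()) // 2
    for chrom, idx in out.groupby("chrom").groups.items():
        genes = ann[ann["chrom"] == chrom]
        if genes.empty:
            logger.info("assign_nearest_gene: no genes on %s; %d peaks unassigned",
                        chrom, len(idx))
            continue
        tss = genes["tss"].to_numpy(dtype=np.int64)
        gid = genes["gene_id"].to_numpy()
        strand = genes["strand"].to_numpy()
        # sort by (|distance| asc, gene_id asc) via lexsort per peak
        m = mid[out.index.get_indexer(idx)]
        dist_abs = np.abs(m[:, None] - tss[None, :])
        # choose, per peak, the column minimising (dist, gene_id)
        order = np.lexsort((gid, ))  # gene_id ascending
        dist_abs = dist_abs[:, order]
        tss_o, gid_o, strand_o = tss[order], gid[order], strand[order]
        best = np.argmin(dist_abs, axis=1)  # first minimum = smallest gene_id on tie
        chosen_tss = tss_o[best]
        signed = np.where(strand_o[best] == "+", m - chosen_tss, chosen_tss - m)
        out.loc[idx, "assigned_gene"] = gid_o[best]
        out.loc[idx, "distance_to_tss"] = signed.astype(float)
    return out


def classify_region(
    peaks: pd.DataFrame,
    ann: pd.DataFrame,
    promoter_halfwidth: int = PROMOTER_HALFWIDTH,
) -> pd.DataFrame:
    """Label each assigned peak with Promoter / 5UTR / 3UTR / other.

    Membership is decided by midpoint containment with precedence
    Promoter > 5UTR > 3UTR > other.
    """
    out = peaks.copy()
    ann_idx = ann.set_index("gene_id")
    mid = (out["start"].to_numpy() + out["end"].to_numpy()) // 2
    labels = []
    for i, (_, peak) in enumerate(out.iterrows()):
        gene = peak["assigned_gene"]
        if not gene or gene not in ann_idx.index:
            labels.append("other")
            continue
        if abs(peak["distance_to_tss"]) <= promoter_halfwidth:
            labels.append("Promoter")
            continue
        g = ann_idx.loc[gene]
        if _in_interval(mid[i], g["utr5_start"], g["utr5_end"]):
            labels.append("5UTR")
        elif _in_interval(mid[i], g["utr3_start"], g["utr3_end"]):
            labels.append("3UTR")
        else:
            labels.append("other")
    out["region"] = labels
    return out


def _in_interval(pos: int, start, end) -> bool:
    return start is not None and start >= 0 and start <= pos < end


def annotate_peaks(
    peaks: pd.DataFrame,
    ann: pd.DataFrame,
    promoter_halfwidth: int = PROMOTER_HALFWIDTH,
) -> pd.DataFrame:
    """Nearest-gene assignment followed by region classification."""
    return classify_region(assign_nearest_gene(peaks, ann), ann, promoter_halfwidth)


def occupancy_matrix(
    peak_counts: pd.DataFrame,
    peaks: pd.DataFrame,
    group_by: str = "gene",
    sf: pd.Series | None = None,
) -> pd.DataFrame:
    """Sum normalised reads-in-peaks per gene (or gene x region).

    ``group_by`` is ``"gene"`` or ``"gene_region"``.  Region sums equal
    gene totals exactly because the same normalised values are summed.
    """
    missing = set(peak_counts.index) - set(peaks["peak_id"])
    if missing:
        raise ValidationError(f"peak ids missing from the peak table: {sorted(missing)[:5]}")
    if sf is None:
        sf = size_factors(peak_counts, method="poscounts")
    norm = peak_counts / sf.reindex(peak_counts.columns)
    meta = peaks.set_index("peak_id").loc[norm.index]
    if group_by == "gene":
        keys = meta["assigned_gene"]
        occ = norm.groupby(keys.to_numpy()).sum()
        occ.index.name = "gene_id"
    elif group_by == "gene_region":
        keys = pd.MultiIndex.from_arrays(
            [meta["assigned_gene"], meta["region"]], names=["gene_id", "region"])
        occ = norm.set_axis(keys).groupby(level=["gene_id", "region"]).sum()
    else:
        raise ValueError(f"unknown group_by {group_by!r}")
    return occ


def occupancy_correlation(occ: pd.DataFrame) -> pd.DataFrame:
    """Pairwise sample PCC on log2(occupancy + 1); unit diagonal.

    Zero-variance samples yield NaN rows/columns with a log notice.
    """
    if occ.shape[0] < 3:
        raise ValidationError("need >= 3 features for occupancy correlation")
    logocc = np.log2(occ.to_numpy(dtype=float) + 1.0)
    sd = logocc.std(axis=0)
    flat = sd == 0
    if flat.any():
        logger.info("occupancy_correlation: %d zero-variance samples -> NaN",
                    int(flat.sum()))
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(logocc, rowvar=False)
    corr[flat, :] = np.nan
    corr[:, flat] = np.nan
    np.fill_diagonal(corr, np.where(flat, np.nan, 1.0))
    return pd.DataFrame(corr, index=occ.columns, columns=occ.columns)


def occupancy_change(
    occ: pd.DataFrame,
    samples_a: list[str],
    samples_b: list[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2 occupancy change: log2((mean_B + c) / (mean_A + c))."""
    for name, cols in (("A", samples_a), ("B", samples_b)):
        if len(cols) < 1:
            raise ValidationError(f"stage {name} has no samples")
        absent = set(cols) - set(occ.columns)
        if absent:
            raise ValidationError(f"stage {name} samples missing from occupancy: {absent}")
    mean_a = occ[samples_a].mean(axis=1)
    mean_b = occ[samples_b].mean(axis=1)
    return np.log2((mean_b + pseudocount) / (mean_a + pseudocount))


def differential_binding(
    peak_counts: pd.DataFrame,
    design: DesignSpec,
    contrast: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """NB Wald differential binding on peak counts (label tau = 0.5)."""
    design = DesignSpec(groups=design.groups, contrasts=design.contrasts,
                        lfc_threshold=0.5, fdr_threshold=design.fdr_threshold)
    sf = size_factors(peak_counts, method="poscounts")
    if contrast is not None:
        return nb_wald_test(peak_counts, design, contrast, sf=sf)
    return run_contrasts(peak_counts, design, sf=sf)
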