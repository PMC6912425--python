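"""Construction of classified regulatory links from combined evidence.

A *direct* link factor -> gene in stage s requires the conjunction of
(i) a promoter-region peak of the factor on the gene, (ii) significant
differential binding of that peak for the contrast ending in s, and
(iii) a stage-s co-expression |r| above the reporting threshold (0.25 by
default).  Links whose factor equals the target are *auto*-regulation;
pairs of reciprocal direct links form *feedback* 2-cycles.  Indirect
links are propagated one step through annotated regulons of intermediate
transcription factors.  Signs come from the co-expression coefficient
and are validated against knockdown contrasts where available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LINK_COLUMNS = [
    "factor", "target", "mode", "stage", "sign",
    "promoter_peak", "peak_id", "binding_change", "coexpr_r",
    "target_de_label", "kd_consistent",
]

#: Map from a stage contrast to the stage a link is attributed to.
CONTRAST_STAGE = {"early_vs_non": "early", "late_vs_non": "late"}


@dataclass
class IntegrationConfig:
    coexpr_threshold: float = 0.25   # |r| needed to support a link
    sign_threshold: float = 0.25     # theta for induction/repression calls
    contrasts: tuple[str, ...] = ("early_vs_non", "late_vs_non")


def direct_targets(
    de: pd.DataFrame,
    binding: pd.DataFrame,
    coexpr: pd.DataFrame,
    peaks: pd.DataFrame,
    config: IntegrationConfig | None = None,
) -> pd.DataFrame:
    """Emit direct regulatory links from peak, binding and co-expression evidence.

    Parameters
    ----------
    de
        Gene-level DE results (``feature_id, contrast, label``) used to
        annotate the target's regulation stratum.
    binding
        Peak-level DE results (``feature_id, contrast, log2fc, label``).
    coexpr
        Per-stage correlations (``factor, target, stage, r``).
    peaks
        Annotated peak table with ``peak_id, factor, assigned_gene, region``.
    """
    cfg = config or IntegrationConfig()
    bind = binding.set_index(["feature_id", "contrast"])
    rtab = coexpr.set_index(["factor", "target", "stage"])["r"]
    de_idx = de.set_index(["feature_id", "contrast"])["label"] if len(de) else None

    links = []
    promoter = peaks[peaks["region"] == "Promoter"]
    for _, peak in promoter.iterrows():
        factor, gene, pid = peak["factor"], peak["assigned_gene"], peak["peak_id"]
        for contrast in cfg.contrasts:
            stage = CONTRAST_STAGE[contrast]
            try:
                brow = bind.loc[(pid, contrast)]
            except KeyError:
                continue
            if brow["label"] == "none":
                continue
            if factor == gene:
                r = 1.0  # auto-regulation: self-correlation is degenerate
            else:
                r = rtab.get((factor, gene, stage), np.nan)
                if np.isnan(r) or abs(r) < cfg.coexpr_threshold:
                    continue
            de_label = "none"
            if de_idx is not None:
                de_label = de_idx.get((gene, contrast), "none")
            links.append({
                "factor": factor, "target": gene,
                "mode": "auto" if factor == gene else "direct",
                "stage": stage, "sign": "ambiguous",
                "promoter_peak": True, "peak_id": pid,
                "binding_change": float(brow["log2fc"]),
                "coexpr_r": float(r),
                "target_de_label": de_label,
                "kd_consistent": "untested",
            })
    out = pd.DataFrame(links, columns=LINK_COLUMNS)
    # one row per (factor, target, stage): keep the strongest binding peak
    if len(out):
        out = (out.reindex(out["binding_change"].abs()
                           .sort_values(ascending=False).index)
                  .drop_duplicates(["factor", "target", "stage"])
                  .sort_values(["factor", "target", "stage"])
                  .reset_index(drop=True))
    return out


def find_feedback(links: pd.DataFrame) -> pd.DataFrame:
    """Reciprocal direct links F->G and G->F reported as feedback pairs."""
    direct = links[links["mode"].isin(["direct", "feedback"])]
    pairs = set(zip(direct["factor"], direct["target"]))
    rows = []
    for f, g in sorted(pairs):
        if f < g and (g, f) in pairs:
            rows.append({"factor_a": f, "factor_b": g})
    return pd.DataFrame(rows, columns=["factor_a", "factor_b"])


def mark_feedback(links: pd.DataFrame) -> pd.DataFrame:
    """Relabel reciprocal direct links as mode='feedback' (in place copy)."""
    links = links.copy()
    fb = find_feedback(links)
    cycle = {(a, b) for _, (a, b) in fb.iterrows()} | \
            {(b, a) for _, (a, b) in fb.iterrows()}
    mask = links.apply(lambda row: (row["factor"], row["target"]) in cycle
                       and row["mode"] == "direct", axis=1)
    if mask.any():
        links.loc[mask, "mode"] = "feedback"
    return links


def indirect_targets(
    direct_links: pd.DataFrame,
    tf_set: list[str] | set[str],
    tf_targets: dict[str, list[str]],
    de: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Propagate direct links one step through intermediate TF regulons.

    For each direct link F -> t with t in *tf_set*, emit F -> g
    (mode ``indirect_via_tf``) for every g in t's annotated regulon.
    A TF without regulon annotation contributes nothing (with a notice).
    """
    tf_set = set(tf_set)
    de_idx = (de.set_index(["feature_id", "contrast"])["label"]
              if de is not None and len(de) else None)
    rows = []
    hits = direct_links[direct_links["target"].isin(tf_set)
                        & direct_links["mode"].isin(["direct", "feedback"])]
    for _, link in hits.iterrows():
        tf = link["target"]
        regulon = tf_targets.get(tf)
        if not regulon:
            logger.info("indirect_targets: no regulon annotation for %s", tf)
            continue
        for g in regulon:
            de_label = "none"
            if de_idx is not None:
                contrast = f"{link['stage']}_vs_non"
                de_label = de_idx.get((g, contrast), "none")
            rows.append({
                "factor": link["factor"], "target": g,
                "mode": "indirect_via_tf", "stage": link["stage"],
                "sign": "ambiguous", "promoter_peak": False, "peak_id": "",
                "binding_change": np.nan, "coexpr_r": np.nan,
                "target_de_label": de_label, "kd_consistent": "untested",
            })
    return pd.DataFrame(rows, columns=LINK_COLUMNS)


def infer_sign(
    links: pd.DataFrame,
    factor_expressed_stages: dict[str, set[str]] | None = None,
    theta: float = 0.25,
) -> pd.DataFrame:
    """Sign each link from its co-expression coefficient.

    induction if r > +theta, repression if r < -theta, ambiguous
    otherwise.  Links in stages where the factor is not expressed
    (per *factor_expressed_stages*) are suppressed.
    """
    links = links.copy()
    r = links["coexpr_r"]
    links["sign"] = np.select(
        [r > theta, r < -theta], ["induction", "repression"], default="ambiguous")
    if factor_expressed_stages is not None:
        keep = links.apply(
            lambda row: row["stage"] in factor_expressed_stages.get(row["factor"], set()),
            axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("infer_sign: suppressed %d links (factor not expressed)",
                        n_dropped)
        links = links[keep].reset_index(drop=True)
    return links


def knockdown_consistency(
    links: pd.DataFrame,
    kd_de: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Check link signs against knockdown-vs-control DE results.

    ``kd_de[factor]`` holds DEResults over time points (``feature_id,
    contrast, label``).  A link is consistent when an induction target is
    down (or a repression target up) under its factor's knockdown at any
    tested time point; ``untested`` when the factor has no KD data or the
    target is absent from it.
    """
    links = links.copy()
    verdicts = []
    for _, link in links.iterrows():
        table = kd_de.get(link["factor"])
        if table is None or link["target"] not in set(table["feature_id"]):
            verdicts.append("untested")
            continue
        labels = set(table.loc[table["feature_id"] == link["target"], "label"])
        if link["sign"] == "induction":
            verdicts.append("yes" if "down" in labels else "no")
        elif link["sign"] == "repression":
            verdicts.append("yes" if "up" in labels else "no")
        else:
            verdicts.append("untested")
    links["kd_consistent"] = verdicts
    return links


def links_to_graph(links: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node/edge tables for graph export of the link summary."""
    nodes = sorted(set(links["factor"]) | set(links["target"]))
    node_df = pd.DataFrame({
        "node_id": nodes,
        "is_factor": [n in set(links["factor"]) for n in nodes],
    })
    edge_df = links[["factor", "target", "mode", "stage", "sign"]].rename(
        columns={"factor": "source", "target": "dest"})
    return node_df, edge_df
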