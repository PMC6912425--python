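"""End-to-end driver: simulate -> analyze -> integrate -> report.

:func:`run_pipeline` executes the full chain on a synthetic scenario and
writes every intermediate table, a manifest (config, seed, checksums) and
a plain-text summary to the output directory.  Runs are deterministic
given identical configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from autoreg import __version__, chip, coexpr, diffexp, enrichment, integrate, io
from autoreg.simulate import (SimConfig, generate_annotation, generate_gene_sets,
                              generate_knockdown_counts, generate_peak_counts,
                              generate_timecourse_counts)
from autoreg.staging import STAGES, filter_low_quality, validate_sample_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; serialisable to/from YAML."""

    out_dir: str = "autoreg_run"
    seed: int = 0
    sim: dict = field(default_factory=dict)  # keyword overrides for SimConfig
    min_count: int = 10
    min_samples: int = 3
    gene_lfc_threshold: float = 1.0
    peak_lfc_threshold: float = 0.5
    fdr_threshold: float = 0.2
    coexpr_threshold: float = 0.25
    sign_threshold: float = 0.25
    promoter_halfwidth: int = 3000
    n_permutations: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must be in (0, 1]")
        if self.gene_lfc_threshold < 0 or self.peak_lfc_threshold < 0:
            raise ValueError("lfc thresholds must be >= 0")
        if self.promoter_halfwidth <= 0:
            raise ValueError("promoter_halfwidth must be > 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, **kwargs) -> Path:
    df.to_csv(path, sep="\t", index=kwargs.pop("index", False),
              float_format="%.6g", **kwargs)
    return path


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full synthetic-scenario pipeline; return key results.

    Writes all declared artifacts under ``cfg.out_dir`` and returns a dict
    with in-memory copies of the main tables (links, feedback, de, ...).
    """
    out = Path(cfg.out_dir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    (out / "results").mkdir(exist_ok=True)
    written: list[Path] = []

    # --- simulate ---------------------------------------------------------
    sim = SimConfig(seed=cfg.seed,
                    promoter_halfwidth_bp=cfg.promoter_halfwidth, **cfg.sim)
    ann = generate_annotation(sim.n_genes, seed=sim.seed)
    counts, samples, truth = generate_timecourse_counts(sim)
    peaks, peak_counts, truth, chip_samples = generate_peak_counts(sim, ann, truth)
    sets = generate_gene_sets(truth, seed=sim.seed)
    kd_data = {f: generate_knockdown_counts(sim, truth, f) for f in truth.factors}

    io.write_counts(counts, out / "inputs" / "gene_counts.tsv")
    io.write_sample_table(pd.concat([samples, chip_samples], ignore_index=True),
                          out / "inputs" / "samples.csv")
    io.write_bed(peaks, out / "inputs" / "peaks.bed")
    io.write_counts(peak_counts, out / "inputs" / "peak_counts.tsv")
    io.write_annotation_tsv(ann, out / "inputs" / "annotation.tsv")
    io.write_gtf(ann, out / "inputs" / "annotation.gtf")
    io.write_gmt(sets, out / "inputs" / "gene_sets.gmt")
    _write(truth.genes, out / "inputs" / "truth_genes.tsv")
    written += sorted((out / "inputs").iterdir())

    # --- filter + stage ---------------------------------------------------
    validate_sample_table(samples)
    filtered = filter_low_quality(counts, samples, cfg.min_count, cfg.min_samples)
    stage_map = {s: [c for c in filtered.columns
                     if samples.set_index("sample_id").loc[c, "stage"] == s]
                 for s in STAGES}

    # --- differential expression + MDS ------------------------------------
    groups = samples.set_index("sample_id")["stage"].reindex(filtered.columns)
    design = diffexp.DesignSpec(groups=groups,
                                lfc_threshold=cfg.gene_lfc_threshold,
                                fdr_threshold=cfg.fdr_threshold)
    de = diffexp.run_contrasts(filtered, design)
    written.append(_write(de, out / "results" / "diffexp.tsv"))

    expr = coexpr.vst(filtered)
    mds_tables = []
    subsets = {"all": None,
               "autophagy": sets["autophagy"] if "autophagy" in sets else None,
               "adipogenic_tf": sets["adipogenic_tf"] if "adipogenic_tf" in sets else None}
    for name, subset in subsets.items():
        coords, varexp = diffexp.classical_mds(expr, subset=subset, k=2)
        coords = coords.reset_index(names="sample_id")
        coords.insert(0, "subset", name)
        coords["var_dim1"], coords["var_dim2"] = varexp[0], varexp[1]
        mds_tables.append(coords)
    written.append(_write(pd.concat(mds_tables, ignore_index=True),
                          out / "results" / "mds.tsv"))

    # --- co-expression ----------------------------------------------------
    factors = [f for f in truth.factors if f in expr.index]
    coexpr_targets = sorted(
        set(sets["autophagy"] if "autophagy" in sets else []) | set(factors))
    coexpr_targets = [t for t in coexpr_targets if t in expr.index]
    de_early = de[de["contrast"] == "early_vs_non"].set_index("feature_id")["label"]
    rtab = coexpr.coexpr_all_stages(expr, factors, coexpr_targets, stage_map,
                                    de_labels=de_early)
    written.append(_write(rtab, out / "results" / "coexpr.tsv"))

    dc_frames = []
    for stage_a, stage_b in (("early", "non"), ("late", "non"), ("late", "early")):
        for factor in factors:
            tab = coexpr.permutation_qvalues(
                expr, factor, [t for t in coexpr_targets if t != factor],
                stage_map[stage_a], stage_map[stage_b],
                n_perm=cfg.n_permutations, seed=cfg.seed,
                q_threshold=cfg.fdr_threshold)
            tab.insert(2, "stage_pair", f"{stage_a}_vs_{stage_b}")
            dc_frames.append(tab)
    written.append(_write(pd.concat(dc_frames, ignore_index=True),
                          out / "results" / "diff_coexpr.tsv"))

    # --- enrichment -------------------------------------------------------
    universe = set(filtered.index)
    de_lists = {}
    for contrast, sub in de.groupby("contrast"):
        hits = set(sub.loc[sub["label"] != "none", "feature_id"])
        if hits:
            de_lists[contrast] = hits
    if de_lists:
        ora = enrichment.enrich_all(de_lists, sets, universe)
        written.append(_write(ora, out / "results" / "enrichment.tsv"))
    else:
        ora = pd.DataFrame()

    # --- ChIP occupancy + differential binding ----------------------------
    annotated = chip.annotate_peaks(peaks, ann, cfg.promoter_halfwidth)
    written.append(_write(annotated, out / "results" / "annotated_peaks.tsv"))
    io.write_bed(annotated.assign(
        name=annotated["peak_id"] + "|" + annotated["region"]),
        out / "results" / "annotated_peaks.bed", name_column="name")
    written.append(out / "results" / "annotated_peaks.bed")

    chip_idx = chip_samples.set_index("sample_id")
    binding_frames, occ_changes = [], []
    for factor in truth.factors:
        fac_peaks = annotated.loc[annotated["factor"] == factor, "peak_id"]
        fac_samples = chip_idx[chip_idx["target"] == factor]
        sub = peak_counts.loc[fac_peaks, fac_samples.index]
        fac_design = diffexp.DesignSpec(
            groups=fac_samples["stage"],
            lfc_threshold=cfg.peak_lfc_threshold,
            fdr_threshold=cfg.fdr_threshold)
        binding_frames.append(chip.differential_binding(sub, fac_design)
                              .assign(factor=factor))
        occ = chip.occupancy_matrix(sub, annotated, group_by="gene")
        for stage in ("early", "late"):
            cols_a = fac_samples.index[fac_samples["stage"] == "non"].tolist()
            cols_b = fac_samples.index[fac_samples["stage"] == stage].tolist()
            change = chip.occupancy_change(occ, cols_a, cols_b)
            occ_changes.append(pd.DataFrame({
                "factor": factor, "stage": stage,
                "gene_id": change.index, "log2_change": change.to_numpy()}))
    binding = pd.concat(binding_frames, ignore_index=True)
    written.append(_write(binding, out / "results" / "diff_binding.tsv"))
    written.append(_write(pd.concat(occ_changes, ignore_index=True),
                          out / "results" / "occupancy_change.tsv"))

    occ_all = chip.occupancy_matrix(peak_counts, annotated, group_by="gene")
    occ_corr = chip.occupancy_correlation(occ_all)
    written.append(_write(occ_corr, out / "results" / "occupancy_correlation.tsv",
                          index=True))

    # --- knockdown contrasts ----------------------------------------------
    kd_de = {}
    for factor, (kd_counts, kd_samples) in kd_data.items():
        kd_filtered = filter_low_quality(kd_counts, kd_samples,
                                         cfg.min_count, cfg.min_samples)
        kd_de[factor] = diffexp.kd_contrasts(kd_filtered, kd_samples,
                                             cfg.gene_lfc_threshold,
                                             cfg.fdr_threshold)
    if kd_de:
        written.append(_write(
            pd.concat([t.assign(factor=f) for f, t in kd_de.items()],
                      ignore_index=True),
            out / "results" / "kd_diffexp.tsv"))

    # --- integration ------------------------------------------------------
    int_cfg = integrate.IntegrationConfig(coexpr_threshold=cfg.coexpr_threshold,
                                          sign_threshold=cfg.sign_threshold)
    links = integrate.direct_targets(de, binding, rtab, annotated, int_cfg)
    links = integrate.mark_feedback(links)
    feedback = integrate.find_feedback(links)
    tf_set = sets["autophagy_tf"] if "autophagy_tf" in sets else []
    indirect = integrate.indirect_targets(links, tf_set, truth.tf_targets, de)

    # a factor is "expressed" in a stage when its mean normalised count
    # clears the low-expression threshold there
    sf = coexpr.size_factors(filtered, method="poscounts")
    norm = filtered / sf
    expressed = {
        f: {s for s in STAGES
            if f in norm.index and norm.loc[f, stage_map[s]].mean() >= cfg.min_count}
        for f in truth.factors}

    links = integrate.infer_sign(links, expressed, theta=cfg.sign_threshold)
    links = integrate.knockdown_consistency(links, kd_de)
    all_links = pd.concat([links, indirect], ignore_index=True)
    written.append(_write(all_links, out / "results" / "links.tsv"))
    written.append(_write(feedback, out / "results" / "feedback_pairs.tsv"))
    nodes, edges = integrate.links_to_graph(all_links)
    written.append(_write(nodes, out / "results" / "graph_nodes.tsv"))
    written.append(_write(edges, out / "results" / "graph_edges.tsv"))

    # --- manifest + summary -----------------------------------------------
    cfg.to_yaml(out / "config.yaml")
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_sha256": _sha256(out / "config.yaml"),
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    summary = [
        f"autoreg {__version__} run (seed={cfg.seed})",
        f"genes: {counts.shape[0]} simulated, {filtered.shape[0]} after filter",
        f"samples: {counts.shape[1]} RNA, {peak_counts.shape[1]} ChIP",
        f"DE calls: " + ", ".join(
            f"{c}={int((sub['label'] != 'none').sum())}"
            for c, sub in de.groupby("contrast")),
        f"links: {len(links)} direct/auto/feedback, {len(indirect)} indirect",
        f"feedback pairs: {len(feedback)}",
        f"kd-consistent links: {int((links['kd_consistent'] == 'yes').sum())}",
    ]
    (out / "summary.txt").write_text("\n".join(summary) + "\n")

    return {
        "truth": truth, "de": de, "binding": binding, "coexpr": rtab,
        "links": links, "indirect": indirect, "feedback": feedback,
        "enrichment": ora, "kd_de": kd_de, "manifest": manifest,
        "annotated_peaks": annotated,
    }
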