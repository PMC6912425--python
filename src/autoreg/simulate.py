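"""Synthetic staged time-course data with planted ground truth.

The generator emulates the statistical structure of a staged adipocyte
differentiation experiment: negative-binomial gene counts over three
stages (non / early / late) with stage-specific log2 fold-changes planted
for designated gene groups, factor ChIP peaks whose promoter occupancy
changes by stage, and knockdown datasets in which a factor's own gene and
its direct targets are perturbed.  Every planted effect is recorded in a
:class:`TruthTable` so downstream recovery can be scored.

Within-stage co-expression between a factor and its direct targets is
induced by a per-sample latent activity: sample s multiplies the factor's
mean by ``2**a_s`` and each target's mean by ``2**(sign * a_s)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from autoreg.errors import CapacityError, ValidationError
from autoreg.io import GeneSetCollection
from autoreg.staging import STAGES, assign_stage

GROUPS = ("adipogenic_tf", "autophagy_tf", "autophagy", "lipogenic", "background")

DEFAULT_TIME_POINTS: dict[str, tuple[float, ...]] = {
    "non": (-48.0, 0.0),
    "early": (4.0, 24.0, 48.0),
    "late": (96.0, 240.0),
}

DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "adipogenic_tf": {"early": 1.5, "late": 2.5},   # monotone induction
    "autophagy_tf": {"early": 0.5, "late": 1.5},
    "autophagy_up": {"early": 0.5, "late": 1.5},
    "autophagy_down": {"early": -1.5, "late": -0.5},
    "lipogenic": {"early": 1.0, "late": 2.0},
}

#: Planted promoter-peak occupancy log2 fold-changes, cycled over targets.
OCCUPANCY_EFFECTS = (2.0, 1.5, 2.75, -1.5, -2.0, -2.75)


@dataclass
class SimConfig:
    """Parameters of the synthetic scenario (all effects in log2 units)."""

    n_genes: int = 2000
    n_peaks: int = 120
    samples_per_stage: int = 8
    stages: tuple[str, ...] = STAGES
    time_points_h: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TIME_POINTS))
    baseline_mean: float = 100.0
    baseline_log2_sd: float = 1.0
    dispersion: float = 0.1
    effect_table: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(e) for g, e in DEFAULT_EFFECTS.items()})
    frac_null: float = 0.9
    seed: int = 0
    n_factors: int = 2
    promoter_halfwidth_bp: int = 3000
    # group sizes
    n_autophagy: int = 40
    n_autophagy_tf: int = 6
    n_lipogenic: int = 10
    # planted regulatory structure
    n_direct_targets: int = 8
    tf_regulon_size: int = 5
    coexpr_sd: float = 0.8
    # ChIP layer
    peak_baseline_mean: float = 50.0
    peak_background_mean: float = 5.0
    n_promoter_decoys: int = 10
    # knockdown layer
    kd_strength: float = 2.0
    kd_target_effect: float = 1.5
    kd_time_points_h: tuple[float, ...] = (0.0, 48.0, 120.0)

    def __post_init__(self) -> None:
        if self.samples_per_stage < 4:
            raise ValidationError("samples_per_stage must be >= 4")
        if not 0.0 <= self.frac_null <= 1.0:
            raise ValidationError("frac_null must be in [0, 1]")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if self.baseline_mean <= 0 or self.peak_baseline_mean <= 0:
            raise ValidationError("all means must be > 0")
        for stage in self.stages:
            if stage not in self.time_points_h:
                raise ValidationError(f"no time points for stage {stage!r}")
            for t in self.time_points_h[stage]:
                if assign_stage(t) != stage:
                    raise ValidationError(
                        f"time point {t} h does not map to stage {stage!r}")


@dataclass
class TruthTable:
    """Planted ground truth for a simulated scenario."""

    genes: pd.DataFrame  # gene_id, group, lfc_early, lfc_late, coexpr_partner, coexpr_sign
    factors: list[str]
    direct_targets: dict[str, dict[str, int]]  # factor -> {target: +1/-1}
    tf_targets: dict[str, list[str]]           # autophagy TF -> regulon
    peak_effects: pd.DataFrame | None = None   # filled by generate_peak_counts

    def __post_init__(self) -> None:
        if self.genes["gene_id"].duplicated().any():
            raise ValidationError("truth table has duplicate genes")
        bad = set(self.genes["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels: {bad}")

    def true_links(self) -> set[tuple[str, str]]:
        """All planted (factor, target) direct pairs."""
        return {(f, t) for f, targets in self.direct_targets.items() for t in targets}


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(n)]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, dispersion alpha) with var = mu + alpha mu^2; Poisson at 0."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(
    n_genes: int,
    chrom_length: int = 3_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Lay non-overlapping genes with alternating strands on toy chromosomes.

    Gene bodies are 1-3 kb with >= 6.5 kb gaps so promoter windows never
    overlap; 5'/3' UTRs sit at the respective gene ends (strand-aware).
    TSS is the gene start on + and the gene end on -.

    Raises
    ------
    CapacityError
        If ``chrom_length`` cannot hold even a single gene.
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    margin, max_gene = 1000, 3000
    if chrom_length < margin + max_gene:
        raise CapacityError(
            f"chrom_length={chrom_length} cannot hold one gene "
            f"(needs >= {margin + max_gene} bp)")
    rng = np.random.default_rng(seed)
    records = []
    chrom_i, pos = 1, margin
    for i, gene_id in enumerate(_gene_ids(n_genes)):
        length = int(rng.integers(1000, max_gene + 1))
        gap = int(rng.integers(6500, 12000))
        if pos + length > chrom_length:
            chrom_i += 1
            pos = margin
        strand = "+" if i % 2 == 0 else "-"
        start, end = pos, pos + length
        if strand == "+":
            utr5 = (start, start + 200)
            utr3 = (end - 300, end)
            tss = start
        else:
            utr5 = (end - 200, end)
            utr3 = (start, start + 300)
            tss = end
        records.append({
            "gene_id": gene_id, "chrom": f"chr{chrom_i}", "strand": strand,
            "start": start, "end": end, "tss": tss,
            "utr5_start": utr5[0], "utr5_end": utr5[1],
            "utr3_start": utr3[0], "utr3_end": utr3[1],
        })
        pos = end + gap
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# expression time course


def _plant_truth(cfg: SimConfig, rng: np.random.Generator) -> TruthTable:
    genes = _gene_ids(cfg.n_genes)
    needed = cfg.n_factors + cfg.n_autophagy_tf + cfg.n_autophagy + cfg.n_lipogenic
    if needed > cfg.n_genes:
        raise ValidationError(f"planted groups need {needed} genes, have {cfg.n_genes}")

    group = np.full(cfg.n_genes, "background", dtype=object)
    cursor = 0
    factors = genes[:cfg.n_factors]
    group[:cfg.n_factors] = "adipogenic_tf"
    cursor += cfg.n_factors
    autophagy_tfs = genes[cursor:cursor + cfg.n_autophagy_tf]
    group[cursor:cursor + cfg.n_autophagy_tf] = "autophagy_tf"
    cursor += cfg.n_autophagy_tf
    autophagy = genes[cursor:cursor + cfg.n_autophagy]
    group[cursor:cursor + cfg.n_autophagy] = "autophagy"
    cursor += cfg.n_autophagy
    lipogenic = genes[cursor:cursor + cfg.n_lipogenic]
    group[cursor:cursor + cfg.n_lipogenic] = "lipogenic"
    cursor += cfg.n_lipogenic

    lfc = pd.DataFrame(0.0, index=genes, columns=["early", "late"])
    partner = pd.Series("", index=genes, dtype=object)
    sign = pd.Series(0, index=genes, dtype=int)
    direct: dict[str, dict[str, int]] = {f: {} for f in factors}
    tf_targets: dict[str, list[str]] = {}

    pure_null = cfg.frac_null >= 1.0
    if not pure_null:
        eff = cfg.effect_table
        lfc.loc[factors] = [eff["adipogenic_tf"]["early"], eff["adipogenic_tf"]["late"]]
        lfc.loc[autophagy_tfs] = [eff["autophagy_tf"]["early"], eff["autophagy_tf"]["late"]]
        half = len(autophagy) // 2
        lfc.loc[autophagy[:half]] = [eff["autophagy_up"]["early"], eff["autophagy_up"]["late"]]
        lfc.loc[autophagy[half:]] = [eff["autophagy_down"]["early"], eff["autophagy_down"]["late"]]
        lfc.loc[lipogenic] = [eff["lipogenic"]["early"], eff["lipogenic"]["late"]]

        # extra background effects to reach the requested non-null fraction
        n_target_nonnull = int(round((1.0 - cfg.frac_null) * cfg.n_genes))
        n_extra = max(0, n_target_nonnull - needed)
        background = genes[cursor:]
        if n_extra > 0 and background:
            extra = rng.choice(background, size=min(n_extra, len(background)),
                               replace=False)
            lfc.loc[extra, "early"] = rng.choice([-2.0, -1.0, 1.0, 2.0], size=len(extra))
            lfc.loc[extra, "late"] = rng.choice([-2.0, -1.0, 1.0, 2.0], size=len(extra))

        # planted regulatory structure
        pool = list(autophagy)
        for fi, factor in enumerate(factors):
            take = pool[fi * cfg.n_direct_targets:(fi + 1) * cfg.n_direct_targets]
            for j, t in enumerate(take):
                s = 1 if j % 2 == 0 else -1
                direct[factor][t] = s
                partner.loc[t] = factor
                sign.loc[t] = s
            if fi < len(autophagy_tfs):
                tf = autophagy_tfs[fi]
                direct[factor][tf] = 1
                partner.loc[tf] = factor
                sign.loc[tf] = 1
        # feedback 2-cycle between the first two factors, plus auto-regulation
        if len(factors) >= 2:
            direct[factors[0]][factors[1]] = 1
            direct[factors[1]][factors[0]] = 1
            partner.loc[factors[1]] = factors[0]
            sign.loc[factors[1]] = 1
        direct[factors[0]][factors[0]] = 1
        # autophagy-TF regulons (for indirect targets); avoid the factors'
        # own direct targets so indirect genes are distinct by default
        used = {t for d in direct.values() for t in d}
        free = [g for g in autophagy if g not in used]
        for ti, tf in enumerate(autophagy_tfs):
            regulon = free[ti * cfg.tf_regulon_size:(ti + 1) * cfg.tf_regulon_size]
            tf_targets[tf] = regulon

    truth_genes = pd.DataFrame({
        "gene_id": genes,
        "group": group,
        "lfc_early": lfc["early"].to_numpy(),
        "lfc_late": lfc["late"].to_numpy(),
        "coexpr_partner": partner.to_numpy(),
        "coexpr_sign": sign.to_numpy(),
    })
    return TruthTable(genes=truth_genes, factors=list(factors),
                      direct_targets=direct, tf_targets=tf_targets)


def _rna_sample_table(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for stage in cfg.stages:
        points = cfg.time_points_h[stage]
        for i in range(cfg.samples_per_stage):
            t = points[i % len(points)]
            rows.append({
                "sample_id": f"rna_{stage}_{i + 1}",
                "time_h": float(t), "stage": stage, "assay": "rnaseq",
                "target": "none", "arm": "none", "quality_flag": True,
            })
    return pd.DataFrame(rows)


def generate_timecourse_counts(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Simulate the staged RNA-seq count matrix.

    Returns ``(counts, samples, truth)`` where counts is genes x samples.
    Counts are NB with mean ``baseline * 2**lfc(stage) * 2**latent * sf``.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = _plant_truth(cfg, rng)
    samples = _rna_sample_table(cfg)
    n_s = len(samples)
    genes = truth.genes["gene_id"].tolist()

    baseline = cfg.baseline_mean * 2.0 ** rng.normal(0.0, cfg.baseline_log2_sd,
                                                     size=cfg.n_genes)
    sf = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=n_s))

    lfc_stage = {"non": np.zeros(cfg.n_genes),
                 "early": truth.genes["lfc_early"].to_numpy(),
                 "late": truth.genes["lfc_late"].to_numpy()}
    stage_of = samples["stage"].to_numpy()

    # latent factor activities -> within-stage co-expression
    weight = np.zeros((cfg.n_genes, len(truth.factors)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    if cfg.frac_null < 1.0:
        for fi, factor in enumerate(truth.factors):
            weight[gene_pos[factor], fi] = 1.0
            for target, s in truth.direct_targets[factor].items():
                if target != factor:
                    weight[gene_pos[target], fi] += float(s)
    activity = rng.normal(0.0, cfg.coexpr_sd, size=(len(truth.factors), n_s))

    log2_mean = (np.log2(baseline)[:, None]
                 + np.stack([lfc_stage[s] for s in stage_of], axis=1)
                 + weight @ activity
                 + np.log2(sf)[None, :])
    counts = _nb_draw(rng, 2.0 ** log2_mean, cfg.dispersion)
    cm = pd.DataFrame(counts, index=pd.Index(genes, name="feature_id"),
                      columns=samples["sample_id"])
    return cm, samples, truth


# ---------------------------------------------------------------------------
# ChIP layer


def generate_peak_counts(
    cfg: SimConfig,
    ann: pd.DataFrame,
    truth: TruthTable,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable, pd.DataFrame]:
    """Simulate peak tables and reads-in-peaks counts for each factor.

    Every planted direct target of a factor gets one peak inside its
    promoter window, with a stage-specific occupancy log2 fold-change
    (cycled through :data:`OCCUPANCY_EFFECTS`).  Promoter decoys (no
    occupancy change) and distal decoys complete the peak set.  Returns
    ``(peak_table, peak_counts, truth, chip_samples)`` with
    ``truth.peak_effects`` filled; the peak table carries a ``factor``
    column identifying the ChIP'd protein.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    ann_idx = ann.set_index("gene_id")
    half = cfg.promoter_halfwidth_bp

    rows, effects = [], []
    counter = 0

    def _new_peak(gene: str, factor: str, offset: int, width: int = 400):
        nonlocal counter
        g = ann_idx.loc[gene]
        mid = max(int(g["tss"]) + offset, width // 2)  # keep interval valid near 0
        counter += 1
        peak_id = f"peak_{counter:04d}"
        rows.append({"peak_id": peak_id, "chrom": g["chrom"],
                     "start": mid - width // 2, "end": mid + width // 2,
                     "score": 0.0, "strand": ".", "factor": factor})
        return peak_id

    eff_cycle = 0
    for factor in truth.factors:
        for target in truth.direct_targets[factor]:
            lfc = OCCUPANCY_EFFECTS[eff_cycle % len(OCCUPANCY_EFFECTS)]
            eff_cycle += 1
            offset = int(rng.integers(-half // 2, half // 2 + 1))
            pid = _new_peak(target, factor, offset)
            effects.append({"peak_id": pid, "factor": factor, "gene": target,
                            "is_target": True, "lfc_early": lfc, "lfc_late": lfc})

    background = truth.genes.loc[truth.genes["group"] == "background", "gene_id"]
    decoy_genes = rng.choice(background, size=min(cfg.n_promoter_decoys,
                                                  len(background)), replace=False)
    for factor in truth.factors:
        for gene in decoy_genes:
            offset = int(rng.integers(-half // 2, half // 2 + 1))
            pid = _new_peak(gene, factor, offset)
            effects.append({"peak_id": pid, "factor": factor, "gene": gene,
                            "is_target": False, "lfc_early": 0.0, "lfc_late": 0.0})

    n_distal = max(0, cfg.n_peaks - counter)
    all_genes = truth.genes["gene_id"].to_numpy()
    for i in range(n_distal):
        factor = truth.factors[i % len(truth.factors)]
        gene = str(rng.choice(all_genes))
        offset = int(rng.integers(3200, 4001)) * (1 if rng.random() < 0.5 else -1)
        pid = _new_peak(gene, factor, offset)
        effects.append({"peak_id": pid, "factor": factor, "gene": gene,
                        "is_target": False, "lfc_early": 0.0, "lfc_late": 0.0})

    peak_table = pd.DataFrame(rows)
    effect_df = pd.DataFrame(effects).set_index("peak_id")

    # ChIP samples: per factor, samples_per_stage per stage
    srows = []
    for factor in truth.factors:
        for stage in cfg.stages:
            points = cfg.time_points_h[stage]
            for i in range(cfg.samples_per_stage):
                srows.append({
                    "sample_id": f"chip_{factor}_{stage}_{i + 1}",
                    "time_h": float(points[i % len(points)]), "stage": stage,
                    "assay": "chipseq", "target": factor, "arm": "none",
                    "quality_flag": True,
                })
    chip_samples = pd.DataFrame(srows)
    sf = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(chip_samples)))

    lfc_cols = {"non": 0.0, "early": "lfc_early", "late": "lfc_late"}
    means = np.empty((len(peak_table), len(chip_samples)))
    for j, (_, s) in enumerate(chip_samples.iterrows()):
        stage = s["stage"]
        own = (peak_table["factor"] == s["target"]).to_numpy()
        lfc = np.zeros(len(peak_table))
        if stage != "non":
            lfc = effect_df.loc[peak_table["peak_id"], lfc_cols[stage]].to_numpy()
        means[:, j] = np.where(
            own, cfg.peak_baseline_mean * 2.0 ** lfc, cfg.peak_background_mean
        ) * sf[j]
    counts = _nb_draw(rng, means, cfg.dispersion)
    peak_counts = pd.DataFrame(
        counts, index=pd.Index(peak_table["peak_id"], name="feature_id"),
        columns=chip_samples["sample_id"])

    truth.peak_effects = effect_df.reset_index()
    return peak_table, peak_counts, truth, chip_samples


# ---------------------------------------------------------------------------
# knockdown layer


def generate_knockdown_counts(
    cfg: SimConfig,
    truth: TruthTable,
    factor: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a knockdown-vs-control count matrix for one factor.

    The KD arm divides the factor's own mean by ``2**kd_strength`` and
    shifts each planted direct target by ``-sign * kd_target_effect``
    log2 units (first-order propagation only).  Returns (counts, samples).
    """
    if factor not in truth.factors:
        raise ValidationError(f"{factor!r} is not a planted adipogenic TF")
    fi = truth.factors.index(factor)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2, fi)))

    genes = truth.genes["gene_id"].tolist()
    gene_pos = {g: i for i, g in enumerate(genes)}
    baseline = cfg.baseline_mean * 2.0 ** rng.normal(0.0, cfg.baseline_log2_sd,
                                                     size=len(genes))
    lfc_stage = {"non": np.zeros(len(genes)),
                 "early": truth.genes["lfc_early"].to_numpy(),
                 "late": truth.genes["lfc_late"].to_numpy()}

    kd_shift = np.zeros(len(genes))
    kd_shift[gene_pos[factor]] -= cfg.kd_strength
    for target, s in truth.direct_targets[factor].items():
        if target != factor:
            kd_shift[gene_pos[target]] -= s * cfg.kd_target_effect

    rows, mean_cols = [], []
    for t in cfg.kd_time_points_h:
        stage = assign_stage(t)
        for arm in ("control", "knockdown"):
            for i in range(cfg.samples_per_stage):
                sid = f"kd_{factor}_{arm}_t{int(t)}_{i + 1}"
                rows.append({"sample_id": sid, "time_h": float(t), "stage": stage,
                             "assay": "rnaseq", "target": factor, "arm": arm,
                             "quality_flag": True})
                shift = kd_shift if arm == "knockdown" else 0.0
                sf = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
                mean_cols.append(baseline * 2.0 ** (lfc_stage[stage] + shift) * sf)
    samples = pd.DataFrame(rows)
    means = np.column_stack(mean_cols)
    counts = _nb_draw(rng, means, cfg.dispersion)
    cm = pd.DataFrame(counts, index=pd.Index(genes, name="feature_id"),
                      columns=samples["sample_id"])
    return cm, samples


# ---------------------------------------------------------------------------
# gene sets


def generate_gene_sets(
    truth: TruthTable,
    n_decoys: int = 20,
    decoy_size: int = 30,
    seed: int = 0,
) -> GeneSetCollection:
    """GMT-style sets: one per planted group plus uniform random decoys.

    The autophagy set is the union of autophagy genes and autophagy TFs;
    the TF set unions both TF groups; their intersection defines the
    autophagy-TF set.  Empty groups are omitted with a warning.
    """
    rng = np.random.default_rng(seed)
    g = truth.genes
    by_group = {name: g.loc[g["group"] == name, "gene_id"].tolist() for name in GROUPS}
    autophagy_all = by_group["autophagy"] + by_group["autophagy_tf"]
    tf_all = by_group["autophagy_tf"] + by_group["adipogenic_tf"]
    autophagy_tf = sorted(set(autophagy_all) & set(tf_all))

    coll = GeneSetCollection()
    candidates = {
        "autophagy": (autophagy_all, "autophagy process genes"),
        "transcription_factor": (tf_all, "DNA-binding transcription factors"),
        "autophagy_tf": (autophagy_tf, "autophagy transcription factors "
                                       "(autophagy ∩ transcription_factor)"),
        "adipogenic_tf": (by_group["adipogenic_tf"], "adipogenic master regulators"),
        "lipogenic": (by_group["lipogenic"], "lipogenesis genes"),
    }
    for name, (members, desc) in candidates.items():
        if not members:
            warnings.warn(f"gene set {name!r} is empty; omitted")
            continue
        coll.add(name, members, desc)
    universe = g["gene_id"].to_numpy()
    size = min(decoy_size, len(universe))
    for i in range(n_decoys):
        members = rng.choice(universe, size=size, replace=False).tolist()
        coll.add(f"decoy_{i + 1:02d}", members, "uniform random decoy set")
    return coll
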