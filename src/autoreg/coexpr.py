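"""Per-stage co-expression and Fisher-z differential co-expression.

Expression is variance-stabilised as ``log2(count / size_factor + 1)``
(a closed-form, monotone stand-in for model-fitted VST).  For a factor
gene and a set of target genes, Pearson correlations are computed within
each stage; the between-stage difference of Fisher z-transformed
correlations is tested against a normal null and, more robustly, against
a pooled permutation null obtained by shuffling stage labels.  Pairs with
empirical q < 0.2 are flagged as differentially co-expressed (gain/loss).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from autoreg.diffexp import bh_adjust, size_factors
from autoreg.errors import ValidationError

logger = logging.getLogger(__name__)

R_CLAMP = 1.0 - 1e-12


def vst(counts: pd.DataFrame, sf: pd.Series | None = None) -> pd.DataFrame:
    """Shifted-log variance-stabilising transform of normalised counts."""
    if sf is None:
        try:
            sf = size_factors(counts)
        except ValidationError:
            sf = size_factors(counts, method="poscounts")
    sf = sf.reindex(counts.columns)
    return np.log2(counts / sf + 1.0)


def _pearson_vec(targets: np.ndarray, factor: np.ndarray) -> np.ndarray:
    """Pearson r of each row of *targets* against *factor* (NaN if flat)."""
    n = factor.shape[0]
    fc = factor - factor.mean()
    tc = targets - targets.mean(axis=1, keepdims=True)
    fnorm = np.sqrt((fc**2).sum())
    tnorm = np.sqrt((tc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (tc @ fc) / (tnorm * fnorm)
    r[(tnorm == 0) | np.isnan(r)] = np.nan
    if fnorm == 0:
        r[:] = np.nan
    return r


def stage_pcc(
    expr: pd.DataFrame,
    factor: str,
    targets: list[str],
    stage_samples: list[str],
    de_labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Pearson correlation of *factor* with each target over one stage.

    Zero-variance vectors yield NaN correlations and the pair is dropped
    with a log notice.  ``de_labels`` (target -> up/down/none) optionally
    stratifies the output.
    """
    if len(stage_samples) < 4:
        raise ValidationError(f"need >= 4 samples in stage, got {len(stage_samples)}")
    f = expr.loc[factor, stage_samples].to_numpy(dtype=float)
    present = [t for t in targets if t in expr.index]
    T = expr.loc[present, stage_samples].to_numpy(dtype=float)
    r = _pearson_vec(T, f)
    out = pd.DataFrame({
        "factor": factor,
        "target": present,
        "r": r,
        "n": len(stage_samples),
    })
    dropped = out["r"].isna()
    if dropped.any():
        logger.info("stage_pcc: dropped %d zero-variance pairs", int(dropped.sum()))
        out = out[~dropped]
    if de_labels is not None:
        out["target_de_label"] = out["target"].map(de_labels).fillna("none")
    return out.reset_index(drop=True)


def fisher_z(r: float | np.ndarray, n: int) -> tuple[np.ndarray, float]:
    """Fisher transform: z = atanh(r), var = 1/(n-3).

    |r| = 1 is clamped just inside the open interval with a warning.
    """
    if n <= 3:
        raise ValidationError(f"Fisher z requires n > 3, got {n}")
    r = np.asarray(r, dtype=float)
    if (np.abs(r) >= 1.0).any():
        warnings.warn("|r| = 1 clamped for Fisher z")
        r = np.clip(r, -R_CLAMP, R_CLAMP)
    return np.arctanh(r), 1.0 / (n - 3)


def diff_coexpr_test(
    r1: float | np.ndarray, n1: int, r2: float | np.ndarray, n2: int
) -> tuple[np.ndarray, np.ndarray]:
    """Normal test of a correlation difference between two conditions.

    z_diff = (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3)); two-sided normal p.
    """
    z1, v1 = fisher_z(r1, n1)
    z2, v2 = fisher_z(r2, n2)
    z_diff = (z1 - z2) / np.sqrt(v1 + v2)
    p = 2.0 * stats.norm.sf(np.abs(z_diff))
    return z_diff, p


def permutation_qvalues(
    expr: pd.DataFrame,
    factor: str,
    targets: list[str],
    samples_a: list[str],
    samples_b: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    pooled_null: bool = True,
    q_threshold: float = 0.2,
) -> pd.DataFrame:
    """Permutation empirical p/q for differential co-expression A vs B.

    Stage labels are shuffled across the pooled samples ``n_perm`` times;
    |z_diff| values from all permutations form the null.  With
    ``pooled_null`` (default) every pair shares one null pool and
    ``p_emp = (1 + #{null >= obs}) / (1 + n_perm * n_pairs)``; otherwise
    each pair is compared to its own per-pair null.  q-values are BH over
    empirical p within the factor's pair set; pairs with q < 0.2 are
    labelled ``gain`` (|r| larger in A) or ``loss``.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives coarse empirical p resolution")
    n1, n2 = len(samples_a), len(samples_b)
    if min(n1, n2) < 4:
        raise ValidationError("both stages need >= 4 samples")
    present = [t for t in targets if t in expr.index]

    fa = expr.loc[factor, samples_a].to_numpy(dtype=float)
    fb = expr.loc[factor, samples_b].to_numpy(dtype=float)
    Ta = expr.loc[present, samples_a].to_numpy(dtype=float)
    Tb = expr.loc[present, samples_b].to_numpy(dtype=float)
    r1, r2 = _pearson_vec(Ta, fa), _pearson_vec(Tb, fb)
    keep = ~(np.isnan(r1) | np.isnan(r2))
    present = [t for t, k in zip(present, keep) if k]
    r1, r2 = r1[keep], r2[keep]
    z_obs, p_normal = diff_coexpr_test(r1, n1, r2, n2)

    pooled = samples_a + samples_b
    F = expr.loc[factor, pooled].to_numpy(dtype=float)
    T = expr.loc[present, pooled].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(present)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # permuted flat vectors
        for b in range(n_perm):
            perm = rng.permutation(len(pooled))
            ia, ib = perm[:n1], perm[n1:]
            rp1 = _pearson_vec(T[:, ia], F[ia])
            rp2 = _pearson_vec(T[:, ib], F[ib])
            zp, _ = diff_coexpr_test(np.nan_to_num(rp1), n1, np.nan_to_num(rp2), n2)
            null[b] = np.abs(zp)

    obs = np.abs(z_obs)
    if pooled_null:
        flat = np.sort(null.ravel())
        n_null = flat.size
        ge = n_null - np.searchsorted(flat, obs, side="left")
        p_emp = (1.0 + ge) / (1.0 + n_null)
    else:
        ge = (null >= obs[None, :]).sum(axis=0)
        p_emp = (1.0 + ge) / (1.0 + n_perm)
    q_emp = bh_adjust(p_emp)

    gain = (q_emp < q_threshold) & (np.abs(r1) > np.abs(r2))
    loss = (q_emp < q_threshold) & ~gain
    label = np.select([gain, loss], ["gain", "loss"], default="none")

    return pd.DataFrame({
        "factor": factor,
        "target": present,
        "r_a": r1, "n_a": n1,
        "r_b": r2, "n_b": n2,
        "z_diff": z_obs,
        "p_normal": p_normal,
        "p_empirical": p_emp,
        "q_empirical": q_emp,
        "pair_label": label,
    })


def coexpr_all_stages(
    expr: pd.DataFrame,
    factors: list[str],
    targets: list[str],
    stage_sample_map: dict[str, list[str]],
    de_labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-stage correlations for every factor (convenience driver)."""
    frames = []
    for stage, cols in stage_sample_map.items():
        for factor in factors:
            tab = stage_pcc(expr, factor, [t for t in targets if t != factor],
                            cols, de_labels=de_labels)
            tab.insert(2, "stage", stage)
            frames.append(tab)
    return pd.concat(frames, ignore_index=True)
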