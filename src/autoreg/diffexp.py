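"""Negative-binomial Wald differential expression and classical MDS.

The model is a simplified NB GLM with log link and group-mean
parameterisation: counts ~ NB(mean = s_j * m_g, dispersion alpha) where
s_j is a per-sample size factor and m_g a per-group mean fitted by Fisher
scoring.  log2 fold-changes are contrasts of fitted log group means; the
Wald statistic uses the expected information.  No Cox-Reid dispersion
adjustment, LFC shrinkage or outlier filtering is applied.

Regulation labels follow fixed thresholds: a feature is ``up`` when
log2FC > +tau and FDR < q (``down`` symmetric), with tau = 1.0 for genes
and tau = 0.5 for peaks by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from autoreg.errors import ValidationError

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)

#: Stage contrasts in (numerator, denominator) order.
STAGE_CONTRASTS = (("early", "non"), ("late", "non"), ("late", "early"))

DISPERSION_FLOOR = 1e-8


@dataclass
class DesignSpec:
    """Sample grouping plus the thresholds used for regulation labels."""

    groups: pd.Series  # sample_id -> group label
    contrasts: tuple[tuple[str, str], ...] = STAGE_CONTRASTS
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.2

    def __post_init__(self) -> None:
        levels = set(self.groups.unique())
        for num, den in self.contrasts:
            if num not in levels or den not in levels:
                raise ValidationError(
                    f"contrast {num} vs {den} references a group absent "
                    f"from the design ({sorted(levels)})"
                )


def size_factors(counts: pd.DataFrame, method: str = "ratio") -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    ``method="ratio"`` uses features with nonzero counts in every sample
    (the classic estimator) and raises if there are none, pointing at the
    ``"poscounts"`` fallback, which takes the geometric mean over positive
    counts only and the median ratio over features positive in the sample.
    """
    values = counts.to_numpy(dtype=float)
    if method == "ratio":
        all_pos = (values > 0).all(axis=1)
        if not all_pos.any():
            raise ValidationError(
                "no feature has nonzero counts in all samples; "
                "use size_factors(..., method='poscounts')"
            )
        logv = np.log(values[all_pos])
        log_geomean = logv.mean(axis=1)
        log_sf = np.median(logv - log_geomean[:, None], axis=0)
    elif method == "poscounts":
        with np.errstate(divide="ignore"):
            logv = np.where(values > 0, np.log(values), np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            log_geomean = np.nanmean(logv, axis=1)
            ratios = logv - log_geomean[:, None]
            log_sf = np.nanmedian(ratios, axis=0)
        if np.isnan(log_sf).any():
            raise ValidationError("a sample has no positive counts")
    else:
        raise ValueError(f"unknown size-factor method {method!r}")
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    groups: pd.Series,
    sf: pd.Series | None = None,
    shrink_weight: float = 0.5,
) -> pd.Series:
    """Per-feature NB dispersion alpha (var = mu + alpha * mu^2).

    Method-of-moments on normalised counts with the within-group variance
    pooled across groups, then shrunk toward a 1/mu trend fit by a fixed
    weighted average.  Values are floored at ``DISPERSION_FLOOR``.
    """
    groups = groups.reindex(counts.columns)
    sizes = groups.value_counts()
    if (sizes < 2).all():
        raise ValidationError("dispersion estimation requires replicates "
                              "(every group has a single sample)")
    if sf is None:
        sf = size_factors(counts, method="poscounts")
    norm = counts.to_numpy(dtype=float) / sf.reindex(counts.columns).to_numpy()

    ss = np.zeros(norm.shape[0])
    dof = 0
    for g in sizes.index:
        cols = np.flatnonzero((groups == g).to_numpy())
        if len(cols) < 2:
            continue
        sub = norm[:, cols]
        ss += sub.var(axis=1, ddof=1) * (len(cols) - 1)
        dof += len(cols) - 1
    pooled_var = ss / dof
    mu = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (pooled_var - mu) / mu**2, 0.0)
    raw = np.maximum(raw, 0.0)

    trend = _dispersion_trend(mu, raw)
    alpha = (1.0 - shrink_weight) * raw + shrink_weight * trend
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _dispersion_trend(mu: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha ~ a0 + a1/mu on informative features."""
    ok = (mu > 0) & (raw > 0)
    if ok.sum() < 10:
        # too few informative features: flat trend at the median raw value
        level = float(np.median(raw[raw > 0])) if (raw > 0).any() else 0.0
        return np.full_like(raw, max(level, DISPERSION_FLOOR))
    x = 1.0 / mu[ok]
    design = np.column_stack([np.ones(ok.sum()), x])
    coef, *_ = np.linalg.lstsq(design, raw[ok], rcond=None)
    a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.where(mu > 0, mu, np.inf)
    return np.maximum(trend, DISPERSION_FLOOR)


def _fit_group_mean(
    y: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 50, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fisher-scoring fit of one log group mean per feature.

    Parameters are arrays over features; ``y`` is features x samples (one
    group), ``s`` the group's size factors, ``alpha`` per-feature
    dispersions.  Returns (eta = log mean, expected information, converged).
    """
    total = y.sum(axis=1)
    zero = total == 0
    # start from the ratio estimator; zero-total features get a half count
    m0 = np.where(zero, 0.5 / s.sum(), total / s.sum())
    eta = np.log(m0)
    converged = zero.copy()  # zero-total groups stay at the half-count start
    info = np.empty_like(eta)
    for _ in range(n_iter):
        mu = s[None, :] * np.exp(eta)[:, None]
        denom = 1.0 + alpha[:, None] * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        newly = np.abs(step) < tol
        converged |= newly
        eta = eta + np.where(converged, 0.0, step)
    mu = s[None, :] * np.exp(eta)[:, None]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return eta, info, converged | zero


def nb_wald_test(
    counts: pd.DataFrame,
    design: DesignSpec,
    contrast: tuple[str, str],
    sf: pd.Series | None = None,
    dispersion: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-feature NB Wald test for one contrast ``(numerator, denominator)``.

    Returns a DataFrame with columns ``feature_id, contrast, log2fc, se,
    stat, p, fdr, label``.  Features that are all-zero in both groups (or
    fail to converge) get ``p = NaN`` and are excluded from the BH
    adjustment.
    """
    num, den = contrast
    groups = design.groups.reindex(counts.columns)
    if sf is None:
        try:
            sf = size_factors(counts)
        except ValidationError:
            sf = size_factors(counts, method="poscounts")
    sf = sf.reindex(counts.columns)
    if dispersion is None:
        dispersion = estimate_dispersion(counts, groups, sf)
    alpha = dispersion.reindex(counts.index).to_numpy()

    values = counts.to_numpy(dtype=float)
    out = {}
    for label_ in (num, den):
        cols = np.flatnonzero((groups == label_).to_numpy())
        if len(cols) == 0:
            raise ValidationError(f"contrast group {label_!r} has no samples")
        out[label_] = _fit_group_mean(values[:, cols], sf.to_numpy()[cols], alpha)

    eta_num, info_num, conv_num = out[num]
    eta_den, info_den, conv_den = out[den]
    log2fc = (eta_num - eta_den) / LN2
    se = np.sqrt(1.0 / np.maximum(info_num, 1e-12)
                 + 1.0 / np.maximum(info_den, 1e-12)) / LN2
    stat = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(stat))

    both_zero = (values[:, np.flatnonzero((groups == num).to_numpy())].sum(axis=1) == 0) & \
                (values[:, np.flatnonzero((groups == den).to_numpy())].sum(axis=1) == 0)
    failed = ~(conv_num & conv_den)
    if failed.any():
        logger.info("nb_wald_test: %d features did not converge; p set to NA",
                    int(failed.sum()))
    invalid = both_zero | failed
    log2fc = np.where(both_zero, 0.0, log2fc)
    p = np.where(invalid, np.nan, p)

    fdr = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    fdr[ok] = bh_adjust(p[ok])

    res = pd.DataFrame({
        "feature_id": counts.index,
        "contrast": f"{num}_vs_{den}",
        "log2fc": log2fc,
        "se": se,
        "stat": np.where(invalid, np.nan, stat),
        "p": p,
        "fdr": fdr,
    })
    return classify_de(res, design.lfc_threshold, design.fdr_threshold)


def classify_de(res: pd.DataFrame, tau: float = 1.0, q: float = 0.2) -> pd.DataFrame:
    """Attach regulation labels: up if log2FC > +tau and FDR < q; down symmetric."""
    res = res.copy()
    up = (res["log2fc"] > tau) & (res["fdr"] < q)
    down = (res["log2fc"] < -tau) & (res["fdr"] < q)
    res["label"] = np.select([up.fillna(False), down.fillna(False)],
                             ["up", "down"], default="none")
    return res


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def run_contrasts(
    counts: pd.DataFrame, design: DesignSpec, sf: pd.Series | None = None
) -> pd.DataFrame:
    """All contrasts of a design, concatenated (shared dispersion fit)."""
    groups = design.groups.reindex(counts.columns)
    if sf is None:
        try:
            sf = size_factors(counts)
        except ValidationError:
            sf = size_factors(counts, method="poscounts")
    disp = estimate_dispersion(counts, groups, sf)
    frames = [
        nb_wald_test(counts, design, contrast, sf=sf, dispersion=disp)
        for contrast in design.contrasts
    ]
    return pd.concat(frames, ignore_index=True)


def kd_contrasts(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.2,
) -> pd.DataFrame:
    """Knockdown-vs-control Wald tests, one contrast per time point.

    *samples* must carry ``arm`` (control/knockdown) and ``time_h``; the
    result gains a ``time_h`` column next to the usual DEResult fields.
    """
    frames = []
    for t in sorted(samples["time_h"].unique()):
        at_t = samples[samples["time_h"] == t]
        cols = [s for s in at_t["sample_id"] if s in counts.columns]
        groups = at_t.set_index("sample_id")["arm"].reindex(cols)
        if set(groups.unique()) != {"control", "knockdown"}:
            raise ValidationError(f"time {t} h lacks a control or knockdown arm")
        design = DesignSpec(groups=groups,
                            contrasts=(("knockdown", "control"),),
                            lfc_threshold=lfc_threshold,
                            fdr_threshold=fdr_threshold)
        res = run_contrasts(counts[cols], design)
        res.insert(1, "time_h", t)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# classical multidimensional scaling


def classical_mds(
    expr: pd.DataFrame, subset: list[str] | None = None, k: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Torgerson MDS of samples on Euclidean distances over a gene subset.

    Parameters
    ----------
    expr
        Transformed expression, features x samples.
    subset
        Optional gene ids restricting the distance computation.
    k
        Number of output dimensions; silently reduced (with a warning) if
        fewer positive eigenvalues exist.

    Returns
    -------
    (coordinates, variance_explained)
        ``coordinates`` is samples x k; ``variance_explained[d]`` is
        lambda_d over the sum of positive eigenvalues.
    """
    X = expr if subset is None else expr.loc[[g for g in subset if g in expr.index]]
    samples = X.columns
    if len(samples) < k + 1:
        raise ValidationError(f"need at least k+1={k + 1} samples, got {len(samples)}")
    M = X.to_numpy(dtype=float).T  # samples x features
    sq = (M**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * M @ M.T
    np.fill_diagonal(d2, 0.0)
    d2 = np.maximum(d2, 0.0)

    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-9 * max(eigval.max(), 1.0)
    n_pos = int(pos.sum())
    if n_pos < k:
        warnings.warn(f"only {n_pos} positive eigenvalues; reducing k from {k}")
        k = n_pos
    lam = eigval[:k]
    coords = eigvec[:, :k] * np.sqrt(lam)[None, :]
    var_explained = lam / eigval[pos].sum()
    coords = pd.DataFrame(coords, index=samples,
                          columns=[f"dim{i + 1}" for i in range(k)])
    return coords, var_explained
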