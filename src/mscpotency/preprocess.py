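"""Feature-table preprocessing: QC filtering, normalization, batch correction.

The MS route is blank/QC filtering -> RSD filtering -> median normalization
-> ComBat batch correction -> autoscaling. The NMR route is ComBat ->
per-flask day-differencing -> PLSR-guided variance filtering. Every filter
returns a :class:`FilterReport` that exactly partitions the input features
into kept and removed.

ComBat is the parametric empirical-Bayes location/scale adjustment: features
are standardized, per-batch per-feature location (gamma) and scale (delta^2)
estimates are shrunk toward batch-level hyperpriors (normal prior on gamma,
inverse-gamma on delta^2) by iterating the EB estimating equations, the
batch effects are removed on the standardized axis, and the grand
location/scale is restored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .core import CompositeScore, FeatureTable, ValidationError, logger


@dataclass
class FilterReport:
    """Outcome of one filtering rule: removed ids + parameters used."""

    rule: str
    removed: list[str]
    kept_count: int
    params: dict = field(default_factory=dict)

    def check_partition(self, input_features: list[str]) -> None:
        removed = set(self.removed)
        if removed - set(input_features):
            raise ValidationError("filter removed features not in the input")
        if len(input_features) - len(removed) != self.kept_count:
            raise ValidationError("filter report does not partition the input")


# ---------------------------------------------------------------------------
# Blank / QC-presence filter
# ---------------------------------------------------------------------------

def blank_qc_filter(
    table: FeatureTable,
    blank_ratio: float = 5.0,
    qc_presence: float = 0.5,
) -> tuple[FeatureTable, FilterReport]:
    """Keep features with mean experimental signal >= ``blank_ratio`` x mean
    blank signal that are nonzero in >= ``qc_presence`` of QC-pool injections.

    Blank and QC samples stay in the output table for audit.
    """
    blanks = table.values.loc[table.role_mask("blank")]
    qcs = table.values.loc[table.role_mask("qc_pool")]
    if blanks.empty or qcs.empty:
        raise ValidationError("blank_qc_filter needs >=1 blank and >=1 qc_pool sample")
    exp_mean = table.experimental_values().mean(axis=0)
    blank_mean = blanks.mean(axis=0)
    presence = (qcs > 0).mean(axis=0)

    keep = (exp_mean >= blank_ratio * blank_mean) & (presence >= qc_presence)
    kept = [f for f in table.feature_ids if keep[f]]
    removed = [f for f in table.feature_ids if not keep[f]]
    report = FilterReport(
        rule="blank_qc",
        removed=removed,
        kept_count=len(kept),
        params={"blank_ratio": blank_ratio, "qc_presence": qc_presence},
    )
    out = table.subset_features(kept, stage="filtered")
    logger.info("blank/QC filter removed %d of %d features", len(removed), table.n_features)
    return out, report


# ---------------------------------------------------------------------------
# RSD filter
# ---------------------------------------------------------------------------

def rsd_filter(
    table: FeatureTable,
    threshold: float = 0.25,
    mode: str = "remove_below",
) -> tuple[FeatureTable, FilterReport]:
    """Filter features by relative SD (sd/|mean|) over experimental samples.

    The default ``remove_below`` discards features whose RSD is *below* the
    threshold (dropping near-constant features); ``remove_above`` gives the
    conventional QC-repeatability reading. Features with zero mean (RSD
    undefined) are removed and logged in either mode.
    """
    if mode not in ("remove_below", "remove_above"):
        raise ValidationError(f"unknown rsd_filter mode {mode!r}")
    exp = table.experimental_values()
    if exp.shape[0] < 2:
        raise ValidationError("rsd_filter needs >=2 experimental samples")
    mean = exp.mean(axis=0)
    sd = exp.std(axis=0, ddof=1)
    undefined = mean == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = sd / mean.abs()

    if mode == "remove_below":
        remove = (rsd < threshold) | undefined
    else:
        remove = (rsd > threshold) | undefined
    if undefined.any():
        logger.warning(
            "rsd_filter: %d feature(s) with zero mean removed (RSD undefined)",
            int(undefined.sum()),
        )
    kept = [f for f in table.feature_ids if not remove[f]]
    removed = [f for f in table.feature_ids if remove[f]]
    report = FilterReport(
        rule="rsd",
        removed=removed,
        kept_count=len(kept),
        params={"threshold": threshold, "mode": mode},
    )
    return table.subset_features(kept, stage="filtered"), report


# ---------------------------------------------------------------------------
# Normalization / scaling
# ---------------------------------------------------------------------------

def median_normalize(table: FeatureTable) -> FeatureTable:
    """Scale each sample so all sample medians equal the global median of
    sample medians."""
    if table.stage not in ("raw", "filtered"):
        raise ValidationError("median_normalize expects a raw or filtered table")
    medians = table.values.median(axis=1)
    if (medians == 0).any():
        sid = medians.index[medians == 0][0]
        raise ValidationError(f"sample {sid!r} has median 0; cannot median-normalize")
    target = medians.median()
    factors = target / medians
    values = table.values.mul(factors, axis=0)
    return table.with_values(values, stage="normalized")


def autoscale(table: FeatureTable) -> FeatureTable:
    """Center/scale each feature to mean 0, SD 1 over experimental samples.

    Scaling parameters come from the experimental samples and are applied to
    every sample. Zero-SD features are set to 0 with a warning.
    """
    exp = table.experimental_values()
    if exp.shape[0] < 2:
        raise ValidationError("autoscale needs >=2 experimental samples")
    mean = exp.mean(axis=0)
    sd = exp.std(axis=0, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.warning("autoscale: %d constant feature(s) set to 0", int(flat.sum()))
    sd_safe = sd.mask(flat, 1.0)
    values = (table.values - mean) / sd_safe
    values.loc[:, flat[flat].index] = 0.0
    return table.with_values(values, stage="scaled")


# ---------------------------------------------------------------------------
# ComBat batch correction
# ---------------------------------------------------------------------------

def _combat_it_sol(
    z: np.ndarray,
    g_hat: np.ndarray,
    d_hat: np.ndarray,
    g_bar: float,
    t2: float,
    a_prior: float,
    b_prior: float,
    conv: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the EB estimating equations for one batch.

    ``z``: standardized data for the batch (features x samples);
    ``g_hat``/``d_hat``: per-feature batch location and scale estimates.
    """
    n = (~np.isnan(z)).sum(axis=1)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        sum2 = np.nansum((z - g_new[:, None]) ** 2, axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old).clip(min=1e-12)),
            np.max(np.abs(d_new - d_old) / np.abs(d_old).clip(min=1e-12)),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat_correct(table: FeatureTable, batch_key: str = "batch_id") -> FeatureTable:
    """Parametric empirical-Bayes ComBat batch correction.

    A single batch is a fixed point (the input is returned unchanged).
    Features with zero variance within any batch are skipped with a warning.
    """
    batches = table.sample_meta[batch_key].astype(str)
    levels = list(dict.fromkeys(batches))
    if len(levels) < 2:
        return table.copy()
    counts = batches.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValidationError(
            f"batch {small.index[0]!r} has {int(small.iloc[0])} sample(s); ComBat needs >=2"
        )

    X = table.values.to_numpy(dtype=float).T  # features x samples
    n_feat, n_samp = X.shape
    masks = [(batches == b).to_numpy() for b in levels]
    n_b = np.array([m.sum() for m in masks], dtype=float)

    batch_means = np.stack([X[:, m].mean(axis=1) for m in masks], axis=1)
    grand = batch_means @ (n_b / n_samp)
    # residual variance after removing batch means
    fitted = np.zeros_like(X)
    for k, m in enumerate(masks):
        fitted[:, m] = batch_means[:, [k]]
    var_pooled = ((X - fitted) ** 2).mean(axis=1)

    within_var = np.stack([X[:, m].var(axis=1, ddof=1) for m in masks], axis=1)
    skip = (var_pooled == 0) | (within_var == 0).any(axis=1)
    if skip.any():
        logger.warning(
            "combat_correct: %d feature(s) with zero within-batch variance skipped",
            int(skip.sum()),
        )
    ok = ~skip
    sd = np.sqrt(var_pooled[ok])
    Z = (X[ok] - grand[ok, None]) / sd[:, None]

    adjusted = X.copy()
    Z_adj = Z.copy()
    for k, m in enumerate(masks):
        zb = Z[:, m]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        g_bar = g_hat.mean()
        t2 = g_hat.var(ddof=1) if len(g_hat) > 1 else 1.0
        m_d, s2_d = d_hat.mean(), d_hat.var(ddof=1) if len(d_hat) > 1 else 1.0
        # method-of-moments inverse-gamma hyperparameters
        a_prior = (2.0 * s2_d + m_d**2) / s2_d if s2_d > 0 else 2.0
        b_prior = (m_d * s2_d + m_d**3) / s2_d if s2_d > 0 else m_d
        if len(g_hat) > 1 and t2 > 0:
            g_star, d_star = _combat_it_sol(zb, g_hat, d_hat, g_bar, t2, a_prior, b_prior)
        else:  # too few features for EB shrinkage: use direct estimates
            g_star, d_star = g_hat, d_hat
        Z_adj[:, m] = (zb - g_star[:, None]) / np.sqrt(d_star)[:, None]
    adjusted[ok] = Z_adj * sd[:, None] + grand[ok, None]

    values = pd.DataFrame(adjusted.T, index=table.values.index, columns=table.values.columns)
    # adjusted values may dip below zero; the table is no longer raw data
    out_stage = "filtered" if table.stage == "raw" else table.stage
    return table.with_values(values, stage=out_stage)


# ---------------------------------------------------------------------------
# NMR day differencing
# ---------------------------------------------------------------------------

def day_difference(
    nmr_table: FeatureTable,
    target_day: int,
    baseline_day: int = 1,
) -> FeatureTable:
    """Per replicate flask, value(target_day) - value(baseline_day).

    Output samples are (line, replicate) pairs at stage ``differenced``;
    negative values are expected and allowed.
    """
    meta = nmr_table.sample_meta
    if "day" not in meta.columns or "replicate_id" not in meta.columns:
        raise ValidationError("day_difference needs 'day' and 'replicate_id' metadata")
    exp = meta[meta["role"] == "experimental"]

    def pick(day: int) -> pd.DataFrame:
        sub = exp[exp["day"].astype(int) == day]
        return sub.set_index([sub["line_id"], sub["replicate_id"]])

    base, targ = pick(baseline_day), pick(target_day)
    for day, sub in ((baseline_day, base), (target_day, targ)):
        if sub.index.has_duplicates:
            flask = sub.index[sub.index.duplicated()][0]
            raise ValidationError(f"flask {flask} has multiple samples on day {day}")
    if not base.index.sort_values().equals(targ.index.sort_values()):
        odd = base.index.symmetric_difference(targ.index)[0]
        raise ValidationError(
            f"flask {odd} lacks a sample on day {baseline_day} or {target_day}"
        )
    # align by original sample ids, sorted by (line, replicate)
    base_ids = exp[exp["day"].astype(int) == baseline_day].sort_values(
        ["line_id", "replicate_id"]).index
    targ_ids = exp[exp["day"].astype(int) == target_day].sort_values(
        ["line_id", "replicate_id"]).index
    diff_vals = (
        nmr_table.values.loc[targ_ids].to_numpy()
        - nmr_table.values.loc[base_ids].to_numpy()
    )
    pairs = exp.loc[base_ids, ["line_id", "replicate_id", "batch_id"]]
    new_ids = [f"{ln}_{rep}" for ln, rep in zip(pairs["line_id"], pairs["replicate_id"])]
    values = pd.DataFrame(
        diff_vals, index=pd.Index(new_ids, name="sample_id"), columns=nmr_table.values.columns
    )
    sample_meta = pd.DataFrame(
        {
            "line_id": pairs["line_id"].to_numpy(),
            "batch_id": pairs["batch_id"].to_numpy(),
            "role": "experimental",
            "day": target_day,
            "replicate_id": pairs["replicate_id"].to_numpy(),
        },
        index=values.index,
    )
    return FeatureTable(values=values, sample_meta=sample_meta,
                        feature_meta=nmr_table.feature_meta.copy(), stage="differenced")


# ---------------------------------------------------------------------------
# PLSR-guided variance filter
# ---------------------------------------------------------------------------

DEFAULT_PERCENT_GRID = tuple(round(0.05 * i, 2) for i in range(1, 21))


def _plsr_loo_r2(X: np.ndarray, y: np.ndarray, n_components: int) -> float:
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        pls = PLSRegression(n_components=n_components, scale=False)
        Xtr = X[mask]
        # center using training folds only
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        pls.fit((Xtr - mu) / sd, y[mask])
        preds[i] = float(np.ravel(pls.predict((X[[i]] - mu) / sd))[0])
    sst = ((y - y.mean()) ** 2).sum()
    return 1.0 - ((y - preds) ** 2).sum() / sst


def variance_filter_select(
    line_matrix: pd.DataFrame,
    y: CompositeScore | pd.Series,
    percent_grid: tuple[float, ...] = DEFAULT_PERCENT_GRID,
) -> tuple[pd.DataFrame, float, dict[float, float]]:
    """Choose the top-variance feature fraction maximizing PLSR LOO-R^2.

    ``line_matrix`` must hold one row per cell line (replicate means).
    Returns (restricted matrix, chosen fraction, LOO-R^2 per grid point);
    ties prefer the smaller fraction.
    """
    if not percent_grid:
        raise ValidationError("percent_grid must be non-empty")
    scores = y.scores if isinstance(y, CompositeScore) else y
    lines = [l for l in line_matrix.index if l in scores.index]
    if len(lines) < 4:
        raise ValidationError("variance_filter_select needs >=4 lines with scores")
    X_full = line_matrix.loc[lines]
    yv = scores.loc[lines].to_numpy(dtype=float)
    variances = X_full.var(axis=0, ddof=1)
    order = variances.sort_values(ascending=False, kind="stable").index

    n_feat = X_full.shape[1]
    n_comp = min(2, len(lines) - 2)
    results: dict[float, float] = {}
    for p in sorted(percent_grid):
        k = max(1, math.ceil(p * n_feat))
        feats = list(order[:k])
        results[p] = _plsr_loo_r2(X_full[feats].to_numpy(dtype=float), yv, n_comp)
    best_p = max(sorted(results), key=lambda p: (results[p], -p))
    k = max(1, math.ceil(best_p * n_feat))
    subset = X_full[list(order[:k])]
    logger.info(
        "variance filter chose top %.0f%% (%d features, LOO-R^2=%.3f)",
        100 * best_p, k, results[best_p],
    )
    return subset, best_p, results
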