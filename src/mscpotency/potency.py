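"""Composite potency scoring and univariate feature screening.

The composite functional score is the first principal component of the
autoscaled five-variable assay panel (CD4/CD8 %CFSE dilution for two PBMC
donors plus IDO activity). PC1 is sign-oriented so that higher T-cell
proliferation (weaker MSC immunomodulation) maps to a higher score — i.e.
lower scores mean higher potency.

Univariate screening regresses the composite score on each feature's
line-level mean by OLS, reports slope, R^2 and a two-sided p-value for the
slope, applies Benjamini-Hochberg FDR across features, and orders by R^2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import (
    ASSAY_COLUMNS,
    PROLIFERATION_COLUMNS,
    CompositeScore,
    PotencyAssayPanel,
    ValidationError,
)


def ido_activity_per_cell(kynurenine_pg: float, cell_count: float, duration_days: float) -> float:
    """L-kynurenine mass normalized per cell per day (pg/cell/day)."""
    if cell_count <= 0 or duration_days <= 0:
        raise ValidationError("cell_count and duration_days must be positive")
    return kynurenine_pg / (cell_count * duration_days)


def composite_score(panel: PotencyAssayPanel) -> CompositeScore:
    """PCA of the autoscaled assay panel; PC1 per line is the score.

    Requires >= 3 lines and non-constant assay columns. The PC1 sign is
    chosen so the loading mass on the four proliferation variables is
    positive, which reproduces the "lower score = higher potency" convention
    deterministically.
    """
    assays = panel.assays[list(ASSAY_COLUMNS)].astype(float)
    if len(assays) < 3:
        raise ValidationError("composite_score needs >= 3 lines")
    sd = assays.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0][0]
        raise ValidationError(f"assay column {bad!r} has zero variance across lines")
    Z = (assays - assays.mean(axis=0)) / sd

    # PCA via SVD of the centered (already scaled) matrix
    U, S, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    var = S**2
    ratios = var / var.sum()
    loadings = pd.Series(Vt[0], index=assays.columns)
    scores = pd.Series(U[:, 0] * S[0], index=assays.index, name="composite_score")

    orientation = 1
    if loadings[list(PROLIFERATION_COLUMNS)].mean() < 0:
        orientation = -1
        scores = -scores
        loadings = -loadings
    return CompositeScore(
        scores=scores,
        variance_explained=float(ratios[0]),
        variance_ratios=ratios,
        loadings=loadings,
        orientation=orientation,
    )


def univariate_screen(
    line_matrix: pd.DataFrame,
    y: CompositeScore | pd.Series,
    fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-feature simple linear regression of the composite score.

    ``line_matrix``: one row per cell line. Returns a DataFrame indexed by
    feature with columns ``slope``, ``r2``, ``p``, ``q``, sorted by R^2
    descending. Constant features get slope 0, R^2 0, p 1.
    """
    scores = y.scores if isinstance(y, CompositeScore) else y
    lines = [l for l in line_matrix.index if l in scores.index]
    if len(lines) < 4:
        raise ValidationError("univariate_screen needs >= 4 lines")
    X = line_matrix.loc[lines].to_numpy(dtype=float)
    yv = scores.loc[lines].to_numpy(dtype=float)
    n = len(yv)

    xc = X - X.mean(axis=0)
    yc = yv - yv.mean()
    sxx = (xc**2).sum(axis=0)
    syy = float((yc**2).sum())
    sxy = xc.T @ yc
    constant = sxx == 0
    sxx_safe = np.where(constant, 1.0, sxx)

    slope = sxy / sxx_safe
    r2 = np.where(constant | (syy == 0), 0.0, (sxy**2) / (sxx_safe * syy))
    r2 = np.clip(r2, 0.0, 1.0)
    # t-test for the slope, df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.sqrt(np.maximum(r2, 0.0) * (n - 2) / np.maximum(1.0 - r2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(constant, 1.0, np.clip(p, 0.0, 1.0))
    slope = np.where(constant, 0.0, slope)

    q = multipletests(p, method=fdr_method)[1]
    out = pd.DataFrame(
        {"slope": slope, "r2": r2, "p": p, "q": q},
        index=line_matrix.columns.copy(),
    )
    return out.sort_values("r2", ascending=False, kind="stable")
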