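"""Seeded synthetic MSC metabolomics studies with planted potency signal.

The generator emulates the statistical structure the downstream analysis
assumes: ~10 cell lines expanded in two batches, a functional assay panel
(CD4/CD8 %CFSE dilution for two PBMC donors plus IDO activity) driven by a
single latent potency factor, and three feature tables — MS lipids, MS small
polars (one pellet sample per line) and NMR media features (replicate flasks
sampled on culture days 1-3). A small planted subset of features per
platform carries a potency-associated signal; for NMR the signal lives in
day-differences on top of non-monotonic background trajectories.

Intensities are generated log-normal (Gaussian on the log scale, then
exponentiated) so raw tables are strictly positive. Batch location/scale
effects are applied on the log scale. All randomness flows from a single
integer seed through numpy's PCG64 generator, so outputs are bit-identical
across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    FeatureTable,
    PotencyAssayPanel,
    ValidationError,
    logger,
)

LIPID_CLASSES = ("PC", "PE", "PE-O", "SM", "PS", "PI", "Cer", "TG", "DG", "LPC")
POLAR_CLASSES = ("amino-acid", "sugar", "organic-acid", "nucleotide", "amine", "other")
TRAJECTORY_SHAPES = ("linear", "saturating", "non_monotonic")


@dataclass
class SyntheticSpec:
    """Study-design parameters for :func:`generate_study`.

    ``effect_size`` is the slope of an informative feature's line-level mean
    (on the log/autoscaled axis, in units of the noise-feature SD) against
    latent potency. ``donor_noise_sd`` perturbs line-level means,
    ``replicate_noise_sd`` individual samples.
    """

    n_lines: int = 10
    n_replicates_nmr: int = 10
    n_features: Mapping[str, int] = field(
        default_factory=lambda: {"ms_lipid": 200, "ms_polar": 200, "nmr": 200}
    )
    n_informative: Mapping[str, int] = field(
        default_factory=lambda: {"ms_lipid": 5, "ms_polar": 5, "nmr": 5}
    )
    effect_size: float = 3.0
    donor_noise_sd: float = 0.3
    replicate_noise_sd: float = 0.3
    batch_split: Sequence[int] | None = None  # per-line batch index (0/1)
    batch_location_shift: float = 0.75
    batch_scale_factor: float = 1.4
    nmr_days: tuple[int, ...] = (1, 2, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 3:
            raise ValidationError("a study needs at least 3 cell lines")
        for plat, k in self.n_informative.items():
            n = self.n_features.get(plat, 0)
            if not (0 <= k <= n):
                raise ValidationError(
                    f"n_informative[{plat!r}]={k} outside [0, n_features={n}]"
                )
        if self.batch_scale_factor <= 0:
            raise ValidationError("batch_scale_factor must be > 0")
        if min(self.donor_noise_sd, self.replicate_noise_sd) < 0:
            raise ValidationError("noise SDs must be >= 0")
        if self.batch_split is not None and len(self.batch_split) != self.n_lines:
            raise ValidationError("batch_split must assign every line")


@dataclass
class GroundTruth:
    """What the generator planted: the latent factor and the signal carriers."""

    latent_potency: pd.Series
    informative: dict[str, list[str]]
    signs: dict[str, dict[str, int]]

    def validate_against(self, tables: Mapping[str, FeatureTable]) -> None:
        for plat, ids in self.informative.items():
            extra = set(ids) - set(tables[plat].feature_ids)
            if extra:
                raise ValidationError(f"informative ids not in {plat} table: {extra}")


def _line_ids(n: int) -> list[str]:
    return [f"L{i + 1:02d}" for i in range(n)]


def _batches(spec: SyntheticSpec) -> np.ndarray:
    if spec.batch_split is not None:
        return np.asarray(spec.batch_split, dtype=int)
    return np.arange(spec.n_lines) % 2


def _assay_panel(rng: np.random.Generator, latent: np.ndarray, lines: list[str]) -> pd.DataFrame:
    """Five assay variables driven by latent potency.

    Higher latent values mean more residual T-cell proliferation (lower
    potency). IDO runs opposite and carries extra noise, mimicking lines
    whose IDO rank disagrees with their T-cell suppression rank.
    """
    n = len(latent)
    panel = pd.DataFrame(index=pd.Index(lines, name="line_id"))
    for col, base, slope in (
        ("cd4_d1", 55.0, 12.0),
        ("cd8_d1", 60.0, 12.0),
        ("cd4_d2", 30.0, 10.0),
        ("cd8_d2", 28.0, 10.0),
    ):
        panel[col] = np.clip(base + slope * latent + rng.normal(0.0, 3.0, n), 0.0, 100.0)
    panel["ido"] = np.clip(50.0 - 14.0 * latent + rng.normal(0.0, 8.0, n), 0.1, None)
    return panel


def _feature_ids(platform: str, n: int, rng: np.random.Generator) -> tuple[list[str], pd.DataFrame]:
    """Ids plus feature metadata; NMR features are named by their ppm shift."""
    if platform == "nmr":
        grid = np.round(np.arange(0.50, 9.50, 0.01), 2)
        ppm = np.sort(rng.choice(grid, size=n, replace=False))[::-1]
        ids = [f"{p:.2f}" for p in ppm]
        meta = pd.DataFrame(
            {"annotation": "", "chem_class": "unknown", "platform": "nmr",
             "nmr_shift_ppm": ppm},
            index=pd.Index(ids, name="feature_id"),
        )
        return ids, meta
    classes = LIPID_CLASSES if platform == "ms_lipid" else POLAR_CLASSES
    prefix = "LIP" if platform == "ms_lipid" else "POL"
    ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "annotation": [f"{prefix.lower()}_analyte_{i + 1}" for i in range(n)],
            "chem_class": rng.choice(classes, size=n),
            "platform": platform,
            "nmr_shift_ppm": np.nan,
        },
        index=pd.Index(ids, name="feature_id"),
    )
    return ids, meta


def _ms_table(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    platform: str,
    latent: np.ndarray,
    lines: list[str],
    batches: np.ndarray,
) -> tuple[FeatureTable, list[str], dict[str, int]]:
    n_feat = spec.n_features[platform]
    n_inf = spec.n_informative[platform]
    ids, meta = _feature_ids(platform, n_feat, rng)
    informative = sorted(rng.choice(n_feat, size=n_inf, replace=False).tolist())
    signs = {ids[j]: int(rng.choice([-1, 1])) for j in informative}

    # log-scale latent matrix z (lines x features)
    z = rng.normal(0.0, 1.0, (spec.n_lines, n_feat))
    for j in informative:
        fid = ids[j]
        z[:, j] = (
            signs[fid] * spec.effect_size * latent
            + rng.normal(0.0, spec.donor_noise_sd, spec.n_lines)
        )
    # batch location/scale on the log axis
    in_b2 = batches == 1
    z[in_b2] = z[in_b2] * spec.batch_scale_factor + spec.batch_location_shift

    mu = rng.uniform(np.log(1e3), np.log(1e6), n_feat)
    s = rng.uniform(0.2, 0.4, n_feat)
    values = np.exp(mu[None, :] + s[None, :] * z)

    sample_ids = [f"{ln}_{platform}" for ln in lines]
    vals = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"), columns=ids)
    sample_meta = pd.DataFrame(
        {
            "line_id": lines,
            "batch_id": [f"B{b + 1}" for b in batches],
            "role": "experimental",
            "replicate_id": "r01",
        },
        index=vals.index,
    )
    table = FeatureTable(values=vals, sample_meta=sample_meta, feature_meta=meta, stage="raw")
    return table, [ids[j] for j in informative], signs


def _nmr_table(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    latent: np.ndarray,
    lines: list[str],
    batches: np.ndarray,
) -> tuple[FeatureTable, list[str], dict[str, int]]:
    n_feat = spec.n_features["nmr"]
    n_inf = spec.n_informative["nmr"]
    days = spec.nmr_days
    ids, meta = _feature_ids("nmr", n_feat, rng)
    informative = sorted(rng.choice(n_feat, size=n_inf, replace=False).tolist())
    signs = {ids[j]: int(rng.choice([-1, 1])) for j in informative}

    shapes = rng.choice(TRAJECTORY_SHAPES, size=n_feat)
    amp = rng.uniform(0.5, 1.5, n_feat)
    meta["trajectory"] = shapes
    meta["trajectory_amplitude"] = amp

    def baseline(shape: str, a: float, day: int) -> float:
        t = day - days[0]
        if shape == "linear":
            return a * t
        if shape == "saturating":
            return a * (1.0 - np.exp(-1.5 * t))
        # non-monotonic: rises to day 2, falls below the day-1 baseline at day 3
        return a * (0.0 if t == 0 else (1.0 if t == 1 else -0.6))

    # donor-level deviation shared by a line's flasks and days
    donor_dev = rng.normal(0.0, spec.donor_noise_sd, (spec.n_lines, n_feat))

    rows, sids, s_line, s_batch, s_day, s_rep = [], [], [], [], [], []
    mu = rng.uniform(np.log(1e2), np.log(1e4), n_feat)
    s = rng.uniform(0.2, 0.4, n_feat)
    span = max(days) - days[0]
    for li, ln in enumerate(lines):
        for r in range(spec.n_replicates_nmr):
            rep = f"r{r + 1:02d}"
            for d in days:
                z = np.array([baseline(shapes[j], amp[j], d) for j in range(n_feat)])
                z = z + donor_dev[li]
                z = z + rng.normal(0.0, spec.replicate_noise_sd, n_feat)
                # informative signal carried in the day-differences
                frac = (d - days[0]) / span if span else 0.0
                for j in informative:
                    z[j] += signs[ids[j]] * spec.effect_size * latent[li] * frac
                if batches[li] == 1:
                    z = z * spec.batch_scale_factor + spec.batch_location_shift
                rows.append(np.exp(mu + s * z))
                sids.append(f"{ln}_{rep}_d{d}")
                s_line.append(ln)
                s_batch.append(f"B{batches[li] + 1}")
                s_day.append(d)
                s_rep.append(rep)
    vals = pd.DataFrame(np.vstack(rows), index=pd.Index(sids, name="sample_id"), columns=ids)
    sample_meta = pd.DataFrame(
        {"line_id": s_line, "batch_id": s_batch, "role": "experimental",
         "day": s_day, "replicate_id": s_rep},
        index=vals.index,
    )
    table = FeatureTable(values=vals, sample_meta=sample_meta, feature_meta=meta, stage="raw")
    return table, [ids[j] for j in informative], signs


def generate_study(
    spec: SyntheticSpec,
) -> tuple[FeatureTable, FeatureTable, FeatureTable, PotencyAssayPanel, GroundTruth]:
    """Generate the full synthetic study.

    Returns the MS lipid, MS small-polar and NMR feature tables, the
    functional assay panel, and the planted ground truth. Deterministic for
    a given ``spec`` (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    lines = _line_ids(spec.n_lines)
    batches = _batches(spec)
    latent = rng.normal(0.0, 1.0, spec.n_lines)

    panel = PotencyAssayPanel(_assay_panel(rng, latent, lines))
    lipid, inf_l, sg_l = _ms_table(spec, rng, "ms_lipid", latent, lines, batches)
    polar, inf_p, sg_p = _ms_table(spec, rng, "ms_polar", latent, lines, batches)
    nmr, inf_n, sg_n = _nmr_table(spec, rng, latent, lines, batches)

    truth = GroundTruth(
        latent_potency=pd.Series(latent, index=pd.Index(lines, name="line_id")),
        informative={"ms_lipid": inf_l, "ms_polar": inf_p, "nmr": inf_n},
        signs={"ms_lipid": sg_l, "ms_polar": sg_p, "nmr": sg_n},
    )
    truth.validate_against({"ms_lipid": lipid, "ms_polar": polar, "nmr": nmr})
    return lipid, polar, nmr, panel, truth


def generate_blanks_and_qcs(
    table: FeatureTable,
    seed: int,
    n_blanks: int = 3,
    n_qcs: int = 5,
    blank_dominated: Sequence[str] = (),
    qc_dropout: Mapping[str, float] | None = None,
) -> FeatureTable:
    """Append blank and pooled-QC samples to an experimental table.

    Blanks carry a low background (2% of the experimental mean) except for
    ``blank_dominated`` features, whose blank level is set to half the
    experimental mean so they deterministically fail the 5x blank rule.
    QC pools are per-feature means of the experimental samples plus small
    noise; ``qc_dropout`` maps feature id -> fraction of QC injections in
    which the feature is zeroed (to exercise the 50%-presence rule).
    """
    rng = np.random.default_rng(seed)
    qc_dropout = dict(qc_dropout or {})
    unknown = (set(blank_dominated) | set(qc_dropout)) - set(table.feature_ids)
    if unknown:
        raise ValidationError(f"unknown feature ids: {sorted(unknown)[:3]}")

    exp_mean = table.experimental_values().mean(axis=0)
    n_feat = table.n_features

    blank_level = exp_mean * 0.02
    for fid in blank_dominated:
        blank_level[fid] = exp_mean[fid] * 0.5
    blank_rows = [
        blank_level.to_numpy() * rng.lognormal(0.0, 0.05, n_feat)
        for _ in range(n_blanks)
    ]
    qc_rows = [
        exp_mean.to_numpy() * rng.lognormal(0.0, 0.05, n_feat) for _ in range(n_qcs)
    ]
    qc = np.vstack(qc_rows)
    cols = list(table.values.columns)
    for fid, frac in qc_dropout.items():
        k = int(round(frac * n_qcs))
        which = rng.choice(n_qcs, size=k, replace=False)
        qc[which, cols.index(fid)] = 0.0

    batch_of_first = table.sample_meta["batch_id"].iloc[0]
    extra_ids = [f"blank_{i + 1}" for i in range(n_blanks)] + [
        f"qc_{i + 1}" for i in range(n_qcs)
    ]
    extra_vals = pd.DataFrame(
        np.vstack([np.vstack(blank_rows), qc]),
        index=pd.Index(extra_ids, name="sample_id"),
        columns=table.values.columns,
    )
    extra_meta = pd.DataFrame(
        {
            "line_id": "pool",
            "batch_id": batch_of_first,
            "role": ["blank"] * n_blanks + ["qc_pool"] * n_qcs,
            "replicate_id": [f"r{i + 1:02d}" for i in range(n_blanks)]
            + [f"r{i + 1:02d}" for i in range(n_qcs)],
        },
        index=extra_vals.index,
    )
    values = pd.concat([table.values, extra_vals])
    sample_meta = pd.concat([table.sample_meta, extra_meta])
    logger.info(
        "added %d blanks and %d QC pools (%d blank-dominated, %d with QC dropout)",
        n_blanks, n_qcs, len(blank_dominated), len(qc_dropout),
    )
    return FeatureTable(values=values, sample_meta=sample_meta,
                        feature_meta=table.feature_meta.copy(), stage=table.stage)
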