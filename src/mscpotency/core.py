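"""Domain types and file I/O for the MSC potency-metabolomics workflow.

The central container is :class:`FeatureTable`, a sample x feature abundance
matrix with per-sample metadata (cell line, batch, sample role, culture day,
replicate flask) and per-feature metadata (annotation, chemical class,
platform). Functional-assay readouts live in :class:`PotencyAssayPanel`,
pathway sets in :class:`PathwayDB`, and the PCA-derived potency score in
:class:`CompositeScore`.

Tables are exchanged as plain CSV (one values file plus one metadata file per
axis); pathway sets use the standard GMT dialect; model and enrichment
results serialize to JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mscpotency")
if not logger.handlers:  # library default: quiet unless the app configures logging
    logger.addHandler(logging.NullHandler())

ROLES = ("experimental", "blank", "qc_pool")
PLATFORMS = ("ms_lipid", "ms_polar", "nmr")
STAGES = ("raw", "filtered", "normalized", "scaled", "differenced")
ASSAY_COLUMNS = ("cd4_d1", "cd8_d1", "cd4_d2", "cd8_d2", "ido")
PROLIFERATION_COLUMNS = ("cd4_d1", "cd8_d1", "cd4_d2", "cd8_d2")

SAMPLE_META_REQUIRED = ("line_id", "batch_id", "role")
FEATURE_META_COLUMNS = ("annotation", "chem_class", "platform", "nmr_shift_ppm")


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Sample x feature abundance matrix with aligned metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, columns are feature ids. Raw-stage
        values must be non-negative and complete (no NaN at any stage).
    sample_meta
        DataFrame indexed by sample id with columns ``line_id``, ``batch_id``,
        ``role`` (one of ``experimental``/``blank``/``qc_pool``) and
        optionally ``day`` (integer culture day, NMR only) and
        ``replicate_id``.
    feature_meta
        DataFrame indexed by feature id with columns ``annotation``,
        ``chem_class``, ``platform`` and optionally ``nmr_shift_ppm``.
    stage
        Processing stage flag, one of ``raw``, ``filtered``, ``normalized``,
        ``scaled``, ``differenced``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        vals = self.values
        if vals.index.has_duplicates:
            dup = vals.index[vals.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if vals.columns.has_duplicates:
            dup = vals.columns[vals.columns.duplicated()][0]
            raise ValidationError(f"duplicate feature id {dup!r}")
        if self.sample_meta.index.has_duplicates:
            dup = self.sample_meta.index[self.sample_meta.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r} in sample_meta")
        if not vals.index.equals(self.sample_meta.index):
            missing = vals.index.symmetric_difference(self.sample_meta.index)
            raise ValidationError(
                f"sample ids of values and sample_meta differ (e.g. {list(missing[:3])})"
            )
        if not vals.columns.equals(self.feature_meta.index):
            missing = vals.columns.symmetric_difference(self.feature_meta.index)
            raise ValidationError(
                f"feature ids of values and feature_meta differ (e.g. {list(missing[:3])})"
            )
        for col in SAMPLE_META_REQUIRED:
            if col not in self.sample_meta.columns:
                raise ValidationError(f"sample_meta lacks required column {col!r}")
            null = self.sample_meta[col].isna()
            if null.any():
                sid = self.sample_meta.index[null][0]
                raise ValidationError(f"sample {sid!r} has missing {col}")
        bad_role = ~self.sample_meta["role"].isin(ROLES)
        if bad_role.any():
            sid = self.sample_meta.index[bad_role][0]
            raise ValidationError(
                f"sample {sid!r} has invalid role {self.sample_meta.loc[sid, 'role']!r}"
            )
        arr = vals.to_numpy()
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"missing/non-finite abundance at sample {vals.index[i]!r}, "
                f"feature {vals.columns[j]!r}"
            )
        if self.stage == "raw" and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative raw abundance at sample {vals.index[i]!r}, "
                f"feature {vals.columns[j]!r}"
            )
        if "day" in self.sample_meta.columns:
            days = self.sample_meta["day"].dropna()
            if len(days) and (days.astype(float) < 1).any():
                raise ValidationError("culture day must be >= 1")

    # -- convenience --------------------------------------------------------

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def role_mask(self, role: str) -> pd.Series:
        return self.sample_meta["role"] == role

    def experimental_values(self) -> pd.DataFrame:
        """Values restricted to experimental (non-blank, non-QC) samples."""
        return self.values.loc[self.role_mask("experimental")]

    def subset_features(self, feature_ids: Sequence, stage: str | None = None) -> "FeatureTable":
        ids = list(feature_ids)
        return FeatureTable(
            values=self.values[ids].copy(),
            sample_meta=self.sample_meta.copy(),
            feature_meta=self.feature_meta.loc[ids].copy(),
            stage=stage or self.stage,
        )

    def subset_samples(self, sample_ids: Sequence, stage: str | None = None) -> "FeatureTable":
        ids = list(sample_ids)
        return FeatureTable(
            values=self.values.loc[ids].copy(),
            sample_meta=self.sample_meta.loc[ids].copy(),
            feature_meta=self.feature_meta.copy(),
            stage=stage or self.stage,
        )

    def with_values(self, new_values: pd.DataFrame, stage: str) -> "FeatureTable":
        """Same metadata, replaced value matrix (must keep both axes)."""
        return FeatureTable(
            values=new_values,
            sample_meta=self.sample_meta.copy(),
            feature_meta=self.feature_meta.copy(),
            stage=stage,
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            values=self.values.copy(),
            sample_meta=self.sample_meta.copy(),
            feature_meta=self.feature_meta.copy(),
            stage=self.stage,
        )

    def aggregate_by_line(self) -> pd.DataFrame:
        """Mean of experimental replicates per cell line (lines x features)."""
        vals = self.experimental_values()
        lines = self.sample_meta.loc[vals.index, "line_id"]
        return vals.groupby(lines).mean().sort_index()


# ---------------------------------------------------------------------------
# PotencyAssayPanel
# ---------------------------------------------------------------------------

@dataclass
class PotencyAssayPanel:
    """Per-cell-line functional assay readouts.

    Columns: ``cd4_d1``, ``cd8_d1``, ``cd4_d2``, ``cd8_d2`` — %CFSE dilution
    of CD4/CD8 T cells for two PBMC donors, each in [0, 100] — and ``ido``,
    IDO activity in pg L-kynurenine per cell per day (>= 0).
    """

    assays: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in ASSAY_COLUMNS if c not in self.assays.columns]
        if missing:
            raise ValidationError(f"assay panel lacks columns {missing}")
        if self.assays.index.has_duplicates:
            raise ValidationError("duplicate line ids in assay panel")
        if self.assays[list(ASSAY_COLUMNS)].isna().any().any():
            bad = self.assays.index[self.assays[list(ASSAY_COLUMNS)].isna().any(axis=1)][0]
            raise ValidationError(f"line {bad!r} has a missing assay value")
        prolif = self.assays[list(PROLIFERATION_COLUMNS)]
        if ((prolif < 0) | (prolif > 100)).any().any():
            raise ValidationError("proliferation values must lie in [0, 100]")
        if (self.assays["ido"] < 0).any():
            raise ValidationError("IDO activity must be >= 0")

    @property
    def line_ids(self) -> list:
        return list(self.assays.index)


# ---------------------------------------------------------------------------
# CompositeScore
# ---------------------------------------------------------------------------

@dataclass
class CompositeScore:
    """PC1-based composite potency score per cell line.

    Higher scores correspond to higher T-cell proliferation, i.e. *lower*
    MSC potency. ``variance_explained`` is the PC1 fraction of total variance
    of the autoscaled assay panel; ``orientation`` records the sign applied
    to enforce the convention.
    """

    scores: pd.Series
    variance_explained: float
    variance_ratios: np.ndarray
    loadings: pd.Series
    orientation: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.variance_explained <= 1.0 + 1e-12):
            raise ValidationError("variance_explained must lie in (0, 1]")
        if self.orientation not in (-1, 1):
            raise ValidationError("orientation must be +1 or -1")


# ---------------------------------------------------------------------------
# PathwayDB
# ---------------------------------------------------------------------------

@dataclass
class PathwayDB:
    """Named metabolite sets plus a background identifier universe."""

    sets: dict[str, tuple[str, ...]]
    background: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.background:
            self.background = frozenset().union(*[set(m) for m in self.sets.values()]) \
                if self.sets else frozenset()
        self.validate()

    def validate(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"pathway {name!r} is empty")
            extra = set(members) - self.background
            if extra:
                raise ValidationError(
                    f"pathway {name!r} has members outside the background: {sorted(extra)[:3]}"
                )

    @property
    def names(self) -> list:
        return list(self.sets)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_feature_table(
    values_path: str | Path,
    sample_meta_path: str | Path,
    feature_meta_path: str | Path | None = None,
    stage: str = "raw",
) -> FeatureTable:
    """Read a feature table from CSV/TSV files.

    ``values_path`` holds the abundance matrix: header row of feature ids,
    first column sample ids. Sample metadata is keyed by sample id; feature
    metadata (optional — defaults are synthesized if absent) by feature id.
    """
    sep_v = "\t" if str(values_path).endswith((".tsv", ".txt")) else ","
    values = pd.read_csv(values_path, sep=sep_v, index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    sep_s = "\t" if str(sample_meta_path).endswith((".tsv", ".txt")) else ","
    sample_meta = pd.read_csv(sample_meta_path, sep=sep_s, index_col=0)
    sample_meta.index = sample_meta.index.astype(str)
    if feature_meta_path is not None:
        sep_f = "\t" if str(feature_meta_path).endswith((".tsv", ".txt")) else ","
        feature_meta = pd.read_csv(feature_meta_path, sep=sep_f, index_col=0)
        feature_meta.index = feature_meta.index.astype(str)
    else:
        feature_meta = default_feature_meta(values.columns)
    try:
        sample_meta = sample_meta.loc[values.index]
        feature_meta = feature_meta.loc[values.columns]
    except KeyError as err:
        raise ValidationError(f"metadata is missing ids present in the value table: {err}")
    return FeatureTable(values=values, sample_meta=sample_meta,
                        feature_meta=feature_meta, stage=stage)


def default_feature_meta(feature_ids: Iterable, platform: str = "ms_lipid") -> pd.DataFrame:
    ids = [str(f) for f in feature_ids]
    return pd.DataFrame(
        {"annotation": "", "chem_class": "unknown", "platform": platform,
         "nmr_shift_ppm": np.nan},
        index=pd.Index(ids, name="feature_id"),
    )


def write_feature_table(table: FeatureTable, prefix: str | Path) -> dict[str, Path]:
    """Write ``<prefix>_values.csv``, ``<prefix>_samples.csv``, ``<prefix>_features.csv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "values": prefix.with_name(prefix.name + "_values.csv"),
        "samples": prefix.with_name(prefix.name + "_samples.csv"),
        "features": prefix.with_name(prefix.name + "_features.csv"),
    }
    table.values.to_csv(paths["values"], index_label="sample_id")
    table.sample_meta.to_csv(paths["samples"], index_label="sample_id")
    table.feature_meta.to_csv(paths["features"], index_label="feature_id")
    return paths


def read_gmt(path: str | Path, background: Iterable | None = None) -> PathwayDB:
    """Parse a GMT file: one pathway per line, ``name<TAB>description<TAB>members...``.

    Blank lines are skipped; a line with no members is an error; duplicate
    members within a set are deduplicated with a warning. The background
    defaults to the union of all members unless supplied.
    """
    sets: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
                raise ValidationError(
                    f"{path}:{lineno}: pathway line has no members"
                )
            name = parts[0].strip()
            members: list[str] = []
            seen = set()
            for m in parts[2:]:
                m = m.strip()
                if not m:
                    continue
                if m in seen:
                    logger.warning("GMT set %r: duplicated member %r deduplicated", name, m)
                    continue
                seen.add(m)
                members.append(m)
            sets[name] = tuple(members)
    bg = frozenset(background) if background is not None else frozenset()
    return PathwayDB(sets=sets, background=bg)


# ---------------------------------------------------------------------------
# JSON result serialization
# ---------------------------------------------------------------------------

class _ResultEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, pd.Series):
            return o.to_dict()
        return super().default(o)


def save_json(obj, path: str | Path) -> Path:
    """Write a result object (dataclass, dict, ...) as indented JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_ResultEncoder, sort_keys=True)
        fh.write("\n")
    return path


def load_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
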