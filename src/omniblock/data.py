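"""Feature-table data model, on-disk CSV formats, and analysis configuration.

The central container is :class:`FeatureTable`: a samples x features intensity
matrix together with per-sample metadata (role in the injection sequence,
injection order, clinical group, optional matched-pair and subgroup labels)
and per-feature metadata (assay, annotation, functional block, lipid class).
Every pipeline stage consumes and returns this object.

On disk a table is three plain CSV files (UTF-8, "." decimal separator):

* ``intensities.csv`` -- header row of feature ids, first column sample ids;
* ``sample_meta.csv`` -- one row per sample, keyed by ``sample_id``;
* ``feature_meta.csv`` -- one row per feature, keyed by ``feature_id``.

Missing intensities are written as the token ``NA``.  Zeros are measured
values, not missing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

SAMPLE_ROLES = ("study", "qc", "blank")
ASSAYS = ("metabolomics", "lipidomics")
NA_TOKENS = ("", "NA", "NaN", "nan")

__all__ = [
    "OmniblockError",
    "FormatError",
    "ValidationError",
    "FeatureTable",
    "AnalysisConfig",
    "read_feature_table",
    "write_feature_table",
    "load_config",
]


class OmniblockError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(OmniblockError):
    """An on-disk file does not conform to the expected dialect."""


class ValidationError(OmniblockError):
    """An in-memory object violates one of its invariants."""


@dataclass
class FeatureTable:
    """Intensity matrix plus sample and feature metadata.

    Parameters
    ----------
    intensities
        DataFrame of non-negative intensities, rows indexed by ``sample_id``,
        columns by ``feature_id``.  ``NaN`` marks a missing measurement.
    sample_meta
        DataFrame indexed by ``sample_id`` with at least columns ``role``
        (one of ``study``/``qc``/``blank``) and ``injection_order`` (unique
        positive integers).  ``group`` is required for study samples;
        ``pair_id`` and arbitrary subgroup columns are optional.
    feature_meta
        DataFrame indexed by ``feature_id`` with at least column ``assay``
        (``metabolomics`` or ``lipidomics``); ``annotation``, ``block_id``
        and ``lipid_class`` are optional.
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame

    # ------------------------------------------------------------------ views
    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def role_mask(self, role: str) -> np.ndarray:
        return (self.sample_meta["role"] == role).to_numpy()

    @property
    def study_mask(self) -> np.ndarray:
        return self.role_mask("study")

    @property
    def qc_mask(self) -> np.ndarray:
        return self.role_mask("qc")

    @property
    def blank_mask(self) -> np.ndarray:
        return self.role_mask("blank")

    def groups(self) -> pd.Series:
        """Group labels of the study samples, indexed by sample id."""
        return self.sample_meta.loc[self.study_mask, "group"]

    # -------------------------------------------------------------- subsetting
    def subset(
        self,
        samples: Sequence[str] | np.ndarray | None = None,
        features: Sequence[str] | np.ndarray | None = None,
    ) -> "FeatureTable":
        """Return a new table restricted to the given sample/feature ids.

        Boolean masks aligned with the current row/column order are accepted.
        """
        inten = self.intensities
        smeta = self.sample_meta
        fmeta = self.feature_meta
        if samples is not None:
            samples = np.asarray(samples)
            if samples.dtype == bool:
                samples = inten.index[samples]
            inten = inten.loc[samples]
            smeta = smeta.loc[samples]
        if features is not None:
            features = np.asarray(features)
            if features.dtype == bool:
                features = inten.columns[features]
            inten = inten[list(features)]
            fmeta = fmeta.loc[list(features)]
        return FeatureTable(inten.copy(), smeta.copy(), fmeta.copy())

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.sample_meta.copy(), self.feature_meta.copy()
        )

    # ------------------------------------------------------------- validation
    def validate(self) -> "FeatureTable":
        """Check all structural invariants; raise :class:`ValidationError`."""
        inten, smeta, fmeta = self.intensities, self.sample_meta, self.feature_meta
        if inten.index.has_duplicates:
            dup = inten.index[inten.index.duplicated()].tolist()
            raise ValidationError(f"duplicated sample ids: {dup}")
        if inten.columns.has_duplicates:
            dup = inten.columns[inten.columns.duplicated()].tolist()
            raise ValidationError(f"duplicated feature ids: {dup}")
        if not inten.index.equals(smeta.index):
            raise ValidationError("intensity rows and sample_meta are not aligned")
        if not inten.columns.equals(fmeta.index):
            raise ValidationError("intensity columns and feature_meta are not aligned")
        for col in ("role", "injection_order"):
            if col not in smeta.columns:
                raise ValidationError(f"sample_meta lacks required column {col!r}")
        if "assay" not in fmeta.columns:
            raise ValidationError("feature_meta lacks required column 'assay'")
        bad_role = set(smeta["role"]) - set(SAMPLE_ROLES)
        if bad_role:
            raise ValidationError(f"unknown sample roles: {sorted(bad_role)}")
        bad_assay = set(fmeta["assay"]) - set(ASSAYS)
        if bad_assay:
            raise ValidationError(f"unknown assays: {sorted(bad_assay)}")
        order = smeta["injection_order"]
        if order.isna().any():
            raise ValidationError("injection_order has missing values")
        if (order.astype(float) != order.astype(float).round()).any() or (order <= 0).any():
            raise ValidationError("injection_order must be positive integers")
        if order.duplicated().any():
            dup = order[order.duplicated()].tolist()
            raise ValidationError(f"injection_order values not unique: {dup}")
        study = smeta["role"] == "study"
        if study.any():
            if "group" not in smeta.columns:
                raise ValidationError("study samples present but no 'group' column")
            missing = smeta.index[study & smeta["group"].isna()].tolist()
            if missing:
                raise ValidationError(f"study samples without group: {missing}")
        vals = inten.to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if np.isinf(vals).any():
            raise ValidationError("intensities contain infinite values")
        if (vals[finite] < 0).any():
            raise ValidationError("intensities contain negative values")
        return self


def _parse_intensity_frame(raw: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Convert a string-typed intensity frame to float, NA tokens -> NaN."""
    out = np.empty(raw.shape, dtype=float)
    arr = raw.to_numpy(dtype=object)
    for idx, cell in np.ndenumerate(arr):
        text = "" if cell is None else str(cell).strip()
        if text in NA_TOKENS:
            out[idx] = np.nan
            continue
        try:
            out[idx] = float(text)
        except ValueError:
            i, j = idx
            raise FormatError(
                f"{path}: non-numeric intensity {text!r} at "
                f"sample {raw.index[i]!r}, feature {raw.columns[j]!r}"
            ) from None
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


def read_feature_table(
    intensity_path: str | Path,
    sample_meta_path: str | Path,
    feature_meta_path: str | Path,
) -> FeatureTable:
    """Read and validate a feature table from its three CSV files.

    Row and column order is preserved exactly as in the intensity file; the
    metadata files may list ids in any order but must cover the same sets.
    """
    raw = pd.read_csv(intensity_path, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    inten = _parse_intensity_frame(raw, intensity_path)

    smeta = pd.read_csv(sample_meta_path, dtype={"sample_id": str})
    if "sample_id" not in smeta.columns:
        raise FormatError(f"{sample_meta_path}: missing 'sample_id' column")
    if smeta["sample_id"].duplicated().any():
        raise FormatError(f"{sample_meta_path}: duplicated sample ids")
    smeta = smeta.set_index("sample_id")

    fmeta = pd.read_csv(feature_meta_path, dtype={"feature_id": str})
    if "feature_id" not in fmeta.columns:
        raise FormatError(f"{feature_meta_path}: missing 'feature_id' column")
    if fmeta["feature_id"].duplicated().any():
        raise FormatError(f"{feature_meta_path}: duplicated feature ids")
    fmeta = fmeta.set_index("feature_id")

    if set(smeta.index) != set(inten.index):
        raise FormatError("sample ids of metadata and intensity files differ")
    if set(fmeta.index) != set(inten.columns):
        raise FormatError("feature ids of metadata and intensity files differ")
    smeta = smeta.loc[inten.index]
    fmeta = fmeta.loc[inten.columns]
    if "injection_order" in smeta.columns:
        smeta["injection_order"] = smeta["injection_order"].astype(int)
    return FeatureTable(inten, smeta, fmeta).validate()


def write_feature_table(table: FeatureTable, out_dir: str | Path) -> tuple[Path, Path, Path]:
    """Write the three CSV files; returns (intensity, sample_meta, feature_meta) paths.

    The round trip through :func:`read_feature_table` is lossless up to the
    17-significant-digit text representation of the intensities.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ipath = out / "intensities.csv"
    spath = out / "sample_meta.csv"
    fpath = out / "feature_meta.csv"
    table.intensities.to_csv(ipath, index_label="sample_id", na_rep="NA", float_format="%.17g")
    table.sample_meta.to_csv(spath, index_label="sample_id", na_rep="NA")
    table.feature_meta.to_csv(fpath, index_label="feature_id", na_rep="NA")
    return ipath, spath, fpath


# --------------------------------------------------------------------- config


@dataclass
class AnalysisConfig:
    """Tunable settings of the whole analysis chain.

    Defaults follow the published workflow: QC coefficient-of-variation
    cutoff of 30%, 200 permutations for model validation, VIP threshold 1.0,
    initial network edge threshold p <= 0.25, and eleven lipid clusters.
    """

    cv_cutoff: float = 0.30
    blank_ratio: float = 3.0
    loess_span: float = 0.75
    n_folds: int = 7
    n_permutations: int = 200
    vip_threshold: float = 1.0
    alpha: float = 0.05
    network_p_threshold: float = 0.25
    n_lipid_clusters: int = 11
    n_orthogonal: int = 1
    weight_scheme: str = "sqrt_size"
    scaling: str = "unit_variance"
    use_adjusted: bool = False
    max_components: int = 5
    seed: int = 0

    def validate(self) -> "AnalysisConfig":
        fractions = ("cv_cutoff", "loess_span", "alpha", "network_p_threshold")
        for key in fractions:
            v = getattr(self, key)
            if not (0 < v <= 1):
                raise ValidationError(f"config key {key!r} must lie in (0, 1], got {v}")
        counts = ("n_folds", "n_permutations", "n_lipid_clusters", "max_components")
        for key in counts:
            v = getattr(self, key)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValidationError(f"config key {key!r} must be an integer >= 1, got {v}")
        if self.blank_ratio <= 0:
            raise ValidationError(f"config key 'blank_ratio' must be > 0, got {self.blank_ratio}")
        if self.vip_threshold < 0:
            raise ValidationError("config key 'vip_threshold' must be >= 0")
        if self.n_orthogonal < 0:
            raise ValidationError("config key 'n_orthogonal' must be >= 0")
        if self.weight_scheme not in ("sqrt_size", "inverse_sqrt_size", "none"):
            raise ValidationError(f"unknown weight_scheme {self.weight_scheme!r}")
        if self.scaling not in ("unit_variance", "pareto", "none"):
            raise ValidationError(f"unknown scaling {self.scaling!r}")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML key/value file.

    Unspecified keys take their defaults; an empty file (or ``None``) yields
    the default configuration.  Unknown keys and out-of-range values raise
    :class:`ValidationError` naming the key.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise FormatError(f"{path}: config must be a mapping")
        data = loaded
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**data).validate()
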