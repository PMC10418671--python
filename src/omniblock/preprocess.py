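"""Feature-table preprocessing: blank removal, QC-anchored LOESS drift
correction, QC-CV filtering, probabilistic quotient normalization (PQN),
model scaling, and PCA-based outlier flagging.

The canonical chain (applied per assay, then joined on sample id) is

    blank removal -> drift correction -> CV filter -> PQN -> scaling

Feature counts are non-increasing along the chain; each step contributes a
:class:`StepReport` to the accumulated :class:`PreprocessReport`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data import AnalysisConfig, FeatureTable, OmniblockError, ValidationError

__all__ = [
    "StepReport",
    "PreprocessReport",
    "Scaler",
    "remove_blank_features",
    "drift_correct",
    "cv_filter",
    "pqn_normalize",
    "scale_for_model",
    "flag_outliers",
    "run_preprocess",
]


@dataclass
class StepReport:
    name: str
    n_features_in: int
    n_features_out: int
    removed: list[str] = field(default_factory=list)
    details: dict = field(default_factory=dict)


@dataclass
class PreprocessReport:
    steps: list[StepReport] = field(default_factory=list)
    qc_cv: pd.Series | None = None           # per-feature QC CV at filter time
    pqn_quotients: pd.Series | None = None   # per-sample total dilution factor
    outliers: pd.DataFrame | None = None     # flagged samples with Hotelling T2

    def add(self, step: StepReport) -> None:
        # within an assay's chain, a step never gains features
        prefix = step.name.split(":")[0]
        prev = [s for s in self.steps if s.name.split(":")[0] == prefix]
        if prev and step.n_features_in > prev[-1].n_features_out:
            raise ValidationError("feature counts must be non-increasing across steps")
        if step.n_features_out > step.n_features_in:
            raise ValidationError("a preprocessing step cannot add features")
        self.steps.append(step)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.name,
                    "n_features_in": s.n_features_in,
                    "n_features_out": s.n_features_out,
                    "n_removed": len(s.removed),
                }
                for s in self.steps
            ]
        )


def _qc_means(table: FeatureTable, mask: np.ndarray) -> pd.Series:
    sub = table.intensities.loc[mask]
    return sub.mean(axis=0, skipna=True)


def remove_blank_features(
    table: FeatureTable, blank_ratio: float = 3.0
) -> tuple[FeatureTable, StepReport]:
    """Drop features whose QC signal does not exceed ``blank_ratio`` x blank signal.

    A feature is kept iff mean QC intensity >= blank_ratio * mean blank
    intensity (missing values excluded from the means; boundary inclusive).
    With no blank rows the step is skipped with a warning.
    """
    if blank_ratio <= 0:
        raise ValidationError("blank_ratio must be > 0")
    n_in = table.n_features
    if not table.blank_mask.any():
        warnings.warn("no blank samples: blank-feature removal skipped")
        return table, StepReport("remove_blank_features", n_in, n_in)
    qc_mask = table.qc_mask if table.qc_mask.any() else table.study_mask
    qc_mean = _qc_means(table, qc_mask)
    blank_mean = _qc_means(table, table.blank_mask).fillna(0.0)
    keep = (qc_mean >= blank_ratio * blank_mean).to_numpy()
    removed = list(table.feature_ids[~keep])
    out = table.subset(features=keep)
    return out, StepReport("remove_blank_features", n_in, out.n_features, removed)


def drift_correct(
    table: FeatureTable, span: float = 0.75
) -> tuple[FeatureTable, StepReport]:
    """QC-anchored LOESS correction of intensity drift along the injection order.

    Per feature, a local-linear LOESS curve (tricube weights, the given span)
    is fitted to QC intensity versus injection order, evaluated at every
    sample's order by interpolation (constant beyond the terminal QCs), and
    each intensity is divided by the fitted relative drift.  The feature's QC
    median is preserved exactly by a final renormalization.  Features whose
    fitted curve is non-positive anywhere are left uncorrected and flagged.
    """
    qc_mask = table.qc_mask
    if qc_mask.sum() < 4:
        raise OmniblockError(
            f"drift correction needs >= 4 QC samples, found {int(qc_mask.sum())}; "
            "skip the step or supply more QCs"
        )
    orders = table.sample_meta["injection_order"].to_numpy(dtype=float)
    qc_orders = orders[qc_mask]
    inten = table.intensities.to_numpy(dtype=float).copy()
    flagged: list[str] = []
    for j, fid in enumerate(table.feature_ids):
        qc_vals = inten[qc_mask, j]
        ok = np.isfinite(qc_vals)
        if ok.sum() < 4:
            flagged.append(fid)
            continue
        fitted = lowess(
            qc_vals[ok], qc_orders[ok], frac=span, it=0, return_sorted=True
        )
        curve = np.interp(orders, fitted[:, 0], fitted[:, 1])
        if np.any(curve <= 0):
            flagged.append(fid)
            continue
        med = np.median(qc_vals[ok])
        corrected = inten[:, j] * (med / curve)
        # exact QC-median preservation
        new_med = np.median(corrected[qc_mask][ok])
        if new_med > 0:
            corrected *= med / new_med
        inten[:, j] = corrected
    out = table.copy()
    out.intensities = pd.DataFrame(inten, index=table.sample_ids, columns=table.feature_ids)
    report = StepReport(
        "drift_correct", table.n_features, table.n_features,
        details={"uncorrected": flagged, "span": span},
    )
    return out, report


def qc_cv(table: FeatureTable) -> pd.Series:
    """Per-feature coefficient of variation (sd/mean) over the QC samples."""
    sub = table.intensities.loc[table.qc_mask]
    mean = sub.mean(axis=0, skipna=True)
    sd = sub.std(axis=0, ddof=1, skipna=True)
    return sd / mean


def cv_filter(
    table: FeatureTable, cv_cutoff: float = 0.30
) -> tuple[FeatureTable, StepReport]:
    """Keep features whose QC CV is strictly below ``cv_cutoff``.

    Features with fewer than two non-missing QC values cannot be assessed and
    are removed (counted separately in the report).
    """
    if not (0 < cv_cutoff <= 1):
        raise ValidationError("cv_cutoff must lie in (0, 1]")
    if table.qc_mask.sum() < 2:
        raise OmniblockError("CV filtering needs >= 2 QC samples")
    sub = table.intensities.loc[table.qc_mask]
    n_obs = sub.notna().sum(axis=0)
    cvs = qc_cv(table)
    unassessable = (n_obs < 2).to_numpy()
    keep = (cvs < cv_cutoff).fillna(False).to_numpy() & ~unassessable
    removed = list(table.feature_ids[~keep])
    out = table.subset(features=keep)
    report = StepReport(
        "cv_filter", table.n_features, out.n_features, removed,
        details={
            "cv": cvs,
            "n_unassessable": int(unassessable.sum()),
            "cutoff": cv_cutoff,
        },
    )
    return out, report


def pqn_normalize(
    table: FeatureTable, max_iter: int = 500, tol: float = 1e-12
) -> tuple[FeatureTable, StepReport]:
    """Probabilistic quotient normalization against the median study spectrum.

    The reference spectrum is the per-feature median over study samples; each
    study/QC sample is divided by the median quotient of its intensities to
    the reference (features positive in both).  The reference is recomputed
    and the step repeated until all quotients are 1 within ``tol``, which
    makes the operation idempotent.  Blank rows are left untouched.
    """
    if not table.study_mask.any():
        raise OmniblockError("PQN needs at least one study sample")
    if table.n_features == 0:
        raise OmniblockError("PQN needs at least one feature")
    inten = table.intensities.to_numpy(dtype=float).copy()
    rows = table.study_mask | table.qc_mask
    row_idx = np.flatnonzero(rows)
    total_q = np.ones(len(row_idx))
    for _ in range(max_iter):
        study = inten[table.study_mask]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            reference = np.nanmedian(study, axis=0)
        quotients = np.empty(len(row_idx))
        for k, i in enumerate(row_idx):
            x = inten[i]
            ok = np.isfinite(x) & (x > 0) & np.isfinite(reference) & (reference > 0)
            if not ok.any():
                sid = table.sample_ids[i]
                raise OmniblockError(
                    f"sample {sid!r} shares no positive feature with the PQN reference"
                )
            quotients[k] = np.median(x[ok] / reference[ok])
        inten[row_idx] /= quotients[:, None]
        total_q *= quotients
        if np.max(np.abs(quotients - 1.0)) < tol:
            break
    out = table.copy()
    out.intensities = pd.DataFrame(inten, index=table.sample_ids, columns=table.feature_ids)
    qser = pd.Series(total_q, index=table.sample_ids[row_idx], name="pqn_quotient")
    report = StepReport(
        "pqn_normalize", table.n_features, table.n_features,
        details={"quotients": qser},
    )
    return out, report


@dataclass
class Scaler:
    """Column centering/scaling fitted on the study rows; projects new samples."""

    feature_ids: list[str]
    center: np.ndarray
    scale: np.ndarray
    mode: str

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.center) / self.scale
        return np.where(np.isfinite(Z), Z, 0.0)  # mean-impute residual missing


def scale_for_model(
    table: FeatureTable, mode: str = "unit_variance"
) -> tuple[np.ndarray, np.ndarray, Scaler]:
    """Center (and scale) the study-row matrix for multivariate modeling.

    Returns ``(X, y_labels, scaler)`` where ``X`` is the scaled study matrix
    (residual missing values imputed at the column mean, i.e. zero after
    centering) and ``y_labels`` the group labels.  ``unit_variance`` divides
    by the column sd, ``pareto`` by its square root, ``none`` centers only.
    Zero-variance columns are dropped with a warning.
    """
    if mode not in ("unit_variance", "pareto", "none"):
        raise ValidationError(f"unknown scaling mode {mode!r}")
    sub = table.intensities.loc[table.study_mask]
    X = sub.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        center = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0, ddof=1)
    zero_var = ~(sd > 0)
    if zero_var.any():
        warnings.warn(
            f"dropping {int(zero_var.sum())} zero-variance features before scaling"
        )
    keep = ~zero_var
    X = X[:, keep]
    center = center[keep]
    sd = sd[keep]
    if mode == "unit_variance":
        scale = sd
    elif mode == "pareto":
        scale = np.sqrt(sd)
    else:
        scale = np.ones_like(sd)
    scaler = Scaler(
        feature_ids=list(table.feature_ids[keep]), center=center, scale=scale, mode=mode
    )
    Z = scaler.transform(X)
    y = table.groups().to_numpy()
    return Z, y, scaler


def flag_outliers(
    table: FeatureTable,
    n_components: int = 2,
    limit: float = 0.99,
    mode: str = "unit_variance",
) -> pd.DataFrame:
    """Advisory PCA/Hotelling-T2 outlier flags on the study samples.

    Samples whose T2 over the first ``n_components`` principal components
    exceeds the F-distribution limit at the ``limit`` quantile are flagged
    (never removed).  Returns a DataFrame with T2, the limit, and the flag.
    """
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    n_study = int(table.study_mask.sum())
    if n_study < n_components + 2:
        raise ValidationError("need at least n_components + 2 study samples")
    Z, _, _ = scale_for_model(table, mode=mode)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    lam = pca.explained_variance_
    t2 = np.sum(scores**2 / lam[None, :], axis=1)
    n, a = n_study, n_components
    t2_lim = a * (n - 1) * (n + 1) / (n * (n - a)) * stats.f.ppf(limit, a, n - a)
    ids = table.sample_ids[table.study_mask]
    return pd.DataFrame(
        {"t2": t2, "t2_limit": t2_lim, "outlier": t2 > t2_lim},
        index=pd.Index(ids, name="sample_id"),
    )


def run_preprocess(
    table: FeatureTable, config: AnalysisConfig | None = None
) -> tuple[FeatureTable, PreprocessReport]:
    """Run the full chain per assay and rejoin the surviving features.

    Metabolomics and lipidomics features are processed independently (their
    QC and blank series come from separate analytical runs), then joined on
    sample id.  The returned report concatenates both assays' steps.
    """
    config = (config or AnalysisConfig()).validate()
    report = PreprocessReport()
    parts: list[FeatureTable] = []
    cvs = []
    quots = []
    for assay in ("metabolomics", "lipidomics"):
        mask = (table.feature_meta["assay"] == assay).to_numpy()
        if not mask.any():
            continue
        sub = table.subset(features=mask)
        sub, step = remove_blank_features(sub, config.blank_ratio)
        step.name = f"{assay}:{step.name}"
        report.add(step)
        sub, step = drift_correct(sub, config.loess_span)
        step.name = f"{assay}:{step.name}"
        report.add(step)
        sub, step = cv_filter(sub, config.cv_cutoff)
        cvs.append(step.details["cv"])
        step.name = f"{assay}:{step.name}"
        report.add(step)
        sub, step = pqn_normalize(sub)
        quots.append(step.details["quotients"].rename(assay))
        step.name = f"{assay}:{step.name}"
        report.add(step)
        parts.append(sub)
    if not parts:
        raise OmniblockError("table contains no metabolomics or lipidomics features")
    joined = parts[0]
    for other in parts[1:]:
        joined = FeatureTable(
            pd.concat([joined.intensities, other.intensities], axis=1),
            joined.sample_meta,
            pd.concat([joined.feature_meta, other.feature_meta], axis=0),
        )
    joined.validate()
    report.qc_cv = pd.concat(cvs)
    report.pqn_quotients = pd.concat(quots, axis=1).mean(axis=1)
    if int(joined.study_mask.sum()) >= 4 and joined.n_features >= 2:
        flags = flag_outliers(joined, n_components=2, mode=config.scaling
                              if config.scaling != "none" else "unit_variance")
        report.outliers = flags
    return joined, report
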