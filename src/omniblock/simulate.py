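"""Synthetic LC-MS feature-table generator with known ground truth.

The generator emulates the statistical structure of a matched two-group
plasma cohort profiled by untargeted metabolomics and lipidomics:

* two groups of ``n_per_group`` study samples (case/control, pair-matched),
  randomly assigned to the injection sequence with a pooled QC sample at
  every ``qc_interval``-th injection and a few solvent blanks up front;
* log-normal feature intensities with a shared latent factor per functional
  block (metabolites) or per lipid cluster, giving a chosen within-block
  pairwise correlation;
* signed group effects (fold changes of magnitude ~1.05-1.9) planted on a
  fraction of the blocks;
* per-feature analytical noise calibrated so the QC coefficient of variation
  falls in a chosen range (straddling the usual 30% filter cutoff);
* a smooth multiplicative per-feature drift along the injection order;
* blanks at a low constant level and optional missingness at random.

Every generated table is accompanied by a :class:`GroundTruth` record so
that recovery of affected features/blocks, lipid-cluster membership, drift
removal and CV filtering can be tested against the planted truth.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import FeatureTable, ValidationError
from .enrich import PathwayCatalog

__all__ = ["SyntheticSpec", "GroundTruth", "generate_table", "generate_pathway_catalog"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study design this generator emulates: 97 samples
    per group, 228 metabolite features in 54 functional blocks, 335 lipid
    features in 11 statistical clusters, QC every 5th injection.
    """

    n_per_group: int = 97
    n_metabolite_features: int = 228
    n_lipid_features: int = 335
    n_functional_blocks: int = 54
    n_lipid_clusters_true: int = 11
    within_block_correlation: float = 0.5
    affected_block_fraction: float = 0.5
    effect_fold_changes: Sequence[float] | None = None
    fold_change_range: tuple[float, float] = (1.05, 1.9)
    feature_cv_range: tuple[float, float] = (0.10, 0.40)
    drift_amplitude: float = 0.2
    qc_interval: int = 5
    n_blanks: int = 4
    missing_rate: float = 0.0
    blank_level_fraction: float = 0.05
    baseline_log_mean: float = float(np.log(1e5))
    baseline_log_sd: float = 1.0
    seed: int = 0

    def validate(self) -> "SyntheticSpec":
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if self.qc_interval < 2:
            raise ValidationError("qc_interval must be >= 2")
        if not (0 <= self.within_block_correlation < 1):
            raise ValidationError("within_block_correlation must lie in [0, 1)")
        if not (0 <= self.affected_block_fraction <= 1):
            raise ValidationError("affected_block_fraction must lie in [0, 1]")
        if self.effect_fold_changes is not None and any(
            abs(fc) < 1 for fc in self.effect_fold_changes
        ):
            raise ValidationError("fold-change magnitudes must be >= 1")
        if self.fold_change_range[0] < 1:
            raise ValidationError("fold-change magnitudes must be >= 1")
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing_rate must lie in [0, 1)")
        if self.affected_block_fraction == 0 and (
            self.effect_fold_changes is None or len(self.effect_fold_changes) > 0
        ):
            warnings.warn("affected_block_fraction is 0: no group effects will be planted")
        return self


@dataclass
class GroundTruth:
    """Planted truth emitted alongside every generated table."""

    affected_feature_ids: set[str]
    affected_block_ids: set[str]
    fold_change: dict[str, float]          # signed, |fc| >= 1; 1.0 for null features
    lipid_cluster: dict[str, str]          # lipid feature id -> true cluster id
    block_of_feature: dict[str, str]       # every feature -> its block/cluster id
    target_cv: dict[str, float]            # planted QC coefficient of variation
    drift_params: dict[str, tuple[float, float]]  # feature -> (frequency, phase)
    drift_amplitude: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fid, block in self.block_of_feature.items():
            freq, phase = self.drift_params[fid]
            rows.append(
                {
                    "feature_id": fid,
                    "block_id": block,
                    "affected": fid in self.affected_feature_ids,
                    "fold_change": self.fold_change[fid],
                    "target_cv": self.target_cv[fid],
                    "drift_frequency": freq,
                    "drift_phase": phase,
                    "drift_amplitude": self.drift_amplitude,
                }
            )
        return pd.DataFrame(rows).set_index("feature_id")


def _assign_blocks(rng: np.random.Generator, n_features: int, n_blocks: int, prefix: str):
    """Random assignment of features to blocks, each block non-empty."""
    if n_blocks > n_features:
        raise ValidationError(f"cannot form {n_blocks} non-empty blocks from {n_features} features")
    assignment = np.concatenate(
        [np.arange(n_blocks), rng.integers(0, n_blocks, n_features - n_blocks)]
    )
    rng.shuffle(assignment)
    return np.array([f"{prefix}{b + 1:02d}" for b in assignment])


def _signed_magnitudes(rng: np.random.Generator, spec: SyntheticSpec, n: int) -> np.ndarray:
    if spec.effect_fold_changes is not None:
        mags = rng.choice(np.abs(np.asarray(spec.effect_fold_changes, dtype=float)), size=n)
    else:
        lo, hi = spec.fold_change_range
        mags = rng.uniform(lo, hi, size=n)
    signs = rng.choice([-1.0, 1.0], size=n)
    return signs * mags


def generate_table(spec: SyntheticSpec) -> tuple[FeatureTable, GroundTruth]:
    """Generate one synthetic feature table plus its ground truth.

    The intensity model per feature ``j`` is log-normal: a study sample in
    block ``b`` has log-intensity ``mu_j + a_j f_{i,b} + s_j log|FC_j| 1[case]
    + eps`` with block factor ``f_{i,b} ~ N(0,1)`` shared by all features of
    the block, loading ``a_j`` chosen so the pairwise within-block correlation
    equals ``within_block_correlation``, and noise sd set so the QC CV of the
    exponentiated intensity matches the planted target.  QC samples are draws
    at the pooled mean (halfway between the two group means on the log scale,
    no block factor), blanks sit at a low constant level, and all injections
    share a smooth multiplicative drift ``1 + amplitude * cos(2 pi (f u + phi))``
    in the normalized injection position ``u``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_met, n_lip = spec.n_metabolite_features, spec.n_lipid_features
    n_feat = n_met + n_lip
    met_ids = [f"met_{i + 1:03d}" for i in range(n_met)]
    lip_ids = [f"lip_{i + 1:03d}" for i in range(n_lip)]
    feature_ids = met_ids + lip_ids

    met_blocks = _assign_blocks(rng, n_met, spec.n_functional_blocks, "FB")
    lip_blocks = _assign_blocks(rng, n_lip, spec.n_lipid_clusters_true, "LC")
    block_of_feature = dict(zip(feature_ids, np.concatenate([met_blocks, lip_blocks])))

    # baseline, noise and block loadings
    mu = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, n_feat)
    cv_lo, cv_hi = spec.feature_cv_range
    target_cv = rng.uniform(cv_lo, cv_hi, n_feat)
    sigma = np.sqrt(np.log1p(target_cv**2))  # lognormal: CV = sqrt(exp(sigma^2)-1)
    rho = spec.within_block_correlation
    loading = sigma * np.sqrt(rho / (1.0 - rho)) if rho > 0 else np.zeros(n_feat)

    # affected blocks and per-feature signed effects
    delta = np.zeros(n_feat)
    affected_blocks: set[str] = set()
    fold_change = dict.fromkeys(feature_ids, 1.0)
    for prefix, blocks in (("FB", met_blocks), ("LC", lip_blocks)):
        uniq = sorted(set(blocks))
        n_aff = int(round(spec.affected_block_fraction * len(uniq)))
        chosen = set(rng.choice(uniq, size=n_aff, replace=False)) if n_aff else set()
        affected_blocks |= chosen
    all_blocks = np.concatenate([met_blocks, lip_blocks])
    aff_mask = np.array([b in affected_blocks for b in all_blocks])
    signed = _signed_magnitudes(rng, spec, int(aff_mask.sum()))
    delta[aff_mask] = np.sign(signed) * np.log(np.abs(signed))
    for fid, fc in zip(np.array(feature_ids)[aff_mask], signed):
        fold_change[fid] = float(fc)
    affected_features = set(np.array(feature_ids)[aff_mask])

    # injection layout: blanks first, then blocks of (interval-1) study + 1 QC
    n_study = 2 * spec.n_per_group
    n_qc = n_study // (spec.qc_interval - 1)
    study_ids = []
    groups = []
    pair_ids = []
    for i in range(spec.n_per_group):
        study_ids += [f"ctrl_{i + 1:03d}", f"case_{i + 1:03d}"]
        groups += ["control", "case"]
        pair_ids += [f"pair_{i + 1:03d}"] * 2
    study_perm = rng.permutation(n_study)
    qc_ids = [f"qc_{i + 1:03d}" for i in range(n_qc)]
    blank_ids = [f"blank_{i + 1:02d}" for i in range(spec.n_blanks)]

    seq: list[str] = list(blank_ids)
    qc_iter = iter(qc_ids)
    for k, idx in enumerate(study_perm):
        seq.append(study_ids[idx])
        if (k + 1) % (spec.qc_interval - 1) == 0:
            nxt = next(qc_iter, None)
            if nxt is not None:
                seq.append(nxt)
    order_of = {sid: pos + 1 for pos, sid in enumerate(seq)}
    n_inj = len(seq)

    # drift functions
    freq = rng.uniform(0.5, 1.5, n_feat)
    phase = rng.uniform(0.0, 1.0, n_feat)

    def drift_factor(order: np.ndarray) -> np.ndarray:
        u = (order[:, None] - 1) / max(n_inj - 1, 1)
        s = np.cos(2 * np.pi * (freq[None, :] * u + phase[None, :]))
        return 1.0 + spec.drift_amplitude * s

    # assemble rows in a canonical (study, qc, blank) order, metadata carries order
    all_ids = study_ids + qc_ids + blank_ids
    roles = ["study"] * n_study + ["qc"] * n_qc + ["blank"] * spec.n_blanks
    logx = np.empty((len(all_ids), n_feat))

    block_index = {b: i for i, b in enumerate(sorted(set(all_blocks)))}
    feat_block_idx = np.array([block_index[b] for b in all_blocks])
    factors = rng.standard_normal((n_study, len(block_index)))
    is_case = np.array([g == "case" for g in groups])
    noise_study = rng.standard_normal((n_study, n_feat)) * sigma[None, :]
    logx[:n_study] = (
        mu[None, :]
        + loading[None, :] * factors[:, feat_block_idx]
        + np.outer(is_case, delta)
        + noise_study
    )
    noise_qc = rng.standard_normal((n_qc, n_feat)) * sigma[None, :]
    logx[n_study : n_study + n_qc] = mu[None, :] + 0.5 * delta[None, :] + noise_qc

    blank_level = np.log(np.median(np.exp(mu)) * spec.blank_level_fraction)
    logx[n_study + n_qc :] = blank_level + rng.normal(0.0, 0.1, (spec.n_blanks, n_feat))

    orders = np.array([order_of[sid] for sid in all_ids])
    intensities = np.exp(logx) * drift_factor(orders)

    if spec.missing_rate > 0:
        mask = rng.random(intensities.shape) < spec.missing_rate
        intensities = np.where(mask, np.nan, intensities)

    inten = pd.DataFrame(intensities, index=all_ids, columns=feature_ids)
    smeta = pd.DataFrame(
        {
            "role": roles,
            "injection_order": orders,
            "group": groups + [None] * (n_qc + spec.n_blanks),
            "pair_id": pair_ids + [None] * (n_qc + spec.n_blanks),
        },
        index=pd.Index(all_ids, name="sample_id"),
    )
    fmeta = pd.DataFrame(
        {
            "assay": ["metabolomics"] * n_met + ["lipidomics"] * n_lip,
            "annotation": feature_ids,
            "block_id": [block_of_feature[f] if f in met_ids else None for f in feature_ids],
            "lipid_class": [None] * n_met + [block_of_feature[f] for f in lip_ids],
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    table = FeatureTable(inten, smeta, fmeta).validate()
    truth = GroundTruth(
        affected_feature_ids=affected_features,
        affected_block_ids=affected_blocks,
        fold_change=fold_change,
        lipid_cluster={f: block_of_feature[f] for f in lip_ids},
        block_of_feature=block_of_feature,
        target_cv=dict(zip(feature_ids, target_cv)),
        drift_params={f: (float(freq[i]), float(phase[i])) for i, f in enumerate(feature_ids)},
        drift_amplitude=spec.drift_amplitude,
    )
    return table, truth


def generate_pathway_catalog(
    spec: SyntheticSpec,
    n_pathways: int,
    truth: GroundTruth | None = None,
    min_size: int = 4,
    max_size: int = 20,
) -> PathwayCatalog:
    """Sample a pathway catalog over the metabolite annotations.

    The first pathway is constructed to coincide with one affected functional
    block (a genuinely enriched set, enlarged to ``min_size`` members if the
    block is smaller); the remaining pathways are random metabolite subsets.
    Deterministic given ``spec.seed``.
    """
    if n_pathways < 1:
        raise ValidationError("n_pathways must be >= 1")
    rng = np.random.default_rng(spec.seed + 104729)
    met_names = [f"met_{i + 1:03d}" for i in range(spec.n_metabolite_features)]
    universe = set(met_names)
    pathways: dict[str, set[str]] = {}
    start = 0
    if truth is not None:
        met_affected_blocks = sorted(b for b in truth.affected_block_ids if b.startswith("FB"))
        if met_affected_blocks:
            block = met_affected_blocks[0]
            members = sorted(
                f for f, b in truth.block_of_feature.items() if b == block and f in universe
            )
            pool = sorted(universe - set(members))
            while len(members) < min(min_size, len(universe)):
                pick = pool.pop(int(rng.integers(len(pool))))
                members.append(pick)
            pathways["pw_true"] = set(members)
            start = 1
    for i in range(start, n_pathways):
        size = int(rng.integers(min_size, min(max_size, len(met_names)) + 1))
        members = rng.choice(met_names, size=size, replace=False)
        pathways[f"pw_{i + 1:03d}"] = set(members)
    return PathwayCatalog(pathways=pathways, universe=universe)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    truth.to_frame().to_csv(path, na_rep="NA", float_format="%.17g")
    return path
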