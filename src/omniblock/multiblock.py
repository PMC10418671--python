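"""Multiblock analysis: block construction, per-block composite scores via
OPLS-DA, block-size weighting, and the hierarchical PLS-DA on block scores.

Metabolites are grouped into curated functional blocks; lipid species into
statistical blocks obtained by Ward hierarchical clustering of their scaled
profiles.  Each block is compressed to a single composite score (the
predictive OPLS-DA score, standardized), the score columns are weighted by
block size, and a PLS-DA on the resulting samples x blocks matrix ranks the
blocks by VIP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

from .data import FeatureTable, OmniblockError, ValidationError
from .latent import (
    ConvergenceError,
    LatentModel,
    compute_vip,
    encode_binary,
    fit_oplsda,
    fit_plsda,
)

__all__ = [
    "BlockMap",
    "BlockScoreMatrix",
    "load_block_map",
    "write_block_map",
    "functional_block_map",
    "cluster_lipids",
    "block_scores",
    "weight_blocks",
    "fit_hierarchical",
    "select_blocks",
]


@dataclass
class BlockMap:
    """Assignment of features to disjoint, non-empty blocks."""

    blocks: dict[str, list[str]]
    kind: str = "functional"  # or "statistical"

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for bid, feats in self.blocks.items():
            if not feats:
                raise ValidationError(f"block {bid!r} is empty")
            for f in feats:
                if f in seen:
                    raise ValidationError(
                        f"feature {f!r} mapped to both {seen[f]!r} and {bid!r}"
                    )
                seen[f] = bid
        self._feature_to_block = seen

    @property
    def block_ids(self) -> list[str]:
        return list(self.blocks)

    @property
    def sizes(self) -> dict[str, int]:
        return {b: len(f) for b, f in self.blocks.items()}

    def block_of(self, feature_id: str) -> str | None:
        return self._feature_to_block.get(feature_id)

    def merged(self, other: "BlockMap") -> "BlockMap":
        overlap = set(self.blocks) & set(other.blocks)
        if overlap:
            raise ValidationError(f"block ids collide: {sorted(overlap)}")
        return BlockMap({**self.blocks, **other.blocks}, kind="mixed")


def load_block_map(path: str | Path, table: FeatureTable) -> tuple[BlockMap, list[str]]:
    """Read a two-column TSV (feature_id, block_id) and validate against a table.

    Features of the table absent from the file form the returned "unassigned"
    list (excluded from multiblock analysis); a file row referencing an
    unknown feature id is an error.
    """
    blocks: dict[str, list[str]] = {}
    mapped: set[str] = set()
    known = set(table.feature_ids)
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 'feature_id<TAB>block_id'")
        fid, bid = parts[0].strip(), parts[1].strip()
        if fid not in known:
            raise ValidationError(f"{path}:{lineno}: unknown feature id {fid!r}")
        if fid in mapped:
            raise ValidationError(f"{path}:{lineno}: feature {fid!r} mapped twice")
        mapped.add(fid)
        blocks.setdefault(bid, []).append(fid)
    unassigned = [f for f in table.feature_ids if f not in mapped]
    return BlockMap(blocks, kind="functional"), unassigned


def write_block_map(block_map: BlockMap, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"{fid}\t{bid}" for bid, feats in block_map.blocks.items() for fid in feats]
    path.write_text("\n".join(lines) + "\n")
    return path


def functional_block_map(table: FeatureTable, assay: str = "metabolomics") -> tuple[BlockMap, list[str]]:
    """Build the functional BlockMap from the table's ``block_id`` column."""
    fmeta = table.feature_meta
    mask = (fmeta["assay"] == assay).to_numpy()
    blocks: dict[str, list[str]] = {}
    unassigned: list[str] = []
    for fid, bid in fmeta.loc[mask, "block_id"].items():
        if bid is None or (isinstance(bid, float) and np.isnan(bid)):
            unassigned.append(fid)
        else:
            blocks.setdefault(str(bid), []).append(fid)
    if not blocks:
        raise OmniblockError(f"no {assay} features carry a block_id")
    return BlockMap(blocks, kind="functional"), unassigned


def cluster_lipids(
    X: np.ndarray, feature_ids: list[str], k: int, prefix: str = "lipid_cluster_"
) -> BlockMap:
    """Ward hierarchical clustering of lipid feature profiles into ``k`` blocks.

    Features are the points (samples are the dimensions) of a Euclidean
    Ward agglomeration; the tree is cut at ``k`` clusters.  ``X`` must be the
    scaled study-row matrix restricted to the lipid features, in the order of
    ``feature_ids``.  Cluster labels are renumbered by first feature
    occurrence, which makes the output deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(feature_ids):
        raise ValidationError("column count must match feature_ids")
    if k < 1 or k > len(feature_ids):
        raise ValidationError(f"k={k} must lie in [1, {len(feature_ids)}]")
    if k == 1:
        return BlockMap({f"{prefix}1": list(feature_ids)}, kind="statistical")
    Z = linkage(X.T, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    for lab in labels:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    blocks: dict[str, list[str]] = {}
    for fid, lab in zip(feature_ids, labels):
        blocks.setdefault(f"{prefix}{relabel[lab]}", []).append(fid)
    return BlockMap(blocks, kind="statistical")


@dataclass
class BlockScoreMatrix:
    """Samples x blocks composite scores, with weights and source models."""

    scores: pd.DataFrame                      # rows = study samples
    weights: dict[str, float]
    sizes: dict[str, int]
    models: dict[str, LatentModel | None]
    dropped: list[str] = field(default_factory=list)

    @property
    def block_ids(self) -> list[str]:
        return list(self.scores.columns)

    def matrix(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)


def block_scores(
    X: np.ndarray,
    y,
    feature_ids: list[str],
    block_map: BlockMap,
    n_orthogonal: int = 1,
    sample_ids=None,
) -> BlockScoreMatrix:
    """Compress each block of the scaled matrix to one composite score.

    Per block the predictive OPLS-DA score is used (``n_orthogonal``
    orthogonal components; 0 for blocks of fewer than 3 features).  Scores
    are standardized to unit variance and sign-aligned to positive
    correlation with the response.  Single-feature blocks return the scaled
    feature itself.  Blocks whose model fails are dropped with a warning.
    """
    X = np.asarray(X, dtype=float)
    yc, _ = encode_binary(y)
    col = {f: j for j, f in enumerate(feature_ids)}
    cols: dict[str, np.ndarray] = {}
    models: dict[str, LatentModel | None] = {}
    dropped: list[str] = []
    sizes: dict[str, int] = {}
    for bid, feats in block_map.blocks.items():
        missing = [f for f in feats if f not in col]
        if missing:
            raise ValidationError(f"block {bid!r} references absent features: {missing[:3]}")
        idx = [col[f] for f in feats]
        sizes[bid] = len(idx)
        Xb = X[:, idx]
        try:
            if len(idx) == 1:
                t = Xb[:, 0].copy()
                models[bid] = None
            else:
                n_orth = 0 if len(idx) < 3 else min(n_orthogonal, len(idx) - 1)
                model = fit_oplsda(Xb, y, n_orthogonal=n_orth)
                t = model.scores[:, 0].copy()
                models[bid] = model
            sd = t.std(ddof=1)
            if sd <= 0:
                raise ConvergenceError("degenerate composite score")
            t /= sd
            if float(t @ yc) < 0:
                t *= -1
            cols[bid] = t
        except (ConvergenceError, ValidationError) as err:
            warnings.warn(f"block {bid!r} dropped: {err}")
            dropped.append(bid)
    if not cols:
        raise OmniblockError("every block failed; no composite scores")
    frame = pd.DataFrame(cols, index=sample_ids if sample_ids is not None else range(X.shape[0]))
    weights = {bid: 1.0 for bid in cols}
    return BlockScoreMatrix(scores=frame, weights=weights,
                            sizes={b: sizes[b] for b in cols}, models=models,
                            dropped=dropped)


def weight_blocks(scores: BlockScoreMatrix, scheme: str = "sqrt_size") -> BlockScoreMatrix:
    """Multiply each score column by a block-size weight.

    ``sqrt_size`` uses ``w_k = sqrt(n_k)``, ``inverse_sqrt_size`` its
    reciprocal, both normalized so that ``sum w_k^2`` equals the number of
    blocks (so equal sizes give all-one weights); ``none`` is the identity.
    """
    if scheme not in ("sqrt_size", "inverse_sqrt_size", "none"):
        raise ValidationError(f"unknown weight scheme {scheme!r}")
    ids = scores.block_ids
    if scheme == "none":
        w = np.ones(len(ids))
    else:
        raw = np.array([np.sqrt(scores.sizes[b]) for b in ids])
        if scheme == "inverse_sqrt_size":
            raw = 1.0 / raw
        w = raw * np.sqrt(len(ids) / np.sum(raw**2))
    frame = scores.scores * w[None, :]
    return BlockScoreMatrix(
        scores=frame, weights=dict(zip(ids, map(float, w))), sizes=dict(scores.sizes),
        models=dict(scores.models), dropped=list(scores.dropped),
    )


def fit_hierarchical(
    scores: BlockScoreMatrix, y, A: int = 2
) -> tuple[LatentModel, pd.Series]:
    """PLS-DA on the (weighted) block-score matrix; returns per-block VIP."""
    if len(scores.block_ids) < 2:
        raise ValidationError("hierarchical model needs >= 2 blocks")
    M = scores.matrix()
    Mc = M - M.mean(axis=0)
    model = fit_plsda(Mc, y, A=min(A, min(Mc.shape[0] - 1, Mc.shape[1])))
    vips = pd.Series(compute_vip(model), index=scores.block_ids, name="vip")
    return model, vips


def select_blocks(
    vips: pd.Series,
    scores: BlockScoreMatrix,
    y,
    vip_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Blocks with VIP above threshold and Benjamini-Yekutieli q below alpha.

    The group comparison is a two-sided Welch t-test on each block's
    composite score.  Composite scores are supervised, so this univariate
    test inherits their optimism; the permutation test of the hierarchical
    model is the honest global check.
    """
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    a_mask, b_mask = (y == classes[0]), (y == classes[1])
    rows = []
    for bid in scores.block_ids:
        s = scores.scores[bid].to_numpy(dtype=float)
        t_stat, p = ttest_ind(s[b_mask], s[a_mask], equal_var=False)
        rows.append(
            {
                "block_id": bid,
                "size": scores.sizes[bid],
                "weight": scores.weights[bid],
                "vip": float(vips[bid]),
                "t": float(t_stat),
                "p": float(p),
                "direction": "up" if t_stat > 0 else "down",
            }
        )
    out = pd.DataFrame(rows).set_index("block_id")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_by")[1]
    out["selected"] = (out["vip"] > vip_threshold) & (out["q"] < alpha)
    return out.sort_values("vip", ascending=False)
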