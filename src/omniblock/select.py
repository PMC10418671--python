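"""Feature-level selection: signed fold changes, univariate tests,
Benjamini-Yekutieli FDR, the VIP-and-significance selection rule, and
signature comparison (Venn regions).

The signed fold-change convention reports the case/control mean ratio ``r``
as ``r`` when ``r >= 1`` and as ``-1/r`` otherwise, so a value of -1.12
means a 12% decrease in cases and ``|FC| >= 1`` always.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import OmniblockError, ValidationError

__all__ = [
    "Signature",
    "signed_fold_change",
    "univariate_test",
    "adjust_by",
    "feature_statistics",
    "select_features",
    "compare_signatures",
]

UNIVARIATE_METHODS = ("welch_t", "student_t", "paired_t", "mann_whitney")


@dataclass
class Signature:
    """A named set of selected feature ids."""

    name: str
    features: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("signature name must be non-empty")


def signed_fold_change(case: np.ndarray, control: np.ndarray) -> float:
    """Case/control mean ratio with the signed reciprocal convention."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    m_case = np.nanmean(case)
    m_ctrl = np.nanmean(control)
    if not (m_case > 0 and m_ctrl > 0):
        raise OmniblockError("fold change requires positive group means")
    r = m_case / m_ctrl
    return float(r if r >= 1 else -1.0 / r)


def univariate_test(
    case: np.ndarray,
    control: np.ndarray,
    method: str = "welch_t",
    case_pairs: Sequence[str] | None = None,
    control_pairs: Sequence[str] | None = None,
) -> tuple[float, float]:
    """Two-sided group comparison; returns ``(statistic, p)``.

    ``paired_t`` aligns the two groups on their pair ids and requires every
    pair to be complete; ``mann_whitney`` uses the normal approximation with
    tie correction so fully tied data yield p = 1.
    """
    if method not in UNIVARIATE_METHODS:
        raise ValidationError(f"unknown method {method!r}")
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    case = case[np.isfinite(case)] if method != "paired_t" else case
    control = control[np.isfinite(control)] if method != "paired_t" else control
    if len(case) < 2 or len(control) < 2:
        raise ValidationError("each group needs >= 2 values")
    if method == "welch_t":
        res = stats.ttest_ind(case, control, equal_var=False)
    elif method == "student_t":
        res = stats.ttest_ind(case, control, equal_var=True)
    elif method == "paired_t":
        if case_pairs is None or control_pairs is None:
            raise ValidationError("paired_t requires pair ids for both groups")
        cmap = dict(zip(case_pairs, case))
        kmap = dict(zip(control_pairs, control))
        missing = sorted(set(cmap) ^ set(kmap))
        if missing:
            raise ValidationError(f"incomplete pairs: {missing}")
        pairs = sorted(cmap)
        a = np.array([cmap[p] for p in pairs])
        b = np.array([kmap[p] for p in pairs])
        ok = np.isfinite(a) & np.isfinite(b)
        res = stats.ttest_rel(a[ok], b[ok])
    else:  # mann_whitney
        if np.all(case[:, None] == control[None, :]):
            return 0.0, 1.0
        res = stats.mannwhitneyu(case, control, alternative="two-sided", method="asymptotic")
    stat = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(p):  # zero-variance identical groups under t-tests
        stat, p = 0.0, 1.0
    return stat, p


def adjust_by(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted q-values (input order preserved).

    ``q_(i) = min_{j >= i} p_(j) m c(m) / j`` with ``c(m) = sum_{1..m} 1/i``,
    capped at 1 -- valid under arbitrary dependence between the tests.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def feature_statistics(
    table_intensities: pd.DataFrame,
    y: np.ndarray,
    case_label,
    method: str = "welch_t",
    pair_ids: Sequence[str] | None = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-feature signed fold change, test statistic, raw p and B-Y q.

    Tests run on log-transformed intensities by default (fold changes stay
    on the natural scale); rows are study samples, ``y`` their group labels.
    """
    y = np.asarray(y)
    case_mask = y == case_label
    ctrl_mask = ~case_mask
    X = table_intensities.to_numpy(dtype=float)
    rows = []
    for j, fid in enumerate(table_intensities.columns):
        xj = X[:, j]
        fc = signed_fold_change(xj[case_mask], xj[ctrl_mask])
        vals = np.log(xj) if log_transform else xj
        kwargs = {}
        if method == "paired_t":
            if pair_ids is None:
                raise ValidationError("paired_t requires pair ids")
            pid = np.asarray(pair_ids)
            kwargs = {"case_pairs": pid[case_mask], "control_pairs": pid[ctrl_mask]}
        stat, p = univariate_test(vals[case_mask], vals[ctrl_mask], method=method, **kwargs)
        rows.append({"feature_id": fid, "fold_change": fc, "statistic": stat, "p": p})
    out = pd.DataFrame(rows).set_index("feature_id")
    out["q"] = adjust_by(out["p"])
    out["direction"] = np.where(out["fold_change"] >= 1, "up", "down")
    out["test"] = method
    return out


def select_features(
    vips: pd.Series,
    stats_frame: pd.DataFrame,
    vip_threshold: float = 1.0,
    alpha: float = 0.05,
    use_adjusted: bool = False,
    name: str = "signature",
) -> tuple[Signature, pd.DataFrame]:
    """Features with VIP above threshold and (q or raw p) below alpha.

    ``vips`` and ``stats_frame`` must share their feature index.  Records are
    returned sorted by VIP descending, with the selection flag; the head of
    the frame is the "top-n" view.
    """
    if not vips.index.sort_values().equals(stats_frame.index.sort_values()):
        raise ValidationError("vips and statistics are not aligned on feature_id")
    records = stats_frame.copy()
    records["vip"] = vips.reindex(records.index)
    crit_p = records["q"] if use_adjusted else records["p"]
    records["selected"] = (records["vip"] > vip_threshold) & (crit_p < alpha)
    records = records.sort_values(["vip", "p"], ascending=[False, True],
                                  kind="mergesort")
    sig = Signature(name=name, features=set(records.index[records["selected"]]))
    return sig, records


def compare_signatures(signatures: Sequence[Signature]) -> pd.DataFrame:
    """Enumerate every Venn region of 2-4 signatures with counts and members.

    The region key is the tuple of membership flags in input order; counts
    over all regions sum to the size of the union.
    """
    if not (2 <= len(signatures) <= 4):
        raise ValidationError(
            "compare_signatures supports 2-4 signatures; use a membership table beyond 4"
        )
    names = [s.name for s in signatures]
    if len(set(names)) != len(names):
        raise ValidationError("signature names must be distinct")
    universe = set().union(*(s.features for s in signatures))
    rows = []
    for flags in itertools.product((True, False), repeat=len(signatures)):
        if not any(flags):
            continue
        region = set(universe)
        for sig, inside in zip(signatures, flags):
            region = region & sig.features if inside else region - sig.features
        rows.append(
            {
                "region": "&".join(n for n, f in zip(names, flags) if f),
                "n_signatures": sum(flags),
                "count": len(region),
                "members": ";".join(sorted(region)),
            }
        )
    return pd.DataFrame(rows)
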