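"""Metabolite set over-representation analysis (hypergeometric ORA).

Given a set of selected metabolite names and a pathway catalog, each pathway
is scored with the upper-tail hypergeometric probability of observing at
least the seen number of selected members, over a background universe of the
annotated metabolites that survived preprocessing.  Benjamini-Hochberg
q-values are attached across pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data import FormatError, OmniblockError, ValidationError

__all__ = [
    "PathwayCatalog",
    "EnrichmentResult",
    "read_pathway_catalog",
    "write_pathway_catalog",
    "match_names",
    "enrich",
]


def _norm(name: str) -> str:
    return " ".join(name.split()).casefold()


@dataclass
class PathwayCatalog:
    """Pathway id -> set of metabolite names, plus the background universe."""

    pathways: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        empty = [pid for pid, members in self.pathways.items() if not members]
        if empty:
            warnings.warn(f"dropping empty pathways: {sorted(empty)}")
            for pid in empty:
                del self.pathways[pid]

    def restricted(self, universe: Iterable[str]) -> "PathwayCatalog":
        """Intersect every pathway with a new background universe."""
        uni = set(universe)
        norm_uni = {_norm(u): u for u in uni}
        restricted = {}
        for pid, members in self.pathways.items():
            kept = {norm_uni[_norm(m)] for m in members if _norm(m) in norm_uni}
            if kept:
                restricted[pid] = kept
        return PathwayCatalog(pathways=restricted, universe=uni)


@dataclass
class EnrichmentResult:
    pathway_id: str
    k_hits: int
    pathway_size: int
    n_selected: int
    n_universe: int
    p_value: float
    q_value: float = float("nan")
    hit_names: tuple[str, ...] = ()


def read_pathway_catalog(path: str | Path) -> PathwayCatalog:
    """Read a TSV catalog: ``pathway_id<TAB>comma-separated metabolite names``."""
    pathways: dict[str, set[str]] = {}
    universe: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected two tab-separated fields")
        pid, names = parts
        members = {n.strip() for n in names.split(",") if n.strip()}
        if pid in pathways:
            raise FormatError(f"{path}:{lineno}: duplicated pathway id {pid!r}")
        pathways[pid] = members
        universe |= members
    return PathwayCatalog(pathways=pathways, universe=universe)


def write_pathway_catalog(catalog: PathwayCatalog, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        f"{pid}\t{','.join(sorted(members))}"
        for pid, members in sorted(catalog.pathways.items())
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def match_names(selected: Iterable[str], catalog: PathwayCatalog):
    """Case-insensitive, whitespace-normalized exact matching to the universe.

    Returns ``(matched_set, unmatched_list, n_duplicates)``; matched names are
    reported in the catalog's own spelling.  No fuzzy matching is attempted.
    """
    norm_uni = {_norm(u): u for u in catalog.universe}
    matched: set[str] = set()
    unmatched: list[str] = []
    seen: set[str] = set()
    n_dup = 0
    for name in selected:
        key = _norm(name)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        if key in norm_uni:
            matched.add(norm_uni[key])
        else:
            unmatched.append(name)
    return matched, unmatched, n_dup


def enrich(selected: Iterable[str], catalog: PathwayCatalog) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``selected`` in every pathway.

    ``p = P(X >= k)`` for ``X ~ Hypergeom(N, K, n)`` with ``N`` the universe
    size, ``K`` the pathway size and ``n`` the number of selected metabolites;
    computed with the survival function for numerical stability.  Results are
    sorted by ascending p with Benjamini-Hochberg q-values attached.
    """
    if not catalog.universe:
        raise OmniblockError("empty background universe")
    matched, unmatched, _ = match_names(selected, catalog)
    if unmatched:
        warnings.warn(f"{len(unmatched)} selected names not in universe, dropped: "
                      f"{unmatched[:5]}{'...' if len(unmatched) > 5 else ''}")
    n_universe = len(catalog.universe)
    n_selected = len(matched)
    results = []
    for pid, members in catalog.pathways.items():
        inside = members & catalog.universe
        if not inside:
            continue
        hits = sorted(matched & inside)
        k = len(hits)
        K = len(inside)
        # P(X >= k); sf(k-1) so that k = 0 gives exactly 1
        p = float(hypergeom.sf(k - 1, n_universe, K, n_selected))
        results.append(
            EnrichmentResult(
                pathway_id=pid,
                k_hits=k,
                pathway_size=K,
                n_selected=n_selected,
                n_universe=n_universe,
                p_value=min(max(p, 0.0), 1.0),
                hit_names=tuple(hits),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    if results:
        qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "k_hits": r.k_hits,
                "pathway_size": r.pathway_size,
                "n_selected": r.n_selected,
                "n_universe": r.n_universe,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "hits": ";".join(r.hit_names),
            }
            for r in results
        ]
    )
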