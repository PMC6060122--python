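"""Hypergeometric term enrichment with Benjamini–Hochberg FDR.

A query entity's target set G_comp is tested against every term set
G_path of an annotation namespace.  With l the background-universe
size, k = |G_path|, r = |G_comp| and z = |G_comp ∩ G_path|, the
one-sided tail probability is

    p = sum_{i=z}^{min(k,r)} C(k, i) C(l-k, r-i) / C(l, r),

the probability of an intersection at least as large as observed when
G_comp is drawn uniformly from the universe.  The enrichment ratio is
z / k, the fraction of a term's proteins hit by the query's targets.
Term sets are restricted to the background universe before testing, and
p-values are corrected per namespace by Benjamini–Hochberg.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import comb
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import AnnotationNamespace, DomainError

__all__ = [
    "EnrichmentQuery",
    "EnrichmentRow",
    "hypergeom_tail",
    "bh_fdr",
    "enrich",
]

logger = logging.getLogger(__name__)

# below this universe size the tail is summed in exact integer
# arithmetic; above it, scipy's log-space survival function is used
_EXACT_L_MAX = 2000


def hypergeom_tail(l: int, k: int, r: int, z: int) -> float:
    """P(X >= z) for X hypergeometric with population l, k successes,
    r draws.

    Exact big-integer arithmetic for l <= 2000 (no cancellation);
    scipy's log-space survival function beyond that.
    """
    for name, value in (("l", l), ("k", k), ("r", r), ("z", z)):
        if int(value) != value or value < 0:
            raise DomainError(f"{name} must be a nonnegative integer, got {value!r}")
    l, k, r, z = int(l), int(k), int(r), int(z)
    if k > l:
        raise DomainError(f"k must satisfy 0 <= k <= l, got k={k}, l={l}")
    if r > l:
        raise DomainError(f"r must satisfy 0 <= r <= l, got r={r}, l={l}")
    if z > min(k, r):
        raise DomainError(f"z must satisfy 0 <= z <= min(k, r), got z={z}")
    if z == 0:
        return 1.0
    if l <= _EXACT_L_MAX:
        num = sum(comb(k, i) * comb(l - k, r - i) for i in range(z, min(k, r) + 1))
        return num / comb(l, r)
    return float(stats.hypergeom.sf(z - 1, l, k, r))


def bh_fdr(p_values: Sequence[float]) -> list:
    """Benjamini–Hochberg adjusted q-values, positionally aligned with
    the input.  Each q >= its p and q <= 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        bad = p[(p < 0) | (p > 1) | np.isnan(p)][0]
        raise DomainError(f"p-values must lie in [0, 1], got {bad!r}")
    return list(multipletests(p, method="fdr_bh")[1])


@dataclass(frozen=True)
class EnrichmentQuery:
    """One enrichment request: the query target set, the namespace to
    test and the background universe (its size is the hypergeometric
    l)."""

    g_comp: frozenset
    namespace: AnnotationNamespace
    background: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "g_comp", frozenset(self.g_comp))
        object.__setattr__(self, "background", frozenset(self.background))
        if not self.g_comp <= self.background:
            extra = sorted(self.g_comp - self.background)[:5]
            raise DomainError(
                f"query targets outside the background universe, e.g. {extra}"
            )


@dataclass(frozen=True)
class EnrichmentRow:
    """Result for one term: intersection z, term size k, query size r,
    enrichment ratio z/k, raw p and BH q."""

    term_id: str
    term_name: str
    z: int
    k: int
    r: int
    ratio: float
    p_value: float
    q_value: float


def enrich(query: EnrichmentQuery) -> list:
    """Test every term of the namespace against the query target set.

    Term protein sets are intersected with the background universe
    first; terms left empty by the restriction are excluded (and
    logged).  Rows are sorted by (p asc, term_id asc).  An empty query
    set yields an empty result with a warning.
    """
    if not query.g_comp:
        warnings.warn("enrich called with an empty query target set", stacklevel=2)
        return []
    l = len(query.background)
    r = len(query.g_comp)

    rows = []
    for term_id in sorted(query.namespace.terms):
        term_name, proteins = query.namespace.terms[term_id]
        g_path = frozenset(proteins) & query.background
        if not g_path:
            logger.info("term %s lies fully outside the background; excluded", term_id)
            continue
        k = len(g_path)
        z = len(g_path & query.g_comp)
        rows.append(
            (term_id, term_name, z, k, hypergeom_tail(l, k, r, z))
        )
    if not rows:
        return []
    q_values = bh_fdr([p for *_, p in rows])
    out = [
        EnrichmentRow(
            term_id=term_id,
            term_name=term_name,
            z=z,
            k=k,
            r=r,
            ratio=z / k,
            p_value=p,
            q_value=q,
        )
        for (term_id, term_name, z, k, p), q in zip(rows, q_values)
    ]
    out.sort(key=lambda row: (row.p_value, row.term_id))
    return out
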