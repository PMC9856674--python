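"""Cross-study gene signature construction and hypergeometric overlap machinery.

The microgravity-responsive signature is built in two steps, in this order:
genes called DE (any direction) in both studies form the *common* set and
are tested for overlap significance against a finite universe; common genes
whose directions disagree between the studies are then discarded, and what
remains is the signature.  The universe for the overlap test is an explicit
required parameter — there is no defensible implicit default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEGTable, bh_adjust

__all__ = [
    "HypergeomResult",
    "SignatureResult",
    "hypergeom_upper_tail",
    "build_signature",
    "gene_set_enrichment",
]


@dataclass
class HypergeomResult:
    """Upper-tail overlap test: P[X >= k] for X ~ Hypergeom(N, K, n)."""

    universe_size: int
    set_a_size: int
    draw_size: int
    overlap: int
    p_value: float


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P[X >= k] for X hypergeometric with universe N, K successes, n draws.

    Computed through scipy's log-gamma based survival function; exact to
    floating precision for small instances.  k = 0 returns exactly 1.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    N, K, n, k = int(N), int(K), int(n), int(k)
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K, n)={min(K, n)}")
    if k == 0:
        return 1.0
    p = stats.hypergeom.sf(k - 1, N, K, n)
    return float(min(max(p, 0.0), 1.0))


@dataclass
class SignatureResult:
    common_ids: frozenset[str]
    conflicting_ids: frozenset[str]
    signature_ids: frozenset[str]
    directions_a: dict[str, str]
    directions_b: dict[str, str]
    overlap_test: HypergeomResult

    def to_jsonable(self) -> dict:
        return {
            "n_common": len(self.common_ids),
            "n_conflicting": len(self.conflicting_ids),
            "n_signature": len(self.signature_ids),
            "common_ids": sorted(self.common_ids),
            "conflicting_ids": sorted(self.conflicting_ids),
            "signature_ids": sorted(self.signature_ids),
            "overlap_test": self.overlap_test.__dict__,
        }


def build_signature(
    study_a: DEGTable, study_b: DEGTable, universe_size: int
) -> SignatureResult:
    """Common DEGs of two studies, minus sign conflicts, with an overlap test.

    ``common`` = genes called DE (any direction) in both studies;
    ``conflicting`` = common genes with opposite directions; ``signature`` =
    common minus conflicting.  The hypergeometric test runs on the
    any-direction DEG sets against ``universe_size`` — sign agreement only
    affects signature membership, not the overlap significance.
    """
    tested = study_a.gene_ids | study_b.gene_ids
    if universe_size < len(tested):
        raise ValueError(
            f"universe_size={universe_size} is smaller than the union of tested "
            f"genes ({len(tested)})"
        )
    dir_a = study_a.directions()
    dir_b = study_b.directions()
    common = set(dir_a) & set(dir_b)
    conflicting = {g for g in common if dir_a[g] != dir_b[g]}
    signature = common - conflicting
    test = HypergeomResult(
        universe_size=universe_size,
        set_a_size=len(dir_a),
        draw_size=len(dir_b),
        overlap=len(common),
        p_value=hypergeom_upper_tail(
            universe_size, len(dir_a), len(dir_b), len(common)
        ),
    )
    return SignatureResult(
        common_ids=frozenset(common),
        conflicting_ids=frozenset(conflicting),
        signature_ids=frozenset(signature),
        directions_a={g: dir_a[g] for g in common},
        directions_b={g: dir_b[g] for g in common},
        overlap_test=test,
    )


def gene_set_enrichment(
    query: Iterable[str],
    collections: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a query gene set against GMT-style collections.

    Each collection is intersected with the universe before testing; one
    upper-tail test per set, BH correction across sets, significance at
    adjusted p < alpha.  Returns a DataFrame with columns set_label, set_size,
    overlap, p_value, p_adj, significant.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    if not q <= uni:
        raise ValueError(f"query ids outside the universe: {sorted(q - uni)[:10]}")
    rows = []
    for label, ids in collections.items():
        s = set(ids) & uni
        k = len(q & s)
        p = hypergeom_upper_tail(len(uni), len(s), len(q), k)
        rows.append({"set_label": label, "set_size": len(s), "overlap": k, "p_value": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = bh_adjust(table["p_value"].to_numpy())
        table["significant"] = table["p_adj"] < alpha
    else:
        table["p_adj"] = np.array([], dtype=float)
        table["significant"] = np.array([], dtype=bool)
    return table
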