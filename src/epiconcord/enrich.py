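"""Gene-set over-representation and 2x2 exact tests.

Over-representation of a query gene list in GMT-format gene sets is
scored with the hypergeometric upper tail P(X >= k) against a
user-supplied universe (by default the assay's annotated genes, the
standard background for array studies), with Benjamini-Hochberg
correction across tested terms. An EASE-style conservative variant
(k - 1 in the tail) is available behind a flag. A generic two-sided
Fisher exact test covers 2x2 frequency comparisons such as
literature-mining gene-frequency contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from epiconcord.transcriptome import bh_fdr


@dataclass
class GeneSetCollection:
    """Named gene sets: term_id -> (term_name, members)."""

    sets: dict

    def __post_init__(self) -> None:
        for term, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {term!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: term, description, then tab-separated members.

    Duplicate members within a line are stored once. Lines with fewer
    than three fields raise a parse error naming the line number.
    """
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            term, description = fields[0], fields[1]
            members = []
            seen = set()
            for g in fields[2:]:
                if g and g not in seen:
                    members.append(g)
                    seen.add(g)
            sets[term] = (description, frozenset(members))
    return GeneSetCollection(sets)


def hypergeom_test(k: int, K: int, n: int, N: int, ease: bool = False) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    ``k`` query genes hit a set of size ``K`` in a universe of size ``N``
    from a query of size ``n``. With ``ease=True`` the tail is evaluated
    at k - 1 (the conservative EASE-score variant).
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    k_eff = max(k - 1, 0) if ease else k
    return float(stats.hypergeom.sf(k_eff - 1, N, K, n))


def enrich_collection(
    query,
    collection: GeneSetCollection,
    universe,
    alpha: float = 0.05,
    ease: bool = False,
) -> pd.DataFrame:
    """Over-representation of ``query`` in every set of the collection.

    Sets are intersected with the universe before testing; only terms
    with at least one query hit are reported. Results carry BH q-values
    across the tested terms and a significance flag at ``q <= alpha``,
    sorted by ascending p (stable for ties).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    query = set(query)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for term, (name, members) in collection:
        members_in = members & universe
        k = len(query & members_in)
        if k == 0:
            continue
        K = len(members_in)
        p = hypergeom_test(k, K, n, N, ease=ease)
        rows.append(
            {
                "term_id": term,
                "term_name": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": p,
                "fold_enrichment": (k / n) / (K / N),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "k", "K", "n", "N", "p_value",
            "fold_enrichment",
        ],
    )
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
        out["significant"] = out["q_value"] <= alpha
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        out["q_value"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be non-negative integers")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("a margin of the table is entirely zero")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
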