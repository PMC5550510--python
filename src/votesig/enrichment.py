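"""Gene-set (term) enrichment of a gene list against a GMT collection.

Two statistics are offered: the exact hypergeometric upper tail
P(X >= k), and the EASE score used by DAVID-style annotation tools --
the same tail after removing one gene from the overlap, a conservative
penalization that damps single-gene hits in small terms.  Multiple
testing is Benjamini-Hochberg by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentRow",
    "hypergeom_tail",
    "ease_p",
    "bh_adjust",
    "enrich_list",
]


@dataclass
class GeneSetCollection:
    """term_id -> (term name, member gene ids)."""

    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {term_id!r} is empty")

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        terms: dict[str, tuple[str, frozenset[str]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}: line {lineno}: GMT needs term, name and >= 1 gene")
                term_id, name, *genes = parts
                if term_id in terms:
                    raise ValueError(f"{path}: line {lineno}: duplicate term id {term_id!r}")
                terms[term_id] = (name, frozenset(g for g in genes if g))
        return cls(terms=terms)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for term_id, (name, genes) in self.terms.items():
                fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    name: str
    k: int  # overlap
    K: int  # term size in universe
    n: int  # list size in universe
    N: int  # universe size
    p_raw: float
    p_adj: float


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k), X ~ Hypergeometric(N total, K marked,
    n drawn), via log-factorial summation.

    Accurate to >= 10 significant digits for N up to ~1e4; the dominant
    term is computed in log space and the remaining terms accumulated by
    a stable downward recurrence.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent hypergeometric counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    log_denom = _log_comb(N, n)
    total = 0.0
    for i in range(k, min(K, n) + 1):
        if n - i > N - K:
            continue
        total += math.exp(_log_comb(K, i) + _log_comb(N - K, n - i) - log_denom)
    return min(total, 1.0)


def ease_p(k: int, K: int, n: int, N: int) -> float:
    """EASE score: hypergeometric upper tail with one overlap gene
    removed; k of 0 or 1 yields 1.0."""
    if not (0 <= k <= min(K, n) <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k <= 1:
        return 1.0
    return hypergeom_tail(k - 1, K, n, N)


def bh_adjust(pvals: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order kept."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if ((p <= 0) | (p > 1)).any():
        bad = p[(p <= 0) | (p > 1)][0]
        raise ValueError(f"p-values must lie in (0, 1], got {bad}")
    return list(multipletests(p, method="fdr_bh")[1])


def enrich_list(
    gene_list: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    config=None,
    *,
    mode: str | None = None,
    p_adjust: str | None = None,
) -> list[EnrichmentRow]:
    """Term enrichment of ``gene_list`` against ``collection`` within
    ``universe``.

    Genes and term members are intersected with the universe before
    counting.  Terms with zero overlap are dropped.  Rows are sorted by
    raw p ascending then term id; the result does not depend on the
    input ordering of the list or the terms.

    ``mode`` ('ease' or 'hypergeometric') and ``p_adjust`` ('bh' or
    'none') default to the values in ``config`` when one is given.
    """
    if config is not None:
        mode = mode or config.enrichment_mode
        p_adjust = p_adjust or config.p_adjust
    mode = mode or "ease"
    p_adjust = p_adjust or "bh"
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    lst = frozenset(gene_list) & uni
    if not lst:
        raise ValueError("gene list is empty after intersection with the universe")
    N = len(uni)
    n = len(lst)
    stat = ease_p if mode == "ease" else hypergeom_tail
    raw: list[tuple[str, str, int, int, float]] = []
    for term_id, (name, genes) in collection.terms.items():
        members = genes & uni
        K = len(members)
        k = len(members & lst)
        if k == 0:
            continue
        raw.append((term_id, name, k, K, stat(k, K, n, N)))
    raw.sort(key=lambda r: (r[4], r[0]))
    pvals = [r[4] for r in raw]
    adj = bh_adjust(pvals) if (p_adjust == "bh" and pvals) else pvals
    return [
        EnrichmentRow(term_id=t, name=nm, k=k, K=K, n=n, N=N, p_raw=p, p_adj=pa)
        for (t, nm, k, K, p), pa in zip(raw, adj)
    ]


def enrichment_to_tsv(rows: list[EnrichmentRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tname\tk\tK\tn\tN\tp_raw\tp_adj\n")
        for r in rows:
            fh.write(f"{r.term_id}\t{r.name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p_raw:.6g}\t{r.p_adj:.6g}\n")
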