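"""Hypergeometric over-representation of gene-list / cluster overlaps.

Quantifies whether a gene list is enriched in a cluster (or any user-supplied
gene set) beyond chance, drawing-without-replacement from a finite universe.
The universe is the set of profiled transcripts of the relevant stage, not the
whole genome: the comparison is among clustered entities.

p = P(X >= k) for X ~ Hypergeom(N, K, n), computed in log space; families of
tests are adjusted with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import false_discovery_control, hypergeom

__all__ = [
    "OverlapTest",
    "hypergeom_overlap",
    "bh_adjust",
    "read_gmt",
    "enrich_sets",
]


@dataclass(frozen=True)
class OverlapTest:
    """One overlap test: universe N, gene-list K, set n, overlap k."""

    N: int
    K: int
    n: int
    k: int
    p_value: float
    q_value: float | None = None


def hypergeom_overlap(N: int, K: int, n: int, k: int) -> OverlapTest:
    """Exact upper-tail hypergeometric probability P(X >= k).

    N: universe size; K: gene-list size; n: cluster/set size; k: overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require K, n <= N; got N={N}, K={K}, n={n}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K, n)={min(K, n)}]")
    if k == 0:
        return OverlapTest(N, K, n, k, 1.0)
    support = np.arange(k, min(K, n) + 1)
    logp = hypergeom.logpmf(support, N, K, n)
    p = float(np.exp(logsumexp(logp)))
    return OverlapTest(N, K, n, k, min(p, 1.0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving and monotone."""
    p = np.asarray(list(p_values), float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return false_discovery_control(p, method="bh")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection: name <TAB> description <TAB> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT needs name, description and >= 1 gene"
                )
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def enrich_sets(
    geneset: Iterable[str],
    collections: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Test a gene list against each set of a collection within a universe.

    Genes outside the universe are dropped before testing. Returns a
    DataFrame (set, N, K, n, k, p, q) sorted by p.
    """
    universe = set(universe)
    genes = set(geneset) & universe
    if not genes:
        raise ValueError("gene list is empty after restriction to the universe")
    rows = []
    for name, members in collections.items():
        members = set(members) & universe
        t = hypergeom_overlap(len(universe), len(genes), len(members),
                              len(genes & members))
        rows.append((name, t.N, t.K, t.n, t.k, t.p_value))
    df = pd.DataFrame(rows, columns=["set", "N", "K", "n", "k", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
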