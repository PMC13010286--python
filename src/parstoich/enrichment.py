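"""Occupancy-binned term enrichment and single-linkage clustering.

Proteins are split into occupancy groups (default <0.1%, 0.1–0.5%, 0.5–1%,
>1%); each group is tested for over-represented annotation terms against a
custom background — the full curated list of modified proteins, not the
whole proteome — with a one-sided hypergeometric test. P-values below 0.05
(strict) mark a term "enriched"; x = −log10(p) values form a term × bin
matrix (0 where not enriched) that is clustered with single-linkage
agglomeration on Euclidean row distances.

No multiple-testing correction is applied by default, mirroring the raw
p < 0.05 convention of list-enrichment tools; Benjamini–Hochberg is
available behind a flag. The clustering is written by hand rather than
delegated so the tie-break (lexicographically smallest member accession
first) and the leaf order (smaller-id subtree first) are deterministic and
independent of input row order; library implementations agree on the merge
heights but not on these conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import false_discovery_control, hypergeom

__all__ = [
    "StoichBins",
    "EnrichmentRecord",
    "ClusterResult",
    "assign_bins",
    "hypergeom_upper_tail",
    "enrich",
    "build_matrix",
    "cluster_single_euclidean",
    "enrichment_to_frame",
]

ENRICHED_ALPHA = 0.05


@dataclass(frozen=True)
class StoichBins:
    """Percent thresholds partitioning the occupancy axis.

    Boundary convention: a value equal to an inner edge opens the interval
    above it (0.1 → "0.1-0.5%"), except that the top group is *strictly*
    above the last edge, so a value exactly at the last edge (1.0) falls in
    the group below (">1%" means > 1, as the label says).
    """

    edges: tuple[float, ...] = (0.1, 0.5, 1.0)

    def __post_init__(self) -> None:
        if not self.edges:
            raise ValueError("at least one bin edge required")
        if any(e <= 0 for e in self.edges) or any(
            b <= a for a, b in zip(self.edges, self.edges[1:])
        ):
            raise ValueError("edges must be positive and strictly increasing")

    @property
    def labels(self) -> list[str]:
        e = [f"{x:g}" for x in self.edges]
        labels = [f"<{e[0]}%"]
        labels += [f"{a}-{b}%" for a, b in zip(e, e[1:])]
        labels.append(f">{e[-1]}%")
        return labels

    def assign(self, value_percent: float) -> str:
        if value_percent < 0 or math.isnan(value_percent):
            raise ValueError(f"occupancy must be >= 0, got {value_percent}")
        if value_percent > self.edges[-1]:
            return self.labels[-1]
        idx = int(np.searchsorted(self.edges, value_percent, side="right"))
        return self.labels[min(idx, len(self.edges) - 1)]


@dataclass(frozen=True)
class EnrichmentRecord:
    """One term × occupancy-bin contingency test.

    k of the n foreground proteins carry the term; K of the N background
    proteins do. ``p_value`` is the one-sided upper tail P(X >= k) and
    ``x`` its −log10."""

    term_id: str
    bin_label: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    x: float
    enriched: bool


@dataclass
class ClusterResult:
    """Deterministic single-linkage dendrogram over matrix rows.

    ``merges`` lists (representative of cluster a, representative of
    cluster b, height) in merge order, representatives being each cluster's
    lexicographically smallest member id with a < b; ``leaf_order`` is the
    depth-first leaf sequence visiting the smaller-representative subtree
    first; ``newick`` is the tree with branch lengths derived from merge
    heights."""

    leaf_order: list[str]
    merges: list[tuple[str, str, float]]
    newick: str = ""


def assign_bins(
    estimates_percent: dict[str, float], bins: StoichBins | None = None
) -> dict[str, str]:
    """Map each protein to its occupancy group (input in percent)."""
    bins = bins or StoichBins()
    return {pid: bins.assign(v) for pid, v in estimates_percent.items()}


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K successes, n draws)."""
    if not (0 <= k <= min(n, K) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent contingency counts k={k} n={n} K={K} N={N}")
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def enrich(
    foreground: set[str],
    background: set[str],
    annotations: dict[str, set[str]],
    bin_label: str = "",
    fdr: bool = False,
) -> list[EnrichmentRecord]:
    """Term over-representation of ``foreground`` within ``background``.

    Unannotated proteins still count in the totals N and n. Terms are those
    annotated on at least one background protein. With ``fdr=True`` the
    enriched call uses Benjamini–Hochberg-adjusted p-values instead of raw
    ones (the x values always come from the raw p).
    """
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    N, n = len(background), len(foreground)
    term_bg: dict[str, int] = {}
    term_fg: dict[str, int] = {}
    for pid in background:
        for term in annotations.get(pid, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
            if pid in foreground:
                term_fg[term] = term_fg.get(term, 0) + 1
    terms = sorted(term_bg)
    pvals = np.array(
        [hypergeom_upper_tail(term_fg.get(t, 0), n, term_bg[t], N) for t in terms]
    )
    flag_p = pvals
    if fdr and len(pvals):
        flag_p = false_discovery_control(pvals, method="bh")
    return [
        EnrichmentRecord(
            term_id=t,
            bin_label=bin_label,
            k=term_fg.get(t, 0),
            n=n,
            K=term_bg[t],
            N=N,
            p_value=float(p),
            x=float(-math.log10(p)) if p > 0 else math.inf,
            enriched=bool(fp < ENRICHED_ALPHA),
        )
        for t, p, fp in zip(terms, pvals, flag_p)
    ]


def build_matrix(
    records: list[EnrichmentRecord], bins: StoichBins | None = None
) -> pd.DataFrame:
    """Term × bin matrix of x = −log10(p).

    Rows are terms enriched (p < 0.05) in at least one bin; a cell holds x
    only where that term is enriched in that bin and 0 elsewhere, keeping
    the matrix complete for Euclidean distances. Columns follow bin order.
    """
    bins = bins or StoichBins()
    labels = bins.labels
    enriched_terms = sorted({r.term_id for r in records if r.enriched})
    matrix = pd.DataFrame(0.0, index=enriched_terms, columns=labels)
    for r in records:
        if r.enriched and r.term_id in matrix.index:
            if r.bin_label not in labels:
                raise ValueError(f"record bin {r.bin_label!r} not among bin labels")
            matrix.loc[r.term_id, r.bin_label] = r.x
    matrix.index.name = "term_id"
    return matrix


def cluster_single_euclidean(matrix: pd.DataFrame) -> ClusterResult:
    """Agglomerative single-linkage clustering of matrix rows.

    Euclidean row distances; at every step the pair of clusters at minimum
    single-linkage distance merges, ties broken by the lexicographically
    smallest (representative a, representative b) pair. Output is invariant
    to row permutation of the input.
    """
    if len(matrix) < 2:
        raise ValueError("clustering needs at least 2 rows")
    order = np.argsort(matrix.index.to_numpy())
    matrix = matrix.iloc[order]
    ids = list(matrix.index.astype(str))
    dist = squareform(pdist(matrix.to_numpy(dtype=float), metric="euclidean"))

    # active clusters: representative id -> (member row indices, tree node)
    clusters: dict[str, tuple[list[int], object]] = {ids[i]: ([i], ids[i]) for i in range(len(ids))}
    merges: list[tuple[str, str, float]] = []
    heights: dict[int, float] = {}
    while len(clusters) > 1:
        reps = sorted(clusters)
        best = None
        for i, a in enumerate(reps):
            for b in reps[i + 1 :]:
                d = min(
                    dist[x, y] for x in clusters[a][0] for y in clusters[b][0]
                )
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        members = clusters[a][0] + clusters[b][0]
        node = (clusters[a][1], clusters[b][1])
        heights[id(node)] = d
        del clusters[a], clusters[b]
        clusters[min(a, b)] = (members, node)
        merges.append((a, b, float(d)))

    root = next(iter(clusters.values()))[1]
    leaves: list[str] = []

    def _walk(node) -> None:
        if isinstance(node, str):
            leaves.append(node)
        else:
            _walk(node[0])
            _walk(node[1])

    def _newick(node, parent_height: float) -> str:
        if isinstance(node, str):
            return f"{node}:{parent_height:g}"
        h = heights[id(node)]
        inner = ",".join(_newick(child, h) for child in node)
        return f"({inner}):{max(parent_height - h, 0.0):g}"

    _walk(root)
    root_h = heights[id(root)] if not isinstance(root, str) else 0.0
    newick = "(" + ",".join(_newick(c, root_h) for c in root) + ");" if not isinstance(root, str) else f"{root};"
    return ClusterResult(leaf_order=leaves, merges=merges, newick=newick)


def enrichment_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "bin": r.bin_label,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p": r.p_value,
                "x": r.x,
                "enriched": r.enriched,
            }
            for r in records
        ]
    )
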