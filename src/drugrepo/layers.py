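"""The three drug-drug dissimilarity layers.

Chemical layer
    One minus the mean of Jaccard, cosine and Dice similarities between
    binary substructure fingerprints.

Target layer
    Mean of (a) the same set-overlap dissimilarity applied to target sets
    and (b) the range-normalized length of the shortest protein-protein
    interaction path between any target of one drug and any target of the
    other.

Expression layer
    Weighted Spearman's Footrule between signed-p-value gene rankings, with
    per-gene weights ``1 - p``, range-normalized over the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from .matrix import DissimilarityMatrix, range_normalize

log = logging.getLogger(__name__)


class LayerError(ValueError):
    """Raised when a layer is undefined on its input (e.g. empty sets)."""


# ---------------------------------------------------------------------------
# set-overlap similarities (chemical layer and first target component)


def _as_set(x) -> frozenset:
    """Coerce a bit-vector or iterable to a set of member identities."""
    arr = np.asarray(x)
    if arr.dtype != object and arr.ndim == 1 and arr.dtype.kind in "biu":
        members = set(np.flatnonzero(arr).tolist())
        if members or arr.size:
            return frozenset(members)
    return frozenset(x)


def binary_set_similarities(a, b) -> tuple[float, float, float]:
    """Jaccard, cosine and Dice similarity of two sets or bit-vectors.

    Bit-vectors must share a length; sets are used as-is.  Both inputs empty
    is an error (all three measures are undefined); one empty set yields
    ``(0, 0, 0)``.
    """
    a_arr, b_arr = np.asarray(a), np.asarray(b)
    if a_arr.ndim == 1 and b_arr.ndim == 1 and a_arr.dtype.kind in "biu" and b_arr.dtype.kind in "biu":
        if a_arr.shape != b_arr.shape:
            raise LayerError(
                f"fingerprint length mismatch: {a_arr.size} vs {b_arr.size}"
            )
        sa, sb = _as_set(a_arr), _as_set(b_arr)
    else:
        sa, sb = frozenset(a), frozenset(b)
    na, nb = len(sa), len(sb)
    if na == 0 and nb == 0:
        raise LayerError("similarities undefined: both sets empty")
    if na == 0 or nb == 0:
        return 0.0, 0.0, 0.0
    inter = len(sa & sb)
    ji = inter / len(sa | sb)
    cs = inter / np.sqrt(na * nb)
    dc = 2.0 * inter / (na + nb)
    return float(ji), float(cs), float(dc)


def chem_dissimilarity(a, b) -> float:
    """``1 - (JI + CS + DC) / 3`` on fingerprints: 0 iff identical, 1 iff
    disjoint."""
    ji, cs, dc = binary_set_similarities(a, b)
    return 1.0 - (ji + cs + dc) / 3.0


def target_overlap_dissimilarity(ti: Iterable[str], tj: Iterable[str]) -> float:
    """The chemical formula applied to target-protein sets."""
    ti, tj = frozenset(ti), frozenset(tj)
    if not ti or not tj:
        raise LayerError("target sets must be nonempty")
    return chem_dissimilarity(ti, tj)


def chem_dissimilarity_matrix(
    fingerprints: Mapping[str, np.ndarray], drugs: Sequence[str]
) -> DissimilarityMatrix:
    """Pairwise chemical dissimilarities, vectorized over the cohort."""
    for d in drugs:
        fp = fingerprints.get(d)
        if fp is None or not np.any(fp):
            raise LayerError(f"drug {d} has an empty or missing fingerprint")
    B = np.stack([np.asarray(fingerprints[d], dtype=float) for d in drugs])
    sizes = B.sum(axis=1)
    inter = B @ B.T
    union = sizes[:, None] + sizes[None, :] - inter
    ji = inter / union
    cs = inter / np.sqrt(np.outer(sizes, sizes))
    dc = 2.0 * inter / (sizes[:, None] + sizes[None, :])
    values = 1.0 - (ji + cs + dc) / 3.0
    np.fill_diagonal(values, 0.0)
    return DissimilarityMatrix(tuple(drugs), np.clip(values, 0.0, 1.0))


# ---------------------------------------------------------------------------
# target layer


def ppi_target_distance(
    ti: Iterable[str], tj: Iterable[str], net: nx.Graph
) -> float | None:
    """Shortest interaction-path length between two drugs' target sets.

    Returns the minimum over all target pairs of the shortest-path edge
    count; 0 when the sets share a target.  Targets absent from the network
    are ignored for the path search; ``None`` signals that no finite path
    exists (handled by the caller with a cohort-level penalty).
    """
    ti, tj = frozenset(ti), frozenset(tj)
    if not ti or not tj:
        raise LayerError("target sets must be nonempty")
    if ti & tj:
        return 0.0
    sources = [t for t in ti if t in net]
    sinks = {t for t in tj if t in net}
    if not sources or not sinks:
        return None
    dist = nx.multi_source_dijkstra_path_length(net, sources, weight=None)
    best = min((dist[t] for t in sinks if t in dist), default=None)
    return float(best) if best is not None else None


def _raw_ppi_matrix(
    targets: Mapping[str, frozenset[str]], net: nx.Graph, drugs: Sequence[str]
) -> np.ndarray:
    """Raw pairwise minimum path lengths; unreachable pairs become the
    longest finite distance observed plus one."""
    n = len(drugs)
    raw = np.zeros((n, n))
    unreachable: list[tuple[int, int]] = []
    # one multi-source BFS per drug covers all pairs
    dist_maps = []
    for d in drugs:
        sources = [t for t in targets[d] if t in net]
        dist_maps.append(
            nx.multi_source_dijkstra_path_length(net, sources, weight=None)
            if sources
            else {}
        )
    for i in range(n):
        for j in range(i + 1, n):
            if targets[drugs[i]] & targets[drugs[j]]:
                raw[i, j] = raw[j, i] = 0.0
                continue
            dmap = dist_maps[i]
            best = min(
                (dmap[t] for t in targets[drugs[j]] if t in dmap), default=None
            )
            if best is None:
                unreachable.append((i, j))
            else:
                raw[i, j] = raw[j, i] = float(best)
    if unreachable:
        penalty = raw.max() + 1.0
        log.info(
            "target layer: %d unreachable pair(s) assigned penalty %.0f",
            len(unreachable), penalty,
        )
        for i, j in unreachable:
            raw[i, j] = raw[j, i] = penalty
    return raw


def target_dissimilarity_matrix(
    targets: Mapping[str, frozenset[str]], net: nx.Graph, drugs: Sequence[str]
) -> DissimilarityMatrix:
    """Mean of the overlap dissimilarity and the range-normalized shortest
    interaction-path distance."""
    if len(drugs) < 2:
        raise LayerError("target layer needs at least two drugs")
    for d in drugs:
        if not targets.get(d):
            raise LayerError(f"drug {d} has an empty target set")
    n = len(drugs)
    overlap = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = target_overlap_dissimilarity(targets[drugs[i]], targets[drugs[j]])
            overlap[i, j] = overlap[j, i] = v
    path = range_normalize(_raw_ppi_matrix(targets, net, drugs))
    return DissimilarityMatrix(tuple(drugs), (overlap + path) / 2.0)


# ---------------------------------------------------------------------------
# expression layer


@dataclass(frozen=True)
class RankedProfile:
    """A drug's genes ranked by signed significance, with weights ``1 - p``.

    Over-expressed genes with low p-values rank first, under-expressed genes
    with low p-values rank last, and non-significant genes sit in the
    middle.  Ties receive average ranks.
    """

    genes: tuple[str, ...]
    ranks: np.ndarray
    weights: np.ndarray


def signed_rank_profile(
    expr_stats: Mapping[str, tuple[float, int]], rank_key: str = "gloss"
) -> RankedProfile:
    """Rank a drug's genes by signed p-value.

    The ``gloss`` key sorts by ``-fc_sign * (1 - p)``, which places
    significant over-expressed genes at the top, significant under-expressed
    genes at the bottom, and non-significant genes in the middle.  The
    ``literal`` key ``-fc_sign * p`` is retained for comparison but inverts
    the within-sign ordering.
    """
    if rank_key not in ("gloss", "literal"):
        raise ValueError(f"unknown rank_key: {rank_key!r}")
    genes = tuple(sorted(expr_stats))
    p = np.array([expr_stats[g][0] for g in genes])
    sign = np.array([expr_stats[g][1] for g in genes], dtype=float)
    key = -sign * (1.0 - p) if rank_key == "gloss" else -sign * p
    ranks = rankdata(key, method="average")
    return RankedProfile(genes=genes, ranks=ranks, weights=1.0 - p)


def wsf_raw(a: RankedProfile, b: RankedProfile) -> float:
    """Unnormalized weighted Spearman's Footrule between two profiles:
    ``sum_g |R_a(g) - R_b(g)| * (W_a(g) + W_b(g)) / 2``."""
    if a.genes != b.genes:
        raise LayerError("profiles cover different gene universes")
    return float(np.sum(np.abs(a.ranks - b.ranks) * (a.weights + b.weights) / 2.0))


def wsf_dissimilarity_matrix(
    profiles: Mapping[str, RankedProfile], drugs: Sequence[str]
) -> DissimilarityMatrix:
    """Pairwise weighted-footrule distances, range-normalized to [0, 1]."""
    if len(drugs) < 2:
        raise LayerError("expression layer needs at least two drugs")
    universe = profiles[drugs[0]].genes
    for d in drugs:
        if profiles[d].genes != universe:
            raise LayerError(f"drug {d} covers a different gene universe")
    R = np.stack([profiles[d].ranks for d in drugs])
    W = np.stack([profiles[d].weights for d in drugs])
    n = len(drugs)
    raw = np.zeros((n, n))
    for i in range(n - 1):
        diffs = np.abs(R[i] - R[i + 1:])
        wts = (W[i] + W[i + 1:]) / 2.0
        raw[i, i + 1:] = raw[i + 1:, i] = (diffs * wts).sum(axis=1)
    return DissimilarityMatrix(tuple(drugs), range_normalize(raw))
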