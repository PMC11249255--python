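"""Triangle end-window link counting and the degree-bounded scaffold graph.

Hi-C linking evidence between two scaffolds is counted in the four
end-combination windows BB, BE, EB, EE ("B" = begin, "E" = end of a
scaffold).  A read pair at end-distances ``(d_i, d_j)`` falls in the
*triangle* window iff ``d_i + d_j < l``: the near-junction half of the
``l x l`` square, which excludes the far corner where long-range
contacts (TADs, compartments) accumulate.  The raw link count is

    N_ij = max(N_BB, N_BE, N_EB, N_EE)

and per scaffold the counts of its top-5 partners are normalized to
link scores ``W_k = N_k / sum_{j<=5} N_j``.  Edges below a weight
cutoff are discarded, and each scaffold end retains at most one edge
(mutually, at both endpoints), so graph components are simple paths or
cycles ready for path extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from triscaf.io_formats import ContactPair

#: deterministic preference order for the orientation arg-max and ties
LABELS = ("EB", "BE", "EE", "BB")
_LABEL_RANK = {lab: r for r, lab in enumerate(LABELS)}

_FLIP = {"BB": "BB", "EE": "EE", "BE": "EB", "EB": "BE"}


def flip_label(label: str) -> str:
    """The same junction seen from the other scaffold (BE <-> EB)."""
    return _FLIP[label]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Component:
    """One original contig embedded in a scaffold."""

    contig_id: str
    offset: int        # bp offset of the component start within the scaffold
    length: int
    orientation: str   # '+' or '-'


@dataclass
class ScaffoldNode:
    """A contig or super-scaffold: a length plus an ordered, oriented
    component list mapping every position back to an original contig."""

    id: str
    length: int
    components: list[Component]

    @classmethod
    def from_contig(cls, contig_id: str, length: int) -> "ScaffoldNode":
        return cls(contig_id, length, [Component(contig_id, 0, length, "+")])

    def __post_init__(self) -> None:
        prev_end = 0
        for c in self.components:
            if c.offset < prev_end:
                raise ValueError(f"overlapping components in scaffold {self.id!r}")
            prev_end = c.offset + c.length
        if prev_end > self.length:
            raise ValueError(f"components exceed length of scaffold {self.id!r}")

    def contig_map(self) -> dict[str, Component]:
        return {c.contig_id: c for c in self.components}

    def locate(self, contig_id: str, pos: int) -> int:
        """Map a 0-based position on an original contig to scaffold coordinates."""
        comp = self.contig_map()[contig_id]
        if not 0 <= pos < comp.length:
            raise ValueError(f"position {pos} outside contig {contig_id!r}")
        if comp.orientation == "+":
            return comp.offset + pos
        return comp.offset + comp.length - 1 - pos


@dataclass(frozen=True)
class EndPairCounts:
    """Read-pair counts in the four end-combination windows of (i, j)."""

    n_bb: int = 0
    n_be: int = 0
    n_eb: int = 0
    n_ee: int = 0

    def as_dict(self) -> dict[str, int]:
        return {"BB": self.n_bb, "BE": self.n_be, "EB": self.n_eb, "EE": self.n_ee}

    def transpose(self) -> "EndPairCounts":
        """Counts for (j, i): BE and EB swap, BB and EE are symmetric."""
        return EndPairCounts(self.n_bb, self.n_eb, self.n_be, self.n_ee)


@dataclass(frozen=True)
class LinkEdge:
    """A candidate junction between scaffolds i and j (label in i->j frame)."""

    i: str
    j: str
    label: str
    n: int
    w_i: float = 0.0
    w_j: float = 0.0

    @property
    def weight(self) -> float:
        return max(self.w_i, self.w_j)

    def end_of(self, node: str) -> str:
        if node == self.i:
            return self.label[0]
        if node == self.j:
            return self.label[1]
        raise KeyError(node)

    def other(self, node: str) -> str:
        return self.j if node == self.i else self.i

    def w_of(self, node: str) -> float:
        return self.w_i if node == self.i else self.w_j


@dataclass
class ScaffoldGraph:
    """Scaffold nodes plus the retained link edges (degree <= 1 per node end)."""

    nodes: list[str]
    edges: list[LinkEdge] = field(default_factory=list)

    def edges_of(self, node: str) -> list[LinkEdge]:
        return [e for e in self.edges if node in (e.i, e.j)]


@dataclass
class WindowParams:
    """Tunable knobs of one linking iteration.

    l            window length in bp (grows between iterations)
    growth       multiplicative window growth per iteration; 1.4 doubles
                 the window every two iterations (1.4**2 = 1.96)
    w_min        link-score cutoff below which an edge is unreliable
    top_k        number of strongest partners entering the normalization
    window       'triangle' (d_i + d_j < l) or 'square' (d_i < l and d_j < l);
                 square is an ablation for benchmarking, not the default
    """

    l: int = 50_000
    growth: float = 1.4
    w_min: float = 0.2
    top_k: int = 5
    edges_per_node: int = 2
    window: str = "triangle"

    def __post_init__(self) -> None:
        if self.l <= 0:
            raise ValueError("window length l must be positive")
        if self.growth <= 1:
            raise ValueError("growth must exceed 1")
        if not 0 <= self.w_min <= 1:
            raise ValueError("w_min must lie in [0, 1]")
        if self.window not in ("triangle", "square"):
            raise ValueError("window must be 'triangle' or 'square'")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def end_distance(pos: int, scaffold: ScaffoldNode | int, end: str) -> int:
    """Distance (bp) from a scaffold position to the B (begin) or E (end) terminus."""
    length = scaffold if isinstance(scaffold, int) else scaffold.length
    if not 0 <= pos < length:
        raise ValueError(f"position {pos} outside scaffold of length {length}")
    if end == "B":
        return pos
    if end == "E":
        return length - 1 - pos
    raise ValueError(f"end must be 'B' or 'E', got {end!r}")


def _in_window(d_i: int, d_j: int, l: int, window: str) -> bool:
    if window == "triangle":
        return d_i + d_j < l
    return d_i < l and d_j < l


# ---------------------------------------------------------------------------
# per-pair counting (reference path; the assembler uses the array path below)
# ---------------------------------------------------------------------------

def count_end_links(pairs: Iterable[ContactPair], i: ScaffoldNode, j: ScaffoldNode,
                    l: int, window: str = "triangle") -> EndPairCounts:
    """Count read pairs in each of the four end windows of scaffolds i and j.

    Pair loci are given on original contigs and resolved through the two
    scaffolds' component maps; pairs with both loci on the same scaffold
    (or on neither) carry no junction information and are skipped.
    """
    if l <= 0:
        raise ValueError("window length l must be positive")
    map_i, map_j = i.contig_map(), j.contig_map()
    counts = {"BB": 0, "BE": 0, "EB": 0, "EE": 0}
    for p in pairs:
        if p.ref1 in map_i and p.ref2 in map_j:
            pos_i, pos_j = i.locate(p.ref1, p.pos1), j.locate(p.ref2, p.pos2)
        elif p.ref2 in map_i and p.ref1 in map_j:
            pos_i, pos_j = i.locate(p.ref2, p.pos2), j.locate(p.ref1, p.pos1)
        else:
            continue
        if p.ref1 in map_i and p.ref1 in map_j:
            # same contig cannot live on two scaffolds; defensive
            continue
        for end_i in "BE":
            d_i = end_distance(pos_i, i, end_i)
            for end_j in "BE":
                d_j = end_distance(pos_j, j, end_j)
                if _in_window(d_i, d_j, l, window):
                    counts[end_i + end_j] += 1
    return EndPairCounts(counts["BB"], counts["BE"], counts["EB"], counts["EE"])


def best_connection(counts: EndPairCounts) -> tuple[int, str]:
    """N_ij = max of the four end-window counts; arg-max label with the
    deterministic tie order EB > BE > EE > BB."""
    d = counts.as_dict()
    label = max(LABELS, key=lambda lab: (d[lab], -_LABEL_RANK[lab]))
    return d[label], label


def link_scores(node_edges: Sequence[tuple[str, int]], top_k: int = 5,
                ) -> list[tuple[str, float]]:
    """Normalize the top-k raw link counts of one scaffold into scores.

    Candidates are ranked by count descending (ties by partner id); only
    the strongest ``top_k`` survive and their counts are divided by the
    top-k sum, so nonzero scores always sum to 1.
    """
    ranked = sorted(node_edges, key=lambda pn: (-pn[1], pn[0]))[:top_k]
    denom = sum(n for _, n in ranked)
    if denom == 0:
        return [(p, 0.0) for p, n in ranked]
    return [(p, n / denom) for p, n in ranked]


# ---------------------------------------------------------------------------
# vectorized all-pairs counting
# ---------------------------------------------------------------------------

class PairArrays:
    """Contact pairs as flat integer arrays for vectorized re-mapping.

    Contig ids are interned against a fixed universe once; each linking
    iteration then maps the same arrays through the current scaffold set
    without rewriting the pairs.
    """

    def __init__(self, contig_ids: Sequence[str],
                 c1: np.ndarray, p1: np.ndarray, c2: np.ndarray, p2: np.ndarray):
        self.contig_ids = list(contig_ids)
        self.index = {cid: k for k, cid in enumerate(self.contig_ids)}
        self.c1, self.p1, self.c2, self.p2 = c1, p1, c2, p2

    @classmethod
    def from_pairs(cls, pairs: Iterable[ContactPair],
                   contig_ids: Sequence[str]) -> "PairArrays":
        index = {cid: k for k, cid in enumerate(contig_ids)}
        rows = [(index[p.ref1], p.pos1, index[p.ref2], p.pos2)
                for p in pairs if p.ref1 in index and p.ref2 in index]
        if rows:
            arr = np.asarray(rows, dtype=np.int64)
            c1, p1, c2, p2 = arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
        else:
            c1 = p1 = c2 = p2 = np.empty(0, dtype=np.int64)
        return cls(contig_ids, c1, p1, c2, p2)

    def __len__(self) -> int:
        return len(self.c1)


def count_all_end_links(scaffolds: Sequence[ScaffoldNode], pairs: PairArrays,
                        l: int, window: str = "triangle",
                        ) -> dict[tuple[int, int], EndPairCounts]:
    """All-pairs end-window counts over a scaffold set, vectorized.

    Returns counts keyed by scaffold-index pair ``(si, sj)`` with
    ``si < sj``; the EndPairCounts are in the (si, sj) frame.
    """
    if l <= 0:
        raise ValueError("window length l must be positive")
    n_contigs = len(pairs.contig_ids)
    scaf_of = np.full(n_contigs, -1, dtype=np.int64)
    off = np.zeros(n_contigs, dtype=np.int64)
    clen = np.zeros(n_contigs, dtype=np.int64)
    fwd = np.zeros(n_contigs, dtype=bool)
    slen = np.zeros(len(scaffolds), dtype=np.int64)
    for si, s in enumerate(scaffolds):
        slen[si] = s.length
        for comp in s.components:
            k = pairs.index.get(comp.contig_id)
            if k is None:
                continue
            scaf_of[k] = si
            off[k] = comp.offset
            clen[k] = comp.length
            fwd[k] = comp.orientation == "+"

    s1, s2 = scaf_of[pairs.c1], scaf_of[pairs.c2]
    keep = (s1 >= 0) & (s2 >= 0) & (s1 != s2)
    if not keep.any():
        return {}
    s1, s2 = s1[keep], s2[keep]
    c1, c2 = pairs.c1[keep], pairs.c2[keep]
    p1, p2 = pairs.p1[keep], pairs.p2[keep]

    q1 = np.where(fwd[c1], off[c1] + p1, off[c1] + clen[c1] - 1 - p1)
    q2 = np.where(fwd[c2], off[c2] + p2, off[c2] + clen[c2] - 1 - p2)

    # canonicalize so the first scaffold index is the smaller one
    swap = s1 > s2
    s1, s2 = np.where(swap, s2, s1), np.where(swap, s1, s2)
    q1, q2 = np.where(swap, q2, q1), np.where(swap, q1, q2)

    dB1, dE1 = q1, slen[s1] - 1 - q1
    dB2, dE2 = q2, slen[s2] - 1 - q2

    key = s1 * len(scaffolds) + s2
    uniq, inv = np.unique(key, return_inverse=True)
    out = np.zeros((len(uniq), 4), dtype=np.int64)
    for col, (d1, d2) in enumerate(((dB1, dB2), (dB1, dE2), (dE1, dB2), (dE1, dE2))):
        if window == "triangle":
            mask = d1 + d2 < l
        else:
            mask = (d1 < l) & (d2 < l)
        out[:, col] = np.bincount(inv[mask], minlength=len(uniq))

    result: dict[tuple[int, int], EndPairCounts] = {}
    for row, k in enumerate(uniq):
        si, sj = divmod(int(k), len(scaffolds))
        result[(si, sj)] = EndPairCounts(*out[row])
    return result


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def build_graph(scaffolds: Sequence[ScaffoldNode],
                pairs: PairArrays | Sequence[ContactPair],
                params: WindowParams) -> ScaffoldGraph:
    """One iteration's scaffold graph: count, score, cut, and retain edges.

    Per scaffold, candidate partners are reduced to their best orientation
    (``best_connection``), scored against the top-k sum, cut at ``w_min``,
    and at most one edge is kept per scaffold end; an edge survives only
    if it is the winner at BOTH of its endpoint ends, so the final degree
    is <= 2 per node and <= 1 per node end.
    """
    if not isinstance(pairs, PairArrays):
        contig_ids = [c.contig_id for s in scaffolds for c in s.components]
        pairs = PairArrays.from_pairs(pairs, contig_ids)
    counts = count_all_end_links(scaffolds, pairs, params.l, params.window)

    ids = [s.id for s in scaffolds]
    candidates: dict[tuple[int, int], tuple[int, str]] = {}
    for key, cnt in counts.items():
        n, label = best_connection(cnt)
        if n > 0:
            candidates[key] = (n, label)

    # per-node link scores over top-k partners
    per_node: dict[int, list[tuple[str, int]]] = {si: [] for si in range(len(ids))}
    partner_idx: dict[tuple[int, str], int] = {}
    for (si, sj), (n, _) in candidates.items():
        per_node[si].append((ids[sj], n))
        per_node[sj].append((ids[si], n))
        partner_idx[(si, ids[sj])] = sj
        partner_idx[(sj, ids[si])] = si
    w_of: dict[tuple[int, int], float] = {}   # (node, partner) -> score
    for si, cand in per_node.items():
        for pid, w in link_scores(cand, params.top_k):
            w_of[(si, partner_idx[(si, pid)])] = w

    # per-end retention: best surviving edge per (node, end), mutual to stick
    best_at: dict[tuple[int, str], tuple[tuple, tuple[int, int]]] = {}
    edge_info: dict[tuple[int, int], tuple[int, str, float, float]] = {}
    for (si, sj), (n, label) in candidates.items():
        wi = w_of.get((si, sj), 0.0)
        wj = w_of.get((sj, si), 0.0)
        if wi < params.w_min or wj < params.w_min:
            continue
        edge_info[(si, sj)] = (n, label, wi, wj)
        for node, other, w_node, end in ((si, sj, wi, label[0]),
                                         (sj, si, wj, label[1])):
            key = (node, end)
            incumbent = best_at.get(key)
            rank = (-w_node, _LABEL_RANK[label], ids[other])
            if incumbent is None or rank < incumbent[0]:
                best_at[key] = (rank, (si, sj))

    retained: list[LinkEdge] = []
    for (si, sj), (n, label, wi, wj) in sorted(edge_info.items()):
        if (best_at.get((si, label[0]), (None, None))[1] == (si, sj)
                and best_at.get((sj, label[1]), (None, None))[1] == (si, sj)):
            retained.append(LinkEdge(ids[si], ids[sj], label, n, wi, wj))
    return ScaffoldGraph(list(ids), retained)


# ---------------------------------------------------------------------------
# diagnostic: window coefficient of variation
# ---------------------------------------------------------------------------

def window_cv(pairs: Iterable[ContactPair], i: ScaffoldNode, j: ScaffoldNode,
              l: int, bins: int, ends: str = "EB") -> tuple[float, float]:
    """Coefficient of variation of interaction density inside the triangle
    window versus the full square window.

    The ``l x l`` end-window (default: E of i facing B of j) is split
    into ``bins x bins`` cells; the CV (std/mean of per-cell counts) is
    computed over cells whose centers satisfy the triangle predicate and
    over all cells of the square.  Long-range enrichment inflates the far
    corner, so the square CV exceeds the triangle CV when such structure
    is present.  Returns (0, 0) for an empty window.
    """
    if l <= 0:
        raise ValueError("window length l must be positive")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    end_i, end_j = ends[0], ends[1]
    grid = np.zeros((bins, bins), dtype=np.int64)
    cell = l / bins
    map_i, map_j = i.contig_map(), j.contig_map()
    for p in pairs:
        if p.ref1 in map_i and p.ref2 in map_j:
            pos_i, pos_j = i.locate(p.ref1, p.pos1), j.locate(p.ref2, p.pos2)
        elif p.ref2 in map_i and p.ref1 in map_j:
            pos_i, pos_j = i.locate(p.ref2, p.pos2), j.locate(p.ref1, p.pos1)
        else:
            continue
        d_i = end_distance(pos_i, i, end_i)
        d_j = end_distance(pos_j, j, end_j)
        if d_i < l and d_j < l:
            grid[min(int(d_i // cell), bins - 1), min(int(d_j // cell), bins - 1)] += 1

    centers = (np.arange(bins) + 0.5) * cell
    tri_mask = centers[:, None] + centers[None, :] < l

    def cv(values: np.ndarray) -> float:
        m = values.mean()
        return float(values.std() / m) if m > 0 else 0.0

    return cv(grid[tri_mask]), cv(grid.ravel())
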