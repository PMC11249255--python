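"""The iterative scaffolding loop and the chromosome builder.

Each round filters scaffolds shorter than the current window ``l``,
builds the degree-bounded link graph, extracts oriented paths, and
merges each path into a longer scaffold; ``l`` then grows by the
configured factor (default 1.4, doubling the window every two rounds)
and the loop repeats until the scaffold count reaches the requested
chromosome number, stalls, or hits the iteration cap.  The builder
finally emits chromosome FASTA plus an AGP that records every contig's
position and direction, joining contigs with N gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import reverse_complement

from triscaf.io_formats import AGPRow, SequenceRecord, TruthLayout
from triscaf.linkgraph import (
    Component,
    LinkEdge,
    PairArrays,
    ScaffoldGraph,
    ScaffoldNode,
    WindowParams,
    build_graph,
)

logger = logging.getLogger(__name__)

_OPPOSITE = {"B": "E", "E": "B"}


@dataclass
class OrientedPath:
    """An ordered, oriented chain of scaffolds joined by retained edges."""

    entries: list[tuple[str, str]]            # (scaffold_id, '+'/'-')
    edges: list[LinkEdge] = field(default_factory=list)

    def mirror(self) -> "OrientedPath":
        flipped = [(sid, "-" if o == "+" else "+") for sid, o in reversed(self.entries)]
        return OrientedPath(flipped, list(reversed(self.edges)))


def _canonical(path: OrientedPath) -> OrientedPath:
    mir = path.mirror()
    key = lambda p: (p.entries[0][0], p.entries[0][1] != "+")
    return path if key(path) <= key(mir) else mir


# ---------------------------------------------------------------------------
# path extraction
# ---------------------------------------------------------------------------

def extract_paths(graph: ScaffoldGraph) -> list[OrientedPath]:
    """Decompose the retained-edge graph into oriented simple paths.

    Under per-end degree <= 1 every connected component is a simple path
    or a cycle; cycles are broken at their lowest-weight edge.  Edge
    labels fix orientations: traversing edge (i, j) with label XY means
    leaving i through end X and entering j through end Y, so a scaffold
    traversed begin-to-end is '+' and end-to-begin is '-'.  Singleton
    nodes are emitted unchanged as length-1 paths.
    """
    at_end: dict[tuple[str, str], LinkEdge] = {}
    for e in graph.edges:
        for node in (e.i, e.j):
            key = (node, e.end_of(node))
            if key in at_end:
                raise AssertionError(f"two edges retained at end {key}")
            at_end[key] = e

    visited: set[str] = set()
    paths: list[OrientedPath] = []

    def walk(start: str, enter_end: str) -> OrientedPath:
        """Follow the chain from ``start``, entered through ``enter_end``."""
        entries: list[tuple[str, str]] = []
        edges: list[LinkEdge] = []
        node, enter = start, enter_end
        while True:
            visited.add(node)
            exit_end = _OPPOSITE[enter]
            entries.append((node, "+" if exit_end == "E" else "-"))
            edge = at_end.get((node, exit_end))
            if edge is None or edge.other(node) in visited:
                break
            edges.append(edge)
            nxt = edge.other(node)
            node, enter = nxt, edge.end_of(nxt)
        return OrientedPath(entries, edges)

    # open chains first: start from every node with a free end
    for node in sorted(graph.nodes):
        if node in visited:
            continue
        free = [end for end in "BE" if (node, end) not in at_end]
        if not free:
            continue
        paths.append(_canonical(walk(node, free[0])))

    # what remains are cycles: break each at its lowest-weight edge
    for node in sorted(graph.nodes):
        if node in visited:
            continue
        cycle_edges: list[LinkEdge] = []
        cur, enter = node, "B"
        while True:
            edge = at_end[(cur, _OPPOSITE[enter])]
            if edge in cycle_edges:
                break
            cycle_edges.append(edge)
            nxt = edge.other(cur)
            if nxt == node:
                break
            cur, enter = nxt, edge.end_of(nxt)
        weakest = min(cycle_edges, key=lambda e: (e.weight, e.i, e.j))
        removed = [((weakest.i, weakest.end_of(weakest.i)), weakest),
                   ((weakest.j, weakest.end_of(weakest.j)), weakest)]
        for key, _ in removed:
            del at_end[key]
        start = min(weakest.i, weakest.j)
        free_end = next(end for end in "BE" if (start, end) not in at_end)
        paths.append(_canonical(walk(start, free_end)))
        for key, e in removed:
            at_end[key] = e
    return paths


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_path(path: OrientedPath, scaffolds: dict[str, ScaffoldNode],
               new_id: str | None = None) -> ScaffoldNode:
    """Concatenate the members of an oriented path into one scaffold.

    '-' members contribute their components reversed and flipped.  No
    gaps enter scaffold coordinates: merged length is the sum of member
    lengths, so triangle counting in later iterations stays exact.
    """
    if new_id is None:
        new_id = "+".join(sid for sid, _ in path.entries)
    components: list[Component] = []
    seen: set[str] = set()
    offset = 0
    for sid, orient in path.entries:
        member = scaffolds[sid]
        if orient == "+":
            for c in member.components:
                components.append(Component(c.contig_id, offset + c.offset,
                                            c.length, c.orientation))
        else:
            for c in reversed(member.components):
                flipped = "-" if c.orientation == "+" else "+"
                new_off = offset + member.length - (c.offset + c.length)
                components.append(Component(c.contig_id, new_off, c.length, flipped))
        offset += member.length
        for c in member.components:
            if c.contig_id in seen:
                raise ValueError(f"duplicate contig {c.contig_id!r} in merge")
            seen.add(c.contig_id)
    return ScaffoldNode(new_id, offset, components)


# ---------------------------------------------------------------------------
# the iterative loop
# ---------------------------------------------------------------------------

def _as_nodes(contigs) -> list[ScaffoldNode]:
    nodes = []
    for c in contigs:
        if isinstance(c, ScaffoldNode):
            nodes.append(c)
        elif isinstance(c, SequenceRecord):
            nodes.append(ScaffoldNode.from_contig(c.id, c.length))
        else:
            cid, length = c
            nodes.append(ScaffoldNode.from_contig(cid, int(length)))
    return nodes


def run_scaffolding(contigs, pairs, n_chrom: int,
                    params: WindowParams | None = None,
                    chrom_tolerance: int = 0,
                    max_iter: int = 30,
                    max_stall: int = 3,
                    ) -> tuple[list[ScaffoldNode], list[dict]]:
    """Iteratively order, orient and cluster contigs into ``n_chrom`` scaffolds.

    Parameters
    ----------
    contigs
        ScaffoldNodes, SequenceRecords, or (id, length) tuples — only
        lengths matter for linking.
    pairs
        Canonical contact pairs in contig coordinates (or a PairArrays).
    n_chrom
        Target chromosome count; iteration stops once the total scaffold
        count is within ``chrom_tolerance`` of it.
    params
        Window parameters; ``params.l`` is the initial window length.

    Returns the final scaffolds (every input contig appears in exactly
    one component list) and a per-iteration log of window length, node
    counts, retained edges and merges.
    """
    params = params or WindowParams()
    scaffolds = _as_nodes(contigs)
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if n_chrom > len(scaffolds):
        raise ValueError(f"n_chrom={n_chrom} exceeds contig count {len(scaffolds)}")
    if not isinstance(pairs, PairArrays):
        contig_ids = [c.contig_id for s in scaffolds for c in s.components]
        pairs = PairArrays.from_pairs(pairs, contig_ids)

    log: list[dict] = []
    l = params.l
    stall = 0
    counter = 0
    for iteration in range(1, max_iter + 1):
        if len(scaffolds) <= n_chrom + chrom_tolerance:
            break
        active = [s for s in scaffolds if s.length >= l]
        deferred = [s for s in scaffolds if s.length < l]
        it_params = WindowParams(l=int(l), growth=params.growth, w_min=params.w_min,
                                 top_k=params.top_k, window=params.window)
        graph = build_graph(active, pairs, it_params)
        paths = extract_paths(graph)

        # stop-at-target: if applying every edge would overshoot below the
        # chromosome target, keep only the strongest edges and re-extract
        used = [e for p in paths for e in p.edges]
        budget = len(scaffolds) - n_chrom
        if len(used) > budget:
            keep = sorted(used, key=lambda e: (-e.weight, e.i, e.j))[:budget]
            paths = extract_paths(ScaffoldGraph(graph.nodes, keep))

        by_id = {s.id: s for s in active}
        merged: list[ScaffoldNode] = []
        n_merges = 0
        for p in paths:
            if len(p.entries) == 1:
                merged.append(by_id[p.entries[0][0]])
            else:
                counter += 1
                merged.append(merge_path(p, by_id, new_id=f"scaffold_{counter}"))
                n_merges += 1
        log.append({"iteration": iteration, "l": int(l),
                    "n_scaffolds": len(scaffolds), "n_active": len(active),
                    "edges_retained": len(graph.edges),
                    "merges": n_merges})
        logger.info("iteration %d: l=%d, %d scaffolds (%d active), "
                    "%d edges, %d merges", iteration, int(l), len(scaffolds),
                    len(active), len(graph.edges), n_merges)
        scaffolds = merged + deferred
        stall = stall + 1 if n_merges == 0 else 0
        if stall >= max_stall:
            break
        l *= params.growth
    return scaffolds, log


# ---------------------------------------------------------------------------
# building
# ---------------------------------------------------------------------------

def build_genome(scaffolds: list[ScaffoldNode],
                 contig_sequences: dict[str, str] | list[SequenceRecord],
                 gap_len: int = 100,
                 n_chrom: int | None = None,
                 ) -> tuple[list[SequenceRecord], list[AGPRow]]:
    """Emit chromosome FASTA records and AGP rows for the final scaffolds.

    Scaffolds are named ``chr_1..chr_n`` by descending length; when
    ``n_chrom`` is given, scaffolds beyond the first ``n_chrom`` are
    treated as unplaced and keep their own ids behind an ``un_`` prefix.
    Adjacent contigs are joined by ``gap_len`` N's, recorded as AGP 'U'
    rows with linkage evidence ``proximity_ligation``.
    """
    if not isinstance(contig_sequences, dict):
        contig_sequences = {r.id: r.sequence for r in contig_sequences}
    ordered = sorted(scaffolds, key=lambda s: (-s.length, s.id))
    records: list[SequenceRecord] = []
    rows: list[AGPRow] = []
    for rank, scaf in enumerate(ordered, start=1):
        if n_chrom is None or rank <= n_chrom:
            name = f"chr_{rank}"
        else:
            name = f"un_{scaf.id}"
        parts: list[str] = []
        beg = 1
        part = 1
        for k, comp in enumerate(scaf.components):
            if k > 0 and gap_len > 0:
                parts.append("N" * gap_len)
                rows.append(AGPRow(name, beg, beg + gap_len - 1, part, "U",
                                   gap_length=gap_len))
                beg += gap_len
                part += 1
            try:
                seq = contig_sequences[comp.contig_id]
            except KeyError:
                raise KeyError(f"no sequence for contig {comp.contig_id!r}") from None
            if len(seq) != comp.length:
                raise ValueError(f"sequence length mismatch for {comp.contig_id!r}")
            if comp.orientation == "-":
                seq = reverse_complement(seq)
            parts.append(seq)
            rows.append(AGPRow(name, beg, beg + comp.length - 1, part, "W",
                               component_id=comp.contig_id, component_beg=1,
                               component_end=comp.length,
                               orientation=comp.orientation))
            beg += comp.length
            part += 1
        records.append(SequenceRecord(name, "".join(parts)))
    return records, rows


def genome_from_agp(rows: list[AGPRow],
                    contig_sequences: dict[str, str] | list[SequenceRecord],
                    ) -> list[SequenceRecord]:
    """Reconstruct object sequences from an AGP and the component contigs."""
    if not isinstance(contig_sequences, dict):
        contig_sequences = {r.id: r.sequence for r in contig_sequences}
    objects: dict[str, list[str]] = {}
    for row in rows:
        parts = objects.setdefault(row.object, [])
        if row.component_type == "U":
            parts.append("N" * row.gap_length)
        else:
            seq = contig_sequences[row.component_id]
            piece = seq[row.component_beg - 1:row.component_end]
            if row.orientation == "-":
                piece = reverse_complement(piece)
            parts.append(piece)
    return [SequenceRecord(name, "".join(parts)) for name, parts in objects.items()]


def scaffolds_to_layout(scaffolds: list[ScaffoldNode],
                        names: dict[str, str] | None = None) -> TruthLayout:
    """Project scaffolds onto an ordered, oriented contig layout."""
    chroms: dict[str, list[tuple[str, str]]] = {}
    for scaf in scaffolds:
        name = names.get(scaf.id, scaf.id) if names else scaf.id
        chroms[name] = [(c.contig_id, c.orientation)
                        for c in sorted(scaf.components, key=lambda c: c.offset)]
    return TruthLayout(chroms)
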