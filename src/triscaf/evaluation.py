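"""Truth-based scaffolding error statistics.

Every adjacent contig pair (junction) in an assembled layout is checked
against the ground-truth layout and classified, in priority order, as a
translocation (the two contigs belong to different truth chromosomes),
an inversion (same chromosome but mutually inconsistent orientation),
or a relocation (consistent orientation but non-adjacent truth ranks).
A junction is correct iff the two contigs are truth-adjacent in the
direction their orientations imply; the rule is invariant under
mirroring a whole scaffold, so chromosome-scale mirror ambiguity —
which Hi-C evidence cannot resolve — is never penalized.

The assembly edit distance is the minimum number of edits (splitting a
scaffold, joining two scaffolds, moving a contiguous contig block —
in either orientation — and inverting a contiguous block) transforming the assembled layout into
the truth layout.  Small instances are solved exactly by bidirectional
breadth-first search over layout states (every edit is invertible);
larger instances fall back to a documented greedy upper bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from triscaf.io_formats import ContactPair, TruthLayout

# a layout state: frozenset of scaffolds; a scaffold: tuple of (contig, +1/-1)
Scaffold = tuple[tuple[str, int], ...]
State = frozenset


@dataclass(frozen=True)
class ErrorReport:
    """Junction error counts and edit distance for one assembly vs truth."""

    relocations: int
    translocations: int
    inversions: int
    edit_distance: int
    n_junctions_evaluated: int
    edit_exact: bool = True

    @property
    def total_errors(self) -> int:
        return self.relocations + self.translocations + self.inversions


# ---------------------------------------------------------------------------
# junction classification
# ---------------------------------------------------------------------------

def classify_junctions(assembly: TruthLayout, truth: TruthLayout) -> ErrorReport:
    """Count relocations, translocations and inversions in an assembly.

    ``assembly`` is any layout-shaped object (scaffold -> ordered,
    oriented contigs); every contig must appear in ``truth``.  The
    returned report has ``edit_distance`` 0 as a placeholder; use
    :func:`evaluate` for the combined report.
    """
    table = truth.rank_table()
    relocations = translocations = inversions = 0
    n_junctions = 0
    for entries in assembly.chromosomes.values():
        for (ca, oa), (cb, ob) in zip(entries, entries[1:]):
            try:
                chrom_a, rank_a, ta = table[ca]
                chrom_b, rank_b, tb = table[cb]
            except KeyError as exc:
                raise KeyError(f"contig {exc.args[0]!r} absent from truth") from None
            n_junctions += 1
            if chrom_a != chrom_b:
                translocations += 1
                continue
            sa = 1 if oa == ta else -1
            sb = 1 if ob == tb else -1
            if sa != sb:
                inversions += 1
            elif not ((sa == 1 and rank_b == rank_a + 1)
                      or (sa == -1 and rank_a == rank_b + 1)):
                relocations += 1
    return ErrorReport(relocations, translocations, inversions, 0, n_junctions)


# ---------------------------------------------------------------------------
# edit distance
# ---------------------------------------------------------------------------

def _mirror(s: Scaffold) -> Scaffold:
    return tuple((c, -o) for c, o in reversed(s))


def _canon(s: Scaffold) -> Scaffold:
    m = _mirror(s)
    return s if s <= m else m


def layout_state(layout: TruthLayout) -> State:
    """Canonical search state: mirror-normalized scaffolds, order-free."""
    return frozenset(
        _canon(tuple((c, 1 if o == "+" else -1) for c, o in entries))
        for entries in layout.chromosomes.values() if entries)


def _successors(state: State) -> Iterable[State]:
    scaffolds = sorted(state)
    # split
    for s in scaffolds:
        rest = state - {s}
        for cut in range(1, len(s)):
            yield rest | {_canon(s[:cut]), _canon(s[cut:])}
    # join (all four end combinations; canonicalization collapses mirrors)
    for ai in range(len(scaffolds)):
        for bi in range(ai + 1, len(scaffolds)):
            a, b = scaffolds[ai], scaffolds[bi]
            rest = state - {a, b}
            for left in (a, _mirror(a)):
                for right in (b, _mirror(b)):
                    yield rest | {_canon(left + right)}
    # invert a contiguous block
    for s in scaffolds:
        rest = state - {s}
        for i in range(len(s)):
            for j in range(i + 1, len(s) + 1):
                if i == 0 and j == len(s):
                    continue  # whole-scaffold mirror is identity
                ns = s[:i] + _mirror(s[i:j]) + s[j:]
                yield rest | {_canon(ns)}
    # move a contiguous block; the block may land in either orientation —
    # mirror-canonical states identify a layout with its mirror, so an
    # orientation-preserving move on one representative is a flipped move
    # on the other and the edit relation stays symmetric only if both
    # insertions are allowed
    for s in scaffolds:
        rest = state - {s}
        for i in range(len(s)):
            for j in range(i + 1, len(s) + 1):
                remainder = s[:i] + s[j:]
                for block in (s[i:j], _mirror(s[i:j])):
                    if remainder:
                        # reinsert elsewhere in the source scaffold
                        for k in range(len(remainder) + 1):
                            ns = remainder[:k] + block + remainder[k:]
                            yield frozenset(rest | {_canon(ns)})
                        # or break it out as its own scaffold
                        yield frozenset(rest | {_canon(remainder), _canon(block)})
                    # or into another scaffold
                    for t in sorted(rest):
                        t_rest = rest - {t}
                        for k in range(len(t) + 1):
                            ns = t[:k] + block + t[k:]
                            out = t_rest | {_canon(ns)}
                            if remainder:
                                out = out | {_canon(remainder)}
                            yield frozenset(out)


def _junction_ok(table, a, b) -> bool:
    (ca, oa), (cb, ob) = a, b
    chrom_a, rank_a, ta = table[ca]
    chrom_b, rank_b, tb = table[cb]
    sa, sb = (1 if oa == ta else -1), (1 if ob == tb else -1)
    return (chrom_a == chrom_b and sa == sb
            and ((sa == 1 and rank_b == rank_a + 1)
                 or (sa == -1 and rank_a == rank_b + 1)))


def _greedy_bound(assembly: TruthLayout, truth: TruthLayout) -> int:
    """Upper bound on the edit distance by constructive repair.

    Phase 1 greedily applies block inversions while any strictly reduces
    the number of incorrect junctions (junction correctness is mirror-
    invariant, so inverting a block only changes its two boundary
    junctions — each accepted inversion is one edit).  Phase 2 splits at
    every remaining incorrect junction and rejoins the truth-consistent
    fragments chromosome by chromosome; split + join counts are exact
    for the layout that phase 1 leaves behind, so the total is a valid
    upper bound.
    """
    table = truth.rank_table()
    flip = {"+": "-", "-": "+"}
    scaffolds = [list(entries) for entries in assembly.chromosomes.values()
                 if entries]
    edits = 0
    improved = True
    while improved:
        improved = False
        best = None  # (delta, scaffold_idx, i, j)
        for si, entries in enumerate(scaffolds):
            m = len(entries)
            for i in range(m):
                for j in range(i + 1, m + 1):
                    if i == 0 and j == m:
                        continue
                    delta = 0
                    block = [(c, flip[o]) for c, o in reversed(entries[i:j])]
                    if i > 0:
                        delta -= int(not _junction_ok(table, entries[i - 1], entries[i]))
                        delta += int(not _junction_ok(table, entries[i - 1], block[0]))
                    if j < m:
                        delta -= int(not _junction_ok(table, entries[j - 1], entries[j]))
                        delta += int(not _junction_ok(table, block[-1], entries[j]))
                    if delta < 0 and (best is None or delta < best[0]):
                        best = (delta, si, i, j)
        if best is not None:
            _, si, i, j = best
            entries = scaffolds[si]
            entries[i:j] = [(c, flip[o]) for c, o in reversed(entries[i:j])]
            edits += 1
            improved = True

    splits = 0
    fragments_per_chrom: dict[str, int] = {}
    for entries in scaffolds:
        frag_chrom = table[entries[0][0]][0]
        for a, b in zip(entries, entries[1:]):
            if not _junction_ok(table, a, b):
                splits += 1
                fragments_per_chrom[frag_chrom] = fragments_per_chrom.get(frag_chrom, 0) + 1
                frag_chrom = table[b[0]][0]
        fragments_per_chrom[frag_chrom] = fragments_per_chrom.get(frag_chrom, 0) + 1
    joins = sum(k - 1 for k in fragments_per_chrom.values())
    return edits + splits + joins


def edit_distance(assembly: TruthLayout, truth: TruthLayout,
                  exact_limit: int = 8,
                  max_states: int = 500_000) -> tuple[int, bool]:
    """Minimum split/join/move/invert edits from assembly to truth.

    Returns ``(distance, exact)``.  Instances with at most
    ``exact_limit`` contigs are solved by bidirectional BFS (exact);
    larger ones, or searches exceeding ``max_states`` explored states,
    return the greedy split-and-rejoin upper bound (``exact=False``).
    """
    if assembly.contigs != truth.contigs:
        raise ValueError("assembly and truth cover different contig sets")
    start, goal = layout_state(assembly), layout_state(truth)
    if start == goal:
        return 0, True
    n_contigs = len(truth.contigs)
    if n_contigs > exact_limit:
        return _greedy_bound(assembly, truth), False

    # bidirectional BFS; every edit is invertible so both frontiers use
    # the same successor function
    dist_f: dict[State, int] = {start: 0}
    dist_b: dict[State, int] = {goal: 0}
    frontier_f, frontier_b = [start], [goal]
    explored = 0
    while frontier_f and frontier_b:
        if len(frontier_f) <= len(frontier_b):
            frontier, dist, other = frontier_f, dist_f, dist_b
            is_fwd = True
        else:
            frontier, dist, other = frontier_b, dist_b, dist_f
            is_fwd = False
        new_frontier: list[State] = []
        best: int | None = None
        for state in frontier:
            d = dist[state]
            for nxt in _successors(state):
                if nxt in dist:
                    continue
                explored += 1
                if explored > max_states:
                    return _greedy_bound(assembly, truth), False
                dist[nxt] = d + 1
                if nxt in other:
                    total = d + 1 + other[nxt]
                    best = total if best is None else min(best, total)
                new_frontier.append(nxt)
        if best is not None:
            return best, True
        if is_fwd:
            frontier_f = new_frontier
        else:
            frontier_b = new_frontier
    return _greedy_bound(assembly, truth), False


def evaluate(assembly: TruthLayout, truth: TruthLayout,
             exact_limit: int = 8) -> ErrorReport:
    """Full report: junction error classes plus the edit distance."""
    base = classify_junctions(assembly, truth)
    dist, exact = edit_distance(assembly, truth, exact_limit=exact_limit)
    return ErrorReport(base.relocations, base.translocations, base.inversions,
                       dist, base.n_junctions_evaluated, exact)


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------

def sample_benchmark(truth: TruthLayout,
                     pairs: Sequence[ContactPair],
                     contig_lengths: dict[str, int],
                     scaffolder: Callable,
                     n_samples: int = 25,
                     chroms_per_sample: int = 5,
                     seed: int = 0,
                     exact_limit: int = 8) -> list[dict]:
    """Repeated subsampled scaffolding runs scored against the truth.

    Each sample draws ``chroms_per_sample`` chromosomes without
    replacement, restricts contigs and contact pairs to that subset,
    runs ``scaffolder(contigs, pairs, n_chrom) -> layout-shaped
    TruthLayout``, and classifies the errors.  Returns one tidy dict
    per sample (columns: sample, relocations, translocations,
    inversions, edit_distance, exact_flag, unplaced_fraction).
    """
    chrom_names = list(truth.chromosomes)
    if len(chrom_names) < chroms_per_sample:
        raise ValueError("not enough chromosomes to sample from")
    rng = np.random.default_rng(seed)
    rows = []
    for sample in range(n_samples):
        chosen = sorted(rng.choice(len(chrom_names), size=chroms_per_sample,
                                   replace=False))
        sub_chroms = {chrom_names[k]: truth.chromosomes[chrom_names[k]]
                      for k in chosen}
        sub_truth = TruthLayout(sub_chroms)
        keep = sub_truth.contigs
        sub_contigs = [(cid, contig_lengths[cid]) for cid in sorted(keep)]
        sub_pairs = [p for p in pairs if p.ref1 in keep and p.ref2 in keep]
        assembly = scaffolder(sub_contigs, sub_pairs, chroms_per_sample)
        placed = assembly.contigs
        report = _evaluate_placed(assembly, sub_truth, exact_limit)
        rows.append({
            "sample": sample,
            "relocations": report.relocations,
            "translocations": report.translocations,
            "inversions": report.inversions,
            "edit_distance": report.edit_distance,
            "exact_flag": report.edit_exact,
            "unplaced_fraction": 1.0 - len(placed & keep) / len(keep),
        })
    return rows


def _evaluate_placed(assembly: TruthLayout, truth: TruthLayout,
                     exact_limit: int) -> ErrorReport:
    """Evaluate on the placed contigs only; unplaced ones are reported
    through the completeness fraction, not as junction errors."""
    placed = assembly.contigs & truth.contigs
    if placed == truth.contigs:
        return evaluate(assembly, truth, exact_limit=exact_limit)
    sub_truth_chroms = {
        chrom: [(c, o) for c, o in entries if c in placed]
        for chrom, entries in truth.chromosomes.items()}
    sub_truth = TruthLayout({k: v for k, v in sub_truth_chroms.items() if v})
    sub_asm = TruthLayout({
        k: [(c, o) for c, o in entries if c in placed]
        for k, entries in assembly.chromosomes.items()})
    return evaluate(sub_asm, sub_truth, exact_limit=exact_limit)


# ---------------------------------------------------------------------------
# summary statistics and diagnostics
# ---------------------------------------------------------------------------

def scaffold_stats(lengths: Sequence[int]) -> dict:
    """Scaffold count, total length, N50 and N90."""
    ls = sorted((int(x) for x in lengths), reverse=True)
    total = sum(ls)
    out = {"count": len(ls), "total_length": total, "n50": 0, "n90": 0}
    acc = 0
    for x in ls:
        acc += x
        if out["n50"] == 0 and acc >= 0.5 * total:
            out["n50"] = x
        if acc >= 0.9 * total:
            out["n90"] = x
            break
    return out


def distance_decay_slope(pairs: Iterable[ContactPair],
                         x_range: tuple[int, int] = (10_000, 1_000_000),
                         n_bins: int = 20) -> float:
    """Log-log slope of cis contact density versus genomic distance.

    Distances of cis pairs are binned into log-spaced bins over
    ``x_range``; per-bin counts are divided by bin width (density per
    bp) and a straight line is fit to log10(density) vs log10(distance)
    over non-empty bins.  Under the x**(-alpha) law the slope is -alpha.
    """
    xs = np.array([p.pos2 - p.pos1 for p in pairs if p.is_cis], dtype=np.int64)
    xs = np.abs(xs)
    lo, hi = x_range
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    counts, _ = np.histogram(xs, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    mask = counts > 0
    if mask.sum() < 2:
        raise ValueError("not enough populated bins to fit a slope")
    slope, _ = np.polyfit(np.log10(centers[mask]),
                          np.log10(counts[mask] / widths[mask]), 1)
    return float(slope)
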