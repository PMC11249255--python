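"""Independent brute-force oracles used by the test suite.

Everything here is written as plainly as possible — per-pair loops,
direct enumeration, unidirectional BFS — and deliberately shares no
code with the library paths it checks.
"""

from __future__ import annotations

from collections import deque

LABELS = ("EB", "BE", "EE", "BB")


# --- end-window counting ----------------------------------------------------

def locate_oracle(scaffold, contig_id, pos):
    """Position of a contig locus on a scaffold, by component scan."""
    for comp in scaffold.components:
        if comp.contig_id == contig_id:
            if comp.orientation == "+":
                return comp.offset + pos
            return comp.offset + comp.length - 1 - pos
    return None


def count_oracle(pairs, scaf_i, scaf_j, l, window="triangle"):
    """Four end-window counts by exhaustive per-pair enumeration."""
    counts = {"BB": 0, "BE": 0, "EB": 0, "EE": 0}
    for p in pairs:
        for (ra, pa, rb, pb) in ((p.ref1, p.pos1, p.ref2, p.pos2),
                                 (p.ref2, p.pos2, p.ref1, p.pos1)):
            qi = locate_oracle(scaf_i, ra, pa)
            qj = locate_oracle(scaf_j, rb, pb)
            if qi is None or qj is None:
                continue
            for ei in "BE":
                di = qi if ei == "B" else scaf_i.length - 1 - qi
                for ej in "BE":
                    dj = qj if ej == "B" else scaf_j.length - 1 - qj
                    if window == "triangle":
                        ok = di + dj < l
                    else:
                        ok = di < l and dj < l
                    if ok:
                        counts[ei + ej] += 1
            break  # count each pair once, in the orientation that resolved
    return counts


def best_connection_oracle(counts: dict) -> tuple[int, str]:
    best_label, best_n = None, -1
    for lab in LABELS:  # first in preference order wins ties
        if counts[lab] > best_n:
            best_label, best_n = lab, counts[lab]
    return best_n, best_label


def link_scores_oracle(cands, top_k=5):
    ranked = sorted(cands, key=lambda pn: (-pn[1], pn[0]))[:top_k]
    total = sum(n for _, n in ranked)
    if total == 0:
        return [(p, 0.0) for p, _ in ranked]
    return [(p, n / total) for p, n in ranked]


def retention_oracle(candidates, ids, w_min, top_k=5):
    """Edge retention by direct rule application.

    candidates: {(si, sj): (n, label)} with si < sj (indices into ids).
    Returns the set of retained (si, sj) keys.
    """
    per_node = {}
    for (si, sj), (n, _) in candidates.items():
        per_node.setdefault(si, []).append((ids[sj], n, sj))
        per_node.setdefault(sj, []).append((ids[si], n, si))
    w = {}
    for node, cand in per_node.items():
        scored = link_scores_oracle([(pid, n) for pid, n, _ in cand], top_k)
        by_pid = {pid: idx for pid, n, idx in cand}
        for pid, score in scored:
            w[(node, by_pid[pid])] = score

    label_rank = {lab: r for r, lab in enumerate(LABELS)}
    chosen = {}
    for (si, sj), (n, label) in sorted(candidates.items()):
        wi, wj = w.get((si, sj), 0.0), w.get((sj, si), 0.0)
        if wi < w_min or wj < w_min:
            continue
        for node, other, wn, end in ((si, sj, wi, label[0]), (sj, si, wj, label[1])):
            key = (node, end)
            rank = (-wn, label_rank[label], ids[other])
            if key not in chosen or rank < chosen[key][0]:
                chosen[key] = (rank, (si, sj))
    retained = set()
    for (si, sj), (n, label) in candidates.items():
        wi, wj = w.get((si, sj), 0.0), w.get((sj, si), 0.0)
        if wi < w_min or wj < w_min:
            continue
        if (chosen.get((si, label[0]), (None, None))[1] == (si, sj)
                and chosen.get((sj, label[1]), (None, None))[1] == (si, sj)):
            retained.add((si, sj))
    return retained


# --- junction classification ------------------------------------------------

def classify_oracle(assembly_chroms, truth_chroms):
    """(relocations, translocations, inversions) by direct rule application.

    Both arguments are {chrom: [(contig, orient), ...]} dicts.
    """
    where = {}
    for chrom, entries in truth_chroms.items():
        for rank, (c, o) in enumerate(entries):
            where[c] = (chrom, rank, o)
    rel = tra = inv = 0
    for entries in assembly_chroms.values():
        for (ca, oa), (cb, ob) in zip(entries, entries[1:]):
            cha, ra, ta = where[ca]
            chb, rb, tb = where[cb]
            if cha != chb:
                tra += 1
                continue
            sa = 1 if oa == ta else -1
            sb = 1 if ob == tb else -1
            if sa != sb:
                inv += 1
            elif not ((sa == 1 and rb == ra + 1) or (sa == -1 and ra == rb + 1)):
                rel += 1
    return rel, tra, inv


# --- edit distance ----------------------------------------------------------

def _mirror(s):
    return tuple((c, -o) for c, o in reversed(s))


def _canon(s):
    m = _mirror(s)
    return s if s <= m else m


def state_of(chroms):
    return frozenset(_canon(tuple((c, 1 if o == "+" else -1) for c, o in e))
                     for e in chroms.values() if e)


def edit_moves_oracle(state):
    """All states one edit away (split / join / invert block / move block)."""
    out = set()
    scaffolds = sorted(state)
    for s in scaffolds:
        rest = state - {s}
        for cut in range(1, len(s)):
            out.add(rest | {_canon(s[:cut]), _canon(s[cut:])})
        for i in range(len(s)):
            for j in range(i + 1, len(s) + 1):
                if not (i == 0 and j == len(s)):
                    out.add(rest | {_canon(s[:i] + _mirror(s[i:j]) + s[j:])})
                remainder = s[:i] + s[j:]
                for block in (s[i:j], _mirror(s[i:j])):
                    if remainder:
                        for k in range(len(remainder) + 1):
                            out.add(rest | {_canon(remainder[:k] + block + remainder[k:])})
                        out.add(rest | {_canon(remainder), _canon(block)})
                    for t in sorted(rest):
                        trest = rest - {t}
                        for k in range(len(t) + 1):
                            ns = trest | {_canon(t[:k] + block + t[k:])}
                            if remainder:
                                ns = ns | {_canon(remainder)}
                            out.add(frozenset(ns))
    return {frozenset(x) for x in out}


def edit_distance_oracle(assembly_chroms, truth_chroms, max_depth=4):
    """Plain unidirectional BFS over layout states."""
    start, goal = state_of(assembly_chroms), state_of(truth_chroms)
    if start == goal:
        return 0
    seen = {start}
    queue = deque([(start, 0)])
    while queue:
        state, d = queue.popleft()
        if d >= max_depth:
            continue
        for nxt in edit_moves_oracle(state):
            if nxt == goal:
                return d + 1
            if nxt not in seen:
                seen.add(nxt)
                queue.append((nxt, d + 1))
    return None  # deeper than max_depth
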