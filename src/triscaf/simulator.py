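"""Seeded synthetic genomes, contig splitting, and Hi-C contact pairs.

The generative model follows the statistical structure Hi-C scaffolding
assumes: within a chromosome the contact probability at genomic
distance ``x`` decays as ``x**(-alpha)`` (alpha = 1 by default, the
canonical contact-decay law, truncated below ``x_min`` where the pure
power law diverges), a small fraction of pairs are trans (uniform loci
on two different chromosomes), and optional long-range enrichment
blocks add contacts between two distant intervals of one chromosome —
the TAD/compartment-like structure that violates monotone distance
decay and is the known failure mode of square-window counting.

Splitting a simulated genome into contigs yields the ground-truth
layout consumed by the evaluator, so every stage of the scaffolder is
testable end to end without external data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from triscaf.io_formats import ContactPair, SequenceRecord, TruthLayout

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for one simulated Hi-C experiment.

    chrom_lengths     chromosome lengths in bp
    n_pairs           number of base contact pairs to draw
    decay_exponent    alpha of the cis contact law density ~ x**(-alpha)
    x_min             lower truncation of the distance law, bp
    trans_fraction    probability that a pair is inter-chromosomal
    longrange_blocks  (chrom, start1, end1, start2, end2, weight): enrich
                      contacts between the two intervals to weight-fold
                      the sampled background count in that rectangle
    seed              RNG seed; all output is a pure function of it
    """

    chrom_lengths: list[int]
    n_pairs: int
    decay_exponent: float = 1.0
    x_min: int = 1000
    trans_fraction: float = 0.05
    longrange_blocks: list[tuple] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths or min(self.chrom_lengths) < 10_000:
            raise ValueError("chromosome lengths must be >= 10 kb")
        if not 0 <= self.trans_fraction <= 1:
            raise ValueError("trans_fraction must lie in [0, 1]")
        if self.x_min >= min(self.chrom_lengths):
            raise ValueError("x_min must be below the shortest chromosome")
        if self.x_min < 1:
            raise ValueError("x_min must be >= 1")
        for blk in self.longrange_blocks:
            chrom, s1, e1, s2, e2, weight = blk
            k = self.chrom_names().index(chrom) if isinstance(chrom, str) else chrom
            L = self.chrom_lengths[k]
            if not (0 <= s1 < e1 <= L and 0 <= s2 < e2 <= L):
                raise ValueError(f"block intervals outside chromosome bounds: {blk}")
            if weight < 1:
                raise ValueError("block weight must be >= 1")

    def chrom_names(self) -> list[str]:
        return [f"chr{k + 1}" for k in range(len(self.chrom_lengths))]


# ---------------------------------------------------------------------------
# genome generation and splitting
# ---------------------------------------------------------------------------

def make_genome(config: SimConfig) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Uniform-random ACGT chromosomes of the configured lengths.

    Returns the records plus a name -> length table.  Deterministic
    under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    for name, length in zip(config.chrom_names(), config.chrom_lengths):
        idx = rng.integers(0, 4, size=length)
        records.append(SequenceRecord(name, _BASES[idx].tobytes().decode("ascii")))
    return records, {r.id: r.length for r in records}


def split_genome(records: list[SequenceRecord], mode: str = "fixed",
                 size: int | None = None, gap_min: int | None = None,
                 ) -> tuple[list[SequenceRecord], TruthLayout]:
    """Cut chromosomes into contigs and record the ground-truth layout.

    ``fixed`` mode cuts consecutive ``size``-bp pieces (the last piece
    of a chromosome may be shorter); ``gap`` mode cuts at runs of N of
    length >= ``gap_min`` and strips the N's.  Truth orientations are
    all '+' since splitting never inverts.
    """
    contigs: list[SequenceRecord] = []
    chroms: dict[str, list[tuple[str, str]]] = {}
    if mode == "fixed":
        if size is None or size <= 0:
            raise ValueError("fixed mode requires a positive size")
        for rec in records:
            entries = []
            for k, start in enumerate(range(0, rec.length, size), start=1):
                cid = f"{rec.id}_c{k}"
                contigs.append(SequenceRecord(cid, rec.sequence[start:start + size]))
                entries.append((cid, "+"))
            chroms[rec.id] = entries
    elif mode == "gap":
        if gap_min is None or gap_min <= 0:
            raise ValueError("gap mode requires a positive gap_min")
        pattern = re.compile(f"N{{{gap_min},}}")
        for rec in records:
            entries = []
            k = 0
            for piece in pattern.split(rec.sequence):
                if not piece:
                    continue
                k += 1
                cid = f"{rec.id}_c{k}"
                contigs.append(SequenceRecord(cid, piece))
                entries.append((cid, "+"))
            chroms[rec.id] = entries
    else:
        raise ValueError("mode must be 'fixed' or 'gap'")
    return contigs, TruthLayout(chroms)


def split_lengths(config: SimConfig, size: int,
                  ) -> tuple[dict[str, int], TruthLayout]:
    """Fixed-size split of the configured chromosomes, lengths only.

    Equivalent to :func:`split_genome` in fixed mode but skips sequence
    generation; linking needs only contig lengths, so benchmarks that
    never touch bases use this fast path.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    contig_lengths: dict[str, int] = {}
    chroms: dict[str, list[tuple[str, str]]] = {}
    for name, L in zip(config.chrom_names(), config.chrom_lengths):
        entries = []
        for k, start in enumerate(range(0, L, size), start=1):
            cid = f"{name}_c{k}"
            contig_lengths[cid] = min(size, L - start)
            entries.append((cid, "+"))
        chroms[name] = entries
    return contig_lengths, TruthLayout(chroms)


# ---------------------------------------------------------------------------
# contact-pair simulation
# ---------------------------------------------------------------------------

def _sample_distances(rng: np.random.Generator, n: int, x_min: int, x_max: np.ndarray,
                      alpha: float) -> np.ndarray:
    """Inverse-CDF sampling from density ~ x**(-alpha) on [x_min, x_max]."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        x = x_min * (x_max / x_min) ** u
    else:
        a, b = float(x_min) ** (1 - alpha), x_max.astype(float) ** (1 - alpha)
        x = (a + u * (b - a)) ** (1 / (1 - alpha))
    return np.clip(x.astype(np.int64), x_min, x_max)


def _sample_cis_distances(rng: np.random.Generator, x_min: int, x_max: np.ndarray,
                          L: np.ndarray, alpha: float) -> np.ndarray:
    """Distances whose JOINT locus density is ~ x**(-alpha).

    The contact law gives the probability that two specific loci at
    separation x interact, so the density over locus pairs is
    f(p1, p2) ~ x**(-alpha); the marginal of x then carries an extra
    (L - x) factor for the number of feasible placements.  Sampling x
    from x**(-alpha) and thinning with acceptance probability
    (L - x)/L realizes exactly that joint density once the left
    endpoint is drawn uniformly.  Without the thinning, pairs spanning
    nearly the whole chromosome would pile up between the two
    chromosome termini — an artifact, not chromatin physics.
    """
    x = _sample_distances(rng, len(x_max), x_min, x_max, alpha)
    pending = np.flatnonzero(rng.random(len(x)) >= (L - x) / L)
    while len(pending):
        redraw = _sample_distances(rng, len(pending), x_min, x_max[pending], alpha)
        x[pending] = redraw
        accepted = rng.random(len(pending)) < (L[pending] - redraw) / L[pending]
        pending = pending[~accepted]
    return x


def simulate_pairs(config: SimConfig, layout: TruthLayout | None = None,
                   contig_lengths: dict[str, int] | None = None,
                   ) -> list[ContactPair]:
    """Draw contact pairs under the configured contact model.

    Cis pairs pick a chromosome proportional to length, a distance from
    the truncated power law, and a uniform feasible left endpoint.
    Trans pairs place both loci uniformly on two distinct chromosomes.
    Each long-range block then adds ``(weight - 1)`` times the sampled
    background count of its rectangle, uniformly inside the rectangle.

    When ``layout`` (plus ``contig_lengths``) is given, loci are emitted
    in contig coordinates through the truth layout; otherwise in
    chromosome coordinates.  Fully deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    names = config.chrom_names()
    lengths = np.asarray(config.chrom_lengths, dtype=np.int64)
    p_chrom = lengths / lengths.sum()

    n = config.n_pairs
    is_trans = rng.random(n) < config.trans_fraction
    n_cis = int((~is_trans).sum())
    n_trans = n - n_cis

    # cis: chromosome ~ length, distance ~ x^-alpha, left endpoint uniform
    cis_chrom = rng.choice(len(lengths), size=n_cis, p=p_chrom)
    x_max = lengths[cis_chrom] - 1
    x = _sample_cis_distances(rng, config.x_min, x_max, lengths[cis_chrom],
                              config.decay_exponent)
    left = rng.integers(0, lengths[cis_chrom] - x)

    # trans: two distinct chromosomes ~ length, uniform loci
    t1 = rng.choice(len(lengths), size=n_trans, p=p_chrom)
    t2 = rng.choice(len(lengths), size=n_trans, p=p_chrom)
    if len(lengths) > 1:
        while True:
            clash = t1 == t2
            if not clash.any():
                break
            t2[clash] = rng.choice(len(lengths), size=int(clash.sum()), p=p_chrom)
    tp1 = rng.integers(0, lengths[t1]) if n_trans else np.empty(0, dtype=np.int64)
    tp2 = rng.integers(0, lengths[t2]) if n_trans else np.empty(0, dtype=np.int64)

    chrom_a = np.concatenate([cis_chrom, t1])
    pos_a = np.concatenate([left, tp1])
    chrom_b = np.concatenate([cis_chrom, t2])
    pos_b = np.concatenate([left + x, tp2])

    # long-range enrichment: weight-fold the sampled background in each block
    for blk in config.longrange_blocks:
        chrom, s1, e1, s2, e2, weight = blk
        k = names.index(chrom) if isinstance(chrom, str) else int(chrom)
        same = (chrom_a == k) & (chrom_b == k)
        in_rect = same & (((pos_a >= s1) & (pos_a < e1) & (pos_b >= s2) & (pos_b < e2))
                          | ((pos_a >= s2) & (pos_a < e2) & (pos_b >= s1) & (pos_b < e1)))
        extra = int(round((weight - 1) * int(in_rect.sum())))
        if extra == 0:
            continue
        ea = rng.integers(s1, e1, size=extra)
        eb = rng.integers(s2, e2, size=extra)
        chrom_a = np.concatenate([chrom_a, np.full(extra, k)])
        pos_a = np.concatenate([pos_a, ea])
        chrom_b = np.concatenate([chrom_b, np.full(extra, k)])
        pos_b = np.concatenate([pos_b, eb])

    if layout is None:
        return [ContactPair.make(names[ca], int(pa), names[cb], int(pb))
                for ca, pa, cb, pb in zip(chrom_a, pos_a, chrom_b, pos_b)]
    if contig_lengths is None:
        raise ValueError("contig_lengths is required to emit contig coordinates")
    return _to_contig_coords(chrom_a, pos_a, chrom_b, pos_b, names, layout,
                             contig_lengths)


def _to_contig_coords(chrom_a, pos_a, chrom_b, pos_b, names, layout,
                      contig_lengths) -> list[ContactPair]:
    """Map chromosome-coordinate loci through a truth layout (all '+')."""
    bounds: dict[int, tuple[np.ndarray, list[str]]] = {}
    for k, name in enumerate(names):
        entries = layout.chromosomes.get(name, [])
        ids = [cid for cid, _ in entries]
        ends = np.cumsum([contig_lengths[cid] for cid in ids])
        bounds[k] = (ends, ids)

    def locate(k: int, pos: int) -> tuple[str, int]:
        ends, ids = bounds[int(k)]
        idx = int(np.searchsorted(ends, pos, side="right"))
        start = 0 if idx == 0 else int(ends[idx - 1])
        return ids[idx], pos - start

    out = []
    for ca, pa, cb, pb in zip(chrom_a, pos_a, chrom_b, pos_b):
        r1, p1 = locate(ca, int(pa))
        r2, p2 = locate(cb, int(pb))
        out.append(ContactPair.make(r1, p1, r2, p2))
    return out
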