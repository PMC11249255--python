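from __future__ import annotations

import random

import numpy as np
import pytest

from triscaf import (
    ScaffoldNode,
    SimConfig,
    simulate_pairs,
    split_lengths,
)
from triscaf.io_formats import ContactPair
from triscaf.linkgraph import Component


@pytest.fixture(scope="session")
def small_sim():
    """A small clean simulation: 5 chromosomes x 600 kb, 100 kb contigs.

    Coverage (120k pairs over 3 Mb) is ample per junction window, so a
    correct scaffolder should recover the truth exactly.
    """
    cfg = SimConfig(chrom_lengths=[600_000] * 5, n_pairs=120_000, seed=11)
    contig_lengths, truth = split_lengths(cfg, 100_000)
    pairs = simulate_pairs(cfg, truth, contig_lengths)
    return {"config": cfg, "contig_lengths": contig_lengths,
            "truth": truth, "pairs": pairs}


def random_scaffolds(rng: random.Random, n_scaffolds: int,
                     min_len: int = 50, max_len: int = 400,
                     ) -> list[ScaffoldNode]:
    """Random multi-component scaffolds over a disjoint contig universe."""
    scaffolds = []
    contig_no = 0
    for s in range(n_scaffolds):
        n_comp = rng.randint(1, 3)
        comps, offset = [], 0
        for _ in range(n_comp):
            length = rng.randint(min_len, max_len)
            comps.append(Component(f"c{contig_no}", offset, length,
                                   rng.choice("+-")))
            contig_no += 1
            offset += length
        scaffolds.append(ScaffoldNode(f"s{s}", offset, comps))
    return scaffolds


def random_pairs(rng: random.Random, scaffolds: list[ScaffoldNode],
                 n_pairs: int) -> list[ContactPair]:
    """Uniform random contact pairs across the scaffolds' contigs."""
    contigs = [(c.contig_id, c.length) for s in scaffolds for c in s.components]
    out = []
    for _ in range(n_pairs):
        (r1, l1), (r2, l2) = rng.choice(contigs), rng.choice(contigs)
        out.append(ContactPair.make(r1, rng.randrange(l1), r2, rng.randrange(l2)))
    return out


def random_layout(rng: random.Random, truth_chroms: dict,
                  n_scaffolds: int | None = None) -> dict:
    """A random reshuffling/reorienting of the truth's contigs."""
    contigs = [c for entries in truth_chroms.values() for c, _ in entries]
    rng.shuffle(contigs)
    k = n_scaffolds or rng.randint(1, max(1, len(contigs) // 2))
    cuts = sorted(rng.sample(range(1, len(contigs)), min(k - 1, len(contigs) - 1)))
    chroms, start = {}, 0
    for idx, cut in enumerate(cuts + [len(contigs)]):
        chroms[f"a{idx}"] = [(c, rng.choice("+-")) for c in contigs[start:cut]]
        start = cut
    return chroms


@pytest.fixture
def rng():
    return random.Random(1234)


@pytest.fixture
def np_rng():
    return np.random.default_rng(1234)
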