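"""Shared fixtures: small synthetic genomes with planted ground truth."""

import numpy as np
import pytest

from retrodup import synthgen as sg
from retrodup.synthgen import EventRegistry


@pytest.fixture(scope="session")
def small_world():
    """A 1 x 300 kb mask-free genome with one gene and a few retrocopies."""
    asm = sg.make_genome(1, 300_000, 0.0, 0.5, seed=21)
    reg = EventRegistry(asm)
    rng = np.random.default_rng(1)
    gene = sg.plant_gene(asm, reg, n_exons=3, exon_len=400, intron_len=500, rng=rng)
    retros = [
        sg.plant_retrocopy(asm, reg, gene, orientation=o, tsd_len=t,
                           polya_len=p, divergence=0.0, rng=rng)
        for o, t, p in [("+", 12, 14), ("-", 10, 9), ("+", 7, 0),
                        ("+", 0, 11), ("-", 15, 20)]
    ]
    return asm, reg, gene, retros


@pytest.fixture(scope="session")
def dup_world():
    """A 2 x 400 kb genome with masked repeats, genes, duplications and
    retrocopies, used by the alignment-stage tests."""
    asm = sg.make_genome(2, 400_000, 0.1, 0.45, seed=11)
    reg = EventRegistry(asm)
    rng = np.random.default_rng(42)
    genes = [
        sg.plant_gene(asm, reg, n_exons=4, exon_len=350, intron_len=600, rng=rng)
        for _ in range(4)
    ]

    def free_source(length):
        c, pos = reg.sample_site(rng, length)
        return (c, pos, pos + length)

    d1 = sg.plant_duplication(asm, reg, free_source(5000), 1, 0.02,
                              "dispersed", rng=rng)
    d2 = sg.plant_duplication(asm, reg, free_source(3000), 2, 0.01,
                              "tandem", rng=rng)
    retros = [
        sg.plant_retrocopy(
            asm, reg, genes[i % 4], orientation="+-"[i % 2],
            tsd_len=12, polya_len=12,
            truncation=0.0 if i % 3 else 0.2, divergence=0.02, rng=rng,
        )
        for i in range(6)
    ]
    return asm, reg, genes, [d1, d2], retros
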