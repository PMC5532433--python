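"""Single-copy-gene (SCG) sets used for completeness and representative scoring.

Completeness of a genome bin is the fraction of the domain's SCG set found at
least once (51 genes for bacteria, 38 for archaea).  The genes themselves are
represented as named toy cassettes: each SCG name maps deterministically to a
short nucleotide tag that the synthetic-community generator embeds verbatim
in genomes and the scanner recovers by exact match.  The cassettes are
synthetic stand-ins for real profile models and carry no biological sequence.
"""

from __future__ import annotations

import zlib

import numpy as np

BACTERIAL_SCGS: tuple[str, ...] = tuple(
    [f"rpL{i}" for i in (1, 2, 3, 4, 5, 6, 9, 10, 11, 13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 24)]
    + [f"rpS{i}" for i in (2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 15, 16, 17, 18, 19, 20)]
    + ["gyrA", "gyrB", "recA", "secY", "infB", "rpoA", "rpoB", "rpoC",
       "ffh", "nusA", "pgk", "tsf", "frr"]
)
ARCHAEAL_SCGS: tuple[str, ...] = tuple(
    [f"arpL{i}" for i in (1, 2, 3, 4, 5, 6, 10, 11, 13, 14, 15, 18, 22, 24, 29, 30)]
    + [f"arpS{i}" for i in (2, 3, 4, 5, 6, 7, 8, 9, 11, 13, 15, 17, 19)]
    + ["aSecY", "aInfB", "aRpoA", "aRpoB", "aEF2", "aPgk", "aTsf", "aFfh", "aNusA"]
)
assert len(BACTERIAL_SCGS) == 51 and len(set(BACTERIAL_SCGS)) == 51
assert len(ARCHAEAL_SCGS) == 38 and len(set(ARCHAEAL_SCGS)) == 38

SCG_SETS: dict[str, tuple[str, ...]] = {
    "bacteria": BACTERIAL_SCGS,
    "archaea": ARCHAEAL_SCGS,
}

CASSETTE_LEN = 60
_NUC = np.frombuffer(b"ACGT", dtype=np.uint8)


def scg_cassette_sequence(name: str) -> str:
    """Deterministic synthetic cassette tag for an SCG name."""
    rng = np.random.default_rng(zlib.crc32(f"scg::{name}".encode()))
    return bytes(_NUC[rng.integers(0, 4, CASSETTE_LEN)]).decode()


def count_scg_cassettes(scaffold_sequences: list[str], domain_tag: str) -> dict[str, int]:
    """Occurrences of each of the domain's SCG cassettes across scaffolds."""
    if domain_tag not in SCG_SETS:
        raise ValueError(f"unknown domain_tag {domain_tag!r}")
    counts: dict[str, int] = {}
    for name in SCG_SETS[domain_tag]:
        tag = scg_cassette_sequence(name)
        n = 0
        for seq in scaffold_sequences:
            start = 0
            while True:
                hit = seq.find(tag, start)
                if hit < 0:
                    break
                n += 1
                start = hit + 1
        counts[name] = n
    return counts
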