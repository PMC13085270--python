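"""Split-reference assembly generation and synthetic genome fixtures.

``split_reference`` cuts each chromosome of a reference into consecutive
equal-size pieces (presets 10 kb .. 1 Mb) with a ground-truth layout;
``make_synthetic_genome`` builds seeded random genomes with controllable
GC, repeat content and haplotig-like redundant contigs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .assembly_io import SequenceRecord
from .errors import ScafevalError
from .layout import FORWARD, GenomeLayout, OrientedContig

logger = logging.getLogger(__name__)

#: The preset piece sizes, in bp.
PIECE_SIZE_PRESETS = {
    "10kb": 10_000,
    "50kb": 50_000,
    "100kb": 100_000,
    "500kb": 500_000,
    "1mb": 1_000_000,
}


@dataclass
class SplitSpec:
    piece_size: int
    min_piece: int | None = None  # default piece_size // 2
    name_template: str = "{chrom}_piece{ordinal}"

    def __post_init__(self) -> None:
        if self.piece_size < 1:
            raise ScafevalError("piece_size must be >= 1")
        if self.min_piece is None:
            self.min_piece = self.piece_size // 2
        if self.min_piece > self.piece_size:
            raise ScafevalError("min_piece must be <= piece_size")


def piece_boundaries(length: int, spec: SplitSpec) -> list[tuple[int, int]]:
    """Cut points for one chromosome, 0-based half-open.

    Consecutive pieces of exactly ``piece_size``; a trailing remainder is
    kept as its own piece when >= ``min_piece``, else merged into the
    previous piece.  A chromosome shorter than a full piece is emitted
    whole.
    """
    bounds = []
    pos = 0
    while pos + spec.piece_size <= length:
        bounds.append((pos, pos + spec.piece_size))
        pos += spec.piece_size
    rem = length - pos
    if rem:
        if rem >= spec.min_piece or not bounds:
            if not bounds and rem < spec.min_piece:
                logger.warning(
                    "chromosome of %d bp shorter than min_piece %d; emitted "
                    "as a single piece",
                    length,
                    spec.min_piece,
                )
            bounds.append((pos, length))
        else:
            s, _ = bounds[-1]
            bounds[-1] = (s, length)
    return bounds


def split_reference(
    genome: list[SequenceRecord], spec: SplitSpec
) -> tuple[list[SequenceRecord], GenomeLayout]:
    """Fragment a genome into pieces plus the matching truth layout.

    Pieces are emitted in genomic order, all forward; concatenating the
    pieces of a chromosome reproduces its sequence exactly.
    """
    pieces = []
    groups: dict[str, list[OrientedContig]] = {}
    for chrom in genome:
        if not chrom.sequence:
            raise ScafevalError(f"chromosome {chrom.name!r} is empty")
        contigs = []
        for ordinal, (s, e) in enumerate(
            piece_boundaries(len(chrom.sequence), spec)
        ):
            name = spec.name_template.format(chrom=chrom.name, ordinal=ordinal)
            pieces.append(SequenceRecord(name, chrom.sequence[s:e]))
            contigs.append(OrientedContig(name, FORWARD, e - s))
        groups[chrom.name] = contigs
    return pieces, GenomeLayout(groups)


BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < divergence)[0]
    arr[hits] = rng.choice(BASES, size=hits.size)
    return arr.tobytes().decode()


def make_synthetic_genome(
    n_chromosomes: int,
    length_range: tuple[int, int],
    gc: float = 0.5,
    repeat_fraction: float = 0.0,
    haplotig_fraction: float = 0.0,
    haplotig_divergence: float = 0.02,
    repeat_unit: int = 500,
    seed: int = 0,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Seeded multi-chromosome random genome with optional confounds.

    ``repeat_fraction`` of each chromosome is overwritten with copies
    drawn from a small shared repeat library (multi-mapping ambiguity);
    haplotigs are ~``haplotig_divergence``-mutated copies of random
    chromosome sub-intervals whose total length approximates
    ``haplotig_fraction`` of the genome.
    """
    if n_chromosomes < 1:
        raise ScafevalError("need at least one chromosome")
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ScafevalError(f"bad length_range {length_range}")
    if not (0 <= gc <= 1 and 0 <= repeat_fraction < 1 and 0 <= haplotig_fraction < 1):
        raise ScafevalError("fractions must be within [0, 1)")
    rng = np.random.default_rng(seed)
    repeat_library = [
        _random_sequence(rng, repeat_unit, gc) for _ in range(3)
    ]
    chroms = []
    for i in range(n_chromosomes):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_sequence(rng, length, gc)
        if repeat_fraction > 0 and length > repeat_unit:
            n_copies = int(repeat_fraction * length / repeat_unit)
            arr = np.frombuffer(seq.encode(), dtype="S1").copy()
            for _ in range(n_copies):
                unit = repeat_library[int(rng.integers(len(repeat_library)))]
                pos = int(rng.integers(0, length - repeat_unit))
                arr[pos : pos + repeat_unit] = np.frombuffer(
                    unit.encode(), dtype="S1"
                )
            seq = arr.tobytes().decode()
        chroms.append(SequenceRecord(f"chr{i + 1:02d}", seq))
    haplotigs = []
    if haplotig_fraction > 0:
        genome_len = sum(len(c.sequence) for c in chroms)
        target = haplotig_fraction * genome_len
        acc = 0
        k = 0
        while acc < target:
            chrom = chroms[int(rng.integers(n_chromosomes))]
            size = int(rng.integers(lo // 20 + 1, max(lo // 5, lo // 20 + 2)))
            size = min(size, len(chrom.sequence))
            pos = int(rng.integers(0, len(chrom.sequence) - size + 1))
            sub = chrom.sequence[pos : pos + size]
            haplotigs.append(
                SequenceRecord(
                    f"haplotig{k:03d}",
                    _mutate(rng, sub, haplotig_divergence),
                )
            )
            acc += size
            k += 1
    return chroms, haplotigs
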