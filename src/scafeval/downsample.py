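"""Hi-C read-pair downsampling to a target density in reads per kilobase.

The unit of counting is the read pair (the contact): read length does
not contribute.  Density presets mirror the coverage-titration design
(1, 50, 100, 500, 1000 pairs per kilobase).  A ``reads`` counting mode
is exposed for pipelines that count individual reads (2 per pair).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from os import PathLike

import numpy as np
import pysam

from .errors import ParseError, ScafevalError

DENSITY_PRESETS = (1, 50, 100, 500, 1000)


@dataclass(frozen=True)
class ReadPairRecord:
    pair_id: str
    contig1: str
    pos1: int
    contig2: str
    pos2: int
    duplicate_flag: bool = False


@dataclass(frozen=True)
class DownsampleSpec:
    target_density: float  # pairs per kilobase
    seed: int = 0
    unit: str = "pairs"  # or "reads": 2 reads per pair

    def __post_init__(self) -> None:
        if self.target_density <= 0:
            raise ScafevalError("target_density must be > 0")
        if self.unit not in ("pairs", "reads"):
            raise ScafevalError(f"unknown counting unit {self.unit!r}")


def downsample_pairs(
    pairs: list[ReadPairRecord],
    assembly_length: int,
    spec: DownsampleSpec,
) -> list[ReadPairRecord]:
    """Uniform subsample without replacement to the target density.

    keep_count = floor(target_density x assembly_length / 1000), halved
    when counting reads rather than pairs.  The retained subset preserves
    the original list order and is fully determined by the seed.  When
    the target exceeds availability all pairs are returned with a
    warning.
    """
    if assembly_length <= 0:
        raise ScafevalError("assembly_length must be positive")
    density = spec.target_density
    if spec.unit == "reads":
        density /= 2
    keep_count = int(density * assembly_length / 1000)
    if keep_count >= len(pairs):
        if keep_count > len(pairs):
            warnings.warn(
                f"target retains {keep_count} pairs but only {len(pairs)} "
                "available; returning all",
                stacklevel=2,
            )
        return list(pairs)
    rng = np.random.default_rng(spec.seed)
    idx = rng.choice(len(pairs), size=keep_count, replace=False)
    idx.sort()
    return [pairs[i] for i in idx]


def density(pairs: list[ReadPairRecord], assembly_length: int) -> float:
    """Pairs per kilobase of assembly."""
    if assembly_length <= 0:
        raise ScafevalError("assembly_length must be positive")
    return len(pairs) / (assembly_length / 1000)


# -- boundary I/O --------------------------------------------------------

_TSV_FIELDS = ("pair_id", "contig1", "pos1", "contig2", "pos2")


def read_pairs_tsv(path: str | PathLike) -> list[ReadPairRecord]:
    pairs = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, 1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 5:
                raise ParseError(
                    f"expected 5 columns {_TSV_FIELDS}, got {len(row)}", lineno
                )
            try:
                pairs.append(
                    ReadPairRecord(row[0], row[1], int(row[2]), row[3], int(row[4]))
                )
            except ValueError as exc:
                raise ParseError(f"bad position: {exc}", lineno)
    return pairs


def write_pairs_tsv(pairs: list[ReadPairRecord], path: str | PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_TSV_FIELDS) + "\n")
        for p in pairs:
            fh.write(f"{p.pair_id}\t{p.contig1}\t{p.pos1}\t{p.contig2}\t{p.pos2}\n")


def read_pairs_sam(path: str | PathLike) -> list[ReadPairRecord]:
    """Extract deduplicated read pairs from a SAM/BAM file.

    Secondary, supplementary, unmapped and duplicate-flagged records are
    skipped; the two primary ends of each template form one pair.
    """
    ends: dict[str, tuple[str, int]] = {}
    pairs = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for aln in sam:
            if (
                aln.is_unmapped
                or aln.is_secondary
                or aln.is_supplementary
                or aln.is_duplicate
            ):
                continue
            key = aln.query_name
            if key in ends:
                c1, p1 = ends.pop(key)
                pairs.append(
                    ReadPairRecord(key, c1, p1, aln.reference_name, aln.reference_start)
                )
            else:
                ends[key] = (aln.reference_name, aln.reference_start)
    return pairs
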