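"""Contig-to-reference alignment parsing and placement inference.

Readers for MUMmer 4 ``show-coords`` tabular output and PAF produce a
common :class:`AlignmentRecord` stream; :func:`place_contigs` reduces
these to one inferred true location per contig, from which
:func:`build_reference_layout` builds the truth layout.

Internal coordinates are 0-based half-open everywhere.  show-coords is
1-based inclusive and converted on read; PAF is native 0-based half-open
and passes through.

Placement rule (the source methodology is silent on this): the winning
chromosome is the one with the largest summed aligned bases, overlapping
hits merged by interval union on the contig so tandem split alignments
are not double counted; position is the aligned-length-weighted midpoint
of the winner's hits; orientation is the strand carrying the majority of
the winner's aligned bases.  Contigs aligning below
``min_aligned_fraction`` are unplaced; a runner-up chromosome holding at
least 30% of the total aligned bases sets ``chimeric_flag``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from os import PathLike

from .errors import ParseError, ScafevalError
from .layout import FORWARD, GenomeLayout, OrientedContig

logger = logging.getLogger(__name__)

CHIMERIC_RUNNER_UP_SHARE = 0.30
DEFAULT_MIN_ALIGNED_FRACTION = 0.5

UNPLACED = None


@dataclass(frozen=True)
class AlignmentRecord:
    """One alignment of a contig interval to a reference interval.

    Coordinates are 0-based half-open; strand refers to the contig
    relative to the reference.
    """

    ref_name: str
    ref_start: int
    ref_end: int
    contig_name: str
    contig_start: int
    contig_end: int
    strand: str
    aligned_bases: int
    identity: float


@dataclass(frozen=True)
class ContigPlacement:
    contig_id: str
    chromosome: str | None  # None = unplaced
    position: float
    orientation: str
    aligned_fraction: float
    chimeric_flag: bool

    @property
    def placed(self) -> bool:
        return self.chromosome is not None


_COORDS_SKIP_PREFIXES = ("=", "[", "/", "NUCMER", "PROMER")


def read_coords(path: str | PathLike) -> list[AlignmentRecord]:
    """Parse MUMmer 4 show-coords output (default or -T layout).

    Expects the positional columns S1 E1 S2 E2 LEN1 LEN2 %IDY REF QRY;
    separator pipes are tolerated.  Reverse-strand rows (query start >
    query end) are normalized to ascending coordinates with strand '-'.
    """
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(_COORDS_SKIP_PREFIXES):
                continue
            tokens = [t for t in line.replace("|", " ").split() if t]
            if len(tokens) < 9:
                # header lines like "1 1000" alone are malformed; but allow
                # the two-path header show-coords prints first
                if lineno <= 2 and all(not t[0].isdigit() for t in tokens):
                    continue
                raise ParseError(
                    f"expected >= 9 columns, got {len(tokens)}", lineno
                )
            try:
                s1, e1, s2, e2 = (int(t) for t in tokens[:4])
                identity = float(tokens[6])
            except ValueError as exc:
                raise ParseError(f"non-numeric position field: {exc}", lineno)
            ref_name, contig_name = tokens[-2], tokens[-1]
            if s2 <= e2:
                strand = "+"
                qs, qe = s2, e2
            else:
                strand = "-"
                qs, qe = e2, s2
            records.append(
                AlignmentRecord(
                    ref_name=ref_name,
                    ref_start=s1 - 1,
                    ref_end=e1,
                    contig_name=contig_name,
                    contig_start=qs - 1,
                    contig_end=qe,
                    strand=strand,
                    aligned_bases=qe - qs + 1,
                    identity=identity,
                )
            )
    return records


def read_paf(path: str | PathLike) -> list[AlignmentRecord]:
    """Parse a PAF file (12+ tab-separated mandatory fields).

    Identity is residue matches / alignment block length x 100;
    aligned_bases is the residue-matches field.
    """
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"PAF row has {len(fields)} fields, expected >= 12", lineno
                )
            try:
                qname = fields[0]
                qstart, qend = int(fields[2]), int(fields[3])
                strand = fields[4]
                tname = fields[5]
                tstart, tend = int(fields[7]), int(fields[8])
                matches, block = int(fields[9]), int(fields[10])
            except ValueError as exc:
                raise ParseError(f"bad PAF field: {exc}", lineno)
            records.append(
                AlignmentRecord(
                    ref_name=tname,
                    ref_start=tstart,
                    ref_end=tend,
                    contig_name=qname,
                    contig_start=qstart,
                    contig_end=qend,
                    strand=strand,
                    aligned_bases=matches,
                    identity=100.0 * matches / block if block else 0.0,
                )
            )
    return records


def _interval_union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    end = -1
    for s, e in sorted(intervals):
        if s > end:
            total += e - s
            end = e
        elif e > end:
            total += e - end
            end = e
    return total


def place_contigs(
    records: list[AlignmentRecord],
    contig_lengths: dict[str, int],
    min_aligned_fraction: float = DEFAULT_MIN_ALIGNED_FRACTION,
) -> list[ContigPlacement]:
    """Infer one placement per contig from its alignment records."""
    by_contig: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        if rec.contig_name not in contig_lengths:
            raise ScafevalError(
                f"contig {rec.contig_name!r} has alignments but no known "
                "length"
            )
        by_contig.setdefault(rec.contig_name, []).append(rec)

    placements = []
    for cid in sorted(by_contig):
        # canonical record order makes float accumulation independent of
        # input row order
        recs = sorted(
            by_contig[cid],
            key=lambda r: (r.ref_name, r.ref_start, r.ref_end,
                           r.contig_start, r.contig_end, r.strand),
        )
        length = contig_lengths[cid]
        by_chrom: dict[str, list[AlignmentRecord]] = {}
        for rec in recs:
            by_chrom.setdefault(rec.ref_name, []).append(rec)
        # union of contig intervals per chromosome avoids double counting
        chrom_bases = {
            chrom: _interval_union_length(
                [(r.contig_start, r.contig_end) for r in rs]
            )
            for chrom, rs in by_chrom.items()
        }
        ranked = sorted(
            chrom_bases.items(), key=lambda kv: (-kv[1], kv[0])
        )
        winner, winner_bases = ranked[0]
        total_bases = sum(chrom_bases.values())
        chimeric = (
            len(ranked) > 1
            and ranked[1][1] >= CHIMERIC_RUNNER_UP_SHARE * total_bases
        )
        fraction = min(winner_bases / length, 1.0)
        if fraction < min_aligned_fraction:
            placements.append(
                ContigPlacement(cid, UNPLACED, 0.0, FORWARD, fraction, chimeric)
            )
            continue
        wrecs = by_chrom[winner]
        weights = [r.aligned_bases for r in wrecs]
        mids = [(r.ref_start + r.ref_end) / 2 for r in wrecs]
        position = sum(w * m for w, m in zip(weights, mids)) / sum(weights)
        fwd = sum(r.aligned_bases for r in wrecs if r.strand == "+")
        rev = sum(r.aligned_bases for r in wrecs if r.strand == "-")
        orientation = "+" if fwd >= rev else "-"
        placements.append(
            ContigPlacement(cid, winner, position, orientation, fraction, chimeric)
        )
    return placements


def build_reference_layout(
    placements: list[ContigPlacement],
    contig_lengths: dict[str, int],
) -> GenomeLayout:
    """Build the truth layout: one group per chromosome, contigs sorted by
    inferred position (ties broken by contig id), group order
    lexicographic by chromosome name."""
    placed = [p for p in placements if p.placed]
    if not placed:
        raise ScafevalError("no contigs could be placed")
    unplaced = [p.contig_id for p in placements if not p.placed]
    if unplaced:
        logger.info("%d contigs unplaced: %s", len(unplaced), unplaced[:10])
    groups: dict[str, list[OrientedContig]] = {}
    by_chrom: dict[str, list[ContigPlacement]] = {}
    for p in placed:
        by_chrom.setdefault(p.chromosome, []).append(p)
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda p: (p.position, p.contig_id))
        groups[chrom] = [
            OrientedContig(p.contig_id, p.orientation, contig_lengths[p.contig_id])
            for p in ordered
        ]
    return GenomeLayout(groups)
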