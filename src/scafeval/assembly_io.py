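"""FASTA and AGP v2.1 reading/writing, and layout extraction from
scaffold FASTA by exact substring matching.

AGP coordinates are 1-based inclusive on disk and converted at this
boundary; gap rows are preserved as metadata but carry no metric weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from os import PathLike
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import reverse_complement

from .errors import ParseError, ScafevalError
from .layout import FORWARD, REVERSE, GenomeLayout, OrientedContig


@dataclass
class SequenceRecord:
    name: str
    sequence: str


@dataclass
class AgpRow:
    """One line of an AGP v2.1 file (component or gap)."""

    object_name: str
    object_start: int  # 1-based inclusive
    object_end: int
    part_number: int
    component_type: str  # W for contigs, N/U for gaps
    # W fields
    component_id: str | None = None
    component_start: int | None = None
    component_end: int | None = None
    orientation: str | None = None
    # gap fields
    gap_length: int | None = None
    gap_type: str | None = None
    linkage: str | None = None

    @property
    def is_gap(self) -> bool:
        return self.component_type in ("N", "U")

    def to_line(self) -> str:
        if self.is_gap:
            fields = [
                self.object_name,
                self.object_start,
                self.object_end,
                self.part_number,
                self.component_type,
                self.gap_length,
                self.gap_type,
                self.linkage,
                "na",
            ]
        else:
            fields = [
                self.object_name,
                self.object_start,
                self.object_end,
                self.part_number,
                self.component_type,
                self.component_id,
                self.component_start,
                self.component_end,
                self.orientation,
            ]
        return "\t".join(str(f) for f in fields)


# -- FASTA ---------------------------------------------------------------


def read_fasta(path: str | PathLike) -> list[SequenceRecord]:
    """Read a FASTA file; names must be unique and sequences non-empty."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate FASTA record name {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ParseError(f"FASTA record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    path: str | PathLike,
    line_width: int = 60,
) -> None:
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i : i + line_width] + "\n")


# -- AGP -----------------------------------------------------------------

_SOFT_ORIENTATIONS = {"?", "0", "na"}


def read_agp_rows(path: str | PathLike) -> list[AgpRow]:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ParseError(
                    f"AGP row has {len(fields)} fields, expected >= 8", lineno
                )
            try:
                obj, start, end, part, ctype = (
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    int(fields[3]),
                    fields[4],
                )
            except ValueError as exc:
                raise ParseError(f"bad AGP coordinates: {exc}", lineno)
            if ctype in ("N", "U"):
                rows.append(
                    AgpRow(
                        obj,
                        start,
                        end,
                        part,
                        ctype,
                        gap_length=int(fields[5]),
                        gap_type=fields[6],
                        linkage=fields[7],
                    )
                )
            elif ctype == "W":
                if len(fields) < 9:
                    raise ParseError("W row needs 9 fields", lineno)
                rows.append(
                    AgpRow(
                        obj,
                        start,
                        end,
                        part,
                        ctype,
                        component_id=fields[5],
                        component_start=int(fields[6]),
                        component_end=int(fields[7]),
                        orientation=fields[8],
                    )
                )
            else:
                raise ParseError(
                    f"unsupported AGP component type {ctype!r}", lineno
                )
    return rows


def _validate_agp(rows: list[AgpRow]) -> None:
    last_part: dict[str, int] = {}
    for row in rows:
        span = row.object_end - row.object_start + 1
        expect = (
            row.gap_length
            if row.is_gap
            else row.component_end - row.component_start + 1
        )
        if span != expect:
            raise ScafevalError(
                f"AGP span mismatch in object {row.object_name!r} part "
                f"{row.part_number}: object span {span} != component span "
                f"{expect}"
            )
        prev = last_part.get(row.object_name)
        if prev is not None and row.part_number != prev + 1:
            raise ScafevalError(
                f"non-monotone part numbers in object {row.object_name!r}: "
                f"{prev} followed by {row.part_number}"
            )
        last_part[row.object_name] = row.part_number


def read_agp(path: str | PathLike) -> tuple[GenomeLayout, list[AgpRow]]:
    """Read an AGP file into a layout; gap rows returned as metadata.

    Orientations '?', '0' and 'na' are mapped to '+' with a warning, since
    the metrics need a concrete orientation.
    """
    rows = read_agp_rows(path)
    _validate_agp(rows)
    groups: dict[str, list[OrientedContig]] = {}
    for row in rows:
        if row.is_gap:
            continue
        orient = row.orientation
        if orient in _SOFT_ORIENTATIONS:
            warnings.warn(
                f"AGP component {row.component_id!r} has orientation "
                f"{orient!r}; treating as '+'",
                stacklevel=2,
            )
            orient = FORWARD
        length = row.component_end - row.component_start + 1
        groups.setdefault(row.object_name, []).append(
            OrientedContig(row.component_id, orient, length)
        )
    if not groups:
        raise ScafevalError(f"AGP file {path} contains no W rows")
    return GenomeLayout(groups), [r for r in rows if r.is_gap]


def layout_to_agp_rows(
    layout: GenomeLayout, gap_length: int = 100, gap_type: str = "scaffold"
) -> list[AgpRow]:
    rows = []
    for name, contigs in layout.groups.items():
        pos = 1
        part = 1
        for i, contig in enumerate(contigs):
            if i > 0:
                rows.append(
                    AgpRow(
                        name,
                        pos,
                        pos + gap_length - 1,
                        part,
                        "N",
                        gap_length=gap_length,
                        gap_type=gap_type,
                        linkage="yes",
                    )
                )
                pos += gap_length
                part += 1
            rows.append(
                AgpRow(
                    name,
                    pos,
                    pos + contig.length - 1,
                    part,
                    "W",
                    component_id=contig.id,
                    component_start=1,
                    component_end=contig.length,
                    orientation=contig.orientation,
                )
            )
            pos += contig.length
            part += 1
    return rows


def write_agp(
    layout: GenomeLayout,
    path: str | PathLike,
    gap_length: int = 100,
    gap_type: str = "scaffold",
) -> None:
    rows = layout_to_agp_rows(layout, gap_length=gap_length, gap_type=gap_type)
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for row in rows:
            fh.write(row.to_line() + "\n")


# -- scaffold FASTA -> layout -------------------------------------------


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def layout_from_scaffold_fasta(
    scaffold_records: list[SequenceRecord],
    contig_records: list[SequenceRecord],
    min_match: int = 1,
) -> tuple[GenomeLayout, list[str]]:
    """Reconstruct the contig layout of scaffolds by exact substring search.

    Each contig (and its reverse complement) is located verbatim within
    the scaffold sequences.  Returns the layout plus the list of contigs
    found in no scaffold (unscaffolded).  A contig found at more than one
    locus raises an ambiguity error; callers may fall back to
    alignment-based placement.
    """
    scaffolds = {r.name: r.sequence.upper() for r in scaffold_records}
    hits: dict[str, list[tuple[str, int, str]]] = {}
    unscaffolded = []
    for contig in contig_records:
        if len(contig.sequence) < min_match:
            unscaffolded.append(contig.name)
            continue
        fwd = contig.sequence.upper()
        rev = reverse_complement(fwd)
        found: list[tuple[str, int, str]] = []
        for sname, sseq in scaffolds.items():
            for pos in _find_all(sseq, fwd):
                found.append((sname, pos, FORWARD))
            if rev != fwd:
                for pos in _find_all(sseq, rev):
                    found.append((sname, pos, REVERSE))
        if not found:
            unscaffolded.append(contig.name)
        elif len(found) > 1:
            loci = ", ".join(f"{s}:{p}({o})" for s, p, o in found)
            raise ScafevalError(
                f"contig {contig.name!r} found at multiple loci: {loci}"
            )
        else:
            hits[contig.name] = found
    lengths = {r.name: len(r.sequence) for r in contig_records}
    groups: dict[str, list[OrientedContig]] = {}
    placed = sorted(
        ((s, p, o, cid) for cid, [(s, p, o)] in hits.items()),
        key=lambda t: (t[0], t[1]),
    )
    for sname, pos, orient, cid in placed:
        groups.setdefault(sname, []).append(
            OrientedContig(cid, orient, lengths[cid])
        )
    if not groups:
        raise ScafevalError("no contig could be located in any scaffold")
    return GenomeLayout(groups), unscaffolded
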