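"""Canonical in-memory representation of genome layouts.

A layout is an ordered collection of named groups (chromosomes or
scaffolds), each an ordered list of oriented contigs.  Layouts convert to
an adjacency/telomere set over contig extremities, which is the
signed-permutation view all rearrangement metrics operate on.

Conventions
-----------
* All groups are linear; circular chromosomes are not supported.
* A contig's *head* is its 3' end in forward orientation, the *tail* its
  5' end.  A forward contig is read tail->head, a reversed contig
  head->tail.
* Extremities are ``(contig_id, "head"|"tail")`` tuples; adjacencies are
  unordered pairs of extremities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from .errors import LayoutError

FORWARD = "+"
REVERSE = "-"
HEAD = "head"
TAIL = "tail"

#: An extremity of a contig: (contig_id, HEAD or TAIL).
Extremity = tuple[str, str]

#: An unordered pair of extremities.
Adjacency = frozenset


@dataclass(frozen=True)
class OrientedContig:
    """A contig with an orientation inside one layout group."""

    id: str
    orientation: str
    length: int

    def __post_init__(self) -> None:
        if self.orientation not in (FORWARD, REVERSE):
            raise LayoutError(
                f"contig {self.id!r}: orientation must be '+' or '-', "
                f"got {self.orientation!r}"
            )
        if self.length < 1:
            raise LayoutError(f"contig {self.id!r}: length must be >= 1")

    def flipped(self) -> "OrientedContig":
        other = REVERSE if self.orientation == FORWARD else FORWARD
        return OrientedContig(self.id, other, self.length)

    @property
    def left_extremity(self) -> Extremity:
        """Extremity encountered first in reading direction."""
        return (self.id, TAIL if self.orientation == FORWARD else HEAD)

    @property
    def right_extremity(self) -> Extremity:
        return (self.id, HEAD if self.orientation == FORWARD else TAIL)


@dataclass
class GenomeLayout:
    """Ordered, oriented contig lists per named group.

    ``groups`` maps group name -> list of :class:`OrientedContig`; insertion
    order of the mapping is the group order.  Every contig id must be
    unique across the whole layout and every group must be non-empty.
    """

    groups: dict[str, list[OrientedContig]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for name, contigs in self.groups.items():
            if not contigs:
                raise LayoutError(f"group {name!r} is empty")
            for c in contigs:
                if c.id in seen:
                    raise LayoutError(f"duplicate contig id {c.id!r} in layout")
                seen.add(c.id)

    # -- queries ---------------------------------------------------------

    def contigs(self) -> Iterator[OrientedContig]:
        for contigs in self.groups.values():
            yield from contigs

    def contig_ids(self) -> set[str]:
        return {c.id for c in self.contigs()}

    def contig_lengths(self) -> dict[str, int]:
        return {c.id: c.length for c in self.contigs()}

    def n_contigs(self) -> int:
        return sum(len(g) for g in self.groups.values())

    def n_groups(self) -> int:
        return len(self.groups)

    def copy(self) -> "GenomeLayout":
        return GenomeLayout({name: list(g) for name, g in self.groups.items()})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeLayout):
            return NotImplemented
        return self.groups == other.groups


@dataclass(frozen=True)
class AdjacencySet:
    """Adjacency/telomere decomposition of a layout's extremities."""

    adjacencies: frozenset  # of frozenset({ext, ext})
    telomeres: frozenset  # of Extremity

    def pairing(self) -> dict[Extremity, Extremity | None]:
        """Map each extremity to its partner, or None for telomeres."""
        out: dict[Extremity, Extremity | None] = {t: None for t in self.telomeres}
        for adj in self.adjacencies:
            a, b = tuple(adj)
            out[a] = b
            out[b] = a
        return out


def layout_to_adjacencies(layout: GenomeLayout) -> AdjacencySet:
    """Extremity pairing induced by contig order and orientation.

    Group ends become telomeres.  For a layout with G linear groups and N
    contigs the result has N - G adjacencies and 2G telomeres.
    """
    adjacencies: list[Adjacency] = []
    telomeres: list[Extremity] = []
    layout.validate()
    for contigs in layout.groups.values():
        telomeres.append(contigs[0].left_extremity)
        for prev, cur in zip(contigs, contigs[1:]):
            adjacencies.append(
                frozenset((prev.right_extremity, cur.left_extremity))
            )
        telomeres.append(contigs[-1].right_extremity)
    return AdjacencySet(frozenset(adjacencies), frozenset(telomeres))


def restrict_layout(layout: GenomeLayout, keep: Iterable[str]) -> GenomeLayout:
    """Drop contigs not in ``keep``, splicing their neighbours together.

    Relative order and orientations of kept contigs are preserved; groups
    left empty are removed.
    """
    keep = set(keep)
    unknown = keep - layout.contig_ids()
    if unknown:
        raise LayoutError(
            "restrict_layout: unknown contig ids: " + ", ".join(sorted(unknown))
        )
    groups: dict[str, list[OrientedContig]] = {}
    for name, contigs in layout.groups.items():
        kept = [c for c in contigs if c.id in keep]
        if kept:
            groups[name] = kept
    return GenomeLayout(groups)


def total_length(layout: GenomeLayout) -> int:
    """Sum of contig lengths over all groups, in bp."""
    return sum(c.length for c in layout.contigs())


def reverse_group(layout: GenomeLayout, name: str) -> GenomeLayout:
    """Return a copy with one group reversed (order and orientations)."""
    if name not in layout.groups:
        raise LayoutError(f"no group named {name!r}")
    groups = {n: list(g) for n, g in layout.groups.items()}
    groups[name] = [c.flipped() for c in reversed(groups[name])]
    return GenomeLayout(groups)
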