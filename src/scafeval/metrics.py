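"""Accuracy metrics between a proposed scaffold layout and a truth layout.

Five metrics are computed over the contigs shared by the two layouts:

* ``dcj_distance`` — minimum number of double-cut-and-join operations
  transforming one layout into the other.
* ``overall_accuracy`` — length fraction of contigs whose two extremities
  have identical pairings (same neighbour or telomere) in both layouts.
* ``grouping_accuracy`` — length-weighted Jaccard agreement between
  scaffolds and chromosomes under an optimal one-to-one matching.
* ``ordering_accuracy`` — length-weighted fraction of adjacent contig
  pairs in the assembly that are also adjacent in the reference.
* ``orientation_accuracy`` — as ordering, additionally requiring a
  consistent relative orientation.

Definitions that the source methodology leaves open (the exact
"correctly placed" rule, the grouping matching, the pair weight) are
fixed here and documented on each function; they are this toolkit's
choices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import MetricError
from .layout import (
    FORWARD,
    REVERSE,
    AdjacencySet,
    Extremity,
    GenomeLayout,
    OrientedContig,
    layout_to_adjacencies,
    restrict_layout,
)

logger = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    """All five metrics plus N50 and evaluation bookkeeping."""

    edit_distance: float
    overall_accuracy: float
    grouping_accuracy: float
    ordering_accuracy: float
    orientation_accuracy: float
    n50: int
    n_contigs_evaluated: int
    n_contigs_excluded: int
    excluded_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    TSV_COLUMNS = (
        "edit_distance",
        "overall_accuracy",
        "grouping_accuracy",
        "ordering_accuracy",
        "orientation_accuracy",
        "n50",
        "n_contigs_evaluated",
        "n_contigs_excluded",
    )

    def tsv_row(self) -> str:
        d = self.to_dict()
        return "\t".join(str(d[c]) for c in self.TSV_COLUMNS)


def _check_comparable(assembly: GenomeLayout, reference: GenomeLayout) -> None:
    a_ids = assembly.contig_ids()
    r_ids = reference.contig_ids()
    if not a_ids or not r_ids:
        raise MetricError("cannot compare layouts with an empty contig set")
    if a_ids != r_ids:
        raise MetricError(
            "layouts have different contig sets; restrict both to the shared "
            "set with restrict_layout before scoring "
            f"(only-in-assembly: {len(a_ids - r_ids)}, "
            f"only-in-reference: {len(r_ids - a_ids)})"
        )
    a_len = assembly.contig_lengths()
    r_len = reference.contig_lengths()
    mismatched = [c for c in a_len if a_len[c] != r_len[c]]
    if mismatched:
        raise MetricError(
            "contig lengths disagree between layouts: "
            + ", ".join(sorted(mismatched)[:5])
        )


def dcj_distance(assembly: GenomeLayout, reference: GenomeLayout) -> int:
    """Minimal DCJ operation count between two layouts over one contig set.

    Computed as ``N - (C + I/2)`` where N is the number of contigs, C the
    number of cycles and I the number of odd paths in the adjacency graph
    formed by the union of both layouts' adjacency sets (telomeres close
    paths).  Path parity follows the standard adjacency-graph convention:
    a path is odd when it covers an odd number of extremities.
    """
    _check_comparable(assembly, reference)
    a_pair = layout_to_adjacencies(assembly).pairing()
    r_pair = layout_to_adjacencies(reference).pairing()
    n = assembly.n_contigs()

    cycles = 0
    odd_paths = 0
    seen: set[Extremity] = set()
    for start in a_pair:
        if start in seen:
            continue
        # walk left then right along alternating assembly/reference edges
        component = {start}
        is_cycle = False
        for first_map in (a_pair, r_pair):
            cur, nxt_map = start, first_map
            while True:
                partner = nxt_map[cur]
                if partner is None:
                    break  # hit a telomere: path end
                if partner in component:
                    is_cycle = True
                    break
                component.add(partner)
                cur = partner
                nxt_map = r_pair if nxt_map is a_pair else a_pair
            if is_cycle:
                break
        seen |= component
        if is_cycle:
            cycles += 1
        elif len(component) % 2 == 1:
            odd_paths += 1
    assert odd_paths % 2 == 0
    return n - (cycles + odd_paths // 2)


def overall_accuracy(assembly: GenomeLayout, reference: GenomeLayout) -> float:
    """Length fraction of contigs correctly placed.

    A contig is correctly placed iff *both* of its extremities have the
    same pairing in assembly and reference: adjacent to the same extremity
    of the same contig, or a telomere in both.
    """
    _check_comparable(assembly, reference)
    a_pair = layout_to_adjacencies(assembly).pairing()
    r_pair = layout_to_adjacencies(reference).pairing()
    correct = 0
    total = 0
    for contig in assembly.contigs():
        total += contig.length
        head = (contig.id, "head")
        tail = (contig.id, "tail")
        if a_pair[head] == r_pair[head] and a_pair[tail] == r_pair[tail]:
            correct += contig.length
    return correct / total


def _length_weighted_jaccard(
    a_members: dict[str, int], b_members: dict[str, int]
) -> float:
    shared = sum(a_members[c] for c in a_members.keys() & b_members.keys())
    union = sum((a_members | b_members).values())
    return shared / union if union else 0.0


def grouping_accuracy(assembly: GenomeLayout, reference: GenomeLayout) -> float:
    """Length-weighted Jaccard agreement between scaffolds and chromosomes.

    Scaffolds are matched one-to-one to chromosomes by maximum-weight
    bipartite matching on the length-weighted Jaccard index J; the score
    is sum over chromosomes of (chromosome length x J of its match, 0 if
    unmatched) divided by total evaluated length.  Optimal matching (not
    greedy) ensures a mega-scaffold cannot be credited to every
    chromosome.
    """
    _check_comparable(assembly, reference)
    chrom_names = list(reference.groups)
    scaf_names = list(assembly.groups)
    chrom_members = [
        {c.id: c.length for c in reference.groups[n]} for n in chrom_names
    ]
    scaf_members = [
        {c.id: c.length for c in assembly.groups[n]} for n in scaf_names
    ]
    weights = np.zeros((len(chrom_names), len(scaf_names)))
    for i, cm in enumerate(chrom_members):
        for j, sm in enumerate(scaf_members):
            weights[i, j] = _length_weighted_jaccard(cm, sm)
    rows, cols = linear_sum_assignment(weights, maximize=True)
    total = sum(sum(m.values()) for m in chrom_members)
    score_sum = 0.0
    for i, j in zip(rows, cols):
        chrom_len = sum(chrom_members[i].values())
        score_sum += chrom_len * weights[i, j]
    return score_sum / total


def _adjacent_pairs(
    layout: GenomeLayout,
) -> list[tuple[OrientedContig, OrientedContig]]:
    pairs = []
    for contigs in layout.groups.values():
        pairs.extend(zip(contigs, contigs[1:]))
    return pairs


def _pair_weight(x: OrientedContig, y: OrientedContig) -> float:
    # arithmetic mean of the two contig lengths
    return (x.length + y.length) / 2


def ordering_accuracy(assembly: GenomeLayout, reference: GenomeLayout) -> float:
    """Length-weighted fraction of assembly-adjacent pairs that are
    reference-adjacent (in either order, orientation ignored).

    Pair weight is the mean of the two contig lengths.  An assembly with
    no adjacent pairs scores 0 with a warning, unless the reference also
    has none (then 1.0: nothing to order).
    """
    _check_comparable(assembly, reference)
    asm_pairs = _adjacent_pairs(assembly)
    if not asm_pairs:
        if not _adjacent_pairs(reference):
            return 1.0  # nothing to order in either layout: vacuously correct
        warnings.warn(
            "assembly has no adjacent contig pairs; ordering accuracy "
            "defined as 0",
            stacklevel=2,
        )
        return 0.0
    ref_adjacent = {
        frozenset((x.id, y.id)) for x, y in _adjacent_pairs(reference)
    }
    got = sum(
        _pair_weight(x, y)
        for x, y in asm_pairs
        if frozenset((x.id, y.id)) in ref_adjacent
    )
    total = sum(_pair_weight(x, y) for x, y in asm_pairs)
    return got / total


def _oriented_pair_keys(x: OrientedContig, y: OrientedContig) -> set[tuple]:
    """The two equivalent directed readings of an adjacent oriented pair."""
    return {
        (x.id, x.orientation, y.id, y.orientation),
        (
            y.id,
            REVERSE if y.orientation == FORWARD else FORWARD,
            x.id,
            REVERSE if x.orientation == FORWARD else FORWARD,
        ),
    }


def orientation_accuracy(
    assembly: GenomeLayout, reference: GenomeLayout
) -> float:
    """As ordering accuracy, but the relative orientation must also match.

    A pair (x, y) counts iff the reference contains it read as (x, y) with
    the same orientations or as (y, x) with both orientations flipped.
    By construction this is never larger than the ordering accuracy.
    """
    _check_comparable(assembly, reference)
    asm_pairs = _adjacent_pairs(assembly)
    if not asm_pairs:
        if not _adjacent_pairs(reference):
            return 1.0  # vacuously correct, mirrors ordering_accuracy
        warnings.warn(
            "assembly has no adjacent contig pairs; orientation accuracy "
            "defined as 0",
            stacklevel=2,
        )
        return 0.0
    ref_keys: set[tuple] = set()
    for x, y in _adjacent_pairs(reference):
        ref_keys |= _oriented_pair_keys(x, y)
    got = sum(
        _pair_weight(x, y)
        for x, y in asm_pairs
        if _oriented_pair_keys(x, y) & ref_keys
    )
    total = sum(_pair_weight(x, y) for x, y in asm_pairs)
    return got / total


def n50(lengths: list[int]) -> int:
    """Length at which contigs of equal or greater length cover half the
    assembly: sort descending, accumulate, return the first length whose
    cumulative sum reaches total/2."""
    if not lengths:
        raise MetricError("n50 of an empty length list is undefined")
    if any(x <= 0 for x in lengths):
        raise MetricError("n50 requires positive lengths")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for x in ordered:
        acc += x
        if acc >= half:
            return x
    raise AssertionError("unreachable")


def score(
    assembly: GenomeLayout,
    reference: GenomeLayout,
    exclude_unscaffolded: bool = False,
    exclude_singletons: bool = False,
) -> MetricsReport:
    """Compute the full metric report between two layouts.

    Contigs present in only one layout cannot enter the comparison.
    Reference contigs missing from the assembly are treated as
    unscaffolded: with ``exclude_unscaffolded`` they are removed from the
    reference before scoring; otherwise they are appended to the assembly
    as singleton groups (the way an unscaffolded contig appears in a
    scaffolder's output FASTA).  ``exclude_singletons`` additionally drops
    assembly singleton groups when excluding.  Assembly contigs absent
    from the reference are always excluded (and reported).
    """
    a_ids = assembly.contig_ids()
    r_ids = reference.contig_ids()
    if not (a_ids & r_ids):
        raise MetricError("layouts share no contigs")

    excluded = sorted(a_ids - r_ids)
    assembly = restrict_layout(assembly, a_ids & r_ids)

    unscaffolded = sorted(r_ids - a_ids)
    if exclude_unscaffolded:
        excluded += unscaffolded
        if exclude_singletons:
            singles = [
                g[0].id for g in assembly.groups.values() if len(g) == 1
            ]
            excluded += singles
            keep = assembly.contig_ids() - set(singles)
            if not keep:
                raise MetricError("excluding singletons removed every contig")
            assembly = restrict_layout(assembly, keep)
        reference = restrict_layout(reference, assembly.contig_ids())
    elif unscaffolded:
        lengths = reference.contig_lengths()
        groups = {n: list(g) for n, g in assembly.groups.items()}
        for cid in unscaffolded:
            name = f"unscaffolded:{cid}"
            groups[name] = [OrientedContig(cid, FORWARD, lengths[cid])]
        assembly = GenomeLayout(groups)
        logger.info(
            "%d unscaffolded contigs scored as singleton groups",
            len(unscaffolded),
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = MetricsReport(
            edit_distance=dcj_distance(assembly, reference),
            overall_accuracy=overall_accuracy(assembly, reference),
            grouping_accuracy=grouping_accuracy(assembly, reference),
            ordering_accuracy=ordering_accuracy(assembly, reference),
            orientation_accuracy=orientation_accuracy(assembly, reference),
            n50=n50([c.length for c in assembly.contigs()]),
            n_contigs_evaluated=assembly.n_contigs(),
            n_contigs_excluded=len(excluded),
            excluded_ids=sorted(excluded),
        )
    return report


def baseline_report(
    contigs: list[tuple[str, int]], reference: GenomeLayout
) -> MetricsReport:
    """Score the no-scaffolding baseline: every contig its own group."""
    if not contigs:
        raise MetricError("baseline requires at least one contig")
    unknown = {cid for cid, _ in contigs} - reference.contig_ids()
    if unknown:
        raise MetricError(
            "baseline contigs absent from reference: "
            + ", ".join(sorted(unknown))
        )
    ref_lengths = reference.contig_lengths()
    mismatched = [
        cid for cid, length in contigs if length != ref_lengths[cid]
    ]
    if mismatched:
        raise MetricError(
            "baseline contig lengths disagree with the reference: "
            + ", ".join(sorted(mismatched)[:5])
        )
    layout = GenomeLayout(
        {cid: [OrientedContig(cid, FORWARD, length)] for cid, length in contigs}
    )
    return score(layout, reference, exclude_unscaffolded=True)
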