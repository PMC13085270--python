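"""Shared layout builders and random generators for the test suite."""

from __future__ import annotations

from itertools import permutations, product

import numpy as np

from scafeval.layout import GenomeLayout, OrientedContig


def chain(*specs: str, lengths: dict[str, int] | None = None,
          group: str = "g1") -> GenomeLayout:
    """Build a one-group layout from specs like 'c1+', 'c2-'."""
    contigs = []
    for spec in specs:
        cid, orient = spec[:-1], spec[-1]
        length = (lengths or {}).get(cid, 100)
        contigs.append(OrientedContig(cid, orient, length))
    return GenomeLayout({group: contigs})


def multi(groups: dict[str, list[str]],
          lengths: dict[str, int] | None = None) -> GenomeLayout:
    """Build a multi-group layout from {'chr1': ['c1+', 'c2-'], ...}."""
    out = {}
    for name, specs in groups.items():
        out[name] = [
            OrientedContig(s[:-1], s[-1], (lengths or {}).get(s[:-1], 100))
            for s in specs
        ]
    return GenomeLayout(out)


def random_layout(
    rng: np.random.Generator,
    contig_ids: list[str],
    lengths: dict[str, int] | None = None,
    max_groups: int | None = None,
) -> GenomeLayout:
    """Uniformly random signed layout over a fixed contig set."""
    ids = list(contig_ids)
    rng.shuffle(ids)
    n = len(ids)
    n_groups = int(rng.integers(1, (max_groups or n) + 1))
    n_groups = min(n_groups, n)
    # random composition of n into n_groups parts
    cuts = sorted(rng.choice(np.arange(1, n), size=n_groups - 1, replace=False)) if n_groups > 1 else []
    bounds = [0, *cuts, n]
    groups = {}
    for g in range(n_groups):
        members = ids[bounds[g]:bounds[g + 1]]
        groups[f"g{g}"] = [
            OrientedContig(
                cid,
                "+" if rng.integers(2) else "-",
                # default lengths must be a function of the id so that two
                # independently drawn layouts stay comparable
                (lengths or {}).get(cid, 100 + 7 * (sum(map(ord, cid)) % 50)),
            )
            for cid in members
        ]
    return GenomeLayout(groups)


def all_layouts(contig_ids: list[str], length: int = 100):
    """Yield every signed layout (every ordering, signing and grouping)
    over a contig set.  Exponential; use only for <= 3 contigs."""
    n = len(contig_ids)
    for perm in permutations(contig_ids):
        for signs in product("+-", repeat=n):
            for split_mask in product((False, True), repeat=n - 1):
                groups: dict[str, list[OrientedContig]] = {}
                cur = [OrientedContig(perm[0], signs[0], length)]
                gi = 0
                for i in range(1, n):
                    if split_mask[i - 1]:
                        groups[f"g{gi}"] = cur
                        gi += 1
                        cur = []
                    cur.append(OrientedContig(perm[i], signs[i], length))
                groups[f"g{gi}"] = cur
                yield GenomeLayout(groups)
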