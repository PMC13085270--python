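"""Seeded rearrangement perturbation of truth layouts.

Every operation kind corresponds to at most one double-cut-and-join
operation, so a layout perturbed with a k-operation trace is guaranteed
to lie within DCJ distance k of the truth:

* ``inversion`` — reverse a contiguous block and flip its orientations.
* ``translocation`` — reciprocal suffix exchange between two groups.
* ``fission`` — split one group in two.
* ``fusion`` — concatenate two groups (optionally reversing the second).
* ``orientation_flip`` — invert a single contig.

Traces replay deterministically and serialize to JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from os import PathLike

import numpy as np

from .errors import ScafevalError
from .layout import GenomeLayout, OrientedContig

KINDS = ("inversion", "translocation", "fission", "fusion", "orientation_flip")


@dataclass(frozen=True)
class Operation:
    kind: str
    params: dict

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ScafevalError(f"unknown operation kind {self.kind!r}")


@dataclass
class PerturbationTrace:
    seed: int
    operations: list[Operation] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.operations)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "k": self.k,
                "operations": [
                    {"kind": op.kind, "params": op.params}
                    for op in self.operations
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PerturbationTrace":
        data = json.loads(text)
        return cls(
            seed=data["seed"],
            operations=[
                Operation(op["kind"], op["params"]) for op in data["operations"]
            ],
        )

    def save(self, path: str | PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | PathLike) -> "PerturbationTrace":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _reverse_block(block: list[OrientedContig]) -> list[OrientedContig]:
    return [c.flipped() for c in reversed(block)]


def _apply_one(
    groups: list[list[OrientedContig]], op: Operation, index: int
) -> None:
    """Mutate ``groups`` in place; raises naming the operation index."""
    p = op.params

    def fail(msg: str) -> None:
        raise ScafevalError(f"operation {index} ({op.kind}): {msg}")

    def group(key: str) -> list[OrientedContig]:
        g = p[key]
        if not (0 <= g < len(groups)):
            fail(f"group index {g} out of range (have {len(groups)})")
        return groups[g]

    if op.kind == "inversion":
        g = group("group")
        s, e = p["start"], p["end"]
        if not (0 <= s < e <= len(g)):
            fail(f"block [{s}, {e}) invalid for group of {len(g)}")
        g[s:e] = _reverse_block(g[s:e])
    elif op.kind == "orientation_flip":
        g = group("group")
        i = p["index"]
        if not (0 <= i < len(g)):
            fail(f"contig index {i} out of range")
        g[i] = g[i].flipped()
    elif op.kind == "fission":
        g = group("group")
        pos = p["position"]
        if not (1 <= pos <= len(g) - 1):
            fail(f"fission position {pos} invalid for group of {len(g)}")
        left, right = g[:pos], g[pos:]
        groups[p["group"]] = left
        groups.append(right)
    elif op.kind == "fusion":
        a, b = p["group_a"], p["group_b"]
        if a == b:
            fail("cannot fuse a group with itself")
        ga, gb = group("group_a"), group("group_b")
        if p.get("flip_b", False):
            gb = _reverse_block(gb)
        groups[a] = ga + gb
        del groups[b]
    elif op.kind == "translocation":
        a, b = p["group_a"], p["group_b"]
        if a == b:
            fail("translocation needs two distinct groups")
        ga, gb = group("group_a"), group("group_b")
        ca, cb = p["cut_a"], p["cut_b"]
        if not (0 <= ca <= len(ga) and 0 <= cb <= len(gb)):
            fail(f"cuts ({ca}, {cb}) out of range")
        new_a = ga[:ca] + gb[cb:]
        new_b = gb[:cb] + ga[ca:]
        groups[a] = new_a
        groups[b] = new_b
        for g in (max(a, b), min(a, b)):
            if not groups[g]:
                del groups[g]


def apply_operations(
    layout: GenomeLayout, trace: PerturbationTrace
) -> GenomeLayout:
    """Replay a trace on a layout; contig set and total length conserved."""
    groups = [list(g) for g in layout.groups.values()]
    for i, op in enumerate(trace.operations):
        _apply_one(groups, op, i)
    return GenomeLayout(
        {f"scaffold{i + 1:04d}": g for i, g in enumerate(groups)}
    )


def _valid_kinds(groups: list[list[OrientedContig]]) -> set[str]:
    kinds = {"inversion", "orientation_flip"}
    if len(groups) >= 2:
        kinds |= {"fusion", "translocation"}
    if any(len(g) >= 2 for g in groups):
        kinds.add("fission")
    return kinds


def random_trace(
    layout: GenomeLayout,
    k: int,
    kind_weights: dict[str, float] | None = None,
    seed: int = 0,
    block_mean: float = 2.0,
) -> PerturbationTrace:
    """Draw k operations with the given kind mix, parameters uniform over
    the valid choices at each step; deterministic per seed.

    Kinds invalid for the evolving layout get weight zero for that step
    (with a warning if that silences a requested kind).  Block lengths
    for inversions are geometric with mean ``block_mean``.
    """
    if k < 0:
        raise ScafevalError("k must be >= 0")
    weights = dict.fromkeys(KINDS, 1.0)
    if kind_weights:
        unknown = set(kind_weights) - set(KINDS)
        if unknown:
            raise ScafevalError(f"unknown kinds: {sorted(unknown)}")
        weights = dict.fromkeys(KINDS, 0.0) | dict(kind_weights)
    if all(w <= 0 for w in weights.values()):
        raise ScafevalError("kind weights must not all be zero")
    rng = np.random.default_rng(seed)
    groups = [list(g) for g in layout.groups.values()]
    ops: list[Operation] = []
    warned: set[str] = set()
    for step in range(k):
        valid = _valid_kinds(groups)
        step_w = {
            kind: (w if kind in valid else 0.0) for kind, w in weights.items()
        }
        silenced = {
            kind
            for kind, w in weights.items()
            if w > 0 and kind not in valid and kind not in warned
        }
        for kind in silenced:
            warnings.warn(
                f"kind {kind!r} not applicable to the current layout; "
                "weight zeroed",
                stacklevel=2,
            )
            warned.add(kind)
        total = sum(step_w.values())
        if total == 0:
            raise ScafevalError("no operation kind applicable to this layout")
        kinds = list(step_w)
        probs = np.array([step_w[kd] for kd in kinds]) / total
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        op = _draw_params(rng, groups, kind, block_mean)
        _apply_one(groups, op, step)
        ops.append(op)
    return PerturbationTrace(seed=seed, operations=ops)


def _draw_params(
    rng: np.random.Generator,
    groups: list[list[OrientedContig]],
    kind: str,
    block_mean: float,
) -> Operation:
    if kind == "inversion":
        g = int(rng.integers(len(groups)))
        n = len(groups[g])
        size = min(int(rng.geometric(1.0 / block_mean)), n)
        start = int(rng.integers(0, n - size + 1))
        return Operation("inversion", {"group": g, "start": start, "end": start + size})
    if kind == "orientation_flip":
        g = int(rng.integers(len(groups)))
        return Operation(
            "orientation_flip",
            {"group": g, "index": int(rng.integers(len(groups[g])))},
        )
    if kind == "fission":
        eligible = [i for i, g in enumerate(groups) if len(g) >= 2]
        g = int(rng.choice(eligible))
        return Operation(
            "fission",
            {"group": g, "position": int(rng.integers(1, len(groups[g])))},
        )
    if kind == "fusion":
        a, b = (int(x) for x in rng.choice(len(groups), size=2, replace=False))
        return Operation(
            "fusion", {"group_a": a, "group_b": b, "flip_b": bool(rng.integers(2))}
        )
    if kind == "translocation":
        a, b = (int(x) for x in rng.choice(len(groups), size=2, replace=False))
        return Operation(
            "translocation",
            {
                "group_a": a,
                "group_b": b,
                "cut_a": int(rng.integers(0, len(groups[a]) + 1)),
                "cut_b": int(rng.integers(0, len(groups[b]) + 1)),
            },
        )
    raise AssertionError(kind)


def make_megascaffold(layout: GenomeLayout) -> GenomeLayout:
    """Concatenate all groups in order into a single scaffold — the
    over-scaffolding failure mode."""
    if not layout.groups:
        raise ScafevalError("layout has no groups")
    merged = [c for g in layout.groups.values() for c in g]
    return GenomeLayout({"megascaffold": merged})
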