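"""Native abstract-shape coarse-graining of dot-bracket structures.

Abstract shapes map a secondary structure to a string over ``[``, ``]`` and
``_`` that retains the helix nesting pattern and, depending on the
abstraction level, some unpaired regions:

* level 1: one ``[]`` per helix; ``_`` for unpaired stretches in the
  exterior loop, multiloops, bulges and internal loops
* level 2: as level 1, but ``_`` only where a helix is interrupted
  (bulges and internal loops)
* level 3: one ``[]`` per helix, no ``_``
* level 4: helices separated by one-sided interruptions (bulges) are merged;
  no ``_``
* level 5: helices separated by any two-way interruption (bulge or internal
  loop) are merged; no ``_``

Hairpin-loop unpaired regions are never represented, at any level.  The
open chain maps to ``"_"`` at every level (the shape of the unfolded
state).  These conventions match the reference implementation in the
ViennaRNA library, against which this module is validated test-side by
exact string comparison.
"""

from __future__ import annotations

from .errors import MapFormatError

__all__ = ["pair_table", "abstract_shape", "OPEN_CHAIN_SHAPE"]

OPEN_CHAIN_SHAPE = "_"


def pair_table(structure: str) -> list[int]:
    """Partner index per position (-1 if unpaired); errors on unbalanced input."""
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise MapFormatError(f"unbalanced ')' at position {i} in {structure!r}")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise MapFormatError(f"invalid character {c!r} at position {i} in {structure!r}")
    if stack:
        raise MapFormatError(f"unbalanced '(' at position {stack[-1]} in {structure!r}")
    return pt


def abstract_shape(structure: str, level: int = 2) -> str:
    """The abstract shape of a dot-bracket ``structure`` at ``level`` (1-5)."""
    if level not in (1, 2, 3, 4, 5):
        raise ValueError(f"shape level must be 1..5, got {level}")
    pt = pair_table(structure)
    if all(p < 0 for p in pt):
        return OPEN_CHAIN_SHAPE
    parts = _region(0, len(structure) - 1, pt, level)
    return "".join(parts)


def _children(i: int, j: int, pt: list[int]):
    """(start, end) of each paired child in [i, j], plus unpaired stretch info."""
    kids = []
    unpaired = []  # lengths of the gaps before/between/after children
    gap = 0
    k = i
    while k <= j:
        if pt[k] >= 0:
            unpaired.append(gap)
            gap = 0
            kids.append((k, pt[k]))
            k = pt[k] + 1
        else:
            gap += 1
            k += 1
    unpaired.append(gap)
    return kids, unpaired


def _region(i: int, j: int, pt: list[int], level: int) -> list[str]:
    """Shape fragments for the loop region [i, j] (exterior or multiloop body)."""
    kids, gaps = _children(i, j, pt)
    mark_gaps = level == 1  # exterior/multiloop unpaired only at level 1
    out: list[str] = []
    for idx, (a, b) in enumerate(kids):
        if mark_gaps and gaps[idx] > 0:
            out.append("_")
        out.extend(_helix(a, b, pt, level))
    if mark_gaps and gaps[-1] > 0:
        out.append("_")
    return out


def _helix(i: int, j: int, pt: list[int], level: int) -> list[str]:
    """Shape fragments for the helix whose outermost pair is (i, j)."""
    # walk to the innermost pair of this helix (consecutive stacked pairs)
    while i + 1 < j and pt[i + 1] == j - 1:
        i, j = i + 1, j - 1
    kids, gaps = _children(i + 1, j - 1, pt)
    if not kids:
        return ["[", "]"]  # hairpin; its loop is never represented
    if len(kids) == 1:
        a, b = kids[0]
        left, right = gaps[0] > 0, gaps[1] > 0
        bulge = left != right  # one-sided interruption
        if level == 5 or (level == 4 and bulge):
            # merge the interruption: continue down as the same helix
            return _helix(a, b, pt, level)
        inner = []
        if level <= 2 and left:
            inner.append("_")
        inner.extend(_helix(a, b, pt, level))
        if level <= 2 and right:
            inner.append("_")
        return ["[", *inner, "]"]
    # multiloop
    return ["[", *_region(i + 1, j - 1, pt, level), "]"]
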