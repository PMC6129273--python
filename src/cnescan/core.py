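"""Shared domain types and the scoring primitives of the CNE search.

A conserved non-coding element (CNE) candidate is judged by two user
criteria: its length must lie in ``[min_len, max_len]`` and its *relative
identity* — one minus the normalised simple (Levenshtein) edit distance —
must reach the threshold ``identity_t``.  Everything downstream (seeding,
chaining, extension) is driven by these two numbers, plus the minimum
anchor length implied by them.

Distances are computed with Myers' bit-vector algorithm via :mod:`edlib`.
``N`` bases (masked or ambiguous positions) never match anything, not even
another ``N``: a masked base must not seed a match nor silently count as
identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import edlib

__all__ = [
    "Params",
    "Region",
    "Anchor",
    "Chain",
    "CneHit",
    "edit_distance",
    "identity_score",
    "edit_budget",
    "min_anchor_length",
    "reverse_complement",
]

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the ``ACGTN`` alphabet (case preserved)."""
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class Params:
    """User-facing search criteria.

    Parameters
    ----------
    min_len :
        Lower bound (bp) on the length of a reported element.
    max_len :
        Upper bound (bp); extension halts when either element reaches it.
    identity_t :
        Relative identity threshold in ``(0, 1]``; ``1`` reports only
        character-identical pairs.
    user_anchor_len :
        Optional explicit minimum anchor (seed) length.  The effective
        seed length is the maximum of this and the value implied by
        ``min_len`` and ``identity_t``.
    min_chain_coverage :
        Minimum combined anchor length (bp) a chain needs to be kept.
        Defaults to ``min_len // 2``.
    ext_step :
        Window size w (bp) added per side and per iteration during
        extension.  Default 5.
    merge_max_gap :
        Largest gap (bp, in either sequence) bridged when chaining
        anchors.  Defaults to ``min_len``.
    """

    min_len: int
    max_len: int
    identity_t: float
    user_anchor_len: Optional[int] = None
    min_chain_coverage: Optional[int] = None
    ext_step: int = 5
    merge_max_gap: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_t <= 1.0):
            raise ValueError(
                f"identity threshold t must be in (0, 1], got {self.identity_t}"
            )
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError(
                f"need 1 <= min_len <= max_len, got [{self.min_len}, {self.max_len}]"
            )
        if self.min_chain_coverage is None:
            object.__setattr__(self, "min_chain_coverage", max(1, self.min_len // 2))
        if self.merge_max_gap is None:
            object.__setattr__(self, "merge_max_gap", self.min_len)
        for name in ("user_anchor_len", "min_chain_coverage", "ext_step", "merge_max_gap"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValueError(f"{name} must be >= 1 when given, got {v}")


@dataclass(frozen=True)
class Region:
    """A coordinate-anchored slice of a source sequence.

    ``offset`` is the 0-based position of ``bases[0]`` within the source
    record named ``seq_name``; all coordinates reported downstream are
    shifted by it back into source-sequence space.
    """

    seq_name: str
    offset: int
    bases: str

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("Region offset must be >= 0")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def end(self) -> int:
        return self.offset + len(self.bases)


class Anchor(NamedTuple):
    """One maximal exact match: region-local starts and its length."""

    ref_start: int
    query_start: int
    length: int

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length

    @property
    def query_end(self) -> int:
        return self.query_start + self.length


@dataclass
class Chain:
    """A co-linear, non-overlapping run of anchors with gap edit cost.

    ``ref_span``/``query_span`` are the half-open hulls of the anchors in
    region-local coordinates; ``gap_edit`` sums the edit distance of the
    paired gap substrings between consecutive anchors.
    """

    anchors: list[Anchor]
    gap_edit: int
    ref_span: tuple[int, int]
    query_span: tuple[int, int]

    @property
    def anchor_coverage(self) -> int:
        return sum(a.length for a in self.anchors)


@dataclass(frozen=True)
class CneHit:
    """A reported CNE pair, in source-sequence (0-based, half-open) coordinates."""

    ref_name: str
    ref_start: int
    ref_end: int
    query_name: str
    query_start: int
    query_end: int
    edit_distance: int
    identity: float
    query_strand: str = "+"

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def query_len(self) -> int:
        return self.query_end - self.query_start


def edit_distance(a: str, b: str) -> int:
    """Simple (unit-cost) edit distance between two DNA strings.

    ``N`` matches nothing — each ``N`` costs one edit against any letter,
    including another ``N``.  Implemented with Myers' bit-vector algorithm
    (edlib); the N semantics are obtained by renaming ``N`` to distinct
    sentinels on the two sides.
    """
    a = a.upper()
    b = b.upper()
    if not a:
        return len(b)
    if not b:
        return len(a)
    if "N" in a:
        a = a.replace("N", "X")
    if "N" in b:
        b = b.replace("N", "Y")
    d = edlib.align(a, b, task="distance")["editDistance"]
    if d < 0:  # pragma: no cover - edlib returns -1 only with bounded k
        raise RuntimeError("edlib returned no distance")
    return d


def identity_score(a: str, b: str) -> float:
    """Relative identity ``1 - d(a, b) / max(|a|, |b|)``.

    Normalising by the longer string penalises indel-length asymmetry and
    keeps the score in ``[0, 1]``; it equals 1 iff the strings are
    identical (and N-free).
    """
    if not a and not b:
        raise ValueError("identity_score undefined for two empty strings")
    return 1.0 - edit_distance(a, b) / max(len(a), len(b))


def edit_budget(min_len: int, identity_t: float) -> int:
    """Maximum edits e = floor(l*(1-t)) a minimum-length element may carry.

    The rounding guard absorbs binary floating-point error: for example
    ``200 - 0.95*200`` evaluates slightly below 10 and a naive floor would
    understate the budget by one.
    """
    return int(math.floor(round(min_len * (1.0 - identity_t), 6)))


def min_anchor_length(p: Params) -> int:
    """Minimum seed length: floor(l / (e + 1)), overridable upward.

    Pigeonhole argument: two length-l strings within e edits of each other
    share an exact aligned run of at least floor(l/(e+1)) bases, so seeding
    at that length loses no qualifying element.  When the user supplies an
    explicit anchor length the maximum of the two values is used.
    """
    e = edit_budget(p.min_len, p.identity_t)
    bound = p.min_len // (e + 1)
    return max(bound, p.user_anchor_len or 0, 1)
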