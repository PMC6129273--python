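"""Independent oracles used only by the test suite.

These deliberately take different algorithmic routes from the package:
the distance oracle is Biopython's quadratic Needleman-Wunsch aligner
(unit costs), the MEM oracle is a full match-matrix run-length scan, and
the anchor-length oracle uses exact rational arithmetic.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

_ALPHABET = "ACGTXY"


def _make_aligner() -> Align.PairwiseAligner:
    m = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            # X/Y are the N stand-ins: they match nothing, not even themselves
            m[a, b] = 0.0 if (a == b and a not in "XY") else -1.0
    al = Align.PairwiseAligner()
    al.substitution_matrix = m
    al.open_gap_score = -1
    al.extend_gap_score = -1
    al.mode = "global"
    return al


_ALIGNER = _make_aligner()


def dp_edit_distance(a: str, b: str) -> int:
    """Unit-cost edit distance by quadratic global DP (N matches nothing)."""
    a = a.upper().replace("N", "X")
    b = b.upper().replace("N", "Y")
    if not a:
        return len(b)
    if not b:
        return len(a)
    return int(-_ALIGNER.score(a, b))


def brute_force_mems(x: str, y: str, l_min: int) -> set[tuple[int, int, int]]:
    """All maximal exact matches by run-length scan of the full match matrix."""
    x = x.upper()
    y = y.upper()
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        return set()
    xa = np.frombuffer(x.encode(), np.uint8)
    ya = np.frombuffer(y.encode(), np.uint8)
    match = (xa[:, None] == ya[None, :]) & (xa[:, None] != ord("N"))
    run = np.zeros((nx + 1, ny + 1), dtype=np.int64)
    for i in range(1, nx + 1):
        run[i, 1:] = (run[i - 1, :-1] + 1) * match[i - 1, :]
    # a run ending at (i-1, j-1) is right-maximal iff the next cell mismatches
    ext = np.zeros((nx + 1, ny + 1), dtype=bool)
    ext[:nx, :ny] = match
    ii, jj = np.nonzero((run[1:, 1:] >= l_min) & ~ext[1:, 1:])
    lens = run[ii + 1, jj + 1]
    return set(zip((ii + 1 - lens).tolist(), (jj + 1 - lens).tolist(), lens.tolist()))


def exact_min_anchor(min_len: int, t: str, user: int | None = None) -> int:
    """floor(l / (floor(l - t*l) + 1)) with exact rational t (decimal string)."""
    tf = Fraction(t)
    e = (min_len - tf * min_len).__floor__()
    bound = min_len // (e + 1)
    return max(bound, user or 0, 1)


def random_dna_string(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    letters = "ACGTN" if with_n else "ACGT"
    p = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(rng.choice(list(letters), size=length, p=p))
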