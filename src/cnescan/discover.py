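"""Seed → merge → extend discovery of conserved non-coding elements.

The three stages:

1. :func:`find_mems` enumerates every maximal exact match (MEM) of length
   at least ``L_min`` between the two regions, by k-mer hashing of the
   reference and lookup of the query k-mers (k-mers are packed into
   integers, 2 bits per base; candidate seeds are verified by direct
   comparison, so the output is the exact MEM set, never probabilistic).
2. :func:`merge_anchors` greedily chains co-linear, non-overlapping
   anchors, paying the edit distance of the inter-anchor gaps, and stops a
   chain when the next gap would push identity below the threshold.
3. :func:`extend_chain` grows each chain outwards in small windows,
   estimating identity from accumulated window distances and re-measuring
   the true edit distance of the whole element whenever the estimate would
   cross the threshold (the estimate is an upper bound on the true
   distance, so identity can only be revised upward).

:func:`discover_cnes` wires the stages together and deduplicates the
result.  All coordinates inside this module are region-local; hits are
shifted into source-sequence space at emission.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .core import (
    Anchor,
    Chain,
    CneHit,
    Params,
    Region,
    edit_distance,
    min_anchor_length,
)

logger = logging.getLogger(__name__)

_EPS = 1e-12
# 2-bit packing of a k-mer into an int64 is exact up to k = 31
_MAX_SEED_K = 31

_CODE_X = np.full(256, 4, dtype=np.uint8)
_CODE_Y = np.full(256, 5, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE_X[ord(_c)] = _i
    _CODE_Y[ord(_c)] = _i
# anything that is not an unambiguous base behaves like N; the two
# sequences use different sentinel codes so N never equals N


def _encode(seq: str, table: np.ndarray) -> np.ndarray:
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return table[raw]


def _kmer_table(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Positions of N-free k-mers and their packed integer values."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    bad = (codes >= 4).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    pos = np.nonzero(valid)[0].astype(np.int64)
    vals = np.zeros(n, dtype=np.int64)
    c = (codes & 3).astype(np.int64)
    for j in range(k):
        vals <<= 2
        vals |= c[j : j + n]
    return pos, vals[pos]


def _mem_arrays(
    xc: np.ndarray, yc: np.ndarray, l_min: int, n_workers: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MEM triples (ref_start, query_start, length) as parallel arrays."""
    k = min(l_min, _MAX_SEED_K)
    nx, ny = len(xc), len(yc)
    xpos, xvals = _kmer_table(xc, k)
    ypos, yvals = _kmer_table(yc, k)
    if len(xpos) == 0 or len(ypos) == 0:
        e = np.empty(0, np.int64)
        return e, e, e

    order = np.argsort(xvals, kind="stable")
    sx_vals = xvals[order]
    sx_pos = xpos[order]

    out_i: list[np.ndarray] = []
    out_j: list[np.ndarray] = []
    out_m: list[np.ndarray] = []

    # the query seed positions are partitioned into blocks; extension reads
    # the full sequences, so the result is independent of the block count
    blocks = np.array_split(np.arange(len(ypos)), max(1, n_workers))
    for blk in blocks:
        if blk.size == 0:
            continue
        bj = ypos[blk]
        bv = yvals[blk]
        lo = np.searchsorted(sx_vals, bv, side="left")
        hi = np.searchsorted(sx_vals, bv, side="right")
        cnt = hi - lo
        has = cnt > 0
        if not has.any():
            continue
        starts = lo[has]
        counts = cnt[has]
        total = int(counts.sum())
        jj = np.repeat(bj[has], counts)
        ends = np.cumsum(counts)
        offs = np.arange(total, dtype=np.int64) - np.repeat(ends - counts, counts)
        ii = sx_pos[np.repeat(starts, counts) + offs]

        # left-maximality: at a boundary, or the preceding bases differ
        # (N codes differ between the two sequences, so N blocks extension)
        keep = np.ones(total, dtype=bool)
        inner = (ii > 0) & (jj > 0)
        keep[inner] = xc[ii[inner] - 1] != yc[jj[inner] - 1]
        ii, jj = ii[keep], jj[keep]

        # right extension, in lock-step over the still-matching pairs
        ext = np.zeros(len(ii), dtype=np.int64)
        act = np.nonzero((ii + k < nx) & (jj + k < ny))[0]
        while act.size:
            pi = ii[act] + k + ext[act]
            pj = jj[act] + k + ext[act]
            eq = xc[pi] == yc[pj]
            act = act[eq]
            ext[act] += 1
            inb = (ii[act] + k + ext[act] < nx) & (jj[act] + k + ext[act] < ny)
            act = act[inb]
        mlen = ext + k
        ok = mlen >= l_min
        out_i.append(ii[ok])
        out_j.append(jj[ok])
        out_m.append(mlen[ok])

    if not out_i:
        e = np.empty(0, np.int64)
        return e, e, e
    ai = np.concatenate(out_i)
    aj = np.concatenate(out_j)
    am = np.concatenate(out_m)
    order = np.lexsort((aj, ai))
    return ai[order], aj[order], am[order]


def find_mems(x: Region, y: Region, l_min: int, n_workers: int = 1) -> list[Anchor]:
    """All maximal exact matches of length >= ``l_min`` between x and y.

    Returns exactly the set of triples ``(i, j, m)`` with
    ``x.bases[i:i+m] == y.bases[j:j+m]``, no ``N`` inside, and the match
    extendable in neither direction; sorted by (ref_start, query_start).
    """
    if l_min < 1:
        raise ValueError("l_min must be >= 1")
    xc = _encode(x.bases, _CODE_X)
    yc = _encode(y.bases, _CODE_Y)
    ai, aj, am = _mem_arrays(xc, yc, l_min, n_workers)
    return [Anchor(int(i), int(j), int(m)) for i, j, m in zip(ai, aj, am)]


def merge_anchors(
    anchors: Sequence[Anchor], x: Region, y: Region, p: Params
) -> list[Chain]:
    """Greedy co-linear chaining of anchors under the identity threshold.

    Anchors are processed in (ref_start, query_start) order; each chain
    repeatedly absorbs, among the unconsumed anchors within
    ``merge_max_gap`` of its end in both sequences, the one minimising the
    summed gap (ties to the smaller query_start).  A chain stops when no
    candidate exists, when either span would exceed ``max_len``, or when
    the next gap's edit cost would drop identity below the threshold.
    Chains shorter than ``min_chain_coverage`` in combined anchor length
    (or violating the identity / span bounds) are discarded; every anchor
    is consumed by at most one chain.
    """
    if not anchors:
        return []
    xb = x.bases.upper()
    yb = y.bases.upper()
    t = p.identity_t
    u = p.max_len
    maxgap = p.merge_max_gap

    rs_a = np.fromiter((a.ref_start for a in anchors), np.int64, len(anchors))
    qs_a = np.fromiter((a.query_start for a in anchors), np.int64, len(anchors))
    ln_a = np.fromiter((a.length for a in anchors), np.int64, len(anchors))
    order = np.lexsort((qs_a, rs_a))
    RS, QS, LN = rs_a[order], qs_a[order], ln_a[order]
    RE, QE = RS + LN, QS + LN
    n = len(RS)
    consumed = np.zeros(n, dtype=bool)
    qkey = len(yb) + 1

    chains: list[Chain] = []
    for s in range(n):
        if consumed[s]:
            continue
        consumed[s] = True
        members = [s]
        rs0, qs0 = int(RS[s]), int(QS[s])
        re, qe = int(RE[s]), int(QE[s])
        gap_edit = 0
        while True:
            lo = int(np.searchsorted(RS, re, side="left"))
            hi = int(np.searchsorted(RS, re + maxgap, side="right"))
            if lo >= hi:
                break
            q_w = QS[lo:hi]
            cand = (~consumed[lo:hi]) & (q_w >= qe) & (q_w - qe <= maxgap)
            cidx = np.nonzero(cand)[0]
            if cidx.size == 0:
                break
            cost = (RS[lo:hi][cidx] - re) + (q_w[cidx] - qe)
            c = lo + int(cidx[np.argmin(cost * qkey + q_w[cidx])])
            nre, nqe = int(RE[c]), int(QE[c])
            if nre - rs0 > u or nqe - qs0 > u:
                break
            gx = xb[re : int(RS[c])]
            gy = yb[qe : int(QS[c])]
            d = edit_distance(gx, gy) if (gx or gy) else 0
            new_gap = gap_edit + d
            if 1.0 - new_gap / max(nre - rs0, nqe - qs0) < t - _EPS:
                break
            consumed[c] = True
            members.append(c)
            re, qe, gap_edit = nre, nqe, new_gap

        span_r, span_q = re - rs0, qe - qs0
        coverage = int(LN[members].sum())
        identity = 1.0 - gap_edit / max(span_r, span_q)
        if (
            coverage >= p.min_chain_coverage
            and identity >= t - _EPS
            and span_r <= u
            and span_q <= u
        ):
            chain_anchors = [
                Anchor(int(RS[m]), int(QS[m]), int(LN[m])) for m in members
            ]
            chains.append(
                Chain(chain_anchors, gap_edit, (rs0, re), (qs0, qe))
            )
    return chains


def _usable(seq: str, pos: int, step: int, direction: int) -> int:
    """Bases available from ``pos`` (exclusive boundary) before an N or end."""
    w = 0
    n = len(seq)
    while w < step:
        q = pos - 1 - w if direction < 0 else pos + w
        if q < 0 or q >= n or seq[q] == "N":
            break
        w += 1
    return w


def extend_chain(
    chain: Chain, x: Region, y: Region, p: Params
) -> Optional[CneHit]:
    """Grow a chain outwards while relative identity stays above threshold.

    Each iteration measures the edit distance of the next ``ext_step``-base
    windows on the left and on the right; both sides are added if the
    estimated identity allows it, otherwise only the cheaper side.  When
    the estimate would fall below the threshold, the actual edit distance
    of the whole current element is computed and adopted (it never exceeds
    the accumulated estimate), and extension resumes; a second failure at
    the same point terminates.  Returns a hit iff both final lengths lie in
    [min_len, max_len] and the measured identity reaches the threshold.
    """
    xb = x.bases.upper()
    yb = y.bases.upper()
    t = p.identity_t
    u = p.max_len
    step = p.ext_step
    rs, re = chain.ref_span
    qs, qe = chain.query_span
    d_est = chain.gap_edit
    refreshed = False

    while True:
        span = max(re - rs, qe - qs)
        room = u - span
        if room <= 0:
            break
        wl = min(_usable(xb, rs, step, -1), _usable(yb, qs, step, -1), room)
        wr = min(_usable(xb, re, step, +1), _usable(yb, qe, step, +1), room)
        if wl == 0 and wr == 0:
            break
        dl = edit_distance(xb[rs - wl : rs], yb[qs - wl : qs]) if wl else 0
        dr = edit_distance(xb[re : re + wr], yb[qe : qe + wr]) if wr else 0

        if wl and wr and wl + wr <= room:
            if 1.0 - (d_est + dl + dr) / (span + wl + wr) >= t - _EPS:
                rs, qs = rs - wl, qs - wl
                re, qe = re + wr, qe + wr
                d_est += dl + dr
                refreshed = False
                continue
        # single side: smaller window distance wins, ties go left
        sides = []
        if wl:
            sides.append((dl, 0, wl))
        if wr:
            sides.append((dr, 1, wr))
        sides.sort()
        d_one, which, w_one = sides[0]
        if 1.0 - (d_est + d_one) / (span + w_one) >= t - _EPS:
            if which == 0:
                rs, qs = rs - w_one, qs - w_one
            else:
                re, qe = re + w_one, qe + w_one
            d_est += d_one
            refreshed = False
            continue
        if not refreshed:
            d_est = edit_distance(xb[rs:re], yb[qs:qe])
            refreshed = True
            continue
        break

    d = edit_distance(xb[rs:re], yb[qs:qe])
    rl, ql = re - rs, qe - qs
    identity = 1.0 - d / max(rl, ql)
    if p.min_len <= rl <= u and p.min_len <= ql <= u and identity >= t - _EPS:
        return CneHit(
            ref_name=x.seq_name,
            ref_start=x.offset + rs,
            ref_end=x.offset + re,
            query_name=y.seq_name,
            query_start=y.offset + qs,
            query_end=y.offset + qe,
            edit_distance=d,
            identity=identity,
        )
    return None


def _reciprocal_overlap(a0: int, a1: int, b0: int, b1: int) -> float:
    ov = min(a1, b1) - max(a0, b0)
    if ov <= 0:
        return 0.0
    return min(ov / (a1 - a0), ov / (b1 - b0))


def dedup_hits(hits: Sequence[CneHit]) -> list[CneHit]:
    """Collapse hits that reciprocally overlap > 50% on both intervals.

    Overlapping hits are grouped transitively; the survivor of each group
    has the highest identity, then the longest reference span, then the
    smallest ref_start.  Output is sorted by (ref_name, ref_start).
    """
    n = len(hits)
    if n <= 1:
        return sorted(
            hits, key=lambda h: (h.ref_name, h.ref_start, h.ref_end, h.query_start)
        )
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    idx = sorted(range(n), key=lambda i: (hits[i].ref_name, hits[i].ref_start))
    for a_pos, i in enumerate(idx):
        hi = hits[i]
        for j in idx[a_pos + 1 :]:
            hj = hits[j]
            if hj.ref_name != hi.ref_name or hj.ref_start >= hi.ref_end:
                break
            if (
                hj.query_name == hi.query_name
                and hj.query_strand == hi.query_strand
                and _reciprocal_overlap(hi.ref_start, hi.ref_end, hj.ref_start, hj.ref_end) > 0.5
                and _reciprocal_overlap(hi.query_start, hi.query_end, hj.query_start, hj.query_end) > 0.5
            ):
                parent[find(i)] = find(j)
    groups: dict[int, list[CneHit]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(hits[i])
    survivors = [
        max(g, key=lambda h: (h.identity, h.ref_end - h.ref_start, -h.ref_start))
        for g in groups.values()
    ]
    survivors.sort(key=lambda h: (h.ref_name, h.ref_start, h.ref_end, h.query_start))
    return survivors


def discover_cnes(
    x: Region, y: Region, p: Params, n_workers: int = 1
) -> list[CneHit]:
    """Run the full seed → merge → extend → dedup pipeline on two regions.

    Every returned hit is independently re-verifiable: the identity of the
    two reported substrings reaches the threshold and both lengths lie in
    [min_len, max_len].  Output is deterministic and independent of
    ``n_workers``.
    """
    l_min = min_anchor_length(p)
    anchors = find_mems(x, y, l_min, n_workers=n_workers)
    logger.info("seed stage: %d anchors (L_min=%d)", len(anchors), l_min)
    chains = merge_anchors(anchors, x, y, p)
    logger.info("merge stage: %d chains kept", len(chains))
    hits = []
    for ch in chains:
        logger.debug(
            "chain ref=%s query=%s cov=%d gap_edit=%d",
            ch.ref_span, ch.query_span, ch.anchor_coverage, ch.gap_edit,
        )
        h = extend_chain(ch, x, y, p)
        if h is not None:
            hits.append(h)
    out = dedup_hits(hits)
    logger.info("extend stage: %d hits reported", len(out))
    return out
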