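"""Seeded synthetic data: sequence pairs with planted conserved elements.

The generator emulates the structure the search targets: two unrelated
random backgrounds sharing a set of planted homologous segments whose
length and divergence are controlled exactly — each planted copy carries
exactly ``ceil(divergence * length)`` mutations at distinct positions,
substitutions always change the base, and indels are single-base.  Decoy
segments are planted above the divergence budget and must not be
reported.  A truth table records every planted interval so recovery can
be scored by reciprocal overlap.

What this does *not* emulate: substitution-rate heterogeneity, large
indels or rearrangements, segmental duplication, and real repeat
structure; passing tests demonstrate algorithmic correctness on the
stated divergence model, not performance on real assemblies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .core import CneHit

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic reference/query pair.

    Defaults describe the standard benchmark condition: a 1 Mbp reference
    and 0.5 Mbp query at human-like GC (0.41), 50 planted CNEs of
    200–500 bp at 2% divergence, and 10 decoys at 20% divergence.
    """

    ref_len: int = 1_000_000
    query_len: int = 500_000
    gc: float = 0.41
    n_cne: int = 50
    cne_len_range: tuple[int, int] = (200, 500)
    divergence: float = 0.02
    indel_fraction: float = 0.1
    n_decoys: int = 10
    decoy_divergence: float = 0.20
    exon_density: float = 0.05
    seed: int = 42
    ref_name: str = "ref1"
    query_name: str = "query1"

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("gc must be in [0, 1]")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence must be in [0, 1)")
        if self.n_decoys and self.decoy_divergence <= self.divergence:
            raise ValueError("decoy_divergence must exceed divergence")
        lo, hi = self.cne_len_range
        if not (1 <= lo <= hi):
            raise ValueError("cne_len_range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class TruthRecord:
    """One planted segment pair and its exact mutation accounting."""

    ref_name: str
    ref_start: int
    ref_end: int
    query_name: str
    query_start: int
    query_end: int
    n_substitutions: int
    n_indels: int
    realized_identity: float
    is_decoy: bool = False


@dataclass
class SynthPair:
    """In-memory result of :func:`generate_pair`, with file writers."""

    ref: dict[str, str]
    query: dict[str, str]
    truth: list[TruthRecord]
    exons: list[tuple[int, int]]  # 0-based half-open, on the reference
    spec: SynthSpec

    def write(self, outdir: Union[str, Path]) -> dict[str, Path]:
        from .io import write_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ref": outdir / "ref.fa",
            "query": outdir / "query.fa",
            "truth": outdir / "truth.tsv",
            "exons": outdir / "exons.gff3",
        }
        write_fasta(self.ref, paths["ref"])
        write_fasta(self.query, paths["query"])
        with open(paths["truth"], "w") as fh:
            fh.write(
                "# ref_name\tref_start\tref_end\tquery_name\tquery_start\t"
                "query_end\tn_substitutions\tn_indels\trealized_identity\tis_decoy\n"
            )
            for r in self.truth:
                fh.write(
                    f"{r.ref_name}\t{r.ref_start}\t{r.ref_end}\t{r.query_name}\t"
                    f"{r.query_start}\t{r.query_end}\t{r.n_substitutions}\t"
                    f"{r.n_indels}\t{r.realized_identity:.6f}\t{int(r.is_decoy)}\n"
                )
        with open(paths["exons"], "w") as fh:
            fh.write("##gff-version 3\n")
            name = self.spec.ref_name
            for i, (s, e) in enumerate(self.exons, start=1):
                fh.write(
                    f"{name}\tsynth\texon\t{s + 1}\t{e}\t.\t+\t."
                    f"\tID=exon{i};Parent=gene{i}\n"
                )
        return paths


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.41) -> str:
    """Random sequence with the given expected GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)].tobytes().decode("ascii")


def mutate_sequence(
    seq: str,
    divergence: float,
    indel_fraction: float,
    rng: np.random.Generator,
) -> tuple[str, int, int, list[int]]:
    """Plant exactly ``ceil(divergence*len)`` mutations at distinct positions.

    Substitutions always change the base; indels are 1-bp insertions or
    deletions.  Returns (mutated sequence, n_substitutions, n_indels,
    sorted mutated positions), so the realized divergence is exact rather
    than binomially noisy.
    """
    n = len(seq)
    n_mut = math.ceil(divergence * n)
    if n_mut == 0:
        return seq, 0, 0, []
    if n_mut > n:
        raise ValueError("divergence implies more mutations than positions")
    positions = np.sort(rng.choice(n, size=n_mut, replace=False))
    n_indel = int(round(indel_fraction * n_mut))
    indel_mask = np.zeros(n_mut, dtype=bool)
    if n_indel:
        indel_mask[rng.choice(n_mut, size=n_indel, replace=False)] = True
    pos_set = {int(p): bool(m) for p, m in zip(positions, indel_mask)}
    out: list[str] = []
    for i, base in enumerate(seq):
        if i not in pos_set:
            out.append(base)
            continue
        if not pos_set[i]:  # substitution: pick a different base
            others = [b for b in "ACGT" if b != base]
            out.append(others[rng.integers(3)])
        elif rng.integers(2) == 0:  # deletion
            pass
        else:  # insertion before the kept base
            out.append("ACGT"[rng.integers(4)])
            out.append(base)
    return "".join(out), n_mut - n_indel, n_indel, [int(p) for p in positions]


def _place_intervals(
    total_len: int,
    lengths: Sequence[int],
    rng: np.random.Generator,
    occupied: Optional[list[tuple[int, int]]] = None,
    margin: int = 10,
    max_tries: int = 10_000,
) -> list[tuple[int, int]]:
    """Place intervals of the given lengths without mutual overlap."""
    placed: list[tuple[int, int]] = []
    taken = list(occupied or [])
    for ln in lengths:
        if ln + 2 * margin > total_len:
            raise ValueError("sequence too short for a planted interval; use longer sequences")
        for _ in range(max_tries):
            s = int(rng.integers(margin, total_len - ln - margin + 1))
            e = s + ln
            if all(e + margin <= ts or s >= te + margin for ts, te in taken):
                placed.append((s, e))
                taken.append((s, e))
                break
        else:
            raise ValueError(
                "could not place planted intervals without overlap; use longer sequences"
            )
    return placed


def generate_pair(spec: SynthSpec) -> SynthPair:
    """Generate a reference/query pair with planted CNEs, decoys and exons.

    Planted segments are copied from the reference background into the
    query at mutually non-overlapping positions; decoys follow the same
    path at ``decoy_divergence``.  Fake exon features cover roughly
    ``exon_density`` of the reference, never intersecting a planted
    interval (planted elements are non-coding by construction).  Output is
    fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    ref_seq = random_dna(rng, spec.ref_len, spec.gc)
    query_bg = random_dna(rng, spec.query_len, spec.gc)

    n_planted = spec.n_cne + spec.n_decoys
    lo, hi = spec.cne_len_range
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n_planted)]
    ref_ivs = _place_intervals(spec.ref_len, lengths, rng)

    segments: list[tuple[tuple[int, int], str, int, int, bool]] = []
    for idx, (s, e) in enumerate(ref_ivs):
        is_decoy = idx >= spec.n_cne
        rate = spec.decoy_divergence if is_decoy else spec.divergence
        mut, n_sub, n_ind, _ = mutate_sequence(
            ref_seq[s:e], rate, spec.indel_fraction, rng
        )
        segments.append(((s, e), mut, n_sub, n_ind, is_decoy))

    q_lengths = [len(m) for _, m, _, _, _ in segments]
    q_ivs = _place_intervals(spec.query_len, q_lengths, rng)

    query = list(query_bg)
    truth: list[TruthRecord] = []
    for ((rs, re), mut, n_sub, n_ind, is_decoy), (qs, qe) in zip(segments, q_ivs):
        query[qs:qe] = mut
        truth.append(
            TruthRecord(
                ref_name=spec.ref_name, ref_start=rs, ref_end=re,
                query_name=spec.query_name, query_start=qs, query_end=qe,
                n_substitutions=n_sub, n_indels=n_ind,
                realized_identity=1.0 - (n_sub + n_ind) / max(re - rs, qe - qs),
                is_decoy=is_decoy,
            )
        )
    truth.sort(key=lambda r: r.ref_start)

    exons: list[tuple[int, int]] = []
    if spec.exon_density > 0:
        target = int(spec.exon_density * spec.ref_len)
        exon_lens = []
        while sum(exon_lens) < target:
            exon_lens.append(int(rng.integers(100, 301)))
        exons = sorted(
            _place_intervals(spec.ref_len, exon_lens, rng, occupied=list(ref_ivs))
        )

    return SynthPair(
        ref={spec.ref_name: ref_seq},
        query={spec.query_name: "".join(query)},
        truth=truth,
        exons=exons,
        spec=spec,
    )


@dataclass
class RecoveryReport:
    """Sensitivity and overlap accounting of hits against planted truth."""

    n_truth: int
    n_recovered: int
    sensitivity: float
    mean_overlap_pct: float  # mean % of truth nucleotides covered, matched pairs only
    n_unmatched_hits: int
    n_decoy_hits: int
    recovered: list[bool] = field(default_factory=list)


def _recip(a0: int, a1: int, b0: int, b1: int) -> float:
    ov = min(a1, b1) - max(a0, b0)
    if ov <= 0:
        return 0.0
    return min(ov / (a1 - a0), ov / (b1 - b0))


def _truth_cov(a0: int, a1: int, b0: int, b1: int) -> float:
    """Fraction of the truth interval (a) covered by the hit (b)."""
    ov = min(a1, b1) - max(a0, b0)
    return max(0.0, ov / (a1 - a0))


def score_recovery(
    hits: Sequence[CneHit],
    truth: Sequence[TruthRecord],
    min_overlap: float = 0.8,
) -> RecoveryReport:
    """Match hits to truth records by reciprocal overlap on both intervals.

    A truth record is recovered when some hit reciprocally overlaps it by
    at least ``min_overlap`` on the reference AND the query interval.
    Hits overlapping a decoy (same rule) are counted separately from hits
    matching nothing.
    """
    cnes = [r for r in truth if not r.is_decoy]
    decoys = [r for r in truth if r.is_decoy]

    def matches(h: CneHit, r: TruthRecord) -> bool:
        return (
            h.ref_name == r.ref_name
            and h.query_name == r.query_name
            and _recip(r.ref_start, r.ref_end, h.ref_start, h.ref_end) >= min_overlap
            and _recip(r.query_start, r.query_end, h.query_start, h.query_end) >= min_overlap
        )

    recovered: list[bool] = []
    overlaps: list[float] = []
    hit_used = [False] * len(hits)
    for r in cnes:
        best = None
        for i, h in enumerate(hits):
            if matches(h, r):
                hit_used[i] = True
                cov = 100.0 * 0.5 * (
                    _truth_cov(r.ref_start, r.ref_end, h.ref_start, h.ref_end)
                    + _truth_cov(r.query_start, r.query_end, h.query_start, h.query_end)
                )
                if best is None or cov > best:
                    best = cov
        recovered.append(best is not None)
        if best is not None:
            overlaps.append(best)

    n_decoy_hits = 0
    n_unmatched = 0
    for i, h in enumerate(hits):
        if hit_used[i]:
            continue
        if any(matches(h, r) for r in decoys):
            n_decoy_hits += 1
        else:
            n_unmatched += 1

    n_rec = sum(recovered)
    return RecoveryReport(
        n_truth=len(cnes),
        n_recovered=n_rec,
        sensitivity=n_rec / len(cnes) if cnes else 0.0,
        mean_overlap_pct=float(np.mean(overlaps)) if overlaps else 0.0,
        n_unmatched_hits=n_unmatched,
        n_decoy_hits=n_decoy_hits,
        recovered=recovered,
    )
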