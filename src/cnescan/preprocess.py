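"""Search-space restriction: masking and region selection.

CNEs live in intergenic and intronic sequence, so exons and repeats are
removed from the search before seeding.  Masking replaces bases with
``N`` rather than deleting them, which keeps every downstream coordinate
in source-sequence space (no offset translation table to get wrong).

Coordinate conventions are converted **here and nowhere else**: GFF3 is
1-based inclusive, BED is 0-based half-open; internally everything is
0-based half-open.
"""

from __future__ import annotations

import difflib
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import gffutils

from .core import Region

logger = logging.getLogger(__name__)

#: GFF3 feature types treated as exonic for masking
DEFAULT_EXON_TYPES: tuple[str, ...] = ("exon", "CDS")

#: default window (bp) taken on each side of a gene in gene mode
DEFAULT_FLANK = 1_000_000

Intervals = list[tuple[int, int]]


@dataclass(frozen=True)
class MaskTrack:
    """Merged, sorted, non-overlapping masked intervals on one sequence."""

    seq_name: str
    intervals: tuple[tuple[int, int], ...]

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass(frozen=True)
class SearchRequest:
    """Where to search: around a gene, an explicit range, or a whole record."""

    mode: str  # "gene" | "range" | "whole"
    seq_name: Optional[str] = None
    gene_name: Optional[str] = None
    flank: int = DEFAULT_FLANK
    start: Optional[int] = None
    end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode not in ("gene", "range", "whole"):
            raise ValueError(f"unknown search mode {self.mode!r}")
        if self.mode == "range":
            if self.start is None or self.end is None or not (0 <= self.start < self.end):
                raise ValueError("range mode requires 0 <= start < end")
        if self.mode == "gene" and not self.gene_name:
            raise ValueError("gene mode requires a gene name")


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> Intervals:
    """Union of half-open intervals: sorted, merged, empties dropped."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: Intervals = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def read_gff3(path: Union[str, Path]) -> gffutils.FeatureDB:
    """Load a GFF3 file into an in-memory feature database.

    Lines are validated first so a malformed row is reported by number.
    """
    path = Path(path)
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{ln}: malformed GFF3 line "
                    f"(expected 9 tab-separated fields, got {len(fields)})"
                )
            try:
                s, e = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer GFF3 coordinates") from exc
            if s < 1 or e < s:
                raise ValueError(f"{path}:{ln}: invalid GFF3 coordinates {s}..{e}")
    return gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )


def read_bed(path: Union[str, Path]) -> dict[str, Intervals]:
    """BED3+ intervals (0-based half-open) grouped by sequence name."""
    path = Path(path)
    out: dict[str, Intervals] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: BED line has fewer than 3 fields")
            try:
                s, e = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer BED coordinates") from exc
            if s < 0 or e < s:
                raise ValueError(f"{path}:{ln}: invalid BED interval {s}-{e}")
            out.setdefault(fields[0], []).append((s, e))
    return out


def exon_intervals(
    db: gffutils.FeatureDB,
    seq_name: str,
    exon_types: Sequence[str] = DEFAULT_EXON_TYPES,
) -> Intervals:
    """0-based half-open intervals of exonic features on one sequence."""
    ivs: Intervals = []
    for ftype in exon_types:
        try:
            feats = db.features_of_type(ftype)
        except gffutils.exceptions.FeatureNotFoundError:  # pragma: no cover
            continue
        for f in feats:
            if f.seqid != seq_name:
                continue
            ivs.append((f.start - 1, f.end))  # GFF3 1-based inclusive -> half-open
    return ivs


def softmask_intervals(sequence: str) -> Intervals:
    """Maximal lowercase runs, as repeat intervals."""
    return [(m.start(), m.end()) for m in re.finditer(r"[a-z]+", sequence)]


def build_mask(
    sequence: str,
    seq_name: str = "",
    annotation: Union[gffutils.FeatureDB, Iterable[tuple[int, int]], None] = None,
    repeats: Optional[Iterable[tuple[int, int]]] = None,
    use_softmask: bool = True,
    exon_types: Sequence[str] = DEFAULT_EXON_TYPES,
) -> MaskTrack:
    """Merged union of exon, repeat and (optionally) soft-mask intervals.

    ``annotation`` may be a gffutils FeatureDB (1-based coordinates are
    converted here) or pre-converted 0-based half-open intervals.
    Intervals are clipped to the sequence.
    """
    ivs: Intervals = []
    if annotation is not None:
        if isinstance(annotation, gffutils.FeatureDB):
            ivs.extend(exon_intervals(annotation, seq_name, exon_types))
        else:
            ivs.extend(annotation)
    if repeats is not None:
        ivs.extend(repeats)
    if use_softmask:
        ivs.extend(softmask_intervals(sequence))
    n = len(sequence)
    clipped = [(max(0, s), min(n, e)) for s, e in ivs]
    return MaskTrack(seq_name, tuple(merge_intervals(clipped)))


def apply_mask(region: Region, mask: MaskTrack) -> Region:
    """Replace masked positions with ``N``; coordinates are untouched.

    Mask intervals are in source-sequence coordinates; the region's offset
    is honoured.  Bases are normalised to uppercase here (soft-mask
    information has already been harvested by :func:`build_mask`).
    """
    bases = list(region.bases.upper())
    lo, hi = region.offset, region.end
    for s, e in mask.intervals:
        s, e = max(s, lo), min(e, hi)
        for i in range(s - lo, e - lo):
            bases[i] = "N"
    return Region(region.seq_name, region.offset, "".join(bases))


def _gene_names(db: gffutils.FeatureDB) -> dict[str, list]:
    """Map every Name/ID-like attribute value to its features."""
    names: dict[str, list] = {}
    for f in db.all_features():
        for key in ("Name", "ID", "gene_name", "gene_id", "gene"):
            for v in f.attributes.get(key, []):
                names.setdefault(v, []).append(f)
    return names


def select_region(
    fasta: dict[str, str],
    request: SearchRequest,
    annotation: Optional[gffutils.FeatureDB] = None,
) -> Region:
    """Carve the search region out of a FASTA record.

    gene mode: the window ``[gene_start - flank, gene_end + flank]``
    clamped to the record; range mode: the requested slice; whole mode:
    the full record.  Masking is applied separately (selection and masking
    are orthogonal).
    """
    if request.mode == "gene":
        if annotation is None:
            raise ValueError("gene mode requires a GFF3 annotation")
        names = _gene_names(annotation)
        feats = names.get(request.gene_name)
        if not feats:
            near = difflib.get_close_matches(request.gene_name, names.keys(), n=5)
            hint = f"; similar names: {', '.join(near)}" if near else ""
            raise ValueError(f"gene {request.gene_name!r} not found in annotation{hint}")
        spans = {(f.seqid, f.start, f.end) for f in feats}
        if len(spans) > 1:
            raise ValueError(
                f"gene name {request.gene_name!r} matches {len(spans)} distinct "
                "features; use an unambiguous ID"
            )
        f = feats[0]
        if f.seqid not in fasta:
            raise ValueError(f"gene {request.gene_name!r} lies on unknown sequence {f.seqid!r}")
        seq = fasta[f.seqid]
        start = max(0, f.start - 1 - request.flank)
        end = min(len(seq), f.end + request.flank)
        return Region(f.seqid, start, seq[start:end])

    name = request.seq_name
    if name is None:
        if len(fasta) != 1:
            raise ValueError("multi-record FASTA: a sequence name is required")
        name = next(iter(fasta))
    if name not in fasta:
        raise ValueError(f"sequence {name!r} not found in FASTA")
    seq = fasta[name]

    if request.mode == "whole":
        return Region(name, 0, seq)
    start = request.start
    end = min(request.end, len(seq))
    if start >= len(seq):
        raise ValueError(f"range start {start} beyond end of {name} ({len(seq)} bp)")
    return Region(name, start, seq[start:end])
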