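"""FASTA input and the tab-separated CNE table output.

The output table is BED-like: 0-based half-open coordinates, one row per
hit, a ``#``-prefixed header recording the tool version and the full
parameter set so a run can be reproduced from its output file alone.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Optional, Sequence, Union

from Bio import SeqIO

from . import __version__
from .core import CneHit, Params

logger = logging.getLogger(__name__)

# IUPAC ambiguity codes (and U) degrade to N; anything else is an error
_AMBIG = "RYSWKMBDHVU"
_TO_N = str.maketrans(_AMBIG + _AMBIG.lower(), "N" * len(_AMBIG) + "n" * len(_AMBIG))
_INVALID = re.compile(r"[^ACGTNacgtn]")

COLUMNS = (
    "ref_name", "ref_start", "ref_end",
    "query_name", "query_start", "query_end",
    "ref_len", "query_len", "edit_distance", "identity", "query_strand",
)


def read_fasta(path: Union[str, Path]) -> dict[str, str]:
    """Read a (possibly wrapped) multi-record FASTA, preserving case.

    Lowercase is kept so soft-masked repeats can be harvested later.
    Record names are the first whitespace-delimited header token and must
    be unique.  IUPAC ambiguity codes are converted to ``N`` (counted in
    the log); any other character is an error.
    """
    path = Path(path)
    out: dict[str, str] = {}
    n_ambig = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate sequence name {rec.id!r}")
        seq = str(rec.seq)
        m = _INVALID.search(seq.translate(_TO_N))
        if m:
            raise ValueError(
                f"{path}: record {rec.id!r} has non-IUPAC character "
                f"{m.group()!r} at position {m.start() + 1}"
            )
        n_ambig += sum(seq.count(c) for c in _AMBIG + _AMBIG.lower())
        out[rec.id] = seq.translate(_TO_N)
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    if n_ambig:
        logger.warning("%s: %d ambiguous IUPAC bases converted to N", path, n_ambig)
    return out


def write_fasta(seqs: dict[str, str], path: Union[str, Path], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_cnes(
    hits: Sequence[CneHit],
    path: Union[str, Path],
    params: Optional[Params] = None,
) -> None:
    """Write hits as a tab-separated table with a reproducibility header."""
    with open(path, "w") as fh:
        fh.write(f"# cnescan {__version__}\n")
        if params is not None:
            fh.write(
                "# params: "
                f"min_len={params.min_len} max_len={params.max_len} "
                f"identity_t={params.identity_t} "
                f"user_anchor_len={params.user_anchor_len} "
                f"min_chain_coverage={params.min_chain_coverage} "
                f"ext_step={params.ext_step} merge_max_gap={params.merge_max_gap}\n"
            )
        fh.write("# " + "\t".join(COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.ref_name}\t{h.ref_start}\t{h.ref_end}\t"
                f"{h.query_name}\t{h.query_start}\t{h.query_end}\t"
                f"{h.ref_len}\t{h.query_len}\t{h.edit_distance}\t"
                f"{h.identity:.4f}\t{h.query_strand}\n"
            )


def read_cnes(path: Union[str, Path]) -> list[CneHit]:
    """Parse a table written by :func:`write_cnes` back into hits.

    Identity is recovered at the printed 4-decimal precision.
    """
    hits: list[CneHit] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != len(COLUMNS):
                raise ValueError(f"{path}:{ln}: expected {len(COLUMNS)} columns, got {len(f)}")
            hits.append(
                CneHit(
                    ref_name=f[0], ref_start=int(f[1]), ref_end=int(f[2]),
                    query_name=f[3], query_start=int(f[4]), query_end=int(f[5]),
                    edit_distance=int(f[8]), identity=float(f[9]),
                    query_strand=f[10],
                )
            )
    return hits
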