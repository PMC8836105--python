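"""Residue-numbering transfer and motif scanning.

Maps positions between alignment columns and full-length coordinates, and
between two reference proteins via a pairwise global alignment (e.g. the
Glc7 K210/K259 -> Ppz1 D566/D615 correspondence).  All positions are
1-based full-length numbers; landing on a gap yields ``None``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .seq_io import GAP, STANDARD_AA, SeqRecord
from .conservation import AlignedGroupSet

__all__ = [
    "AlignParams",
    "PairwiseAlignment",
    "global_align",
    "transfer_position",
    "column_to_residue",
    "residue_to_column",
    "scan_motif",
]


@dataclass(frozen=True)
class AlignParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass
class PairwiseAlignment:
    idA: str
    idB: str
    alignedA: str
    alignedB: str
    score: float
    params: AlignParams
    offsetA: int = 1
    offsetB: int = 1

    def __post_init__(self) -> None:
        if len(self.alignedA) != len(self.alignedB):
            raise ValueError("aligned strings must have equal length")


def global_align(
    A: SeqRecord, B: SeqRecord, params: AlignParams | None = None
) -> PairwiseAlignment:
    """Needleman-Wunsch global alignment with affine gaps (BLOSUM62, 10/0.5).

    Backed by Bio.Align.PairwiseAligner; the first optimal traceback is
    taken, which is deterministic for fixed inputs and parameters.
    """
    params = params or AlignParams()
    if not A.residues or not B.residues:
        raise ValueError("cannot align empty sequences")
    for rec in (A, B):
        bad = set(rec.residues) - STANDARD_AA - {"X"}
        if bad:
            raise ValueError(f"record {rec.id!r}: non-standard residues {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    aln = aligner.align(A.residues, B.residues)[0]
    return PairwiseAlignment(
        idA=A.id,
        idB=B.id,
        alignedA=str(aln[0]),
        alignedB=str(aln[1]),
        score=float(aln.score),
        params=params,
        offsetA=A.offset,
        offsetB=B.offset,
    )


def _column_of_position(gapped: str, stored_pos: int) -> int:
    """Column index (0-based) holding the ``stored_pos``-th non-gap char."""
    count = 0
    for col, ch in enumerate(gapped):
        if ch != GAP:
            count += 1
            if count == stored_pos:
                return col
    raise ValueError(f"position {stored_pos} outside sequence")


def transfer_position(
    pa: PairwiseAlignment, pos: int, source: str = "A"
) -> int | None:
    """Map a full-length position in one sequence to the other via ``pa``.

    Returns the partner's full-length residue number, or ``None`` when the
    partner has a gap in that column.
    """
    if source not in ("A", "B"):
        raise ValueError("source must be 'A' or 'B'")
    if source == "A":
        src_aln, dst_aln = pa.alignedA, pa.alignedB
        src_off, dst_off = pa.offsetA, pa.offsetB
    else:
        src_aln, dst_aln = pa.alignedB, pa.alignedA
        src_off, dst_off = pa.offsetB, pa.offsetA
    stored = pos - src_off + 1
    n_src = sum(1 for ch in src_aln if ch != GAP)
    if not 1 <= stored <= n_src:
        raise ValueError(
            f"position {pos} outside sequence range "
            f"{src_off}..{src_off + n_src - 1}"
        )
    col = _column_of_position(src_aln, stored)
    if dst_aln[col] == GAP:
        return None
    return dst_off + sum(1 for ch in dst_aln[: col + 1] if ch != GAP) - 1


def column_to_residue(aln: AlignedGroupSet, column: int, seq_id: str) -> int | None:
    """Full-length residue number at an alignment column for one sequence.

    Returns ``None`` when the sequence has a gap in that column.
    """
    rec = aln.record_by_id(seq_id)
    if not 1 <= column <= aln.ncol:
        raise ValueError(f"column {column} outside 1..{aln.ncol}")
    if rec.residues[column - 1] == GAP:
        return None
    nongaps = sum(1 for ch in rec.residues[:column] if ch != GAP)
    return rec.offset + nongaps - 1


def residue_to_column(aln: AlignedGroupSet, pos: int, seq_id: str) -> int:
    """Inverse of :func:`column_to_residue` on non-gap positions."""
    rec = aln.record_by_id(seq_id)
    stored = pos - rec.offset + 1
    n = sum(1 for ch in rec.residues if ch != GAP)
    if not 1 <= stored <= n:
        raise ValueError(f"position {pos} outside sequence {seq_id!r}")
    return _column_of_position(rec.residues, stored) + 1


_MOTIF_TOKEN = re.compile(r"([A-WYZ])|x|X|\[([A-Z]+)\]")


def _motif_to_regex(pattern: str) -> str:
    """Translate a motif expression (letters, 'x' wildcard, [KR] classes)."""
    out = []
    i = 0
    any_res = "[" + "".join(sorted(STANDARD_AA)) + "]"
    while i < len(pattern):
        m = _MOTIF_TOKEN.match(pattern, i)
        if m is None:
            raise ValueError(f"malformed motif pattern at position {i + 1}: {pattern!r}")
        if m.group(0) in ("x", "X"):
            out.append(any_res)
        elif m.group(2) is not None:
            bad = set(m.group(2)) - STANDARD_AA
            if bad:
                raise ValueError(f"illegal residues in class: {sorted(bad)}")
            out.append("[" + m.group(2) + "]")
        else:
            if m.group(1) not in STANDARD_AA:
                raise ValueError(f"illegal residue letter {m.group(1)!r}")
            out.append(m.group(1))
        i = m.end()
    if not out:
        raise ValueError("empty motif pattern")
    return "".join(out)


def scan_motif(record: SeqRecord, pattern: str) -> list[tuple[int, int, str]]:
    """All (possibly overlapping) motif matches, 1-based full-length coords."""
    regex = re.compile("(?=(" + _motif_to_regex(pattern) + "))")
    seq = record.ungapped()
    hits = []
    for m in regex.finditer(seq):
        sub = m.group(1)
        start = record.offset + m.start()
        hits.append((start, start + len(sub) - 1, sub))
    return hits
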