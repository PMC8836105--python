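"""Sequence I/O, catalytic-domain trimming and small per-proteome statistics.

Residue numbering is 1-based, inclusive and always expressed in full-length
coordinates.  A trimmed record keeps its original numbering through the
``offset`` attribute: the full-length position of stored residue *i*
(1-based) is ``offset + i - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"

__all__ = [
    "SeqRecord",
    "GroupLabel",
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
    "trim_to_domain",
    "count_ser_thr",
    "theoretical_pi",
    "net_charge",
    "DEFAULT_PKA",
]


@dataclass
class SeqRecord:
    """A protein sequence (optionally gapped) with full-length numbering.

    Parameters
    ----------
    id : str
        Sequence identifier.
    residues : str
        Uppercase amino-acid string; ``-`` allowed when aligned, ``X`` for
        unknown residues.
    offset : int
        Full-length residue number of the first stored residue (>= 1).
    description : str
        Free-text description (may be empty).
    """

    id: str
    residues: str
    offset: int = 1
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.offset < 1:
            raise ValueError(f"record {self.id!r}: offset must be >= 1")
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)

    def full_position(self, i: int) -> int:
        """Full-length residue number of stored residue ``i`` (1-based)."""
        if not 1 <= i <= len(self.residues):
            raise IndexError(f"position {i} outside 1..{len(self.residues)}")
        return self.offset + i - 1

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass(frozen=True)
class GroupLabel:
    """Group (PP1 or PPZ) and clade assignment for one aligned sequence."""

    group: str
    clade: str

    def __post_init__(self) -> None:
        if self.group not in ("PP1", "PPZ"):
            raise ValueError(f"group must be 'PP1' or 'PPZ', got {self.group!r}")


def _validate_residues(rec_id: str, residues: str, aligned: bool) -> None:
    allowed = STANDARD_AA | {"X"} | ({GAP} if aligned else set())
    for i, ch in enumerate(residues, start=1):
        if ch not in allowed:
            raise ValueError(
                f"record {rec_id!r}: illegal character {ch!r} at position {i}"
            )


def read_fasta(path: str | Path, aligned: bool = False) -> list[SeqRecord]:
    """Read a (plain or aligned) protein FASTA file.

    Residues are uppercased, a single trailing ``*`` is stripped, gaps are
    legal only with ``aligned=True`` (where all records must have equal
    length).  Internal ``*`` or other illegal characters raise ``ValueError``.
    """
    records: list[SeqRecord] = []
    for bio in _BioSeqIO.parse(str(path), "fasta"):
        seq = str(bio.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        desc = bio.description
        if desc.startswith(bio.id):
            desc = desc[len(bio.id) :].strip()
        _validate_residues(bio.id, seq, aligned)
        records.append(SeqRecord(id=bio.id, residues=seq, description=desc))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if aligned:
        lengths = {len(r) for r in records}
        if len(lengths) > 1:
            raise ValueError(
                f"aligned FASTA {path} has unequal record lengths: {sorted(lengths)}"
            )
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA (60-column wrap)."""
    bio_records = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio_records)


def read_labels(path: str | Path) -> dict[str, GroupLabel]:
    """Read the sidecar label table (TSV: seq_id, group, clade)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"seq_id", "group", "clade"}
    if not required.issubset(df.columns):
        raise ValueError(f"label table {path} must have columns {sorted(required)}")
    labels: dict[str, GroupLabel] = {}
    for row in df.itertuples(index=False):
        if row.seq_id in labels:
            raise ValueError(f"duplicate seq_id {row.seq_id!r} in label table")
        labels[row.seq_id] = GroupLabel(group=row.group, clade=row.clade)
    return labels


def write_labels(labels: Mapping[str, GroupLabel], path: str | Path) -> None:
    rows = [
        {"seq_id": sid, "group": lab.group, "clade": lab.clade}
        for sid, lab in labels.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def trim_to_domain(record: SeqRecord, domain_start: int) -> SeqRecord:
    """Trim ``record`` to residues ``domain_start..end``, preserving numbering.

    The returned record's ``offset`` equals ``domain_start`` so that
    full-length coordinates survive the trim.
    """
    if domain_start < 1:
        raise ValueError("domain_start must be >= 1")
    if domain_start > len(record):
        raise ValueError(
            f"domain_start {domain_start} beyond sequence length {len(record)}"
        )
    if domain_start == 1:
        return replace(record)
    return replace(
        record,
        residues=record.residues[domain_start - 1 :],
        offset=record.offset + domain_start - 1,
    )


def count_ser_thr(records: Iterable[SeqRecord]) -> pd.DataFrame:
    """Count Ser and Thr per record (gaps excluded, case-normalised).

    Returns a DataFrame with columns id, nSer, nThr, length, fraction.
    """
    rows = []
    for rec in records:
        seq = rec.ungapped().upper()
        n_ser = seq.count("S")
        n_thr = seq.count("T")
        rows.append(
            {
                "id": rec.id,
                "nSer": n_ser,
                "nThr": n_thr,
                "length": len(seq),
                "fraction": (n_ser + n_thr) / len(seq) if seq else 0.0,
            }
        )
    if not rows:
        raise ValueError("count_ser_thr requires at least one record")
    return pd.DataFrame(rows)


# Bjellqvist-style side-chain / terminal pKa values, as used by common pI
# calculators.  Swappable; exact agreement with any one web tool is not
# asserted.
DEFAULT_PKA: dict[str, float] = {
    "Nterm": 7.50,
    "Cterm": 3.55,
    "D": 4.05,
    "E": 4.45,
    "C": 9.00,
    "Y": 10.00,
    "H": 5.98,
    "K": 10.00,
    "R": 12.00,
}

_POSITIVE = ("Nterm", "H", "K", "R")
_NEGATIVE = ("Cterm", "D", "E", "C", "Y")


def net_charge(
    sequence: str, ph: float, pka_table: Mapping[str, float] | None = None
) -> float:
    """Henderson-Hasselbalch net charge of ``sequence`` at ``ph``."""
    pka = dict(DEFAULT_PKA if pka_table is None else pka_table)
    seq = sequence.replace(GAP, "").upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues not allowed for pI: {sorted(bad)}")
    counts = {aa: seq.count(aa) for aa in "DECYHKR"}
    counts["Nterm"] = 1
    counts["Cterm"] = 1
    charge = 0.0
    for grp in _POSITIVE:
        n = counts.get(grp, 0)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pka[grp]))
    for grp in _NEGATIVE:
        n = counts.get(grp, 0)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka[grp] - ph))
    return charge


def theoretical_pi(
    record: SeqRecord | str,
    pka_table: Mapping[str, float] | None = None,
    tol: float = 1e-4,
) -> float:
    """Isoelectric point: pH where the net charge is zero (bisection on 0..14)."""
    seq = record.residues if isinstance(record, SeqRecord) else record
    lo, hi = 0.0, 14.0
    # net_charge is strictly decreasing in pH
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid, pka_table) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0
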