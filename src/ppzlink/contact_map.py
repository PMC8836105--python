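"""Bidimensional cross-link contact mapping.

Turns validated cross-links, or a tab-separated table in the Table-2 style
(ambiguous sites written ``356/359``, partner lists comma-separated), into
intra/inter link statistics, region-pair counts and exportable edge lists /
incidence matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CrossLinkRecord",
    "RegionScheme",
    "parse_xl_table",
    "classify_links",
    "fraction_by_type",
    "region_counts",
    "export_map",
]


@dataclass
class CrossLinkRecord:
    """One observed cross-link; site sets of size > 1 encode ambiguity."""

    protA: str
    protB: str
    sitesA: tuple[int, ...]
    sitesB: tuple[int, ...]
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sitesA or not self.sitesB:
            raise ValueError("site sets must be non-empty")
        self.sitesA = tuple(sorted(set(self.sitesA)))
        self.sitesB = tuple(sorted(set(self.sitesB)))

    @property
    def kind(self) -> str:
        return "intra" if self.protA == self.protB else "inter"


@dataclass
class RegionScheme:
    """Named half-open residue intervals per protein, e.g.
    ``{"Hal3": [("Nterm", 1, 260), ("PD_1", 260, 360), ...]}``."""

    regions: dict[str, list[tuple[str, int, int]]]

    def __post_init__(self) -> None:
        for prot, ivals in self.regions.items():
            names = [n for n, _, _ in ivals]
            if len(names) != len(set(names)):
                raise ValueError(f"duplicate region names for {prot!r}")

    def region_of(self, prot: str, site: int) -> str:
        for name, start, stop in self.regions.get(prot, []):
            if start <= site < stop:
                return name
        raise ValueError(f"site {site} of {prot!r} outside every region")


def _parse_sites(cell: str, row: int) -> tuple[int, ...]:
    sites = []
    for tok in str(cell).split("/"):
        tok = tok.strip()
        if not tok.isdigit():
            raise ValueError(f"row {row}: non-numeric site {tok!r}")
        sites.append(int(tok))
    return tuple(sites)


def parse_xl_table(
    path: str | Path,
    protA: str = "Ppz1",
    protB: str = "Hal3",
    offsetA: int = 0,
    offsetB: int = 0,
) -> list[CrossLinkRecord]:
    """Parse a Table-2-dialect TSV (two columns: siteA, partner list).

    ``/``-separated sites denote ambiguity; comma-separated partners expand
    to one record per partner.  ``offsetA``/``offsetB`` convert construct
    numbering to full-length on ingest (e.g. 344 for a Δ1-344 construct).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns")
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        sitesA = tuple(s + offsetA for s in _parse_sites(row[0], idx))
        for partner in str(row[1]).split(","):
            partner = partner.strip()
            if not partner:
                continue
            sitesB = tuple(s + offsetB for s in _parse_sites(partner, idx))
            records.append(CrossLinkRecord(protA, protB, sitesA, sitesB))
    return records


def classify_links(records: Sequence[CrossLinkRecord]) -> list[tuple[CrossLinkRecord, str]]:
    """Tag each record intra or inter (order-preserving)."""
    return [(r, r.kind) for r in records]


def fraction_by_type(records: Sequence[CrossLinkRecord]) -> dict[str, float]:
    """Proportion of links per type: ``intra:<protein>`` and ``inter``."""
    if not records:
        raise ValueError("fraction_by_type requires at least one record")
    counts: dict[str, int] = {}
    for r in records:
        key = f"intra:{r.protA}" if r.kind == "intra" else "inter"
        counts[key] = counts.get(key, 0) + 1
    n = len(records)
    return {k: v / n for k, v in sorted(counts.items())}


def region_counts(
    records: Sequence[CrossLinkRecord], scheme: RegionScheme
) -> dict[tuple[str, str], float]:
    """Link counts per (regionA, regionB) pair.

    Ambiguous sites are attributed fractionally (1/|set| per member), so
    the grand total equals the number of records.
    """
    counts: dict[tuple[str, str], float] = {}
    for r in records:
        wA = 1.0 / len(r.sitesA)
        wB = 1.0 / len(r.sitesB)
        for sA in r.sitesA:
            regA = scheme.region_of(r.protA, sA)
            for sB in r.sitesB:
                regB = scheme.region_of(r.protB, sB)
                counts[(regA, regB)] = counts.get((regA, regB), 0.0) + wA * wB
    return counts


def export_map(
    records: Sequence[CrossLinkRecord], lengths: Mapping[str, int]
) -> tuple[pd.DataFrame, dict[tuple[str, str], np.ndarray]]:
    """Edge-list DataFrame plus dense residue-keyed incidence matrices.

    The edge list has one row per member-site combination (ambiguous
    records flagged); matrices are keyed by (protA, protB) with shape
    (lenA, lenB), entry [i-1, j-1] counting links between residues i and j
    (fractional for ambiguous records).
    """
    rows = []
    matrices: dict[tuple[str, str], np.ndarray] = {}
    for ridx, r in enumerate(records):
        for prot in (r.protA, r.protB):
            if prot not in lengths:
                raise ValueError(f"unknown protein length for {prot!r}")
        for s in r.sitesA:
            if not 1 <= s <= lengths[r.protA]:
                raise ValueError(f"site {s} outside {r.protA}")
        for s in r.sitesB:
            if not 1 <= s <= lengths[r.protB]:
                raise ValueError(f"site {s} outside {r.protB}")
        key = (r.protA, r.protB)
        if key not in matrices:
            matrices[key] = np.zeros((lengths[r.protA], lengths[r.protB]))
        ambiguous = len(r.sitesA) > 1 or len(r.sitesB) > 1
        w = 1.0 / (len(r.sitesA) * len(r.sitesB))
        for sA in r.sitesA:
            for sB in r.sitesB:
                rows.append(
                    {
                        "record": ridx,
                        "protA": r.protA,
                        "siteA": sA,
                        "protB": r.protB,
                        "siteB": sB,
                        "ambiguous": ambiguous,
                    }
                )
                matrices[key][sA - 1, sB - 1] += w
    edges = pd.DataFrame(
        rows, columns=["record", "protA", "siteA", "protB", "siteB", "ambiguous"]
    )
    if not edges.empty:
        edges = edges.sort_values(
            ["protA", "siteA", "protB", "siteB", "record"]
        ).reset_index(drop=True)
    return edges, matrices
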