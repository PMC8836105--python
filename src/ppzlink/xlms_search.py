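"""Desk-scale BS3 cross-link identification.

Workflow: MGF ingestion -> scan filter (charge 3..9, tryptic y1 signature
peak, linker signature peak) -> tryptic digestion (4 missed cleavages) ->
candidate enumeration at 10 ppm precursor accuracy (cross-links, dead-ends,
linear peptides) -> theoretical b/y fragments of cross-linked pairs ->
fragment matching at 0.10 Da -> approval iff b- and/or y-ions from *both*
peptides are matched.

Scoring is matched-ion count; intensity is ignored (presence within
tolerance suffices).  No decoy/FDR machinery.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

from . import _chem
from ._chem import (
    BS3_BRIDGE,
    BS3_DEADEND_AMMONIA,
    BS3_DEADEND_WATER,
    CARBAMIDOMETHYL,
    OXIDATION,
    PROTON,
    RESIDUE_MASS,
    WATER,
)
from .seq_io import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Scan",
    "Peptide",
    "CrossLinkCandidate",
    "DeadEndCandidate",
    "LinearCandidate",
    "CandidateSet",
    "Ion",
    "XlmsConfig",
    "read_mgf",
    "write_mgf",
    "filter_scans",
    "digest",
    "peptide_mass",
    "oxidized_variants",
    "enumerate_candidates",
    "theoretical_fragments",
    "validate_and_score",
    "rank_candidates",
    "search_scan",
]


@dataclass
class Scan:
    title: str
    precursor_mz: float
    charge: int
    peaks: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"scan {self.title!r}: precursor m/z must be > 0")
        if self.charge < 1:
            raise ValueError(f"scan {self.title!r}: charge must be >= 1")
        self.peaks = sorted(self.peaks)

    def neutral_mass(self) -> float:
        return self.precursor_mz * self.charge - self.charge * PROTON


@dataclass
class Peptide:
    """A tryptic peptide with 1-based full-length coordinates.

    ``modifications`` holds *variable* modifications as
    (position-in-peptide, mass delta, name); the fixed carbamidomethyl on
    Cys is applied implicitly by the mass functions.
    """

    protein_id: str
    sequence: str
    start: int
    end: int
    missed_cleavages: int
    at_protein_nterm: bool = False
    at_protein_cterm: bool = False
    modifications: list[tuple[int, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("peptide coordinates inconsistent with sequence length")


@dataclass
class CrossLinkCandidate:
    pepA: Peptide
    pepB: Peptide
    siteA: int
    siteB: int
    neutral_mass: float
    precursor_error_ppm: float
    matched_fragments: dict[str, dict[str, int]] = field(default_factory=dict)
    approved: bool = False

    def total_matched(self) -> int:
        return sum(sum(v.values()) for v in self.matched_fragments.values())


@dataclass
class DeadEndCandidate:
    pep: Peptide
    site: int
    kind: str  # "water" | "ammonia"
    neutral_mass: float
    precursor_error_ppm: float


@dataclass
class LinearCandidate:
    pep: Peptide
    neutral_mass: float
    precursor_error_ppm: float


@dataclass
class CandidateSet:
    crosslinks: list[CrossLinkCandidate] = field(default_factory=list)
    deadends: list[DeadEndCandidate] = field(default_factory=list)
    linears: list[LinearCandidate] = field(default_factory=list)


@dataclass
class Ion:
    series: str  # "b" | "y"
    ordinal: int
    peptide: str  # "A" | "B"
    charge: int
    mz: float


def _default_y1() -> tuple[float, ...]:
    return (
        RESIDUE_MASS["K"] + WATER + PROTON,  # y1 of K-terminated peptides
        RESIDUE_MASS["R"] + WATER + PROTON,  # y1 of R-terminated peptides
    )


def _default_linker_signature() -> tuple[float, ...]:
    # y1-of-K carrying a BS3-water dead-end; placeholder default, the real
    # instrument signature list is configurable.
    return (RESIDUE_MASS["K"] + WATER + PROTON + BS3_DEADEND_WATER,)


@dataclass
class XlmsConfig:
    charge_min: int = 3
    charge_max: int = 9
    signature_y1_masses: tuple[float, ...] = field(default_factory=_default_y1)
    linker_signature_masses: tuple[float, ...] = field(
        default_factory=_default_linker_signature
    )
    ms1_tol_ppm: float = 10.0
    ms2_tol_da: float = 0.10
    max_missed: int = 4
    min_peptide_length: int = 1
    cleave_before_proline: bool = False  # True blocks cleavage K/R-P
    max_oxidations: int = 2
    max_fragment_charge: int = 2
    min_ions_per_peptide: int = 1

    # chemistry constants, derived from molecular formulas in _chem
    bridge_mass: float = BS3_BRIDGE
    deadend_water_mass: float = BS3_DEADEND_WATER
    deadend_ammonia_mass: float = BS3_DEADEND_AMMONIA


# ---------------------------------------------------------------------------
# MGF I/O


def read_mgf(path: str | Path) -> list[Scan]:
    """Parse an MGF peak-list file.

    Blocks without a CHARGE line are skipped with a logged warning (MGF
    dialects vary and the downstream filter discards unknown charges
    anyway); a block without PEPMASS, or a malformed peak line, is an error
    naming the block index.
    """
    scans: list[Scan] = []
    block_idx = 0
    in_block = False
    title = ""
    pepmass: float | None = None
    charge: int | None = None
    peaks: list[tuple[float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                block_idx += 1
                in_block = True
                title, pepmass, charge, peaks = f"scan_{block_idx}", None, None, []
                continue
            if line == "END IONS":
                if not in_block:
                    raise ValueError(f"MGF block {block_idx}: stray END IONS")
                if pepmass is None:
                    raise ValueError(f"MGF block {block_idx}: missing PEPMASS")
                if charge is None:
                    logger.warning(
                        "MGF block %d (%s): missing CHARGE, scan skipped",
                        block_idx,
                        title,
                    )
                else:
                    scans.append(Scan(title, pepmass, charge, peaks))
                in_block = False
                continue
            if not in_block:
                continue
            if "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                key = key.upper()
                if key == "TITLE":
                    title = value
                elif key == "PEPMASS":
                    pepmass = float(value.split()[0])
                elif key == "CHARGE":
                    charge = int(value.rstrip("+-"))
                continue
            parts = line.split()
            try:
                mz = float(parts[0])
                inten = float(parts[1]) if len(parts) > 1 else 0.0
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"MGF block {block_idx}: malformed peak line {line!r}"
                ) from exc
            peaks.append((mz, inten))
    if in_block:
        raise ValueError(f"MGF block {block_idx}: unterminated block")
    return scans


def write_mgf(scans: Iterable[Scan], path: str | Path) -> None:
    with open(path, "w") as fh:
        for scan in scans:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={scan.title}\n")
            fh.write(f"PEPMASS={scan.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={scan.charge}+\n")
            for mz, inten in scan.peaks:
                fh.write(f"{mz:.6f} {inten:.4f}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# Scan filter


def _has_peak_near(peaks_mz: list[float], target: float, tol: float) -> bool:
    i = bisect.bisect_left(peaks_mz, target - tol)
    return i < len(peaks_mz) and peaks_mz[i] <= target + tol


def filter_scans(scans: Sequence[Scan], cfg: XlmsConfig | None = None) -> list[Scan]:
    """Retain scans with charge in range, a tryptic y1 signature peak and a
    cross-linker signature peak (both within ``ms2_tol_da``)."""
    cfg = cfg or XlmsConfig()
    kept = []
    for scan in scans:
        if not cfg.charge_min <= scan.charge <= cfg.charge_max:
            continue
        mzs = [mz for mz, _ in scan.peaks]
        if not any(
            _has_peak_near(mzs, m, cfg.ms2_tol_da) for m in cfg.signature_y1_masses
        ):
            continue
        if not any(
            _has_peak_near(mzs, m, cfg.ms2_tol_da)
            for m in cfg.linker_signature_masses
        ):
            continue
        kept.append(scan)
    return kept


# ---------------------------------------------------------------------------
# Digestion and masses


def digest(protein: SeqRecord, cfg: XlmsConfig | None = None) -> list[Peptide]:
    """Tryptic digest: cleave C-terminal to K/R (optionally not before P),
    emitting every peptide with 0..max_missed missed cleavages."""
    cfg = cfg or XlmsConfig()
    seq = protein.ungapped()
    n = len(seq)
    cuts = [0]
    for i in range(1, n):
        if seq[i - 1] in "KR":
            if cfg.cleave_before_proline and seq[i] == "P":
                continue
            cuts.append(i)
    cuts.append(n)
    peptides = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + cfg.max_missed, len(cuts))):
            sub = seq[cuts[a] : cuts[b]]
            if len(sub) < cfg.min_peptide_length:
                continue
            peptides.append(
                Peptide(
                    protein_id=protein.id,
                    sequence=sub,
                    start=protein.offset + cuts[a],
                    end=protein.offset + cuts[b] - 1,
                    missed_cleavages=b - a - 1,
                    at_protein_nterm=(cuts[a] == 0),
                    at_protein_cterm=(cuts[b] == n),
                )
            )
    return peptides


def _residue_mass(aa: str) -> float:
    try:
        return RESIDUE_MASS[aa]
    except KeyError:
        raise ValueError(f"no monoisotopic mass for residue {aa!r}") from None


def peptide_mass(pep: Peptide, cfg: XlmsConfig | None = None) -> float:
    """Neutral monoisotopic peptide mass (fixed carbamidomethyl-C included)."""
    mass = WATER + sum(_residue_mass(aa) for aa in pep.sequence)
    mass += CARBAMIDOMETHYL * pep.sequence.count("C")
    for pos, delta, name in pep.modifications:
        if not 1 <= pos <= len(pep.sequence):
            raise ValueError(f"modification {name!r} outside peptide")
        if name.lower().startswith("oxidation") and pep.sequence[pos - 1] != "M":
            raise ValueError(
                f"oxidation on {pep.sequence[pos - 1]!r} at peptide position {pos}"
            )
        mass += delta
    return mass


def oxidized_variants(pep: Peptide, cfg: XlmsConfig | None = None) -> list[Peptide]:
    """The peptide plus variants carrying 1..max_oxidations Met oxidations."""
    cfg = cfg or XlmsConfig()
    met_pos = [i + 1 for i, aa in enumerate(pep.sequence) if aa == "M"]
    variants = [pep]
    for k in range(1, min(cfg.max_oxidations, len(met_pos)) + 1):
        for combo in combinations(met_pos, k):
            mods = pep.modifications + [(p, OXIDATION, "Oxidation") for p in combo]
            variants.append(replace(pep, modifications=mods))
    return variants


def legal_link_sites(pep: Peptide) -> list[int]:
    """Full-length positions in ``pep`` where a BS3 link may sit.

    Lysines anywhere except the C-terminal cleavage site (a linked K is
    uncleavable), unless that K is the protein C-terminus; plus the protein
    N-terminal residue, whatever it is.
    """
    sites = []
    n = len(pep.sequence)
    for i, aa in enumerate(pep.sequence, start=1):
        if aa == "K" and (i < n or pep.at_protein_cterm):
            sites.append(pep.start + i - 1)
    if pep.at_protein_nterm and pep.start not in sites:
        sites.insert(0, pep.start)
    return sites


# ---------------------------------------------------------------------------
# Candidate enumeration


def _ppm(measured: float, reference: float) -> float:
    return (measured - reference) / reference * 1e6


def _variant_masses(
    peps: Sequence[Peptide], cfg: XlmsConfig
) -> list[tuple[float, Peptide]]:
    out = []
    for pep in peps:
        for var in oxidized_variants(pep, cfg):
            out.append((peptide_mass(var, cfg), var))
    out.sort(key=lambda t: t[0])
    return out


def enumerate_candidates(
    pepsA: Sequence[Peptide],
    pepsB: Sequence[Peptide],
    scan: Scan,
    cfg: XlmsConfig | None = None,
) -> CandidateSet:
    """All precursor-mass-compatible explanations of ``scan`` at 10 ppm:
    cross-linked pairs (one peptide from each digest), single peptides with
    one BS3 dead-end, and plain linear peptides."""
    cfg = cfg or XlmsConfig()
    neutral = scan.neutral_mass()
    tol = cfg.ms1_tol_ppm * neutral / 1e6
    va = _variant_masses(pepsA, cfg)
    vb = _variant_masses(pepsB, cfg)
    vb_masses = [m for m, _ in vb]
    out = CandidateSet()

    target = neutral - cfg.bridge_mass
    for mA, pA in va:
        sitesA = legal_link_sites(pA)
        if not sitesA:
            continue
        lo = bisect.bisect_left(vb_masses, target - mA - tol)
        hi = bisect.bisect_right(vb_masses, target - mA + tol)
        for k in range(lo, hi):
            mB, pB = vb[k]
            sitesB = legal_link_sites(pB)
            if not sitesB:
                continue
            total = mA + mB + cfg.bridge_mass
            err = _ppm(total, neutral)
            if abs(err) > cfg.ms1_tol_ppm:
                continue
            for sA in sitesA:
                for sB in sitesB:
                    out.crosslinks.append(
                        CrossLinkCandidate(pA, pB, sA, sB, total, err)
                    )

    for masses in (va, vb):
        for m, pep in masses:
            err = _ppm(m, neutral)
            if abs(err) <= cfg.ms1_tol_ppm:
                out.linears.append(LinearCandidate(pep, m, err))
            for kind, delta in (
                ("water", cfg.deadend_water_mass),
                ("ammonia", cfg.deadend_ammonia_mass),
            ):
                total = m + delta
                err = _ppm(total, neutral)
                if abs(err) > cfg.ms1_tol_ppm:
                    continue
                for site in legal_link_sites(pep):
                    out.deadends.append(DeadEndCandidate(pep, site, kind, total, err))
    return out


# ---------------------------------------------------------------------------
# Fragments, matching, approval


def _fragment_neutrals(
    pep: Peptide, link_pos: int | None, partner_add: float
) -> list[tuple[str, int, float]]:
    """Neutral b_i / y_i masses (i = 1..n-1); ions spanning the linked
    residue carry the partner peptide + bridge as a modification."""
    seq = pep.sequence
    n = len(seq)
    res = [
        _residue_mass(aa) + (CARBAMIDOMETHYL if aa == "C" else 0.0) for aa in seq
    ]
    for pos, delta, _name in pep.modifications:
        res[pos - 1] += delta
    out = []
    prefix = 0.0
    for i in range(1, n):
        prefix += res[i - 1]
        b = prefix
        if link_pos is not None and i >= link_pos:
            b += partner_add
        out.append(("b", i, b))
    suffix = 0.0
    for i in range(1, n):
        suffix += res[n - i]
        y = suffix + WATER
        if link_pos is not None and n - i + 1 <= link_pos:
            y += partner_add
        out.append(("y", i, y))
    return out


def theoretical_fragments(
    cand: CrossLinkCandidate, cfg: XlmsConfig | None = None
) -> list[Ion]:
    """b/y ions of both peptides of a cross-link candidate, charges 1..max."""
    cfg = cfg or XlmsConfig()
    ions = []
    pair = (
        ("A", cand.pepA, cand.siteA, peptide_mass(cand.pepB, cfg)),
        ("B", cand.pepB, cand.siteB, peptide_mass(cand.pepA, cfg)),
    )
    for label, pep, site, partner_mass in pair:
        link_pos = site - pep.start + 1
        if not 1 <= link_pos <= len(pep.sequence):
            raise ValueError(f"link site {site} outside peptide {pep.sequence}")
        partner_add = partner_mass + cfg.bridge_mass
        for series, ordinal, neutral in _fragment_neutrals(pep, link_pos, partner_add):
            for z in range(1, cfg.max_fragment_charge + 1):
                ions.append(Ion(series, ordinal, label, z, (neutral + z * PROTON) / z))
    return ions


def linear_fragments(pep: Peptide, cfg: XlmsConfig | None = None) -> list[Ion]:
    """b/y ions of an unlinked peptide (used by the simulator and tests)."""
    cfg = cfg or XlmsConfig()
    ions = []
    for series, ordinal, neutral in _fragment_neutrals(pep, None, 0.0):
        for z in range(1, cfg.max_fragment_charge + 1):
            ions.append(Ion(series, ordinal, "A", z, (neutral + z * PROTON) / z))
    return ions


def validate_and_score(
    scan: Scan, cand: CrossLinkCandidate, cfg: XlmsConfig | None = None
) -> CrossLinkCandidate:
    """Count matched b/y ions per peptide; approve iff every peptide has at
    least ``min_ions_per_peptide`` matches."""
    cfg = cfg or XlmsConfig()
    mzs = [mz for mz, _ in scan.peaks]
    counts = {"A": {"b": 0, "y": 0}, "B": {"b": 0, "y": 0}}
    seen: set[tuple[str, str, int]] = set()
    for ion in theoretical_fragments(cand, cfg):
        key = (ion.peptide, ion.series, ion.ordinal)
        if key in seen:
            continue
        if _has_peak_near(mzs, ion.mz, cfg.ms2_tol_da):
            counts[ion.peptide][ion.series] += 1
            seen.add(key)
    cand.matched_fragments = counts
    cand.approved = all(
        sum(counts[p].values()) >= cfg.min_ions_per_peptide for p in ("A", "B")
    )
    return cand


def rank_candidates(cands: Sequence[CrossLinkCandidate]) -> list[CrossLinkCandidate]:
    """Rank by total matched ions (desc), ties by |precursor ppm error|."""
    return sorted(
        cands,
        key=lambda c: (-c.total_matched(), abs(c.precursor_error_ppm)),
    )


def search_scan(
    scan: Scan,
    pepsA: Sequence[Peptide],
    pepsB: Sequence[Peptide],
    cfg: XlmsConfig | None = None,
) -> CandidateSet:
    """Enumerate, score and rank all cross-link candidates for one scan."""
    cfg = cfg or XlmsConfig()
    cands = enumerate_candidates(pepsA, pepsB, scan, cfg)
    for c in cands.crosslinks:
        validate_and_score(scan, c, cfg)
    cands.crosslinks = rank_candidates(cands.crosslinks)
    return cands
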