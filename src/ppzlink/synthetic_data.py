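"""Ground-truthed synthetic inputs for both pipeline arms.

``simulate_family`` builds a joint two-group alignment over a star-of-stars
clade structure with planted class A/B/C/D columns and charge-swap columns
at known positions.  ``simulate_xlms`` builds MGF spectra of known BS3
cross-linked tryptic peptide pairs plus optional noise peaks and
out-of-charge-range decoy scans.

All randomness flows from a single seed through named child generators per
sub-task, so partial reruns are stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .conservation import AlignedGroupSet, ConservationConfig, GROUPS
from .seq_io import GroupLabel, SeqRecord
from .xlms_search import (
    CrossLinkCandidate,
    Peptide,
    Scan,
    XlmsConfig,
    digest,
    legal_link_sites,
    peptide_mass,
    theoretical_fragments,
)
from ._chem import PROTON

__all__ = [
    "CladeSpec",
    "FamilySimConfig",
    "simulate_family",
    "XlmsSimConfig",
    "simulate_xlms",
]

# Neutral residues drawn from pairwise-distinct default similarity groups,
# so planted "different dominants" can never collapse into one group.
_NEUTRAL_DISTINCT = ("A", "F", "S", "N", "H", "C", "G", "P", "W")
_VARIABLE_POOL = ("A", "F", "S", "N", "H")  # >= 5 distinct-group residues
_ALL_AA = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class CladeSpec:
    name: str
    n_species: int
    divergence: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must be in [0, 1)")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")


@dataclass
class FamilySimConfig:
    clades: tuple[CladeSpec, ...] = (
        CladeSpec("Saccharomycotina", 10),
        CladeSpec("Pezizomycotina", 10),
        CladeSpec("Basidiomycota", 10),
    )
    ncol: int = 200
    planted_a: tuple[int, ...] = ()
    planted_b: tuple[int, ...] = ()
    planted_c: tuple[int, ...] = ()
    planted_d: tuple[int, ...] = ()  # restricted to d_clade
    charge_swap_columns: tuple[int, ...] = ()  # planted as class A, basic->acidic
    d_clade: str | None = None  # default: first clade
    background: str = "uniform"  # "uniform" over 19 alternatives | "simgroup"
    seed: int = 0

    def __post_init__(self) -> None:
        planted = (
            list(self.planted_a)
            + list(self.planted_b)
            + list(self.planted_c)
            + list(self.planted_d)
            + list(self.charge_swap_columns)
        )
        if len(planted) != len(set(planted)):
            raise ValueError("planted column sets must be disjoint")
        for c in planted:
            if not 1 <= c <= self.ncol:
                raise ValueError(f"planted column {c} outside 1..{self.ncol}")


def _mutate(
    residue: str, rng: np.random.Generator, cfg: FamilySimConfig, sim: ConservationConfig
) -> str:
    if cfg.background == "simgroup":
        grp = sim.simgroup_of(residue) or residue
        pool = [aa for aa in grp if aa != residue]
        if not pool:
            pool = [aa for aa in _ALL_AA if aa != residue]
    else:
        pool = [aa for aa in _ALL_AA if aa != residue]
    return pool[int(rng.integers(len(pool)))]


def simulate_family(cfg: FamilySimConfig) -> tuple[AlignedGroupSet, pd.DataFrame]:
    """Simulate two paralog groups over the clade structure with planted
    difference columns; returns the alignment and a planted-truth table."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_anc, rng_mut, rng_plant = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    sim = ConservationConfig()
    ancestor = [
        _NEUTRAL_DISTINCT[int(rng_anc.integers(len(_NEUTRAL_DISTINCT)))]
        for _ in range(cfg.ncol)
    ]

    # choose planted residue patterns
    def pick_distinct(k: int) -> list[str]:
        idx = rng_plant.permutation(len(_NEUTRAL_DISTINCT))[:k]
        return [_NEUTRAL_DISTINCT[i] for i in idx]

    d_clade = cfg.d_clade or cfg.clades[0].name
    if d_clade not in {c.name for c in cfg.clades}:
        raise ValueError(f"unknown d_clade {d_clade!r}")
    plans: dict[int, dict] = {}
    for col in cfg.planted_a:
        r1, r2 = pick_distinct(2)
        plans[col] = {"klass": "A", "pp1": r1, "ppz": r2}
    for col in cfg.charge_swap_columns:
        basic = ("K", "R")[int(rng_plant.integers(2))]
        acidic = ("D", "E")[int(rng_plant.integers(2))]
        plans[col] = {"klass": "A", "pp1": basic, "ppz": acidic, "swap": True}
    for col in cfg.planted_b:
        (r1,) = pick_distinct(1)
        plans[col] = {"klass": "B", "pp1": r1, "ppz": None}
    for col in cfg.planted_c:
        (r2,) = pick_distinct(1)
        plans[col] = {"klass": "C", "pp1": None, "ppz": r2}
    for col in cfg.planted_d:
        r1, r2, r3 = pick_distinct(3)
        plans[col] = {"klass": "D", "pp1": r1, "ppz": r2, "other": r3, "clade": d_clade}

    records: list[SeqRecord] = []
    labels: dict[str, GroupLabel] = {}
    seq_idx = 0
    for group in GROUPS:
        for clade in cfg.clades:
            for i in range(clade.n_species):
                seq_idx += 1
                seq = list(ancestor)
                # background evolution
                for j in range(cfg.ncol):
                    if rng_mut.random() < clade.divergence:
                        seq[j] = _mutate(seq[j], rng_mut, cfg, sim)
                # planted structure overrides evolution
                for col, plan in plans.items():
                    j = col - 1
                    klass = plan["klass"]
                    if klass == "A":
                        seq[j] = plan["pp1"] if group == "PP1" else plan["ppz"]
                    elif klass == "B":
                        if group == "PP1":
                            seq[j] = plan["pp1"]
                        else:
                            # spread over >= 5 distinct-group residues so the
                            # dominant frequency stays well below theta_var
                            seq[j] = _VARIABLE_POOL[(seq_idx + col) % len(_VARIABLE_POOL)]
                    elif klass == "C":
                        if group == "PPZ":
                            seq[j] = plan["ppz"]
                        else:
                            seq[j] = _VARIABLE_POOL[(seq_idx + col) % len(_VARIABLE_POOL)]
                    elif klass == "D":
                        if clade.name == plan["clade"]:
                            seq[j] = plan["pp1"] if group == "PP1" else plan["ppz"]
                        else:
                            seq[j] = plan["other"]
                sid = f"{group}_{clade.name}_s{i}"
                records.append(SeqRecord(id=sid, residues="".join(seq)))
                labels[sid] = GroupLabel(group=group, clade=clade.name)

    truth_rows = []
    for col in sorted(plans):
        plan = plans[col]
        truth_rows.append(
            {
                "column": col,
                "klass": plan["klass"],
                "pp1_residue": plan.get("pp1") or "",
                "ppz_residue": plan.get("ppz") or "",
                "clade": plan.get("clade", ""),
                "charge_swap": bool(plan.get("swap", False)),
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["column", "klass", "pp1_residue", "ppz_residue", "clade", "charge_swap"],
    )
    return AlignedGroupSet(records=records, labels=labels), truth


# ---------------------------------------------------------------------------
# Cross-link spectra


@dataclass
class XlmsSimConfig:
    protA: SeqRecord | None = None
    protB: SeqRecord | None = None
    len_a: int = 120
    len_b: int = 100
    n_links: int = 5
    true_links: tuple[tuple[int, int], ...] | None = None
    noise_peaks_per_scan: int = 0
    decoy_scans: int = 0
    mz_jitter_ppm: float = 0.0
    intensity: float = 100.0
    seed: int = 0
    search: XlmsConfig = field(default_factory=XlmsConfig)


def _random_protein(
    rng: np.random.Generator, name: str, length: int
) -> SeqRecord:
    """Random protein with regularly spaced K/R so tryptic peptides stay short."""
    pool = tuple("ACDEFGHILMNPQSTVWY")  # no K/R in background
    seq = [pool[int(rng.integers(len(pool)))] for _ in range(length)]
    pos = 0
    while pos < length - 2:
        step = int(rng.integers(5, 10))
        pos += step
        if pos >= length - 1:
            break
        seq[pos] = "K" if rng.random() < 0.7 else "R"
    return SeqRecord(id=name, residues="".join(seq))


def _linkable_sites(protein: SeqRecord, peps: Sequence[Peptide]) -> list[int]:
    sites: set[int] = set()
    for pep in peps:
        for s in legal_link_sites(pep):
            if protein.residues[s - protein.offset] == "K":
                sites.add(s)
    return sorted(sites)


def _host_peptide(site: int, peps: Sequence[Peptide]) -> Peptide:
    hosts = [p for p in peps if site in legal_link_sites(p)]
    if not hosts:
        raise ValueError(f"site {site} not coverable by any legal peptide")
    return min(hosts, key=lambda p: (p.missed_cleavages, len(p.sequence), p.start))


def simulate_xlms(
    cfg: XlmsSimConfig,
) -> tuple[SeqRecord, SeqRecord, list[Scan], pd.DataFrame]:
    """Emit spectra of known cross-linked peptide pairs plus decoys/noise.

    Returns (protA, protB, scans, truth); truth maps scan title to the
    planted peptide pair and link sites.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_prot, rng_links, rng_charge, rng_noise, rng_jitter = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    search = cfg.search
    protA = cfg.protA or _random_protein(rng_prot, "protA", cfg.len_a)
    protB = cfg.protB or _random_protein(rng_prot, "protB", cfg.len_b)
    pepsA = digest(protA, search)
    pepsB = digest(protB, search)

    if cfg.true_links is None:
        sitesA = _linkable_sites(protA, pepsA)
        sitesB = _linkable_sites(protB, pepsB)
        if not sitesA or not sitesB:
            raise ValueError("no linkable lysines in simulated proteins")
        links = []
        for _ in range(cfg.n_links):
            links.append(
                (
                    sitesA[int(rng_links.integers(len(sitesA)))],
                    sitesB[int(rng_links.integers(len(sitesB)))],
                )
            )
        links = sorted(set(links))
    else:
        links = list(cfg.true_links)
        for sA, sB in links:
            if protA.residues[sA - protA.offset] != "K":
                raise ValueError(f"true link site {sA} in protA is not K")
            if protB.residues[sB - protB.offset] != "K":
                raise ValueError(f"true link site {sB} in protB is not K")

    scans: list[Scan] = []
    truth_rows = []
    for i, (sA, sB) in enumerate(links):
        pepA = _host_peptide(sA, pepsA)
        pepB = _host_peptide(sB, pepsB)
        mass = peptide_mass(pepA, search) + peptide_mass(pepB, search) + search.bridge_mass
        cand = CrossLinkCandidate(pepA, pepB, sA, sB, mass, 0.0)
        peaks = [(ion.mz, cfg.intensity) for ion in theoretical_fragments(cand, search)]
        for m in search.signature_y1_masses:
            peaks.append((m, cfg.intensity))
        for m in search.linker_signature_masses:
            peaks.append((m, cfg.intensity))
        for _ in range(cfg.noise_peaks_per_scan):
            peaks.append(
                (float(rng_noise.uniform(100.0, 1600.0)), float(rng_noise.uniform(1, 50)))
            )
        charge = int(rng_charge.integers(search.charge_min, search.charge_max + 1))
        mz = (mass + charge * PROTON) / charge
        if cfg.mz_jitter_ppm > 0:
            mz *= 1.0 + rng_jitter.normal(0.0, cfg.mz_jitter_ppm) / 1e6
        title = f"xl_{i}_{protA.id}K{sA}_{protB.id}K{sB}"
        scans.append(Scan(title=title, precursor_mz=mz, charge=charge, peaks=peaks))
        truth_rows.append(
            {
                "title": title,
                "pepA": pepA.sequence,
                "pepB": pepB.sequence,
                "siteA": sA,
                "siteB": sB,
                "charge": charge,
                "neutral_mass": mass,
            }
        )

    for i in range(cfg.decoy_scans):
        peaks = [
            (float(rng_noise.uniform(100.0, 1600.0)), float(rng_noise.uniform(1, 50)))
            for _ in range(20)
        ]
        for m in search.signature_y1_masses:
            peaks.append((m, cfg.intensity))
        for m in search.linker_signature_masses:
            peaks.append((m, cfg.intensity))
        scans.append(
            Scan(
                title=f"decoy_{i}",
                precursor_mz=float(rng_noise.uniform(400.0, 1200.0)),
                charge=2,  # outside the 3..9 retention window
                peaks=peaks,
            )
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=["title", "pepA", "pepB", "siteA", "siteB", "charge", "neutral_mass"],
    )
    return protA, protB, scans, truth
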