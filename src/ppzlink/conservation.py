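"""Per-column conservation profiling of a joint two-group alignment.

Classifies alignment columns into difference classes:

* **A** — both groups strongly conserved, with different dominant residues;
* **B** — strongly conserved in PP1 but variable in PPZ;
* **C** — the symmetric case (conserved in PPZ, variable in PP1);
* **D** — an A-style difference that holds within at least one clade but not
  globally.

Also provides charge-category swap scanning, motif-window identity /
conservation reports, Shannon information-content logo matrices, pairwise
identity summaries, and a deterministic Saitou-Nei neighbor-joining tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seq_io import GAP, STANDARD_AA, GroupLabel, SeqRecord

GROUPS = ("PP1", "PPZ")

__all__ = [
    "AlignedGroupSet",
    "ConservationConfig",
    "ColumnProfile",
    "GroupColumnStats",
    "ColumnClassification",
    "ChargeChangeRecord",
    "column_profiles",
    "conserved_positions",
    "classify_columns",
    "classify_alignment",
    "charge_change_scan",
    "motif_report",
    "shannon_logo_matrix",
    "pairwise_identity",
    "divergence_summary",
    "nj_tree",
]


@dataclass
class ConservationConfig:
    """Thresholds and category tables for column classification.

    ``theta_cons`` operationalises "invariant or largely maintained",
    ``theta_var`` bounds "substantial variation", ``theta_charge`` is the
    modal-charge-category constancy needed to call a swap "quite constant".
    """

    theta_cons: float = 0.90
    theta_var: float = 0.70
    allow_simgroup: bool = True
    max_gap_conserved: float = 0.0
    max_gap_classify: float = 0.1
    similarity_groups: tuple[str, ...] = (
        "AVLIM",
        "FWY",
        "ST",
        "NQ",
        "DE",
        "KR",
        "H",
        "C",
        "G",
        "P",
    )
    acidic: str = "DE"
    basic: str = "KR"
    theta_charge: float = 0.90
    exclude_clades: tuple[str, ...] = ()
    min_clade_seqs: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_var <= self.theta_cons <= 1.0):
            raise ValueError("require 0 < theta_var <= theta_cons <= 1")

    def simgroup_of(self, residue: str) -> str | None:
        for grp in self.similarity_groups:
            if residue in grp:
                return grp
        return None

    def charge_category(self, residue: str) -> str:
        if residue in self.acidic:
            return "acidic"
        if residue in self.basic:
            return "basic"
        return "neutral"


@dataclass
class AlignedGroupSet:
    """A joint MSA of two ortholog groups with per-sequence labels."""

    records: list[SeqRecord]
    labels: dict[str, GroupLabel]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty alignment")
        lengths = {len(r) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"unequal aligned lengths: {sorted(lengths)}")
        missing = [r.id for r in self.records if r.id not in self.labels]
        if missing:
            raise ValueError(f"sequences without labels: {missing}")

    @property
    def ncol(self) -> int:
        return len(self.records[0])

    def clades(self) -> list[str]:
        seen: list[str] = []
        for r in self.records:
            c = self.labels[r.id].clade
            if c not in seen:
                seen.append(c)
        return seen

    def subset(
        self,
        groups: Iterable[str] | None = None,
        clades: Iterable[str] | None = None,
        exclude_clades: Iterable[str] = (),
    ) -> "AlignedGroupSet":
        groups = set(groups) if groups is not None else None
        clades = set(clades) if clades is not None else None
        excl = set(exclude_clades)
        keep = []
        for r in self.records:
            lab = self.labels[r.id]
            if groups is not None and lab.group not in groups:
                continue
            if clades is not None and lab.clade not in clades:
                continue
            if lab.clade in excl:
                continue
            keep.append(r)
        if not keep:
            raise ValueError("subset selects no sequences")
        return AlignedGroupSet(
            records=keep, labels={r.id: self.labels[r.id] for r in keep}
        )

    def group_matrix(self, group: str) -> np.ndarray:
        """Character matrix (nseq x ncol) for one group."""
        rows = [r for r in self.records if self.labels[r.id].group == group]
        if not rows:
            raise ValueError(f"no sequences in group {group!r}")
        return np.array([list(r.residues) for r in rows], dtype="<U1")

    def record_by_id(self, seq_id: str) -> SeqRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(f"unknown sequence id {seq_id!r}")


@dataclass
class GroupColumnStats:
    freqs: dict[str, float]
    gap_fraction: float
    dominant_residue: str | None
    dominant_freq: float
    dominant_simgroup_freq: float
    charge_freqs: dict[str, float]

    @property
    def modal_charge(self) -> str | None:
        if not self.charge_freqs:
            return None
        return max(sorted(self.charge_freqs), key=lambda c: self.charge_freqs[c])


@dataclass
class ColumnProfile:
    column: int  # 1-based
    groups: dict[str, GroupColumnStats]


@dataclass
class ColumnClassification:
    column: int
    klass: str  # "A" | "B" | "C" | "D" | "none"
    clade_restricted_to: frozenset[str] = frozenset()
    charge_swap: tuple[str, str, float, float] | None = None


@dataclass
class ChargeChangeRecord:
    column: int
    pp1_category: str
    ppz_category: str
    pp1_freq: float
    ppz_freq: float
    constant: bool

    @property
    def change(self) -> str:
        return f"{self.pp1_category}->{self.ppz_category}"


def _column_stats(col: np.ndarray, cfg: ConservationConfig) -> GroupColumnStats:
    n = col.size
    nongap = col[col != GAP]
    gap_fraction = 1.0 - nongap.size / n
    if nongap.size == 0:
        return GroupColumnStats({}, 1.0, None, 0.0, 0.0, {})
    residues, counts = np.unique(nongap, return_counts=True)
    freqs = {str(r): float(c) / int(nongap.size) for r, c in zip(residues, counts)}
    # deterministic: highest frequency, residue alphabetical on ties
    dominant = max(sorted(freqs), key=lambda r: freqs[r])
    sim = cfg.simgroup_of(dominant)
    sim_freq = (
        sum(f for r, f in freqs.items() if sim is not None and r in sim)
        if sim
        else freqs[dominant]
    )
    charge: dict[str, float] = {}
    for r, f in freqs.items():
        cat = cfg.charge_category(r)
        charge[cat] = charge.get(cat, 0.0) + f
    return GroupColumnStats(freqs, gap_fraction, dominant, freqs[dominant], sim_freq, charge)


def column_profiles(
    aln: AlignedGroupSet, cfg: ConservationConfig | None = None
) -> list[ColumnProfile]:
    """One profile per column; both groups profiled on the same column index.

    ``cfg.exclude_clades`` is applied before profiling.  A group with fewer
    than two sequences after exclusion is an error.
    """
    cfg = cfg or ConservationConfig()
    sub = aln.subset(exclude_clades=cfg.exclude_clades)
    matrices = {}
    for group in GROUPS:
        mat = sub.group_matrix(group)
        if mat.shape[0] < 2:
            raise ValueError(f"group {group!r} has < 2 sequences after exclusion")
        matrices[group] = mat
    profiles = []
    for j in range(sub.ncol):
        stats = {g: _column_stats(matrices[g][:, j], cfg) for g in GROUPS}
        profiles.append(ColumnProfile(column=j + 1, groups=stats))
    return profiles


def conserved_positions(
    aln: AlignedGroupSet, group: str, cfg: ConservationConfig | None = None
) -> set[int]:
    """Columns where every non-excluded sequence of ``group`` carries the
    identical residue and the gap fraction is within ``max_gap_conserved``."""
    cfg = cfg or ConservationConfig()
    sub = aln.subset(groups=[group], exclude_clades=cfg.exclude_clades)
    mat = sub.group_matrix(group)
    out: set[int] = set()
    for j in range(mat.shape[1]):
        col = mat[:, j]
        nongap = col[col != GAP]
        if nongap.size == 0:
            continue
        gap_fraction = 1.0 - nongap.size / col.size
        if gap_fraction > cfg.max_gap_conserved + 1e-12:
            continue
        if np.all(nongap == nongap[0]):
            out.add(j + 1)
    return out


def _passes_cons(stats: GroupColumnStats, cfg: ConservationConfig) -> bool:
    if stats.dominant_residue is None:
        return False
    if stats.dominant_freq >= cfg.theta_cons:
        return True
    return cfg.allow_simgroup and stats.dominant_simgroup_freq >= cfg.theta_cons


def _a_style(p1: GroupColumnStats, p2: GroupColumnStats, cfg: ConservationConfig) -> bool:
    return (
        _passes_cons(p1, cfg)
        and _passes_cons(p2, cfg)
        and p1.dominant_residue is not None
        and p2.dominant_residue is not None
        and p1.dominant_residue != p2.dominant_residue
    )


def _charge_swap_info(
    p1: GroupColumnStats, p2: GroupColumnStats
) -> tuple[str, str, float, float] | None:
    c1, c2 = p1.modal_charge, p2.modal_charge
    if c1 is None or c2 is None or c1 == c2:
        return None
    return (c1, c2, p1.charge_freqs[c1], p2.charge_freqs[c2])


def classify_columns(
    profiles: Sequence[ColumnProfile],
    cfg: ConservationConfig | None = None,
    clade_profiles: Mapping[str, Sequence[ColumnProfile]] | None = None,
) -> list[ColumnClassification]:
    """Assign each column to exactly one of classes A, B, C, D or none.

    Precedence is A > B > C > D.  ``clade_profiles`` maps clade name to
    per-clade profiles (same column indexing) and is needed only for class D
    detection; clades under ``cfg.min_clade_seqs`` per group must already be
    excluded by the caller (``classify_alignment`` does this).
    """
    cfg = cfg or ConservationConfig()
    clade_profiles = clade_profiles or {}
    out: list[ColumnClassification] = []
    for i, prof in enumerate(profiles):
        p1, p2 = prof.groups["PP1"], prof.groups["PPZ"]
        swap = _charge_swap_info(p1, p2)
        if max(p1.gap_fraction, p2.gap_fraction) > cfg.max_gap_classify + 1e-12:
            out.append(ColumnClassification(prof.column, "none"))
            continue
        if _a_style(p1, p2, cfg):
            out.append(ColumnClassification(prof.column, "A", charge_swap=swap))
            continue
        if p1.dominant_freq >= cfg.theta_cons and p2.dominant_freq < cfg.theta_var:
            out.append(ColumnClassification(prof.column, "B", charge_swap=swap))
            continue
        if p2.dominant_freq >= cfg.theta_cons and p1.dominant_freq < cfg.theta_var:
            out.append(ColumnClassification(prof.column, "C", charge_swap=swap))
            continue
        d_clades = set()
        for clade, cprofs in clade_profiles.items():
            cp = cprofs[i]
            if _a_style(cp.groups["PP1"], cp.groups["PPZ"], cfg):
                d_clades.add(clade)
        if d_clades:
            out.append(
                ColumnClassification(
                    prof.column, "D", clade_restricted_to=frozenset(d_clades),
                    charge_swap=swap,
                )
            )
            continue
        out.append(ColumnClassification(prof.column, "none"))
    return out


def classify_alignment(
    aln: AlignedGroupSet, cfg: ConservationConfig | None = None
) -> list[ColumnClassification]:
    """Convenience wrapper: profile globally and per clade, then classify."""
    cfg = cfg or ConservationConfig()
    profiles = column_profiles(aln, cfg)
    clade_profiles: dict[str, list[ColumnProfile]] = {}
    sub = aln.subset(exclude_clades=cfg.exclude_clades)
    for clade in sub.clades():
        csub = sub.subset(clades=[clade])
        ok = True
        for group in GROUPS:
            n = sum(1 for r in csub.records if csub.labels[r.id].group == group)
            if n < cfg.min_clade_seqs:
                ok = False
        if ok:
            clade_profiles[clade] = column_profiles(csub, cfg)
    return classify_columns(profiles, cfg, clade_profiles)


def charge_change_scan(
    profiles: Sequence[ColumnProfile], cfg: ConservationConfig | None = None
) -> list[ChargeChangeRecord]:
    """Columns whose modal charge category differs between the two groups."""
    cfg = cfg or ConservationConfig()
    hits = []
    for prof in profiles:
        p1, p2 = prof.groups["PP1"], prof.groups["PPZ"]
        info = _charge_swap_info(p1, p2)
        if info is None:
            continue
        c1, c2, f1, f2 = info
        hits.append(
            ChargeChangeRecord(
                column=prof.column,
                pp1_category=c1,
                ppz_category=c2,
                pp1_freq=f1,
                ppz_freq=f2,
                constant=(f1 >= cfg.theta_charge and f2 >= cfg.theta_charge),
            )
        )
    return hits


def motif_report(
    aln: AlignedGroupSet,
    motif_columns: Sequence[int],
    reference: str,
    cfg: ConservationConfig | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-group identity% / conservation% over a motif window.

    identity% counts motif columns whose group consensus (dominant residue)
    equals the reference sequence's residue; conservation% additionally
    accepts a consensus in the reference residue's similarity group.
    """
    cfg = cfg or ConservationConfig()
    if not motif_columns:
        raise ValueError("motif_columns must be non-empty")
    for c in motif_columns:
        if not 1 <= c <= aln.ncol:
            raise ValueError(f"motif column {c} outside alignment 1..{aln.ncol}")
    ref = aln.record_by_id(reference)
    profiles = column_profiles(aln, cfg)
    report: dict[str, tuple[float, float]] = {}
    for group in GROUPS:
        ident = 0
        conserved = 0
        for c in motif_columns:
            ref_res = ref.residues[c - 1]
            if ref_res != GAP and cfg.simgroup_of(ref_res) is None:
                raise ValueError(
                    f"reference residue {ref_res!r} absent from similarity table"
                )
            cons = profiles[c - 1].groups[group].dominant_residue
            if cons is None or ref_res == GAP:
                continue
            if cons == ref_res:
                ident += 1
                conserved += 1
            elif cfg.simgroup_of(cons) == cfg.simgroup_of(ref_res):
                conserved += 1
        n = len(motif_columns)
        report[group] = (100.0 * ident / n, 100.0 * conserved / n)
    return report


def shannon_logo_matrix(
    aln: AlignedGroupSet,
    group: str,
    columns: Sequence[int] | None = None,
    cfg: ConservationConfig | None = None,
    scale_by_nongap: bool = False,
) -> pd.DataFrame:
    """Per-column letter heights in bits (Shannon information content).

    IC = log2(20) - H with H the entropy of non-gap residue frequencies;
    letter height = frequency x IC.  A gap-only column has IC 0.
    """
    cfg = cfg or ConservationConfig()
    sub = aln.subset(exclude_clades=cfg.exclude_clades)
    mat = sub.group_matrix(group)
    if columns is None:
        columns = range(1, sub.ncol + 1)
    letters = sorted(STANDARD_AA)
    data = {}
    for c in columns:
        if not 1 <= c <= sub.ncol:
            raise ValueError(f"column {c} outside alignment")
        col = mat[:, c - 1]
        nongap = col[col != GAP]
        heights = dict.fromkeys(letters, 0.0)
        if nongap.size:
            residues, counts = np.unique(nongap, return_counts=True)
            freqs = counts / nongap.size
            entropy = -float(np.sum(freqs * np.log2(freqs)))
            ic = math.log2(20) - entropy
            if scale_by_nongap:
                ic *= nongap.size / col.size
            for r, f in zip(residues, freqs):
                if str(r) in heights:
                    heights[str(r)] = float(f) * ic
        data[c] = heights
    return pd.DataFrame(data).T[letters]


def pairwise_identity(aln: AlignedGroupSet, group: str) -> pd.DataFrame:
    """Symmetric identity matrix: matches / mutually non-gap columns.

    Pairs with no mutually non-gap column are NaN; the diagonal is 1.
    """
    sub = aln.subset(groups=[group])
    ids = [r.id for r in sub.records]
    if len(ids) < 2:
        raise ValueError("pairwise_identity needs >= 2 sequences")
    mat = sub.group_matrix(group)
    nongap = mat != GAP
    n = len(ids)
    out = np.full((n, n), np.nan)
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            denom = int(both.sum())
            if denom == 0:
                continue
            matches = int(np.sum((mat[i] == mat[j]) & both))
            out[i, j] = out[j, i] = matches / denom
    return pd.DataFrame(out, index=ids, columns=ids)


def divergence_summary(matrix: pd.DataFrame) -> dict[str, float]:
    """Mean/sd/min/max of off-diagonal identities (NaN pairs ignored)."""
    vals = matrix.values[np.triu_indices(len(matrix), k=1)]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no defined off-diagonal identities")
    return {
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        "min": float(vals.min()),
        "max": float(vals.max()),
    }


class _Node:
    __slots__ = ("newick", "key")

    def __init__(self, newick: str, key: str):
        self.newick = newick  # subtree without trailing branch length
        self.key = key  # smallest leaf label, for deterministic ordering


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def nj_tree(dist: np.ndarray | pd.DataFrame, labels: Sequence[str] | None = None) -> str:
    """Saitou-Nei neighbor joining; returns a newick string.

    Deterministic: ties in the Q-matrix are broken by the lexically lowest
    label pair; negative branch lengths are clamped to 0 with the deficit
    shifted to the sister branch; children are ordered by smallest leaf label.
    """
    if isinstance(dist, pd.DataFrame):
        if labels is None:
            labels = list(dist.index)
        dist = dist.values
    d = np.asarray(dist, dtype=float)
    if labels is None:
        raise ValueError("labels required with a bare matrix")
    n = d.shape[0]
    if d.shape != (n, n) or len(labels) != n:
        raise ValueError("distance matrix / labels shape mismatch")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if n < 2:
        raise ValueError("need >= 2 taxa")

    nodes = [_Node(lbl, lbl) for lbl in labels]
    dm = {(i, j): float(d[i, j]) for i in range(n) for j in range(n)}
    active = list(range(n))
    next_idx = n

    def get(i: int, j: int) -> float:
        return 0.0 if i == j else dm[(min(i, j), max(i, j))]

    def join(i: int, li: float, j: int, lj: float) -> _Node:
        # clamp negatives, shifting the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        children = sorted(
            [(nodes[i], li), (nodes[j], lj)], key=lambda t: t[0].key
        )
        nw = "(" + ",".join(f"{c.newick}:{_fmt(l)}" for c, l in children) + ")"
        return _Node(nw, min(nodes[i].key, nodes[j].key))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                tie = tuple(sorted((nodes[i].key, nodes[j].key)))
                cand = (q, tie, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        dij = get(i, j)
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        node = join(i, li, j, lj)
        u = next_idx
        next_idx += 1
        nodes.append(node)
        for k in active:
            if k in (i, j):
                continue
            dm[(min(u, k), max(u, k))] = (get(i, k) + get(j, k) - dij) / 2.0
        active = [k for k in active if k not in (i, j)] + [u]

    if len(active) == 2:
        i, j = active
        dij = get(i, j)
        node = join(i, dij / 2.0, j, dij / 2.0)
        return node.newick + ";"

    i, j, k = active
    li = (get(i, j) + get(i, k) - get(j, k)) / 2.0
    lj = (get(i, j) + get(j, k) - get(i, k)) / 2.0
    lk = (get(i, k) + get(j, k) - get(i, j)) / 2.0
    branches = sorted(
        [(nodes[i], li), (nodes[j], lj), (nodes[k], lk)], key=lambda t: t[0].key
    )
    branches = [(c, max(0.0, l)) for c, l in branches]
    nw = "(" + ",".join(f"{c.newick}:{_fmt(l)}" for c, l in branches) + ");"
    return nw
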