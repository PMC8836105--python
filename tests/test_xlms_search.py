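import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppzlink import _chem
from ppzlink.seq_io import SeqRecord
from ppzlink.xlms_search import (
    CrossLinkCandidate,
    Peptide,
    Scan,
    XlmsConfig,
    digest,
    enumerate_candidates,
    filter_scans,
    legal_link_sites,
    linear_fragments,
    oxidized_variants,
    peptide_mass,
    rank_candidates,
    read_mgf,
    search_scan,
    theoretical_fragments,
    validate_and_score,
    write_mgf,
)

CFG = XlmsConfig()
PROTON = _chem.PROTON


def make_scan(neutral_mass, charge=4, peaks=(), title="s"):
    mz = (neutral_mass + charge * PROTON) / charge
    return Scan(title=title, precursor_mz=mz, charge=charge, peaks=list(peaks))


class TestChem:
    def test_bridge_from_formula(self):
        assert _chem.BS3_BRIDGE == pytest.approx(138.06808, abs=1e-4)

    def test_deadend_masses(self):
        assert _chem.BS3_DEADEND_WATER == pytest.approx(156.07864, abs=1e-4)
        assert _chem.BS3_DEADEND_AMMONIA == pytest.approx(155.09463, abs=1e-4)

    def test_carbamidomethyl_and_oxidation(self):
        assert _chem.CARBAMIDOMETHYL == pytest.approx(57.02146, abs=1e-4)
        assert _chem.OXIDATION == pytest.approx(15.99491, abs=1e-4)

    def test_malformed_formula(self):
        with pytest.raises(ValueError):
            _chem.formula_mass("C8Xx2")


class TestMgfIO:
    def test_three_blocks(self, tmp_path):
        p = tmp_path / "in.mgf"
        p.write_text(
            "\n".join(
                [
                    "BEGIN IONS", "TITLE=a", "PEPMASS=500.25", "CHARGE=3+",
                    "100.0 1.0", "END IONS",
                    "BEGIN IONS", "TITLE=b", "PEPMASS=600.5 1000", "CHARGE=4+",
                    "END IONS",
                    "BEGIN IONS", "TITLE=c", "PEPMASS=700.1", "CHARGE=2+",
                    "101.5 2.0", "END IONS",
                ]
            )
        )
        scans = read_mgf(p)
        assert [s.title for s in scans] == ["a", "b", "c"]
        assert scans[1].precursor_mz == 600.5

    def test_round_trip(self, tmp_path):
        scans = [
            Scan("x", 512.345678, 5, [(100.123456, 1.5), (200.2, 3.0)]),
            Scan("y", 800.0, 3, [(147.11328, 10.0)]),
        ]
        p = tmp_path / "out.mgf"
        write_mgf(scans, p)
        back = read_mgf(p)
        assert len(back) == 2
        for a, b in zip(scans, back):
            assert a.title == b.title and a.charge == b.charge
            assert b.precursor_mz == pytest.approx(a.precursor_mz, abs=1e-6)
            for (mz1, _), (mz2, _) in zip(a.peaks, b.peaks):
                assert mz2 == pytest.approx(mz1, abs=1e-6)

    def test_missing_pepmass_errors(self, tmp_path):
        p = tmp_path / "bad.mgf"
        p.write_text("BEGIN IONS\nTITLE=a\nCHARGE=3+\nEND IONS\n")
        with pytest.raises(ValueError, match="block 1"):
            read_mgf(p)

    def test_missing_charge_skipped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "in.mgf"
        p.write_text(
            "BEGIN IONS\nTITLE=a\nPEPMASS=500\n100 1\nEND IONS\n"
            "BEGIN IONS\nTITLE=b\nPEPMASS=600\nCHARGE=3+\nEND IONS\n"
        )
        with caplog.at_level("WARNING"):
            scans = read_mgf(p)
        assert [s.title for s in scans] == ["b"]
        assert "missing CHARGE" in caplog.text

    def test_malformed_peak_errors(self, tmp_path):
        p = tmp_path / "bad.mgf"
        p.write_text("BEGIN IONS\nTITLE=a\nPEPMASS=500\nCHARGE=3+\n1x0 1\nEND IONS\n")
        with pytest.raises(ValueError, match="malformed peak"):
            read_mgf(p)


class TestFilterScans:
    y1_k = CFG.signature_y1_masses[0]
    linker = CFG.linker_signature_masses[0]

    def test_charge_2_removed(self):
        scan = Scan("s", 500.0, 2, [(self.y1_k, 1.0), (self.linker, 1.0)])
        assert filter_scans([scan], CFG) == []

    def test_charge_4_with_signatures_retained(self):
        # y1 of K ~ 147.113 Da
        assert self.y1_k == pytest.approx(147.11280, abs=1e-4)
        scan = Scan("s", 500.0, 4, [(self.y1_k, 1.0), (self.linker, 1.0)])
        assert filter_scans([scan], CFG) == [scan]

    def test_no_peaks_removed(self):
        scan = Scan("s", 500.0, 4, [(300.0, 1.0)])
        assert filter_scans([scan], CFG) == []

    def test_missing_linker_signature_removed(self):
        scan = Scan("s", 500.0, 4, [(self.y1_k, 1.0)])
        assert filter_scans([scan], CFG) == []

    def test_idempotent_and_charge_range_sound(self):
        scans = [
            Scan(f"s{z}", 500.0, z, [(self.y1_k, 1.0), (self.linker, 1.0)])
            for z in range(1, 12)
        ]
        kept = filter_scans(scans, CFG)
        assert filter_scans(kept, CFG) == kept
        assert all(3 <= s.charge <= 9 for s in kept)
        assert len(kept) == 7


def brute_force_digest(seq: str, max_missed: int, proline_rule: bool) -> set:
    """Independent oracle: enumerate all substrings with valid tryptic
    boundaries and at most max_missed internal cleavage sites."""
    n = len(seq)

    def is_site(i):  # cleavage between i-1 and i
        if i == 0 or i == n:
            return True
        if seq[i - 1] in "KR":
            return not (proline_rule and seq[i] == "P")
        return False

    out = set()
    for i in range(n):
        for j in range(i + 1, n + 1):
            if not (is_site(i) and is_site(j)):
                continue
            if i != 0 and seq[i - 1] not in "KR":
                continue
            if j != n and seq[j - 1] not in "KR":
                continue
            internal = sum(1 for k in range(i + 1, j) if is_site(k) and seq[k - 1] in "KR")
            if internal <= max_missed:
                out.add((i + 1, j, seq[i:j]))
    return out


class TestDigest:
    def test_one_missed_enumeration(self):
        peps = digest(SeqRecord(id="p", residues="AAKAAR"), XlmsConfig(max_missed=1))
        assert {p.sequence for p in peps} == {"AAK", "AAR", "AAKAAR"}

    def test_no_cleavage_sites(self):
        peps = digest(SeqRecord(id="p", residues="AAAGGG"), CFG)
        assert len(peps) == 1
        assert peps[0].sequence == "AAAGGG" and peps[0].missed_cleavages == 0

    def test_proline_rule(self):
        cfg = XlmsConfig(cleave_before_proline=True)
        peps = digest(SeqRecord(id="p", residues="AKPA"), cfg)
        assert {p.sequence for p in peps} == {"AKPA"}
        # rule off: cleavage after K
        peps = digest(SeqRecord(id="p", residues="AKPA"), XlmsConfig())
        assert {p.sequence for p in peps} == {"AK", "PA", "AKPA"}

    def test_coordinates_match_protein(self):
        rec = SeqRecord(id="p", residues="MKWVTFKISLLR", offset=100)
        for pep in digest(rec, CFG):
            sub = rec.residues[pep.start - rec.offset : pep.end - rec.offset + 1]
            assert sub == pep.sequence

    @given(
        seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60),
        proline=st.booleans(),
    )
    @settings(max_examples=60)
    def test_matches_brute_force_oracle(self, seq, proline):
        cfg = XlmsConfig(cleave_before_proline=proline)
        got = {(p.start, p.end, p.sequence) for p in digest(SeqRecord(id="p", residues=seq), cfg)}
        expected = {(i, j, s) for i, j, s in brute_force_digest(seq, 4, proline)}
        assert got == expected


class TestPeptideMass:
    def pep(self, seq, mods=()):
        return Peptide("p", seq, 1, len(seq), 0, modifications=list(mods))

    def test_glycine(self):
        assert peptide_mass(self.pep("G"), CFG) == pytest.approx(75.03203, abs=1e-4)

    def test_cysteine_fixed_cam(self):
        assert peptide_mass(self.pep("C"), CFG) == pytest.approx(178.04121, abs=1e-4)

    def test_met_oxidation(self):
        pep = self.pep("M", [(1, _chem.OXIDATION, "Oxidation")])
        assert peptide_mass(pep, CFG) == pytest.approx(165.04596, abs=1e-4)

    def test_oxidation_on_wrong_residue_errors(self):
        pep = self.pep("A", [(1, _chem.OXIDATION, "Oxidation")])
        with pytest.raises(ValueError):
            peptide_mass(pep, CFG)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            peptide_mass(self.pep("AXA"), CFG)

    def test_oxidized_variants_count(self):
        pep = self.pep("MAMAM")
        variants = oxidized_variants(pep, XlmsConfig(max_oxidations=2))
        # 1 + C(3,1) + C(3,2)
        assert len(variants) == 7


class TestLinkSites:
    def test_internal_k_legal_cterm_k_not(self):
        pep = Peptide("p", "AKGGK", 10, 14, 1)
        assert legal_link_sites(pep) == [11]

    def test_protein_cterm_k_legal(self):
        pep = Peptide("p", "AKGGK", 10, 14, 1, at_protein_cterm=True)
        assert legal_link_sites(pep) == [11, 14]

    def test_protein_nterm_always_legal(self):
        pep = Peptide("p", "MAGK", 1, 4, 0, at_protein_nterm=True)
        assert legal_link_sites(pep) == [1]


class TestEnumerateCandidates:
    def setup_method(self):
        self.protA = SeqRecord(id="A", residues="AAKAGRLLLK")
        self.protB = SeqRecord(id="B", residues="GGLKAARWW")
        self.pepsA = digest(self.protA, CFG)
        self.pepsB = digest(self.protB, CFG)

    def test_exact_mass_pair_emitted_at_zero_ppm(self):
        pepA = next(p for p in self.pepsA if p.sequence == "AAKAGR")
        pepB = next(p for p in self.pepsB if p.sequence == "GGLKAAR")
        mass = peptide_mass(pepA, CFG) + peptide_mass(pepB, CFG) + CFG.bridge_mass
        scan = make_scan(mass)
        cands = enumerate_candidates(self.pepsA, self.pepsB, scan, CFG)
        hits = [
            c
            for c in cands.crosslinks
            if c.pepA.sequence == "AAKAGR" and c.pepB.sequence == "GGLKAAR"
        ]
        assert hits
        assert all(abs(c.precursor_error_ppm) < 1e-6 for c in hits)
        pairs = {(c.siteA, c.siteB) for c in hits}
        assert (3, 4) in pairs  # the two lysines
        # every emitted site is a lysine or the protein N-terminus
        for sA, sB in pairs:
            assert self.protA.residues[sA - 1] == "K" or sA == 1
            assert self.protB.residues[sB - 1] == "K" or sB == 1

    def test_mass_additivity_invariant(self):
        pepA, pepB = self.pepsA[0], self.pepsB[0]
        mass = peptide_mass(pepA, CFG) + peptide_mass(pepB, CFG) + CFG.bridge_mass
        scan = make_scan(mass)
        for c in enumerate_candidates(self.pepsA, self.pepsB, scan, CFG).crosslinks:
            total = peptide_mass(c.pepA, CFG) + peptide_mass(c.pepB, CFG) + CFG.bridge_mass
            assert total == pytest.approx(c.neutral_mass, abs=1e-9)
            assert abs(c.precursor_error_ppm) <= CFG.ms1_tol_ppm

    def test_shifted_precursor_not_emitted(self):
        pepA = next(p for p in self.pepsA if p.sequence == "AAKAGR")
        pepB = next(p for p in self.pepsB if p.sequence == "GGLKAAR")
        mass = peptide_mass(pepA, CFG) + peptide_mass(pepB, CFG) + CFG.bridge_mass
        scan = make_scan(mass + 0.02)  # ~15 ppm at M~1300
        assert mass == pytest.approx(1300, abs=100)
        cands = enumerate_candidates(self.pepsA, self.pepsB, scan, CFG)
        assert not [
            c
            for c in cands.crosslinks
            if c.pepA.sequence == "AAKAGR" and c.pepB.sequence == "GGLKAAR"
        ]

    def test_no_legal_site_pair_not_emitted(self):
        # GGGLLLR has no K and is not at the protein N-terminus, so it has
        # no legal link site despite an exact precursor-mass match
        protA = SeqRecord(id="A", residues="AARGGGLLLR")
        pepsA = digest(protA, CFG)
        pepA = next(p for p in pepsA if p.sequence == "GGGLLLR")
        assert legal_link_sites(pepA) == []
        pepB = next(p for p in self.pepsB if p.sequence == "GGLKAAR")
        mass = peptide_mass(pepA, CFG) + peptide_mass(pepB, CFG) + CFG.bridge_mass
        cands = enumerate_candidates(pepsA, self.pepsB, make_scan(mass), CFG)
        assert not [c for c in cands.crosslinks if c.pepA.sequence == "GGGLLLR"]

    def test_deadend_explanation(self):
        pepA = next(p for p in self.pepsA if p.sequence == "AAKAGR")
        mass = peptide_mass(pepA, CFG) + CFG.deadend_water_mass
        cands = enumerate_candidates(self.pepsA, self.pepsB, make_scan(mass), CFG)
        assert any(
            d.pep.sequence == "AAKAGR" and d.kind == "water" and d.site == 3
            for d in cands.deadends
        )


class TestFragments:
    def test_b2_of_agk(self):
        pep = Peptide("p", "AGK", 1, 3, 0)
        ions = {
            (i.series, i.ordinal, i.charge): i.mz for i in linear_fragments(pep, CFG)
        }
        assert ions[("b", 2, 1)] == pytest.approx(129.06585, abs=1e-4)

    def test_y1_of_k_terminated(self):
        pep = Peptide("p", "AGK", 1, 3, 0)
        ions = {
            (i.series, i.ordinal, i.charge): i.mz for i in linear_fragments(pep, CFG)
        }
        assert ions[("y", 1, 1)] == pytest.approx(147.11280, abs=1e-4)

    @given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=20))
    @settings(max_examples=40)
    def test_sum_rule(self, seq):
        pep = Peptide("p", seq, 1, len(seq), 0)
        total = peptide_mass(pep, CFG)
        neutral = {}
        for ion in linear_fragments(pep, XlmsConfig(max_fragment_charge=1)):
            neutral[(ion.series, ion.ordinal)] = ion.mz - PROTON
        n = len(seq)
        for i in range(1, n):
            assert neutral[("b", i)] + neutral[("y", n - i)] == pytest.approx(
                total, abs=1e-9
            )

    def test_link_spanning_ions_carry_partner(self):
        pepA = Peptide("A", "AKGG", 1, 4, 0)
        pepB = Peptide("B", "LKAA", 1, 4, 0)
        cand = CrossLinkCandidate(
            pepA, pepB, 2, 2,
            peptide_mass(pepA, CFG) + peptide_mass(pepB, CFG) + CFG.bridge_mass, 0.0,
        )
        partner_add = peptide_mass(pepB, CFG) + CFG.bridge_mass
        ions = {
            (i.peptide, i.series, i.ordinal): i.mz
            for i in theoretical_fragments(cand, CFG)
            if i.charge == 1
        }
        # b1 of A does not span the link at position 2; b2 does
        b1_plain = _chem.RESIDUE_MASS["A"] + PROTON
        assert ions[("A", "b", 1)] == pytest.approx(b1_plain, abs=1e-6)
        b2_linked = _chem.RESIDUE_MASS["A"] + _chem.RESIDUE_MASS["K"] + partner_add + PROTON
        assert ions[("A", "b", 2)] == pytest.approx(b2_linked, abs=1e-6)


class TestValidateAndScore:
    def build(self):
        pepA = Peptide("A", "AAKAGR", 1, 6, 1)
        pepB = Peptide("B", "GGLKAAR", 1, 7, 1)
        mass = peptide_mass(pepA, CFG) + peptide_mass(pepB, CFG) + CFG.bridge_mass
        cand = CrossLinkCandidate(pepA, pepB, 3, 4, mass, 0.0)
        return cand, mass

    def test_full_series_approved(self):
        cand, mass = self.build()
        peaks = [(i.mz, 100.0) for i in theoretical_fragments(cand, CFG)]
        scan = make_scan(mass, peaks=peaks)
        scored = validate_and_score(scan, cand, CFG)
        assert scored.approved
        assert scored.total_matched() > 10

    def test_one_sided_not_approved(self):
        # keep only pepA ions that are not coincidentally within tolerance
        # of any pepB ion, so the scan truly contains no pepB evidence
        cand, mass = self.build()
        ions = theoretical_fragments(cand, CFG)
        b_mzs = [i.mz for i in ions if i.peptide == "B"]
        peaks = [
            (i.mz, 100.0)
            for i in ions
            if i.peptide == "A"
            and all(abs(i.mz - m) > 2 * CFG.ms2_tol_da for m in b_mzs)
        ]
        assert peaks
        scan = make_scan(mass, peaks=peaks)
        scored = validate_and_score(scan, cand, CFG)
        assert sum(scored.matched_fragments["B"].values()) == 0
        assert not scored.approved

    def test_single_pepb_ion_keeps_approval(self):
        cand, mass = self.build()
        ions = theoretical_fragments(cand, CFG)
        a_ions = [i for i in ions if i.peptide == "A"]
        b_ion = next(i for i in ions if i.peptide == "B")
        peaks = [(i.mz, 100.0) for i in a_ions] + [(b_ion.mz, 100.0)]
        scan = make_scan(mass, peaks=peaks)
        assert validate_and_score(scan, cand, CFG).approved

    def test_ranking_by_matches_then_ppm(self):
        cand, mass = self.build()
        peaks = [(i.mz, 100.0) for i in theoretical_fragments(cand, CFG)]
        scan = make_scan(mass, peaks=peaks)
        validate_and_score(scan, cand, CFG)
        other = CrossLinkCandidate(cand.pepA, cand.pepB, 3, 4, mass, 5.0)
        other.matched_fragments = {"A": {"b": 1, "y": 0}, "B": {"b": 0, "y": 1}}
        ranked = rank_candidates([other, cand])
        assert ranked[0] is cand
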