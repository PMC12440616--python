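"""Scanner unit and property tests.

The brute-force oracle here enumerates every 2-residue motif occurrence
directly and expands each to its maximal basic run — an independent path to
the same site definition the scanner implements with a single left-to-right
pass.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnidapep.scanner import (
    DEFAULT_MOTIFS,
    CleavageSite,
    MaturePeptide,
    ScannerConfig,
    assign_family,
    find_cleavage_sites,
    score_precursor,
    segment_peptides,
)

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def oracle_sites(residues, motifs=DEFAULT_MOTIFS):
    """Enumerate motif occurrences; expand each to its maximal K/R run."""
    motifs = set(motifs)
    n = len(residues)
    found = {}
    for i in range(n - 1):
        if residues[i:i + 2] not in motifs:
            continue
        j = i if residues[i] in "KR" else i + 1  # first basic residue of the pair
        a = j
        while a > 0 and residues[a - 1] in "KR":
            a -= 1
        b = j
        while b + 1 < n and residues[b + 1] in "KR":
            b += 1
        g = a > 0 and residues[a - 1] == "G"
        if residues[i] == "G" and a != i + 1:
            continue  # the G is not adjacent to the run start: not a real occurrence
        start = a if g else a + 1  # 1-based consumed start (a is 0-based run start)
        found[(start, b + 1)] = CleavageSite(
            start=start, end=b + 1, basic_run=residues[a:b + 1], amide_donor=g
        )
    return [found[k] for k in sorted(found)]


class TestFindCleavageSites:
    def test_no_basic_residues_no_sites(self):
        assert find_cleavage_sites("EPEPPETGLW") == []

    def test_g_kr_run_consumed_with_donor(self):
        sites = find_cleavage_sites("AAAGKRAAA")
        assert len(sites) == 1
        site = sites[0]
        assert (site.start, site.end) == (4, 6)
        assert site.basic_run == "KR"
        assert site.amide_donor is True

    def test_isolated_monobasic_is_not_a_site(self):
        assert find_cleavage_sites("AAKAA") == []

    def test_g_before_single_basic_is_a_site(self):
        sites = find_cleavage_sites("AAGKAA")
        assert len(sites) == 1
        assert sites[0].amide_donor and sites[0].basic_run == "K"

    def test_motif_subset_respected(self):
        config = ScannerConfig(cleavage_motifs=("RR",))
        assert find_cleavage_sites("AAKKAA", config) == []
        assert len(find_cleavage_sites("AARRAA", config)) == 1

    def test_adding_motifs_never_removes_sites(self, rng):
        base = ScannerConfig(cleavage_motifs=("KR", "RK"))
        full = ScannerConfig()
        for _ in range(200):
            seq = "".join(rng.choice(list(RESIDUES), size=60))
            n_base = len(find_cleavage_sites(seq, base))
            n_full = len(find_cleavage_sites(seq, full))
            assert n_full >= n_base

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.text(alphabet=RESIDUES, min_size=1, max_size=120))
    def test_agrees_with_enumeration_oracle(self, seq):
        assert find_cleavage_sites(seq) == oracle_sites(seq)


class TestSegmentPeptides:
    def _scan(self, residues, signal_end=0, config=None):
        config = config or ScannerConfig()
        sites = [s for s in find_cleavage_sites(residues, config) if s.start > signal_end]
        return segment_peptides(residues, sites, signal_end, config)

    def test_non_amidated_lw_peptide(self):
        peptides = self._scan("MKR" + "EPEPPETGLW" + "KR" + "AAA")
        passing = [p for p in peptides if p.counts_toward_pass]
        assert [p.mature for p in passing] == ["EPEPPETGLW"]
        pep = passing[0]
        assert pep.amidated is False and pep.xp is True and pep.family == "LW_peptide"

    def test_amide_donor_consumed(self):
        peptides = self._scan("AAA" + "QFRFG" + "KR" + "AAA", signal_end=3)
        passing = [p for p in peptides if p.counts_toward_pass]
        assert [p.mature for p in passing] == ["QFRF"]
        assert passing[0].amidated and passing[0].pyroglu

    def test_overlong_segment_emitted_but_not_counted(self):
        long_seg = "ADENSTPHY" * 3  # 27 residues between two sites
        peptides = self._scan("AKR" + long_seg + "KRA")
        overlong = [p for p in peptides if p.mature == long_seg]
        assert len(overlong) == 1
        assert overlong[0].counts_toward_pass is False

    def test_terminal_peptide_needs_family_match(self):
        # terminal LW-matching tail counts; a plain tail does not
        with_family = self._scan("AKR" + "EPETNSLW")
        assert any(p.counts_toward_pass and p.mature == "EPETNSLW" for p in with_family)
        plain = self._scan("AKR" + "EPETNSAA")
        assert not any(p.counts_toward_pass for p in plain)

    def test_terminal_peptide_can_be_disabled(self):
        config = ScannerConfig(allow_terminal_peptide=False)
        peptides = self._scan("AKR" + "EPETNSLW", config=config)
        assert not any(p.mature == "EPETNSLW" for p in peptides)

    def test_require_n_motif_strict_reading(self):
        config = ScannerConfig(require_n_motif=True)
        # N-boundary is the protein start (not a site), no Q/XP: fails strict rule
        peptides = self._scan("ADENSTW" + "KRA", config=config)
        assert not any(p.counts_toward_pass for p in peptides)
        # pyroglutamate start satisfies it
        peptides = self._scan("QDENSTW" + "KRA", config=config)
        assert any(p.counts_toward_pass for p in peptides)

    def test_window_monotonicity(self, rng):
        for _ in range(100):
            seq = "".join(rng.choice(list(RESIDUES), size=150))
            counts = []
            for window in (10, 20, 40):
                config = ScannerConfig(window=window)
                peptides = self._scan(seq, config=config)
                counts.append(sum(p.counts_toward_pass for p in peptides))
            assert counts == sorted(counts)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.text(alphabet=RESIDUES, min_size=1, max_size=200))
    def test_reconstruction_invariant(self, seq):
        """Pre-signal region + segments + consumed sites reassemble the input."""
        config = ScannerConfig()
        sites = find_cleavage_sites(seq, config)
        peptides = segment_peptides(seq, sites, 0, config)
        pieces = [(p.start, p.end, p.raw) for p in peptides]
        pieces += [(s.start, s.end, seq[s.start - 1:s.end]) for s in sites]
        rebuilt = "".join(text for _, _, text in sorted(pieces))
        assert rebuilt == seq

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet=RESIDUES, min_size=1, max_size=200))
    def test_no_overlap_between_peptides_and_sites(self, seq):
        sites = find_cleavage_sites(seq)
        peptides = segment_peptides(seq, sites, 0)
        spans = sorted(
            [(p.start, p.end) for p in peptides] + [(s.start, s.end) for s in sites]
        )
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            assert e1 < s2


class TestAssignFamily:
    @pytest.mark.parametrize(
        "mature,amidated,family",
        [
            ("EPEPPETGLW", False, "LW_peptide"),
            ("QFRF", True, "RFamide"),
            ("AAAA", False, "unassigned"),
            ("NAGLW", True, "GLWamide"),
            ("APSNPRG", True, "PRXamide"),
            ("ANKV", True, "KVamide"),
            ("ANFR", True, "FRamide"),
            ("QFRF", False, "unassigned"),  # amidation state must match
            ("ANXW", False, "unassigned"),  # sequence X never satisfies pattern L
        ],
    )
    def test_family_assignment(self, mature, amidated, family):
        pep = MaturePeptide("p", 1, len(mature), mature, amidated, False, False)
        assert assign_family(pep) == family


def _pep(mature, amidated=False, pyroglu=False, xp=False, counts=True):
    return MaturePeptide(
        "p", 1, len(mature), mature, amidated, pyroglu, xp,
        counts_toward_pass=counts,
    )


class TestScorePrecursor:
    def test_no_peptides(self):
        score = score_precursor([])
        assert score.score == 0 and score.passes is False

    def test_three_repeated_amidated_peptides(self):
        peptides = [_pep("QFRF", amidated=True, pyroglu=True) for _ in range(3)]
        score = score_precursor(peptides)
        assert score.n_peptides == 3
        assert score.n_repeat_groups == 1
        assert score.n_modified == 3
        assert score.score == pytest.approx(6.5)
        assert score.passes

    def test_single_plain_peptide(self):
        score = score_precursor([_pep("ADENST")])
        assert score.score == pytest.approx(1.0)
        assert score.passes

    def test_non_passing_peptides_do_not_score(self):
        score = score_precursor([_pep("AD", counts=False)])
        assert score.score == 0 and not score.passes
        assert score.n_peptides == 1 and score.n_passing == 0
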