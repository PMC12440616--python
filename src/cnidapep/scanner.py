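"""Cleavage-site scanning, mature-peptide extraction and precursor scoring.

This is the toolkit's core computation. Neuropeptide precursors are
processed by prohormone convertases at dibasic motifs (KK, RK, KR, RR) and
at glycine-extended monobasic motifs (GK, GR); a glycine immediately
preceding the basic residues is the amide donor, converted into a
C-terminal amide on the upstream mature peptide. The scanner locates these
sites, cuts the precursor into candidate mature peptides, annotates
N-terminal protection motifs (pyroglutamate from a leading Q; proline at
position 2), assigns peptides to C-terminal sequence families (RFamide,
GLWamide, PRXamide, non-amidated LW peptides, ...), and scores each
precursor.

Scanning rules, applied left to right over the signal-trimmed region:

* a maximal run of K/R forms a cleavage site iff some length-2 window over
  the run (optionally extended by an immediately preceding G) matches a
  configured motif — so an isolated K or R with no preceding G is never a
  site (monobasic cleavage is outside the motif set);
* the whole K/R run is consumed, plus the preceding G when present
  (``amide_donor``); maximal-run consumption resolves overlapping motifs
  such as GKR or KKR deterministically into one site;
* X never matches K, R or G.

All coordinates are 1-based and inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io import PrecursorRecord, write_table

DEFAULT_MOTIFS = ("KK", "RK", "KR", "RR", "GK", "GR")


@dataclass
class ScannerConfig:
    """Scanner parameters.

    ``window`` is the maximum candidate peptide length in residues (a
    segment longer than this is still reported but does not count toward
    the precursor pass criterion). ``require_n_motif`` switches the
    N-terminal motifs (pyroglutamate Q, proline at position 2) from bonus
    evidence to a requirement.
    """

    cleavage_motifs: tuple[str, ...] = DEFAULT_MOTIFS
    window: int = 20
    min_len: int = 3
    require_n_motif: bool = False
    allow_terminal_peptide: bool = True
    #: score = w_peptide*n_passing + w_repeat*n_repeat_groups + w_modified*n_modified.
    #: These weights are this toolkit's own, exposed here because no canonical
    #: scoring function exists for the pass criterion (>= 1 peptide).
    weight_peptide: float = 1.0
    weight_repeat: float = 2.0
    weight_modified: float = 0.5

    def __post_init__(self):
        if not (self.window >= self.min_len >= 1):
            raise ValueError("require window >= min_len >= 1")
        for m in self.cleavage_motifs:
            if len(m) != 2 or any(c not in "KRG" for c in m):
                raise ValueError(f"cleavage motif must be 2 residues over K/R/G, got {m!r}")


@dataclass
class CleavageSite:
    """A located processing site: optional amide-donor G plus a K/R run.

    ``start``..``end`` (1-based, inclusive) span the consumed residues,
    including the G when ``amide_donor`` is true; ``basic_run`` is the K/R
    run itself.
    """

    start: int
    end: int
    basic_run: str
    amide_donor: bool


@dataclass
class MaturePeptide:
    """A candidate mature peptide cut from a precursor.

    ``mature`` equals ``raw``: the amide-donor G and the basic residues are
    already excluded because the site consumed them. ``counts_toward_pass``
    marks peptides satisfying the length and boundary criteria.
    """

    parent_id: str
    start: int
    end: int
    raw: str
    amidated: bool
    pyroglu: bool
    xp: bool
    family: str = "unassigned"
    counts_toward_pass: bool = False

    @property
    def mature(self) -> str:
        return self.raw


@dataclass
class FamilyMotif:
    """A C-terminal family signature: 1-3 residue pattern, X = wildcard."""

    name: str
    c_terminal_pattern: str
    amidation_required: bool

    def __post_init__(self):
        if not 1 <= len(self.c_terminal_pattern) <= 3:
            raise ValueError("family pattern must be 1-3 residues")


#: Default family table, checked in order; first match wins. The GLWamide
#: pattern G-[LIV]-W is simplified to X-L-W (the leading-G preference is
#: resolved by table order: GLWamide is checked before the PRXamide and
#: plain-LW rows).
DEFAULT_FAMILIES = (
    FamilyMotif("RFamide", "RF", amidation_required=True),
    FamilyMotif("GLWamide", "XLW", amidation_required=True),
    FamilyMotif("PRXamide", "PRX", amidation_required=True),
    FamilyMotif("LW_peptide", "LW", amidation_required=False),
    FamilyMotif("KVamide", "KV", amidation_required=True),
    FamilyMotif("FRamide", "FR", amidation_required=True),
)


@dataclass
class CandidateScore:
    """Per-precursor summary: peptide counts, repeat groups and score.

    A repeat group is >= 2 passing peptides sharing their C-terminal
    dipeptide and amidation state (repeated peptide copies are a hallmark
    of neuropeptide precursors). ``passes`` is the pipeline criterion:
    at least one passing peptide.
    """

    precursor_id: str
    n_peptides: int
    n_passing: int
    n_repeat_groups: int
    n_modified: int
    score: float
    passes: bool


def find_cleavage_sites(
    residues: str, config: Optional[ScannerConfig] = None
) -> list[CleavageSite]:
    """Locate cleavage sites as maximal K/R runs matching a configured motif.

    See the module docstring for the site-formation rules. Sites are
    returned sorted and non-overlapping.
    """
    config = config or ScannerConfig()
    motifs = set(config.cleavage_motifs)
    sites: list[CleavageSite] = []
    n = len(residues)
    i = 0  # 0-based scan index
    while i < n:
        if residues[i] in "KR":
            j = i
            while j + 1 < n and residues[j + 1] in "KR":
                j += 1
            run = residues[i:j + 1]
            g_before = i > 0 and residues[i - 1] == "G"
            candidate = ("G" + run) if g_before else run
            matched = any(candidate[k:k + 2] in motifs for k in range(len(candidate) - 1))
            if matched:
                start = i if g_before else i + 1  # 1-based consumed start
                sites.append(
                    CleavageSite(start=start, end=j + 1, basic_run=run, amide_donor=g_before)
                )
            i = j + 1
        else:
            i += 1
    return sites


def _match_family(mature: str, amidated: bool, family: FamilyMotif) -> bool:
    pat = family.c_terminal_pattern
    if family.amidation_required != amidated or len(mature) < len(pat):
        return False
    tail = mature[-len(pat):]
    for p, r in zip(pat, tail):
        if p == "X":
            continue
        if p != r:  # a sequence X never matches a concrete pattern residue
            return False
    return True


def assign_family(
    peptide: MaturePeptide, family_table: Sequence[FamilyMotif] = DEFAULT_FAMILIES
) -> str:
    """First family (table order) matching the mature C-terminus and amidation."""
    for fam in family_table:
        if _match_family(peptide.mature, peptide.amidated, fam):
            return fam.name
    return "unassigned"


def segment_peptides(
    residues: str,
    sites: Sequence[CleavageSite],
    signal_end: int = 0,
    config: Optional[ScannerConfig] = None,
    family_table: Sequence[FamilyMotif] = DEFAULT_FAMILIES,
    parent_id: str = "",
) -> list[MaturePeptide]:
    """Cut the precursor into candidate mature peptides between sites.

    Candidate segments are the maximal non-empty substrings strictly
    between consumed site regions, plus the segment from signal_end to the
    first site and (when ``allow_terminal_peptide``) the tail after the
    last site. A segment counts toward the precursor pass criterion iff

    * ``min_len`` <= length <= ``window``, and
    * its C-terminal boundary is a cleavage site, or the protein terminus
      when ``allow_terminal_peptide`` and the segment matches a family, and
    * when ``require_n_motif``: it starts with Q, has P at position 2, or
      its N-terminal boundary is a cleavage site.

    ``amidated`` is inherited from the terminating site's amide donor.
    """
    config = config or ScannerConfig()
    peptides: list[MaturePeptide] = []
    n = len(residues)

    boundaries: list[tuple[int, int, Optional[CleavageSite], bool]] = []
    prev_end = signal_end  # last consumed/trimmed position so far
    prev_was_site = False
    for site in sites:
        boundaries.append((prev_end + 1, site.start - 1, site, prev_was_site))
        prev_end, prev_was_site = site.end, True
    boundaries.append((prev_end + 1, n, None, prev_was_site))

    for seg_start, seg_end, term_site, n_bound_is_site in boundaries:
        if seg_end < seg_start:
            continue
        is_terminal = term_site is None
        if is_terminal and not config.allow_terminal_peptide:
            continue
        raw = residues[seg_start - 1:seg_end]
        pep = MaturePeptide(
            parent_id=parent_id,
            start=seg_start,
            end=seg_end,
            raw=raw,
            amidated=bool(term_site and term_site.amide_donor),
            pyroglu=raw.startswith("Q"),
            xp=len(raw) >= 2 and raw[1] == "P",
        )
        pep.family = assign_family(pep, family_table)
        length_ok = config.min_len <= len(raw) <= config.window
        c_ok = (not is_terminal) or pep.family != "unassigned"
        n_ok = (not config.require_n_motif) or pep.pyroglu or pep.xp or n_bound_is_site
        pep.counts_toward_pass = length_ok and c_ok and n_ok
        peptides.append(pep)
    return peptides


def score_precursor(
    peptides: Sequence[MaturePeptide],
    config: Optional[ScannerConfig] = None,
    precursor_id: str = "",
) -> CandidateScore:
    """Score one precursor from its extracted peptides.

    score = w_peptide * n_passing + w_repeat * n_repeat_groups
    + w_modified * n_modified, over passing peptides; the pass criterion
    itself is simply n_passing >= 1.
    """
    config = config or ScannerConfig()
    passing = [p for p in peptides if p.counts_toward_pass]
    groups: dict[tuple[str, bool], int] = {}
    for p in passing:
        key = (p.mature[-2:], p.amidated)
        groups[key] = groups.get(key, 0) + 1
    n_repeat_groups = sum(1 for c in groups.values() if c >= 2)
    n_modified = sum(1 for p in passing if p.amidated or p.pyroglu or p.xp)
    score = (
        config.weight_peptide * len(passing)
        + config.weight_repeat * n_repeat_groups
        + config.weight_modified * n_modified
    )
    return CandidateScore(
        precursor_id=precursor_id,
        n_peptides=len(peptides),
        n_passing=len(passing),
        n_repeat_groups=n_repeat_groups,
        n_modified=n_modified,
        score=score,
        passes=len(passing) >= 1,
    )


@dataclass
class ScanResult:
    """Everything the scanner derived from one precursor."""

    record: PrecursorRecord
    signal_end: int
    sites: list[CleavageSite]
    peptides: list[MaturePeptide]
    score: CandidateScore


def scan_record(
    record: PrecursorRecord,
    config: Optional[ScannerConfig] = None,
    family_table: Sequence[FamilyMotif] = DEFAULT_FAMILIES,
) -> ScanResult:
    """Run the full scan on one record: sites, peptides, families, score.

    The signal region (1..signal_end, from the record's evidence when
    present) is excluded from scanning; the first candidate segment starts
    at signal_end + 1.
    """
    config = config or ScannerConfig()
    signal_end = 0
    if record.evidence is not None and record.evidence.signal_end:
        signal_end = record.evidence.signal_end
    trimmed_sites = [
        s for s in find_cleavage_sites(record.residues, config) if s.start > signal_end
    ]
    peptides = segment_peptides(
        record.residues, trimmed_sites, signal_end, config, family_table, record.id
    )
    score = score_precursor(peptides, config, record.id)
    return ScanResult(record, signal_end, trimmed_sites, peptides, score)


def scan_records(
    records: Iterable[PrecursorRecord],
    config: Optional[ScannerConfig] = None,
    family_table: Sequence[FamilyMotif] = DEFAULT_FAMILIES,
) -> list[ScanResult]:
    return [scan_record(r, config, family_table) for r in records]


def peptide_table(results: Iterable[ScanResult]) -> pd.DataFrame:
    rows = [
        {
            "parent_id": p.parent_id,
            "start": p.start,
            "end": p.end,
            "mature": p.mature,
            "amidated": int(p.amidated),
            "pyroglu": int(p.pyroglu),
            "xp": int(p.xp),
            "family": p.family,
            "counts_toward_pass": int(p.counts_toward_pass),
        }
        for res in results
        for p in res.peptides
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "parent_id", "start", "end", "mature", "amidated", "pyroglu", "xp",
            "family", "counts_toward_pass",
        ],
    )


def write_peptide_table(results: Iterable[ScanResult], path) -> None:
    write_table(peptide_table(results), path, coordinate_note=True)


def write_peptide_fasta(results: Iterable[ScanResult], path) -> None:
    """Mature peptides as FASTA, headers ``parentid|start-end|family|amid={0,1}``."""
    with open(path, "w") as fh:
        for res in results:
            for p in res.peptides:
                fh.write(
                    f">{p.parent_id}|{p.start}-{p.end}|{p.family}|amid={int(p.amidated)}\n"
                )
                fh.write(p.mature + "\n")
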