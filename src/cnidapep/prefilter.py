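"""Secretome prefilter: keep putative secreted, domain-free proteins.

A precursor candidate must carry an N-terminal signal peptide, no
transmembrane segment outside that signal, and no known functional domain.
Evidence normally comes from external caller tables; when a record has no
signal-caller row, a deliberately crude hydrophobic-run heuristic can stand
in (policy ``heuristic``), so the pipeline is testable without running any
external annotator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd

from .io import Evidence, EvidenceTable, PrecursorRecord

HYDROPHOBIC = frozenset("AILFVMWC")
#: Small residues favoured at the signal-peptidase cleavage position.
CLEAVAGE_SMALL = frozenset("AGSCT")

REASONS = ("pass", "no_signal", "tm", "domain", "no_evidence")


@dataclass
class PrefilterConfig:
    """Knobs for the secreted-protein prefilter.

    ``missing_evidence_policy`` decides what happens when a record has no
    signal-caller row: ``drop`` it, ``keep`` it (signal_end 0), or apply the
    built-in ``heuristic`` (default).
    """

    require_signal: bool = True
    max_tm_regions: int = 0
    exclude_domains: bool = True
    missing_evidence_policy: str = "heuristic"
    heuristic_window: int = 30
    heuristic_min_hydrophobic_run: int = 8

    def __post_init__(self):
        if not (self.heuristic_window >= self.heuristic_min_hydrophobic_run >= 1):
            raise ValueError("require heuristic_window >= heuristic_min_hydrophobic_run >= 1")
        if self.missing_evidence_policy not in ("drop", "keep", "heuristic"):
            raise ValueError(f"unknown missing_evidence_policy {self.missing_evidence_policy!r}")


def heuristic_signal_peptide(
    residues: str, config: Optional[PrefilterConfig] = None
) -> tuple[bool, Optional[int]]:
    """Crude signal-peptide call from an N-terminal hydrophobic run.

    A signal is called iff the first ``heuristic_window`` residues contain a
    run of at least ``heuristic_min_hydrophobic_run`` hydrophobic residues
    (A,I,L,F,V,M,W,C). The predicted cleavage position (``signal_end``, the
    last residue of the signal) is the first small residue (A,G,S,C,T)
    1-10 positions after the run ends, else run end + 5, clamped to len-1.

    Total function: never raises on a valid residue string.
    """
    config = config or PrefilterConfig()
    window = residues[: config.heuristic_window]
    run_len = 0
    run_end = None  # 1-based position of the last residue of the first long run
    for pos, ch in enumerate(window, start=1):
        if ch in HYDROPHOBIC:
            run_len += 1
            if run_len >= config.heuristic_min_hydrophobic_run:
                run_end = pos
        else:
            if run_end is not None:
                break
            run_len = 0
    if run_end is None:
        return False, None
    signal_end = None
    for offset in range(1, 11):
        pos = run_end + offset
        if pos > len(residues):
            break
        if residues[pos - 1] in CLEAVAGE_SMALL:
            signal_end = pos
            break
    if signal_end is None:
        signal_end = run_end + 5
    signal_end = min(signal_end, len(residues) - 1)
    return True, signal_end


def _collate_evidence(
    record: PrecursorRecord,
    tables: dict[str, EvidenceTable],
) -> Evidence:
    ev = Evidence()
    sig = tables.get("signal_caller")
    if sig is not None:
        ev.has_signal, ev.signal_end = sig.signal_call(record.id)
    tm = tables.get("tm_caller")
    if tm is not None:
        regions = tm.tm_regions(record.id)
        if regions is not None:
            ev.tm_regions = regions
            ev.n_tm_regions = len(regions)
    dom = tables.get("domain_scanner")
    if dom is not None:
        hit = dom.has_domain(record.id)
        if hit is not None:
            ev.has_domain = hit
    return ev


def apply_prefilter(
    records: Iterable[PrecursorRecord],
    evidence_tables: Iterable[EvidenceTable] = (),
    config: Optional[PrefilterConfig] = None,
) -> tuple[list[PrecursorRecord], pd.DataFrame]:
    """Restrict records to putative secreted, domain-free proteins.

    A record is kept iff it has a signal peptide (caller evidence, else per
    ``missing_evidence_policy``), at most ``max_tm_regions`` transmembrane
    segments outside the signal region, and (when ``exclude_domains``) no
    domain hit. Kept records carry their signal_end for downstream trimming.

    TM segments lying entirely within the signal region (1..signal_end) are
    discounted: some TM callers report the signal peptide itself as a
    membrane segment, and counting it would systematically drop true
    secreted precursors.

    Returns the kept records (with evidence attached) and a per-record
    report with columns id, kept, reason (reason in
    pass/no_signal/tm/domain/no_evidence).
    """
    config = config or PrefilterConfig()
    tables = {t.source: t for t in evidence_tables}
    kept: list[PrecursorRecord] = []
    report_rows = []

    for record in records:
        ev = _collate_evidence(record, tables)
        reason = "pass"

        if ev.has_signal is None:  # no signal-caller row for this record
            if config.missing_evidence_policy == "drop":
                ev.has_signal = None
                reason = "no_evidence"
            elif config.missing_evidence_policy == "keep":
                ev.has_signal, ev.signal_end = True, 0
            else:
                ev.has_signal, ev.signal_end = heuristic_signal_peptide(
                    record.residues, config
                )
        if reason == "pass" and config.require_signal and not ev.has_signal:
            reason = "no_signal"

        if reason == "pass":
            signal_end = ev.signal_end or 0
            outside = [r for r in ev.tm_regions if r[1] > signal_end]
            if len(outside) > config.max_tm_regions:
                reason = "tm"

        if reason == "pass" and config.exclude_domains and ev.has_domain:
            reason = "domain"

        if reason == "pass":
            kept.append(replace(record, evidence=ev))
        report_rows.append({"id": record.id, "kept": int(reason == "pass"), "reason": reason})

    report = pd.DataFrame(report_rows, columns=["id", "kept", "reason"])
    return kept, report
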