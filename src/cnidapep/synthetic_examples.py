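"""Synthetic stand-in precursors for the characterized worked examples.

Four *Hydra* precursor genes are used as worked examples throughout the
documentation and tests: RFamide Preprohormone E (two amidated RF-terminal
peptides), PRGamide precursor B (two PRX-terminal amidated peptides),
RFamide Preprohormone D (two unique peptides), and LW-peptide precursor A
(multiple peptides, none carrying the glycine amide donor). The full
precursor protein sequences are not redistributed here; the records below
are SYNTHETIC reconstructions that reproduce each gene's published peptide
architecture — peptide counts, family signatures, amidation state and
N-terminal motifs — around hand-built signal peptides and dibasic sites.
Only the LWa1 mature peptide EPEPPETGLW is a real reported sequence.

Scanning these records with default settings demonstrates each
architecture; see the tests for the asserted properties.
"""

from __future__ import annotations

from .io import PrecursorRecord
from .prefilter import PrefilterConfig, heuristic_signal_peptide
from .scanner import ScannerConfig, ScanResult, scan_record

#: Hand-built signal peptide: Met start, basic residue, an 8-residue
#: hydrophobic core, then the small-residue cleavage region. The prefilter
#: heuristic places the cleavage after the S at position 11.
SIGNAL = "MKLLLFVAILSA"

#: The one real sequence here: the LWa1 mature peptide.
LWA1_PEPTIDE = "EPEPPETGLW"


def _assemble(cores: list[str], amidated: bool) -> str:
    """signal + separator site + core[+donor G]+KR per core + short tail."""
    parts = [SIGNAL, "KR"]
    for core in cores:
        parts.append(core + ("G" if amidated else "") + "KR")
    parts.append("SD")
    return "".join(parts)


#: Two amidated RF-terminal peptides (RFamide family), the first starting
#: with a pyroglutamate Q.
SYNTHETIC_PREPROHORMONE_E = PrecursorRecord(
    id="synE",
    description="synE synthetic RFamide preprohormone E stand-in",
    residues=_assemble(["QSDNPYRF", "ANTPESRF"], amidated=True),
)

#: Two amidated PRX-terminal peptides (PRXamide family), both with the
#: proline-at-position-2 protection motif.
SYNTHETIC_PRGAMIDE_B = PrecursorRecord(
    id="synB",
    description="synB synthetic PRGamide precursor B stand-in",
    residues=_assemble(["APSNPRG", "TPDSEPRG"], amidated=True),
)

#: Two unique (non-repeated) amidated RF-terminal peptides.
SYNTHETIC_PREPROHORMONE_D = PrecursorRecord(
    id="synD",
    description="synD synthetic RFamide preprohormone D stand-in",
    residues=_assemble(["QDESNRF", "NPTHSRF"], amidated=True),
)

#: Three LW-terminal peptides with no amide-donor glycine anywhere before
#: the basic runs: every extracted peptide is non-amidated. The first core
#: is the real LWa1 peptide.
SYNTHETIC_LW_PRECURSOR_A = PrecursorRecord(
    id="synA",
    description="synA synthetic LW-peptide precursor A stand-in",
    residues=_assemble([LWA1_PEPTIDE, "QPETNSLW", "DPNAHTLW"], amidated=False),
)

WORKED_EXAMPLES = (
    SYNTHETIC_PREPROHORMONE_E,
    SYNTHETIC_PRGAMIDE_B,
    SYNTHETIC_PREPROHORMONE_D,
    SYNTHETIC_LW_PRECURSOR_A,
)


def scan_example(record: PrecursorRecord, config: ScannerConfig | None = None) -> ScanResult:
    """Scan one example with the heuristic signal call applied first."""
    from dataclasses import replace

    from .io import Evidence

    has_signal, signal_end = heuristic_signal_peptide(record.residues, PrefilterConfig())
    ev = Evidence(has_signal=has_signal, signal_end=signal_end)
    return scan_record(replace(record, evidence=ev), config)
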