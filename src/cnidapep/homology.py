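"""Homology-based removal of candidates that are known non-neuropeptide proteins.

Candidates whose best database hit is a strong match (>30% identity,
e-value < 0.05 by default) to a protein that is *not* described as a
neuropeptide precursor or an uncharacterized protein are removed; hits
described as neuropeptide precursors or uncharacterized proteins do not
disqualify a candidate, and candidates with no hits at all are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .io import EvidenceTable

DEFAULT_ALLOW_KEYWORDS = (
    "neuropeptide",
    "preprohormone",
    "prohormone",
    "precursor",
    "uncharacterized",
    "hypothetical",
)


@dataclass
class HomologyConfig:
    """Thresholds for the non-neuropeptide-homologue filter.

    The strict inequalities (identity strictly above ``min_identity_pct``,
    e-value strictly below ``max_evalue``) are deliberate. The keyword
    allow-list approximates the manual inclusion of neuropeptide-precursor
    and uncharacterized-protein hits and is fully configurable.
    """

    min_identity_pct: float = 30.0
    max_evalue: float = 0.05
    allow_keywords: tuple[str, ...] = DEFAULT_ALLOW_KEYWORDS
    deny_on_no_keyword: bool = True

    def __post_init__(self):
        if not 0 <= self.min_identity_pct <= 100:
            raise ValueError("min_identity_pct must be in [0, 100]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")


def top_hit(hits: pd.DataFrame) -> Optional[pd.Series]:
    """Best hit: smallest e-value; ties by highest bitscore, then subject id."""
    if hits.empty:
        return None
    ordered = hits.sort_values(
        ["e_value", "bitscore", "subject"], ascending=[True, False, True]
    )
    return ordered.iloc[0]


def filter_by_homology(
    candidate_ids: Iterable[str],
    hit_table: EvidenceTable,
    config: Optional[HomologyConfig] = None,
) -> tuple[list[str], pd.DataFrame]:
    """Split candidates into kept and removed by their top alignment hit.

    A candidate is removed iff its top hit exists, exceeds the identity
    threshold, beats the e-value threshold, and its description contains no
    allow-listed keyword (case-insensitive substring). Decisions are
    independent across candidates.

    Returns kept ids and a reasons table (id, kept, top_subject, identity,
    evalue, matched_keyword).
    """
    config = config or HomologyConfig()
    kept: list[str] = []
    rows = []
    for cid in candidate_ids:
        hit = top_hit(hit_table.hits(cid))
        matched_kw = ""
        if hit is None:
            keep = True
            subject, identity, evalue = "", float("nan"), float("nan")
        else:
            subject = hit["subject"]
            identity = float(hit["pct_identity"])
            evalue = float(hit["e_value"])
            desc = str(hit.get("description", "")).lower()
            matched_kw = next((k for k in config.allow_keywords if k in desc), "")
            strong = identity > config.min_identity_pct and evalue < config.max_evalue
            if strong and not matched_kw and config.deny_on_no_keyword:
                keep = False
            else:
                keep = True
        if keep:
            kept.append(cid)
        rows.append(
            {
                "id": cid,
                "kept": int(keep),
                "top_subject": subject,
                "identity": identity,
                "evalue": evalue,
                "matched_keyword": matched_kw,
            }
        )
    report = pd.DataFrame(
        rows, columns=["id", "kept", "top_subject", "identity", "evalue", "matched_keyword"]
    )
    return kept, report
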