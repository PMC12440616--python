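"""Neuronal-expression filter over gene-by-cluster single-cell summaries.

A candidate precursor gene is retained only if it is expressed in neuronal
cell populations. Two knobs implement "neuronally expressed": a detection
threshold on the best neuronal cluster mean, and a neuronal share — the
best neuronal mean divided by the best overall mean — which tolerates
broadly expressed genes while rejecting genes whose expression is dominated
by non-neuronal populations. Neither threshold is canonical; both are
exposed in the config.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .io import ExpressionProfile


@dataclass
class ExpressionConfig:
    """Thresholds for the neuronal-expression filter.

    ``min_neuronal_expression`` — a gene must exceed this in at least one
    neuronal cluster (0 means any detection). ``min_neuronal_share`` — the
    best neuronal mean must be at least this fraction of the best overall
    mean. ``missing_gene_policy`` decides genes with no profile.
    """

    min_neuronal_expression: float = 0.0
    min_neuronal_share: float = 0.5
    missing_gene_policy: str = "drop"

    def __post_init__(self):
        if not 0 <= self.min_neuronal_share <= 1:
            raise ValueError("min_neuronal_share must be in [0, 1]")
        if self.missing_gene_policy not in ("drop", "keep"):
            raise ValueError(f"unknown missing_gene_policy {self.missing_gene_policy!r}")


def filter_by_expression(
    candidate_ids: Iterable[str],
    profiles: Iterable[ExpressionProfile] | Mapping[str, ExpressionProfile],
    config: Optional[ExpressionConfig] = None,
    id_map: Optional[Mapping[str, str]] = None,
) -> tuple[list[str], pd.DataFrame]:
    """Keep candidates expressed in neuronal clusters.

    A candidate is kept iff its profile exists (else per
    ``missing_gene_policy``), its best neuronal cluster mean exceeds
    ``min_neuronal_expression``, and its neuronal share (best neuronal mean
    over best overall mean) is at least ``min_neuronal_share``. All-zero
    profiles fail the detection test before any ratio is computed, so the
    share is never a division by zero.

    ``id_map`` optionally translates candidate ids to profile gene ids.
    Returns kept ids and a reasons table (id, kept, reason, neuronal_max,
    overall_max, share).
    """
    config = config or ExpressionConfig()
    if not isinstance(profiles, Mapping):
        profiles = {p.gene_id: p for p in profiles}
    kept: list[str] = []
    rows = []
    for cid in candidate_ids:
        gene_id = id_map.get(cid, cid) if id_map else cid
        profile = profiles.get(gene_id)
        neuronal_max = overall_max = share = float("nan")
        if profile is None:
            keep = config.missing_gene_policy == "keep"
            reason = "pass" if keep else "no_profile"
        else:
            neuronal_max = profile.neuronal_max
            overall_max = profile.overall_max
            if neuronal_max <= config.min_neuronal_expression:
                keep, reason = False, "not_neuronal"
                share = float("nan")
            else:
                share = neuronal_max / overall_max  # overall_max > 0 here
                if share < config.min_neuronal_share:
                    keep, reason = False, "low_share"
                else:
                    keep, reason = True, "pass"
        if keep:
            kept.append(cid)
        rows.append(
            {
                "id": cid,
                "kept": int(keep),
                "reason": reason,
                "neuronal_max": neuronal_max,
                "overall_max": overall_max,
                "share": share,
            }
        )
    report = pd.DataFrame(
        rows, columns=["id", "kept", "reason", "neuronal_max", "overall_max", "share"]
    )
    return kept, report
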