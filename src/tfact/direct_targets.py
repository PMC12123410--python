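"""Restrict regulons to direct targets: genes regulated by super-enhancers
bound by the TF in the tissue of interest.

Binding evidence is taken as given by the SE table (the table aggregates
ChIP-seq and motif evidence upstream); no motif scanning or coordinate
arithmetic happens here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io_formats import SETable
from .regulon_inference import Regulon

logger = logging.getLogger(__name__)

__all__ = ["direct_target_genes", "filter_regulon", "filter_all", "FilterSummary"]


def direct_target_genes(se_table: SETable, tf: str) -> set[str]:
    """Union of regulated-gene sets over all SEs bound by the TF."""
    out: set[str] = set()
    for rec in se_table.records:
        if tf in rec.tf_ids:
            out |= rec.gene_ids
    return out


def filter_regulon(regulon: Regulon, se_table: SETable) -> Regulon:
    """Keep only SE-supported targets; edge statistics carried unchanged."""
    direct = direct_target_genes(se_table, regulon.tf)
    kept = {t: e for t, e in regulon.targets.items() if t in direct}
    return Regulon(tf=regulon.tf, targets=kept)


@dataclass
class FilterSummary:
    """Per-TF bookkeeping of the SE filter: counts and kept/filtered-out flag."""

    rows: list[dict] = field(default_factory=list)

    def add(self, tf: str, n_before: int, n_direct: int) -> None:
        self.rows.append(
            {
                "tf": tf,
                "n_targets_before": n_before,
                "n_direct": n_direct,
                "status": "kept" if n_direct > 0 else "filtered-out",
            }
        )


def filter_all(
    regulons: dict[str, Regulon], se_table: SETable
) -> tuple[dict[str, Regulon], FilterSummary]:
    """SE-filter every regulon; TFs left with no direct targets are reported,
    not raised."""
    summary = FilterSummary()
    out: dict[str, Regulon] = {}
    for tf, reg in regulons.items():
        filtered = filter_regulon(reg, se_table)
        summary.add(tf, len(reg), len(filtered))
        if len(filtered) == 0:
            logger.info("TF %s filtered out: no SE-supported targets", tf)
            continue
        out[tf] = filtered
    return out, summary
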