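"""Correction of experimental RFUs for back- and forward-exchange artifacts.

Raw relative fractional uptake contains deuterium gained during quench
(forward exchange, FEX) and is depressed by deuterium lost during workup
(back exchange, BEX). With per-peptide control RFUs for both artifacts,
the corrected uptake is the two-point normalization

    RFU_corr = (RFU_exp - RFU_FEX) / (RFU_BEX - RFU_FEX)

which maps the FEX level to 0 (no genuine labelling) and the fully
deuterated BEX control to 1. Corrected values are clamped to [0, 1];
clamps are counted and logged, never silent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

from hdx2ss._errors import DegenerateControlError
from hdx2ss.hdx_io import PeptideRecord, UptakeTable

logger = logging.getLogger(__name__)


@dataclass
class CorrectedUptakeTable(UptakeTable):
    """Uptake table whose records carry ``rfu_corr`` per exposure."""

    n_clamped: int = 0


def correct_rfu(rfu_exp: float, rfu_fex: float, rfu_bex: float, peptide: str = "?") -> float:
    """Normalize one experimental RFU against its FEX/BEX controls.

    Returns ``(rfu_exp - rfu_fex) / (rfu_bex - rfu_fex)`` clamped to [0, 1].

    Raises
    ------
    DegenerateControlError
        if ``rfu_bex <= rfu_fex`` (normalization undefined).
    """
    if rfu_bex <= rfu_fex:
        raise DegenerateControlError(
            f"peptide {peptide}: BEX control ({rfu_bex}) does not exceed FEX control ({rfu_fex})"
        )
    corr = (rfu_exp - rfu_fex) / (rfu_bex - rfu_fex)
    return min(1.0, max(0.0, corr))


def correct_table(table: UptakeTable) -> CorrectedUptakeTable:
    """Apply the FEX/BEX correction to every exposure of every peptide.

    The number of values clamped into [0, 1] is recorded on the result
    and logged.
    """
    records: List[PeptideRecord] = []
    n_clamped = 0
    for rec in table.records:
        corr = {}
        for t, r in rec.exposures.items():
            raw = (r - rec.rfu_fex) / (rec.rfu_bex - rec.rfu_fex) if rec.rfu_bex > rec.rfu_fex else None
            value = correct_rfu(r, rec.rfu_fex, rec.rfu_bex, peptide=f"{rec.sequence} {rec.start}-{rec.end}")
            if raw is not None and (raw < 0.0 or raw > 1.0):
                n_clamped += 1
            corr[t] = value
        records.append(
            PeptideRecord(
                sequence=rec.sequence,
                start=rec.start,
                end=rec.end,
                exposures=dict(rec.exposures),
                rfu_fex=rec.rfu_fex,
                rfu_bex=rec.rfu_bex,
                rfu_corr=corr,
                n_replicates=dict(rec.n_replicates),
            )
        )
    if n_clamped:
        logger.info("RFU correction clamped %d value(s) into [0, 1]", n_clamped)
    return CorrectedUptakeTable(protein_id=table.protein_id, records=records, n_clamped=n_clamped)
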