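"""Readers and writers for uptake tables, intrinsic-rate tables, residue-rate
models and protein backbone coordinates.

CSV layouts
-----------
Uptake CSV: columns ``protein, sequence, start, end, exposure, rfu,
rfu_fex, rfu_bex`` — one row per (peptide, exposure time, replicate).
Replicate rows for the same peptide and time are averaged at parse time,
with the replicate count recorded. An optional ``rfu_corr`` column carries
corrected values (written by :func:`hdx2ss.rfu_correction.correct_table`).

k_int CSV: columns ``residue_index, k_int`` (rates in 1/min). Prolines and
the N-terminal residue are simply absent.

Residue numbering is 1-based and inclusive throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import gemmi
import numpy as np
import pandas as pd

from hdx2ss._errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

UPTAKE_COLUMNS = ["protein", "sequence", "start", "end", "exposure", "rfu", "rfu_fex", "rfu_bex"]


@dataclass
class PeptideRecord:
    """One proteolytic peptide with its uptake time course.

    ``exposures`` maps exposure time in seconds to the (replicate-averaged)
    experimental RFU. ``rfu_fex``/``rfu_bex`` are the forward- and
    back-exchange control RFUs for this peptide. ``rfu_corr`` is filled by
    the correction step and is ``None`` on raw tables.
    """

    sequence: str
    start: int
    end: int
    exposures: Dict[float, float]
    rfu_fex: float
    rfu_bex: float
    rfu_corr: Optional[Dict[float, float]] = None
    n_replicates: Dict[float, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.start < 1:
            raise ValidationError(f"peptide {self.sequence}: start {self.start} < 1")
        if self.end < self.start:
            raise ValidationError(f"peptide {self.sequence}: end {self.end} < start {self.start}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValidationError(
                f"peptide {self.sequence} ({self.start}-{self.end}): length "
                f"{len(self.sequence)} != end - start + 1 = {self.end - self.start + 1}"
            )
        if not self.exposures:
            raise ValidationError(f"peptide {self.sequence}: no exposure times")
        for t, r in self.exposures.items():
            if t <= 0:
                raise ValidationError(f"peptide {self.sequence}: non-positive exposure time {t}")
            if not np.isfinite(r):
                raise ValidationError(f"peptide {self.sequence}: non-finite RFU at t={t}")

    @property
    def times(self) -> List[float]:
        return sorted(self.exposures)

    def key(self) -> Tuple[str, int, int]:
        return (self.sequence, self.start, self.end)


@dataclass
class UptakeTable:
    """Per-peptide relative fractional uptake for one protein."""

    protein_id: str
    records: List[PeptideRecord]

    def __len__(self) -> int:
        return len(self.records)

    def coverage(self) -> set:
        """Set of residue indices covered by at least one peptide."""
        cov = set()
        for rec in self.records:
            cov.update(range(rec.start, rec.end + 1))
        return cov


@dataclass
class KintTable:
    """Per-residue intrinsic exchange rates (1/min), keyed by residue index.

    Prolines (no amide hydrogen) and the N-terminal residue (no stably
    measurable amide) are absent.
    """

    rates: Dict[int, float]

    def __post_init__(self):
        for idx, k in self.rates.items():
            if k <= 0:
                raise ValidationError(f"residue {idx}: non-positive k_int {k}")

    def __len__(self) -> int:
        return len(self.rates)

    def __contains__(self, idx: int) -> bool:
        return idx in self.rates

    def __getitem__(self, idx: int) -> float:
        return self.rates[idx]

    def get(self, idx: int, default=None):
        return self.rates.get(idx, default)


def read_uptake_csv(path) -> UptakeTable:
    """Parse an uptake CSV into an :class:`UptakeTable`.

    Replicate rows (same peptide and exposure) are averaged; the replicate
    count per time point is kept on the record. Row order is irrelevant.
    """
    df = pd.read_csv(path)
    for col in UPTAKE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"uptake CSV {path}: missing required column '{col}'")
    if df.empty:
        raise FormatError(f"uptake CSV {path}: no data rows")
    has_corr = "rfu_corr" in df.columns

    proteins = df["protein"].unique()
    if len(proteins) > 1:
        raise ValidationError(f"uptake CSV {path}: multiple proteins {list(proteins)}")
    protein_id = str(proteins[0])

    records = []
    for (seq, start, end), grp in sorted(
        df.groupby(["sequence", "start", "end"]), key=lambda kv: (kv[0][1], kv[0][2], kv[0][0])
    ):
        start, end = int(start), int(end)
        if end - start + 1 != len(seq):
            rows = grp.index.min() + 2  # 1-based, plus header
            raise ValidationError(
                f"uptake CSV {path} row {rows}: peptide {seq} ({start}-{end}) "
                f"length inconsistent with start/end"
            )
        fex_vals = grp["rfu_fex"].unique()
        bex_vals = grp["rfu_bex"].unique()
        if len(fex_vals) > 1 or len(bex_vals) > 1:
            raise ValidationError(
                f"peptide {seq} ({start}-{end}): controls differ across rows"
            )
        exposures: Dict[float, float] = {}
        corr: Dict[float, float] = {}
        counts: Dict[float, int] = {}
        for t, tgrp in grp.groupby("exposure"):
            t = float(t)
            exposures[t] = float(tgrp["rfu"].mean())
            counts[t] = int(len(tgrp))
            if counts[t] > 1:
                logger.debug(
                    "peptide %s t=%.1fs: averaged %d replicates (sd %.4f)",
                    seq, t, counts[t], float(tgrp["rfu"].std()),
                )
            if has_corr:
                corr[t] = float(tgrp["rfu_corr"].mean())
        records.append(
            PeptideRecord(
                sequence=str(seq),
                start=start,
                end=end,
                exposures=exposures,
                rfu_fex=float(fex_vals[0]),
                rfu_bex=float(bex_vals[0]),
                rfu_corr=corr if has_corr else None,
                n_replicates=counts,
            )
        )
    return UptakeTable(protein_id=protein_id, records=records)


def write_uptake_csv(table: UptakeTable, path) -> None:
    """Write an uptake table (optionally with corrected RFUs) to CSV."""
    rows = []
    for rec in table.records:
        for t in rec.times:
            row = {
                "protein": table.protein_id,
                "sequence": rec.sequence,
                "start": rec.start,
                "end": rec.end,
                "exposure": t,
                "rfu": rec.exposures[t],
                "rfu_fex": rec.rfu_fex,
                "rfu_bex": rec.rfu_bex,
            }
            if rec.rfu_corr is not None:
                row["rfu_corr"] = rec.rfu_corr[t]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_kint_csv(path) -> KintTable:
    """Parse a two-column ``residue_index, k_int`` CSV."""
    df = pd.read_csv(path)
    for col in ("residue_index", "k_int"):
        if col not in df.columns:
            raise FormatError(f"k_int CSV {path}: missing required column '{col}'")
    if df.empty:
        raise FormatError(f"k_int CSV {path}: empty table")
    rates = {int(r): float(k) for r, k in zip(df["residue_index"], df["k_int"])}
    return KintTable(rates=rates)


def write_kint_csv(table: KintTable, path) -> None:
    pd.DataFrame(
        {"residue_index": sorted(table.rates), "k_int": [table.rates[i] for i in sorted(table.rates)]}
    ).to_csv(path, index=False)


#: map three-letter residue names to one-letter codes
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class BackboneResidue:
    """One residue's backbone: N, CA, C coordinates in Angstroms."""

    index: int
    aa: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray


def read_structure(path, chain: Optional[str] = None) -> List[BackboneResidue]:
    """Read backbone (N, CA, C) coordinates from a PDB file.

    Residues missing any of the three backbone atoms are skipped with a
    warning. For alternate locations the highest-occupancy conformer is
    kept (gemmi's ``remove_alternative_conformations`` policy).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    st.remove_alternative_conformations()
    model = st[0]
    if chain is None:
        ch = model[0]
    else:
        ch = None
        for c in model:
            if c.name == chain:
                ch = c
                break
        if ch is None:
            raise ValidationError(f"{path}: chain '{chain}' not found")
    residues = []
    for res in ch:
        one = _THREE_TO_ONE.get(res.name)
        if one is None:
            continue
        atoms = {}
        for name in ("N", "CA", "C"):
            a = res.find_atom(name, "*")
            if a is not None:
                atoms[name] = np.array([a.pos.x, a.pos.y, a.pos.z])
        if len(atoms) < 3:
            missing = [n for n in ("N", "CA", "C") if n not in atoms]
            logger.warning(
                "residue %s%d: missing backbone atom(s) %s — skipped",
                res.name, res.seqid.num, ",".join(missing),
            )
            continue
        residues.append(
            BackboneResidue(index=res.seqid.num, aa=one, n=atoms["N"], ca=atoms["CA"], c=atoms["C"])
        )
    return residues


def save_model_json(model, path) -> None:
    """Serialize a fitted GBModel to JSON (f0, nu, nested tree nodes)."""
    import json

    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def load_model_json(path):
    """Load a GBModel saved by :func:`save_model_json`."""
    import json

    from hdx2ss.gb_core import GBModel

    with open(path) as fh:
        return GBModel.from_dict(json.load(fh))


def write_pdb(residues: List[BackboneResidue], path, chain: str = "A") -> None:
    """Write backbone residues to a minimal PDB file (N, CA, C only)."""
    lines = []
    serial = 1
    for res in residues:
        three = {v: k for k, v in _THREE_TO_ONE.items()}[res.aa]
        for name, xyz in (("N", res.n), ("CA", res.ca), ("C", res.c)):
            elem = name[0]
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {three} {chain}{res.index:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           {elem}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
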