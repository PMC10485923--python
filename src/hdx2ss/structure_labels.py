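"""Binary secondary-structure targets from backbone dihedral angles.

Each residue's (phi, psi) pair is classified as alpha-helix (label 0) or
beta-strand (label 1) by kernel-density classification on the
Ramachandran torus: two fixed-reference Gaussian kernels centered on the
canonical helix basin (-63, -43) and strand basin (-120, 130), each with
a 30 degree bandwidth, and the residue takes the class with the higher
density at its angles. Every residue with both angles defined receives a
label — coil/loop conformations are force-assigned to the nearer basin,
a deliberate simplification of the two-state model.

Amino-acid identity is encoded as an ordinal 0..19 in alphabetical
one-letter order (A=0 ... Y=19) so it can enter a numeric feature table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from hdx2ss._errors import ValidationError
from hdx2ss.hdx_io import BackboneResidue

logger = logging.getLogger(__name__)

#: canonical Ramachandran basin centers (phi, psi) in degrees
HELIX_CENTER = (-63.0, -43.0)
STRAND_CENTER = (-120.0, 130.0)
#: kernel bandwidth on each angular axis, degrees
BANDWIDTH = 30.0

#: peptide-bond C-N distance threshold for chain continuity, Angstroms
PEPTIDE_BOND_CUTOFF = 2.5

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_CODE = {aa: i for i, aa in enumerate(AA_ALPHABET)}


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention.

    Raises :class:`ValidationError` when consecutive bond vectors are
    collinear and the angle is geometrically undefined.
    """
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-9:
        raise ValidationError("undefined dihedral: coincident atoms")
    b1u = b1 / nb1
    v = b0 - (b0 @ b1u) * b1u
    w = b2 - (b2 @ b1u) * b1u
    if np.linalg.norm(v) < 1e-9 or np.linalg.norm(w) < 1e-9:
        raise ValidationError("undefined dihedral: collinear atoms")
    x = v @ w
    y = np.cross(b1u, v) @ w
    return math.degrees(math.atan2(y, x))


def compute_dihedrals(
    backbone: List[BackboneResidue],
) -> Dict[int, Tuple[Optional[float], Optional[float]]]:
    """Phi/psi for each residue of a backbone coordinate list.

    phi_i needs the preceding residue's C, psi_i the next residue's N, so
    the first residue lacks phi and the last lacks psi. A chain break
    (C-N distance above 2.5 A) leaves the flanking residues with only
    their defined angle.
    """
    out: Dict[int, Tuple[Optional[float], Optional[float]]] = {}
    n = len(backbone)
    bonded = [
        np.linalg.norm(backbone[i + 1].n - backbone[i].c) < PEPTIDE_BOND_CUTOFF
        for i in range(n - 1)
    ]
    for i, res in enumerate(backbone):
        phi = psi = None
        if i > 0 and bonded[i - 1]:
            phi = dihedral(backbone[i - 1].c, res.n, res.ca, res.c)
        if i < n - 1 and bonded[i]:
            psi = dihedral(res.n, res.ca, res.c, backbone[i + 1].n)
        out[res.index] = (phi, psi)
    return out


def _wrap(delta: np.ndarray) -> np.ndarray:
    """Wrap angular differences into (-180, 180]."""
    return (np.asarray(delta) + 180.0) % 360.0 - 180.0


def _log_kernel(phi, psi, center, bandwidth=BANDWIDTH):
    dphi = _wrap(np.asarray(phi) - center[0])
    dpsi = _wrap(np.asarray(psi) - center[1])
    return -(dphi**2 + dpsi**2) / (2.0 * bandwidth**2)


@dataclass
class StructureLabelTable:
    """Per-residue dihedrals, binary class and amino-acid ordinal.

    ``labels``: 0 = alpha-helix, 1 = beta-strand.
    """

    phi: Dict[int, float] = field(default_factory=dict)
    psi: Dict[int, float] = field(default_factory=dict)
    labels: Dict[int, int] = field(default_factory=dict)
    aa_code: Dict[int, int] = field(default_factory=dict)

    def residues(self) -> List[int]:
        return sorted(self.labels)


def classify_secondary_structure(
    dihedrals: Dict[int, Tuple[Optional[float], Optional[float]]],
    aa_by_residue: Optional[Dict[int, str]] = None,
    mode: str = "fixed",
) -> StructureLabelTable:
    """Assign each residue the class with the higher kernel density.

    ``mode='fixed'`` (default) evaluates two single-kernel reference
    densities at the canonical basin centers — reproducible with no
    per-protein fitting. ``mode='fitted'`` refines this with one
    data-driven pass: residues are first assigned by the fixed rule, then
    each class's density is re-estimated as a KDE over its own members'
    angles and residues are reassigned by the refit densities.

    Residues missing either angle are excluded with a warning.
    """
    usable = {r: (a[0], a[1]) for r, a in dihedrals.items() if a[0] is not None and a[1] is not None}
    skipped = len(dihedrals) - len(usable)
    if skipped:
        logger.warning("%d residue(s) missing an angle — excluded from labels", skipped)
    if not usable:
        raise ValidationError("no residue has both phi and psi defined")

    res_idx = sorted(usable)
    phi = np.array([usable[r][0] for r in res_idx])
    psi = np.array([usable[r][1] for r in res_idx])
    log_h = _log_kernel(phi, psi, HELIX_CENTER)
    log_s = _log_kernel(phi, psi, STRAND_CENTER)
    labels = (log_s > log_h).astype(int)

    if mode == "fitted":
        new = labels.copy()
        for cls in (0, 1):
            if not (labels == cls).any():
                logger.warning("fitted mode: class %d empty after seed pass; keeping fixed labels", cls)
                break
        else:
            dens = np.zeros((2, len(res_idx)))
            for cls in (0, 1):
                mphi, mpsi = phi[labels == cls], psi[labels == cls]
                dphi = _wrap(phi[:, None] - mphi[None, :])
                dpsi = _wrap(psi[:, None] - mpsi[None, :])
                dens[cls] = np.exp(-(dphi**2 + dpsi**2) / (2.0 * BANDWIDTH**2)).mean(axis=1)
            new = (dens[1] > dens[0]).astype(int)
        labels = new
    elif mode != "fixed":
        raise ValidationError(f"unknown classification mode '{mode}'")

    table = StructureLabelTable()
    for j, r in enumerate(res_idx):
        table.phi[r] = float(phi[j])
        table.psi[r] = float(psi[j])
        table.labels[r] = int(labels[j])
        if aa_by_residue and r in aa_by_residue:
            table.aa_code[r] = _AA_CODE[aa_by_residue[r]]
    return table


def encode_amino_acid(sequence: str) -> Dict[int, int]:
    """Ordinal encoding of a sequence: 1-based residue index -> 0..19.

    Alphabetical one-letter order (A=0, C=1, ... Y=19); deterministic.
    """
    out = {}
    for i, aa in enumerate(sequence, start=1):
        if aa not in _AA_CODE:
            raise ValidationError(f"nonstandard residue '{aa}' at position {i}")
        out[i] = _AA_CODE[aa]
    return out
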