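"""End-to-end assembly: from fitted rates and structure labels to a
trained, cross-validated classifier.

`assemble_features` joins a :class:`ResidueRateModel` with a
:class:`StructureLabelTable` on residue index, producing the
four-dimensional covariate (k_obs, k_int, r_matrix, aa_code) with the
binary helix/strand target. Residues missing from either side are
dropped — rates exist only for covered, exchanging residues and labels
only for residues with both dihedral angles.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from hdx2ss._errors import ValidationError
from hdx2ss.gb_core import FeatureTable
from hdx2ss.residue_optimizer import ResidueRateModel
from hdx2ss.structure_labels import StructureLabelTable


def assemble_features(
    rates: ResidueRateModel,
    labels: StructureLabelTable,
    drop_features: Tuple[str, ...] = (),
) -> FeatureTable:
    """Join fitted rates and structure labels into a training table.

    ``drop_features`` removes named columns (e.g. ``("r_matrix",)`` for
    the ablation experiment).
    """
    common = sorted(set(rates.lnp) & set(labels.labels) & set(labels.aa_code))
    if not common:
        raise ValidationError("no residues common to rates and labels")
    names = ["k_obs", "k_int", "r_matrix", "aa_code"]
    cols = {
        "k_obs": [rates.k_obs[r] for r in common],
        "k_int": [rates.k_int[r] for r in common],
        "r_matrix": [rates.rmatrix_of_residue(r) for r in common],
        "aa_code": [float(labels.aa_code[r]) for r in common],
    }
    keep = [n for n in names if n not in drop_features]
    X = np.column_stack([cols[n] for n in keep])
    y = np.array([labels.labels[r] for r in common])
    return FeatureTable(X=X, y=y, feature_names=tuple(keep))
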