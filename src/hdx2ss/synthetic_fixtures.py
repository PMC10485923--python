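"""Fully synthetic proteins, structures, peptide maps and uptake data.

The generator emulates the statistical structure the pipeline assumes:
proteins built from alternating helix/strand segments; class-dependent
protection factors (helical residues more protected than strand residues,
marginally lnP ~ Normal(8, 1.5) vs Normal(5, 1.5), spatially correlated
within a segment as an AR(1) process because protection tracks local
hydrogen-bonding environment, clipped to the optimizer bounds); backbone
coordinates built from ideal segment dihedrals with
small angular jitter; overlapping pepsin-like peptide maps with
configurable redundancy, deliberate coverage gaps and junctions; and
noisy time-course RFUs synthesized through the same first-order forward
model the optimizer fits, de-normalized into raw experimental RFUs with
configurable BEX/FEX control levels.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from hdx2ss._errors import ValidationError
from hdx2ss.hdx_io import BackboneResidue, KintTable, PeptideRecord, UptakeTable
from hdx2ss.intrinsic_rates import compute_kint
from hdx2ss.residue_optimizer import exchanging_indices, forward_rfu

#: ideal segment dihedrals (phi, psi) in degrees
HELIX_DIHEDRALS = (-57.0, -47.0)
STRAND_DIHEDRALS = (-120.0, 130.0)

#: default exposure times: nine points spanning 5 s to 24 h (seconds),
#: log-spaced so both weakly and strongly protected residues show
#: curvature inside the observation window
DEFAULT_TIMES = (5.0, 15.0, 60.0, 300.0, 900.0, 3600.0, 14400.0, 43200.0, 86400.0)

#: residue sampling weights — proline kept rare so peptides retain
#: exchanging residues, as in real sequences
_AA = "ACDEFGHIKLMNQRSTVWY"
_P_FRACTION = 0.03

# ideal backbone internal coordinates (Angstroms / degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_OMEGA = 180.0


@dataclass
class FixtureConfig:
    """Study conditions for the synthetic data generator.

    The class-dependent lnP means encode the direction that strands are
    less protected than helices; the 3-unit separation and 1.5 sd are
    this package's chosen effect size. ``redundancy`` is the target mean
    coverage depth of the base peptide tiling; the degeneracy-breaking
    pass (``break_degeneracies``, see :func:`make_peptide_map`) adds
    further peptides on top of it, so well-constrained maps end up denser
    than the base target. Disable it to study underdetermined maps.
    """

    n_residues: int = 500
    segment_length_range: Tuple[int, int] = (8, 20)
    helix_lnp_mean: float = 8.0
    strand_lnp_mean: float = 5.0
    lnp_sd: float = 1.5
    lnp_rho: float = 0.7
    lnp_bounds: Tuple[float, float] = (0.0, 14.0)
    peptide_length_range: Tuple[int, int] = (4, 9)
    redundancy: float = 3.0
    noise_sd: float = 0.01
    bex: float = 0.92
    fex: float = 0.05
    dihedral_jitter_sd: float = 5.0
    break_degeneracies: bool = True
    temperature: float = 293.15
    pd_value: float = 7.0
    gaps: List[Tuple[int, int]] = field(default_factory=list)
    junctions: List[int] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.lnp_sd <= 0:
            raise ValidationError("lnp_sd must be > 0")
        if not (0.0 <= self.lnp_rho < 1.0):
            raise ValidationError("lnp_rho must be in [0, 1)")
        if self.bex <= self.fex:
            raise ValidationError("bex must exceed fex")


@dataclass
class SyntheticProtein:
    """Ground truth for one synthetic protein."""

    sequence: str
    segments: List[Tuple[int, int, int]]  # (start, end, label) with 0=helix, 1=strand
    lnp_true: Dict[int, float]
    labels_true: Dict[int, int]
    backbone: List[BackboneResidue]
    kint: KintTable


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position of atom d given a-b-c, with c-d bond
    length, b-c-d angle and a-b-c-d torsion (degrees)."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def build_backbone(
    sequence: str,
    phi: Sequence[float],
    psi: Sequence[float],
    start_index: int = 1,
) -> List[BackboneResidue]:
    """Build N/CA/C coordinates from per-residue phi/psi (ideal geometry).

    ``phi[0]`` and ``psi[-1]`` are unused (undefined at the termini) but
    must be supplied for alignment.
    """
    n_res = len(sequence)
    if len(phi) != n_res or len(psi) != n_res:
        raise ValidationError("phi/psi length must match sequence length")
    coords: List[Dict[str, np.ndarray]] = []
    # first residue: arbitrary rigid placement
    n0 = np.zeros(3)
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = coords[i - 1]
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi[i - 1])
        ca_i = _place_atom(prev["CA"], prev["C"], n_i, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_i = _place_atom(prev["C"], n_i, ca_i, _B_CA_C, _A_N_CA_C, phi[i])
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})
    return [
        BackboneResidue(index=start_index + i, aa=sequence[i], n=c["N"], ca=c["CA"], c=c["C"])
        for i, c in enumerate(coords)
    ]


def make_protein(cfg: FixtureConfig) -> SyntheticProtein:
    """Generate a synthetic protein with ground-truth protection factors.

    Alternating helix/strand segments of random length; per-residue lnP
    drawn as a within-segment AR(1) process (correlation ``lnp_rho``)
    whose marginal distribution is the segment class's normal (helix
    mean 8, strand mean 5, sd 1.5 by default), clipped to the optimizer
    bounds; ideal-geometry coordinates with angular jitter; intrinsic
    rates from the sequence. Spatial correlation of protection within a
    structural element mirrors real proteins, where neighbouring residues
    share a hydrogen-bonding environment.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_residues
    p_other = (1.0 - _P_FRACTION) / len(_AA)
    letters = list(_AA) + ["P"]
    probs = [p_other] * len(_AA) + [_P_FRACTION]
    sequence = "".join(rng.choice(letters, size=n, p=probs))

    segments: List[Tuple[int, int, int]] = []
    pos = 1
    label = int(rng.integers(0, 2))
    lo, hi = cfg.segment_length_range
    while pos <= n:
        length = int(rng.integers(lo, hi + 1))
        end = min(pos + length - 1, n)
        segments.append((pos, end, label))
        pos = end + 1
        label = 1 - label

    lnp_true: Dict[int, float] = {}
    labels_true: Dict[int, int] = {}
    phi = np.empty(n)
    psi = np.empty(n)
    b_lo, b_hi = cfg.lnp_bounds
    rho = cfg.lnp_rho
    innov_sd = cfg.lnp_sd * math.sqrt(1.0 - rho**2)
    for start, end, lab in segments:
        mean = cfg.helix_lnp_mean if lab == 0 else cfg.strand_lnp_mean
        base_phi, base_psi = HELIX_DIHEDRALS if lab == 0 else STRAND_DIHEDRALS
        z = 0.0
        for r in range(start, end + 1):
            labels_true[r] = lab
            # AR(1) deviation from the class mean; marginal sd stays lnp_sd
            if r == start:
                z = rng.normal(0.0, cfg.lnp_sd)
            else:
                z = rho * z + rng.normal(0.0, innov_sd)
            lnp_true[r] = float(min(b_hi, max(b_lo, mean + z)))
            phi[r - 1] = base_phi + rng.normal(0.0, cfg.dihedral_jitter_sd)
            psi[r - 1] = base_psi + rng.normal(0.0, cfg.dihedral_jitter_sd)

    backbone = build_backbone(sequence, phi, psi)
    kint = compute_kint(sequence, cfg.temperature, cfg.pd_value)
    return SyntheticProtein(
        sequence=sequence,
        segments=segments,
        lnp_true=lnp_true,
        labels_true=labels_true,
        backbone=backbone,
        kint=kint,
    )


def make_peptide_map(protein: SyntheticProtein, cfg: FixtureConfig) -> List[Tuple[int, int]]:
    """Generate an overlapping peptide map as (start, end) ranges.

    Peptides tile each block between configured junction boundaries,
    skipping configured gap windows entirely. Successive start positions
    advance by a random stride averaging mean_length / redundancy (drawn
    uniformly from 1 to twice that, capped at the minimum peptide length
    so coverage stays contiguous), giving diverse peptide boundaries —
    the boundary diversity, not just depth, is what makes per-residue
    rates identifiable. A final pass breaks residual exchange
    degeneracies: consecutive residues that appear in exactly the same
    set of peptides are mutually interchangeable in the uptake signal (no
    data can order their rates), so for each such run an extra peptide is
    added whose boundary falls inside the run. Peptides without
    exchanging residues are dropped. Deterministic under the config seed.
    """
    lo, hi = cfg.peptide_length_range
    mean_len = 0.5 * (lo + hi)
    if cfg.redundancy > mean_len:
        raise ValidationError(
            f"redundancy {cfg.redundancy} infeasible for peptide length range {lo}-{hi}"
        )
    mean_step = max(1, round(mean_len / cfg.redundancy))
    max_step = min(lo, 2 * mean_step - 1)
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(protein.sequence)

    boundaries = sorted(set(j for j in cfg.junctions if 1 <= j < n))
    blocks: List[Tuple[int, int]] = []
    start = 1
    for j in boundaries:
        blocks.append((start, j))
        start = j + 1
    blocks.append((start, n))

    def in_gap(a: int, b: int) -> bool:
        return any(not (b < g0 or a > g1) for g0, g1 in cfg.gaps)

    peptides: List[Tuple[int, int]] = []
    for b_start, b_end in blocks:
        block_len = b_end - b_start + 1
        if block_len < 4:
            continue
        last_start = b_end - min(lo, block_len) + 1
        s = b_start
        while s <= last_start:
            length = int(rng.integers(lo, hi + 1))
            e = min(s + length - 1, b_end)
            if e - s + 1 >= 4 and not in_gap(s, e) and exchanging_indices(protein.sequence, s, e):
                peptides.append((s, e))
            s += int(rng.integers(1, max_step + 1))
        # anchor a peptide at the block's end so coverage reaches b_end
        length = int(rng.integers(lo, hi + 1))
        s = max(b_start, b_end - length + 1)
        if b_end - s + 1 >= 4 and not in_gap(s, b_end):
            if exchanging_indices(protein.sequence, s, b_end):
                peptides.append((s, b_end))

    # break exchange degeneracies: a run of consecutive residues covered by
    # exactly the same peptides is unorderable from uptake data alone
    peptide_set = set(peptides)
    if not cfg.break_degeneracies:
        return sorted(peptide_set)
    for _ in range(4):
        added = False
        for b_start, b_end in blocks:
            groups = _signature_runs(protein.sequence, sorted(peptide_set), b_start, b_end)
            for run in groups:
                r = run[0]  # split after the run's first residue
                length = int(rng.integers(lo, hi + 1))
                cands = [
                    (max(b_start, r - length + 1), r),  # peptide ending inside the run
                    (r - 1, min(r - 1 + length - 1, b_end)),  # peptide starting just before r+1
                ]
                for s, e in cands:
                    if s < b_start or e > b_end or e - s + 1 < 4 or in_gap(s, e):
                        continue
                    if (s, e) in peptide_set or not exchanging_indices(protein.sequence, s, e):
                        continue
                    ex = set(exchanging_indices(protein.sequence, s, e))
                    if (r in ex) == (run[1] in ex):
                        continue  # does not actually separate the pair
                    peptide_set.add((s, e))
                    added = True
                    break
        if not added:
            break
    return sorted(peptide_set)


def _signature_runs(sequence: str, peptides: List[Tuple[int, int]], b_start: int, b_end: int) -> List[List[int]]:
    """Runs (length >= 2) of consecutive exchanging residues within a block
    that belong to exactly the same set of peptides."""
    membership: Dict[int, frozenset] = {}
    for i, (s, e) in enumerate(peptides):
        for r in exchanging_indices(sequence, s, e):
            if b_start <= r <= b_end:
                membership.setdefault(r, set())
                membership[r].add(i)
    runs: List[List[int]] = []
    current: List[int] = []
    for r in range(b_start, b_end + 1):
        if current and r in membership and membership.get(r) == membership.get(current[-1]) and r == current[-1] + 1:
            current.append(r)
        else:
            if len(current) >= 2:
                runs.append(current)
            current = [r] if r in membership else []
    if len(current) >= 2:
        runs.append(current)
    return runs


def coverage_fraction(peptides: List[Tuple[int, int]], n_residues: int) -> float:
    covered = set()
    for s, e in peptides:
        covered.update(range(s, e + 1))
    return len(covered) / n_residues


def make_uptake(
    protein: SyntheticProtein,
    peptides: List[Tuple[int, int]],
    times: Sequence[float] = DEFAULT_TIMES,
    cfg: Optional[FixtureConfig] = None,
) -> UptakeTable:
    """Synthesize a raw uptake table from the ground truth.

    True corrected RFUs come from the optimizer's forward model; raw
    experimental RFUs are obtained by inverting the two-point FEX/BEX
    normalization, adding Gaussian noise (sd ``cfg.noise_sd``) and
    clamping to the physically plausible range [-0.05, 1.2].
    """
    cfg = cfg or FixtureConfig()
    if any(t <= 0 for t in times):
        raise ValidationError("exposure times must be positive")
    rng = np.random.default_rng(cfg.seed + 2)
    records = []
    for s, e in peptides:
        seq = protein.sequence[s - 1 : e]
        exposures = {}
        for t in times:
            corr = forward_rfu(protein.lnp_true, protein.kint, seq, s, e, t)
            exp_val = cfg.fex + corr * (cfg.bex - cfg.fex)
            if cfg.noise_sd > 0:
                exp_val += rng.normal(0.0, cfg.noise_sd)
            exposures[float(t)] = float(min(1.2, max(-0.05, exp_val)))
        records.append(
            PeptideRecord(
                sequence=seq,
                start=s,
                end=e,
                exposures=exposures,
                rfu_fex=cfg.fex,
                rfu_bex=cfg.bex,
            )
        )
    return UptakeTable(protein_id="synthetic", records=records)


def make_gated_feature_table(n: int = 1200, seed: int = 0):
    """Feature table where the R-matrix score gates the usefulness of k_obs.

    Half the rows carry a high confidence score (0.9): there, k_obs is
    drawn from class-separated lognormals (k_obs = k_ref exp(-lnP) at a
    common reference intrinsic rate) and genuinely predicts the label.
    The other half carry a low score (0.2) and their labels are pure
    noise, so k_obs is uninformative. A model must consult r_matrix to
    know when to trust k_obs; the k_int and aa_code columns are
    independent noise throughout, so any importance they earn is
    overfitting.
    """
    from hdx2ss.gb_core import FeatureTable

    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    r_matrix = np.where(rng.random(n) < 0.5, 0.9, 0.2)
    k_int = 10.0 ** rng.uniform(0.5, 3.0, size=n)  # noise: decoupled from k_obs
    aa_code = rng.integers(0, 20, size=n).astype(float)
    k_ref = 100.0
    k_obs = np.empty(n)
    for i in range(n):
        if r_matrix[i] > 0.5:
            lnp = rng.normal(8.0 if y[i] == 0 else 5.0, 1.0)
        else:
            y[i] = rng.integers(0, 2)  # label is noise where confidence is low
            lnp = rng.normal(6.5, 2.0)
        k_obs[i] = k_ref * math.exp(-lnp)
    X = np.column_stack([k_obs, k_int, r_matrix, aa_code])
    return FeatureTable(X=X, y=y, feature_names=("k_obs", "k_int", "r_matrix", "aa_code"))
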