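"""Sequence-based intrinsic amide exchange rates.

Implements the reference-rate scheme of the Englander laboratory
(Bai et al., Proteins 1993): the intrinsic rate of an amide in an
unstructured chain is the sum of acid-, base- and water-catalyzed terms,

    k_int = k_A * F_A * [D+] + k_B * F_B * [OD-] + k_W * F_B

where k_A, k_B, k_W are poly-DL-alanine reference rate constants at the
20 degC reference temperature, and F_A, F_B are nearest-neighbor
side-chain factors: the amide of residue i is modulated by its own side
chain and by the side chain of residue i-1. Temperature is handled by
Arrhenius scaling of each catalytic term.

Units: rates in 1/min, time constants referenced to 293.15 K. pD is used
as read (no glass-electrode +0.4 correction is applied here). Ionizable
side chains (Asp, Glu, His) use their near-neutral protonation-state
factors (carboxylates deprotonated, His neutral), appropriate for the
pD 6-8 range this package targets.

The N-terminal residue has no stably measurable amide and prolines have
no amide hydrogen; both are omitted from the output table.
"""

from __future__ import annotations

import math
from typing import Dict

from hdx2ss._errors import ValidationError
from hdx2ss.hdx_io import KintTable

# poly-DL-alanine reference rate constants, D2O, 293.15 K (log10 scale):
# acid (1/(M*min)), base (1/(M*min)), water (1/min)
LOG_KA_REF = 1.62
LOG_KB_REF = 10.18
LOG_KW_REF = -1.5

#: apparent ion product of D2O at the reference temperature (log10 scale)
PKD = 15.05

#: reference temperature (K) of the rate constants above
T_REF = 293.15

#: activation energies, kcal/mol (acid-, base-, water-catalyzed exchange)
EA_ACID = 14.0
EA_BASE = 17.0
EA_WATER = 19.0

R_GAS = 1.987e-3  # kcal/(mol*K)

# Nearest-neighbor side-chain factors (log10 scale), Bai et al. conventions:
# for each residue type, (acid_own, acid_next, base_own, base_next) —
# "own" modifies the amide of the residue carrying the side chain,
# "next" modifies the amide of the following residue.
# Asp/Glu are the carboxylate forms; His the neutral form.
SIDE_CHAIN_FACTORS: Dict[str, tuple] = {
    "A": (0.00, 0.00, 0.00, 0.00),
    "R": (-0.59, -0.32, 0.08, 0.22),
    "N": (-0.58, -0.13, 0.49, 0.32),
    "D": (0.90, 0.58, 0.10, -0.18),
    "C": (-0.54, -0.46, 0.62, 0.55),
    "Q": (-0.47, -0.27, 0.06, 0.20),
    "E": (-0.90, 0.31, -0.11, -0.15),
    "G": (-0.22, 0.22, 0.27, 0.17),
    "H": (-0.10, -0.10, -0.10, 0.14),
    "I": (-0.91, -0.59, -0.73, -0.23),
    "L": (-0.57, -0.13, -0.58, -0.21),
    "K": (-0.56, -0.29, -0.04, 0.12),
    "M": (-0.64, -0.28, -0.01, 0.11),
    "F": (-0.52, -0.43, -0.24, 0.06),
    "P": (0.00, -0.19, 0.00, -0.24),
    "S": (-0.44, -0.39, 0.37, 0.30),
    "T": (-0.79, -0.47, -0.07, 0.20),
    "W": (-0.40, -0.44, -0.41, -0.11),
    "Y": (-0.41, -0.37, -0.27, 0.05),
    "V": (-0.74, -0.30, -0.70, -0.14),
}

#: extra factors for the protonated alpha-amino group on the amide of residue 2
N_TERM_FACTORS = (-1.32, 1.62)  # (acid_next, base_next)
#: extra factors contributed by the C-terminal carboxylate to the last amide
C_TERM_FACTORS = (0.96, -1.80)  # (acid_own, base_own)


def _arrhenius(ea: float, temperature: float) -> float:
    return math.exp(-ea / R_GAS * (1.0 / temperature - 1.0 / T_REF))


def compute_kint(sequence: str, temperature: float = 293.15, pd_value: float = 7.0) -> KintTable:
    """Compute per-residue intrinsic exchange rates for a sequence.

    Parameters
    ----------
    sequence : one-letter amino-acid string (length >= 2)
    temperature : labelling temperature in kelvin (273-373)
    pd_value : solution pD, used as read

    Returns
    -------
    KintTable with rates in 1/min, keyed by 1-based residue index.
    Residue 1 and all prolines are absent.
    """
    if len(sequence) < 2:
        raise ValidationError("sequence must have at least 2 residues")
    if not (273.0 <= temperature <= 373.0):
        raise ValidationError(f"temperature {temperature} K outside supported range 273-373 K")
    for pos, aa in enumerate(sequence, start=1):
        if aa not in SIDE_CHAIN_FACTORS:
            raise ValidationError(f"unknown residue letter '{aa}' at position {pos}")

    conc_d = 10.0 ** (-pd_value)
    conc_od = 10.0 ** (pd_value - PKD)
    fa_t = _arrhenius(EA_ACID, temperature)
    fb_t = _arrhenius(EA_BASE, temperature)
    fw_t = _arrhenius(EA_WATER, temperature)

    rates: Dict[int, float] = {}
    n = len(sequence)
    for i in range(2, n + 1):  # residue 1 omitted
        aa = sequence[i - 1]
        if aa == "P":
            continue
        prev = sequence[i - 2]
        acid_log = SIDE_CHAIN_FACTORS[aa][0] + SIDE_CHAIN_FACTORS[prev][1]
        base_log = SIDE_CHAIN_FACTORS[aa][2] + SIDE_CHAIN_FACTORS[prev][3]
        if i == 2:
            acid_log += N_TERM_FACTORS[0]
            base_log += N_TERM_FACTORS[1]
        if i == n:
            acid_log += C_TERM_FACTORS[0]
            base_log += C_TERM_FACTORS[1]
        k_acid = 10.0 ** (LOG_KA_REF + acid_log) * conc_d * fa_t
        k_base = 10.0 ** (LOG_KB_REF + base_log) * conc_od * fb_t
        k_water = 10.0 ** (LOG_KW_REF + base_log) * fw_t
        rates[i] = k_acid + k_base + k_water
    return KintTable(rates=rates)
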