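"""Nearest-neighbor duplex thermodynamics for amplicon melting prediction.

The duplex enthalpy and entropy are sums of the 16 dinucleotide stack
contributions plus terminal initiation terms (unified nearest-neighbor
parameter set, 1 M NaCl reference), with an entropic monovalent-salt
correction. The two-state melting temperature is

    Tm(K) = dH * 1000 / (dS_salt + R * ln(C_T / x)),   R = 1.987 cal/(mol K)

with x = 4 for non-self-complementary duplexes (x = 1, plus a symmetry
entropy penalty, when the sequence equals its own reverse complement).

Absolute agreement with instrument Tm values is explicitly not promised —
dye, buffer and ramp effects shift observed peaks — only ranks and Tm
differences are meaningful. The published HRM rules of thumb (about 6 C for
the loss of a G-C pair, about 0.6 C for a G-C to A-T substitution, about
0.15 C for an isobond swap such as A-T to T-A, instrument resolution
+/- 0.02 C) ship as documentation constants and are exercised only as
order-of-magnitude checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .primers import Amplicon, revcomp

__all__ = [
    "ThermoResult",
    "HeuristicDeltaTm",
    "HEURISTICS",
    "nn_thermo",
    "amplicon_tm",
    "NN_TABLE_ID",
]

R_GAS = 1.987  # cal / (mol K)

NN_TABLE_ID = "santalucia1998_unified"

# Stack parameters: dH kcal/mol, dS cal/(mol K), 1 M NaCl.
# Keyed by the top-strand dinucleotide; the other six dinucleotides map to
# the reverse complement of a listed key.
_NN_STACKS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_INIT_GC = (0.1, -2.8)   # per terminal G-C pair
_INIT_AT = (2.3, 4.1)    # per terminal A-T pair
_SYMMETRY_DS = -1.4      # self-complementary duplexes only


def _stack(dinuc: str) -> tuple[float, float]:
    try:
        return _NN_STACKS[dinuc]
    except KeyError:
        return _NN_STACKS[revcomp(dinuc)]


@dataclass(frozen=True)
class ThermoResult:
    """Hybridization thermodynamics of one duplex under stated conditions."""

    dH: float            # kcal/mol, negative
    dS: float            # cal/(mol K) at 1 M NaCl, negative
    tm_celsius: float
    strand_conc: float   # mol/L total strand concentration
    monovalent_salt: float  # mol/L
    nn_table_id: str = NN_TABLE_ID


@dataclass(frozen=True)
class HeuristicDeltaTm:
    """Published HRM rules of thumb; documentation values, not predictions."""

    gc_pair_loss: float = 6.0       # C, losing one G-C pair outright
    gc_to_at: float = 0.6           # C, G-C mutated to A-T
    isobond_swap: float = 0.15      # C, hydrogen-bond-count-preserving swap
    instrument_resolution: float = 0.02  # C, +/-


HEURISTICS = HeuristicDeltaTm()


def nn_thermo(
    seq: str,
    strand_conc: float = 2.5e-7,
    monovalent_salt: float = 0.05,
) -> ThermoResult:
    """Nearest-neighbor dH, dS and two-state Tm of a duplex.

    Parameters
    ----------
    seq : str
        One strand, 5'->3', ACGT only, length >= 8 (shorter oligos are
        outside the two-state regime this toolkit cares about).
    strand_conc : float
        Total single-strand concentration C_T in mol/L.
    monovalent_salt : float
        Monovalent cation concentration in mol/L; entropic correction
        0.368 * (N - 1) * ln[Na+] with N the duplex length.
    """
    s = seq.strip().upper()
    if set(s) - set("ACGT"):
        raise ValueError(f"non-ACGT characters in sequence: "
                         f"{sorted(set(s) - set('ACGT'))}")
    if len(s) < 8:
        raise ValueError(f"sequence length {len(s)} < 8")
    if strand_conc <= 0 or monovalent_salt <= 0:
        raise ValueError("strand_conc and monovalent_salt must be positive")

    dh = 0.0
    ds = 0.0
    for i in range(len(s) - 1):
        h, sv = _stack(s[i:i + 2])
        dh += h
        ds += sv
    for terminal in (s[0], s[-1]):
        h, sv = _INIT_GC if terminal in "GC" else _INIT_AT
        dh += h
        ds += sv

    selfcomp = s == revcomp(s)
    if selfcomp:
        ds += _SYMMETRY_DS

    ds_salt = ds + 0.368 * (len(s) - 1) * math.log(monovalent_salt)
    x = 1.0 if selfcomp else 4.0
    tm_k = dh * 1000.0 / (ds_salt + R_GAS * math.log(strand_conc / x))
    return ThermoResult(
        dH=dh,
        dS=ds,
        tm_celsius=tm_k - 273.15,
        strand_conc=strand_conc,
        monovalent_salt=monovalent_salt,
    )


def amplicon_tm(
    amplicon: Amplicon | str,
    strand_conc: float = 2.5e-7,
    monovalent_salt: float = 0.05,
) -> float:
    """Predicted melting temperature (C) of a full amplicon duplex.

    Only rank order and Tm differences between amplicons are contractual;
    absolute instrument agreement is not.
    """
    seq = amplicon.sequence if isinstance(amplicon, Amplicon) else amplicon
    return nn_thermo(seq, strand_conc, monovalent_salt).tm_celsius
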