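"""Nearest-neighbor melting temperatures and pair ΔTm.

Tm is computed with the unified nearest-neighbor thermodynamic model
(SantaLucia 1998 parameter set by default) and an entropy-based salt
correction, at hybridization-buffer-style conditions: 50 mM monovalent
cation, no Mg2+, 50 nM oligo.  Pairs of probe variants whose predicted Tm
differs by more than 5 °C hybridize with a bias toward the higher-Tm member
and are discarded upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import MeltingTemp as _mt

from ._seq import is_acgt

#: registered nearest-neighbor parameter sets (name -> Biopython table)
PARAMETER_SETS = {
    "santalucia1998": _mt.DNA_NN3,  # unified Allawi & SantaLucia parameters
    "santalucia2004": _mt.DNA_NN4,
    "sugimoto1996": _mt.DNA_NN2,
    "breslauer1986": _mt.DNA_NN1,
}

MIN_LEN, MAX_LEN = 15, 60


@dataclass(frozen=True)
class ThermoConditions:
    """Solution conditions and parameter set for Tm prediction."""

    monovalent_mM: float = 50.0
    divalent_mM: float = 0.0
    dntp_mM: float = 0.0
    oligo_conc_nM: float = 50.0
    parameter_set: str = "santalucia1998"

    def __post_init__(self):
        for name in ("monovalent_mM", "divalent_mM", "dntp_mM", "oligo_conc_nM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.parameter_set not in PARAMETER_SETS:
            raise ValueError(
                f"unknown parameter set {self.parameter_set!r}; "
                f"known: {sorted(PARAMETER_SETS)}"
            )


DEFAULT_CONDITIONS = ThermoConditions()


def melting_temperature(seq: str, cond: ThermoConditions = DEFAULT_CONDITIONS) -> float:
    """Nearest-neighbor Tm (°C) of a probe against its perfect complement."""
    if not MIN_LEN <= len(seq) <= MAX_LEN:
        raise ValueError(
            f"sequence length {len(seq)} outside [{MIN_LEN}, {MAX_LEN}]: {seq!r}"
        )
    if not is_acgt(seq):
        raise ValueError(f"sequence contains non-ACGT characters: {seq!r}")
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=PARAMETER_SETS[cond.parameter_set],
            dnac1=cond.oligo_conc_nM,
            dnac2=0,
            Na=cond.monovalent_mM,
            Mg=cond.divalent_mM,
            dNTPs=cond.dntp_mM,
            saltcorr=5,  # SantaLucia 1998 entropy correction
        )
    )


def delta_tm(a: str, b: str, cond: ThermoConditions = DEFAULT_CONDITIONS) -> float:
    """|Tm(a) - Tm(b)| in °C; symmetric in its arguments."""
    return abs(melting_temperature(a, cond) - melting_temperature(b, cond))


def gc_content(seq: str) -> float:
    """GC fraction of a sequence."""
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0
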