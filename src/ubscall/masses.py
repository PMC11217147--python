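"""Neutral average masses of short DNA/RNA oligos across bisulfite reaction states.

Bisulfite conversion of an unmethylated cytosine proceeds through a
uracil-bisulfite sulfonate adduct (U-BS, +H2SO3 relative to the deaminated
base) before desulphonation yields uracil.  Monitoring a short probe by
MALDI-TOF therefore shows up to three peaks per reacting C: unreacted
(C-containing), the U-BS adduct, and the final U-containing product.
5-methylcytosine resists deamination, so a 5mC/m5C probe shows only the
unreacted peak; the would-be adduct product mass is still useful to predict
(to confirm its absence).  N4-methylcytosine deaminates to uracil, losing the
N4-methyl with the exocyclic amine.

Masses are neutral average masses from IUPAC standard atomic weights; MALDI
peak labels in linear negative mode track these within 1 Da, so the charged
[M-H]- offset is ignored.  Rounding for peak comparison is round-half-up to
the nearest Da.
"""

from __future__ import annotations

import math
import re
from typing import Iterable, Mapping

__all__ = [
    "ATOMIC_MASS",
    "formula_mass",
    "oligo_mass",
    "predict_maldi_series",
    "conversion_speedup",
    "round_da",
]

#: IUPAC 2021 standard (average) atomic weights, Da.
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_mass(formula: str) -> float:
    """Average mass (Da) of a molecular formula such as ``'C9H13N3O4'``."""
    mass = 0.0
    matched = ""
    for element, count in _FORMULA_RE.findall(formula):
        if not element:
            continue
        if element not in ATOMIC_MASS:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        mass += ATOMIC_MASS[element] * int(count or 1)
        matched += element + count
    if matched != formula:
        raise ValueError(f"could not parse formula {formula!r}")
    return mass


# Free nucleoside compositions (base + sugar, no phosphate).
_DEOXYNUCLEOSIDE = {
    "A": "C10H13N5O3",
    "C": "C9H13N3O4",
    "G": "C10H13N5O4",
    "T": "C10H14N2O5",
    "U": "C9H12N2O5",  # deoxyuridine: deamination product of dC
}
_RIBONUCLEOSIDE = {
    "A": "C10H13N5O4",
    "C": "C9H13N3O5",
    "G": "C10H13N5O5",
    "U": "C9H12N2O6",
    "T": "C10H14N2O6",  # 5-methyluridine: deamination product of m5C
}

M_H2O = formula_mass("H2O")
M_HPO3 = formula_mass("HPO3")
M_H2SO3 = formula_mass("H2SO3")
M_CH2 = formula_mass("CH2")

#: mass added by a 5-methyl (5mC/m5C) or N4-methyl (4mC) group
METHYL_MASS = M_CH2

_MOD_TAGS = {"none", "5mC", "m5C", "4mC"}


def round_da(mass: float) -> int:
    """Round-half-up to the nearest integer Da (printed-peak convention)."""
    return int(math.floor(mass + 0.5))


def _nucleoside_mass(base: str, nucleic_type: str, modification: str) -> float:
    table = _DEOXYNUCLEOSIDE if nucleic_type == "DNA" else _RIBONUCLEOSIDE
    mass = formula_mass(table[base])
    if modification in ("5mC", "m5C", "4mC"):
        if base != "C":
            raise ValueError(f"{modification} tag on non-C base {base!r}")
        mass += METHYL_MASS
    return mass


def _validate_sequence(
    sequence: str,
    nucleic_type: str,
    allow_deamination_products: bool,
) -> str:
    if nucleic_type not in ("DNA", "RNA"):
        raise ValueError(f"nucleic_type must be 'DNA' or 'RNA', got {nucleic_type!r}")
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    native = set("ACGT") if nucleic_type == "DNA" else set("ACGU")
    product = "U" if nucleic_type == "DNA" else "T"
    for base in seq:
        if base in native:
            continue
        if base == product and allow_deamination_products:
            continue
        raise ValueError(
            f"invalid base {base!r} for {nucleic_type}"
            + (
                f" ({product!r} only allowed as a flagged deamination product)"
                if base == product
                else ""
            )
        )
    return seq


def oligo_mass(
    sequence: str,
    nucleic_type: str = "DNA",
    five_prime: str = "OH",
    modifications: Mapping[int, str] | None = None,
    allow_deamination_products: bool = False,
) -> float:
    """Neutral average mass (Da) of a linear oligo with 3'-OH.

    The backbone sum is Σ nucleoside masses − (n−1)·M(H2O) + (n−1)·M(HPO3);
    a 5'-phosphate adds one further HPO3 (as phosphorylation of the 5'-OH
    adds HPO3 net).  ``modifications`` maps 0-based positions to a tag in
    {'5mC', 'm5C', '4mC'}; each methyl tag adds one CH2.

    >>> round_da(oligo_mass("AGCGA", "DNA"))
    1512
    """
    seq = _validate_sequence(sequence, nucleic_type, allow_deamination_products)
    mods = dict(modifications or {})
    for pos, tag in mods.items():
        if not 0 <= pos < len(seq):
            raise ValueError(f"modification position {pos} outside sequence")
        if tag not in _MOD_TAGS:
            raise ValueError(f"unknown modification tag {tag!r}")
    if five_prime not in ("OH", "phosphate"):
        raise ValueError(f"five_prime must be 'OH' or 'phosphate', got {five_prime!r}")
    n = len(seq)
    mass = sum(
        _nucleoside_mass(base, nucleic_type, mods.get(i, "none"))
        for i, base in enumerate(seq)
    )
    mass += (n - 1) * (M_HPO3 - M_H2O)
    if five_prime == "phosphate":
        mass += M_HPO3
    return mass


def predict_maldi_series(
    sequence: str,
    nucleic_type: str = "DNA",
    position: int | None = None,
    modification: str = "none",
    five_prime: str = "OH",
) -> list[tuple[str, float]]:
    """Predict the MALDI peak series for one reacting pyrimidine position.

    ``position`` is the 0-based index of the reacting C (defaults to the
    single C in the sequence, if unique); ``modification`` is its tag.
    Returns ``(state, mass)`` pairs:

    * unmodified C — ``unreacted``, ``deaminated`` (C→U, +0.98 Da) and
      ``bisulfite_adduct`` (deaminated +H2SO3, +82.07 Da);
    * 5mC/m5C — ``unreacted`` plus the hypothetical deaminated and adduct
      products (observed to be absent: 5mC resists deamination);
    * 4mC — ``unreacted``, ``deaminated`` (4mC→U, −13.04 Da: the N4-methyl
      leaves with the amine) and ``bisulfite_adduct``.
    """
    seq = _validate_sequence(sequence, nucleic_type, allow_deamination_products=False)
    if position is None:
        c_positions = [i for i, b in enumerate(seq) if b == "C"]
        if len(c_positions) != 1:
            raise ValueError(
                "position must be given when the sequence does not contain "
                "exactly one C"
            )
        position = c_positions[0]
    if not 0 <= position < len(seq):
        raise ValueError(f"position {position} outside sequence")
    if seq[position] != "C":
        raise ValueError(f"designated position {position} is not a C/5mC/4mC")
    if modification not in _MOD_TAGS:
        raise ValueError(f"unknown modification tag {modification!r}")

    mods = {position: modification} if modification != "none" else {}
    unreacted = oligo_mass(seq, nucleic_type, five_prime, mods)

    product_base = "U" if nucleic_type == "DNA" else "U"
    if modification in ("5mC", "m5C"):
        # 5mC would deaminate to 5-methyl-U (thymidine / 5-methyluridine)
        product_base = "T"
    deaminated = unreacted + (
        _nucleoside_mass(product_base, nucleic_type, "none")
        - _nucleoside_mass("C", nucleic_type, modification)
    )
    adduct = deaminated + M_H2SO3

    if modification in ("5mC", "m5C"):
        return [
            ("unreacted", unreacted),
            ("deaminated_hypothetical", deaminated),
            ("bisulfite_adduct_hypothetical", adduct),
        ]
    return [
        ("unreacted", unreacted),
        ("deaminated", deaminated),
        ("bisulfite_adduct", adduct),
    ]


def conversion_speedup(
    minutes_conventional: float = 40.0, minutes_ultrafast: float = 3.0
) -> float:
    """Fold-acceleration of complete probe conversion (conventional / ultrafast).

    With the printed completion times — 40 min for a conventional bisulfite
    reaction and 3 min under ultrafast conditions — this rounds to ~13-fold.
    """
    if minutes_conventional <= 0 or minutes_ultrafast <= 0:
        raise ValueError("reaction times must be positive")
    return minutes_conventional / minutes_ultrafast
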