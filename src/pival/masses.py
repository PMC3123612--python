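"""Monoisotopic mass constants and fragment-ion m/z arithmetic.

All masses are monoisotopic (Da). Residue masses come from the standard
amino-acid table; I and L are distinct letters sharing one mass. Cysteine is
unmodified by default; a fixed carbamidomethyl (+57.02146 Da) can be enabled
where peptides were alkylated.
"""

from __future__ import annotations

import numpy as np
from pyteomics import mass as _pmass

PROTON = 1.00727646688
WATER = 18.0105646863
AMMONIA = 17.02654910101
CO = 27.99491461957
ISOTOPE_SPACING = 1.00335483507
CARBAMIDOMETHYL = 57.02146372057

#: The 20 standard residues, in the fixed order used for every parameter array.
AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
AA_TO_INDEX = {a: i for i, a in enumerate(AA_LETTERS)}
RESIDUE_MASS = {a: _pmass.std_aa_mass[a] for a in AA_LETTERS}

_MASS_ARRAY = np.array([RESIDUE_MASS[a] for a in AA_LETTERS])

ION_TYPES = ("b", "y", "a")


def validate_peptide(peptide: str) -> None:
    """Raise ValueError unless *peptide* uses only the 20 standard letters."""
    if not peptide:
        raise ValueError("empty peptide sequence")
    bad = set(peptide) - set(AA_LETTERS)
    if bad:
        raise ValueError(f"unknown residue(s) {sorted(bad)} in peptide {peptide!r}")


def residue_indices(peptide: str) -> np.ndarray:
    """Map a peptide to integer residue indices into :data:`AA_LETTERS`."""
    validate_peptide(peptide)
    return np.array([AA_TO_INDEX[a] for a in peptide], dtype=np.intp)


def residue_masses(peptide: str, fixed_cys_mod: bool = False) -> np.ndarray:
    validate_peptide(peptide)
    m = _MASS_ARRAY[residue_indices(peptide)]
    if fixed_cys_mod:
        m = m + (np.frombuffer(peptide.encode(), dtype=np.uint8) == ord("C")) * CARBAMIDOMETHYL
    return m


def peptide_mh(peptide: str, fixed_cys_mod: bool = False) -> float:
    """Singly-protonated peptide mass M+H (Da)."""
    return float(residue_masses(peptide, fixed_cys_mod).sum() + WATER + PROTON)


def fragment_mz(
    peptide: str,
    ion_type: str,
    index: int,
    charge: int = 1,
    fixed_cys_mod: bool = False,
) -> float:
    """m/z of a backbone fragment ion.

    ``b``/``a`` ions take the first *index* residues (N-terminal series);
    ``y`` ions take the last *index* residues and keep the C-terminal water.
    ``a = b − CO``. *index* runs from 1 to L−1.
    """
    if ion_type not in ION_TYPES:
        raise ValueError(f"unsupported ion type {ion_type!r}; expected one of {ION_TYPES}")
    masses = residue_masses(peptide, fixed_cys_mod)
    L = len(masses)
    if not 1 <= index <= L - 1:
        raise ValueError(f"fragment index {index} out of range [1, {L - 1}] for length {L}")
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    if ion_type == "y":
        neutral = masses[L - index:].sum() + WATER
    else:
        neutral = masses[:index].sum()
        if ion_type == "a":
            neutral -= CO
    return float((neutral + charge * PROTON) / charge)
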