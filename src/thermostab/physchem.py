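"""Global physicochemical descriptor block (28 features).

A fixed, versioned inventory of whole-sequence physicochemical parameters:
size and mass, charge, atomic composition, stability/hydropathy indices,
extinction coefficients and N-end-rule half-lives. Molecular weight,
theoretical pI, instability index and GRAVY are delegated to Biopython's
ProtParam implementation (average isotopic masses, Bjellqvist pKa set,
Guruprasad DIWV weights, Kyte–Doolittle scale respectively).
"""

from __future__ import annotations

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .tables import (
    ATOMIC_COMPOSITION,
    EXTINCTION_CYSTINE,
    EXTINCTION_TRP,
    EXTINCTION_TYR,
    HALF_LIFE_HOURS,
    WATER_MASS,
)

#: Fixed feature order of the block. 28 features.
PHYSCHEM_NAMES: tuple[str, ...] = (
    "length",
    "molecular_weight",
    "mean_residue_weight",
    "pI",
    "net_charge_pH7",
    "charge_density",
    "n_negative",
    "n_positive",
    "frac_negative",
    "frac_positive",
    "atoms_C",
    "atoms_H",
    "atoms_N",
    "atoms_O",
    "atoms_S",
    "atoms_total",
    "instability_index",
    "aliphatic_index",
    "gravy",
    "frac_aromatic",
    "frac_tiny",
    "half_life_mammal_h",
    "half_life_yeast_h",
    "half_life_ecoli_h",
    "ext_coeff_cystines",
    "ext_coeff_reduced",
    "abs_0.1pct_cystines",
    "abs_0.1pct_reduced",
)


def physchem_block(seq: str) -> np.ndarray:
    """Compute the 28-feature physicochemical block for a validated sequence.

    Units: masses in Da, half-lives in hours, extinction coefficients in
    M^-1 cm^-1, absorbance 0.1% as extinction / molecular weight; fractions
    are mole fractions, the aliphatic index uses mole percent.
    """
    if not seq:
        raise ValueError("empty sequence")
    length = len(seq)
    pa = ProteinAnalysis(seq)

    mw = pa.molecular_weight()
    pi = pa.isoelectric_point()
    charge7 = pa.charge_at_pH(7.0)
    instability = pa.instability_index() if length >= 2 else 0.0
    gravy = pa.gravy()

    counts = {a: seq.count(a) for a in set(seq)}

    def n_of(letters: str) -> int:
        return sum(counts.get(a, 0) for a in letters)

    n_neg = n_of("DE")
    n_pos = n_of("RK")

    atoms = np.zeros(5)
    for a, c in counts.items():
        atoms += c * np.array(ATOMIC_COMPOSITION[a])
    atoms += np.array([0, 2, 0, 1, 0])  # one water per chain

    # Ikai aliphatic index, mole percent
    aliphatic = 100.0 * (
        counts.get("A", 0) / length
        + 2.9 * counts.get("V", 0) / length
        + 3.9 * (counts.get("I", 0) + counts.get("L", 0)) / length
    )

    n_w, n_y, n_c = counts.get("W", 0), counts.get("Y", 0), counts.get("C", 0)
    ext_reduced = n_w * EXTINCTION_TRP + n_y * EXTINCTION_TYR
    ext_cystines = ext_reduced + (n_c // 2) * EXTINCTION_CYSTINE

    half_life = HALF_LIFE_HOURS[seq[0]]

    return np.array(
        [
            float(length),
            mw,
            (mw - WATER_MASS) / length,
            pi,
            charge7,
            charge7 / length,
            float(n_neg),
            float(n_pos),
            n_neg / length,
            n_pos / length,
            *atoms,
            atoms.sum(),
            instability,
            aliphatic,
            gravy,
            n_of("FWY") / length,
            n_of("ACGST") / length,
            *half_life,
            ext_cystines,
            ext_reduced,
            ext_cystines / mw,
            ext_reduced / mw,
        ]
    )
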