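"""Simple empirical chemical-shift forward model.

Predicted shift = random-coil value + a fixed secondary-structure offset,
with the residue classed as strand or coil from its backbone phi/psi.  This
is the back-calculation used for the ensemble-selection pseudo-energy; the
synthetic-data generator uses the same forward model, so the selection term
is exercised end-to-end without an external shift predictor.  A different
predictor (e.g. wrapping an external program) can be plugged into
``select_ensemble`` as any callable with the same signature.
"""

from __future__ import annotations

import numpy as np

from . import geom

#: random-coil shifts (ppm) per residue type: N, HN, CA, HA, C
RANDOM_COIL = {
    "A": {"N": 123.8, "HN": 8.24, "CA": 52.5, "HA": 4.32, "C": 177.8},
    "C": {"N": 118.8, "HN": 8.32, "CA": 58.2, "HA": 4.55, "C": 174.6},
    "D": {"N": 120.4, "HN": 8.34, "CA": 54.2, "HA": 4.64, "C": 176.3},
    "E": {"N": 120.2, "HN": 8.42, "CA": 56.6, "HA": 4.35, "C": 176.6},
    "F": {"N": 120.3, "HN": 8.30, "CA": 57.7, "HA": 4.62, "C": 175.8},
    "G": {"N": 108.8, "HN": 8.33, "CA": 45.1, "HA": 3.96, "C": 174.9},
    "H": {"N": 118.2, "HN": 8.42, "CA": 55.0, "HA": 4.73, "C": 174.1},
    "I": {"N": 119.9, "HN": 8.00, "CA": 61.1, "HA": 4.17, "C": 176.4},
    "K": {"N": 120.4, "HN": 8.29, "CA": 56.2, "HA": 4.32, "C": 176.6},
    "L": {"N": 121.8, "HN": 8.16, "CA": 55.1, "HA": 4.34, "C": 177.6},
    "M": {"N": 119.6, "HN": 8.28, "CA": 55.4, "HA": 4.48, "C": 176.3},
    "N": {"N": 118.7, "HN": 8.40, "CA": 53.1, "HA": 4.74, "C": 175.2},
    "P": {"N": 135.8, "HN": 8.30, "CA": 63.3, "HA": 4.42, "C": 177.3},
    "Q": {"N": 119.8, "HN": 8.32, "CA": 55.7, "HA": 4.34, "C": 176.0},
    "R": {"N": 120.5, "HN": 8.23, "CA": 56.0, "HA": 4.34, "C": 176.3},
    "S": {"N": 115.7, "HN": 8.31, "CA": 58.3, "HA": 4.47, "C": 174.6},
    "T": {"N": 113.6, "HN": 8.15, "CA": 61.8, "HA": 4.35, "C": 174.7},
    "V": {"N": 119.2, "HN": 8.03, "CA": 62.2, "HA": 4.12, "C": 176.3},
    "W": {"N": 121.3, "HN": 8.25, "CA": 57.5, "HA": 4.66, "C": 176.1},
    "Y": {"N": 120.3, "HN": 8.12, "CA": 57.9, "HA": 4.55, "C": 175.9},
}

#: random-coil shifts of the side-chain beta protons (pseudo-atom QB), ppm
RANDOM_COIL_QB = {
    "A": 1.39, "C": 2.95, "D": 2.72, "E": 2.03, "F": 3.10, "H": 3.15,
    "I": 1.80, "K": 1.77, "L": 1.62, "M": 2.05, "N": 2.80, "P": 2.05,
    "Q": 2.05, "R": 1.80, "S": 3.88, "T": 4.22, "V": 2.10, "W": 3.25,
    "Y": 2.95,
}

#: signed secondary-structure offsets (ppm) applied on top of the coil value
STRAND_OFFSETS = {"N": 2.0, "HN": 0.3, "CA": -1.4, "HA": 0.4, "C": -1.2, "QB": 0.1}
COIL_OFFSETS = {"N": 0.0, "HN": 0.0, "CA": 0.0, "HA": 0.0, "C": 0.0, "QB": 0.0}

SHIFT_ATOMS = ("N", "HN", "CA", "HA", "C", "QB")


def classify_secondary(phi_deg: float | None, psi_deg: float | None) -> str:
    """'strand' if phi/psi fall in the broad beta region, else 'coil'."""
    if phi_deg is None or psi_deg is None:
        return "coil"
    if -180.0 <= phi_deg <= -45.0 and (psi_deg >= 90.0 or psi_deg <= -150.0):
        return "strand"
    return "coil"


def backbone_dihedrals(topology, coords: np.ndarray) -> dict[int, tuple[float | None, float | None]]:
    """phi/psi per residue (degrees); None where a flanking atom is missing."""
    out: dict[int, tuple[float | None, float | None]] = {}
    for res in topology.residue_indices:
        phi = psi = None
        try:
            quad = [topology.atom_index(res - 1, "C"), topology.atom_index(res, "N"),
                    topology.atom_index(res, "CA"), topology.atom_index(res, "C")]
            phi = float(np.degrees(geom.torsions(
                coords, *[np.array([q]) for q in quad])[0]))
        except KeyError:
            pass
        try:
            quad = [topology.atom_index(res, "N"), topology.atom_index(res, "CA"),
                    topology.atom_index(res, "C"), topology.atom_index(res + 1, "N")]
            psi = float(np.degrees(geom.torsions(
                coords, *[np.array([q]) for q in quad])[0]))
        except KeyError:
            pass
        out[res] = (phi, psi)
    return out


def predict_shifts(topology, coords: np.ndarray) -> dict[tuple[int, str], float]:
    """Forward model: coil + strand/coil offset per (residue, atom)."""
    dihedrals = backbone_dihedrals(topology, coords)
    out: dict[tuple[int, str], float] = {}
    for res in topology.residue_indices:
        rtype = topology.residue_type(res)
        coil = RANDOM_COIL.get(rtype)
        if coil is None:
            continue
        ss = classify_secondary(*dihedrals[res])
        offsets = STRAND_OFFSETS if ss == "strand" else COIL_OFFSETS
        for atom in SHIFT_ATOMS:
            if not topology.has_atom(res, atom):
                continue
            base = RANDOM_COIL_QB.get(rtype) if atom == "QB" else coil[atom]
            if base is None:
                continue
            out[(res, atom)] = base + offsets[atom]
    return out
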