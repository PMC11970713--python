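"""Desk-scale restrained conformer generation.

A reduced all-atom representation (backbone N, HN, CA, HA, C', O plus the
side-chain atoms any restraint references, plus pseudo-protons) is refined
against ideal covalent geometry plus the restraint energies.  The protocol
is deterministic under a seed:

1. a torsion-space fold search — the chain is built with exact internal
   geometry from backbone and side-chain torsions, restrained torsions
   start at their dihedral targets, and the unrestrained torsions are
   folded against the distance restraints under a soft-core repulsion
   ramp, from several random starts;
2. a Cartesian relaxation (soft covalent terms first, then full weights)
   and a final quench whose per-iteration energies are recorded (the trace
   is monotone nonincreasing).

This stands in for a full torsion-dynamics engine; it is adequate for
restraint-driven folding of toys up to ~40 residues.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from . import chemshift, geom
from .io import AtomRecord, infer_nucleus
from .restraints import METAL, NcsCoupling, RestraintSet

log = logging.getLogger(__name__)

DEG = math.pi / 180.0

# ideal covalent geometry (lengths in Å, angles in degrees)
BOND_LENGTHS = {
    ("N", "HN"): 0.98, ("N", "CA"): 1.458, ("CA", "HA"): 1.09,
    ("CA", "C"): 1.525, ("C", "O"): 1.231, ("C", "N+"): 1.329,
    ("CA", "CB"): 1.53, ("CB", "SG"): 1.81, ("CB", "QB"): 1.00,
    ("CB", "CG"): 1.52, ("CG", "SD"): 1.81, ("SD", "CE"): 1.79,
    ("CE", "QE"): 1.00,
}
BOND_ANGLES = {
    ("C-", "N", "CA"): 121.7, ("C-", "N", "HN"): 119.5, ("HN", "N", "CA"): 118.8,
    ("N", "CA", "C"): 111.2, ("N", "CA", "HA"): 108.5, ("C", "CA", "HA"): 108.5,
    ("N", "CA", "CB"): 110.5, ("C", "CA", "CB"): 110.1,
    ("CA", "C", "O"): 120.8, ("CA", "C", "N+"): 116.2, ("O", "C", "N+"): 123.0,
    ("CA", "CB", "SG"): 114.0, ("CA", "CB", "QB"): 110.0,
    ("CA", "CB", "CG"): 114.0, ("CB", "CG", "SD"): 112.7, ("CG", "SD", "CE"): 100.2,
}

#: side-chain connectivity per residue type: atom -> parent
SIDECHAIN_PARENTS = {
    "C": {"CB": "CA", "SG": "CB", "QB": "CB"},
    "M": {"CB": "CA", "CG": "CB", "SD": "CG", "CE": "SD", "QE": "CE"},
}
_GENERIC_SIDECHAIN = {"CB": "CA", "QB": "CB"}

PSEUDO_ATOMS = {"QB", "QE"}
#: upper-bound pad for restraints that involve a pseudo-proton (Å)
PSEUDO_CORRECTION = 1.0


def _element_of(atom: str) -> str:
    if atom == "AG":
        return "AG"
    if atom.startswith("Q"):
        return "H"
    return atom[0]


@dataclass(frozen=True)
class AtomSpec:
    residue_index: int
    residue_type: str
    atom_name: str
    element: str


class Topology:
    """Atom list with ideal internal geometry terms; deterministic ordering."""

    def __init__(self, sequence: dict[int, str], atoms: list[AtomSpec],
                 bonds, angle_terms, planar_quads, chirality_terms, has_metal: bool):
        self.sequence = dict(sequence)
        self.atoms = atoms
        self.bonds = bonds                    # (i, j, r0)
        self.angle_terms = angle_terms        # (i, j, k, theta0_rad)
        self.planar_quads = planar_quads      # (a, b, c, d, trans)
        self.chirality_terms = chirality_terms  # (center, p1, p2, p3, v0)
        self.has_metal = has_metal
        self._index = {(a.residue_index, a.atom_name): i for i, a in enumerate(self.atoms)}

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residue_indices(self) -> list[int]:
        return sorted(self.sequence)

    def residue_type(self, residue_index: int) -> str:
        return self.sequence[residue_index]

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        return self._index[(residue_index, atom_name)]

    def has_atom(self, residue_index: int, atom_name: str) -> bool:
        return (residue_index, atom_name) in self._index

    def backbone_indices(self, residues=None, atom_names=("N", "CA", "C")) -> np.ndarray:
        residues = self.residue_indices if residues is None else residues
        idx = [
            self._index[(r, a)]
            for r in residues for a in atom_names
            if (r, a) in self._index
        ]
        return np.asarray(idx, dtype=int)

    def atom_records(self) -> list[AtomRecord]:
        return [
            AtomRecord(a.residue_index, a.residue_type, a.atom_name, a.element,
                       hetatm=(a.atom_name == "AG"))
            for a in self.atoms
        ]

    def protons(self) -> list[tuple[int, str]]:
        return [
            (a.residue_index, a.atom_name) for a in self.atoms
            if a.element == "H"
        ]


def _triple_volume(l1, l2, l3, a12, a13, a23) -> float:
    """|u||v||w| sqrt(det Gram) for three bond vectors with given lengths/angles."""
    c12, c13, c23 = (math.cos(a * DEG) for a in (a12, a13, a23))
    det = (1 - c23 * c23) - c12 * (c12 - c13 * c23) + c13 * (c12 * c23 - c13)
    return l1 * l2 * l3 * math.sqrt(max(det, 0.0))


def build_topology(
    sequence: str,
    restraint_atoms=(),
    start_residue: int = 1,
    with_metal: bool = False,
) -> Topology:
    """Reduced topology: backbone + referenced side-chain atoms (+ metal).

    ``sequence`` is one-letter; residues are numbered ``start_residue``
    onward.  ``restraint_atoms`` is any iterable of (residue_index,
    atom_name) that must resolve — side-chain atoms are instantiated only on
    demand (their connectivity parents are pulled in automatically).
    Referencing an atom a residue type does not have raises.
    """
    seq = {start_residue + i: aa.upper() for i, aa in enumerate(sequence)}
    wanted: dict[int, set[str]] = {r: set() for r in seq}
    for res, atom in restraint_atoms:
        if (res, atom) == METAL:
            with_metal = True
            continue
        if res not in seq:
            raise ValueError(f"restraint references residue {res} outside the sequence")
        backbone = {"N", "HN", "CA", "HA", "C", "O"}
        if atom in backbone:
            continue
        side = SIDECHAIN_PARENTS.get(seq[res], _GENERIC_SIDECHAIN)
        if atom not in side:
            raise ValueError(
                f"residue {res} ({seq[res]}) has no atom {atom!r} in the reduced topology"
            )
        # pull in the connectivity chain up to CA
        a = atom
        while a in side:
            wanted[res].add(a)
            a = side[a]

    atoms: list[AtomSpec] = []
    for res in sorted(seq):
        rtype = seq[res]
        names = ["N"]
        if rtype != "P":
            names.append("HN")
        names += ["CA", "HA", "C", "O"]
        side = SIDECHAIN_PARENTS.get(rtype, _GENERIC_SIDECHAIN)
        names += [a for a in ("CB", "CG", "SG", "SD", "CE", "QB", "QE")
                  if a in wanted[res] and a in side]
        for a in names:
            atoms.append(AtomSpec(res, rtype, a, _element_of(a)))
    if with_metal:
        atoms.append(AtomSpec(0, "AG", "AG", "AG"))

    index = {(a.residue_index, a.atom_name): i for i, a in enumerate(atoms)}
    bonds: list[tuple[int, int, float]] = []
    angle_terms: list[tuple[int, int, int, float]] = []
    planar: list[tuple[int, int, int, int, bool]] = []
    chirality: list[tuple[int, int, int, int, float]] = []

    def idx(res, atom):
        return index.get((res, atom))

    def add_bond(i, j, key):
        bonds.append((i, j, BOND_LENGTHS[key]))

    def add_angle(i, j, k, key):
        angle_terms.append((i, j, k, BOND_ANGLES[key] * DEG))

    residues = sorted(seq)
    for res in residues:
        n, hn, ca, ha, c, o = (idx(res, a) for a in ("N", "HN", "CA", "HA", "C", "O"))
        add_bond(n, ca, ("N", "CA"))
        add_bond(ca, ha, ("CA", "HA"))
        add_bond(ca, c, ("CA", "C"))
        add_bond(c, o, ("C", "O"))
        if hn is not None:
            add_bond(n, hn, ("N", "HN"))
            add_angle(hn, n, ca, ("HN", "N", "CA"))
        add_angle(n, ca, c, ("N", "CA", "C"))
        add_angle(n, ca, ha, ("N", "CA", "HA"))
        add_angle(c, ca, ha, ("C", "CA", "HA"))
        add_angle(ca, c, o, ("CA", "C", "O"))
        # L-center chirality: signed volume of (N, C, HA) around CA
        v0 = _triple_volume(
            BOND_LENGTHS[("N", "CA")], BOND_LENGTHS[("CA", "C")], BOND_LENGTHS[("CA", "HA")],
            BOND_ANGLES[("N", "CA", "C")], BOND_ANGLES[("N", "CA", "HA")],
            BOND_ANGLES[("C", "CA", "HA")],
        )
        chirality.append((ca, n, c, ha, -v0))

        side = SIDECHAIN_PARENTS.get(seq[res], _GENERIC_SIDECHAIN)
        cb = idx(res, "CB")
        if cb is not None:
            add_bond(ca, cb, ("CA", "CB"))
            add_angle(n, ca, cb, ("N", "CA", "CB"))
            add_angle(c, ca, cb, ("C", "CA", "CB"))
            v0b = _triple_volume(
                BOND_LENGTHS[("N", "CA")], BOND_LENGTHS[("CA", "C")], BOND_LENGTHS[("CA", "CB")],
                BOND_ANGLES[("N", "CA", "C")], BOND_ANGLES[("N", "CA", "CB")],
                BOND_ANGLES[("C", "CA", "CB")],
            )
            chirality.append((ca, n, c, cb, v0b))
        for a, parent in side.items():
            ia, ip = idx(res, a), idx(res, parent)
            if ia is None or ip is None or a == "CB":
                continue
            add_bond(ip, ia, (parent, a))
            grand = "CA" if parent == "CB" else side.get(parent)
            ig = idx(res, grand) if grand else None
            if ig is not None and (grand, parent, a) in BOND_ANGLES:
                add_angle(ig, ip, ia, (grand, parent, a))

        nxt = res + 1
        if nxt in seq:
            n1, ca1, hn1 = idx(nxt, "N"), idx(nxt, "CA"), idx(nxt, "HN")
            add_bond(c, n1, ("C", "N+"))
            add_angle(ca, c, n1, ("CA", "C", "N+"))
            add_angle(o, c, n1, ("O", "C", "N+"))
            add_angle(c, n1, ca1, ("C-", "N", "CA"))
            if hn1 is not None:
                add_angle(c, n1, hn1, ("C-", "N", "HN"))
                planar.append((c, ca1, n1, hn1, True))
            planar.append((ca, c, n1, ca1, True))   # omega trans
            planar.append((ca, n1, c, o, True))     # carbonyl plane

    return Topology(seq, atoms, bonds, angle_terms, planar, chirality, with_metal)


# ---------------------------------------------------------------------------
# energy model
# ---------------------------------------------------------------------------

@dataclass
class EnergyWeights:
    bond: float = 300.0
    angle: float = 40.0          # per rad^2
    planarity: float = 15.0
    chirality: float = 30.0
    repulsion: float = 8.0
    noe: float = 15.0
    hbond: float = 15.0
    dihedral: float = 8.0        # per rad^2
    metal_bond: float = 60.0
    metal_angle: float = 25.0
    ncs: float = 3.0
    tether: float = 2.0


_REP_RMIN = {("H", "H"): 1.6, ("H", "X"): 1.6, ("X", "X"): 2.35,
             ("AG", "H"): 1.6, ("AG", "X"): 2.0, ("AG", "AG"): 2.0}


def _rep_class(el: str) -> str:
    return el if el in ("H", "AG") else "X"


class EnergyModel:
    """Total energy and gradient for a topology plus restraint set."""

    def __init__(self, topology: Topology, restraints: RestraintSet,
                 weights: EnergyWeights | None = None,
                 tethers=None):
        self.top = topology
        self.rs = restraints
        self.w = weights or EnergyWeights()
        n = topology.n_atoms

        b = topology.bonds
        self.b_i = np.array([t[0] for t in b], dtype=int)
        self.b_j = np.array([t[1] for t in b], dtype=int)
        self.b_r0 = np.array([t[2] for t in b])

        a = topology.angle_terms
        self.a_i = np.array([t[0] for t in a], dtype=int)
        self.a_j = np.array([t[1] for t in a], dtype=int)
        self.a_k = np.array([t[2] for t in a], dtype=int)
        self.a_t0 = np.array([t[3] for t in a])

        p = topology.planar_quads
        self.p_quads = {
            trans: tuple(
                np.array([q[c] for q in p if q[4] == trans], dtype=int)
                for c in range(4)
            )
            for trans in (True, False)
        }

        ch = topology.chirality_terms
        self.c_center = np.array([t[0] for t in ch], dtype=int)
        self.c_p1 = np.array([t[1] for t in ch], dtype=int)
        self.c_p2 = np.array([t[2] for t in ch], dtype=int)
        self.c_p3 = np.array([t[3] for t in ch], dtype=int)
        self.c_v0 = np.array([t[4] for t in ch])

        self._build_repulsion()
        self._build_distance_terms()
        self._build_angle_restraints()
        self._build_dihedral_terms()

        self.tether_idx = None
        if tethers:
            self.tether_idx = np.array([t[0] for t in tethers], dtype=int)
            self.tether_xyz = np.array([t[1] for t in tethers], dtype=float)
            self.tether_k = np.array([t[2] for t in tethers], dtype=float)

        # external (coupled-refinement) tether, set by anneal_coupled
        self.ncs_idx: np.ndarray | None = None
        self.ncs_target: np.ndarray | None = None

        self.components: dict[str, float] = {}
        self._n = n

    def _build_repulsion(self):
        n = self.top.n_atoms
        excl = {(t[0], t[1]) for t in self.top.bonds}
        excl |= {(t[1], t[0]) for t in self.top.bonds}
        neigh: dict[int, set[int]] = {i: set() for i in range(n)}
        for i, j, _ in self.top.bonds:
            neigh[i].add(j)
            neigh[j].add(i)
        for i in range(n):
            for j in neigh[i]:
                for k in neigh[j]:
                    if k != i:
                        excl.add((i, k))
                        excl.add((k, i))
        els = [_rep_class(a.element) for a in self.top.atoms]
        ii, jj, rr = [], [], []
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in excl:
                    continue
                key = tuple(sorted((els[i], els[j])))
                rmin = _REP_RMIN.get(key) or _REP_RMIN.get((key[1], key[0])) or 1.6
                ii.append(i)
                jj.append(j)
                rr.append(rmin)
        self.rep_i = np.array(ii, dtype=int)
        self.rep_j = np.array(jj, dtype=int)
        self.rep_rmin = np.array(rr)

    def _resolve(self, ref) -> int:
        res, atom = ref
        try:
            return self.top.atom_index(res, atom)
        except KeyError:
            raise KeyError(f"restraint atom {atom} of residue {res} absent from topology")

    def _build_distance_terms(self):
        # flattened member pairs grouped per restraint, bucketed by energy group
        groups = {"noe": [], "hbond": [], "metal": [], "ncs": []}
        for r in self.rs.distances:
            grp = {"noe": "noe", "hbond": "hbond", "metal_implicit": "metal",
                   "metal_bond": "metal", "ncs": "ncs"}[r.kind]
            groups[grp].append(r)
        self.dist_groups = {}
        for grp, rlist in groups.items():
            if not rlist:
                continue
            mi, mj, rid, mw = [], [], [], []
            lower, upper, wt = [], [], []
            for k, r in enumerate(rlist):
                weights = r.member_weights or [1.0] * len(r.member_pairs)
                for (pa, pb), w in zip(r.member_pairs, weights):
                    mi.append(self._resolve(pa))
                    mj.append(self._resolve(pb))
                    rid.append(k)
                    mw.append(w)
                lower.append(r.lower)
                upper.append(r.upper)
                wt.append(r.weight)
            self.dist_groups[grp] = (
                np.array(mi, dtype=int), np.array(mj, dtype=int),
                np.array(rid, dtype=int), np.array(lower), np.array(upper),
                np.array(wt), len(rlist), np.array(mw),
            )

    def _build_angle_restraints(self):
        rlist = self.rs.angles
        self.ar_i = np.array([self._resolve(r.atoms[0]) for r in rlist], dtype=int)
        self.ar_j = np.array([self._resolve(r.atoms[1]) for r in rlist], dtype=int)
        self.ar_k = np.array([self._resolve(r.atoms[2]) for r in rlist], dtype=int)
        self.ar_t0 = np.array([r.target * DEG for r in rlist])
        self.ar_w = np.array([r.weight for r in rlist])

    def _build_dihedral_terms(self):
        quads, targets, halfwidths = [], [], []
        for r in self.rs.dihedrals:
            res = r.residue_index
            try:
                if r.angle_name == "phi":
                    q = (self.top.atom_index(res - 1, "C"), self.top.atom_index(res, "N"),
                         self.top.atom_index(res, "CA"), self.top.atom_index(res, "C"))
                else:
                    q = (self.top.atom_index(res, "N"), self.top.atom_index(res, "CA"),
                         self.top.atom_index(res, "C"), self.top.atom_index(res + 1, "N"))
            except KeyError:
                log.info("dihedral restraint %s@%d skipped: flanking atom missing",
                         r.angle_name, res)
                continue
            quads.append(q)
            targets.append(r.target * DEG)
            halfwidths.append(r.halfwidth * DEG)
        self.dh_a = np.array([q[0] for q in quads], dtype=int)
        self.dh_b = np.array([q[1] for q in quads], dtype=int)
        self.dh_c = np.array([q[2] for q in quads], dtype=int)
        self.dh_d = np.array([q[3] for q in quads], dtype=int)
        self.dh_t0 = np.array(targets)
        self.dh_hw = np.array(halfwidths)

    # -- evaluation ---------------------------------------------------------

    def _distance_group_energy(self, x, grad, grp, kf) -> float:
        mi, mj, rid, lower, upper, wt, n_r, mw = self.dist_groups[grp]
        d = x[mi] - x[mj]
        r = np.maximum(np.sqrt(np.sum(d * d, axis=1)), 1e-8)
        rsix = mw * r ** -6.0
        s = np.bincount(rid, weights=rsix, minlength=n_r)
        reff = s ** (-1.0 / 6.0)
        over = np.maximum(reff - upper, 0.0)
        under = np.maximum(lower - reff, 0.0)
        dev = over - under
        e = float(kf * np.sum(wt * dev * dev))
        dedreff = 2.0 * kf * wt * dev
        if np.any(dedreff != 0.0):
            coef = dedreff[rid] * (reff[rid] ** 7.0) * mw * (r ** -7.0)
            g = (coef / r)[:, None] * d
            geom._scatter(grad, mi, g)
            geom._scatter(grad, mj, -g)
        return e

    def __call__(self, xflat: np.ndarray):
        x = xflat.reshape(-1, 3)
        grad = np.zeros_like(x)
        w = self.w
        comp: dict[str, float] = {}

        e_geo = geom.harmonic_pair_energy(
            x, self.b_i, self.b_j, self.b_r0, w.bond, grad)
        e_geo += geom.harmonic_angle_energy(
            x, self.a_i, self.a_j, self.a_k, self.a_t0, w.angle, grad)
        for trans, (qa, qb, qc, qd) in self.p_quads.items():
            if qa.size:
                e_geo += geom.torsion_cos_energy(x, qa, qb, qc, qd, w.planarity,
                                                 grad, trans=trans)
        if self.c_center.size:
            e_geo += geom.chirality_energy(
                x, self.c_center, self.c_p1, self.c_p2, self.c_p3, self.c_v0,
                w.chirality, grad)
        if self.rep_i.size:
            e_geo += geom.repulsion_energy(
                x, self.rep_i, self.rep_j, self.rep_rmin, w.repulsion, grad)
        if self.tether_idx is not None:
            d = x[self.tether_idx] - self.tether_xyz
            e_geo += float(np.sum(self.tether_k * np.sum(d * d, axis=1)) * w.tether)
            grad[self.tether_idx] += 2.0 * w.tether * self.tether_k[:, None] * d
        comp["geometry"] = e_geo

        comp["noe"] = (self._distance_group_energy(x, grad, "noe", w.noe)
                       if "noe" in self.dist_groups else 0.0)
        comp["hbond"] = (self._distance_group_energy(x, grad, "hbond", w.hbond)
                         if "hbond" in self.dist_groups else 0.0)

        e_metal = (self._distance_group_energy(x, grad, "metal", w.metal_bond)
                   if "metal" in self.dist_groups else 0.0)
        if self.ar_i.size:
            e_metal += geom.harmonic_angle_energy(
                x, self.ar_i, self.ar_j, self.ar_k, self.ar_t0,
                w.metal_angle * self.ar_w, grad)
        comp["metal"] = e_metal

        comp["dihedral"] = (
            geom.torsion_well_energy(x, self.dh_a, self.dh_b, self.dh_c, self.dh_d,
                                     self.dh_t0, self.dh_hw, w.dihedral, grad)
            if self.dh_a.size else 0.0
        )

        e_ncs = 0.0
        if self.ncs_idx is not None:
            d = x[self.ncs_idx] - self.ncs_target
            e_ncs = float(w.ncs * np.sum(d * d))
            grad[self.ncs_idx] += 2.0 * w.ncs * d
        comp["ncs"] = e_ncs

        self.components = comp
        total = float(sum(comp.values()))
        return total, grad.ravel()


# ---------------------------------------------------------------------------
# conformers, schedules, annealing
# ---------------------------------------------------------------------------

@dataclass
class Conformer:
    coords: np.ndarray
    energies: dict[str, float]
    seed: int | None = None
    quench_trace: list[float] = field(default_factory=list)

    @property
    def total_energy(self) -> float:
        return float(sum(self.energies.values()))


@dataclass
class AnnealSchedule:
    """Two-phase protocol: torsion-space folding rounds, then Cartesian polish.

    ``torsion_rounds`` are (repulsion scale, perturbation sd in degrees,
    L-BFGS iteration budget); the repulsion ramp lets the chain pass through
    itself early, mimicking the soft-core start of a standard
    simulated-annealing run.
    """

    n_starts: int = 4           # multistart count for the fold search
    perturb_sd: float = 35.0    # deg, perturbation of unrestrained torsions
    rep_ramp: tuple = (0.1, 1.0)
    maxiter_fold: int = 250     # per torsion-space round
    maxiter_stage: int = 250    # Cartesian soft-relax budget
    maxiter_final: int = 600    # final quench budget


def _minimize(model: EnergyModel, x0: np.ndarray, maxiter: int, callback=None):
    res = _scipy_minimize(
        model, x0.ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "maxcor": 20},
        callback=callback,
    )
    return res.x.reshape(-1, 3), float(res.fun)


def _nerf_place(a, b, c, bond, theta_deg, chi_deg):
    """Place atom d bonded to c: |cd| = bond, angle(b,c,d) = theta,
    torsion(a,b,c,d) = chi."""
    theta = math.radians(theta_deg)
    chi = math.radians(chi_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-8:
        n = np.cross(np.array([0.0, 0.0, 1.0]), bc)
        nn = np.linalg.norm(n)
    n = n / nn
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * math.cos(theta),
        bond * math.cos(chi) * math.sin(theta),
        -bond * math.sin(chi) * math.sin(theta),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _tetra_direction(u, v, theta1, theta2, sign):
    """Unit direction making angles theta1/theta2 (deg) with unit vectors u, v;
    ``sign`` picks the side of the (u, v) plane (sign of u . (v x d))."""
    c = float(np.dot(u, v))
    t1, t2 = math.cos(math.radians(theta1)), math.cos(math.radians(theta2))
    det = 1.0 - c * c
    alpha = (t1 - c * t2) / det
    beta = (t2 - c * t1) / det
    rest = 1.0 - (alpha * alpha + beta * beta + 2 * alpha * beta * c)
    gamma = math.copysign(math.sqrt(max(rest, 0.0) / det), sign)
    d = alpha * u + beta * v + gamma * np.cross(u, v)
    return d / np.linalg.norm(d)


class TorsionBuilder:
    """Chain construction with ideal covalent geometry from backbone and
    side-chain torsions, with analytic torsion-space gradients.

    Variables are phi/psi per residue (phi of the first residue is fixed)
    plus side-chain chi angles down to any restrained atom; omega is held
    trans and all bond lengths/angles at their ideal values, so the
    torsion-space energy surface contains only restraint and repulsion
    terms.
    """

    def __init__(self, topology: Topology):
        self.top = topology
        self.residues = topology.residue_indices
        self.variables: list[tuple[str, int]] = []   # (name, residue)
        for k, res in enumerate(self.residues):
            if k > 0:
                self.variables.append(("phi", res))
            self.variables.append(("psi", res))
            rtype = topology.residue_type(res)
            if topology.has_atom(res, "SG"):
                self.variables.append(("chi1", res))
            if rtype == "M" and topology.has_atom(res, "SD"):
                self.variables.extend([("chi1", res), ("chi2", res), ("chi3", res)])
        self._var_index = {v: i for i, v in enumerate(self.variables)}
        self._downstream = self._compute_downstream()
        self._compile()
        self._compile_projection()

    def n_variables(self) -> int:
        return len(self.variables)

    def _compute_downstream(self):
        top = self.top
        down: list[tuple[np.ndarray, tuple[int, int]]] = []
        order = {res: k for k, res in enumerate(self.residues)}
        for name, res in self.variables:
            idx: list[int] = []
            for i, a in enumerate(top.atoms):
                if a.atom_name == "AG":
                    continue
                k = order.get(a.residue_index)
                if k is None:
                    continue
                if name == "phi":
                    if a.residue_index > res or (
                        a.residue_index == res and a.atom_name in
                        ("HA", "CB", "CG", "SG", "SD", "CE", "QB", "QE", "C", "O")
                    ):
                        idx.append(i)
                elif name == "psi":
                    if a.residue_index > res or (
                        a.residue_index == res and a.atom_name == "O"
                    ):
                        idx.append(i)
                elif name == "chi1":
                    if a.residue_index == res and a.atom_name in ("SG", "CG", "SD", "CE", "QE"):
                        idx.append(i)
                elif name == "chi2":
                    if a.residue_index == res and a.atom_name in ("SD", "CE", "QE"):
                        idx.append(i)
                elif name == "chi3":
                    if a.residue_index == res and a.atom_name in ("CE", "QE"):
                        idx.append(i)
            axis = {
                "phi": ("N", "CA"), "psi": ("CA", "C"),
                "chi1": ("CA", "CB"), "chi2": ("CB", "CG"), "chi3": ("CG", "SD"),
            }[name]
            down.append((np.array(idx, dtype=int),
                         (top.atom_index(res, axis[0]), top.atom_index(res, axis[1]))))
        return down

    def default_torsions(self, restraints: RestraintSet | None = None) -> np.ndarray:
        """Extended-chain start, with restrained dihedrals at their targets."""
        targets = {}
        if restraints is not None:
            for r in restraints.dihedrals:
                targets[(r.angle_name, r.residue_index)] = r.target
        tau = np.zeros(self.n_variables())
        for i, (name, res) in enumerate(self.variables):
            if name in ("phi", "psi"):
                tau[i] = targets.get((name, res), -120.0 if name == "phi" else 130.0)
            else:
                tau[i] = 180.0
        return tau

    def _compile(self):
        """Precompute the placement program executed by build()."""
        top = self.top
        prog: list[tuple] = []
        vidx = self._var_index

        def var(v):
            return vidx.get(v, -1)

        def nerf(idx, a, b, c, bkey, akey, vi, offset):
            prog.append(("N", idx, a, b, c, BOND_LENGTHS[bkey],
                         math.radians(BOND_ANGLES[akey]), vi, math.radians(offset)))

        prev_n = prev_ca = prev_c = None
        for k, res in enumerate(self.residues):
            i_n = top.atom_index(res, "N")
            i_ca = top.atom_index(res, "CA")
            i_c = top.atom_index(res, "C")
            i_hn = top._index.get((res, "HN"))
            if k == 0:
                prog.append(("F", i_n, (0.0, 0.0, 0.0)))
                prog.append(("F", i_ca, (BOND_LENGTHS[("N", "CA")], 0.0, 0.0)))
                prog.append(("N", i_c, -1, i_n, i_ca, BOND_LENGTHS[("CA", "C")],
                             math.radians(BOND_ANGLES[("N", "CA", "C")]), -1,
                             math.radians(57.0)))
                if i_hn is not None:
                    prog.append(("H1", i_hn, i_n, i_ca))
            else:
                nerf(i_n, prev_n, prev_ca, prev_c, ("C", "N+"), ("CA", "C", "N+"),
                     var(("psi", self.residues[k - 1])), 0.0)
                nerf(i_ca, prev_ca, prev_c, i_n, ("N", "CA"), ("C-", "N", "CA"),
                     -1, 180.0)
                nerf(i_c, prev_c, i_n, i_ca, ("CA", "C"), ("N", "CA", "C"),
                     var(("phi", res)), 0.0)
                if i_hn is not None:
                    prog.append(("HB", i_hn, prev_c, i_n, i_ca))
            # carbonyl O anti to the next amide nitrogen
            nerf(top.atom_index(res, "O"), i_n, i_ca, i_c, ("C", "O"),
                 ("CA", "C", "O"), var(("psi", res)), 180.0)
            prog.append(("T", top.atom_index(res, "HA"), i_n, i_ca, i_c,
                         BOND_LENGTHS[("CA", "HA")],
                         math.cos(math.radians(BOND_ANGLES[("N", "CA", "HA")])),
                         math.cos(math.radians(BOND_ANGLES[("C", "CA", "HA")])), -1.0))
            i_cb = top._index.get((res, "CB"))
            if i_cb is not None:
                prog.append(("T", i_cb, i_n, i_ca, i_c, BOND_LENGTHS[("CA", "CB")],
                             math.cos(math.radians(BOND_ANGLES[("N", "CA", "CB")])),
                             math.cos(math.radians(BOND_ANGLES[("C", "CA", "CB")])), 1.0))
                if top.has_atom(res, "SG"):
                    nerf(top.atom_index(res, "SG"), i_n, i_ca, i_cb, ("CB", "SG"),
                         ("CA", "CB", "SG"), var(("chi1", res)), 0.0)
                if top.has_atom(res, "QB"):
                    nerf(top.atom_index(res, "QB"), i_n, i_ca, i_cb, ("CB", "QB"),
                         ("CA", "CB", "QB"), -1, 60.0)
                if top.has_atom(res, "CG"):
                    i_cg = top.atom_index(res, "CG")
                    nerf(i_cg, i_n, i_ca, i_cb, ("CB", "CG"), ("CA", "CB", "CG"),
                         var(("chi1", res)), 0.0)
                    if top.has_atom(res, "SD"):
                        i_sd = top.atom_index(res, "SD")
                        nerf(i_sd, i_ca, i_cb, i_cg, ("CG", "SD"), ("CB", "CG", "SD"),
                             var(("chi2", res)), 0.0)
                        if top.has_atom(res, "CE"):
                            nerf(top.atom_index(res, "CE"), i_cb, i_cg, i_sd,
                                 ("SD", "CE"), ("CG", "SD", "CE"),
                                 var(("chi3", res)), 0.0)
            prev_n, prev_ca, prev_c = i_n, i_ca, i_c
        self._program = prog

    def build(self, tau_deg: np.ndarray) -> np.ndarray:
        x = np.zeros((self.top.n_atoms, 3))
        tau_rad = np.radians(tau_deg)
        sqrt, cos, sin = math.sqrt, math.cos, math.sin
        for ins in self._program:
            op = ins[0]
            if op == "N":
                _, idx, ia, ib, ic, bond, theta, vi, off = ins
                chi = off + (tau_rad[vi] if vi >= 0 else 0.0)
                if ia < 0:
                    ax, ay, az = 0.0, 1.0, 0.0
                else:
                    ax, ay, az = x[ia, 0], x[ia, 1], x[ia, 2]
                bx, by, bz = x[ib, 0], x[ib, 1], x[ib, 2]
                cx, cy, cz = x[ic, 0], x[ic, 1], x[ic, 2]
                ux, uy, uz = cx - bx, cy - by, cz - bz
                un = sqrt(ux * ux + uy * uy + uz * uz) or 1e-9
                ux, uy, uz = ux / un, uy / un, uz / un
                abx, aby, abz = bx - ax, by - ay, bz - az
                nx = aby * uz - abz * uy
                ny = abz * ux - abx * uz
                nz = abx * uy - aby * ux
                nn = sqrt(nx * nx + ny * ny + nz * nz)
                if nn < 1e-8:
                    nx = -uy
                    ny = ux
                    nz = 0.0
                    nn = sqrt(nx * nx + ny * ny) or 1e-9
                nx, ny, nz = nx / nn, ny / nn, nz / nn
                mx = ny * uz - nz * uy
                my = nz * ux - nx * uz
                mz = nx * uy - ny * ux
                st = sin(theta)
                d0 = -bond * cos(theta)
                d1 = bond * cos(chi) * st
                d2 = -bond * sin(chi) * st
                x[idx, 0] = cx + d0 * ux + d1 * mx + d2 * nx
                x[idx, 1] = cy + d0 * uy + d1 * my + d2 * ny
                x[idx, 2] = cz + d0 * uz + d1 * mz + d2 * nz
            elif op == "T":
                _, idx, i_n, i_ca, i_c, bond, t1, t2, sign = ins
                nhx = x[i_n, 0] - x[i_ca, 0]
                nhy = x[i_n, 1] - x[i_ca, 1]
                nhz = x[i_n, 2] - x[i_ca, 2]
                nn = sqrt(nhx * nhx + nhy * nhy + nhz * nhz) or 1e-9
                nhx, nhy, nhz = nhx / nn, nhy / nn, nhz / nn
                chx = x[i_c, 0] - x[i_ca, 0]
                chy = x[i_c, 1] - x[i_ca, 1]
                chz = x[i_c, 2] - x[i_ca, 2]
                cn = sqrt(chx * chx + chy * chy + chz * chz) or 1e-9
                chx, chy, chz = chx / cn, chy / cn, chz / cn
                c = nhx * chx + nhy * chy + nhz * chz
                det = 1.0 - c * c
                alpha = (t1 - c * t2) / det
                beta = (t2 - c * t1) / det
                rest = 1.0 - (alpha * alpha + beta * beta + 2.0 * alpha * beta * c)
                gamma = math.copysign(sqrt(max(rest, 0.0) / det), sign)
                dx = alpha * nhx + beta * chx + gamma * (nhy * chz - nhz * chy)
                dy = alpha * nhy + beta * chy + gamma * (nhz * chx - nhx * chz)
                dz = alpha * nhz + beta * chz + gamma * (nhx * chy - nhy * chx)
                dn = sqrt(dx * dx + dy * dy + dz * dz) or 1e-9
                x[idx, 0] = x[i_ca, 0] + bond * dx / dn
                x[idx, 1] = x[i_ca, 1] + bond * dy / dn
                x[idx, 2] = x[i_ca, 2] + bond * dz / dn
            elif op == "HB":
                _, idx, i_pc, i_n, i_ca = ins
                ux = x[i_pc, 0] - x[i_n, 0]
                uy = x[i_pc, 1] - x[i_n, 1]
                uz = x[i_pc, 2] - x[i_n, 2]
                un = sqrt(ux * ux + uy * uy + uz * uz) or 1e-9
                vx = x[i_ca, 0] - x[i_n, 0]
                vy = x[i_ca, 1] - x[i_n, 1]
                vz = x[i_ca, 2] - x[i_n, 2]
                vn = sqrt(vx * vx + vy * vy + vz * vz) or 1e-9
                dx = -(ux / un + vx / vn)
                dy = -(uy / un + vy / vn)
                dz = -(uz / un + vz / vn)
                dn = sqrt(dx * dx + dy * dy + dz * dz) or 1e-9
                bl = BOND_LENGTHS[("N", "HN")]
                x[idx, 0] = x[i_n, 0] + bl * dx / dn
                x[idx, 1] = x[i_n, 1] + bl * dy / dn
                x[idx, 2] = x[i_n, 2] + bl * dz / dn
            elif op == "H1":
                _, idx, i_n, i_ca = ins
                ux = x[i_ca, 0] - x[i_n, 0]
                uy = x[i_ca, 1] - x[i_n, 1]
                uz = x[i_ca, 2] - x[i_n, 2]
                un = sqrt(ux * ux + uy * uy + uz * uz) or 1e-9
                dx, dy, dz = -ux / un, -uy / un, -uz / un + 0.8
                dn = sqrt(dx * dx + dy * dy + dz * dz) or 1e-9
                bl = BOND_LENGTHS[("N", "HN")]
                x[idx, 0] = x[i_n, 0] + bl * dx / dn
                x[idx, 1] = x[i_n, 1] + bl * dy / dn
                x[idx, 2] = x[i_n, 2] + bl * dz / dn
            else:  # "F"
                _, idx, pos = ins
                x[idx] = pos
        return x

    def _compile_projection(self):
        """Suffix structure of the downstream sets for O(n) projection.

        For backbone torsions the moving atoms are a contiguous suffix of
        the atom order (phi: from the residue's HA onward; psi: from the
        next residue's N onward plus this residue's carbonyl O), so the
        required sums come from reverse cumulative sums; side-chain chis
        keep their explicit index sets.
        """
        top = self.top
        plans = []
        n = top.n_atoms
        for vi, (name, res) in enumerate(self.variables):
            idx, (ia, ib) = self._downstream[vi]
            if name == "phi":
                plans.append(("suffix", top.atom_index(res, "HA"), -1, ia, ib))
            elif name == "psi":
                pos = self.residues.index(res)
                if pos + 1 < len(self.residues):
                    start = top.atom_index(self.residues[pos + 1], "N")
                else:
                    start = n  # empty suffix
                plans.append(("suffix", start, top.atom_index(res, "O"), ia, ib))
            else:
                plans.append(("set", idx, None, ia, ib))
        self._proj_plans = plans
        self._metal_idx = top.atom_index(0, "AG") if top.has_metal else -1
        suff = [(vi, p) for vi, p in enumerate(plans) if p[0] == "suffix"]
        self._suf_vi = np.array([vi for vi, _ in suff], dtype=int)
        self._suf_start = np.array([p[1] for _, p in suff], dtype=int)
        self._suf_extra = np.array([p[2] for _, p in suff], dtype=int)
        self._suf_ia = np.array([p[3] for _, p in suff], dtype=int)
        self._suf_ib = np.array([p[4] for _, p in suff], dtype=int)
        self._set_plans = [(vi, p) for vi, p in enumerate(plans) if p[0] == "set"]

    def project_gradient(self, x: np.ndarray, cart_grad: np.ndarray) -> np.ndarray:
        """dE/dtau (per degree) from the Cartesian gradient."""
        g = cart_grad
        if self._metal_idx >= 0:
            g = cart_grad.copy()
            g[self._metal_idx] = 0.0
        rxg = np.cross(x, g)
        # reverse cumulative sums: suffix_rxg[i] = sum_{j >= i} (r_j x g_j)
        suffix_rxg = np.vstack([np.cumsum(rxg[::-1], axis=0)[::-1],
                                np.zeros((1, 3))])
        suffix_g = np.vstack([np.cumsum(g[::-1], axis=0)[::-1],
                              np.zeros((1, 3))])
        out = np.zeros(self.n_variables())
        # backbone torsions, fully vectorized
        axis = x[self._suf_ib] - x[self._suf_ia]
        nrm = np.maximum(np.linalg.norm(axis, axis=1), 1e-9)
        tot_rxg = suffix_rxg[self._suf_start]
        tot_g = suffix_g[self._suf_start]
        has_extra = self._suf_extra >= 0
        if has_extra.any():
            ex = self._suf_extra[has_extra]
            tot_rxg = tot_rxg.copy()
            tot_g = tot_g.copy()
            tot_rxg[has_extra] += rxg[ex]
            tot_g[has_extra] += g[ex]
        val = np.einsum("ij,ij->i", axis,
                        tot_rxg - np.cross(x[self._suf_ib], tot_g)) / nrm
        # the builder's torsion sense is clockwise about the axis
        out[self._suf_vi] = -val * DEG
        for vi, (kind, a1, a2, ia, ib) in self._set_plans:
            if a1.size == 0:
                continue
            ax = x[ib] - x[ia]
            n2 = math.sqrt(ax[0] ** 2 + ax[1] ** 2 + ax[2] ** 2) or 1e-9
            v = np.dot(ax, rxg[a1].sum(axis=0)
                       - np.cross(x[ib], g[a1].sum(axis=0))) / n2
            out[vi] = -v * DEG
        return out


def _init_metal(model: EnergyModel, x: np.ndarray) -> None:
    """Place the metal at the centroid of the coordinating sulfurs."""
    top = model.top
    if not top.has_metal or not model.rs.metal_site:
        return
    try:
        mi = top.atom_index(*METAL)
        sidx = [top.atom_index(*s) for s in model.rs.metal_site]
    except KeyError:
        return
    x[mi] = x[sidx].mean(axis=0)


def _torsion_minimize(tb: TorsionBuilder, model: EnergyModel, tau: np.ndarray,
                      maxiter: int, free_mask: np.ndarray | None = None) -> np.ndarray:
    """L-BFGS over the torsion variables (optionally a masked subset)."""
    tau = np.asarray(tau, dtype=float)
    if free_mask is None:
        free_idx = np.arange(tau.size)
    else:
        free_idx = np.where(free_mask)[0]
    base = tau.copy()

    def fun(tfree):
        t = base.copy()
        t[free_idx] = tfree
        x = tb.build(t)
        _init_metal(model, x)
        e, g = model(x.ravel())
        return e, tb.project_gradient(x, g.reshape(-1, 3))[free_idx]

    res = _scipy_minimize(fun, tau[free_idx], jac=True, method="L-BFGS-B",
                          options={"maxiter": maxiter, "maxcor": 30})
    out = base.copy()
    out[free_idx] = res.x
    return out


def _torsion_fold(model: EnergyModel, schedule: AnnealSchedule,
                  rng: np.random.Generator) -> np.ndarray:
    """Restrained fold search in torsion space.

    Backbone torsions covered by dihedral restraints start at their targets
    (and are held there during the search); the remaining torsions — loops,
    termini, side chains — are folded against the distance restraints with
    a soft-core repulsion ramp, from several random starts.  A final round
    releases all torsions.  The best start by full energy wins.
    """
    top = model.top
    tb = TorsionBuilder(top)
    weights = model.w
    restrained = {(r.angle_name, r.residue_index) for r in model.rs.dihedrals}
    free = np.array([
        (name, res) not in restrained for (name, res) in tb.variables
    ])
    if not free.any():
        free = np.ones(tb.n_variables(), bool)
    tau0 = tb.default_torsions(model.rs)

    def full_energy(tau):
        model.w = weights
        x = tb.build(tau)
        _init_metal(model, x)
        e, _ = model(x.ravel())
        return e

    best_tau, best_e = None, np.inf
    for start in range(schedule.n_starts):
        tau = tau0.copy()
        tau[free] += rng.normal(0.0, schedule.perturb_sd, int(free.sum()))
        for rep_scale in schedule.rep_ramp:
            model.w = replace(weights, bond=0.0, angle=0.0, planarity=0.0,
                              chirality=0.0,
                              repulsion=weights.repulsion * rep_scale)
            tau = _torsion_minimize(tb, model, tau, schedule.maxiter_fold, free)
        # release everything for a short all-torsion refinement
        model.w = replace(weights, bond=0.0, angle=0.0, planarity=0.0,
                          chirality=0.0)
        tau = _torsion_minimize(tb, model, tau, schedule.maxiter_fold)
        e = full_energy(tau)
        if e < best_e:
            best_tau, best_e = tau, e
    model.w = weights
    x = tb.build(best_tau)
    _init_metal(model, x)
    return x


def anneal(
    topology: Topology,
    restraints: RestraintSet,
    seed: int,
    schedule: AnnealSchedule | None = None,
    weights: EnergyWeights | None = None,
    tethers=None,
    init_coords: np.ndarray | None = None,
) -> Conformer:
    """Restrained annealing of one conformer; bit-reproducible under the seed."""
    schedule = schedule or AnnealSchedule()
    weights = weights or EnergyWeights()
    model = EnergyModel(topology, restraints, weights, tethers=tethers)
    rng = np.random.default_rng(seed)

    if init_coords is not None:
        best_x = np.array(init_coords, dtype=float)
        _init_metal(model, best_x)
        best_x, _ = _minimize(model, best_x, schedule.maxiter_stage)
    else:
        best_x = _torsion_fold(model, schedule, rng)

    # Cartesian relaxation: soft covalent geometry first, then full weights
    soft_w = replace(weights, bond=weights.bond * 0.15, angle=weights.angle * 0.15,
                     planarity=weights.planarity * 0.15,
                     repulsion=weights.repulsion * 0.5)
    model.w = soft_w
    best_x, _ = _minimize(model, best_x, schedule.maxiter_stage)
    model.w = weights

    trace: list[float] = []

    def record(xk):
        e, _ = model(xk)
        trace.append(min(e, trace[-1]) if trace else e)

    final_x, final_e = _minimize(model, best_x, schedule.maxiter_final, callback=record)
    if not math.isfinite(final_e):
        raise FloatingPointError("non-finite energy after annealing")
    model(final_x.ravel())
    return Conformer(coords=final_x, energies=dict(model.components), seed=seed,
                     quench_trace=trace)


def anneal_coupled(
    topology: Topology,
    restraints_apo: RestraintSet,
    restraints_bound: RestraintSet,
    ncs: NcsCoupling | None,
    seed: int,
    schedule: AnnealSchedule | None = None,
    weights: EnergyWeights | None = None,
    n_outer: int = 12,
    maxiter_inner: int = 80,
) -> tuple[Conformer, Conformer]:
    """Joint two-form refinement with an inter-form superposition penalty.

    Both forms share the topology (the bound form's restraints reference the
    metal).  Each outer round superposes the coupled backbone segments with
    the current coordinates (optimal rotation recomputed, then frozen), adds
    a harmonic coupling tether to each form and quenches both.  With ``ncs``
    None the forms refine independently.
    """
    schedule = schedule or AnnealSchedule()
    weights = weights or EnergyWeights()
    conf_a = anneal(topology, restraints_apo, seed, schedule, weights)
    conf_b = anneal(topology, restraints_bound, seed + 1, schedule, weights)
    if ncs is None:
        return conf_a, conf_b

    sel = topology.backbone_indices(ncs.residues, ncs.atom_names)
    model_a = EnergyModel(topology, restraints_apo, weights)
    model_b = EnergyModel(topology, restraints_bound, weights)
    w_ncs = weights.ncs * ncs.weight
    model_a.w = replace(model_a.w, ncs=w_ncs)
    model_b.w = replace(model_b.w, ncs=w_ncs)
    xa, xb = conf_a.coords.copy(), conf_b.coords.copy()

    for _ in range(n_outer):
        r, t, _ = geom.kabsch(xa[sel], xb[sel])
        model_a.ncs_idx, model_a.ncs_target = sel, xb[sel] @ r.T + t
        xa, _ = _minimize(model_a, xa, maxiter_inner)
        rb, tb, _ = geom.kabsch(xb[sel], xa[sel])
        model_b.ncs_idx, model_b.ncs_target = sel, xa[sel] @ rb.T + tb
        xb, _ = _minimize(model_b, xb, maxiter_inner)

    ea, _ = model_a(xa.ravel())
    comp_a = dict(model_a.components)
    eb, _ = model_b(xb.ravel())
    comp_b = dict(model_b.components)
    return (
        Conformer(coords=xa, energies=comp_a, seed=seed),
        Conformer(coords=xb, energies=comp_b, seed=seed + 1),
    )


# ---------------------------------------------------------------------------
# ensembles and selection
# ---------------------------------------------------------------------------

@dataclass
class Ensemble:
    topology: Topology
    models: list[Conformer]
    scores: list[float]

    def __len__(self) -> int:
        return len(self.models)

    def coordinates(self) -> list[np.ndarray]:
        return [m.coords for m in self.models]

    def proton_distance(self, pair) -> list[float]:
        """Per-model distance between two (residue, atom) references."""
        (ri, ai), (rj, aj) = pair
        i = self.topology.atom_index(ri, ai)
        j = self.topology.atom_index(rj, aj)
        return [float(np.linalg.norm(m.coords[i] - m.coords[j])) for m in self.models]

    def write(self, path) -> None:
        from .io import write_ensemble

        write_ensemble(self.coordinates(), self.topology.atom_records(), path)

    def pairwise_backbone_rmsd(self) -> np.ndarray:
        sel = self.topology.backbone_indices()
        n = len(self.models)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                _, _, r = geom.kabsch(self.models[i].coords[sel],
                                      self.models[j].coords[sel])
                out[i, j] = out[j, i] = r
        return out


def shift_pseudo_energy(topology: Topology, coords: np.ndarray,
                        observed_shifts, predictor=None) -> float:
    """Sum of squared (sigma-scaled) differences observed vs back-calculated."""
    predictor = predictor or chemshift.predict_shifts
    predicted = predictor(topology, coords)
    sigma = {"H": 1.0, "HN": 1.0, "N": 10.0, "C": 4.0, "Cprime": 4.0}
    total = 0.0
    for entry in observed_shifts:
        if entry.form != "S":
            continue
        calc = predicted.get((entry.residue_index, entry.atom_name))
        if calc is None:
            continue
        total += ((entry.shift - calc) / sigma[entry.nucleus]) ** 2
    return total


def select_ensemble(
    conformers,
    observed_shifts=None,
    predictor=None,
    n_select: int = 10,
    topology: Topology | None = None,
) -> Ensemble:
    """The n lowest conformers by restraint+geometry energy plus shift pseudo-energy.

    With ``observed_shifts`` (and optionally a custom predictor) the combined
    score adds the squared difference between observed and back-calculated
    shifts; without them the ranking is by energy alone.  Ties break by
    conformer index.
    """
    conformers = list(conformers)
    if not conformers:
        raise ValueError("empty conformer pool")
    if topology is None:
        raise ValueError("select_ensemble requires the topology")
    if n_select > len(conformers):
        warnings.warn(
            f"requested {n_select} models from a pool of {len(conformers)}; "
            "returning the whole pool", stacklevel=2,
        )
        n_select = len(conformers)
    scored = []
    for idx, c in enumerate(conformers):
        pseudo = 0.0
        if observed_shifts is not None:
            pseudo = shift_pseudo_energy(topology, c.coords, observed_shifts, predictor)
        energies = dict(c.energies)
        energies["shift_pseudo"] = pseudo
        scored.append((c.total_energy + pseudo, idx,
                       Conformer(c.coords, energies, c.seed, c.quench_trace)))
    scored.sort(key=lambda s: (s[0], s[1]))
    chosen = scored[:n_select]
    return Ensemble(
        topology=topology,
        models=[c for _, _, c in chosen],
        scores=[s for s, _, _ in chosen],
    )


def superpose_rmsd(model_a, model_b, atom_selection=None):
    """Least-squares superposition of model_b onto model_a.

    Accepts Conformers or plain (n, 3) arrays; ``atom_selection`` is an
    index array applied to both.  Returns (rotation, translation, rmsd).
    """
    a = model_a.coords if isinstance(model_a, Conformer) else np.asarray(model_a, float)
    b = model_b.coords if isinstance(model_b, Conformer) else np.asarray(model_b, float)
    if atom_selection is not None:
        sel = np.asarray(atom_selection, dtype=int)
        a, b = a[sel], b[sel]
    return geom.kabsch(a, b)
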