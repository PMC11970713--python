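"""Typed structural restraints and their construction rules.

Atoms are referenced as ``(residue_index, atom_name)`` tuples; the metal ion
is residue index 0, atom ``AG``.  Distance restraints carry absolute
lower/target/upper bounds in Å; an ambiguous restraint lists several member
atom pairs and is satisfied through the r^-6-summed effective distance

    r_eff = (sum_k r_k^-6)^(-1/6),

which is always <= the closest member distance.  Outside the flat
[lower, upper] well the energy grows quadratically with the excess.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import DihedralPrediction

log = logging.getLogger(__name__)

AtomRef = tuple[int, str]
METAL = (0, "AG")

DISTANCE_KINDS = ("noe", "hbond", "metal_implicit", "metal_bond", "ncs")
ANGLE_KINDS = ("metal_bond_angle", "metal_ligand_angle")

#: NOE calibration ceiling (Å) and flat-well fraction
D_MAX_DEFAULT = 4.25
FLAT_FRACTION = 0.33
#: hydrogen-bond H..O=C target and absolute half-width (Å)
HBOND_TARGET = 1.7
HBOND_DELTA = 0.3
#: trigonal thiolate coordination geometry
METAL_BOND_LENGTH = 2.3       # Ag-S, Å
METAL_BOND_ANGLE = 120.0      # S-Ag-S, degrees
METAL_LIGAND_ANGLE = 109.5    # Ag-S-C, degrees
METAL_IMPLICIT_SS = 4.0       # S-S distance in implicit mode, Å


@dataclass
class DistanceRestraint:
    member_pairs: tuple[tuple[AtomRef, AtomRef], ...]
    target: float
    lower: float
    upper: float
    kind: str = "noe"
    weight: float = 1.0
    source: str = ""
    #: optional per-member contribution weights for the r^-6 sum (ARIA-style
    #: normalized assignment probabilities); None = plain unweighted sum
    member_weights: tuple[float, ...] | None = None

    def __post_init__(self):
        if not self.member_pairs:
            raise ValueError("distance restraint needs at least one atom pair")
        if self.member_weights is not None and \
                len(self.member_weights) != len(self.member_pairs):
            raise ValueError("one contribution weight per member pair required")
        if not (self.lower <= self.target <= self.upper):
            raise ValueError(
                f"bounds must satisfy lower <= target <= upper, got "
                f"{self.lower}/{self.target}/{self.upper}"
            )
        if self.kind not in DISTANCE_KINDS:
            raise ValueError(f"unknown distance restraint kind {self.kind!r}")

    @property
    def ambiguous(self) -> bool:
        return len(self.member_pairs) > 1


@dataclass
class AngleRestraint:
    atoms: tuple[AtomRef, AtomRef, AtomRef]  # vertex in the middle
    target: float
    halfwidth: float = 0.0
    kind: str = "metal_bond_angle"
    weight: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.target <= 180.0):
            raise ValueError("angle target must be in (0, 180]")
        if self.kind not in ANGLE_KINDS:
            raise ValueError(f"unknown angle restraint kind {self.kind!r}")


@dataclass
class DihedralRestraint:
    residue_index: int
    angle_name: str
    target: float
    halfwidth: float
    weight: float = 1.0

    def __post_init__(self):
        if self.halfwidth <= 0:
            raise ValueError("dihedral halfwidth must be > 0")


@dataclass
class NcsCoupling:
    """Keeps backbone segments of two co-refined forms superimposable."""

    superimpose_segments: tuple[tuple[int, int], ...]
    free_segments: tuple[tuple[int, int], ...] = ()
    atom_names: tuple[str, ...] = ("N", "CA", "C")
    weight: float = 1.0

    def __post_init__(self):
        if not self.superimpose_segments:
            raise ValueError("superimpose segment list is empty")
        sup = set(self.residues)
        free = {
            r for a, b in self.free_segments for r in range(a, b + 1)
        }
        if sup & free:
            raise ValueError(
                f"superimposed and free segments overlap at residues {sorted(sup & free)}"
            )

    @property
    def residues(self) -> list[int]:
        out: list[int] = []
        for a, b in self.superimpose_segments:
            if b < a:
                raise ValueError(f"bad segment ({a}, {b})")
            out.extend(range(a, b + 1))
        return out


@dataclass
class RestraintSet:
    distances: list[DistanceRestraint] = field(default_factory=list)
    angles: list[AngleRestraint] = field(default_factory=list)
    dihedrals: list[DihedralRestraint] = field(default_factory=list)
    ncs: NcsCoupling | None = None
    metal_site: tuple[AtomRef, ...] = ()

    def __len__(self) -> int:
        return len(self.distances) + len(self.angles) + len(self.dihedrals)

    def by_kind(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.distances:
            counts[r.kind] = counts.get(r.kind, 0) + 1
        for r in self.angles:
            counts[r.kind] = counts.get(r.kind, 0) + 1
        if self.dihedrals:
            counts["dihedral"] = len(self.dihedrals)
        return counts

    def extend(self, other: "RestraintSet") -> "RestraintSet":
        self.distances.extend(other.distances)
        self.angles.extend(other.angles)
        self.dihedrals.extend(other.dihedrals)
        if other.ncs is not None:
            self.ncs = other.ncs
        if other.metal_site:
            self.metal_site = other.metal_site
        return self


# ---------------------------------------------------------------------------
# construction rules
# ---------------------------------------------------------------------------

def calibrate_noe_distance(intensity: float, i_min: float, d_max: float = D_MAX_DEFAULT) -> float:
    """Target distance d = d_max (I / I_min)^(-1/6); the weakest peak maps to d_max."""
    if i_min <= 0 or d_max <= 0:
        raise ValueError("i_min and d_max must be > 0")
    if intensity < i_min:
        warnings.warn(
            f"intensity {intensity:g} below i_min {i_min:g}; clamped to the weakest peak",
            stacklevel=2,
        )
        intensity = i_min
    return d_max * (intensity / i_min) ** (-1.0 / 6.0)


def make_noe_restraint(
    member_pairs: Sequence[tuple[AtomRef, AtomRef]],
    intensity: float,
    i_min: float,
    d_max: float = D_MAX_DEFAULT,
    flat: float = FLAT_FRACTION,
    pseudo_correction: float = 0.0,
    source: str = "",
) -> DistanceRestraint:
    """NOE distance restraint with a flat well of width ``flat * d`` each side."""
    d = calibrate_noe_distance(intensity, i_min, d_max)
    return DistanceRestraint(
        member_pairs=tuple(member_pairs),
        target=d,
        lower=max(0.0, d * (1.0 - flat)),
        upper=d * (1.0 + flat) + pseudo_correction,
        kind="noe",
        source=source,
    )


def effective_distance(distances) -> float:
    """r^-6-summed effective distance of an ambiguous member set."""
    arr = np.asarray(distances, dtype=float)
    if arr.size == 0:
        raise ValueError("no member distances")
    return float(np.sum(arr ** -6.0) ** (-1.0 / 6.0))


def square_well_energy(distance, restraint: DistanceRestraint, k_force: float = 1.0) -> float:
    """0 inside [lower, upper]; k (excess)^2 outside; boundary inclusive.

    ``distance`` may be a scalar or the per-member distances of an ambiguous
    restraint, in which case the effective r^-6 sum is penalized.
    """
    d = effective_distance(np.atleast_1d(distance))
    if d < restraint.lower:
        return k_force * restraint.weight * (restraint.lower - d) ** 2
    if d > restraint.upper:
        return k_force * restraint.weight * (d - restraint.upper) ** 2
    return 0.0


def make_hbond_restraints(
    beta_probabilities: dict[int, float],
    residues: Sequence[int],
    threshold: float = 0.75,
    separation_floor: int = 2,
    target: float = HBOND_TARGET,
    delta: float = HBOND_DELTA,
) -> list[DistanceRestraint]:
    """Ambiguous H-bond restraints for residues predicted to be in β-sheet.

    For each qualifying residue i, two restraints encode that at least one
    edge of the strand is hydrogen bonded:

      1. HN(i)·C'(x)  or  HN(x)·C'(i-1)
      2. HN(i+1)·C'(x)  or  HN(x)·C'(i)

    with x running over every modeled residue at sequence separation >=
    ``separation_floor`` from the anchor.  C'(j) denotes the carbonyl group
    of residue j; the distance is measured from the amide proton to its
    oxygen acceptor (atom O), where the standard 1.7 ± 0.3 Å hydrogen-bond
    geometry applies.  Alternatives whose anchor atom falls outside the
    modeled range (chain termini) are omitted.
    """
    for r, p in beta_probabilities.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"residue {r}: probability {p} out of [0, 1]")
    modeled = sorted(residues)
    present = set(modeled)
    out: list[DistanceRestraint] = []

    def partners(anchor: int) -> list[int]:
        return [x for x in modeled if abs(x - anchor) >= separation_floor]

    for i in sorted(r for r, p in beta_probabilities.items() if p > threshold):
        if i not in present:
            continue
        specs = (
            ((i, "HN"), i - 1),       # HN(i)/C'(x) or HN(x)/C'(i-1)
            ((i + 1, "HN"), i),       # HN(i+1)/C'(x) or HN(x)/C'(i)
        )
        for (hn_res, hn_atom), co_res in specs:
            members: list[tuple[AtomRef, AtomRef]] = []
            if hn_res in present:
                members += [((hn_res, hn_atom), (x, "O")) for x in partners(hn_res)]
            else:
                log.info("hbond residue %d: HN(%d) outside modeled range, omitted", i, hn_res)
            if co_res in present:
                members += [((x, "HN"), (co_res, "O")) for x in partners(co_res)]
            else:
                log.info("hbond residue %d: C'(%d) outside modeled range, omitted", i, co_res)
            if members:
                out.append(DistanceRestraint(
                    member_pairs=tuple(members),
                    target=target,
                    lower=target - delta,
                    upper=target + delta,
                    kind="hbond",
                    source=f"beta@{i}",
                ))
    return out


def make_dihedral_restraints(
    predictions: Iterable[DihedralPrediction],
    min_halfwidth: float = 5.0,
    accepted_classes: tuple[str, ...] = ("Strong",),
) -> list[DihedralRestraint]:
    """Square-well dihedral restraints from predictions classified Strong.

    The half-width is twice the prediction spread; a zero spread falls back
    to ``min_halfwidth`` with a warning.
    """
    out = []
    for p in predictions:
        if p.classification not in accepted_classes:
            continue
        hw = 2.0 * p.spread
        if hw <= 0:
            warnings.warn(
                f"residue {p.residue_index} {p.angle_name}: zero spread, "
                f"using minimum halfwidth {min_halfwidth} deg",
                stacklevel=2,
            )
            hw = min_halfwidth
        out.append(DihedralRestraint(p.residue_index, p.angle_name, p.predicted_value, hw))
    return out


def make_metal_restraints(
    coordinating_atoms: Sequence[AtomRef],
    mode: str = "explicit",
    attached_atoms: dict[AtomRef, AtomRef] | None = None,
    bond_length: float = METAL_BOND_LENGTH,
    bond_angle: float = METAL_BOND_ANGLE,
    ligand_angle: float = METAL_LIGAND_ANGLE,
    implicit_target: float = METAL_IMPLICIT_SS,
) -> RestraintSet:
    """Trigonal tri-sulfur coordination restraints.

    ``explicit`` mode: three metal–sulfur bonds (2.3 Å), three S–metal–S
    angles (120°) and three metal–S–C angles (109.5°), with the metal to be
    initialized at the sulfur centroid; ``implicit`` mode: three pairwise
    S–S distance restraints (4.0 Å) and no metal atom.  For reference, ideal
    trigonal geometry gives S–S = 2·2.3·sin 60° ≈ 3.98 Å, consistent with
    the implicit target.

    ``attached_atoms`` maps each sulfur to its covalently bonded carbon for
    the ligand angles (defaults to CB, the Cys arrangement).
    """
    sulfurs = tuple(coordinating_atoms)
    if len(sulfurs) != 3:
        raise ValueError("only the trigonal (three-sulfur) site is supported")
    if mode not in ("explicit", "implicit"):
        raise ValueError(f"unknown metal mode {mode!r}")
    rs = RestraintSet(metal_site=sulfurs)
    pairs = [(0, 1), (0, 2), (1, 2)]
    if mode == "implicit":
        for a, b in pairs:
            rs.distances.append(DistanceRestraint(
                member_pairs=((sulfurs[a], sulfurs[b]),),
                target=implicit_target, lower=implicit_target, upper=implicit_target,
                kind="metal_implicit", source="metal",
            ))
        return rs
    attached = attached_atoms or {s: (s[0], "CB") for s in sulfurs}
    for s in sulfurs:
        rs.distances.append(DistanceRestraint(
            member_pairs=((METAL, s),),
            target=bond_length, lower=bond_length, upper=bond_length,
            kind="metal_bond", source="metal",
        ))
    for a, b in pairs:
        rs.angles.append(AngleRestraint(
            atoms=(sulfurs[a], METAL, sulfurs[b]),
            target=bond_angle, kind="metal_bond_angle",
        ))
    for s in sulfurs:
        rs.angles.append(AngleRestraint(
            atoms=(METAL, s, attached[s]),
            target=ligand_angle, kind="metal_ligand_angle",
        ))
    return rs


def make_ncs_coupling(
    superimpose_segments: Sequence[tuple[int, int]],
    free_segments: Sequence[tuple[int, int]] = (),
    atom_names: Sequence[str] = ("N", "CA", "C"),
    weight: float = 1.0,
) -> NcsCoupling:
    return NcsCoupling(
        superimpose_segments=tuple(tuple(s) for s in superimpose_segments),
        free_segments=tuple(tuple(s) for s in free_segments),
        atom_names=tuple(atom_names),
        weight=weight,
    )


# ---------------------------------------------------------------------------
# TSV / CYANA-style export and import
# ---------------------------------------------------------------------------

def _fmt_pair(pair: tuple[AtomRef, AtomRef]) -> str:
    (ri, ai), (rj, aj) = pair
    return f"{ri}:{ai}-{rj}:{aj}"


def _parse_pair(s: str) -> tuple[AtomRef, AtomRef]:
    left, right = s.split("-")
    ri, ai = left.split(":")
    rj, aj = right.split(":")
    return ((int(ri), ai), (int(rj), aj))


def restraints_to_tsv(rs: RestraintSet, path) -> None:
    lines = ["type\tkind\ttarget\tlower_or_halfwidth\tupper\tweight\tmembers"]
    for r in rs.distances:
        members = ";".join(_fmt_pair(p) for p in r.member_pairs)
        lines.append(
            f"distance\t{r.kind}\t{r.target:.6f}\t{r.lower:.6f}\t{r.upper:.6f}"
            f"\t{r.weight:g}\t{members}"
        )
    for r in rs.angles:
        members = ";".join(f"{ri}:{ai}" for ri, ai in r.atoms)
        lines.append(
            f"angle\t{r.kind}\t{r.target:.6f}\t{r.halfwidth:.6f}\t-\t{r.weight:g}\t{members}"
        )
    for r in rs.dihedrals:
        lines.append(
            f"dihedral\t{r.angle_name}\t{r.target:.6f}\t{r.halfwidth:.6f}\t-"
            f"\t{r.weight:g}\t{r.residue_index}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def restraints_from_tsv(path) -> RestraintSet:
    rs = RestraintSet()
    rows = Path(path).read_text().splitlines()
    for lineno, line in enumerate(rows[1:], start=2):
        if not line.strip():
            continue
        toks = line.split("\t")
        rtype, kind, target, aux, upper, weight, members = toks
        if rtype == "distance":
            rs.distances.append(DistanceRestraint(
                member_pairs=tuple(_parse_pair(m) for m in members.split(";")),
                target=float(target), lower=float(aux), upper=float(upper),
                kind=kind, weight=float(weight),
            ))
        elif rtype == "angle":
            atoms = tuple(
                (int(m.split(":")[0]), m.split(":")[1]) for m in members.split(";")
            )
            rs.angles.append(AngleRestraint(
                atoms=atoms, target=float(target), halfwidth=float(aux),
                kind=kind, weight=float(weight),
            ))
        elif rtype == "dihedral":
            rs.dihedrals.append(DihedralRestraint(
                residue_index=int(members), angle_name=kind,
                target=float(target), halfwidth=float(aux), weight=float(weight),
            ))
        else:
            raise ValueError(f"{path}:{lineno}: unknown restraint type {rtype!r}")
    return rs


def restraints_to_upl(rs: RestraintSet, sequence: dict[int, str]) -> str:
    """CYANA-style .upl text (upper limits) for the distance restraints."""
    lines = []
    for r in rs.distances:
        for (ri, ai), (rj, aj) in r.member_pairs:
            lines.append(
                f"{ri:4d} {sequence.get(ri, 'X'):>4s} {ai:<5s}"
                f"{rj:4d} {sequence.get(rj, 'X'):>4s} {aj:<5s} {r.upper:8.2f}"
            )
    return "\n".join(lines) + "\n"


def restraints_to_aco(rs: RestraintSet, sequence: dict[int, str]) -> str:
    """CYANA-style .aco text for the dihedral restraints."""
    lines = []
    for r in rs.dihedrals:
        lo = r.target - r.halfwidth
        hi = r.target + r.halfwidth
        lines.append(
            f"{r.residue_index:4d} {sequence.get(r.residue_index, 'X'):>4s} "
            f"{r.angle_name.upper():<4s} {lo:8.1f} {hi:8.1f}"
        )
    return "\n".join(lines) + "\n"
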