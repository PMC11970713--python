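"""Ground-truth generator: a miniature three-strand sheet with a trigonal
tri-sulfur metal site, its two-form chemical shifts, NOESY peaks and a
metal-titration HSQC series.

The toy emulates the statistical structure the analysis pipeline assumes:

* a structured (S) and an unstructured (U) resonance set for the same
  sequence — the U form carries random-coil shifts with small dispersion,
  the S form carries coil + secondary-structure offsets + a deterministic
  per-residue dispersion term (standing in for ring-current and packing
  effects);
* NOESY cross-peak intensities proportional to r^-6 with log-normal noise,
  per-nucleus position jitter, random peak loss, and decoy peaks drawn from
  U-form intra-residue/sequential proton pairs;
* a titration with stoichiometric single-site binding: fast-exchange drift
  for most residues, intermediate-exchange peak dropout at the binding-site
  residues over a bound-fraction window, and U->S population conversion.

Every peak carries its true origin in a side channel (the assignment map)
that the pipeline under test never sees.  Everything is deterministic given
the seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import chemshift
from .engine import AnnealSchedule, Topology, anneal, build_topology
from .io import Peak, PeakList, ShiftEntry, ShiftTable, TitrationSeries, infer_nucleus
from .restraints import DistanceRestraint, RestraintSet, make_metal_restraints

STRAND_PATTERN = "TIVEFK"
LOOP1_PATTERN = "GDSAKG"      # 6 residues
LOOP2_PATTERN = "GCDCACG"     # 7 residues; the three Cys carry the site


@dataclass
class NoiseModel:
    """Measurement noise for simulated spectra."""

    jitter_by_nucleus: dict = field(default_factory=lambda: {
        "H": 0.008, "HN": 0.008, "N": 0.08, "C": 0.12, "Cprime": 0.12,
    })
    intensity_sigma: float = 0.3     # sd of log-normal intensity factor
    miss_probability: float = 0.05
    decoy_rate: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.miss_probability <= 1.0:
            raise ValueError("miss probability must be in [0, 1]")
        if not 0.0 <= self.decoy_rate <= 1.0:
            raise ValueError("decoy rate must be in [0, 1]")
        if any(v < 0 for v in self.jitter_by_nucleus.values()):
            raise ValueError("jitter sds must be >= 0")
        if self.intensity_sigma < 0:
            raise ValueError("intensity sigma must be >= 0")

    @staticmethod
    def noiseless(seed: int = 0) -> "NoiseModel":
        return NoiseModel(
            jitter_by_nucleus={k: 0.0 for k in ("H", "HN", "N", "C", "Cprime")},
            intensity_sigma=0.0, miss_probability=0.0, decoy_rate=0.0, seed=seed,
        )


@dataclass
class ToyGroundTruth:
    topology: Topology
    topology_bound: Topology
    coords: np.ndarray          # apo structured form
    coords_bound: np.ndarray    # metal-bound form (includes the Ag atom row)
    metal_position: np.ndarray
    site_residues: tuple[int, ...]
    strand_segments: tuple[tuple[int, int], ...]
    loop_segments: tuple[tuple[int, int], ...]
    sheet_registry: tuple[tuple[int, int], ...]   # paired (i, j) across strands
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def sequence(self) -> str:
        return "".join(self.topology.sequence[r] for r in self.topology.residue_indices)

    @property
    def strand_residues(self) -> set[int]:
        return {r for a, b in self.strand_segments for r in range(a, b + 1)}

    def beta_probabilities(self) -> dict[int, float]:
        return {
            r: (0.9 if r in self.strand_residues else 0.1)
            for r in self.topology.residue_indices
        }

    def dihedral_predictions(self):
        """TALOS-like records from the true coordinates; strands are Strong."""
        from .io import DihedralPrediction

        dihedrals = chemshift.backbone_dihedrals(self.topology, self.coords)
        out = []
        for res, (phi, psi) in dihedrals.items():
            strong = res in self.strand_residues
            for name, val in (("phi", phi), ("psi", psi)):
                if val is None:
                    continue
                out.append(DihedralPrediction(
                    res, name, float(np.clip(val, -180.0, 180.0)),
                    10.0 if strong else 25.0,
                    "Strong" if strong else "Dyn",
                ))
        return out

    def dispersion(self) -> dict[tuple[int, str], float]:
        """Deterministic per-resonance structural dispersion of the S form.

        Magnitudes reflect a well-folded mini-domain (amide protons spread
        over roughly 7.5-9.5 ppm, nitrogens over tens of ppm); the
        unstructured form stays clustered near coil values.
        """
        rng = np.random.default_rng([self.seed % (2**31), 11])
        sd = {"H": 0.45, "HN": 0.45, "N": 3.5, "C": 1.8, "Cprime": 1.8}
        out = {}
        for res in self.topology.residue_indices:
            for atom in chemshift.SHIFT_ATOMS:
                if self.topology.has_atom(res, atom):
                    out[(res, atom)] = float(
                        rng.normal(0.0, sd[infer_nucleus(atom)])
                    )
        return out

    def u_form_dispersion(self) -> dict[tuple[int, str], float]:
        rng = np.random.default_rng([self.seed % (2**31), 13])
        sd = {"H": 0.04, "HN": 0.04, "N": 0.4, "C": 0.25, "Cprime": 0.25}
        out = {}
        for res in self.topology.residue_indices:
            for atom in chemshift.SHIFT_ATOMS:
                if self.topology.has_atom(res, atom):
                    out[(res, atom)] = float(
                        rng.normal(0.0, sd[infer_nucleus(atom)])
                    )
        return out

    def structure_offsets(self) -> dict[tuple[int, str], float]:
        """True S-minus-U shift difference per resonance (noise-free)."""
        s_base = chemshift.predict_shifts(self.topology, self.coords)
        disp = self.dispersion()
        u_disp = self.u_form_dispersion()
        out = {}
        for key, s_val in s_base.items():
            res, atom = key
            coil = _coil_value(self.topology.residue_type(res), atom)
            out[key] = (s_val + disp[key]) - (coil + u_disp[key])
        return out


def _coil_value(rtype: str, atom: str) -> float:
    if atom == "QB":
        return chemshift.RANDOM_COIL_QB[rtype]
    return chemshift.RANDOM_COIL[rtype][atom]


def _ca_trace(n: int) -> tuple[np.ndarray, dict]:
    """CA positions for G + strand1 + loop1 + strand2 + loop2 + strand3 + G."""
    rise, sep = 3.4, 4.8
    x_end = rise * (n - 1)
    trace: list[np.ndarray] = []
    seg: dict[str, list[int]] = {k: [] for k in
                                 ("strand1", "loop1", "strand2", "loop2", "strand3")}

    def add(p, segment=None):
        trace.append(np.asarray(p, dtype=float))
        if segment:
            seg[segment].append(len(trace))  # 1-based residue index

    add([-rise, -1.5, 0.5])  # N-terminal G, off the sheet
    for i in range(n):
        add([i * rise, 0.0, 0.4 * (-1) ** i], "strand1")
    # loop1 arches over the sheet face so its residues pack against the strands
    loop1 = [
        [3.0, 0.5, 1.5], [5.2, 1.6, 3.4], [3.8, 2.4, 5.2],
        [0.8, 3.2, 5.4], [-1.6, 4.0, 3.8], [-1.0, 4.6, 1.6],
    ]
    for dx, dy, z in loop1:
        add([x_end + dx, dy, z], "loop1")
    for i in range(n):
        add([x_end - i * rise, sep, 0.4 * (-1) ** (i + 1)], "strand2")
    # loop2: compact knuckle whose three site residues triangulate the tip
    loop2 = [
        [-3.4, sep + 0.2, 1.2],
        [-6.4, sep + 0.7, 2.4],
        [-8.9, sep + 1.5, 1.4],
        [-10.6, sep + 2.4, -0.4],
        [-8.9, sep + 3.3, -1.6],
        [-6.4, sep + 4.1, -0.6],
        [-3.4, sep + 4.6, 0.6],
    ]
    for p in loop2:
        add(p, "loop2")
    for i in range(n):
        add([i * rise, 2 * sep, 0.4 * (-1) ** i], "strand3")
    add([x_end + rise, 2 * sep + 1.5, 0.5])  # C-terminal G
    return np.vstack(trace), seg


def make_toy_fold(n_strand_residues: int = 6, seed: int = 0) -> ToyGroundTruth:
    """Construct the toy fold with ideal local geometry.

    Three antiparallel strands of ``n_strand_residues`` connected by two
    loops; the second loop hosts three cysteines whose SG atoms form a
    near-trigonal site (pairwise S-S within 3.8-4.2 Å, matching the ideal
    2·2.3·sin 60° ≈ 3.98 Å of a trigonal thiolate site).

    Construction is a torsion-space loop-closure: strand backbones are held
    at ideal β torsions while each loop's torsions are optimized (with
    multistart) to close the antiparallel hydrogen-bond ladder of the next
    strand — the donor/acceptor parity of each interface is chosen by trying
    both — and, for the second loop, the trigonal sulfur site.  A final
    all-torsion refinement plus gentle Cartesian relaxation leaves an
    essentially strain-free structure on the package's own geometry model.
    """
    n = n_strand_residues
    total = 3 * n + len(LOOP1_PATTERN) + len(LOOP2_PATTERN) + 2
    if n < 3 or not 15 <= total <= 40:
        raise ValueError(
            f"total residue count {total} (strands of {n}) outside the "
            "supported range [15, 40]")

    trace, seg = _ca_trace(n)
    strands = lambda k: "".join(STRAND_PATTERN[i % len(STRAND_PATTERN)] for i in range(k))
    sequence = "G" + strands(n) + LOOP1_PATTERN + strands(n) + LOOP2_PATTERN + strands(n) + "G"
    loop2_first = seg["loop2"][0]
    site = (loop2_first + 1, loop2_first + 3, loop2_first + 5)
    site_atoms = [(r, "SG") for r in site]
    # side-chain beta pseudo-protons everywhere they exist (NOESY coverage)
    proton_atoms = [(k + 1, "QB") for k, aa in enumerate(sequence) if aa != "G"]

    topology = build_topology(sequence, restraint_atoms=site_atoms + proton_atoms)
    topology_bound = build_topology(sequence, restraint_atoms=site_atoms + proton_atoms,
                                    with_metal=True)

    from dataclasses import replace

    from .engine import EnergyModel, EnergyWeights, TorsionBuilder, _minimize, _torsion_minimize
    from .restraints import DihedralRestraint

    rng = np.random.default_rng([seed % (2**31), 3])
    s1, s2, s3 = seg["strand1"], seg["strand2"], seg["strand3"]
    strand_res = set(s1 + s2 + s3)
    registry = [(s1[i], s2[n - 1 - i]) for i in range(n)]
    registry += [(s2[i], s3[n - 1 - i]) for i in range(n)]

    tb = TorsionBuilder(topology)
    w = EnergyWeights()
    tau = tb.default_torsions()
    for i, (name, res) in enumerate(tb.variables):
        if name in ("phi", "psi") and res in strand_res:
            tau[i] = -139.0 if name == "phi" else 135.0

    def free_mask(residues):
        mask = np.zeros(tb.n_variables(), bool)
        for i, (name, res) in enumerate(tb.variables):
            if res in residues:
                mask[i] = True
        return mask

    def ladder(sa, sb, parity):
        out = []
        for k in range(n):
            if k % 2 != parity:
                continue
            a, b = sa[k], sb[n - 1 - k]
            for hn_res, o_res in ((a, b), (b, a)):
                out.append(DistanceRestraint(
                    member_pairs=(((hn_res, "HN"), (o_res, "O")),),
                    target=1.9, lower=1.8, upper=2.0, kind="hbond"))
            out.append(DistanceRestraint(
                member_pairs=(((a, "CA"), (b, "CA")),),
                target=5.0, lower=4.8, upper=5.2, kind="hbond", weight=0.5))
        return out

    ss_ideal = 2.0 * 2.3 * math.sin(math.radians(60.0))
    site_rs = [
        DistanceRestraint(member_pairs=(((site[a], "SG"), (site[b], "SG")),),
                          target=ss_ideal, lower=ss_ideal, upper=ss_ideal,
                          kind="metal_implicit", weight=4.0)
        for a, b in ((0, 1), (0, 2), (1, 2))
    ]

    def close_loop(tau, loop_residues, extra_rs, parities, n_trials):
        """Optimize one loop's torsions to close the next interface."""
        mask = free_mask(set(loop_residues))
        best = None
        for parity in parities:
            rs_i = RestraintSet(distances=extra_rs(parity))
            model = EnergyModel(topology, rs_i, replace(
                w, bond=0.0, angle=0.0, planarity=0.0, chirality=0.0,
                repulsion=w.repulsion * 0.5, hbond=20.0, metal_bond=80.0))
            for trial in range(n_trials):
                tau_t = tau.copy()
                if trial:
                    tau_t[mask] += rng.normal(0.0, 25.0, mask.sum())
                tau_t = _torsion_minimize(tb, model, tau_t, 300, mask)
                x = tb.build(tau_t)
                e, _ = model(x.ravel())
                if best is None or e < best[0]:
                    best = (e, tau_t, parity)
        return best

    _, tau, par1 = close_loop(tau, seg["loop1"],
                              lambda p: ladder(s1, s2, p), (0, 1), 3)
    _, tau, par2 = close_loop(
        tau, seg["loop2"],
        lambda p: ladder(s2, s3, p) + ladder(s1, s2, par1) + site_rs, (0, 1), 4)

    bonded_pairs = [(s1[i], s2[n - 1 - i]) for i in range(n) if i % 2 == par1]
    bonded_pairs += [(s2[i], s3[n - 1 - i]) for i in range(n) if i % 2 == par2]
    dihedrals = [DihedralRestraint(r, a, t, 25.0)
                 for r in sorted(strand_res) for a, t in (("phi", -139.0), ("psi", 135.0))]
    rs = RestraintSet(
        distances=ladder(s1, s2, par1) + ladder(s2, s3, par2) + site_rs,
        dihedrals=dihedrals, metal_site=tuple(site_atoms))

    w_cons = replace(w, hbond=20.0, metal_bond=80.0)
    model = EnergyModel(topology, rs, replace(
        w_cons, bond=0.0, angle=0.0, planarity=0.0, chirality=0.0))
    tau = _torsion_minimize(tb, model, tau, 300)
    x = tb.build(tau)
    model_full = EnergyModel(topology, rs, replace(
        w_cons, bond=w.bond * 0.2, angle=w.angle * 0.2, planarity=w.planarity * 0.2))
    x, _ = _minimize(model_full, x, 400)
    model_full.w = w_cons
    x, e_final = _minimize(model_full, x, 2500)

    sg_idx = [topology.atom_index(r, "SG") for r in site]
    ss = [float(np.linalg.norm(x[a] - x[b]))
          for a, b in ((sg_idx[0], sg_idx[1]), (sg_idx[0], sg_idx[2]),
                       (sg_idx[1], sg_idx[2]))]
    if not all(3.8 <= d <= 4.2 for d in ss):
        raise RuntimeError(f"construction failed: S-S distances {ss}")

    # bound form: same fold refined under explicit coordination restraints,
    # started from perturbed metal-loop torsions so the loops settle
    # slightly differently (the strand core is pinned by its restraints)
    rs_bound = RestraintSet(
        distances=ladder(s1, s2, par1) + ladder(s2, s3, par2),
        dihedrals=list(dihedrals))
    rs_bound.extend(make_metal_restraints(site_atoms, mode="explicit"))
    tau_b = tau.copy()
    loop_mask = free_mask(set(seg["loop1"]) | set(seg["loop2"]))
    tau_b[loop_mask] += rng.normal(0.0, 12.0, loop_mask.sum())
    tb_b = TorsionBuilder(topology_bound)
    model_b = EnergyModel(topology_bound, rs_bound, replace(
        w_cons, bond=0.0, angle=0.0, planarity=0.0, chirality=0.0))
    tau_b = _torsion_minimize(tb_b, model_b, tau_b, 400)
    x_b = tb_b.build(tau_b)
    from .engine import _init_metal
    model_bf = EnergyModel(topology_bound, rs_bound, replace(
        w_cons, bond=w.bond * 0.2, angle=w.angle * 0.2, planarity=w.planarity * 0.2))
    _init_metal(model_bf, x_b)
    x_b, _ = _minimize(model_bf, x_b, 400)
    model_bf.w = w_cons
    x_b, _ = _minimize(model_bf, x_b, 2000)

    metal_idx = topology_bound.atom_index(0, "AG")
    segments = {
        "strand1": (s1[0], s1[-1]), "strand2": (s2[0], s2[-1]),
        "strand3": (s3[0], s3[-1]),
        "loop1": (seg["loop1"][0], seg["loop1"][-1]),
        "loop2": (seg["loop2"][0], seg["loop2"][-1]),
    }
    return ToyGroundTruth(
        topology=topology,
        topology_bound=topology_bound,
        coords=x,
        coords_bound=x_b,
        metal_position=x_b[metal_idx].copy(),
        site_residues=site,
        strand_segments=(segments["strand1"], segments["strand2"], segments["strand3"]),
        loop_segments=(segments["loop1"], segments["loop2"]),
        sheet_registry=tuple(registry),
        seed=seed,
        params={"n_strand_residues": n, "ss_distances": ss,
                "bonded_pairs": bonded_pairs, "construction_energy": float(e_final)},
    )


# ---------------------------------------------------------------------------
# shifts
# ---------------------------------------------------------------------------

def simulate_shifts(truth: ToyGroundTruth, forms=("S", "U"),
                    noise: NoiseModel | None = None) -> ShiftTable:
    """Two-form shift table: U = coil + dispersion, S = forward model + dispersion.

    Measurement jitter from ``noise`` is added on top of the deterministic
    truth values; a noiseless model reproduces the truth exactly.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng([noise.seed % (2**31), 17])
    s_base = chemshift.predict_shifts(truth.topology, truth.coords)
    disp = truth.dispersion()
    u_disp = truth.u_form_dispersion()
    table = ShiftTable()
    for res in truth.topology.residue_indices:
        rtype = truth.topology.residue_type(res)
        for atom in chemshift.SHIFT_ATOMS:
            if not truth.topology.has_atom(res, atom) or (res, atom) not in s_base:
                continue
            nuc = infer_nucleus(atom)
            jit = noise.jitter_by_nucleus.get(nuc, 0.0)
            if "S" in forms:
                val = s_base[(res, atom)] + disp[(res, atom)]
                table.add(ShiftEntry(res, rtype, atom, nuc,
                                     val + rng.normal(0.0, jit) if jit else val, "S"))
            if "U" in forms:
                val = _coil_value(rtype, atom) + u_disp[(res, atom)]
                table.add(ShiftEntry(res, rtype, atom, nuc,
                                     val + rng.normal(0.0, jit) if jit else val, "U"))
    return table


# ---------------------------------------------------------------------------
# NOESY
# ---------------------------------------------------------------------------

def simulate_noesy(
    truth: ToyGroundTruth,
    shifts: ShiftTable,
    cutoff: float = 5.0,
    noise: NoiseModel | None = None,
    bound: bool = False,
):
    """NOESY peaks plus the hidden true-assignment map.

    One peak per S-form proton pair closer than ``cutoff`` in the true
    structure, intensity k r^-6 under log-normal noise, positions from the
    S-form shifts with per-nucleus jitter.  Pairs involving an amide proton
    are emitted as amide-anchored 3D peaks (dims H, HN, N — the
    nitrogen-edited experiment), other pairs as 2D proton-proton peaks (the
    carbon-edited spectrum reduced to its proton axes).  Decoys are drawn
    from U-form intra-residue and sequential proton pairs.  Returns
    ``(peaks, truth_map)`` where ``truth_map[peak_id]`` is the generating
    ((res, atom), (res, atom)) pair or ``None`` for a decoy.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng([noise.seed % (2**31), 23])
    top = truth.topology
    protons = [(r, a) for (r, a) in top.protons()]
    # the bound form shares the apo atom ordering (metal is appended last)
    coords = truth.coords_bound[:top.n_atoms] if bound else truth.coords
    kscale = 1.0e4 * cutoff ** 6

    def shift_of(res, atom, form):
        e = shifts.get(res, atom, form)
        return None if e is None else e.shift

    jit_h = noise.jitter_by_nucleus.get("H", 0.0)
    jit_n = noise.jitter_by_nucleus.get("N", 0.0)

    def jit(val, sd):
        return val + (rng.normal(0.0, sd) if sd else 0.0)

    peaks = PeakList()
    truth_map: dict[str, tuple | None] = {}
    counter = 0

    def emit(pair, form, intensity):
        """Amide-anchored 3D peak if an HN is involved, else 2D H-H."""
        nonlocal counter
        (ri, ai), (rj, aj) = pair
        if aj != "HN" and ai == "HN":
            (ri, ai), (rj, aj) = (rj, aj), (ri, ai)
        counter += 1
        pid = f"x{counter}"
        si = shift_of(ri, ai, form)
        sj = shift_of(rj, aj, form)
        if si is None or sj is None:
            counter -= 1
            return False
        if aj == "HN":
            sn = shift_of(rj, "N", form)
            if sn is None:
                counter -= 1
                return False
            peaks.add(Peak(pid, ("H", "HN", "N"),
                           (jit(si, jit_h), jit(sj, jit_h), jit(sn, jit_n)),
                           intensity))
        else:
            peaks.add(Peak(pid, ("H", "H"), (jit(si, jit_h), jit(sj, jit_h)),
                           intensity))
        truth_map[pid] = ((ri, ai), (rj, aj))
        return True

    for i in range(len(protons)):
        for j in range(i + 1, len(protons)):
            ri, ai = protons[i]
            rj, aj = protons[j]
            d = float(np.linalg.norm(
                coords[top.atom_index(ri, ai)] - coords[top.atom_index(rj, aj)]))
            if d >= cutoff:
                continue
            if rng.random() < noise.miss_probability:
                continue
            inten = kscale * d ** -6.0
            if noise.intensity_sigma:
                inten *= float(np.exp(rng.normal(0.0, noise.intensity_sigma)))
            emit(((ri, ai), (rj, aj)), "S", inten)

    n_true = len(peaks)
    n_decoys = int(round(noise.decoy_rate * n_true))
    residues = top.residue_indices
    made = 0
    while made < n_decoys:
        res = int(rng.choice(residues))
        choice = rng.integers(0, 3)
        if choice == 0:
            pair = ((res, "HA"), (res, "HN"))
        elif choice == 1 and (res - 1) in top.sequence:
            pair = ((res - 1, "HA"), (res, "HN"))
        elif choice == 2 and (res + 1) in top.sequence:
            pair = ((res, "HN"), (res + 1, "HN"))
        else:
            continue
        r_fake = float(rng.uniform(2.4, 3.6))
        inten = kscale * r_fake ** -6.0
        if noise.intensity_sigma:
            inten *= float(np.exp(rng.normal(0.0, noise.intensity_sigma)))
        if emit(pair, "U", inten):
            made += 1
            truth_map[f"x{counter}"] = None
    return peaks, truth_map


def true_noe_restraints(truth: ToyGroundTruth, peaks: PeakList, truth_map,
                        d_max: float = 4.25):
    """Unambiguous NOE restraints from the generator's own assignments."""
    from .restraints import make_noe_restraint

    true_peaks = [p for p in peaks if truth_map.get(p.peak_id) is not None]
    if not true_peaks:
        return []
    i_min = min(p.intensity for p in true_peaks)
    out = []
    for p in true_peaks:
        pair = truth_map[p.peak_id]
        pseudo = sum(1.0 for _, atom in pair if atom.startswith("Q"))
        out.append(make_noe_restraint([pair], p.intensity, i_min, d_max,
                                      pseudo_correction=pseudo, source=p.peak_id))
    return out


# ---------------------------------------------------------------------------
# titration
# ---------------------------------------------------------------------------

def bound_fraction(ratio: float, kd: float) -> float:
    """Single-site stoichiometric binding at unit protein concentration."""
    b = 1.0 + ratio + kd
    return (b - math.sqrt(max(b * b - 4.0 * ratio, 0.0))) / 2.0


DEFAULT_RATIOS = (0.0, 0.25, 0.5, 0.75, 1.0, 1.2)


def hsqc_assignments(truth: ToyGroundTruth) -> dict[str, tuple[int, str, str]]:
    """peak_id -> (residue, residue_type, form) for the simulated HSQC series."""
    out = {}
    for res in truth.topology.residue_indices:
        rtype = truth.topology.residue_type(res)
        if truth.topology.has_atom(res, "HN"):
            out[f"S{res}"] = (res, rtype, "S")
            out[f"U{res}"] = (res, rtype, "U")
    return out


def simulate_titration(
    truth: ToyGroundTruth,
    ratios=DEFAULT_RATIOS,
    kd: float = 0.005,
    noise: NoiseModel | None = None,
    dropout_window: tuple[float, float] = (0.2, 0.8),
    s_population_apo: float = 0.55,
) -> TitrationSeries:
    """HSQC titration series with fast/intermediate-exchange phenomenology.

    Non-site S-form peaks drift linearly with the bound fraction; site
    residues drop out while the bound fraction is inside ``dropout_window``
    (intermediate exchange) and reappear, strongly shifted, near saturation;
    U-form peak intensities scale with the remaining free population.
    """
    noise = noise or NoiseModel()
    ratios = list(ratios)
    if not ratios or ratios[0] != 0.0:
        raise ValueError("titration ratios must start at 0 (apo reference)")
    rng_truth = np.random.default_rng([truth.seed % (2**31), 29])
    rng_noise = np.random.default_rng([noise.seed % (2**31), 31])
    top = truth.topology
    shifts = simulate_shifts(truth, forms=("S", "U"), noise=NoiseModel.noiseless())

    site = set(truth.site_residues)
    ca = {r: truth.coords[top.atom_index(r, "CA")] for r in top.residue_indices}
    site_center = np.mean([ca[r] for r in site], axis=0)

    # endpoint perturbations per residue (deterministic truth)
    deltas: dict[int, tuple[float, float]] = {}
    for res in top.residue_indices:
        if res in site:
            dh, dn = 0.35, 3.0
        elif float(np.linalg.norm(ca[res] - site_center)) < 9.0:
            dh, dn = 0.08, 0.8
        else:
            dh, dn = 0.02, 0.2
        sh = 1.0 if rng_truth.random() < 0.5 else -1.0
        sn = 1.0 if rng_truth.random() < 0.5 else -1.0
        scale = float(rng_truth.uniform(0.8, 1.2))
        deltas[res] = (sh * dh * scale, sn * dn * scale)

    jit_h = noise.jitter_by_nucleus.get("HN", 0.0)
    jit_n = noise.jitter_by_nucleus.get("N", 0.0)
    lo, hi = dropout_window
    i_s0, i_u0 = 1.0e6, 1.3e6

    points = []
    for k, ratio in enumerate(ratios):
        f = bound_fraction(ratio, kd)
        plist = PeakList()
        for res in top.residue_indices:
            if not top.has_atom(res, "HN"):
                continue
            hn = shifts.get(res, "HN", "S").shift
            nn = shifts.get(res, "N", "S").shift
            dh, dn = deltas[res]
            if res in site and lo < f < hi:
                pass  # broadened beyond detection
            else:
                jh = rng_noise.normal(0.0, jit_h) if (jit_h and k > 0) else 0.0
                jn = rng_noise.normal(0.0, jit_n) if (jit_n and k > 0) else 0.0
                inten = i_s0 * (s_population_apo + (1.0 - s_population_apo) * f)
                plist.add(Peak(f"S{res}", ("HN", "N"),
                               (hn + f * dh + jh, nn + f * dn + jn), inten))
            uh = shifts.get(res, "HN", "U").shift
            un = shifts.get(res, "N", "U").shift
            u_int = i_u0 * max(1.0 - f, 1e-4)
            jh = rng_noise.normal(0.0, jit_h) if (jit_h and k > 0) else 0.0
            jn = rng_noise.normal(0.0, jit_n) if (jit_n and k > 0) else 0.0
            plist.add(Peak(f"U{res}", ("HN", "N"), (uh + jh, un + jn), u_int))
        points.append((float(ratio), plist))
    return TitrationSeries(points)
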