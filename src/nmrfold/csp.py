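"""Chemical-shift comparison between states and titration peak tracking.

The per-residue statistic is the weighted, truncated mean of squared shift
differences

    value(res) = (1/n) * sum_i  chi(|d_a_i - d_b_i| / sigma_i, tau_i)

over the residue's n atoms present in both tables, with the truncation

    chi(x, tau) = x**2  if x >= 2*tau  else 0.

sigma scales the raw ppm difference per nucleus (1.0 for protons, 10.0 for
nitrogen, 4.0 for carbon), so differences of different nuclei are compared on
a common axis; tau is the per-atom-class noise floor on that same scaled
axis, estimated from residues known to be unstructured in both states.

Despite the conventional "rms" name the statistic is, as defined above, a
mean of truncated squares; ``apply_sqrt`` restores a root-mean-square scale
when set.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import PeakList, ShiftTable, TitrationSeries

log = logging.getLogger(__name__)

DEFAULT_SIGMA = {"H": 1.0, "HN": 1.0, "N": 10.0, "C": 4.0, "Cprime": 4.0}
#: scaled-axis truncation thresholds per nucleus class
DEFAULT_TAU = {
    "HN": 0.01977,
    "N": 0.01761,
    "Cprime": 0.01780,
    "H": 0.02620,
    "C": 0.042974,
}


@dataclass
class CspConfig:
    sigma_by_nucleus: dict = field(default_factory=lambda: dict(DEFAULT_SIGMA))
    tau_by_atomclass: dict = field(default_factory=lambda: dict(DEFAULT_TAU))
    apply_sqrt: bool = False

    def __post_init__(self):
        if any(s <= 0 for s in self.sigma_by_nucleus.values()):
            raise ValueError("sigma weights must be > 0")
        if any(t < 0 for t in self.tau_by_atomclass.values()):
            raise ValueError("tau thresholds must be >= 0")

    def sigma(self, nucleus: str) -> float:
        return self.sigma_by_nucleus[nucleus]

    def tau(self, nucleus: str) -> float:
        return self.tau_by_atomclass[nucleus]


@dataclass
class CspProfile:
    values: dict[int, float]
    atoms: dict[int, list[str]]
    config: CspConfig

    def __getitem__(self, residue_index: int) -> float:
        return self.values[residue_index]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "residue_index": sorted(self.values),
                "delta_rms": [self.values[r] for r in sorted(self.values)],
                "n_atoms": [len(self.atoms[r]) for r in sorted(self.values)],
            }
        )


def compute_delta_rms(
    shifts_a: ShiftTable,
    shifts_b: ShiftTable,
    config: CspConfig | None = None,
    form_a: str | None = None,
    form_b: str | None = None,
) -> CspProfile:
    """Per-residue weighted truncated shift difference between two tables.

    Atoms are matched on (residue_index, atom_name); ``form_a``/``form_b``
    optionally restrict each table to one conformational form (so the same
    table can be compared S against U).  Residues with no shared atoms are
    absent from the profile rather than reported as zero.
    """
    config = config or CspConfig()
    a_entries = [e for e in shifts_a if form_a is None or e.form == form_a]
    b_index = {
        (e.residue_index, e.atom_name): e
        for e in shifts_b
        if form_b is None or e.form == form_b
    }
    per_res: dict[int, list[float]] = {}
    per_atoms: dict[int, list[str]] = {}
    for ea in a_entries:
        eb = b_index.get((ea.residue_index, ea.atom_name))
        if eb is None:
            continue
        x = abs(ea.shift - eb.shift) / config.sigma(ea.nucleus)
        chi = x * x if x >= 2.0 * config.tau(ea.nucleus) else 0.0
        per_res.setdefault(ea.residue_index, []).append(chi)
        per_atoms.setdefault(ea.residue_index, []).append(ea.atom_name)

    all_res = {e.residue_index for e in a_entries}
    missing = all_res - set(per_res)
    if missing:
        log.info("no shared atoms for residues %s; omitted from profile", sorted(missing))

    values = {}
    for res, chis in per_res.items():
        v = float(np.mean(chis))
        values[res] = math.sqrt(v) if config.apply_sqrt else v
    return CspProfile(values=values, atoms=per_atoms, config=config)


def estimate_tau(
    shifts_a: ShiftTable,
    shifts_b: ShiftTable,
    reference_residues,
    config: CspConfig | None = None,
    form_a: str | None = None,
    form_b: str | None = None,
) -> dict[str, float]:
    """Noise-floor thresholds from unstructured reference residues.

    Per nucleus class, the sample (n-1) standard deviation of the
    sigma-scaled differences over the reference residues; classes with fewer
    than two observations fall back to the configured default with a warning.
    """
    config = config or CspConfig()
    refset = set(reference_residues)
    if not refset:
        raise ValueError("reference residue set is empty")
    b_index = {
        (e.residue_index, e.atom_name): e
        for e in shifts_b
        if form_b is None or e.form == form_b
    }
    diffs: dict[str, list[float]] = {}
    for ea in shifts_a:
        if form_a is not None and ea.form != form_a:
            continue
        if ea.residue_index not in refset:
            continue
        eb = b_index.get((ea.residue_index, ea.atom_name))
        if eb is None:
            continue
        diffs.setdefault(ea.nucleus, []).append(
            (ea.shift - eb.shift) / config.sigma(ea.nucleus)
        )
    out: dict[str, float] = {}
    for cls, default in config.tau_by_atomclass.items():
        obs = diffs.get(cls, [])
        if len(obs) < 2:
            warnings.warn(
                f"tau class {cls}: {len(obs)} reference observation(s); "
                f"falling back to default {default}",
                stacklevel=2,
            )
            out[cls] = default
        else:
            out[cls] = float(np.std(obs, ddof=1))
    return out


# ---------------------------------------------------------------------------
# titration tracking
# ---------------------------------------------------------------------------

MATCHED = "matched"
BROADENED = "broadened_out"
REAPPEARED = "reappeared"


@dataclass
class PeakTrajectory:
    peak_id: str
    statuses: list[str]
    positions: list[tuple[float, ...] | None]
    drift: tuple[float, ...]

    @property
    def ever_broadened(self) -> bool:
        return BROADENED in self.statuses

    @property
    def reappeared(self) -> bool:
        return REAPPEARED in self.statuses


def track_titration(
    series: TitrationSeries,
    matching_radius_by_nucleus: dict[str, float],
    unmatched_penalty: float = 3.0,
    continuation_fraction: float = 0.3,
) -> list[PeakTrajectory]:
    """Follow each apo peak across the titration point to point.

    Matching happens in two stages per point, each an optimal assignment
    minimizing the total radius-scaled displacement.  First, trajectories
    that were visible at the previous point are matched within tight radii
    (``continuation_fraction`` of the full radii) — under fast exchange a
    visible peak moves only a little per step.  Then every still-unmatched
    trajectory, in particular those broadened out earlier, competes for the
    leftover peaks within the full radii; this is where strongly shifted
    reappearing peaks are picked up without stealing a continuing
    neighbor's peak.  Candidates outside the radii are infeasible and an
    unmatched trajectory costs ``unmatched_penalty`` scaled units.  A peak
    with no match is ``broadened_out`` at that point; a first match after a
    gap is ``reappeared``.
    """
    from scipy.optimize import linear_sum_assignment

    if len(series.points) < 2:
        raise ValueError("titration series needs at least two points")
    for nuc, r in matching_radius_by_nucleus.items():
        if r <= 0:
            raise ValueError(f"matching radius for {nuc} must be > 0")

    _, apo = series.points[0]
    trajectories = [
        PeakTrajectory(p.peak_id, [MATCHED], [p.position], tuple(0.0 for _ in p.position))
        for p in apo
    ]
    last_pos = {t.peak_id: t.positions[0] for t in trajectories}
    dims = apo.dims or ()
    radii = np.array([matching_radius_by_nucleus[d] for d in dims])
    infeasible = 1e6

    def assign(t_indices, p_indices, peaks, scale):
        if not t_indices or not p_indices:
            return {}
        cost = np.full((len(t_indices), len(p_indices) + len(t_indices)),
                       infeasible)
        for row, ti in enumerate(t_indices):
            ref = np.array(last_pos[trajectories[ti].peak_id])
            cost[row, len(p_indices) + row] = unmatched_penalty
            for col, pi in enumerate(p_indices):
                delta = (np.array(peaks[pi].position) - ref) / (radii * scale)
                if np.all(np.abs(delta) <= 1.0):
                    cost[row, col] = float(np.sqrt(np.sum(delta ** 2)))
        rows, cols = linear_sum_assignment(cost)
        return {
            t_indices[r]: p_indices[c] for r, c in zip(rows, cols)
            if c < len(p_indices) and cost[r, c] < infeasible
        }

    for _, plist in series.points[1:]:
        peaks = list(plist)
        visible = [ti for ti, t in enumerate(trajectories)
                   if t.statuses[-1] != BROADENED]
        match_of = assign(visible, list(range(len(peaks))), peaks,
                          continuation_fraction)
        remaining_t = [ti for ti in range(len(trajectories))
                       if ti not in match_of]
        leftover_p = [pi for pi in range(len(peaks))
                      if pi not in match_of.values()]
        match_of.update(assign(remaining_t, leftover_p, peaks, 1.0))
        for ti, traj in enumerate(trajectories):
            if ti in match_of:
                p = peaks[match_of[ti]]
                was_gone = traj.statuses and traj.statuses[-1] == BROADENED
                traj.statuses.append(REAPPEARED if was_gone else MATCHED)
                traj.positions.append(p.position)
                last_pos[traj.peak_id] = p.position
            else:
                traj.statuses.append(BROADENED)
                traj.positions.append(None)

    for traj in trajectories:
        final = next((p for p in reversed(traj.positions) if p is not None), None)
        start = traj.positions[0]
        traj.drift = tuple(f - s for f, s in zip(final, start)) if final else traj.drift
    return trajectories


def rank_binding_site(profile: CspProfile, k: int) -> list[tuple[int, float]]:
    """Top-k residues by profile value, descending; zeros never rank."""
    if not profile.values:
        raise ValueError("empty CSP profile")
    nonzero = [(r, v) for r, v in profile.values.items() if v > 0]
    if not nonzero:
        log.info("flat zero CSP profile; empty ranking")
        return []
    ranked = sorted(nonzero, key=lambda rv: (-rv[1], rv[0]))
    if k > len(ranked):
        warnings.warn(
            f"requested top-{k} but only {len(ranked)} residues have nonzero values",
            stacklevel=2,
        )
    return ranked[:k]


def shifts_from_hsqc(peaks: PeakList, assignments: dict[str, tuple[int, str]],
                     residue_types: dict[int, str] | None = None,
                     form: str = "S") -> ShiftTable:
    """Build a (HN, N) shift table from an assigned HSQC peak list.

    ``assignments`` maps peak_id -> (residue_index, residue_type).
    """
    from .io import ShiftEntry

    table = ShiftTable()
    for p in peaks:
        if p.peak_id not in assignments:
            continue
        res, rtype = assignments[p.peak_id]
        for dim, pos in zip(p.dims, p.position):
            nuc = "HN" if dim in ("HN", "H") else dim
            atom = "HN" if nuc == "HN" else dim
            table.add(ShiftEntry(res, rtype, atom, nuc if nuc in ("HN", "N") else "H",
                                 pos, form))
    return table
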