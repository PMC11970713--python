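"""Inferential restraint assignment: probabilistic ranking of NOESY
cross-peak assignment possibilities against evolving template structures.

Each candidate assignment of a cross-peak to a proton pair is scored as

    P = P_F * P_D

where P_F measures agreement between the peak position and the assigned
chemical shifts and P_D the probability that the two protons are close
enough to produce an observable peak.  P_F is a unit-max Gaussian kernel
over the dimensions,

    P_F = prod_d exp(-Delta_d^2 / 2),
    Delta_d = (mu_d - a_d) / sqrt(sigma_F_d^2 + gamma_F_d^2),

so the retention gate P_F > 0.07 corresponds to about 2.3 combined
standardized deviations (a density-normalized variant is selectable).
Without a template structure P_D falls back to conservative priors by
residue-separation class; with a template,

    P_D = k_D * Phi( n (r_min - r_0) / sqrt(n^2 sigma_D^2 + gamma_D^2) ),

with n = 6 (the NOE intensity exponent), r_0 the template distance and Phi
the standard normal CDF; over an ensemble P_D is averaged across models.

Refinement proceeds over cycles: candidates with P below P_max / f for
their peak are stripped (strict inequality — the top candidate always
survives), with f and sigma_D following per-cycle schedules that tighten as
the template improves.  Candidates whose protons both belong to the
unstructured (U) form at short sequence separation are excluded up front:
an unstructured chain produces only short-range NOEs, so such peaks carry
no information about the structured form.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .io import Peak, PeakList, ShiftEntry, ShiftTable
from .restraints import RestraintSet, make_noe_restraint

log = logging.getLogger(__name__)

ACTIVE = "active"
STRIPPED = "stripped"
EXCLUDED_U = "excluded_medium_range_U"

SEPARATION_CLASSES = ("intra", "sequential", "rd2", "rd3", "rd4", "long")


def separation_class(delta: int) -> str:
    d = abs(delta)
    if d >= 5:
        return "long"
    return SEPARATION_CLASSES[d]


@dataclass
class IraConfig:
    gamma_f_by_nucleus: dict = field(default_factory=lambda: {
        "N": 0.2, "HN": 0.02, "C": 0.3, "Cprime": 0.3, "H": 0.05,
    })
    pf_threshold: float = 0.07
    n_exponent: float = 6.0
    gamma_d: float = 1.0
    k_d: float = 1.0
    r_min: float = 4.25
    sigma_d_schedule: tuple = (0.15, 0.15, 0.15, 0.1, 0.05)
    f_schedule: tuple = (50.0, 50.0, 20.0, 10.0, 5.0)
    no_template_pd: dict = field(default_factory=lambda: {
        "intra": 1.0, "sequential": 0.5, "rd2": 0.3, "rd3": 0.2,
        "rd4": 0.15, "long": 0.1,
    })
    medium_range_u_limit: int = 4
    normalized_density: bool = False
    sigma_f_floor_factor: float = 0.5   # sigma_F floor = factor * gamma_F
    sigma_f_by_atom: dict = field(default_factory=dict)  # (res, atom, form) -> sd

    def __post_init__(self):
        if len(self.sigma_d_schedule) != len(self.f_schedule):
            raise ValueError(
                "sigma_D and f schedules must have the same length "
                f"({len(self.sigma_d_schedule)} vs {len(self.f_schedule)})"
            )
        if any(f <= 1 for f in self.f_schedule):
            raise ValueError("stripping factors f must be > 1")
        if any(s <= 0 for s in self.sigma_d_schedule):
            raise ValueError("sigma_D values must be > 0")
        if any(g <= 0 for g in self.gamma_f_by_nucleus.values()):
            raise ValueError("gamma_F values must be > 0")
        if not 0 < self.pf_threshold < 1:
            raise ValueError("P_F threshold must be in (0, 1)")

    @property
    def n_cycles(self) -> int:
        return len(self.f_schedule)

    def sigma_f(self, entry: ShiftEntry) -> float:
        key = (entry.residue_index, entry.atom_name, entry.form)
        if key in self.sigma_f_by_atom:
            return self.sigma_f_by_atom[key]
        return self.sigma_f_floor_factor * self.gamma_f_by_nucleus[entry.nucleus]


def estimate_sigma_f(observations: dict) -> dict:
    """Per-resonance sd across repeated observations within a spin system.

    ``observations`` maps (residue, atom, form) -> list of observed ppm
    values; resonances with a single observation are left to the configured
    floor.
    """
    out = {}
    for key, vals in observations.items():
        if len(vals) >= 2:
            out[key] = float(np.std(vals, ddof=1))
    return out


@dataclass
class AssignmentCandidate:
    peak_id: str
    pair: tuple[ShiftEntry, ShiftEntry]
    p_f: float
    p_d: float = 1.0
    status: str = ACTIVE

    @property
    def p(self) -> float:
        return self.p_f * self.p_d

    @property
    def residue_separation(self) -> int:
        return abs(self.pair[0].residue_index - self.pair[1].residue_index)

    @property
    def sep_class(self) -> str:
        return separation_class(self.residue_separation)

    @property
    def atom_pair(self):
        a, b = self.pair
        return ((a.residue_index, a.atom_name), (b.residue_index, b.atom_name))

    @property
    def both_u(self) -> bool:
        return self.pair[0].form == "U" and self.pair[1].form == "U"


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_pf(deviations: Sequence[float], config: IraConfig) -> float:
    """P_F from the per-dimension standardized deviations Delta_d.

    Default convention: unit-max Gaussian kernel product (bounded by 1).
    The density-normalized variant divides by sqrt(2 pi) per dimension.
    """
    d2 = float(np.sum(np.square(deviations)))
    pf = math.exp(-0.5 * d2)
    if config.normalized_density:
        pf /= (2.0 * math.pi) ** (len(deviations) / 2.0)
    return pf


def pf_for_pair(peak: Peak, entries: Sequence[ShiftEntry], config: IraConfig) -> float:
    if len(entries) != len(peak.dims):
        raise ValueError("one shift entry per peak dimension required")
    devs = []
    for a, entry in zip(peak.position, entries):
        gamma = config.gamma_f_by_nucleus[entry.nucleus]
        sigma = config.sigma_f(entry)
        devs.append((entry.shift - a) / math.sqrt(sigma * sigma + gamma * gamma))
    return score_pf(devs, config)


def score_pd(
    candidate: AssignmentCandidate,
    template,
    cycle_index: int,
    config: IraConfig,
) -> float:
    """P_D from the template distance (or the class prior without a template).

    ``template`` must expose ``proton_distance(((res, atom), (res, atom)))``
    returning one distance per ensemble model; P_D is averaged over models.
    """
    if template is None:
        return config.no_template_pd[candidate.sep_class]
    try:
        r0s = template.proton_distance(candidate.atom_pair)
    except KeyError:
        log.debug("candidate %s: atoms missing from template; class prior used",
                  candidate.peak_id)
        warnings.warn(
            f"peak {candidate.peak_id}: candidate atoms absent from template; "
            "falling back to the class prior", stacklevel=2,
        )
        return config.no_template_pd[candidate.sep_class]
    n = config.n_exponent
    sigma_d = config.sigma_d_schedule[cycle_index]
    denom = math.sqrt(n * n * sigma_d * sigma_d + config.gamma_d ** 2)
    vals = [
        config.k_d * float(norm.cdf(n * (config.r_min - r0) / denom))
        for r0 in np.atleast_1d(r0s)
    ]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# candidate generation
# ---------------------------------------------------------------------------

def generate_candidates(
    peaks: PeakList,
    shifts: ShiftTable,
    config: IraConfig | None = None,
) -> list[AssignmentCandidate]:
    """All proton-pair assignments consistent with the peak positions.

    Supports 2D proton-proton peaks (both dims H-type) and amide-anchored
    3D peaks with dims (H, HN, N), where the last two dimensions are matched
    jointly against each residue's amide proton/nitrogen resonance pair.
    Candidates are kept when the joint P_F exceeds the gate.

    A peak with any assignment possibility mapping both protons to U-form
    resonances at sequence separation <= 4 is excluded outright — an
    unstructured chain produces essentially only short-range NOEs, so such
    a peak most likely belongs to the unstructured form and would otherwise
    inject a false constraint into the structured form.  All of the peak's
    candidates are marked ``excluded_medium_range_U`` (kept for audit).
    Peaks with no candidate at all simply produce none (the audit notes
    them as dropped).
    """
    config = config or IraConfig()
    h_entries = shifts.by_nucleus(("H", "HN"))
    amides = []
    for hn in shifts.by_nucleus(("HN",)):
        n_entry = shifts.get(hn.residue_index, "N", hn.form)
        if n_entry is not None:
            amides.append((hn, n_entry))
    # per-dimension pre-filter radius: |Delta| such that exp(-D^2/2) = gate
    dmax = math.sqrt(-2.0 * math.log(config.pf_threshold))

    def deviation(entry, a):
        gamma = config.gamma_f_by_nucleus[entry.nucleus]
        sigma = config.sigma_f(entry)
        return (entry.shift - a) / math.sqrt(sigma * sigma + gamma * gamma)

    out: list[AssignmentCandidate] = []
    for peak in peaks:
        matches_1 = []
        for e in h_entries:
            dev = deviation(e, peak.position[0])
            if abs(dev) <= dmax:
                matches_1.append((e, dev))
        matches_2: list[tuple[ShiftEntry, tuple[float, ...]]] = []
        if len(peak.dims) == 2 and all(d in ("H", "HN") for d in peak.dims):
            for e in h_entries:
                dev = deviation(e, peak.position[1])
                if abs(dev) <= dmax:
                    matches_2.append((e, (dev,)))
        elif tuple(peak.dims) == ("H", "HN", "N"):
            for hn, n_entry in amides:
                dev_h = deviation(hn, peak.position[1])
                dev_n = deviation(n_entry, peak.position[2])
                if abs(dev_h) <= dmax and abs(dev_n) <= dmax:
                    matches_2.append((hn, (dev_h, dev_n)))
        else:
            raise ValueError(
                f"peak {peak.peak_id}: unsupported dimensionality {peak.dims}; "
                "expected 2D proton-proton or 3D (H, HN, N)"
            )
        peak_cands: list[AssignmentCandidate] = []
        likely_u_form = False
        for e1, d1 in matches_1:
            for e2, d2 in matches_2:
                # same physical proton (form labels aside) cannot pair with itself
                if (e1.residue_index, e1.atom_name) == (e2.residue_index, e2.atom_name):
                    continue
                # a cross peak between conformational forms is unphysical:
                # the two forms are distinct molecules in solution
                if e1.form != e2.form:
                    continue
                pf = score_pf((d1, *d2), config)
                if pf <= config.pf_threshold:
                    continue
                cand = AssignmentCandidate(peak.peak_id, (e1, e2), p_f=pf)
                if cand.both_u and cand.residue_separation <= config.medium_range_u_limit:
                    likely_u_form = True
                peak_cands.append(cand)
        if likely_u_form:
            for cand in peak_cands:
                cand.status = EXCLUDED_U
        out.extend(peak_cands)
    return out


def strip_candidates(candidates: Iterable[AssignmentCandidate], f: float) -> None:
    """Strip candidates with P < P_max / f per peak (strict; in place).

    The maximum is taken over the peak's active candidates, so the best
    candidate of every peak always survives and exact ties at the maximum
    are kept.  Stripped candidates keep their scores for audit.
    """
    if f <= 1:
        raise ValueError("stripping factor f must be > 1")
    by_peak: dict[str, list[AssignmentCandidate]] = {}
    for c in candidates:
        if c.status == ACTIVE:
            by_peak.setdefault(c.peak_id, []).append(c)
    for peak_id, cands in by_peak.items():
        p_max = max(c.p for c in cands)
        for c in cands:
            if c.p < p_max / f:
                c.status = STRIPPED


# ---------------------------------------------------------------------------
# iterative cycles
# ---------------------------------------------------------------------------

@dataclass
class CycleAudit:
    cycle: int
    f: float
    sigma_d: float
    n_active: int
    n_stripped: int
    n_excluded: int
    n_peaks_assigned: int
    n_peaks_dropped: int
    n_unambiguous: int

    def as_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class IraResult:
    candidates: list[AssignmentCandidate]
    audit: list[CycleAudit]
    restraints: RestraintSet

    def active(self) -> list[AssignmentCandidate]:
        return [c for c in self.candidates if c.status == ACTIVE]

    def assignments_tsv(self) -> str:
        lines = ["peak_id\tres_i\tatom_i\tform_i\tres_j\tatom_j\tform_j\tp_f\tp_d\tp"]
        for c in self.active():
            a, b = c.pair
            lines.append(
                f"{c.peak_id}\t{a.residue_index}\t{a.atom_name}\t{a.form}"
                f"\t{b.residue_index}\t{b.atom_name}\t{b.form}"
                f"\t{c.p_f:.4g}\t{c.p_d:.4g}\t{c.p:.4g}"
            )
        return "\n".join(lines) + "\n"

    def audit_jsonl(self) -> str:
        return "\n".join(json.dumps(a.as_dict()) for a in self.audit) + "\n"


def restraints_from_candidates(
    peaks: PeakList,
    candidates: Iterable[AssignmentCandidate],
    d_max: float = 4.25,
) -> RestraintSet:
    """Ambiguous NOE restraints from the active candidates, one per peak.

    Member pairs contribute to the effective r^-6 sum with weights
    proportional to their assignment probabilities (normalized per peak),
    so a clearly best candidate dominates its restraint while genuinely
    ambiguous peaks contribute their probability-weighted expectation.
    """
    by_peak: dict[str, list[AssignmentCandidate]] = {}
    for c in candidates:
        if c.status == ACTIVE:
            by_peak.setdefault(c.peak_id, []).append(c)
    if not by_peak:
        return RestraintSet()
    i_min = min(peaks[pid].intensity for pid in by_peak)
    rs = RestraintSet()
    for pid in by_peak:
        cands = by_peak[pid]
        members = [c.atom_pair for c in cands]
        total_p = sum(c.p for c in cands) or 1.0
        weights = tuple(c.p / total_p for c in cands)
        pseudo = max(
            sum(1.0 for _, atom in pair if atom.startswith("Q"))
            for pair in members
        )
        restraint = make_noe_restraint(members, peaks[pid].intensity, i_min,
                                       d_max, pseudo_correction=pseudo,
                                       source=pid)
        restraint.member_weights = weights
        rs.distances.append(restraint)
    return rs


def run_cycles(
    peaks: PeakList,
    shifts: ShiftTable,
    engine: Callable[[RestraintSet], object],
    config: IraConfig | None = None,
    d_max: float = 4.25,
) -> IraResult:
    """The full iterative assignment refinement.

    Cycle 1 scores P_D with the no-template class priors; every later cycle
    rescoring uses the template ensemble the ``engine`` computed from the
    previous cycle's restraints, with that cycle's sigma_D, then strips with
    that cycle's f.  The engine is any callable mapping a RestraintSet to a
    template exposing ``proton_distance``; an engine failure aborts with the
    last completed cycle's state preserved in the raised exception.
    """
    config = config or IraConfig()
    candidates = generate_candidates(peaks, shifts, config)
    audits: list[CycleAudit] = []
    template = None
    n_input = len(peaks)

    for cycle in range(config.n_cycles):
        for c in candidates:
            if c.status == ACTIVE:
                c.p_d = score_pd(c, template, cycle, config)
        strip_candidates(candidates, config.f_schedule[cycle])
        audits.append(_audit(cycle, config, candidates, n_input))
        if cycle < config.n_cycles - 1:
            rs = restraints_from_candidates(peaks, candidates, d_max)
            try:
                template = engine(rs)
            except Exception as exc:
                raise RuntimeError(
                    f"structure engine failed in cycle {cycle + 1}; "
                    f"state after {cycle + 1} completed cycle(s) retained"
                ) from exc

    rs = restraints_from_candidates(peaks, candidates, d_max)
    return IraResult(candidates=candidates, audit=audits, restraints=rs)


def _audit(cycle, config, candidates, n_input_peaks) -> CycleAudit:
    active = [c for c in candidates if c.status == ACTIVE]
    by_peak: dict[str, int] = {}
    for c in active:
        by_peak[c.peak_id] = by_peak.get(c.peak_id, 0) + 1
    return CycleAudit(
        cycle=cycle + 1,
        f=config.f_schedule[cycle],
        sigma_d=config.sigma_d_schedule[cycle],
        n_active=len(active),
        n_stripped=sum(1 for c in candidates if c.status == STRIPPED),
        n_excluded=sum(1 for c in candidates if c.status == EXCLUDED_U),
        n_peaks_assigned=len(by_peak),
        n_peaks_dropped=n_input_peaks - len(by_peak),
        n_unambiguous=sum(1 for n in by_peak.values() if n == 1),
    )
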