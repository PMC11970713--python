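"""End-to-end orchestration: iterative assignment + structure calculation,
and the titration (chemical-shift-perturbation) analysis.

Both pipelines run either on files named in a :class:`RunConfig` or, in
synthetic mode, on data generated on the fly by :mod:`nmrfold.synth` with a
known ground truth.  Configuration files are TOML with sections
``[inputs]``, ``[ira]``, ``[engine]``, ``[metal]``, ``[ncs]``, ``[outputs]``;
every printed constant of the method is the default, so an empty config is
a valid run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import csp, ira, synth
from .engine import (
    AnnealSchedule, Ensemble, EnergyWeights, anneal, anneal_coupled,
    build_topology, select_ensemble,
)
from .io import ShiftTable, TitrationSeries, parse_dihedral_predictions, \
    parse_peak_list, parse_shift_table
from .restraints import (
    RestraintSet, make_dihedral_restraints, make_hbond_restraints,
    make_metal_restraints, make_ncs_coupling,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; file paths may be omitted in
    synthetic mode."""

    # inputs
    shifts_path: str | None = None
    peaks_path: str | None = None
    dihedral_path: str | None = None
    titration_paths: list = field(default_factory=list)
    titration_ratios: list = field(default_factory=list)
    sequence: str | None = None
    modeled_range: tuple[int, int] | None = None
    synthetic: bool = True
    # method parameters
    ira: ira.IraConfig = field(default_factory=ira.IraConfig)
    d_max: float = 4.25
    beta_probabilities: dict = field(default_factory=dict)
    metal_mode: str = "explicit"          # explicit | implicit | none
    coordinating_atoms: list = field(default_factory=list)
    ncs_superimpose: list = field(default_factory=list)
    ncs_free: list = field(default_factory=list)
    coupled: bool = False
    # engine
    pool_size: int = 16
    n_select: int = 10
    template_models: int = 2
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    template_schedule: AnnealSchedule = field(default_factory=lambda: AnnealSchedule(
        n_starts=2, maxiter_fold=150, maxiter_stage=150, maxiter_final=300))
    weights: EnergyWeights = field(default_factory=EnergyWeights)
    # outputs
    output_dir: str = "nmrfold_out"
    seed: int = 0

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        raw = tomllib.loads(Path(path).read_text())
        cfg = cls()
        inputs = raw.get("inputs", {})
        for key in ("shifts_path", "peaks_path", "dihedral_path", "sequence"):
            if key in inputs:
                setattr(cfg, key, inputs[key])
        cfg.titration_paths = inputs.get("titration_paths", [])
        cfg.titration_ratios = inputs.get("titration_ratios", [])
        if "modeled_range" in inputs:
            cfg.modeled_range = tuple(inputs["modeled_range"])
        cfg.synthetic = inputs.get("synthetic", cfg.shifts_path is None)
        if "ira" in raw:
            cfg.ira = ira.IraConfig(**raw["ira"])
        eng = raw.get("engine", {})
        for key in ("pool_size", "n_select", "template_models", "d_max"):
            if key in eng:
                setattr(cfg, key, eng[key])
        metal = raw.get("metal", {})
        cfg.metal_mode = metal.get("mode", cfg.metal_mode)
        cfg.coordinating_atoms = [tuple(a) for a in metal.get("coordinating_atoms", [])]
        ncs = raw.get("ncs", {})
        cfg.ncs_superimpose = [tuple(s) for s in ncs.get("superimpose", [])]
        cfg.ncs_free = [tuple(s) for s in ncs.get("free", [])]
        cfg.coupled = ncs.get("coupled", False)
        out = raw.get("outputs", {})
        cfg.output_dir = out.get("directory", cfg.output_dir)
        cfg.seed = raw.get("seed", out.get("seed", cfg.seed))
        return cfg

    def validate(self) -> None:
        if not self.synthetic:
            for p in (self.shifts_path, self.peaks_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"missing input file: {p}")
            for p in self.titration_paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"missing titration peak list: {p}")


@dataclass
class RunReport:
    cycles: list = field(default_factory=list)
    restraint_counts: dict = field(default_factory=dict)
    separation_counts: dict = field(default_factory=dict)
    ensemble_energies: list = field(default_factory=list)
    mean_pairwise_rmsd: float | None = None
    n_models: int = 0
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=float)


def _separation_counts(rs: RestraintSet) -> dict[str, int]:
    out = {"intra": 0, "sequential": 0, "medium": 0, "long": 0}
    for r in rs.distances:
        if r.kind != "noe":
            continue
        seps = [abs(pa[0] - pb[0]) for pa, pb in r.member_pairs]
        d = min(seps)
        if d == 0:
            out["intra"] += 1
        elif d == 1:
            out["sequential"] += 1
        elif d <= 4:
            out["medium"] += 1
        else:
            out["long"] += 1
    return out


def _load_structure_inputs(config: RunConfig):
    """(shifts, peaks, dihedral predictions, sequence, extras) per config."""
    if config.synthetic:
        truth = synth.make_toy_fold(seed=config.seed)
        noise = synth.NoiseModel(seed=config.seed)
        shifts = synth.simulate_shifts(truth, noise=noise)
        peaks, truth_map = synth.simulate_noesy(truth, shifts, noise=noise)
        preds = truth.dihedral_predictions()
        beta = truth.beta_probabilities()
        coordinating = [(r, "SG") for r in truth.site_residues]
        return shifts, peaks, preds, truth.sequence, {
            "truth": truth, "truth_map": truth_map, "beta": beta,
            "coordinating": coordinating,
        }
    shifts = parse_shift_table(config.shifts_path)
    peaks = parse_peak_list(config.peaks_path)
    preds = (parse_dihedral_predictions(config.dihedral_path)
             if config.dihedral_path else [])
    if config.sequence is None:
        raise ValueError("sequence required for file-based runs")
    return shifts, peaks, preds, config.sequence, {
        "beta": config.beta_probabilities,
        "coordinating": config.coordinating_atoms,
    }


def run_structure_pipeline(config: RunConfig):
    """Iterative assignment, pool annealing, ensemble selection, reporting.

    Returns ``(ensemble, report)`` in single-form mode, or
    ``((ensemble_apo, ensemble_bound), report)`` in coupled mode.
    """
    config.validate()
    shifts, peaks, preds, sequence, extra = _load_structure_inputs(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    beta = extra.get("beta", {})
    coordinating = [tuple(a) for a in extra.get("coordinating", [])]
    restraint_atoms = list(coordinating)
    restraint_atoms += [
        (e.residue_index, e.atom_name) for e in shifts
        if e.atom_name not in ("N", "HN", "CA", "HA", "C", "O")
    ]
    topology = build_topology(
        sequence, restraint_atoms=restraint_atoms,
        with_metal=(config.metal_mode == "explicit" and bool(coordinating)),
    )
    residues = topology.residue_indices

    base_rs = RestraintSet()
    base_rs.distances += make_hbond_restraints(beta, residues)
    base_rs.dihedrals += make_dihedral_restraints(preds)

    def template_engine(noe_rs: RestraintSet) -> Ensemble:
        rs = RestraintSet(distances=list(noe_rs.distances))
        rs.extend(RestraintSet(distances=list(base_rs.distances),
                               dihedrals=list(base_rs.dihedrals)))
        confs = [
            anneal(topology, rs, seed=config.seed * 1009 + 7 * k,
                   schedule=config.template_schedule, weights=config.weights)
            for k in range(config.template_models)
        ]
        return select_ensemble(confs, n_select=len(confs), topology=topology)

    result = ira.run_cycles(peaks, shifts, template_engine, config.ira,
                            d_max=config.d_max)
    (outdir / "assignments.tsv").write_text(result.assignments_tsv())
    (outdir / "ira_audit.jsonl").write_text(result.audit_jsonl())

    final_rs = RestraintSet(distances=list(result.restraints.distances))
    final_rs.extend(RestraintSet(distances=list(base_rs.distances),
                                 dihedrals=list(base_rs.dihedrals)))
    metal_rs = RestraintSet()
    if config.metal_mode in ("explicit", "implicit") and coordinating:
        metal_rs = make_metal_restraints(coordinating, mode=config.metal_mode)

    report = RunReport(cycles=[a.as_dict() for a in result.audit])

    if config.coupled:
        rs_bound = RestraintSet(distances=list(final_rs.distances),
                                dihedrals=list(final_rs.dihedrals))
        rs_bound.extend(metal_rs)
        ncs = make_ncs_coupling(config.ncs_superimpose, config.ncs_free) \
            if config.ncs_superimpose else None
        pairs = [
            anneal_coupled(topology, final_rs, rs_bound, ncs,
                           seed=config.seed * 2003 + 11 * k,
                           schedule=config.schedule, weights=config.weights)
            for k in range(max(config.pool_size // 4, 2))
        ]
        ens_a = select_ensemble([a for a, _ in pairs], shifts,
                                n_select=min(config.n_select, len(pairs)),
                                topology=topology)
        ens_b = select_ensemble([b for _, b in pairs], shifts,
                                n_select=min(config.n_select, len(pairs)),
                                topology=topology)
        ens_a.write(outdir / "ensemble_apo.pdb")
        ens_b.write(outdir / "ensemble_bound.pdb")
        ensembles = (ens_a, ens_b)
        report.n_models = len(ens_a)
        report.ensemble_energies = [m.total_energy for m in ens_a.models]
    else:
        final_rs.extend(metal_rs)
        pool = [
            anneal(topology, final_rs, seed=config.seed * 3001 + 13 * k,
                   schedule=config.schedule, weights=config.weights)
            for k in range(config.pool_size)
        ]
        ensemble = select_ensemble(pool, shifts, n_select=config.n_select,
                                   topology=topology)
        ensemble.write(outdir / "ensemble.pdb")
        ensembles = ensemble
        report.n_models = len(ensemble)
        report.ensemble_energies = [m.total_energy for m in ensemble.models]
        rmsd = ensemble.pairwise_backbone_rmsd()
        if len(ensemble) > 1:
            report.mean_pairwise_rmsd = float(
                rmsd[np.triu_indices(len(ensemble), 1)].mean())

    report.restraint_counts = final_rs.by_kind()
    report.separation_counts = _separation_counts(final_rs)
    (outdir / "report.json").write_text(report.to_json())
    return ensembles, report


def run_titration_pipeline(config: RunConfig):
    """Track an HSQC titration, compute the endpoint CSP profile and rank
    candidate binding-site residues.

    Returns ``(profile, trajectories, report)``.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.synthetic:
        truth = synth.make_toy_fold(seed=config.seed)
        noise = synth.NoiseModel(seed=config.seed)
        series = synth.simulate_titration(truth, noise=noise)
        assignments = {
            pid: (res, rtype)
            for pid, (res, rtype, form) in synth.hsqc_assignments(truth).items()
            if form == "S"
        }
        reference = sorted(
            set(truth.topology.residue_indices)
            - truth.strand_residues - set(truth.site_residues))
    else:
        if len(config.titration_paths) < 2:
            raise ValueError("titration needs at least two peak lists")
        points = []
        for ratio, path in zip(config.titration_ratios, config.titration_paths):
            points.append((float(ratio), parse_peak_list(path)))
        series = TitrationSeries(points)
        assignments = {}
        reference = []

    radii = {"HN": 0.5, "H": 0.5, "N": 4.0}
    trajectories = csp.track_titration(series, radii)

    # endpoint shift tables from the apo and final matched positions
    apo_peaks = series.points[0][1]
    final_positions = {
        t.peak_id: next((p for p in reversed(t.positions) if p is not None), None)
        for t in trajectories
    }
    from .io import Peak, PeakList

    end_peaks = PeakList()
    for p in apo_peaks:
        pos = final_positions.get(p.peak_id)
        if pos is not None:
            end_peaks.add(Peak(p.peak_id, p.dims, tuple(pos), p.intensity))
    table_a = csp.shifts_from_hsqc(apo_peaks, assignments)
    table_b = csp.shifts_from_hsqc(end_peaks, assignments)

    cfg = csp.CspConfig()
    if reference:
        cfg.tau_by_atomclass.update(
            csp.estimate_tau(table_a, table_b, reference, cfg))
    else:
        log.warning("no unstructured reference residues; default tau in use")
    profile = csp.compute_delta_rms(table_a, table_b, cfg)
    ranking = csp.rank_binding_site(profile, k=3) if profile.values else []

    broadened = sorted({
        assignments[t.peak_id][0] for t in trajectories
        if t.peak_id in assignments and t.ever_broadened
    })
    report = RunReport(extras={
        "top_residues": [[r, v] for r, v in ranking],
        "broadened_residues": broadened,
        "n_trajectories": len(trajectories),
        "tau": cfg.tau_by_atomclass,
    })
    (outdir / "csp_profile.csv").write_text(
        "residue_index,delta_rms,n_atoms\n" + "\n".join(
            f"{r},{profile.values[r]:.6g},{len(profile.atoms[r])}"
            for r in sorted(profile.values)) + "\n")
    (outdir / "titration_report.json").write_text(report.to_json())
    return profile, trajectories, report
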