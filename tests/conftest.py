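"""Shared fixtures.

The toy ground truth and its simulated datasets are expensive enough that
they are built once per session and shared; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from nmrfold import synth
from nmrfold.restraints import (
    RestraintSet, make_dihedral_restraints, make_hbond_restraints,
    make_metal_restraints,
)

TRUTH_SEED = 0


@pytest.fixture(scope="session")
def truth():
    return synth.make_toy_fold(seed=TRUTH_SEED)


@pytest.fixture(scope="session")
def clean_shifts(truth):
    return synth.simulate_shifts(truth, noise=synth.NoiseModel.noiseless())


@pytest.fixture(scope="session")
def clean_noesy(truth, clean_shifts):
    return synth.simulate_noesy(truth, clean_shifts,
                                noise=synth.NoiseModel.noiseless())


@pytest.fixture(scope="session")
def noisy_shifts(truth):
    return synth.simulate_shifts(truth, noise=synth.NoiseModel(seed=1))


@pytest.fixture(scope="session")
def noisy_noesy(truth, noisy_shifts):
    return synth.simulate_noesy(truth, noisy_shifts,
                                noise=synth.NoiseModel(seed=1))


def ground_truth_restraints(truth, peaks, truth_map) -> RestraintSet:
    """The generator's own restraints: unambiguous NOEs + H-bonds +
    dihedrals + the implicit-mode site distances."""
    rs = RestraintSet(distances=list(synth.true_noe_restraints(truth, peaks, truth_map)))
    rs.distances += make_hbond_restraints(
        truth.beta_probabilities(), truth.topology.residue_indices)
    rs.dihedrals += make_dihedral_restraints(truth.dihedral_predictions())
    rs.extend(make_metal_restraints(
        [(r, "SG") for r in truth.site_residues], mode="implicit"))
    return rs


@pytest.fixture(scope="session")
def clean_restraints(truth, clean_noesy):
    peaks, tmap = clean_noesy
    return ground_truth_restraints(truth, peaks, tmap)


def mean_structure(models, reference=None):
    """Coordinate mean after pairwise superposition onto the first model."""
    from nmrfold import geom

    ref = models[0].coords if reference is None else reference
    acc = np.zeros_like(ref)
    for m in models:
        r, t, _ = geom.kabsch(ref, m.coords)
        acc += m.coords @ r.T + t
    return acc / len(models)
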