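import numpy as np
import pytest

from dhpmd.io_formats import Frame, build_topology
from dhpmd.regions import assign_secondary_structure
from dhpmd.synthetic_data import generate_solvated_box, generate_toy_protein


@pytest.fixture(scope="session")
def small_protein():
    """Helix-loop-helix toy protein with a compact box."""
    topology, frame = generate_toy_protein(
        [("helix", 4), ("loop", 6), ("helix", 4)], seed=2, margin=5.0
    )
    partition = assign_secondary_structure(topology, frame)
    return topology, frame, partition


@pytest.fixture(scope="session")
def solvated_protein(small_protein):
    """The small protein in near-liquid-density pseudo-water."""
    topology, frame, partition = small_protein
    n_water = int(0.02 * float(np.prod(frame.box)))
    stop, sfr = generate_solvated_box(topology, frame, n_water=n_water, seed=4)
    return stop, sfr, partition


def make_atoms(positions, elements=None, molecule_classes=None, residue_indices=None,
               residue_names=None, box=(20.0, 20.0, 20.0), atom_names=None):
    """Convenience builder for tiny ad-hoc systems in tests."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if elements is None:
        elements = ["C"] * n
    if atom_names is None:
        atom_names = [f"{el}{i+1}" for i, el in enumerate(elements)]
    if residue_indices is None:
        residue_indices = list(range(1, n + 1))
    if residue_names is None:
        residue_names = ["UNK"] * n
    topology = build_topology(
        atom_names, elements, residue_indices, residue_names,
        coordinates=positions, molecule_classes=molecule_classes,
    )
    return topology, Frame(time=0.0, coordinates=positions, box=np.asarray(box, float))
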