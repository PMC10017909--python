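"""Structure, trajectory and score-table I/O.

Coordinates are held internally in Å (GRO files, which use nm, are
converted on read/write).  Only orthorhombic periodic boxes are
supported; triclinic input raises :class:`FormatError`.

Structure parsing and serialisation are delegated to :mod:`biotite`;
this module layers the package's own annotated :class:`Topology` /
:class:`Frame` containers on top, with molecule-class, polarity and
van-der-Waals-radius assignment needed by the downstream volumetric and
solvation analyses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import AA3_TO_AA1, DEFAULT_VDW_RADII, POLAR_ELEMENTS

__all__ = [
    "FormatError",
    "TopologyError",
    "Topology",
    "Frame",
    "Condition",
    "build_topology",
    "read_trajectory",
    "write_trajectory",
    "read_ddg_table",
    "write_ddg_table",
]

MOLECULE_CLASSES = ("protein", "water", "ethanol", "ion")

WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP", "TIP3", "SPC", "W"}
ETHANOL_RESNAMES = {"ETH", "EOH", "EOL", "ETA", "ETOH"}
ION_RESNAMES = {"NA", "CL", "K", "MG", "CA2", "SOD", "CLA", "NA+", "CL-", "ZN"}


class FormatError(ValueError):
    """Malformed or unsupported input file."""


class TopologyError(ValueError):
    """Inconsistent per-atom annotations."""


@dataclass(frozen=True)
class Condition:
    """A simulated environment: pressure (bar) × ethanol fraction (v/v) at
    a fixed absolute temperature (K)."""

    pressure: float
    ethanol_fraction: float
    temperature: float

    def __post_init__(self) -> None:
        if self.pressure <= 0:
            raise ValueError(f"pressure must be positive, got {self.pressure}")
        if not 0.0 <= self.ethanol_fraction <= 1.0:
            raise ValueError(
                f"ethanol_fraction must lie in [0, 1], got {self.ethanol_fraction}"
            )
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    def label(self) -> str:
        return f"{self.pressure:g}bar_{100 * self.ethanol_fraction:g}pct"


@dataclass
class Topology:
    """Per-atom annotations for a simulated system.

    All fields are parallel arrays of equal length.  ``residue_index`` is
    1-based and ``molecule_class`` is one of ``protein``, ``water``,
    ``ethanol``, ``ion``.
    """

    atom_id: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    residue_index: np.ndarray
    residue_name: np.ndarray
    molecule_class: np.ndarray
    vdw_radius: np.ndarray
    polarity: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.atom_id)
        for f in dataclasses.fields(self):
            arr = np.asarray(getattr(self, f.name))
            if arr.shape[0] != n:
                raise TopologyError(f"field {f.name} has length {arr.shape[0]}, expected {n}")
            setattr(self, f.name, arr)
        bad = set(np.unique(self.molecule_class)) - set(MOLECULE_CLASSES)
        if bad:
            raise TopologyError(f"unknown molecule_class values: {sorted(bad)}")
        if np.any(self.vdw_radius <= 0):
            i = int(np.argmax(self.vdw_radius <= 0))
            raise TopologyError(
                f"non-positive vdW radius for atom {self.atom_name[i]} (id {self.atom_id[i]})"
            )
        bad_pol = set(np.unique(self.polarity)) - {"polar", "apolar"}
        if bad_pol:
            raise TopologyError(f"unknown polarity values: {sorted(bad_pol)}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_id)

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.element != "H"

    def class_mask(self, molecule_class: str) -> np.ndarray:
        return self.molecule_class == molecule_class

    @property
    def protein_mask(self) -> np.ndarray:
        return self.class_mask("protein")

    def residue_atoms(self, residue_index: int, heavy_only: bool = False) -> np.ndarray:
        """Indices of atoms belonging to a (protein) residue."""
        mask = (self.residue_index == residue_index) & self.protein_mask
        if heavy_only:
            mask &= self.heavy_mask
        return np.flatnonzero(mask)

    def protein_residue_indices(self) -> np.ndarray:
        """Sorted unique residue indices of the protein chain."""
        return np.unique(self.residue_index[self.protein_mask])

    def sequence(self) -> str:
        """One-letter protein sequence in residue order; ``X`` for
        non-standard residue names."""
        letters = []
        for res in self.protein_residue_indices():
            i = self.residue_atoms(res)[0]
            letters.append(AA3_TO_AA1.get(str(self.residue_name[i]), "X"))
        return "".join(letters)

    def solvent_molecules(self, molecule_class: str) -> list[np.ndarray]:
        """Atom-index groups of whole solvent molecules of one class.

        Molecules are identified by their residue index; a residue index
        carrying more than one molecule class among solvent atoms is a
        topology error (a molecule must not be split across classes).
        """
        if molecule_class not in ("water", "ethanol"):
            raise ValueError(f"not a solvent class: {molecule_class}")
        mask = self.class_mask(molecule_class)
        groups: dict[int, list[int]] = {}
        for i in np.flatnonzero(mask):
            groups.setdefault(int(self.residue_index[i]), []).append(int(i))
        for res, idx in groups.items():
            classes = set(
                self.molecule_class[self.residue_index == res]
            )
            if len(classes) > 1:
                raise TopologyError(
                    f"residue {res} spans molecule classes {sorted(classes)}"
                )
        return [np.array(v) for _, v in sorted(groups.items())]


@dataclass
class Frame:
    """One trajectory snapshot: coordinates (N×3, Å) in an orthorhombic
    periodic box (edge lengths in Å) at a time point (ns)."""

    time: float
    coordinates: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError(f"coordinates must be N×3, got {self.coordinates.shape}")
        if self.box.shape != (3,):
            raise ValueError("box must be 3 orthorhombic edge lengths")
        if np.any(self.box <= 0):
            raise ValueError(f"box edges must be positive, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def copy(self) -> "Frame":
        return Frame(self.time, self.coordinates.copy(), self.box.copy())


# ---------------------------------------------------------------------------
# topology construction helpers


def _infer_molecule_class(res_name: str, n_atoms_in_res: int) -> str:
    name = res_name.strip().upper()
    if name in WATER_RESNAMES:
        return "water"
    if name in ETHANOL_RESNAMES:
        return "ethanol"
    if name in ION_RESNAMES and n_atoms_in_res == 1:
        return "ion"
    return "protein"


def _element_from_name(atom_name: str) -> str:
    for ch in atom_name.strip():
        if ch.isalpha():
            return ch.upper()
    raise TopologyError(f"cannot infer element for atom name {atom_name!r}")


def build_topology(
    atom_names: Sequence[str],
    elements: Sequence[str],
    residue_indices: Sequence[int],
    residue_names: Sequence[str],
    coordinates: Optional[np.ndarray] = None,
    molecule_classes: Optional[Sequence[str]] = None,
    radii: Optional[dict[str, float]] = None,
) -> Topology:
    """Assemble a :class:`Topology`, inferring what is not given.

    Molecule classes default to residue-name-based inference; vdW radii
    come from the element table (``radii`` overrides entries); polarity
    is element-based (N/O/S polar, C apolar), with hydrogens inheriting
    the polarity of the nearest heavy atom of their residue when
    coordinates are available (else apolar).
    """
    n = len(atom_names)
    elements = np.array(
        [e.strip().upper() if e.strip() else _element_from_name(a)
         for e, a in zip(elements, atom_names)],
        dtype=object,
    )
    res_idx = np.asarray(residue_indices, dtype=int)
    res_names_arr = np.array([r.strip().upper() for r in residue_names], dtype=object)

    if molecule_classes is None:
        counts: dict[int, int] = {}
        for r in res_idx:
            counts[int(r)] = counts.get(int(r), 0) + 1
        molecule_classes = [
            _infer_molecule_class(rn, counts[int(ri)])
            for rn, ri in zip(res_names_arr, res_idx)
        ]
    classes = np.array(molecule_classes, dtype=object)

    radius_table = dict(DEFAULT_VDW_RADII)
    if radii:
        radius_table.update({k.upper(): v for k, v in radii.items()})
    vdw = np.empty(n, dtype=float)
    for i, el in enumerate(elements):
        try:
            vdw[i] = radius_table[el]
        except KeyError:
            raise TopologyError(
                f"unknown element {el!r} for atom {atom_names[i]!r} "
                f"(id {i + 1}); supply a radius table entry"
            ) from None

    polarity = np.where(np.isin(elements.astype(str), list(POLAR_ELEMENTS)),
                        "polar", "apolar").astype(object)
    polarity[np.asarray(classes) == "ion"] = "polar"
    h_idx = np.flatnonzero(elements == "H")
    if len(h_idx) and coordinates is not None:
        coords = np.asarray(coordinates, dtype=float)
        for i in h_idx:
            same_res = np.flatnonzero((res_idx == res_idx[i]) & (elements != "H"))
            if len(same_res):
                d = np.linalg.norm(coords[same_res] - coords[i], axis=1)
                polarity[i] = polarity[same_res[np.argmin(d)]]

    return Topology(
        atom_id=np.arange(1, n + 1),
        atom_name=np.array([a.strip() for a in atom_names], dtype=object),
        element=elements,
        residue_index=res_idx,
        residue_name=res_names_arr,
        molecule_class=classes,
        vdw_radius=vdw,
        polarity=polarity,
    )


# ---------------------------------------------------------------------------
# trajectory I/O (biotite-backed)


def _detect_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("pdb-multimodel", "gro-series"):
            raise ValueError(f"unknown trajectory format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".pdb":
        return "pdb-multimodel"
    if suffix == ".gro":
        return "gro-series"
    raise FormatError(f"cannot infer trajectory format from {path.name!r}")


def _boxes_from_stack(stack) -> np.ndarray:
    if stack.box is None:
        raise FormatError(
            "no periodic box found (PDB needs a CRYST1 record, GRO a box line)"
        )
    boxes = np.asarray(stack.box, dtype=float)
    if boxes.ndim == 2:
        boxes = boxes[None]
    edges = np.empty((boxes.shape[0], 3))
    for k, b in enumerate(boxes):
        off = b - np.diag(np.diag(b))
        if np.max(np.abs(off)) > 1e-6:
            raise FormatError("triclinic boxes are unsupported; orthorhombic only")
        edges[k] = np.diag(b)
    return edges


def read_trajectory(
    path: str | Path,
    fmt: Optional[str] = None,
    radii: Optional[dict[str, float]] = None,
) -> tuple[Topology, list[Frame]]:
    """Read a multi-model PDB or a multi-frame GRO file.

    Returns the inferred :class:`Topology` and the frames in file order.
    Times are 0, 1, 2, … ns (neither format carries reliable time
    stamps).  Models must share atom count and order.
    """
    import biotite.structure as struc
    import biotite.structure.io.gro as groio
    import biotite.structure.io.pdb as pdbio

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    kind = _detect_format(path, fmt)
    try:
        if kind == "pdb-multimodel":
            stack = pdbio.get_structure(pdbio.PDBFile.read(path))
        else:
            stack = groio.GROFile.read(path).get_structure()
    except FileNotFoundError:
        raise
    except Exception as exc:  # biotite raises assorted exception types
        raise FormatError(f"cannot parse {path.name}: {exc}") from exc

    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    edges = _boxes_from_stack(stack)
    if edges.shape[0] == 1 and stack.stack_depth() > 1:
        edges = np.repeat(edges, stack.stack_depth(), axis=0)

    topology = build_topology(
        atom_names=list(stack.atom_name),
        elements=list(stack.element),
        residue_indices=list(stack.res_id),
        residue_names=list(stack.res_name),
        coordinates=stack.coord[0],
        radii=radii,
    )
    frames = [
        Frame(time=float(t), coordinates=stack.coord[t].copy(), box=edges[t])
        for t in range(stack.stack_depth())
    ]
    return topology, frames


def write_trajectory(
    path: str | Path,
    topology: Topology,
    frames: Sequence[Frame],
    fmt: Optional[str] = None,
) -> None:
    """Write frames as a multi-model PDB or multi-frame GRO file."""
    import biotite.structure as struc
    import biotite.structure.io.gro as groio
    import biotite.structure.io.pdb as pdbio

    path = Path(path)
    kind = _detect_format(path, fmt)
    if not frames:
        raise ValueError("no frames to write")
    n = topology.n_atoms
    for fr in frames:
        if fr.n_atoms != n:
            raise FormatError(
                f"frame has {fr.n_atoms} atoms but topology has {n}"
            )

    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(frames[0].coordinates, dtype=np.float32)
    atoms.atom_name = np.array([str(a) for a in topology.atom_name])
    atoms.element = np.array([str(e) for e in topology.element])
    atoms.res_id = topology.residue_index.astype(int)
    atoms.res_name = np.array([str(r) for r in topology.residue_name])
    atoms.chain_id = np.array(["A"] * n)
    atoms.hetero = ~topology.protein_mask

    stack = struc.stack([atoms] * len(frames))
    stack.coord = np.stack([f.coordinates for f in frames]).astype(np.float32)
    stack.box = np.stack([np.diag(f.box) for f in frames])

    if kind == "pdb-multimodel":
        out = pdbio.PDBFile()
        pdbio.set_structure(out, stack)
        out.write(path)
    else:
        out = groio.GROFile()
        out.set_structure(stack)
        out.write(path)


# ---------------------------------------------------------------------------
# ΔΔG score tables

DDG_COLUMNS = ["position", "wt", "mut", "ddg_foldx_kcal_mol", "ddg_imutant_kcal_mol"]


def read_ddg_table(
    path: str | Path,
    sequence: Optional[str] = None,
) -> dict[tuple[int, str], tuple[Optional[float], Optional[float]]]:
    """Read a tab-separated mutant ΔΔG table.

    Columns: ``position wt mut ddg_foldx_kcal_mol ddg_imutant_kcal_mol``.
    Returns a mapping ``(position, mut_aa) → (ΔΔG_A, ΔΔG_B)`` where a
    missing score is ``None`` (never silently zero).  Duplicate
    ``(position, mut)`` rows and wild-type letters contradicting
    ``sequence`` (1-based) are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"position": int, "wt": str, "mut": str})
    missing = set(DDG_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"ΔΔG table missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["position", "mut"], keep=False)
    if dup.any():
        rows = df.loc[dup, ["position", "mut"]].drop_duplicates()
        pairs = [f"({int(r.position)}, {r.mut})" for r in rows.itertuples()]
        raise FormatError(f"duplicate (position, mut) rows: {', '.join(pairs)}")

    table: dict[tuple[int, str], tuple[Optional[float], Optional[float]]] = {}
    for r in df.itertuples():
        pos, wt, mut = int(r.position), str(r.wt).strip(), str(r.mut).strip()
        if sequence is not None:
            if not 1 <= pos <= len(sequence):
                raise FormatError(f"position {pos} outside sequence (length {len(sequence)})")
            if sequence[pos - 1] != wt:
                raise FormatError(
                    f"wild-type mismatch at position {pos}: table says {wt}, "
                    f"sequence has {sequence[pos - 1]}"
                )
        a = None if pd.isna(r.ddg_foldx_kcal_mol) else float(r.ddg_foldx_kcal_mol)
        b = None if pd.isna(r.ddg_imutant_kcal_mol) else float(r.ddg_imutant_kcal_mol)
        table[(pos, mut)] = (a, b)
    return table


def write_ddg_table(
    path: str | Path,
    rows: Iterable[tuple[int, str, str, Optional[float], Optional[float]]],
) -> None:
    """Write ``(position, wt, mut, ΔΔG_A, ΔΔG_B)`` rows as TSV; ``None``
    scores become empty fields."""
    df = pd.DataFrame(rows, columns=DDG_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="")
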