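"""Secondary-structure segmentation and named candidate regions.

A :class:`RegionPartition` splits the protein chain into contiguous
helix/sheet/loop segments named ``class_start-end`` (1-based, inclusive:
``loop_67-76`` covers residues 67..76, ten residues).  Assignment comes
either from an external one-letter-per-residue file (H/E/C) or from a
built-in backbone-dihedral window heuristic (P-SEA-style).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_formats import Frame, Topology

__all__ = [
    "Segment",
    "RegionPartition",
    "dihedral",
    "backbone_dihedrals",
    "assign_secondary_structure",
    "region_atoms",
]

SS_CLASSES = ("helix", "sheet", "loop")
_LETTER_TO_CLASS = {"H": "helix", "E": "sheet", "C": "loop"}

# (φ, ψ) acceptance windows (degrees) for the dihedral heuristic
_HELIX_PHI = (-100.0, -30.0)
_HELIX_PSI = (-80.0, -5.0)
_SHEET_PHI = (-180.0, -80.0)
_SHEET_PSI = (80.0, 180.0)


@dataclass(frozen=True)
class Segment:
    name: str
    ss_class: str
    start: int  # first residue, 1-based
    end: int    # last residue, inclusive

    @property
    def n_residues(self) -> int:
        return self.end - self.start + 1

    def residues(self) -> range:
        return range(self.start, self.end + 1)


@dataclass
class RegionPartition:
    segments: list[Segment]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("partition must contain at least one segment")
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("segment names must be unique")
        ordered = sorted(self.segments, key=lambda s: s.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise ValueError(f"segments {a.name} and {b.name} overlap")
        for s in self.segments:
            if s.ss_class not in SS_CLASSES:
                raise ValueError(f"unknown class {s.ss_class!r} in {s.name}")
            if s.start > s.end or s.start < 1:
                raise ValueError(f"bad residue range in {s.name}")
        self.segments = ordered

    def names(self) -> list[str]:
        return [s.name for s in self.segments]

    def segment(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(f"unknown region {name!r}; known: {self.names()}")

    def loops(self) -> list[Segment]:
        return [s for s in self.segments if s.ss_class == "loop"]

    @classmethod
    def from_classes(cls, classes: Sequence[str], first_residue: int = 1) -> "RegionPartition":
        """Build a partition from one class per residue by merging
        contiguous equal-class runs."""
        segments = []
        start = 0
        for i in range(1, len(classes) + 1):
            if i == len(classes) or classes[i] != classes[start]:
                lo = first_residue + start
                hi = first_residue + i - 1
                segments.append(
                    Segment(f"{classes[start]}_{lo}-{hi}", classes[start], lo, hi)
                )
                start = i
        return cls(segments)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle (degrees) of four points, IUPAC convention."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def backbone_dihedrals(
    topology: Topology, frame: Frame
) -> dict[int, tuple[Optional[float], Optional[float]]]:
    """φ/ψ (degrees) per protein residue; ``None`` at chain termini.

    Raises if any residue lacks backbone N, CA or C atoms.
    """
    residues = topology.protein_residue_indices()
    backbone: dict[int, dict[str, np.ndarray]] = {}
    missing = []
    for res in residues:
        atoms = {}
        for i in topology.residue_atoms(int(res)):
            name = str(topology.atom_name[i])
            if name in ("N", "CA", "C"):
                atoms[name] = frame.coordinates[i]
        if set(atoms) != {"N", "CA", "C"}:
            missing.append(int(res))
        backbone[int(res)] = atoms
    if missing:
        raise ValueError(f"residues missing backbone N/CA/C atoms: {missing}")

    out: dict[int, tuple[Optional[float], Optional[float]]] = {}
    res_list = [int(r) for r in residues]
    for k, res in enumerate(res_list):
        prev_res = res_list[k - 1] if k > 0 and res_list[k - 1] == res - 1 else None
        next_res = res_list[k + 1] if k + 1 < len(res_list) and res_list[k + 1] == res + 1 else None
        phi = psi = None
        b = backbone[res]
        if prev_res is not None:
            phi = dihedral(backbone[prev_res]["C"], b["N"], b["CA"], b["C"])
        if next_res is not None:
            psi = dihedral(b["N"], b["CA"], b["C"], backbone[next_res]["N"])
        out[res] = (phi, psi)
    return out


def _in_window(value: Optional[float], window: tuple[float, float]) -> bool:
    return value is not None and window[0] <= value <= window[1]


def _reclassify_short_runs(classes: list[str], min_helix: int, min_sheet: int) -> list[str]:
    out = list(classes)
    start = 0
    for i in range(1, len(out) + 1):
        if i == len(out) or out[i] != out[start]:
            run = out[start]
            length = i - start
            if (run == "helix" and length < min_helix) or (
                run == "sheet" and length < min_sheet
            ):
                out[start:i] = ["loop"] * length
            start = i
    return out


def _read_ss_file(path: str | Path, residues: Sequence[int]) -> list[str]:
    table: dict[int, str] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{line_no}: expected 'residue<TAB>letter'")
        res, letter = int(parts[0]), parts[1].upper()
        if letter not in _LETTER_TO_CLASS:
            raise ValueError(f"{path}:{line_no}: unknown class letter {letter!r}")
        if res in table:
            raise ValueError(f"{path}:{line_no}: duplicate residue {res}")
        table[res] = _LETTER_TO_CLASS[letter]
    missing = [r for r in residues if r not in table]
    if missing:
        raise ValueError(f"secondary-structure file lacks residues: {missing}")
    return [table[r] for r in residues]


def assign_secondary_structure(
    topology: Topology,
    frame: Optional[Frame] = None,
    method: str = "dihedral-heuristic",
    ss_file: Optional[str | Path] = None,
    min_helix: int = 4,
    min_sheet: int = 3,
) -> RegionPartition:
    """Classify every protein residue as helix/sheet/loop and merge runs
    into named segments.

    ``external-file`` mode reads a plain-text one-letter-per-residue
    (H/E/C) assignment; ``dihedral-heuristic`` classifies by (φ, ψ)
    windows, with termini defaulting to loop.  Helix runs shorter than
    ``min_helix`` and sheet runs shorter than ``min_sheet`` are
    reclassified as loop.
    """
    residues = [int(r) for r in topology.protein_residue_indices()]
    if not residues:
        raise ValueError("topology contains no protein residues")

    if method == "external-file":
        if ss_file is None:
            raise ValueError("external-file mode needs ss_file")
        classes = _read_ss_file(ss_file, residues)
    elif method == "dihedral-heuristic":
        if frame is None:
            raise ValueError("dihedral-heuristic mode needs a frame")
        dihedrals = backbone_dihedrals(topology, frame)
        classes = []
        for res in residues:
            phi, psi = dihedrals[res]
            # chain termini lack one angle; classify on the available one
            def fits(phi_win, psi_win):
                if phi is None and psi is None:
                    return False
                return (phi is None or _in_window(phi, phi_win)) and (
                    psi is None or _in_window(psi, psi_win)
                )

            if fits(_HELIX_PHI, _HELIX_PSI):
                classes.append("helix")
            elif fits(_SHEET_PHI, _SHEET_PSI):
                classes.append("sheet")
            else:
                classes.append("loop")
    else:
        raise ValueError(f"unknown method {method!r}")

    classes = _reclassify_short_runs(classes, min_helix, min_sheet)
    return RegionPartition.from_classes(classes, first_residue=residues[0])


def region_atoms(
    partition: RegionPartition,
    topology: Topology,
    region_name: str,
    scope: str = "heavy-atom",
) -> np.ndarray:
    """Atom indices of a named region's protein atoms, ``heavy-atom`` or
    ``all-atom`` scope."""
    seg = partition.segment(region_name)
    if scope not in ("heavy-atom", "all-atom"):
        raise ValueError(f"unknown scope {scope!r}")
    mask = (
        topology.protein_mask
        & (topology.residue_index >= seg.start)
        & (topology.residue_index <= seg.end)
    )
    if scope == "heavy-atom":
        mask &= topology.heavy_mask
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError(f"region {region_name!r} matches no atoms")
    return idx
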