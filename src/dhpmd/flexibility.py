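"""Rigid-body superposition, RMSD time series and per-residue RMSF.

Frames are least-squares superposed onto a reference over a selection
(default: Cα atoms) with an optimal proper rotation + translation; RMSD
is then the root-mean-square deviation over the selection and RMSF the
per-residue root-mean-square fluctuation about the time-mean position.
RMSF uses the population mean over frames (divide by n_frames) and is
unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .io_formats import Frame, Topology

__all__ = [
    "FlexibilityProfile",
    "select_atoms",
    "superpose",
    "rmsd",
    "rmsf",
    "flexibility_profile",
]


@dataclass
class FlexibilityProfile:
    rmsd: np.ndarray               # per frame, Å
    rmsf: pd.Series                # per residue, Å (index = residue_index)
    reference_frame_index: int
    selection: str


def select_atoms(topology: Topology, selection: str = "ca") -> np.ndarray:
    """Atom indices for a named selection: ``ca`` (protein Cα), ``heavy``
    (protein heavy atoms) or ``all`` (protein atoms)."""
    prot = topology.protein_mask
    if selection == "ca":
        mask = prot & (topology.atom_name == "CA")
    elif selection == "heavy":
        mask = prot & topology.heavy_mask
    elif selection == "all":
        mask = prot
    else:
        raise ValueError(f"unknown selection {selection!r}")
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    return idx


def _fit_transform(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[Rotation, np.ndarray, np.ndarray]:
    """Optimal proper rotation and centroids aligning ``mobile`` to
    ``target`` (Kabsch, via scipy's align_vectors)."""
    if len(mobile) < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    mob_c = mobile.mean(axis=0)
    tar_c = target.mean(axis=0)
    centered = mobile - mob_c
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("selected atoms are collinear; rotation is undefined")
    rot, _ = Rotation.align_vectors(target - tar_c, centered)
    return rot, mob_c, tar_c


def superpose(
    frames: Sequence[Frame],
    reference: Frame,
    selection_indices: np.ndarray,
) -> list[Frame]:
    """Superpose every frame onto the reference over the selection.

    The fitted rigid motion (proper rotation + translation, handedness
    preserved) is applied to *all* atoms of each frame.
    """
    sel = np.asarray(selection_indices, dtype=int)
    ref_sel = reference.coordinates[sel]
    aligned = []
    for fr in frames:
        rot, mob_c, tar_c = _fit_transform(fr.coordinates[sel], ref_sel)
        coords = rot.apply(fr.coordinates - mob_c) + tar_c
        aligned.append(Frame(fr.time, coords, fr.box.copy()))
    return aligned


def rmsd(
    frames: Sequence[Frame],
    reference: Frame,
    selection_indices: np.ndarray,
) -> np.ndarray:
    """Per-frame RMSD (Å) over the selection; frames are assumed already
    superposed."""
    sel = np.asarray(selection_indices, dtype=int)
    ref = reference.coordinates[sel]
    return np.array([
        float(np.sqrt(np.mean(np.sum((fr.coordinates[sel] - ref) ** 2, axis=1))))
        for fr in frames
    ])


def rmsf(
    frames: Sequence[Frame],
    topology: Topology,
    selection_indices: np.ndarray,
    representative: str = "CA-only",
) -> pd.Series:
    """Per-residue RMSF (Å) from already-superposed frames.

    Per selected atom, RMSF = √(mean over frames of squared deviation
    from its time-mean position); residues aggregate their atoms'
    values per ``representative`` (``CA-only`` keeps the Cα value,
    ``all-atom-mean`` averages over the residue's selected atoms).
    Residues with no selected atoms are absent from the output.
    """
    if len(frames) < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = np.asarray(selection_indices, dtype=int)
    if representative not in ("CA-only", "all-atom-mean"):
        raise ValueError(f"unknown representative {representative!r}")
    if representative == "CA-only":
        keep = topology.atom_name[sel] == "CA"
        sel = sel[keep]
        if len(sel) == 0:
            raise ValueError("selection contains no CA atoms")

    coords = np.stack([fr.coordinates[sel] for fr in frames])  # (T, n, 3)
    mean_pos = coords.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((coords - mean_pos) ** 2, axis=2), axis=0))

    residues = topology.residue_index[sel]
    series = pd.Series(per_atom).groupby(residues).mean()
    series.index.name = "residue"
    series.name = "rmsf"
    return series


def flexibility_profile(
    topology: Topology,
    frames: Sequence[Frame],
    selection: str = "ca",
    reference_index: int = 0,
    representative: str = "CA-only",
) -> FlexibilityProfile:
    """Superpose onto a trajectory frame and compute RMSD + RMSF."""
    sel = select_atoms(topology, selection)
    reference = frames[reference_index]
    aligned = superpose(frames, reference, sel)
    return FlexibilityProfile(
        rmsd=rmsd(aligned, reference, sel),
        rmsf=rmsf(aligned, topology, sel, representative=representative),
        reference_frame_index=reference_index,
        selection=selection,
    )
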