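"""Solvent-shell counting, polar/apolar accessible surface area and
geometric hydrogen-bond detection.

Solvent molecules (water, ethanol) are counted once per molecule when
any of their atoms comes within a cutoff of any site atom, using
minimum-image periodic distances.  SASA follows Shrake–Rupley with a
deterministic golden-spiral point set and is split into hydrophilic
(polar atoms) and hydrophobic (apolar atoms) contributions by the
topology's polarity field.  Hydrogen bonds use the usual
donor–acceptor distance plus D–H…A linearity criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import Frame, Topology

__all__ = [
    "SolvationCount",
    "SurfaceArea",
    "HydrogenBond",
    "minimum_image_distance",
    "count_solvent_near",
    "sphere_points",
    "sasa",
    "detect_hbonds",
]


@dataclass(frozen=True)
class SolvationCount:
    site_label: str
    cutoff: float
    n_water: int
    n_ethanol: int
    frame_index: int


@dataclass(frozen=True)
class SurfaceArea:
    total: float        # Ų
    hydrophilic: float  # Ų (polar atoms)
    hydrophobic: float  # Ų (apolar atoms)
    probe_radius: float

    def __post_init__(self) -> None:
        if self.total < 0 or self.hydrophilic < 0 or self.hydrophobic < 0:
            raise ValueError("surface areas must be non-negative")
        if self.total > 0 and abs(
            self.hydrophilic + self.hydrophobic - self.total
        ) > 1e-6 * self.total:
            raise ValueError("hydrophilic + hydrophobic must equal total")


@dataclass(frozen=True)
class HydrogenBond:
    donor: int      # atom index of the donor heavy atom
    hydrogen: int   # atom index of the shared hydrogen
    acceptor: int   # atom index of the acceptor heavy atom
    distance: float # donor–acceptor distance, Å
    angle: float    # D–H…A angle, degrees


def minimum_image_distance(
    a: np.ndarray, b: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """Pairwise minimum-image distances between point sets ``a`` (n×3)
    and ``b`` (m×3) in an orthorhombic box."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    delta = a[:, None, :] - b[None, :, :]
    delta -= box * np.round(delta / box)
    return np.sqrt(np.sum(delta**2, axis=-1))


def count_solvent_near(
    frame: Frame,
    topology: Topology,
    site_atoms: Sequence[int],
    cutoff: float = 5.0,
    site_label: str = "site",
    frame_index: int = 0,
) -> SolvationCount:
    """Count whole water/ethanol molecules with any atom within
    ``cutoff`` Å (minimum image) of any site atom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    site = np.asarray(site_atoms, dtype=int)
    if len(site) == 0:
        raise ValueError("site_atoms must be non-empty")
    site_xyz = frame.coordinates[site]

    counts = {}
    for species in ("water", "ethanol"):
        n = 0
        for mol in topology.solvent_molecules(species):
            d = minimum_image_distance(frame.coordinates[mol], site_xyz, frame.box)
            if np.min(d) <= cutoff:
                n += 1
        counts[species] = n
    return SolvationCount(
        site_label=site_label,
        cutoff=cutoff,
        n_water=counts["water"],
        n_ethanol=counts["ethanol"],
        frame_index=frame_index,
    )


def sphere_points(n: int) -> np.ndarray:
    """``n`` near-uniform unit-sphere points (golden-spiral lattice);
    deterministic."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sasa(
    frame: Frame,
    topology: Topology,
    subset: Optional[Sequence[int]] = None,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> SurfaceArea:
    """Shrake–Rupley solvent-accessible surface area of a subset
    (default: all protein atoms), split by the polarity annotation.

    Per atom, the fraction of test points on the expanded sphere of
    radius r_vdw + probe not buried inside any neighbour's expanded
    sphere is multiplied by 4π(r_vdw + probe)².  Occlusion is evaluated
    within the subset only and without periodic images.
    """
    if subset is None:
        subset = np.flatnonzero(topology.protein_mask)
    subset = np.asarray(subset, dtype=int)
    if len(subset) == 0:
        raise ValueError("empty atom subset")
    coords = frame.coordinates[subset]
    radii = topology.vdw_radius[subset].astype(float) + probe_radius
    polar = topology.polarity[subset] == "polar"

    unit = sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    max_r = float(np.max(radii))

    philic = phobic = 0.0
    for i in range(len(subset)):
        pts = coords[i] + radii[i] * unit
        neighbours = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
                      if j != i]
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in neighbours:
            d = np.linalg.norm(pts - coords[j], axis=1)
            exposed &= d >= radii[j]
            if not exposed.any():
                break
        area = 4.0 * np.pi * radii[i] ** 2 * exposed.sum() / n_sphere_points
        if polar[i]:
            philic += area
        else:
            phobic += area
    return SurfaceArea(
        total=philic + phobic,
        hydrophilic=philic,
        hydrophobic=phobic,
        probe_radius=probe_radius,
    )


def _attached_hydrogens(
    topology: Topology, frame: Frame, donor: int, max_bond: float = 1.25
) -> list[int]:
    h_idx = np.flatnonzero(topology.element == "H")
    if len(h_idx) == 0:
        return []
    d = np.linalg.norm(frame.coordinates[h_idx] - frame.coordinates[donor], axis=1)
    return [int(i) for i in h_idx[d <= max_bond]]


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    donors: Sequence[int],
    acceptors: Sequence[int],
    max_da_distance: float = 3.5,
    max_dha_angle: float = 30.0,
) -> list[HydrogenBond]:
    """Geometric hydrogen bonds between donor and acceptor heavy atoms.

    A bond is reported when the donor–acceptor distance is ≤
    ``max_da_distance`` and the D–H…A angle deviates from linear (180°)
    by at most ``max_dha_angle``, for some hydrogen covalently attached
    to the donor (≤1.25 Å).  Donors without an attached hydrogen are
    skipped.
    """
    import warnings

    bonds = []
    for donor in donors:
        hydrogens = _attached_hydrogens(topology, frame, int(donor))
        if not hydrogens:
            warnings.warn(
                f"donor atom {donor} has no attached hydrogen; skipped",
                stacklevel=2,
            )
            continue
        d_xyz = frame.coordinates[int(donor)]
        for acceptor in acceptors:
            if int(acceptor) == int(donor):
                continue
            a_xyz = frame.coordinates[int(acceptor)]
            dist = float(np.linalg.norm(a_xyz - d_xyz))
            if dist > max_da_distance:
                continue
            for h in hydrogens:
                if int(acceptor) == h:
                    continue
                h_xyz = frame.coordinates[h]
                v1 = d_xyz - h_xyz
                v2 = a_xyz - h_xyz
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if 180.0 - angle <= max_dha_angle:
                    bonds.append(
                        HydrogenBond(int(donor), h, int(acceptor), dist, angle)
                    )
                    break
    return bonds
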