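"""Deterministic synthetic fixtures: toy proteins, breathing
trajectories with prescribed compressibility, solvated boxes and noisy
kinetics datasets.

Everything here is seeded end-to-end: the same spec and seed reproduce
bit-identical output.  The generators are deliberately geometric rather
than physical — volume fluctuations are injected by isotropic scaling
calibrated against the Voronoi volume itself, and solvent molecules are
pseudo-molecules placed at prescribed shell densities — because what
the rest of the package tests is the estimators and screens, not force
fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .constants import AA1, AA1_TO_AA3, A3_TO_M3, BAR_TO_PA, K_B
from .io_formats import Condition, Frame, Topology, build_topology
from .regions import RegionPartition, region_atoms
from .volumetrics import VolumeSeries, periodic_voronoi_volumes

__all__ = [
    "SyntheticSpec",
    "ShellSpec",
    "build_backbone",
    "generate_toy_protein",
    "toy_hydrolase_segments",
    "toy_hydrolase_sequence",
    "generate_volume_series",
    "generate_volume_trajectory",
    "generate_jitter_trajectory",
    "generate_solvated_box",
    "generate_kinetics_dataset",
    "condition_beta",
]

# ideal backbone geometry (Å, degrees)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.8

#: ideal (φ, ψ) per secondary-structure class; loop gets seeded jitter
_CLASS_DIHEDRALS = {"helix": (-57.0, -47.0), "sheet": (-139.0, 135.0),
                    "loop": (-70.0, 150.0)}
_LOOP_JITTER_DEG = 8.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Default study conditions for synthetic screens: the 3 × 3
    pressure/ethanol grid at 313 K, five parallels of 30 ns sampled
    every 1 ns."""

    seed: int = 0
    pressures: tuple[float, ...] = (1.0, 500.0, 1000.0)
    ethanol_fractions: tuple[float, ...] = (0.1, 0.5, 1.0)
    temperature: float = 313.0
    parallels: int = 5
    run_length_ns: float = 30.0
    sample_interval_ns: float = 1.0

    def conditions(self) -> list[Condition]:
        return [
            Condition(p, x, self.temperature)
            for p in self.pressures
            for x in self.ethanol_fractions
        ]


@dataclass(frozen=True)
class ShellSpec:
    """Exact solvent placement: ``n_water``/``n_ethanol`` molecules
    anchored within [r_min, r_max] Å of the site atoms; all other
    molecules are kept farther than ``exclusion`` Å from the site so a
    shell count with a cutoff between r_max and exclusion recovers the
    placed numbers exactly."""

    site_atoms: tuple[int, ...]
    n_water: int = 0
    n_ethanol: int = 0
    r_min: float = 2.5
    r_max: float = 4.0
    exclusion: float = 7.0


# ---------------------------------------------------------------------------
# backbone construction


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D with |CD| = bond, ∠BCD = angle and dihedral
    A-B-C-D = torsion (NeRF)."""
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        -bond * math.sin(theta) * math.cos(chi),
        -bond * math.sin(theta) * math.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    phi: Sequence[float], psi: Sequence[float], omega: float = 180.0
) -> np.ndarray:
    """Backbone coordinates (Å) for a chain with the given per-residue
    φ/ψ (degrees); returns an (n_res × 4, 3) array ordered
    N, CA, C, O per residue.

    φ of the first residue is unused (no preceding carbonyl), as is ψ of
    the last for chain extension; ψ values still orient every carbonyl
    oxygen.
    """
    n_res = len(phi)
    if len(psi) != n_res or n_res < 1:
        raise ValueError("phi and psi must be equal-length, non-empty")
    coords = np.zeros((n_res * 4, 3))

    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_BOND_N_CA, 0.0, 0.0])
    theta = math.radians(_ANGLE_N_CA_C)
    C = CA + _BOND_CA_C * np.array([-math.cos(theta), math.sin(theta), 0.0])

    for i in range(n_res):
        coords[4 * i + 0] = N
        coords[4 * i + 1] = CA
        coords[4 * i + 2] = C
        # carbonyl O: torsion N-CA-C-O = ψ + 180
        coords[4 * i + 3] = _place_atom(
            N, CA, C, _BOND_C_O, _ANGLE_CA_C_O, psi[i] + 180.0
        )
        if i + 1 < n_res:
            N_next = _place_atom(N, CA, C, _BOND_C_N, _ANGLE_CA_C_N, psi[i])
            CA_next = _place_atom(CA, C, N_next, _BOND_N_CA, _ANGLE_C_N_CA, omega)
            C_next = _place_atom(C, N_next, CA_next, _BOND_CA_C, _ANGLE_N_CA_C, phi[i + 1])
            N, CA, C = N_next, CA_next, C_next
    return coords


def generate_toy_protein(
    segments: Sequence[tuple[str, int]],
    sequence: Optional[str] = None,
    seed: int = 0,
    box: Optional[Sequence[float]] = None,
    margin: float = 12.0,
) -> tuple[Topology, Frame]:
    """Backbone-only toy protein with ideal per-class dihedrals.

    ``segments`` is a list of ``(class, length)`` with class in
    helix/sheet/loop; loop dihedrals get a small seeded jitter so loops
    are irregular but reproducible.  The chain is centred in the box
    (default: bounding box + margin per side); a given box too small to
    contain the chain is an error.
    """
    classes: list[str] = []
    for ss_class, length in segments:
        if ss_class not in _CLASS_DIHEDRALS:
            raise ValueError(f"unknown segment class {ss_class!r}")
        if length < 1:
            raise ValueError("segment length must be ≥ 1")
        classes.extend([ss_class] * int(length))
    n_res = len(classes)
    if sequence is None:
        sequence = "A" * n_res
    if len(sequence) != n_res:
        raise ValueError(
            f"sequence length {len(sequence)} != total segment length {n_res}"
        )

    rng = np.random.default_rng(seed)
    phi, psi = [], []
    for c in classes:
        p, q = _CLASS_DIHEDRALS[c]
        if c == "loop":
            p += float(rng.uniform(-_LOOP_JITTER_DEG, _LOOP_JITTER_DEG))
            q += float(rng.uniform(-_LOOP_JITTER_DEG, _LOOP_JITTER_DEG))
        phi.append(p)
        psi.append(q)
    coords = build_backbone(phi, psi)

    extent = coords.max(axis=0) - coords.min(axis=0)
    if box is None:
        box_arr = extent + 2.0 * margin
    else:
        box_arr = np.asarray(box, dtype=float)
        if np.any(extent >= box_arr):
            raise ValueError(
                f"box {box_arr} too small for chain extent {np.round(extent, 1)}"
            )
    coords = coords - coords.min(axis=0) + (box_arr - extent) / 2.0

    atom_names = []
    elements = []
    res_idx = []
    res_names = []
    for i, aa in enumerate(sequence, start=1):
        if aa not in AA1:
            raise ValueError(f"non-standard residue {aa!r} at position {i}")
        for name, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            atom_names.append(name)
            elements.append(el)
            res_idx.append(i)
            res_names.append(AA1_TO_AA3[aa])
    topology = build_topology(atom_names, elements, res_idx, res_names, coords)
    return topology, Frame(time=0.0, coordinates=coords, box=box_arr)


def toy_hydrolase_segments() -> list[tuple[str, int]]:
    """Segment layout of the 392-residue toy hydrolase whose loop
    segments sit exactly at 67-76, 82-107, 176-181, 254-261, 320-333
    and 381-392."""
    return [
        ("helix", 25), ("sheet", 10), ("helix", 31),   # 1-66
        ("loop", 10),                                  # 67-76
        ("helix", 5),                                  # 77-81
        ("loop", 26),                                  # 82-107
        ("helix", 33), ("sheet", 10), ("helix", 25),   # 108-175
        ("loop", 6),                                   # 176-181
        ("sheet", 10), ("helix", 62),                  # 182-253
        ("loop", 8),                                   # 254-261
        ("helix", 29), ("sheet", 10), ("helix", 19),   # 262-319
        ("loop", 14),                                  # 320-333
        ("helix", 47),                                 # 334-380
        ("loop", 12),                                  # 381-392
    ]


def toy_hydrolase_sequence() -> str:
    """Synthetic 392-residue stand-in sequence for the EC hydrolase.

    This is *not* the enzyme's real sequence (which the screening
    pipeline never needs in full); it is a deterministic repeating
    pattern with the experimentally mutated wild-type identities pinned
    at their published positions: H68, K70, A178, A321, S325, Q332.
    """
    pattern = "ADGKLSTVIE"
    seq = list((pattern * 40)[:392])
    for pos, aa in ((68, "H"), (70, "K"), (178, "A"), (321, "A"), (325, "S"), (332, "Q")):
        seq[pos - 1] = aa
    return "".join(seq)


# ---------------------------------------------------------------------------
# volume fluctuations


def target_volume_variance(
    beta_T_bar: float, mean_volume_A3: float, temperature: float
) -> float:
    """⟨δV²⟩ (Å⁶) implied by a target β_T (bar⁻¹) via the fluctuation
    relation — the inverse of the estimator."""
    beta_pa = beta_T_bar / BAR_TO_PA
    var_m6 = beta_pa * K_B * temperature * (mean_volume_A3 * A3_TO_M3)
    return var_m6 / A3_TO_M3**2


def generate_volume_series(
    target_beta_T: float,
    mean_volume: float = 1000.0,
    temperature: float = 313.0,
    n: int = 30,
    dt: float = 1.0,
    seed: int = 0,
    region_name: str = "region",
    condition: Optional[Condition] = None,
) -> VolumeSeries:
    """Gaussian volume series (Å³) whose population statistics imply the
    target β_T (bar⁻¹) at the given temperature."""
    if target_beta_T < 0:
        raise ValueError("target β_T must be non-negative")
    if condition is None:
        condition = Condition(1.0, 0.0, temperature)
    sigma = math.sqrt(target_volume_variance(target_beta_T, mean_volume, temperature))
    if sigma > 0.2 * mean_volume:
        raise ValueError(
            f"target β_T implies σ_V/⟨V⟩ = {sigma / mean_volume:.2f} > 0.2; "
            "not achievable as a small fluctuation"
        )
    rng = np.random.default_rng(seed)
    volumes = mean_volume + sigma * rng.standard_normal(n)
    volumes = np.maximum(volumes, 1e-3 * mean_volume)
    times = dt * np.arange(n)
    return VolumeSeries(region_name, times, volumes, condition)


def _region_scaled(coords, atoms, centroid, s):
    out = coords.copy()
    out[atoms] = centroid + s * (coords[atoms] - centroid)
    return out


def generate_volume_trajectory(
    topology: Topology,
    base_frame: Frame,
    partition: RegionPartition,
    targets: dict[str, float],
    n_frames: int = 30,
    dt: float = 1.0,
    temperature: float = 313.0,
    seed: int = 0,
    condition: Optional[Condition] = None,
) -> list[Frame]:
    """Trajectory whose named regions breathe with prescribed β_T.

    Each target region's atoms are scaled isotropically about the
    region centroid; the scale factor for each frame is obtained by
    inverting a calibration curve of measured region Voronoi volume
    versus scale, so the realised volume series follows the prescribed
    Gaussian closely.  Non-target atoms are fixed.  Target regions must
    be distinct partition segments (hence disjoint).
    """
    names = list(targets)
    if len(set(names)) != len(names):
        raise ValueError("duplicate target regions")
    coords0 = base_frame.coordinates
    box = base_frame.box

    per_region = {}
    for name in names:
        beta = targets[name]
        if beta < 0:
            raise ValueError(f"negative target β_T for {name}")
        atoms_all = region_atoms(partition, topology, name, scope="all-atom")
        atoms_heavy = region_atoms(partition, topology, name, scope="heavy-atom")
        centroid = coords0[atoms_all].mean(axis=0)
        v0 = float(np.sum(periodic_voronoi_volumes(coords0, box, indices=atoms_heavy)))
        sigma = math.sqrt(target_volume_variance(beta, v0, temperature))
        if sigma > 0.2 * v0:
            raise ValueError(
                f"target β_T for {name} implies σ_V/⟨V⟩ > 0.2; unachievable"
            )
        inverse = None
        if sigma > 0:
            # probe the local volume response to scaling (the cell
            # boundaries against fixed surroundings respond much more
            # weakly than s³), then size the scale grid to cover ±5σ
            def volume_at(s: float) -> float:
                scaled = _region_scaled(coords0, atoms_all, centroid, s)
                return float(
                    np.sum(periodic_voronoi_volumes(scaled, box, indices=atoms_heavy))
                )

            delta = 0.02
            slope = (volume_at(1 + delta) - volume_at(1 - delta)) / (2 * delta)
            if slope <= 0:
                raise RuntimeError(
                    f"region volume does not grow with the scale factor for {name}"
                )
            half_width = min(1.3 * 5.0 * sigma / slope, 0.25)
            s_grid = np.linspace(1.0 - half_width, 1.0 + half_width, 9)
            v_grid = np.asarray([volume_at(s) for s in s_grid])
            if np.any(np.diff(v_grid) <= 0):
                raise RuntimeError(
                    f"region volume is not monotone in the scale factor for {name}; "
                    "region may be entangled with fixed atoms"
                )
            inverse = PchipInterpolator(v_grid, s_grid)
        per_region[name] = (atoms_all, centroid, v0, sigma, inverse)

    rng = np.random.default_rng(seed)
    frames = []
    for k in range(n_frames):
        coords = coords0.copy()
        for name in names:
            atoms_all, centroid, v0, sigma, inverse = per_region[name]
            if sigma == 0:
                continue
            v_t = float(np.clip(rng.normal(v0, sigma),
                                inverse.x[0], inverse.x[-1]))
            s_t = float(inverse(v_t))
            coords[atoms_all] = centroid + s_t * (coords[atoms_all] - centroid)
        frames.append(Frame(time=k * dt, coordinates=coords, box=box.copy()))
    return frames


def generate_jitter_trajectory(
    topology: Topology,
    base_frame: Frame,
    partition: Optional[RegionPartition] = None,
    n_frames: int = 20,
    dt: float = 1.0,
    seed: int = 0,
    sigma_by_class: Optional[dict[str, float]] = None,
) -> list[Frame]:
    """Trajectory of seeded Gaussian positional jitter around the base
    frame, with per-class amplitudes (loops wobble more than helices and
    sheets by default) — a lightweight stand-in for thermal motion used
    by the RMSD/RMSF stage."""
    if sigma_by_class is None:
        sigma_by_class = {"helix": 0.25, "sheet": 0.25, "loop": 0.6}
    rng = np.random.default_rng(seed)
    sigma = np.full(topology.n_atoms, 0.3)
    if partition is not None:
        for seg in partition.segments:
            mask = (
                topology.protein_mask
                & (topology.residue_index >= seg.start)
                & (topology.residue_index <= seg.end)
            )
            sigma[mask] = sigma_by_class.get(seg.ss_class, 0.3)
    frames = []
    for k in range(n_frames):
        noise = rng.standard_normal((topology.n_atoms, 3)) * sigma[:, None]
        frames.append(Frame(
            time=k * dt,
            coordinates=base_frame.coordinates + noise,
            box=base_frame.box.copy(),
        ))
    return frames


# ---------------------------------------------------------------------------
# solvated boxes


def _random_unit(rng) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _water_atoms(anchor: np.ndarray, rng) -> tuple[list[str], list[str], np.ndarray]:
    u1 = _random_unit(rng)
    # second O-H at ~104.5° from the first
    perp = np.cross(u1, _random_unit(rng))
    perp /= np.linalg.norm(perp)
    ang = math.radians(104.5)
    u2 = math.cos(ang) * u1 + math.sin(ang) * perp
    coords = np.array([anchor, anchor + 0.96 * u1, anchor + 0.96 * u2])
    return ["OW", "HW1", "HW2"], ["O", "H", "H"], coords


def _ethanol_atoms(anchor: np.ndarray, rng) -> tuple[list[str], list[str], np.ndarray]:
    u1 = _random_unit(rng)
    perp = np.cross(u1, _random_unit(rng))
    perp /= np.linalg.norm(perp)
    ang = math.radians(109.5)
    u2 = math.cos(ang) * u1 + math.sin(ang) * perp
    c2 = anchor + 1.53 * u1
    o = c2 + 1.43 * u2
    coords = np.array([anchor, c2, o])
    return ["C1", "C2", "OH"], ["C", "C", "O"], coords


def generate_solvated_box(
    topology: Topology,
    frame: Frame,
    n_water: int = 0,
    n_ethanol: int = 0,
    shells: Sequence[ShellSpec] = (),
    seed: int = 0,
    min_separation: float = 2.0,
    max_attempts: int = 2000,
) -> tuple[Topology, Frame]:
    """Add pseudo-molecule solvent (3-atom water, 3-heavy-atom ethanol)
    to a protein frame.

    Shell placements are satisfied first and exactly; bulk molecules
    (the remaining ``n_water``/``n_ethanol``) avoid every shell's
    exclusion zone.  All atoms keep ``min_separation`` Å (minimum
    image) from previously placed atoms.  Placement failure after
    bounded retries raises.
    """
    from .solvation import minimum_image_distance

    rng = np.random.default_rng(seed)
    box = frame.box
    placed_xyz = [frame.coordinates]

    names: list[str] = []
    elements: list[str] = []
    res_idx: list[int] = []
    res_names: list[str] = []
    classes: list[str] = []
    coords_new: list[np.ndarray] = []
    next_res = int(np.max(topology.residue_index)) + 1 if topology.n_atoms else 1

    shell_sites = [frame.coordinates[list(sh.site_atoms)] for sh in shells]

    def _clear_of(pos_block: np.ndarray, skip_shell: Optional[int]) -> bool:
        for block in placed_xyz:
            if np.min(minimum_image_distance(pos_block, block, box)) < min_separation:
                return False
        for si, sh in enumerate(shells):
            if si == skip_shell:
                continue
            if np.min(minimum_image_distance(pos_block, shell_sites[si], box)) < sh.exclusion:
                return False
        return True

    def _place(species: str, anchor_fn, shell_index: Optional[int]) -> None:
        nonlocal next_res
        for _ in range(max_attempts):
            anchor = anchor_fn()
            if species == "water":
                a_names, a_el, xyz = _water_atoms(anchor, rng)
                resname = "HOH"
            else:
                a_names, a_el, xyz = _ethanol_atoms(anchor, rng)
                resname = "ETH"
            xyz = np.mod(xyz, box)
            if shell_index is not None:
                sh = shells[shell_index]
                d = minimum_image_distance(xyz, shell_sites[shell_index], box)
                if not (sh.r_min <= np.min(d) <= sh.r_max):
                    continue
            if not _clear_of(xyz, skip_shell=shell_index):
                continue
            names.extend(a_names)
            elements.extend(a_el)
            res_idx.extend([next_res] * 3)
            res_names.extend([resname] * 3)
            classes.extend([species] * 3)
            coords_new.append(xyz)
            placed_xyz.append(xyz)
            next_res += 1
            return
        raise RuntimeError(
            f"could not place a {species} molecule after {max_attempts} attempts"
        )

    for si, sh in enumerate(shells):
        sites = shell_sites[si]

        def shell_anchor() -> np.ndarray:
            site = sites[rng.integers(len(sites))]
            r = rng.uniform(sh.r_min, sh.r_max)
            return np.mod(site + r * _random_unit(rng), box)

        for _ in range(sh.n_water):
            _place("water", shell_anchor, si)
        for _ in range(sh.n_ethanol):
            _place("ethanol", shell_anchor, si)

    def bulk_anchor() -> np.ndarray:
        return rng.uniform(0.0, box)

    for _ in range(n_water):
        _place("water", bulk_anchor, None)
    for _ in range(n_ethanol):
        _place("ethanol", bulk_anchor, None)

    all_names = [str(a) for a in topology.atom_name] + names
    all_elements = [str(e) for e in topology.element] + elements
    all_res_idx = list(topology.residue_index) + res_idx
    all_res_names = [str(r) for r in topology.residue_name] + res_names
    all_classes = list(topology.molecule_class) + classes
    all_coords = np.vstack([frame.coordinates] + coords_new) if coords_new else frame.coordinates.copy()

    merged = build_topology(
        all_names, all_elements, all_res_idx, all_res_names,
        coordinates=all_coords, molecule_classes=all_classes,
    )
    return merged, Frame(frame.time, all_coords, box.copy())


# ---------------------------------------------------------------------------
# kinetics


def generate_kinetics_dataset(
    km: float,
    vmax: float,
    levels: Sequence[float] = (5, 10, 25, 50, 100, 150, 200, 300),
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Michaelis–Menten rate data v = V_max·S/(K_m+S)·(1+ε) with
    multiplicative Gaussian noise ε ~ N(0, noise_cv²); substrate levels
    in (0, 300] mM per the standard assay range."""
    s = np.asarray(levels, dtype=float)
    if np.any((s <= 0) | (s > 300)):
        raise ValueError("substrate levels must lie in (0, 300] mM")
    rng = np.random.default_rng(seed)
    v = vmax * s / (km + s)
    if noise_cv > 0:
        v = v * (1.0 + noise_cv * rng.standard_normal(len(s)))
        v = np.maximum(v, 0.0)
    return pd.DataFrame({"substrate_mM": s, "rate": v})


# ---------------------------------------------------------------------------
# condition response model for synthetic screens


def condition_beta(
    base_beta: float, amplitude: float, condition: Condition,
    max_pressure: float = 1000.0,
) -> float:
    """Synthetic per-region β_T response over the condition grid.

    β = base + amplitude · g(x) · h(p), with g(x) = 4x(1−x) peaking at
    50 % (v/v) ethanol — the concentration at which conformational
    change is largest, with near-pure ethanol suppressing it — and
    h(p) = 0.2 + 0.8·p/p_max increasing with pressure.  A region's
    spread across the grid is therefore ≈ its amplitude.
    """
    x = condition.ethanol_fraction
    g = 4.0 * x * (1.0 - x)
    h = 0.2 + 0.8 * condition.pressure / max_pressure
    return base_beta + amplitude * g * h
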