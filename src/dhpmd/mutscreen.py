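"""Virtual saturation mutagenesis and the dual-predictor consensus
stability filter.

Every position of the selected regions is substituted by the 19
non-identity standard amino acids.  Each candidate carries two predicted
folding free-energy changes with opposite sign conventions: ΔΔG_A
(FoldX convention, negative = stabilising) and ΔΔG_B (I-mutant
convention, positive = stabilising).  The consensus verdict is
``stabilizing`` only when *both* predictors agree, with strict
inequalities: ΔΔG_A < 0 and ΔΔG_B > 0.  A candidate missing either
score is ``incomplete`` and never enters the stabilising subset.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import AA1, HELIX_PROPENSITY, HYDROPATHY, RESIDUE_VOLUME
from .regions import RegionPartition, Segment

__all__ = [
    "MutationCandidate",
    "enumerate_saturation",
    "attach_scores",
    "consensus_filter",
    "surrogate_scorer",
    "score_candidates",
    "heatmap_matrix",
]

VERDICTS = ("stabilizing", "not-stabilizing", "incomplete")


@dataclass(frozen=True)
class MutationCandidate:
    position: int          # 1-based residue index
    wt_aa: str
    mut_aa: str
    ddg_a: Optional[float] = None  # kcal/mol, negative = stabilising
    ddg_b: Optional[float] = None  # kcal/mol, positive = stabilising
    verdict: Optional[str] = None

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


def _region_positions(regions: Sequence) -> list[int]:
    positions: list[int] = []
    for region in regions:
        if isinstance(region, Segment):
            positions.extend(region.residues())
        else:
            start, end = region
            if start > end:
                raise ValueError(f"bad region range {region}")
            positions.extend(range(int(start), int(end) + 1))
    return sorted(set(positions))


def enumerate_saturation(
    sequence: str,
    regions: Sequence,
    partition: Optional[RegionPartition] = None,
) -> list[MutationCandidate]:
    """All 19 substitutions at every position of the given regions.

    ``regions`` may contain :class:`Segment` objects, ``(start, end)``
    tuples, or region names resolved through ``partition``.  Candidates
    come out ordered by position, then alphabetically by mutant residue.
    """
    resolved = []
    for region in regions:
        if isinstance(region, str):
            if partition is None:
                raise ValueError("region names need a partition to resolve them")
            resolved.append(partition.segment(region))
        else:
            resolved.append(region)

    candidates = []
    for pos in _region_positions(resolved):
        if not 1 <= pos <= len(sequence):
            raise ValueError(f"position {pos} outside sequence of length {len(sequence)}")
        wt = sequence[pos - 1]
        if wt not in AA1:
            raise ValueError(f"non-standard wild-type residue {wt!r} at position {pos}")
        for mut in AA1:
            if mut != wt:
                candidates.append(MutationCandidate(pos, wt, mut))
    return candidates


def attach_scores(
    candidates: Iterable[MutationCandidate],
    scores: Mapping[tuple[int, str], tuple[Optional[float], Optional[float]]],
) -> list[MutationCandidate]:
    """Attach (ΔΔG_A, ΔΔG_B) from a score table; missing entries stay
    ``None`` (recorded as absent, never zero)."""
    out = []
    for c in candidates:
        a, b = scores.get((c.position, c.mut_aa), (None, None))
        out.append(replace(c, ddg_a=a, ddg_b=b))
    return out


def _verdict(ddg_a: Optional[float], ddg_b: Optional[float]) -> str:
    if ddg_a is None or ddg_b is None:
        return "incomplete"
    return "stabilizing" if (ddg_a < 0.0 and ddg_b > 0.0) else "not-stabilizing"


def consensus_filter(
    candidates: Iterable[MutationCandidate],
) -> tuple[list[MutationCandidate], list[MutationCandidate]]:
    """Assign verdicts and extract the stabilising subset.

    Returns ``(all candidates with verdicts, stabilising subset)``.
    """
    scored = [replace(c, verdict=_verdict(c.ddg_a, c.ddg_b)) for c in candidates]
    stabilizing = [c for c in scored if c.verdict == "stabilizing"]
    return scored, stabilizing


def surrogate_scorer(
    sequence: str,
    candidate: MutationCandidate,
    seed: int = 0,
) -> tuple[float, float]:
    """Deterministic stand-in (ΔΔG_A, ΔΔG_B) scores for pipeline runs
    without external predictor output.

    The scores are a stated heuristic — weighted differences of
    Kyte–Doolittle hydropathy, residue volume and helix propensity
    between mutant and wild type, plus seeded Gaussian noise — and are
    emphatically *not* a reimplementation of FoldX or I-mutant; they
    only make the screen executable end-to-end.  Identical inputs and
    seed give identical scores.
    """
    wt, mut, pos = candidate.wt_aa, candidate.mut_aa, candidate.position
    if not 1 <= pos <= len(sequence) or sequence[pos - 1] != wt:
        raise ValueError(f"candidate {candidate.label} disagrees with sequence")
    if wt == mut:
        raise ValueError("synonymous substitution is not a mutation")

    d_hydro = HYDROPATHY[mut] - HYDROPATHY[wt]
    d_vol = (RESIDUE_VOLUME[mut] - RESIDUE_VOLUME[wt]) / 50.0
    d_helix = HELIX_PROPENSITY[mut] - HELIX_PROPENSITY[wt]

    key = f"{seed}:{pos}:{wt}:{mut}".encode()
    rng = np.random.default_rng(zlib.crc32(key) % (2**31))
    noise_a, noise_b = rng.normal(0.0, 0.3, size=2)

    # pseudo-energy: burial-favouring hydropathy gain stabilises (negative),
    # large volume changes and helix-propensity penalties destabilise
    base = -0.35 * d_hydro + 0.25 * abs(d_vol) + 0.5 * d_helix
    ddg_a = base + noise_a
    ddg_b = -0.8 * base + noise_b
    return float(ddg_a), float(ddg_b)


def score_candidates(
    sequence: str,
    candidates: Iterable[MutationCandidate],
    seed: int = 0,
) -> list[MutationCandidate]:
    """Attach surrogate scores to every candidate."""
    out = []
    for c in candidates:
        a, b = surrogate_scorer(sequence, c, seed=seed)
        out.append(replace(c, ddg_a=a, ddg_b=b))
    return out


def heatmap_matrix(candidates: Iterable[MutationCandidate]) -> dict:
    """Positions × 20 amino-acid matrix of paired (ΔΔG_A, ΔΔG_B) cells.

    Wild-type cells are ``None``; serialisable straight to JSON.  Cells
    carry the consensus verdict so stabilising entries can be flagged in
    a rendering.
    """
    candidates = list(candidates)
    positions = sorted({c.position for c in candidates})
    wt_at = {c.position: c.wt_aa for c in candidates}
    cells: dict[int, dict[str, Optional[dict]]] = {
        p: {aa: None for aa in AA1} for p in positions
    }
    for c in candidates:
        cells[c.position][c.mut_aa] = {
            "ddg_a": c.ddg_a,
            "ddg_b": c.ddg_b,
            "verdict": c.verdict if c.verdict is not None else _verdict(c.ddg_a, c.ddg_b),
        }
    return {
        "amino_acids": list(AA1),
        "rows": [
            {"position": p, "wt": wt_at[p], "cells": cells[p]}
            for p in positions
        ],
    }


def candidates_frame(candidates: Iterable[MutationCandidate]) -> pd.DataFrame:
    """Tabular view of candidates for TSV export."""
    return pd.DataFrame(
        [
            {
                "position": c.position,
                "wt": c.wt_aa,
                "mut": c.mut_aa,
                "ddg_foldx_kcal_mol": c.ddg_a,
                "ddg_imutant_kcal_mol": c.ddg_b,
                "verdict": c.verdict,
            }
            for c in candidates
        ]
    )
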