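"""Isothermal compressibility from volume fluctuations, and ranking of
regions by their compressibility spread across a condition grid.

The statistical-mechanics fluctuation relation ⟨δV²⟩ = k_B·T·⟨V⟩·β_T
turns a region's volume time series into an estimate of its isothermal
compressibility β_T.  Regions whose β_T varies most across the pressure
× ethanol condition grid are the "sensitive fluctuation" regions that
the mutant screen targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .constants import A3_TO_M3, BAR_TO_PA, K_B
from .io_formats import Condition
from .volumetrics import VolumeSeries

__all__ = [
    "CompressibilityEstimate",
    "SensitivityRanking",
    "beta_T_from_samples",
    "beta_T",
    "sensitivity_ranking",
]


@dataclass(frozen=True)
class CompressibilityEstimate:
    region_name: str
    condition: Condition
    mean_volume: float       # Å³
    volume_variance: float   # Å⁶
    beta_T: float            # bar⁻¹
    n_samples: int


@dataclass
class SensitivityRanking:
    """Regions ordered by descending β_T spread across conditions.

    ``scores`` is a list of ``(region_name, score)`` pairs; ``table`` is
    the full region × condition β_T grid (bar⁻¹).
    """

    scores: list[tuple[str, float]]
    table: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def top(self, k: int) -> list[str]:
        return [name for name, _ in self.scores[:k]]


def beta_T_from_samples(
    volumes: np.ndarray,
    temperature: float,
    ddof: int = 0,
) -> tuple[float, float, float]:
    """β_T (bar⁻¹) from volume samples (Å³) at a temperature (K).

    Returns ``(beta_T, mean_volume, volume_variance)``.  The variance is
    the population variance (``ddof=0``) by default, matching the
    ensemble-average convention of the fluctuation formula.
    """
    v = np.asarray(volumes, dtype=float)
    if v.size < 2:
        raise ValueError(f"need at least 2 volume samples, got {v.size}")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    mean = float(np.mean(v))
    if mean <= 0:
        raise ValueError("mean volume must be positive")
    var = float(np.var(v, ddof=ddof))
    # ⟨δV²⟩ / (k_B T ⟨V⟩) in SI gives Pa⁻¹; Å⁶/(J·Å³) → ×1e-30, then bar⁻¹ → ×1e5
    beta_pa = var * A3_TO_M3 / (K_B * temperature * mean)
    return beta_pa * BAR_TO_PA, mean, var


def beta_T(series: VolumeSeries, ddof: int = 0) -> CompressibilityEstimate:
    """Estimate β_T for one region volume series; temperature is taken
    from the series condition."""
    value, mean, var = beta_T_from_samples(
        series.volumes, series.condition.temperature, ddof=ddof
    )
    return CompressibilityEstimate(
        region_name=series.region_name,
        condition=series.condition,
        mean_volume=mean,
        volume_variance=var,
        beta_T=value,
        n_samples=series.n_samples,
    )


def sensitivity_ranking(
    estimates: Iterable[CompressibilityEstimate],
    relative: bool = False,
) -> SensitivityRanking:
    """Rank regions by β_T spread over the condition grid.

    score(region) = max over conditions of β_T − min over conditions
    (absolute range, bar⁻¹); with ``relative=True`` the range is divided
    by the region's mean β_T.  Ties break alphabetically by region
    name.  A region missing some conditions is scored on those it has,
    with a warning recorded on the result.
    """
    rows: dict[str, dict[str, float]] = {}
    for est in estimates:
        rows.setdefault(est.region_name, {})[est.condition.label()] = est.beta_T
    if not rows:
        raise ValueError("no estimates given")

    all_conditions = sorted({c for row in rows.values() for c in row})
    table = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=all_conditions
    ).sort_index()

    warn: list[str] = []
    scores = []
    for region, row in table.iterrows():
        values = row.dropna().to_numpy()
        if len(values) < 2:
            raise ValueError(
                f"region {region!r} has estimates for fewer than 2 conditions"
            )
        if row.isna().any():
            warn.append(
                f"region {region} missing {int(row.isna().sum())} condition(s); "
                "scored on available conditions"
            )
        score = float(values.max() - values.min())
        if relative:
            mean = float(values.mean())
            score = score / mean if mean > 0 else 0.0
        scores.append((str(region), score))

    scores.sort(key=lambda item: (-item[1], item[0]))
    return SensitivityRanking(scores=scores, table=table, warnings=warn)
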