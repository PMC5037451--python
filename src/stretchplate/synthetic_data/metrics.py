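"""Well-level injury-metric tables from the generalized logistic model.

Each injury metric follows the four-parameter logistic in strain (see
:mod:`stretchplate.dose_response`); wells add independent Gaussian
noise. The default parameter sets below describe the dose response of
hiPSC-derived neurons to equibiaxial stretch: zero-strain plateau y0,
high-strain asymptote yf, rate constant k, transition strain E_t, and
the fit quality (R^2) observed for that metric, used to calibrate a
realistic noise level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from stretchplate.dose_response import METRIC_COLUMNS, LogisticParams, logistic_eval
from stretchplate.layout import PlateLayout, Well


@dataclass(frozen=True)
class MetricModel:
    """Ground-truth logistic parameters for one metric plus fit quality."""

    params: LogisticParams
    r_squared: float

    def __post_init__(self) -> None:
        if not 0 < self.r_squared <= 1:
            raise ValueError("r_squared must lie in (0, 1]")


def _mm(y0, yf, k, e_t, r2) -> MetricModel:
    return MetricModel(LogisticParams(y0, yf, k, e_t), r2)


#: Default generator truth for the nine injury metrics (units: um for
#: lengths, percent of thawed viability for cell_viability, counts per
#: image otherwise). Dead cells per image is the one metric that rises
#: with strain (yf > y0).
DEFAULT_METRIC_MODELS: Mapping[str, MetricModel] = {
    "neurite_length_per_cell": _mm(141.0, 31.55, 14.43, 0.339, 0.834),
    "cell_viability": _mm(78.44, 18.91, 18.43, 0.357, 0.828),
    "processes_per_cell": _mm(3.36, 1.327, 16.43, 0.353, 0.828),
    "total_neurite_length": _mm(43411.0, 2645.0, 16.46, 0.322, 0.819),
    "branches_per_cell": _mm(2.462, 0.199, 15.0, 0.334, 0.745),
    "total_processes": _mm(1063.0, 103.3, 17.24, 0.337, 0.708),
    "viable_cells_per_image": _mm(312.8, 77.03, 17.8, 0.361, 0.689),
    "total_branches": _mm(801.5, 15.94, 15.8, 0.305, 0.589),
    "dead_cells_per_image": _mm(271.1, 528.2, 24.58, 0.356, 0.459),
}

assert tuple(DEFAULT_METRIC_MODELS) == METRIC_COLUMNS


def noise_sd_for_r2(
    params: LogisticParams, strains: np.ndarray, r_squared: float
) -> float:
    """Gaussian well-noise sd reproducing a target R^2 at given strains.

    Uses sd^2 = SS_tot * (1 - R^2) / n where SS_tot is taken over the
    noise-free curve values at the supplied strains: the noise then
    contributes the residual share of variance the target R^2 implies.
    """
    clean = np.asarray(logistic_eval(params, strains), dtype=float)
    ss_tot = float(((clean - clean.mean()) ** 2).sum())
    return float(np.sqrt(ss_tot * (1.0 - r_squared) / len(clean)))


@dataclass(frozen=True)
class DoseResponseSpec:
    """Generating prescription for one simulated plate of metric values.

    ``strain_assignment`` maps each injured well to its true strain;
    control wells are always at strain 0. ``noise_sd`` may be given per
    metric; metrics absent from it get R^2-calibrated noise.
    """

    metric_models: Mapping[str, MetricModel] = field(
        default_factory=lambda: dict(DEFAULT_METRIC_MODELS)
    )
    strain_assignment: Mapping[Well, float] | None = None
    noise_sd: Mapping[str, float] | None = None
    strain_range: tuple[float, float] = (0.0, 0.6)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, model in self.metric_models.items():
            if self.noise_sd is not None and self.noise_sd.get(name, 0.0) < 0:
                raise ValueError(f"noise sd for {name} must be >= 0")


def _metric_values(
    models: Mapping[str, MetricModel],
    strains: np.ndarray,
    noise_sd: Mapping[str, float] | None,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    out = {}
    for name, model in models.items():
        clean = np.asarray(logistic_eval(model.params, strains), dtype=float)
        if noise_sd is not None and name in noise_sd:
            sd = float(noise_sd[name])
        else:
            sd = noise_sd_for_r2(model.params, strains, model.r_squared)
        out[name] = clean + (rng.normal(0.0, sd, size=len(strains)) if sd > 0 else 0.0)
    return out


def gen_plate_metrics(layout: PlateLayout, spec: DoseResponseSpec) -> pd.DataFrame:
    """One simulated metric record per non-excluded well of a plate.

    Wells without an entry in ``strain_assignment`` draw their strain
    uniformly from ``spec.strain_range``. Control wells sit at strain 0.
    Regeneration with the same spec (same seed) is bit-identical.
    """
    rng = np.random.default_rng(spec.seed)
    wells = list(layout.active_wells)
    strains = np.empty(len(wells))
    lo, hi = spec.strain_range
    for i, w in enumerate(wells):
        if layout.is_control(w):
            strains[i] = 0.0
        elif spec.strain_assignment is not None and w in spec.strain_assignment:
            strains[i] = spec.strain_assignment[w]
        else:
            strains[i] = rng.uniform(lo, hi)
    values = _metric_values(spec.metric_models, strains, spec.noise_sd, rng)
    df = pd.DataFrame(
        {
            "well": [w.name for w in wells],
            "is_control": [layout.is_control(w) for w in wells],
            "strain": strains,
            **values,
        }
    )
    return df.set_index("well")


#: Mean well strain at each of the five stage-displacement amplitudes of
#: the dose-response protocol. The lowest amplitude produces negligible
#: strain; above it strain rises roughly linearly with displacement.
DISPLACEMENT_LEVEL_STRAINS = (0.02, 0.19, 0.37, 0.55, 0.71)

#: Across-well strain spread within one displacement level. The post
#: array is deliberately misaligned in dose-response runs, spreading the
#: per-well strains so the sampled strain spectrum has no gaps.
LEVEL_STRAIN_SD = 0.09


def experiment_strains(
    n_injured: int = 152,
    n_controls: int = 8,
    level_means: Sequence[float] = DISPLACEMENT_LEVEL_STRAINS,
    level_sd: float = LEVEL_STRAIN_SD,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-well true strains of a simulated dose-response experiment.

    Injured wells are split evenly over the displacement levels; each
    draws around its level mean with the misalignment spread (clipped at
    zero — a membrane cannot carry negative stretch here). Controls sit
    at exactly zero. Shuffled so well order carries no structure.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    levels = np.resize(np.asarray(level_means, dtype=float), n_injured)
    injured = np.clip(rng.normal(levels, level_sd), 0.0, None)
    strains = np.concatenate([injured, np.zeros(n_controls)])
    rng.shuffle(strains)
    return strains


def simulate_experiment(
    metric_models: Mapping[str, MetricModel] | None = None,
    metrics: Sequence[str] | None = None,
    n_injured: int = 152,
    n_controls: int = 8,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a multi-plate dose-response experiment as one flat table.

    Defaults mirror the study scale and design: 152 injured wells pooled
    over five plates, stretched at five stage-displacement amplitudes
    (strain negligible at the lowest), plus unstretched controls, with
    per-metric noise calibrated to the observed R^2 of each metric.
    """
    models = dict(metric_models or DEFAULT_METRIC_MODELS)
    if metrics is not None:
        models = {m: models[m] for m in metrics}
    rng = rng if rng is not None else np.random.default_rng(seed)
    strains = experiment_strains(n_injured, n_controls, rng=rng)
    values = _metric_values(models, strains, None, rng)
    return pd.DataFrame({"strain": strains, **values})
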