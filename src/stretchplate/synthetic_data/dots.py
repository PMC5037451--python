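"""Fiducial-dot deformations from a prescribed strain field.

Each well carries a stamped circular dot of known diameter. Under an
equibiaxial Green-Lagrange strain E the dot's width and height are both
scaled by the stretch ratio lambda = sqrt(1 + 2E), which is the exact
inverse of the strain computation. The generator draws a true strain
per well (aligned mode: i.i.d. around the mean; misaligned mode: plus a
linear left-to-right column gradient), applies replicate-level strain
noise, and emits pre/post width-height pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from stretchplate.layout import COLUMNS, PlateLayout, Well
from stretchplate.strain_mechanics import DotMeasurement, stretch_ratio_for_strain

log = logging.getLogger(__name__)

#: Stamped dot diameter in mm.
DEFAULT_DOT_DIAMETER_MM = 1.5

#: Default misaligned-mode gradient (strain per column index). Chosen so
#: the spread across the ten used columns spans roughly 0.2 strain,
#: comparable to the systematic right-side excess seen with the post
#: array deliberately misaligned.
DEFAULT_GRADIENT = 0.02


@dataclass(frozen=True)
class StrainFieldSpec:
    """Prescription for the true per-well strain field of one plate.

    mode
        ``"aligned"``: strains vary only randomly across wells.
        ``"misaligned"``: adds ``gradient`` * (column - mean column), so
        strain rises linearly toward the right side of the plate.
    mean_strain, well_sd
        Mean and across-well standard deviation of the true strains.
    replicate_sd
        Standard deviation of replicate-to-replicate strain variation
        (repeat stretches of different plates at the same well location).
    """

    mode: str = "aligned"
    mean_strain: float = 0.45
    well_sd: float = 0.051
    replicate_sd: float = 0.0
    gradient: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("aligned", "misaligned"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mean_strain < 0 or self.well_sd < 0 or self.replicate_sd < 0:
            raise ValueError("mean_strain and sd values must be >= 0")
        if self.mode == "aligned" and self.gradient != 0:
            raise ValueError("aligned mode requires gradient = 0")

    @classmethod
    def misaligned(cls, mean_strain: float = 0.3, well_sd: float = 0.03,
                   gradient: float = DEFAULT_GRADIENT, **kw) -> "StrainFieldSpec":
        return cls(mode="misaligned", mean_strain=mean_strain,
                   well_sd=well_sd, gradient=gradient, **kw)


def _draw_valid(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw a strain, resampling draws that imply no real stretch ratio."""
    for _ in range(1000):
        e = float(rng.normal(mean, sd)) if sd > 0 else mean
        if e > -0.5:
            return e
        log.info("rejected strain draw %.3f (stretch ratio not real); resampling", e)
    raise RuntimeError("could not draw a valid strain in 1000 attempts")


def true_well_strains(
    layout: PlateLayout, spec: StrainFieldSpec, rng: np.random.Generator | None = None
) -> dict[Well, float]:
    """True strain per non-excluded well; controls are unstretched (0)."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    used_cols = sorted({w.column for w in layout.active_wells})
    col_center = float(np.mean(used_cols)) if used_cols else np.mean(COLUMNS)
    out: dict[Well, float] = {}
    for well in layout.active_wells:
        if layout.is_control(well):
            out[well] = 0.0
            continue
        mean = spec.mean_strain
        if spec.mode == "misaligned":
            mean = mean + spec.gradient * (well.column - col_center)
        out[well] = _draw_valid(rng, mean, spec.well_sd)
    return out


def gen_dot_measurements(
    layout: PlateLayout,
    spec: StrainFieldSpec,
    pre_dot_diameter: float = DEFAULT_DOT_DIAMETER_MM,
    n_replicates: int = 5,
    rng: np.random.Generator | None = None,
) -> tuple[list[DotMeasurement], dict[Well, float]]:
    """Generate dot width/height measurements for every non-excluded well.

    Returns the measurements plus the ground-truth per-well strain. With
    ``replicate_sd = 0`` the strain implied by each replicate equals the
    well's true strain exactly (closed-form inverse), so the analysis
    round trip is exact to numerical precision.
    """
    if pre_dot_diameter <= 0:
        raise ValueError("pre_dot_diameter must be > 0")
    if n_replicates < 1:
        raise ValueError("need >= 1 replicate")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    truth = true_well_strains(layout, spec, rng)

    measurements: list[DotMeasurement] = []
    for well, e_true in truth.items():
        for rep in range(1, n_replicates + 1):
            e_rep = (
                _draw_valid(rng, e_true, spec.replicate_sd)
                if spec.replicate_sd > 0
                else e_true
            )
            lam = stretch_ratio_for_strain(e_rep)
            measurements.append(
                DotMeasurement(
                    well=well,
                    replicate=rep,
                    pre_width=pre_dot_diameter,
                    pre_height=pre_dot_diameter,
                    post_width=pre_dot_diameter * lam,
                    post_height=pre_dot_diameter * lam,
                    unit="mm",
                )
            )
    return measurements, truth
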