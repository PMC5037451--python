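"""Equibiaxial Lagrangian strain from fiducial-dot measurements.

A dot of known size is stamped in each well bottom; its width and height
before and at peak stretch give the axial Green-Lagrange strains

    E_axial = u/X + (1/2) (u/X)^2,      u = x - X,

where ``X`` is the undeformed length and ``x`` the deformed length.
Shear is neglected (validated for this indentation geometry), so the
well strain ``E`` is the mean of ``E_xx`` (widths) and ``E_yy``
(heights). Replicates are aggregated by averaging replicate strains,
not dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from stretchplate.layout import PlateLayout, Well

#: Strains below this are flagged as negligible in displacement sweeps
#: (the lowest stage amplitude produces essentially no membrane strain).
NEGLIGIBLE_STRAIN = 0.02


class InvalidMeasurementError(ValueError):
    """A dot dimension is non-positive or units are inconsistent."""


@dataclass(frozen=True)
class DotMeasurement:
    """Pre/post width and height of one stamped dot replicate in one well."""

    well: Well
    replicate: int
    pre_width: float
    pre_height: float
    post_width: float
    post_height: float
    unit: str = "mm"

    def __post_init__(self) -> None:
        dims = (self.pre_width, self.pre_height, self.post_width, self.post_height)
        if any(not np.isfinite(d) or d <= 0 for d in dims):
            raise InvalidMeasurementError(
                f"non-positive dot dimension in well {self.well}: {dims}"
            )


@dataclass(frozen=True)
class WellStrain:
    """Per-well equibiaxial strain summary.

    ``E`` is exactly ``(E_xx + E_yy) / 2``; ``se`` is the standard error
    of the replicate-level strain values (0 for a single replicate).
    """

    well: Well
    E_xx: float
    E_yy: float
    E: float
    n: int
    se: float


@dataclass(frozen=True)
class DisplacementPulse:
    """One stage-displacement pulse: prescribed vs measured amplitude."""

    prescribed_mm: float
    measured_mm: float
    duration_ms: float

    def __post_init__(self) -> None:
        if self.prescribed_mm < 0 or self.measured_mm < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.duration_ms <= 0:
            raise ValueError("duration must be > 0")


def axial_lagrangian_strain(initial_length: float, final_length: float) -> float:
    """Uniaxial Green-Lagrange strain of a length change, shear neglected."""
    initial = np.asarray(initial_length, dtype=float)
    final = np.asarray(final_length, dtype=float)
    if np.any(initial <= 0) or np.any(final <= 0):
        raise InvalidMeasurementError("lengths must be positive")
    ratio = (final - initial) / initial
    out = ratio + 0.5 * ratio**2
    return float(out) if out.ndim == 0 else out


def stretch_ratio_for_strain(strain: float) -> float:
    """Inverse map: the stretch ratio lambda with E(lambda) = strain.

    lambda = sqrt(1 + 2E); requires E > -1/2 (a real deformation).
    """
    strain = np.asarray(strain, dtype=float)
    if np.any(strain <= -0.5):
        raise ValueError("strain must exceed -0.5 for a real stretch ratio")
    out = np.sqrt(1.0 + 2.0 * strain)
    return float(out) if out.ndim == 0 else out


def well_strain(measurements: Sequence[DotMeasurement]) -> WellStrain:
    """Aggregate dot replicates of a single well into a :class:`WellStrain`."""
    if not measurements:
        raise InvalidMeasurementError("no measurements supplied")
    wells = {m.well for m in measurements}
    if len(wells) > 1:
        raise InvalidMeasurementError(f"measurements span several wells: {wells}")
    units = {m.unit for m in measurements}
    if len(units) > 1:
        raise InvalidMeasurementError(f"mixed units: {units}")

    exx = np.array(
        [axial_lagrangian_strain(m.pre_width, m.post_width) for m in measurements]
    )
    eyy = np.array(
        [axial_lagrangian_strain(m.pre_height, m.post_height) for m in measurements]
    )
    e_rep = 0.5 * (exx + eyy)
    n = len(measurements)
    se = float(np.std(e_rep, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    e_xx = float(exx.mean())
    e_yy = float(eyy.mean())
    return WellStrain(
        well=next(iter(wells)),
        E_xx=e_xx,
        E_yy=e_yy,
        E=0.5 * (e_xx + e_yy),
        n=n,
        se=se,
    )


def plate_strain_map(
    measurements: Iterable[DotMeasurement],
    layout: PlateLayout | None = None,
) -> pd.DataFrame:
    """Per-well strain table for a plate.

    Returns a DataFrame indexed by well name with columns
    ``Exx, Eyy, E, se, n, is_control``. Measurements that land in
    excluded wells are dropped with a warning.
    """
    layout = layout or PlateLayout.default()
    by_well: dict[Well, list[DotMeasurement]] = {}
    for m in measurements:
        if layout.is_excluded(m.well):
            warnings.warn(
                f"measurement in excluded well {m.well} dropped", stacklevel=2
            )
            continue
        by_well.setdefault(m.well, []).append(m)

    rows = []
    for well in sorted(by_well):
        ws = well_strain(by_well[well])
        rows.append(
            {
                "well": well.name,
                "Exx": ws.E_xx,
                "Eyy": ws.E_yy,
                "E": ws.E,
                "se": ws.se,
                "n": ws.n,
                "is_control": layout.is_control(well),
            }
        )
    return pd.DataFrame(rows).set_index("well")


def summarize_strain_distribution(
    strain_maps: pd.DataFrame | Sequence[pd.DataFrame],
    include_controls: bool = False,
) -> dict[str, float]:
    """Across-well strain statistics for one plate or several plates.

    Returns the mean and sample (n-1) standard deviation of the per-well
    mean strains. With several plates, wells are pooled for the overall
    mean/sd and the average per-well sd across plates is also reported
    (the repeatability of the strain a given well location sees).
    """
    if isinstance(strain_maps, pd.DataFrame):
        plates = [strain_maps]
    else:
        plates = list(strain_maps)
    frames = []
    for p in plates:
        f = p if include_controls else p.loc[~p["is_control"]]
        frames.append(f)
    pooled = pd.concat(frames)
    if len(pooled) < 2:
        raise ValueError("need at least 2 wells to summarize a distribution")
    out = {
        "mean": float(pooled["E"].mean()),
        "sd": float(pooled["E"].std(ddof=1)),
        "n_wells": int(len(pooled)),
        "n_plates": len(plates),
    }
    if len(plates) > 1:
        per_well = pd.concat(
            [f["E"].rename(i) for i, f in enumerate(frames)], axis=1
        )
        # sd of a given well location across plates, averaged over locations
        out["mean_within_well_sd"] = float(
            per_well.std(axis=1, ddof=1).mean()
        )
    return out


def displacement_strain_curve(
    levels: Sequence[tuple[float, float]],
    negligible_threshold: float = NEGLIGIBLE_STRAIN,
) -> dict[str, object]:
    """Least-squares line through (stage displacement, mean strain) points.

    Levels whose strain falls below ``negligible_threshold`` are flagged:
    at very small displacements the membrane barely engages the posts and
    the measured strain is effectively zero, off the linear trend.
    """
    pts = np.asarray(levels, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("levels must be (displacement, strain) pairs")
    if len(np.unique(pts[:, 0])) < 2:
        raise ValueError("need >= 2 distinct displacement levels")
    x, y = pts[:, 0], pts[:, 1]
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    residuals = y - (slope * x + intercept)
    return {
        "slope": slope,
        "intercept": intercept,
        "residuals": residuals,
        "negligible_levels": [float(d) for d, s in pts if s < negligible_threshold],
    }


def read_dot_measurements(path) -> list[DotMeasurement]:
    """Read a dot-measurement CSV.

    Expected columns: well, replicate, pre_width, pre_height, post_width,
    post_height and optionally unit (defaults to mm).
    """
    df = pd.read_csv(path)
    required = {
        "well",
        "replicate",
        "pre_width",
        "pre_height",
        "post_width",
        "post_height",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dot-measurement CSV missing columns: {sorted(missing)}")
    if "unit" not in df.columns:
        df["unit"] = "mm"
    return [
        DotMeasurement(
            well=Well.parse(r.well),
            replicate=int(r.replicate),
            pre_width=float(r.pre_width),
            pre_height=float(r.pre_height),
            post_width=float(r.post_width),
            post_height=float(r.post_height),
            unit=str(r.unit),
        )
        for r in df.itertuples()
    ]


def write_strain_map(strain_map: pd.DataFrame, path) -> None:
    strain_map.to_csv(path)
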