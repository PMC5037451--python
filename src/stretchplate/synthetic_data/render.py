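"""Rendering of culture scenes into fluorescence channels.

Channels are grayscale float images in [0, 1]: a nuclear (Hoechst)
channel, a viability (calcein AM) channel showing somata, neurites and
injury beads of live cells only, a MAP2 channel covering the neuronal
morphology, and a punctate synaptophysin channel. Structures are
stamped as disks/strokes, blurred with a Gaussian point-spread
approximation, and overlaid with additive Gaussian noise plus an
optional left-to-right background ramp (to exercise illumination
correction).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk

from stretchplate.synthetic_data.scene import CultureScene, SceneSpec, build_scene

PSF_SIGMA_PX = 1.0

_BG = 0.03
_MAP2_BG = 0.20  # immunofluorescence background is higher than live-cell
_LEVELS = {
    "nucleus": 0.75,
    "soma": 0.85,
    "neurite": 0.55,
    "bead": 0.70,
    "map2_soma": 0.80,
    "map2_neurite": 0.60,
    "syn_diffuse": 0.10,
    "punctum": 0.85,
}


def _stamp_disk(mask: np.ndarray, center, radius: float) -> None:
    rr, cc = draw_disk(center, max(radius, 0.5), shape=mask.shape)
    mask[rr, cc] = True


def _stamp_stroke(mask: np.ndarray, path: np.ndarray, thickness: float) -> None:
    """Paint a polyline with round caps by stamping disks densely."""
    if len(path) == 0:
        return
    if len(path) == 1:
        _stamp_disk(mask, path[0], thickness / 2)
        return
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    total = seg.sum()
    n = max(int(total / 0.5), 2)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    samples = np.interp(
        np.linspace(0, total, n), cum, np.arange(len(path)), left=0, right=len(path) - 1
    )
    idx = samples.astype(int)
    frac = samples - idx
    idx2 = np.minimum(idx + 1, len(path) - 1)
    pts = path[idx] * (1 - frac[:, None]) + path[idx2] * frac[:, None]
    r = max(thickness / 2.0, 0.6)
    for p in pts:
        _stamp_disk(mask, p, r)


@dataclass(frozen=True)
class SceneGroundTruth:
    """What the renderer knows to be true about one field of view."""

    viable_count: int
    dead_count: int
    process_count: int
    branch_count: int
    total_neurite_length_um: float
    nuclear_mask: np.ndarray
    soma_labels: np.ndarray  # labeled viable somata, 0 = background
    neurite_mask: np.ndarray  # neurites + beads of viable cells
    viability_mask: np.ndarray
    puncta_per_compartment: dict[str, int]

    def as_metrics_dict(self) -> dict[str, float]:
        per = max(self.viable_count, 1)
        return {
            "viable_cells_per_image": self.viable_count,
            "dead_cells_per_image": self.dead_count,
            "total_processes": self.process_count,
            "total_branches": self.branch_count,
            "total_neurite_length": self.total_neurite_length_um,
            "processes_per_cell": self.process_count / per if self.viable_count else 0.0,
            "branches_per_cell": self.branch_count / per if self.viable_count else 0.0,
            "neurite_length_per_cell": (
                self.total_neurite_length_um / per if self.viable_count else 0.0
            ),
        }


def _finish(
    base: np.ndarray, spec: SceneSpec, rng: np.random.Generator
) -> np.ndarray:
    h, w = spec.shape
    img = base.copy()
    if spec.background_gradient:
        img += spec.background_gradient * np.linspace(0, 1, w)[None, :]
    img = ndi.gaussian_filter(img, PSF_SIGMA_PX)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def render_scene(scene: CultureScene) -> tuple[dict[str, np.ndarray], SceneGroundTruth]:
    """Render all four channels plus ground truth for a scene."""
    spec = scene.spec
    shape = spec.shape
    rng = np.random.default_rng(spec.seed + 32452843)  # render noise stream

    nuclear_mask = np.zeros(shape, dtype=bool)
    soma_labels = np.zeros(shape, dtype=np.int32)
    soma_mask = np.zeros(shape, dtype=bool)
    neurite_mask = np.zeros(shape, dtype=bool)
    bead_mask = np.zeros(shape, dtype=bool)

    label = 0
    for s in scene.somata:
        if s.has_nucleus:
            _stamp_disk(nuclear_mask, s.nucleus_center, s.nucleus_radius)
        if s.viable:
            label += 1
            tmp = np.zeros(shape, dtype=bool)
            _stamp_disk(tmp, s.center, s.radius)
            soma_mask |= tmp
            soma_labels[tmp] = label
    for fy, fx, fr in scene.free_nuclei:
        _stamp_disk(nuclear_mask, (fy, fx), fr)
    for n in scene.neurites:
        _stamp_stroke(neurite_mask, n.path, n.thickness)
        for by, bx, br in n.beads:
            _stamp_disk(bead_mask, (by, bx), br)

    viability_mask = soma_mask | neurite_mask | bead_mask

    nuclear = np.full(shape, _BG)
    nuclear[nuclear_mask] = _LEVELS["nucleus"]

    viability = np.full(shape, _BG)
    viability[neurite_mask] = _LEVELS["neurite"]
    viability[bead_mask] = _LEVELS["bead"]
    viability[soma_mask] = _LEVELS["soma"]

    map2 = np.full(shape, _MAP2_BG)
    map2[neurite_mask | bead_mask] = _LEVELS["map2_neurite"]
    map2[soma_mask] = _LEVELS["map2_soma"]

    syn = np.full(shape, _BG)
    syn[viability_mask] += _LEVELS["syn_diffuse"]
    puncta_counts = {"soma": 0, "neurite": 0}
    for p in scene.puncta:
        tmp = np.zeros(shape, dtype=bool)
        _stamp_disk(tmp, p.center, p.radius)
        syn[tmp] = _LEVELS["punctum"]
        puncta_counts[p.compartment] = puncta_counts.get(p.compartment, 0) + 1

    channels = {
        "nuclear": _finish(nuclear, spec, rng),
        "viability": _finish(viability, spec, rng),
        "map2": _finish(map2, spec, rng),
        "synaptophysin": _finish(syn, spec, rng),
    }
    truth = SceneGroundTruth(
        viable_count=scene.viable_count,
        dead_count=scene.dead_count,
        process_count=scene.process_count,
        branch_count=scene.branch_count,
        total_neurite_length_um=scene.total_neurite_length_um,
        nuclear_mask=nuclear_mask,
        soma_labels=soma_labels,
        neurite_mask=neurite_mask | bead_mask,
        viability_mask=viability_mask,
        puncta_per_compartment=puncta_counts,
    )
    return channels, truth


def gen_culture_image(
    spec: SceneSpec, injury_level: float = 0.0
) -> tuple[dict[str, np.ndarray], SceneGroundTruth, CultureScene]:
    """Build and render a culture scene at the given injury level."""
    scene = build_scene(spec, injury_level)
    channels, truth = render_scene(scene)
    return channels, truth, scene


def write_scene(
    outdir: str | Path,
    channels: dict[str, np.ndarray],
    truth: SceneGroundTruth,
    scene: CultureScene,
    stem: str = "scene",
) -> None:
    """Write channels as single-plane grayscale TIFFs, scalar ground truth
    as CSV, and the scene parameters as a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, img in channels.items():
        tifffile.imwrite(outdir / f"{stem}_{name}.tif", img.astype(np.float32))
    metrics = truth.as_metrics_dict()
    with open(outdir / f"{stem}_truth.csv", "w") as fh:
        fh.write("metric,value\n")
        for k, v in metrics.items():
            fh.write(f"{k},{v}\n")
    sidecar = {
        "spec": dataclasses.asdict(scene.spec),
        "injury_level": scene.injury_level,
        "n_somata": len(scene.somata),
        "n_neurites": len(scene.neurites),
        "puncta_per_compartment": truth.puncta_per_compartment,
    }
    with open(outdir / f"{stem}_scene.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
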