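"""Parametric neuronal culture scenes with injury-dependent morphology.

A scene is built in two stages. First the uninjured ("control")
geometry — soma positions and sizes, nuclei, branched neurite paths —
is drawn from the seed alone. Then the injury level in [0, 1] is
applied as a deterministic transform of that geometry: neurite paths
are truncated and thinned, round beads appear along them, and a nested
subset of cells becomes calcein-negative (nucleus retained, viability
signal lost, neurites gone). Because the control geometry never depends
on the injury level, ground-truth total neurite length is non-increasing
in injury for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

# injury response shape: fraction of neurite length lost and of cells
# dead at full injury, and neurite thinning range in px
LENGTH_LOSS_AT_FULL_INJURY = 0.7
DEAD_FRACTION_AT_FULL_INJURY = 0.6
CONTROL_THICKNESS_PX = 3.2
THINNING_AT_FULL_INJURY = 1.4
BEADS_PER_100PX_AT_FULL_INJURY = 1.7


@dataclass(frozen=True)
class Soma:
    """One cell body: a disk with an (optional) nuclear disk inside."""

    center: tuple[float, float]  # (row, col) px
    radius: float
    nucleus_center: tuple[float, float]
    nucleus_radius: float
    has_nucleus: bool = True
    viable: bool = True


@dataclass(frozen=True)
class Neurite:
    """A polyline process attached to a soma (or to a parent neurite)."""

    soma_index: int
    path: np.ndarray  # (N, 2) float px coordinates, starts at soma edge
    thickness: float
    beads: tuple[tuple[float, float, float], ...] = ()  # (row, col, radius)
    is_branch: bool = False

    @property
    def arc_length(self) -> float:
        if len(self.path) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.path, axis=0), axis=1).sum())


@dataclass(frozen=True)
class Punctum:
    """A synaptophysin-positive punctum with its compartment tag."""

    center: tuple[float, float]
    radius: float
    compartment: str  # "soma" | "neurite"


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic culture field of view.

    The defaults emulate a modest field at 0.33 um/px: cell bodies
    ~10-15 um across with Hoechst-positive nuclei, two to four smooth
    neurites per cell of 60-110 um, occasional branching. The default
    cell count matches the study's seeding density (33,750 cells/cm^2,
    about 5-6 cells in a 127 um field).
    """

    n_cells: int = 6
    shape: tuple[int, int] = (384, 384)
    pixel_size_um: float = 0.33
    noise_sd: float = 0.01
    background_gradient: float = 0.0  # peak-to-peak additive ramp, left to right
    n_free_nuclei: int = 0  # extracellular (calcein-negative) nuclei
    puncta_per_soma: int = 4
    puncta_per_neurite: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_free_nuclei < 0:
            raise ValueError("counts must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CultureScene:
    """Ground-truth description of one rendered field of view."""

    spec: SceneSpec
    injury_level: float
    somata: tuple[Soma, ...]
    neurites: tuple[Neurite, ...]
    free_nuclei: tuple[tuple[float, float, float], ...]  # (row, col, radius)
    puncta: tuple[Punctum, ...] = ()

    def __post_init__(self) -> None:
        h, w = self.spec.shape
        for n in self.neurites:
            if not (0 <= n.soma_index < len(self.somata)):
                raise ValueError("neurite references a missing soma")
            soma = self.somata[n.soma_index]
            for _, _, r in n.beads:
                if r >= soma.radius:
                    raise ValueError("bead radius must be below soma radius")
            if len(n.path) and (
                n.path.min() < 0 or n.path[:, 0].max() >= h or n.path[:, 1].max() >= w
            ):
                raise ValueError("neurite path leaves the image bounds")

    @property
    def viable_count(self) -> int:
        return sum(s.viable for s in self.somata)

    @property
    def dead_count(self) -> int:
        """Calcein-negative, Hoechst-positive objects: dead cells plus
        extracellular nuclei."""
        dead_somata = sum(s.has_nucleus and not s.viable for s in self.somata)
        return dead_somata + len(self.free_nuclei)

    @property
    def process_count(self) -> int:
        return sum(1 for n in self.neurites if not n.is_branch and len(n.path) >= 2)

    @property
    def branch_count(self) -> int:
        return sum(1 for n in self.neurites if n.is_branch and len(n.path) >= 2)

    @property
    def total_neurite_length_um(self) -> float:
        return sum(n.arc_length for n in self.neurites) * self.spec.pixel_size_um


def _place_points(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: float,
    min_dist: float,
    existing: Sequence[tuple[float, float]] = (),
    max_tries: int = 20000,
) -> list[tuple[float, float]]:
    pts: list[tuple[float, float]] = []
    h, w = shape
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} points with min distance {min_dist} "
                f"in a {shape} field"
            )
        cand = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        ok = all(
            np.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_dist
            for p in list(existing) + pts
        )
        if ok:
            pts.append(cand)
    return pts


def _walk(
    rng: np.random.Generator,
    start: np.ndarray,
    heading: float,
    max_len: float,
    shape: tuple[int, int],
    avoid: np.ndarray,
    avoid_radius: float,
    step: float = 4.0,
    wiggle: float = 0.12,
    margin: float = 6.0,
) -> np.ndarray:
    """Random smooth path from ``start``; stops at borders and keeps away
    from other cells' centers so scenes stay separable."""
    h, w = shape
    pts = [start.astype(float)]
    pos = start.astype(float)
    travelled = 0.0
    while travelled < max_len:
        heading += rng.normal(0.0, wiggle)
        nxt = pos + step * np.array([np.sin(heading), np.cos(heading)])
        if not (margin <= nxt[0] < h - margin and margin <= nxt[1] < w - margin):
            break
        if len(avoid) and np.min(np.linalg.norm(avoid - nxt, axis=1)) < avoid_radius:
            break
        pts.append(nxt)
        pos = nxt
        travelled += step
    return np.asarray(pts)


def _truncate_path(path: np.ndarray, fraction: float) -> np.ndarray:
    """Keep the leading ``fraction`` of the path's arc length."""
    if len(path) < 2 or fraction >= 1.0:
        return path
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    target = fraction * cum[-1]
    keep = int(np.searchsorted(cum, target, side="right"))
    return path[: max(keep, 2)]


def _point_at_fraction(path: np.ndarray, fraction: float) -> tuple[np.ndarray, float]:
    """Path point closest to the given arc-length fraction, plus the local
    heading there."""
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    i = int(np.clip(np.searchsorted(cum, fraction * cum[-1]), 1, len(path) - 1))
    d = path[i] - path[i - 1]
    return path[i], float(np.arctan2(d[0], d[1]))


def build_scene(spec: SceneSpec, injury_level: float = 0.0) -> CultureScene:
    """Construct the ground-truth scene for a given injury level."""
    if not 0.0 <= injury_level <= 1.0:
        raise ValueError("injury_level must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    soma_margin = 30.0
    min_sep = min(90.0, 0.9 * min(h, w) / max(1, np.sqrt(spec.n_cells)))

    centers = _place_points(rng, spec.n_cells, spec.shape, soma_margin, min_sep)
    somata: list[Soma] = []
    for cy, cx in centers:
        r = float(rng.uniform(16.0, 22.0))
        nr = float(rng.uniform(9.0, 12.0))
        max_off = max(r - nr - 2.0, 0.0)
        ang = rng.uniform(0, 2 * np.pi)
        off = rng.uniform(0, max_off)
        ncy, ncx = cy + off * np.sin(ang), cx + off * np.cos(ang)
        somata.append(Soma((cy, cx), r, (ncy, ncx), nr))

    free_centers = _place_points(
        rng,
        spec.n_free_nuclei,
        spec.shape,
        20.0,
        60.0,
        existing=centers,
    )
    free_nuclei = tuple(
        (fy, fx, float(rng.uniform(9.0, 12.0))) for fy, fx in free_centers
    )

    avoid_all = np.asarray(
        centers + [(fy, fx) for fy, fx, _ in free_nuclei], dtype=float
    ).reshape(-1, 2)

    # control neurite geometry: drawn independently of injury level
    control: list[dict] = []
    for i, soma in enumerate(somata):
        avoid = np.delete(avoid_all, i, axis=0) if len(avoid_all) else avoid_all
        n_prim = int(rng.integers(2, 5))
        for _ in range(n_prim):
            heading = float(rng.uniform(0, 2 * np.pi))
            start = np.array(soma.center) + (soma.radius + 1.0) * np.array(
                [np.sin(heading), np.cos(heading)]
            )
            max_len = float(rng.uniform(200.0, 340.0))
            path = _walk(rng, start, heading, max_len, spec.shape, avoid, 45.0)
            has_branch = rng.random() < 0.6
            branch_frac = float(rng.uniform(0.4, 0.75))
            branch_turn = float(rng.uniform(0.6, 1.2)) * (1 if rng.random() < 0.5 else -1)
            branch_len = float(rng.uniform(80.0, 160.0))
            branch_path = None
            if has_branch and len(path) >= 3:
                bp, local_heading = _point_at_fraction(path, branch_frac)
                branch_path = _walk(
                    rng, bp, local_heading + branch_turn, branch_len,
                    spec.shape, avoid, 45.0,
                )
            control.append(
                {
                    "soma": i,
                    "path": path,
                    "branch_frac": branch_frac,
                    "branch_path": branch_path,
                }
            )

    # injury transform: nested death set, truncation, thinning, beads
    death_order = np.random.default_rng(spec.seed + 7919).permutation(spec.n_cells)
    n_dead = int(round(DEAD_FRACTION_AT_FULL_INJURY * injury_level * spec.n_cells))
    dead = set(death_order[:n_dead].tolist())
    somata = [
        replace(s, viable=(i not in dead)) for i, s in enumerate(somata)
    ]

    keep_frac = 1.0 - LENGTH_LOSS_AT_FULL_INJURY * injury_level
    thickness = max(CONTROL_THICKNESS_PX - THINNING_AT_FULL_INJURY * injury_level, 1.6)
    bead_rng = np.random.default_rng(spec.seed + 104729)

    def _beads_for(path: np.ndarray) -> tuple[tuple[float, float, float], ...]:
        if injury_level <= 0 or len(path) < 2:
            return ()
        arc = float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum())
        lam = BEADS_PER_100PX_AT_FULL_INJURY * injury_level * arc / 100.0
        n_beads = int(bead_rng.poisson(lam))
        beads = []
        for _ in range(n_beads):
            p, _head = _point_at_fraction(path, float(bead_rng.uniform(0.1, 0.95)))
            beads.append((float(p[0]), float(p[1]), float(bead_rng.uniform(4.0, 6.0))))
        return tuple(beads)

    neurites: list[Neurite] = []
    for rec in control:
        if rec["soma"] in dead:
            continue  # dead cells have lost their processes
        path = _truncate_path(rec["path"], keep_frac)
        if len(path) >= 2:
            neurites.append(
                Neurite(rec["soma"], path, thickness, _beads_for(path), False)
            )
        bpath = rec["branch_path"]
        if bpath is not None and len(path) >= 2:
            # branch survives only while its attachment point survives
            seg = np.linalg.norm(np.diff(rec["path"], axis=0), axis=1).sum()
            kept = np.linalg.norm(np.diff(path, axis=0), axis=1).sum()
            if seg > 0 and kept / seg >= rec["branch_frac"]:
                bpath_t = _truncate_path(bpath, keep_frac)
                if len(bpath_t) >= 2:
                    neurites.append(
                        Neurite(
                            rec["soma"], bpath_t, thickness,
                            _beads_for(bpath_t), True,
                        )
                    )

    # synaptic puncta over the viable morphology
    punct_rng = np.random.default_rng(spec.seed + 15485863)
    puncta: list[Punctum] = []
    for s in somata:
        if not s.viable:
            continue
        for _ in range(spec.puncta_per_soma):
            ang = punct_rng.uniform(0, 2 * np.pi)
            rad = punct_rng.uniform(0, max(s.radius - 5.0, 1.0))
            puncta.append(
                Punctum(
                    (s.center[0] + rad * np.sin(ang), s.center[1] + rad * np.cos(ang)),
                    float(punct_rng.uniform(2.0, 3.0)),
                    "soma",
                )
            )
    for n in neurites:
        if n.is_branch or len(n.path) < 4:
            continue
        for _ in range(spec.puncta_per_neurite):
            p, _head = _point_at_fraction(n.path, float(punct_rng.uniform(0.15, 0.95)))
            puncta.append(
                Punctum((float(p[0]), float(p[1])), float(punct_rng.uniform(1.5, 2.5)), "neurite")
            )

    return CultureScene(
        spec=spec,
        injury_level=float(injury_level),
        somata=tuple(somata),
        neurites=tuple(neurites),
        free_nuclei=free_nuclei,
        puncta=tuple(puncta),
    )
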