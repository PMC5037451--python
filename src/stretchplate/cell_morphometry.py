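"""Segmentation and neurite morphometry of two-channel live-cell images.

The live-cell assay images each well in a nuclear (Hoechst) channel and
a viability (calcein AM) channel. Segmentation follows the scheme of
the high-content assay:

* nuclei from the nuclear channel (threshold + watershed declumping),
* candidate cell bodies from the viability channel; a candidate counts
  as a viable cell only if it overlaps a nucleus AND exceeds a minimum
  soma area — injury beads on neurites fail both rules and are rejected,
* nuclei with no calcein signal are dead cells (extracellular nuclei
  are likewise never promoted to cell bodies),
* the remaining calcein-positive area is skeletonized into a neurite
  graph from which per-well injury metrics are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk, opening, skeletonize
from skimage.segmentation import watershed

from stretchplate.dose_response import METRIC_COLUMNS


@dataclass(frozen=True)
class MorphometryConfig:
    """Tunable segmentation parameters.

    Areas are in um^2 and converted with ``pixel_size_um`` (default is
    the 0.33 um widefield pixel). ``soma_opening_radius_px`` must exceed
    half the neurite thickness (to detach cell-body candidates from the
    neurite meshwork) while staying below the bead radius so that beads
    surface as rejectable candidates.
    """

    pixel_size_um: float = 0.33
    min_nucleus_area_um2: float = 20.0
    min_soma_area_um2: float = 60.0
    soma_opening_radius_px: int = 4
    soma_refine_radius_px: int = 7  # opening that trims neurite-entry wedges
    declump_min_distance_px: int = 12
    nucleus_alive_overlap: float = 0.5  # fraction of nucleus area on calcein
    soma_dilate_px: int = 1  # gap between soma mask and neurite mask
    soma_halo_px: int = 2  # PSF halo by which the soma mask overshoots the cell
    background_radius_px: int = 50
    min_skeleton_px: int = 6
    prune_spur_px: int = 7  # terminal skeleton spurs shorter than this are noise

    @property
    def px_area_um2(self) -> float:
        return self.pixel_size_um**2

    def area_px(self, area_um2: float) -> int:
        return max(int(round(area_um2 / self.px_area_um2)), 1)


@dataclass
class SegmentationResult:
    """Labeled nuclei/somata, dead nuclei, rejections, neurite graph."""

    nuclei: np.ndarray  # labeled nuclei
    somata: np.ndarray  # labeled viable somata
    dead_nuclei: tuple[int, ...]  # nucleus labels scored as dead
    rejected: tuple[dict, ...]  # candidate objects rejected as cell bodies
    viability_mask: np.ndarray
    skeleton: nx.Graph | None = None  # nodes: (r, c); edges carry length_um
    component_soma: Mapping[int, int] = field(default_factory=dict)
    processes_per_soma: Mapping[int, int] = field(default_factory=dict)
    n_branches: int = 0
    tip_extension_um: float = 0.0  # endpoint-retraction correction
    pixel_size_um: float | None = None

    @property
    def viable_count(self) -> int:
        return int(self.somata.max())

    @property
    def dead_count(self) -> int:
        return len(self.dead_nuclei)


def preprocess_live(
    image: np.ndarray, config: MorphometryConfig | None = None
) -> np.ndarray:
    """3x3 median filter followed by background-illumination correction.

    The background is estimated by a large-scale separable median (two
    1-D median passes; window set by ``background_radius_px``, large
    relative to any cellular structure) and subtracted; the result is
    clipped at 0. The median reproduces a smooth illumination ramp
    exactly — including at the image borders, where reflection makes the
    ramp locally symmetric — while rejecting cells, which never fill
    half of a window in either pass.
    """
    config = config or MorphometryConfig()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    img = ndi.median_filter(img, size=3)
    size = 2 * config.background_radius_px + 1
    rough = ndi.median_filter(
        ndi.median_filter(img, size=(1, size)), size=(size, 1)
    )
    # the median background is biased near the borders of a tilted
    # field; refine with a quadratic surface fit to background pixels
    resid = img - rough
    mad = np.median(np.abs(resid - np.median(resid)))
    bg_px = resid <= np.median(resid) + 5 * max(mad, 1e-6)
    background = _quadratic_surface(img, bg_px)
    return np.clip(img - background, 0.0, 1.0)


def _quadratic_surface(img: np.ndarray, where: np.ndarray) -> np.ndarray:
    """Least-squares quadratic surface through the selected pixels."""
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    yn, xn = yy / max(h - 1, 1), xx / max(w - 1, 1)
    design = np.stack(
        [np.ones_like(xn), xn, yn, xn * xn, xn * yn, yn * yn], axis=-1
    )
    rows = design[where]
    # subsample for speed; the surface has only six coefficients
    if len(rows) > 20000:
        idx = np.linspace(0, len(rows) - 1, 20000).astype(int)
        rows = rows[idx]
        vals = img[where][idx]
    else:
        vals = img[where]
    coef, *_ = np.linalg.lstsq(rows, vals, rcond=None)
    return design @ coef


def _threshold(img: np.ndarray, method: str = "otsu", frac: float = 0.3) -> np.ndarray:
    """Foreground mask. Otsu suits the bright, well-separated nuclear
    channel. The viability channel instead gets a background-referenced
    threshold at ``frac`` of the way from the background level (median)
    to the bright-signal level (99.5th percentile): its histogram is
    dominated by background, faint injury-thinned neurites must stay
    above the cut (bimodal criteria like Otsu place it far too high),
    and a cut too close to background inflates a blur halo around every
    structure, merging neighboring strands."""
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=bool)
    if method == "otsu":
        thr = threshold_otsu(img)
    else:
        med = float(np.median(img))
        bright = float(np.percentile(img, 99.5))
        thr = med + frac * max(bright - med, 1e-4)
    return img > thr


def _drop_small(mask_or_labels: np.ndarray, min_px: int, connectivity: int = 1):
    """Remove objects with area < min_px (labels keep their ids)."""
    if min_px <= 1:
        return mask_or_labels
    if mask_or_labels.dtype == bool:
        from skimage.morphology import remove_small_objects

        return remove_small_objects(
            mask_or_labels, max_size=min_px - 1, connectivity=connectivity
        )
    out = mask_or_labels.copy()
    counts = np.bincount(out.ravel())
    small = counts < min_px
    small[0] = False
    out[small[out]] = 0
    return out


def segment_nuclei(
    nuclear_channel: np.ndarray, config: MorphometryConfig | None = None
) -> np.ndarray:
    """Label nuclei: Otsu threshold, area filter, watershed declumping."""
    config = config or MorphometryConfig()
    mask = _threshold(np.asarray(nuclear_channel, dtype=float), "otsu")
    min_px = config.area_px(config.min_nucleus_area_um2)
    mask = _drop_small(mask, min_px)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance,
        min_distance=config.declump_min_distance_px,
        labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels, _ = ndi.label(mask)
        return labels.astype(np.int32)
    labels = watershed(-distance, markers, mask=mask)
    # watershed can shave fragments below the area rule; drop them
    labels = _drop_small(labels, min_px)
    out, _, _ = _relabel(labels)
    return out


def _relabel(labels: np.ndarray) -> tuple[np.ndarray, int, dict]:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    mapping = {}
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
        mapping[int(old)] = new
    return out, len(ids), mapping


def segment_cells(
    viability_channel: np.ndarray,
    nuclei: np.ndarray,
    config: MorphometryConfig | None = None,
) -> SegmentationResult:
    """Classify viability-channel objects into viable somata, rejected
    beads, and score calcein-negative nuclei as dead cells."""
    config = config or MorphometryConfig()
    via = np.asarray(viability_channel, dtype=float)
    if via.shape != nuclei.shape:
        raise ValueError("viability channel and nuclei label shapes differ")
    via_mask = _threshold(via, "background")

    # detach cell-body candidates from the thin neurite meshwork; the
    # smaller radius keeps beads detectable as (rejectable) candidates
    candidates = opening(via_mask, disk(config.soma_opening_radius_px))
    cand_labels, n_cand = ndi.label(candidates)
    # a stricter opening trims the wedges where neurites enter the soma,
    # so the accepted soma mask hugs the actual cell body
    refined = opening(via_mask, disk(config.soma_refine_radius_px))

    min_soma_px = config.area_px(config.min_soma_area_um2)
    soma = np.zeros(via.shape, dtype=np.int32)
    rejected: list[dict] = []
    next_label = 0
    for cid in range(1, n_cand + 1):
        obj = cand_labels == cid
        area = int(obj.sum())
        nuc_overlap = np.unique(nuclei[obj])
        has_nucleus = bool((nuc_overlap > 0).any())
        if has_nucleus and area >= min_soma_px:
            next_label += 1
            core = obj & refined
            soma[core if core.any() else obj] = next_label
        else:
            reason = []
            if not has_nucleus:
                reason.append("no_nucleus")
            if area < min_soma_px:
                reason.append("too_small")
            com = ndi.center_of_mass(obj)
            rejected.append(
                {
                    "area_px": area,
                    "reason": "+".join(reason),
                    "centroid": (float(com[0]), float(com[1])),
                }
            )

    # a nucleus is alive only if enough of it sits on calcein signal
    dead: list[int] = []
    for nid in range(1, int(nuclei.max()) + 1):
        nuc = nuclei == nid
        area = nuc.sum()
        if area == 0:
            continue
        frac = float((via_mask & nuc).sum()) / float(area)
        if frac < config.nucleus_alive_overlap:
            dead.append(nid)

    return SegmentationResult(
        nuclei=nuclei,
        somata=soma,
        dead_nuclei=tuple(dead),
        rejected=tuple(rejected),
        viability_mask=via_mask,
        pixel_size_um=config.pixel_size_um,
    )


def _polyline_length(chain: np.ndarray, step: int = 5) -> float:
    """Arc length of a skeleton pixel chain, in px.

    Sub-sampling the chain every few pixels before summing chord
    lengths suppresses the overestimation bias of per-pixel step counts
    on digital lines (up to ~8% at unfavorable angles).
    """
    if len(chain) < 2:
        return 0.0
    if len(chain) <= step:
        d = np.diff(chain.astype(float), axis=0)
        return float(np.linalg.norm(d, axis=1).sum())
    idx = list(range(0, len(chain) - 1, step)) + [len(chain) - 1]
    pts = chain[idx].astype(float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _pixel_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    coords = np.argwhere(skel)
    pixel_set = {tuple(p) for p in coords}
    g.add_nodes_from(pixel_set)
    for r, c in pixel_set:
        for dr, dc in _NEIGHBORS:
            q = (r + dr, c + dc)
            if q in pixel_set:
                g.add_edge((r, c), q)
    return g


def _prune_spurs(pg: nx.Graph, min_len: int) -> nx.Graph:
    """Remove terminal chains shorter than ``min_len`` pixels that hang
    off a junction — artifacts of skeletonizing slightly lumpy strokes."""
    changed = True
    while changed:
        changed = False
        for ep in [n for n in pg.nodes if pg.degree(n) == 1]:
            if ep not in pg:
                continue
            chain = [ep]
            prev: tuple | None = None
            cur = ep
            while pg.degree(cur) <= 2 and len(chain) <= min_len:
                nxts = [q for q in pg.neighbors(cur) if q != prev]
                if not nxts:
                    break
                prev, cur = cur, nxts[0]
                chain.append(cur)
            if len(chain) <= min_len and cur in pg and pg.degree(cur) >= 3:
                pg.remove_nodes_from(chain[:-1])
                changed = True
    return pg


def _condense_skeleton(pg: nx.Graph, pixel_size: float) -> nx.Graph:
    """Condense a pixel graph into a junction/endpoint graph whose edges
    carry the polyline and its physical length."""
    g = nx.MultiGraph()
    for comp in nx.connected_components(pg):
        sub = pg.subgraph(comp)
        nodes = [n for n in sub if sub.degree(n) != 2]
        if not nodes:  # pure cycle: break it at an arbitrary pixel
            nodes = [next(iter(comp))]
        node_set = set(nodes)
        visited_edges = set()
        for start in nodes:
            for nbr in sub.neighbors(start):
                if (start, nbr) in visited_edges:
                    continue
                chain = [start, nbr]
                prev, cur = start, nbr
                while cur not in node_set:
                    nxts = [q for q in sub.neighbors(cur) if q != prev]
                    if not nxts:
                        break
                    prev, cur = cur, nxts[0]
                    chain.append(cur)
                visited_edges.add((start, nbr))
                visited_edges.add((chain[-1], chain[-2]))
                arr = np.asarray(chain)
                g.add_edge(
                    chain[0],
                    chain[-1],
                    length_um=_polyline_length(arr) * pixel_size,
                    polyline=arr,
                )
        if len(comp) == 1:
            g.add_node(next(iter(comp)))
    return g


def trace_neurites(
    segmentation: SegmentationResult, config: MorphometryConfig | None = None
) -> SegmentationResult:
    """Skeletonize the non-soma calcein area into a neurite graph.

    Each skeleton component is attached to the viable soma it contacts
    (the soma with the most skeleton pixels in its dilated rim); parts
    touching no soma stay flagged as unattached fragments (label 0) but
    still count toward total length. Processes are counted as distinct
    skeleton clusters entering a soma's rim; branch points are skeleton
    junctions away from somata.
    """
    config = config or MorphometryConfig()
    if segmentation.pixel_size_um is None and config.pixel_size_um is None:
        raise ValueError("pixel size metadata is required for neurite tracing")
    pixel_size = segmentation.pixel_size_um or config.pixel_size_um

    soma_mask = segmentation.somata > 0
    soma_dil = (
        dilation(soma_mask, disk(config.soma_dilate_px))
        if config.soma_dilate_px > 0
        else soma_mask
    )
    neurite_mask = segmentation.viability_mask & ~soma_dil
    skel = skeletonize(neurite_mask)
    skel = _drop_small(skel, config.min_skeleton_px, connectivity=2)

    pg = _pixel_graph(skel)
    pg = _prune_spurs(pg, config.prune_spur_px)
    skel = np.zeros_like(skel)
    for r, c in pg.nodes:
        skel[r, c] = True

    # rim in which skeleton pixels are considered attached to a soma
    contact_rad = config.soma_dilate_px + 2
    grown = ndi.grey_dilation(segmentation.somata, footprint=disk(contact_rad))
    rim_labels = np.where(soma_dil, 0, grown)

    skel_labels, n_comp = ndi.label(skel, structure=np.ones((3, 3)))
    component_soma: dict[int, int] = {}
    for comp_id in range(1, n_comp + 1):
        comp_mask = skel_labels == comp_id
        touching = rim_labels[comp_mask]
        touching = touching[touching > 0]
        component_soma[comp_id] = (
            int(np.bincount(touching).argmax()) if len(touching) else 0
        )

    # processes: connected clusters of skeleton pixels inside each rim
    contact = skel & (rim_labels > 0)
    contact_labels, n_contact = ndi.label(contact, structure=np.ones((3, 3)))
    processes: dict[int, int] = {}
    for cid in range(1, n_contact + 1):
        soma_ids = rim_labels[contact_labels == cid]
        soma_ids = soma_ids[soma_ids > 0]
        if len(soma_ids):
            sid = int(np.bincount(soma_ids).argmax())
            processes[sid] = processes.get(sid, 0) + 1

    graph = _condense_skeleton(pg, pixel_size)

    # branch points: junction pixels (degree >= 3) outside soma rims,
    # adjacent junction pixels collapsed into one
    junction = np.zeros_like(skel)
    for n in pg.nodes:
        if pg.degree(n) >= 3 and rim_labels[n] == 0 and not soma_dil[n]:
            junction[n] = True
    _, n_branch = ndi.label(junction, structure=np.ones((3, 3)))

    # skeletons retract from stroke ends by roughly the local half-width;
    # credit free tips with the local mask radius (capped so endpoints in
    # merged blobs cannot contribute blob-scale radii). Roots cut at the
    # soma rim are instead credited with their distance to the halo-
    # corrected soma surface: the thresholded soma overshoots the true
    # cell body by the PSF halo, and the process really extends there.
    from skimage.morphology import erosion

    dt = ndi.distance_transform_edt(neurite_mask)
    core = (
        erosion(soma_mask, disk(config.soma_halo_px))
        if config.soma_halo_px > 0
        else soma_mask
    )
    dist_core = (
        ndi.distance_transform_edt(~core) if core.any() else np.zeros_like(dt)
    )
    tip_px = 0.0
    for n in pg.nodes:
        if pg.degree(n) != 1:
            continue
        if rim_labels[n] > 0:
            tip_px += min(float(dist_core[n]), 8.0)
        else:
            tip_px += min(float(dt[n]), 5.0)

    segmentation.tip_extension_um = tip_px * pixel_size
    segmentation.skeleton = graph
    segmentation.component_soma = component_soma
    segmentation.processes_per_soma = processes
    segmentation.n_branches = int(n_branch)
    segmentation.pixel_size_um = pixel_size
    return segmentation


def total_skeleton_length_um(segmentation: SegmentationResult) -> float:
    if segmentation.skeleton is None:
        raise ValueError("run trace_neurites first")
    edges = sum(d["length_um"] for _, _, d in segmentation.skeleton.edges(data=True))
    return float(edges + segmentation.tip_extension_um)


def well_injury_metrics(
    segmentation: SegmentationResult, reference_count: float | None = None
) -> dict[str, float]:
    """The nine per-well injury metrics.

    ``reference_count`` is the expected number of cells per image for a
    healthy culture at the seeding density (the denominator of the
    viability percentage); when absent or non-positive the viability
    metric is reported as NaN while everything else is computed.
    """
    viable = segmentation.viable_count
    dead = segmentation.dead_count
    total_len = (
        total_skeleton_length_um(segmentation)
        if segmentation.skeleton is not None
        else 0.0
    )
    total_proc = int(sum(segmentation.processes_per_soma.values()))
    total_branch = int(segmentation.n_branches)
    per = float(viable) if viable > 0 else None
    metrics = {
        "viable_cells_per_image": float(viable),
        "dead_cells_per_image": float(dead),
        "total_neurite_length": total_len,
        "total_processes": float(total_proc),
        "total_branches": float(total_branch),
        "neurite_length_per_cell": total_len / per if per else 0.0,
        "processes_per_cell": total_proc / per if per else 0.0,
        "branches_per_cell": total_branch / per if per else 0.0,
        "cell_viability": (
            100.0 * viable / reference_count
            if reference_count and reference_count > 0
            else float("nan")
        ),
    }
    assert set(metrics) == set(METRIC_COLUMNS)
    return metrics


def analyze_well(
    nuclear_channel: np.ndarray,
    viability_channel: np.ndarray,
    config: MorphometryConfig | None = None,
    reference_count: float | None = None,
    preprocess: bool = True,
) -> tuple[dict[str, float], SegmentationResult]:
    """Full per-well pipeline: preprocess, segment, trace, measure."""
    config = config or MorphometryConfig()
    nuc = preprocess_live(nuclear_channel, config) if preprocess else np.asarray(nuclear_channel, float)
    via = preprocess_live(viability_channel, config) if preprocess else np.asarray(viability_channel, float)
    nuclei = segment_nuclei(nuc, config)
    seg = segment_cells(via, nuclei, config)
    seg = trace_neurites(seg, config)
    return well_injury_metrics(seg, reference_count), seg
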