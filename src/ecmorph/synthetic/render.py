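"""Renderer for synthetic multichannel endothelial-monolayer fields.

Produces already-projected 2D 16-bit fields with the five stains of the
profiling panel (HOECHST nuclei, VE-cadherin junctions, phalloidin F-actin,
MitoTracker mitochondria, vWF) together with pixel-exact ground truth for
benchmarking segmentation and feature extraction.

Geometry: nucleus seed points on a jittered grid; the confluent monolayer
is the Voronoi tessellation of the seeds (cells tile the field without
overlap, as in a cobblestone endothelial monolayer). Mitochondria are drawn
as a connected perinuclear ring with persistent random-walk tubules at low
``mito_fragmentation`` and progressively broken into puncta — biased into
the perinuclear annulus by ``mito_perinuclear`` — as fragmentation rises.
Noise is Poisson (shot) plus Gaussian (read) at a configurable SNR.

This is a phenomenological phantom: no optics/PSF model, no z-stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import draw as skdraw
from skimage import morphology, segmentation

from ..core import CHANNELS, FieldImage
from .phenotypes import PhenotypeParams

#: Outer radius of the perinuclear annulus, in units of the nucleus
#: equivalent radius. Shared with the feature extractor.
PERINUCLEAR_FACTOR = 1.5

#: Peak signal amplitude of a rendered channel, in camera counts.
SIGNAL_AMPLITUDE = 8000.0
BACKGROUND = 200.0


@dataclass
class FieldGeometry:
    """Field size and sampling. Default 512 px square at 0.33 um/px."""

    shape: tuple = (512, 512)
    pixel_size_um: float = 0.33

    def __post_init__(self) -> None:
        h, w = self.shape
        if h * w == 0:
            raise ValueError("degenerate field geometry (zero area)")
        if min(h, w) < 128:
            raise ValueError("field must be at least 128x128 px")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class GroundTruth:
    """Pixel-exact annotation of one rendered field."""

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    centroids: np.ndarray  # (n, 2) row/col seed positions
    nucleus_equiv_radius_px: np.ndarray
    mito_object_counts: np.ndarray
    mito_perinuclear_fraction: np.ndarray
    phenotype: PhenotypeParams
    pixel_size_um: float
    extras: dict = dc_field(default_factory=dict)

    @property
    def cell_count(self) -> int:
        return len(self.centroids)


def _seed_points(n: int, shape, rng) -> np.ndarray:
    """Jittered-grid seed points giving near-confluent coverage."""
    h, w = shape
    aspect = w / h
    ny = max(1, int(round(np.sqrt(n / aspect))))
    nx = max(1, int(np.ceil(n / ny)))
    ys = (np.arange(ny) + 0.5) * h / ny
    xs = (np.arange(nx) + 0.5) * w / nx
    pts = np.array([(y, x) for y in ys for x in xs])
    jitter = np.column_stack(
        [rng.uniform(-0.33 * h / ny, 0.33 * h / ny, len(pts)),
         rng.uniform(-0.33 * w / nx, 0.33 * w / nx, len(pts))]
    )
    pts = pts + jitter
    rng.shuffle(pts)
    pts = pts[:n]
    return np.clip(pts, [2, 2], [h - 3, w - 3])


def _voronoi_labels(points: np.ndarray, shape) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    grid = np.column_stack([rr.ravel(), cc.ravel()])
    _, idx = cKDTree(points).query(grid, k=1)
    return (idx + 1).reshape(shape).astype(np.int32)


def _smooth_noise(shape, rng, sigma: float) -> np.ndarray:
    """Gaussian-filtered uniform noise rescaled to [0, 1]."""
    f = ndi.gaussian_filter(rng.random(shape), sigma)
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def _random_walk(start, angle, n_steps, rng, shape, wobble=0.35, step=1.2):
    pts = []
    y, x = start
    a = angle
    for _ in range(n_steps):
        y += step * np.sin(a)
        x += step * np.cos(a)
        a += rng.normal(0.0, wobble)
        iy, ix = int(round(y)), int(round(x))
        if not (0 <= iy < shape[0] and 0 <= ix < shape[1]):
            break
        pts.append((iy, ix))
    return pts


def _ring_points(center, radius, n=None):
    if n is None:
        n = max(12, int(2 * np.pi * radius))
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.sin(th), center[1] + radius * np.cos(th)]
    )


def render_field(
    phenotype: PhenotypeParams,
    geometry: FieldGeometry | None = None,
    seed: int = 0,
    field_id: str = "F000",
    well_id: str = "A01",
    site: int = 1,
) -> tuple[FieldImage, GroundTruth]:
    """Render one field and its ground truth.

    Deterministic for a given (phenotype, geometry, seed). Channels are
    returned as uint16 arrays keyed by the canonical names in
    :data:`ecmorph.core.CHANNELS`.
    """
    geometry = geometry or FieldGeometry()
    shape = tuple(geometry.shape)
    px = geometry.pixel_size_um
    rng = np.random.default_rng(seed)

    n_cells = max(1, int(round(phenotype.cell_density)))
    seeds = _seed_points(n_cells, shape, rng)
    cell_labels = _voronoi_labels(seeds, shape)
    if n_cells > 1:
        from scipy.spatial import distance

        nn = np.sort(distance.squareform(distance.pdist(seeds)), axis=1)[:, 1]
    else:
        nn = np.full(1, np.inf)

    # --- nuclei ------------------------------------------------------------
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    r_eq_px = np.zeros(n_cells)
    nuc_clean = np.zeros(shape)
    for i, (cy, cx) in enumerate(seeds):
        lab = i + 1
        # cap the radius so neighbouring nuclei stay separated
        r_um = max(3.0, min(rng.normal(6.3, 0.55), 0.40 * nn[i] * px))
        aspect = rng.uniform(0.72, 0.98)
        r1 = r_um / px / np.sqrt(aspect)
        r2 = r_um / px * np.sqrt(aspect)
        rot = rng.uniform(0, np.pi)
        rr, cc = skdraw.ellipse(cy, cx, r1, r2, shape=shape, rotation=rot)
        keep = cell_labels[rr, cc] == lab  # one nucleus strictly per cell
        rr, cc = rr[keep], cc[keep]
        nucleus_labels[rr, cc] = lab
        r_eq_px[i] = np.sqrt(len(rr) / np.pi)
    chromatin = 0.72 + 0.28 * _smooth_noise(shape, rng, 2.0)
    nuc_clean = (nucleus_labels > 0) * chromatin
    nuc_clean = ndi.gaussian_filter(nuc_clean, 1.0)

    # --- VE-cadherin junctions --------------------------------------------
    irr = phenotype.junction_irregularity
    boundary = segmentation.find_boundaries(cell_labels, mode="thick")
    modfield = _smooth_noise(shape, rng, 6.0)
    bvals = modfield[boundary]
    gap_cut = np.quantile(bvals, 0.55 * irr) if bvals.size else 0.0
    junction = boundary & (modfield >= gap_cut)
    junction = morphology.dilation(junction, morphology.disk(1))
    ve_clean = junction * (0.55 + 0.45 * modfield)
    ve_clean += 0.08 * (cell_labels > 0)
    ve_clean = ndi.gaussian_filter(ve_clean, 1.0)

    # --- F-actin -----------------------------------------------------------
    act = phenotype.actin_stress
    actin_clean = 0.22 * (0.75 + 0.5 * _smooth_noise(shape, rng, 3.0))
    actin_clean += 0.30 * ndi.gaussian_filter(boundary.astype(float), 1.5)
    fibre = np.zeros(shape)
    for i, (cy, cx) in enumerate(seeds):
        lab = i + 1
        n_fib = rng.poisson(0.6 + 6.0 * act)
        theta = rng.uniform(0, np.pi)
        half = 0.9 * np.sqrt((cell_labels == lab).sum() / np.pi)
        for _ in range(n_fib):
            a = theta + rng.normal(0.0, 0.25)
            oy = cy + rng.normal(0, half * 0.45)
            ox = cx + rng.normal(0, half * 0.45)
            y0, x0 = oy - half * np.sin(a), ox - half * np.cos(a)
            y1, x1 = oy + half * np.sin(a), ox + half * np.cos(a)
            rr, cc, val = skdraw.line_aa(
                int(np.clip(y0, 0, shape[0] - 1)),
                int(np.clip(x0, 0, shape[1] - 1)),
                int(np.clip(y1, 0, shape[0] - 1)),
                int(np.clip(x1, 0, shape[1] - 1)),
            )
            keep = cell_labels[rr, cc] == lab
            fibre[rr[keep], cc[keep]] = np.maximum(
                fibre[rr[keep], cc[keep]], 0.85 * val[keep]
            )
    actin_clean += fibre
    actin_clean = ndi.gaussian_filter(actin_clean, 0.8)

    # --- mitochondria ------------------------------------------------------
    frag = phenotype.mito_fragmentation
    peri = phenotype.mito_perinuclear
    mito_skel = np.zeros(shape, dtype=bool)
    cytoplasm = (cell_labels > 0) & (nucleus_labels == 0)
    dist_to_centroid = np.zeros(shape)
    annulus = np.zeros(shape, dtype=bool)
    for i, (cy, cx) in enumerate(seeds):
        lab = i + 1
        cellmask = cell_labels == lab
        sl = ndi.find_objects(cellmask.astype(np.int8))[0]
        yy, xx = np.mgrid[sl[0], sl[1]]
        d = np.hypot(yy - cy, xx - cx)
        dist_to_centroid[sl][cellmask[sl]] = d[cellmask[sl]]
        ann_i = (
            cellmask[sl]
            & (nucleus_labels[sl] == 0)
            & (d <= PERINUCLEAR_FACTOR * max(r_eq_px[i], 1.0))
        )
        annulus[sl] |= ann_i

        r_ring = 1.22 * max(r_eq_px[i], 2.0)
        ring = _ring_points((cy, cx), r_ring)
        tub_pts = [
            (iy, ix)
            for iy, ix in ((int(round(y)), int(round(x))) for y, x in ring)
            if 0 <= iy < shape[0] and 0 <= ix < shape[1]
        ]
        cell_rad = np.sqrt(cellmask.sum() / np.pi)
        n_walks = 5
        walk_len = int((1.0 - 0.85 * frag) * cell_rad * 0.8 / 1.2)
        for w in range(n_walks if walk_len >= 3 else 0):
            a0 = rng.uniform(0, 2 * np.pi)
            sy = cy + r_ring * np.sin(a0)
            sx = cx + r_ring * np.cos(a0)
            tub_pts += _random_walk((sy, sx), a0, walk_len, rng, shape)
        for y, x in tub_pts:
            if cellmask[y, x] and nucleus_labels[y, x] == 0:
                mito_skel[y, x] = True
        # breaks: erase small discs along the network as fragmentation rises
        n_breaks = int(round(frag * 22))
        cand = np.argwhere(mito_skel & cellmask)
        if n_breaks and len(cand):
            picks = cand[rng.integers(0, len(cand), n_breaks)]
            for y, x in picks:
                rr, cc = skdraw.disk((y, x), 2.2, shape=shape)
                mito_skel[rr, cc] = False
        # puncta, biased into the perinuclear annulus
        n_punc = rng.poisson(25 * frag)
        ann_coords = np.argwhere(annulus[sl])
        cyt_coords = np.argwhere(cellmask[sl] & (nucleus_labels[sl] == 0))
        for _ in range(n_punc):
            pool = ann_coords if (rng.random() < peri and len(ann_coords)) else cyt_coords
            if not len(pool):
                continue
            y, x = pool[rng.integers(0, len(pool))]
            rr, cc = skdraw.disk(
                (y + sl[0].start, x + sl[1].start),
                rng.uniform(1.0, 1.9),
                shape=shape,
            )
            mito_skel[rr, cc] = True
    mito_binary = morphology.dilation(mito_skel, morphology.disk(1))
    mito_binary &= cytoplasm
    mito_clean = mito_binary * (0.7 + 0.3 * _smooth_noise(shape, rng, 1.5))
    mito_clean = ndi.gaussian_filter(mito_clean, 0.7)

    # ground truth mito stats from the noiseless mask / clean channel
    struct = np.ones((3, 3), dtype=bool)
    counts = np.zeros(n_cells, dtype=int)
    peri_frac = np.zeros(n_cells)
    for i in range(n_cells):
        lab = i + 1
        cellmask = cell_labels == lab
        objs, n_obj = ndi.label(mito_binary & cellmask, structure=struct)
        if n_obj:
            sizes = np.bincount(objs.ravel())[1:]
            n_obj = int((sizes >= 3).sum())
        counts[i] = n_obj
        tot = mito_clean[cellmask].sum()
        peri_frac[i] = mito_clean[cellmask & annulus].sum() / tot if tot > 0 else 0.0

    # --- vWF (Weibel-Palade bodies) ---------------------------------------
    vwf_skel = np.zeros(shape, dtype=bool)
    for i, (cy, cx) in enumerate(seeds):
        lab = i + 1
        coords = np.argwhere((cell_labels == lab) & (nucleus_labels == 0))
        if not len(coords):
            continue
        for _ in range(rng.poisson(phenotype.wpb_count_mean)):
            y, x = coords[rng.integers(0, len(coords))]
            a = rng.uniform(0, np.pi)
            length = rng.uniform(3, 8)
            y1 = int(np.clip(y + length * np.sin(a), 0, shape[0] - 1))
            x1 = int(np.clip(x + length * np.cos(a), 0, shape[1] - 1))
            rr, cc = skdraw.line(y, x, y1, x1)
            vwf_skel[rr, cc] = True
    vwf_clean = ndi.gaussian_filter(
        morphology.dilation(vwf_skel, morphology.disk(1)).astype(float), 0.7
    )

    clean = {
        "nuclei": nuc_clean,
        "ve_cadherin": ve_clean,
        "f_actin": actin_clean,
        "mitochondria": mito_clean,
        "vwf": vwf_clean,
    }
    channels = {}
    for name in CHANNELS:
        img = BACKGROUND + SIGNAL_AMPLITUDE * np.clip(clean[name], 0.0, 1.2)
        if np.isfinite(phenotype.intensity_snr):
            img = rng.poisson(img).astype(float)
            img += rng.normal(
                0.0, SIGNAL_AMPLITUDE / phenotype.intensity_snr, shape
            )
        channels[name] = np.clip(img, 0, 65535).astype(np.uint16)

    image = FieldImage(
        channels=channels,
        pixel_size_um=px,
        field_id=field_id,
        well_id=well_id,
        site=site,
    )
    truth = GroundTruth(
        cell_labels=cell_labels,
        nucleus_labels=nucleus_labels,
        centroids=seeds,
        nucleus_equiv_radius_px=r_eq_px,
        mito_object_counts=counts,
        mito_perinuclear_fraction=peri_frac,
        phenotype=phenotype,
        pixel_size_um=px,
        extras={"annulus": annulus, "mito_binary": mito_binary},
    )
    return image, truth
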