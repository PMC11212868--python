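"""Nuclear morphometrics from multi-channel images.

Quantifies, per nucleus: shape (length, width, aspect ratio from principal
moments of the segmented chromatin mask), perinuclear-to-cytoplasmic
tubulin enrichment (mean intensity in a 1 um band outside the nuclear
boundary over the mean in a 2-4 um cytoplasmic band, optionally split into
tip and side sectors), chromatin protrusions at the nuclear tips (residual
chromatin outside the moment-fitted ellipse), and perinuclear reporter foci
(bright connected components whose centroid lies within 1 um of the nuclear
border or inside the nucleus).

All metrics are invariant to global intensity scaling: thresholds are
defined relative to image statistics and enrichment is a ratio.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from ._util import rng_from
from .errors import SegmentationError

#: fractional clearance outside the fitted ellipse before a pixel counts as
#: residual chromatin — absorbs pixelation of the ellipse boundary
ELLIPSE_RESIDUAL_MARGIN = 0.03


@dataclass
class RingGeometry:
    """Bands (um, measured outward from the nuclear boundary) and sectors."""

    pn_ring_width: float = 1.0
    cyt_inner_offset: float = 2.0
    cyt_outer_offset: float = 4.0
    tip_sector_half_angle: float = 30.0    # degrees, around the major axis
    #: trim at both edges of the perinuclear band, excluding pixels whose
    #: intensity is contaminated by PSF blur across the band edges
    psf_guard: float = 0.2

    def validate(self):
        if not 0 < self.pn_ring_width <= self.cyt_inner_offset < self.cyt_outer_offset:
            raise ValueError("require 0 < pn_ring_width <= cyt_inner < cyt_outer")
        if not 0 <= self.psf_guard < self.pn_ring_width / 2:
            raise ValueError("psf_guard must be < half the perinuclear band width")


@dataclass
class NucleusMorphometry:
    nuclear_length: float        # um, extent along the major axis
    nuclear_width: float         # um, extent along the minor axis
    aspect_ratio: float
    area: float                  # um^2 (2-D)
    enrichment_overall: float
    enrichment_tips: float
    enrichment_sides: float
    protrusion_present: bool
    protrusion_area: float       # um^2
    foci_count: int
    foci_areas: list = field(default_factory=list)


def segment_nucleus(chromatin: np.ndarray, voxel_size: float = 0.1):
    """Otsu threshold -> largest connected component -> hole fill.

    Returns the binary mask; raises SegmentationError when nothing usable
    survives (e.g. an all-background field).
    """
    img = np.asarray(chromatin, dtype=float)
    if img.max() <= img.min():
        raise SegmentationError("flat image, nothing to segment")
    thr = threshold_otsu(img)
    fg = img > thr
    if not fg.any() or fg.mean() < 1e-4:
        raise SegmentationError("empty foreground after thresholding")
    # Otsu splits pure background noise roughly in half; a real nucleus
    # separates foreground and background by several image SDs
    separation = (img[fg].mean() - img[~fg].mean()) / img.std()
    if separation < 2.2:
        raise SegmentationError(
            f"foreground/background separation too weak ({separation:.2f} SD)")
    lab, n = ndimage.label(fg)
    if n == 0:
        raise SegmentationError("no connected component found")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    # an Otsu split of pure background produces a speckle "component";
    # a nucleus occupies a meaningful part of the field
    if mask.sum() < 10 or mask.sum() < 0.002 * mask.size:
        raise SegmentationError("largest component too small to be a nucleus")
    return mask


def _principal_axes(mask: np.ndarray):
    """Centroid, unit major/minor axes and second central moments."""
    coords = np.argwhere(mask).astype(float)      # (row, col)
    centroid = coords.mean(axis=0)
    d = coords - centroid
    cov = d.T @ d / len(d)
    evals, evecs = np.linalg.eigh(cov)            # ascending
    major = evecs[:, 1]
    minor = evecs[:, 0]
    return centroid, major, minor, evals[::-1], d


def nuclear_dimensions(mask: np.ndarray, voxel_size: float = 0.1):
    """Length, width (um), aspect ratio and area from the mask moments.

    Full extents along the principal axes of the second central moments;
    for a uniform ellipse the semi-axis equals twice the moment root
    (lambda = a^2/4), which is rotation invariant up to pixelation.
    """
    if mask.sum() < 10:
        raise ValueError("degenerate mask (< 10 pixels)")
    _, _, _, evals, _ = _principal_axes(mask)
    length = 4.0 * np.sqrt(evals[0]) * voxel_size
    width = 4.0 * np.sqrt(evals[1]) * voxel_size
    if width > length:
        length, width = width, length
    area = float(mask.sum()) * voxel_size ** 2
    return {"nuclear_length": float(length), "nuclear_width": float(width),
            "aspect_ratio": float(length / width), "area": area}


def _band_masks(mask, rings: RingGeometry, voxel_size):
    dist_out = ndimage.distance_transform_edt(~mask) * voxel_size
    pn = (~mask) & (dist_out > rings.psf_guard) \
        & (dist_out <= rings.pn_ring_width - rings.psf_guard)
    cyt = (dist_out > rings.cyt_inner_offset) & (dist_out <= rings.cyt_outer_offset)
    return pn, cyt, dist_out


def _sector_split(mask, shape):
    """Boolean map of the tip sectors (True) around the mask's major axis."""
    centroid, major, _, _, _ = _principal_axes(mask)
    rows, cols = np.indices(shape)
    dr = rows - centroid[0]
    dc = cols - centroid[1]
    along = dr * major[0] + dc * major[1]
    radial = np.hypot(dr, dc)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.abs(along) / np.where(radial == 0, np.inf, radial)
    return cosang


def perinuclear_enrichment(tubulin: np.ndarray, mask: np.ndarray,
                           rings: RingGeometry | None = None,
                           voxel_size: float = 0.1):
    """Perinuclear / cytoplasmic mean tubulin ratios: overall, tips, sides.

    The perinuclear band is the first ``pn_ring_width`` um outside the
    nuclear boundary; the cytoplasmic reference is the band between the two
    cyt offsets.  Tip/side sectors split the perinuclear band at
    ``tip_sector_half_angle`` around the major axis.
    """
    rings = rings or RingGeometry()
    rings.validate()
    pn, cyt, _ = _band_masks(mask, rings, voxel_size)
    if cyt.sum() == 0:
        raise ValueError("empty cytoplasmic band: nucleus too close to the field edge")
    if pn.sum() == 0:
        raise ValueError("empty perinuclear band")
    cyt_mean = float(tubulin[cyt].mean())
    if cyt_mean <= 0:
        raise ValueError("non-positive cytoplasmic mean intensity")
    cosang = _sector_split(mask, mask.shape)
    cos_cut = np.cos(np.deg2rad(rings.tip_sector_half_angle))
    tips = pn & (cosang >= cos_cut)
    sides = pn & (cosang < cos_cut)
    out = {
        "enrichment_overall": float(tubulin[pn].mean()) / cyt_mean,
        "enrichment_tips": float(tubulin[tips].mean()) / cyt_mean if tips.any() else np.nan,
        "enrichment_sides": float(tubulin[sides].mean()) / cyt_mean if sides.any() else np.nan,
    }
    return out


def _fit_ellipse_metric(mask, shape, n_refit: int = 5):
    """Normalized ellipse metric m (m<=1 inside the moment-fit ellipse).

    The fit is made robust to protrusions by iterating: fit from moments,
    drop mask pixels falling outside the current ellipse, refit.  The
    refitted core converges to the main nuclear body so a protrusion shows
    up cleanly as residual mass.
    """
    core = mask
    m = None
    for _ in range(n_refit):
        centroid, major, minor, evals, _ = _principal_axes(core)
        a = 2.0 * np.sqrt(evals[0])  # uniform ellipse: lambda = (semi axis)^2/4
        b = 2.0 * np.sqrt(evals[1])
        rows, cols = np.indices(shape)
        dr = rows - centroid[0]
        dc = cols - centroid[1]
        u = dr * major[0] + dc * major[1]
        v = dr * minor[0] + dc * minor[1]
        m = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        new_core = mask & (m <= 1.0)
        if new_core.sum() < 10 or new_core.sum() == core.sum():
            break
        core = new_core
    return m


def detect_protrusion(chromatin: np.ndarray, mask: np.ndarray,
                      tip_sector_half_angle: float = 30.0,
                      min_protrusion_area: float = 1.0,
                      voxel_size: float = 0.1):
    """Chromatin spilling past the fitted nuclear ellipse at a tip.

    Residual mask pixels outside the moment-fitted ellipse (with a small
    pixelation margin), restricted to the tip sectors, connected, and of
    total area >= ``min_protrusion_area`` um^2 flag a protrusion.  Returns
    ``(present, area_um2)``.
    """
    m = _fit_ellipse_metric(mask, mask.shape)
    residual = mask & (m > 1.0)
    if not residual.any():
        return False, 0.0
    cosang = _sector_split(mask, mask.shape)
    cos_cut = np.cos(np.deg2rad(tip_sector_half_angle))
    lab, n = ndimage.label(residual)
    best_area = 0.0
    for region in regionprops(lab):
        r, c = region.centroid
        if cosang[int(round(r)), int(round(c))] < cos_cut:
            continue
        coords = tuple(region.coords.T)
        # pixelation leaves thin slivers hugging the ellipse; a protrusion
        # has pixels well beyond it (radial clearance gate)
        if float(np.max(m[coords])) - 1.0 < ELLIPSE_RESIDUAL_MARGIN:
            continue
        area = region.area * voxel_size ** 2
        best_area = max(best_area, area)
    return best_area >= min_protrusion_area, float(best_area)


def _background_stats(img, n_clip=4, clip=3.0):
    """Sigma-clipped mean/SD: robust background statistics of a channel."""
    data = np.asarray(img, dtype=float).ravel()
    for _ in range(n_clip):
        mu, sd = data.mean(), data.std()
        if sd == 0:
            break
        keep = np.abs(data - mu) <= clip * sd
        if keep.all():
            break
        data = data[keep]
    return float(data.mean()), float(data.std())


def detect_foci(foci_img: np.ndarray, mask: np.ndarray,
                rings: RingGeometry | None = None,
                threshold_k: float = 3.0,
                min_focus_area: float = 0.05, max_focus_area: float = 5.0,
                mode: str = "perinuclear", voxel_size: float = 0.1):
    """Count bright foci in the admissible zone.

    Candidate pixels exceed background mean + k*SD; connected components are
    filtered by area bounds and kept iff their centroid lies in the
    admissible zone: the perinuclear ring union the nucleus (``perinuclear``
    mode, default ring width 1 um) or the nuclear interior (``nuclear``
    mode).  Returns ``(count, areas_um2)``.
    """
    rings = rings or RingGeometry()
    rings.validate()
    mu, sd = _background_stats(foci_img)
    candidates = foci_img > mu + threshold_k * sd
    if not candidates.any():
        return 0, []
    if mode == "perinuclear":
        dist_out = ndimage.distance_transform_edt(~mask) * voxel_size
        zone = mask | (dist_out <= rings.pn_ring_width)
    elif mode == "nuclear":
        zone = mask
    else:
        raise ValueError(f"unknown foci mode {mode!r}")
    lab_img = label(candidates)
    areas = []
    for region in regionprops(lab_img, intensity_image=foci_img):
        area = region.area * voxel_size ** 2
        if not min_focus_area <= area <= max_focus_area:
            continue
        r, c = (int(round(v)) for v in region.centroid)
        if not zone[r, c]:
            continue
        # size each focus at half maximum above background so the reported
        # area tracks the physical focus, not the detection threshold
        half = mu + 0.5 * (region.intensity_max - mu)
        fwhm_area = float(np.sum(region.image_intensity >= half)) * voxel_size ** 2
        areas.append(max(fwhm_area, voxel_size ** 2))
    return len(areas), areas


def measure_nucleus(channels: dict, rings: RingGeometry | None = None,
                    voxel_size: float = 0.1, **protrusion_kwargs) -> NucleusMorphometry:
    """Full per-nucleus morphometry from a channel dict."""
    mask = segment_nucleus(channels["chromatin"], voxel_size)
    dims = nuclear_dimensions(mask, voxel_size)
    enr = perinuclear_enrichment(channels["tubulin"], mask, rings, voxel_size)
    present, area = detect_protrusion(channels["chromatin"], mask,
                                      voxel_size=voxel_size, **protrusion_kwargs)
    count, areas = detect_foci(channels["foci"], mask, rings, voxel_size=voxel_size)
    return NucleusMorphometry(
        nuclear_length=dims["nuclear_length"], nuclear_width=dims["nuclear_width"],
        aspect_ratio=dims["aspect_ratio"], area=dims["area"],
        enrichment_overall=enr["enrichment_overall"],
        enrichment_tips=enr["enrichment_tips"],
        enrichment_sides=enr["enrichment_sides"],
        protrusion_present=present, protrusion_area=area,
        foci_count=count, foci_areas=areas,
    )


def bootstrap_ci(values, stat=np.mean, n_boot: int = 2000, seed: int = 0,
                 alpha: float = 0.05):
    """Seeded percentile bootstrap CI for a cohort statistic."""
    values = np.asarray(values, dtype=float)
    rng = rng_from(seed, "bootstrap")
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    boots = stat(values[idx], axis=1)
    return float(np.quantile(boots, alpha / 2)), float(np.quantile(boots, 1 - alpha / 2))


def score_cohort(images, mode: str = "protrusion", voxel_size: float = 0.1,
                 rings: RingGeometry | None = None, n_boot: int = 2000,
                 seed: int = 0):
    """Score a cohort of images and summarize with bootstrap CIs.

    ``images`` yields channel dicts or ``(channels, truth)`` pairs.  Modes:
    ``protrusion`` (prevalence of nuclei with protrusions), ``foci`` (mean
    foci count), ``shape`` (mean aspect ratio).  Returns
    ``(per_nucleus_rows, summary_dict)``.
    """
    import pandas as pd
    rows = []
    for i, item in enumerate(images):
        channels = item[0] if isinstance(item, tuple) else item
        mask = segment_nucleus(channels["chromatin"], voxel_size)
        row = {"image_id": i}
        if mode == "protrusion":
            present, area = detect_protrusion(channels["chromatin"], mask,
                                              voxel_size=voxel_size)
            row.update(protrusion_present=present, protrusion_area=area)
        elif mode == "foci":
            count, areas = detect_foci(channels["foci"], mask, rings,
                                       voxel_size=voxel_size)
            row.update(foci_count=count, foci_total_area=float(np.sum(areas)))
        elif mode == "shape":
            row.update(nuclear_dimensions(mask, voxel_size))
        else:
            raise ValueError(f"unknown cohort mode {mode!r}")
        rows.append(row)
    if not rows:
        raise ValueError("empty cohort")
    table = pd.DataFrame(rows)
    key = {"protrusion": "protrusion_present", "foci": "foci_count",
           "shape": "aspect_ratio"}[mode]
    values = table[key].to_numpy(dtype=float)
    lo, hi = bootstrap_ci(values, n_boot=n_boot, seed=seed)
    summary = {"metric": key, "mean": float(values.mean()), "n": len(values),
               "ci_low": lo, "ci_high": hi}
    if mode == "protrusion":
        summary["prevalence"] = summary["mean"]
    return table, summary
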