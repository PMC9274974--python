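"""Adrenal-section histology: nanoparticle coverage per sub-region.

Each section supplies a binary tissue mask and a binary particle mask.
The tissue outline is summarised by the ellipse with the same second
central moments, pixels are mapped to a normalized elliptical radius
(r = 1 on the fitted boundary), and concentric radial bands label the
anatomical sub-regions from the inside out: medulla, zona reticularis
(ZR), zona fasciculata (ZF) and zona glomerulosa (ZG).  Coverage is the
percentage of each zone's pixels that carry particles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.measure import label as cc_label, regionprops

__all__ = [
    "ZONES",
    "DEFAULT_BANDS",
    "SectionMask",
    "EllipseFit",
    "ZoneMap",
    "CoverageReport",
    "fit_ellipse_moments",
    "assign_zones",
    "coverage_by_zone",
]

#: Inside-out anatomical order of the radial bands.
ZONES = ("medulla", "ZR", "ZF", "ZG")
ZONE_CODES = {"outside": 0, "medulla": 1, "ZR": 2, "ZF": 3, "ZG": 4}
#: Default radial band edges (fractions of the fitted boundary radius).
DEFAULT_BANDS = (0.4, 0.7, 0.9)


@dataclass
class SectionMask:
    tissue: np.ndarray  # bool 2-D
    particles: np.ndarray  # bool 2-D
    pixel_size_um: float = 1.0

    def __post_init__(self):
        self.tissue = np.asarray(self.tissue, dtype=bool)
        self.particles = np.asarray(self.particles, dtype=bool)
        if self.tissue.shape != self.particles.shape:
            raise ValueError("tissue and particle masks must have the same shape")
        if self.tissue.ndim != 2:
            raise ValueError("masks must be 2-D")


@dataclass
class EllipseFit:
    center: tuple[float, float]  # (row, col) px
    semi_major: float  # px
    semi_minor: float  # px
    orientation: float  # rad, major axis vs row axis (skimage convention)

    def __post_init__(self):
        if self.semi_major <= 0 or self.semi_minor <= 0:
            raise ValueError("semi-axes must be positive")
        if self.semi_major < self.semi_minor:
            raise ValueError("major semi-axis must be >= minor")


@dataclass
class ZoneMap:
    zones: np.ndarray  # int codes per pixel (ZONE_CODES)
    bands: tuple
    fit: EllipseFit

    def pixels_in(self, zone: str) -> int:
        return int(np.sum(self.zones == ZONE_CODES[zone]))


@dataclass
class CoverageReport:
    zone_pixels: dict
    particle_pixels: dict
    coverage_percent: dict  # NaN where the zone is empty

    def to_dict(self) -> dict:
        return {
            "zone_pixels": {k: int(v) for k, v in self.zone_pixels.items()},
            "particle_pixels": {k: int(v) for k, v in self.particle_pixels.items()},
            "coverage_percent": {
                k: (None if np.isnan(v) else float(v)) for k, v in self.coverage_percent.items()
            },
        }


def fit_ellipse_moments(mask: SectionMask) -> EllipseFit:
    """Moment-based ellipse of the tissue mask.

    The largest connected component is selected and holes are filled;
    the returned ellipse has the same normalized second central moments
    as the resulting region (skimage ``regionprops`` conventions).
    """
    if not mask.tissue.any():
        raise ValueError("empty tissue mask")
    lab = cc_label(mask.tissue)
    props = regionprops(lab)
    biggest = max(props, key=lambda p: p.area)
    filled = binary_fill_holes(lab == biggest.label)
    p = regionprops(cc_label(filled))[0]
    return EllipseFit(center=tuple(p.centroid),
                      semi_major=p.axis_major_length / 2.0,
                      semi_minor=p.axis_minor_length / 2.0,
                      orientation=float(p.orientation))


def _normalized_radius(shape, fit: EllipseFit) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dr = rr - fit.center[0]
    dc = cc - fit.center[1]
    # skimage orientation: angle between the major axis and the ROW
    # (vertical) axis, counter-clockwise positive
    th = fit.orientation
    u = dr * np.cos(th) + dc * np.sin(th)  # along major axis
    v = -dr * np.sin(th) + dc * np.cos(th)  # along minor axis
    return np.sqrt((u / fit.semi_major) ** 2 + (v / fit.semi_minor) ** 2)


def assign_zones(fit: EllipseFit, shape: tuple[int, int],
                 bands: tuple = DEFAULT_BANDS,
                 tissue_mask: np.ndarray | None = None) -> ZoneMap:
    """Label pixels by normalized elliptical radius.

    medulla r < b1, ZR b1 <= r < b2, ZF b2 <= r < b3, ZG b3 <= r <= 1.
    With a tissue mask supplied, labels are restricted to tissue and
    tissue pixels beyond the fitted boundary (r > 1, inevitable for a
    moment ellipse) are assigned to the outermost zone so the zone
    areas partition the tissue exactly.  Without a mask, r > 1 is
    'outside'.
    """
    b = tuple(float(x) for x in bands)
    if len(b) != 3 or not (0.0 < b[0] < b[1] < b[2] <= 1.0):
        raise ValueError("bands must be strictly increasing in (0, 1]")
    r = _normalized_radius(shape, fit)
    zones = np.zeros(shape, dtype=np.int8)
    zones[r < b[0]] = ZONE_CODES["medulla"]
    zones[(r >= b[0]) & (r < b[1])] = ZONE_CODES["ZR"]
    zones[(r >= b[1]) & (r < b[2])] = ZONE_CODES["ZF"]
    zones[(r >= b[2]) & (r <= 1.0)] = ZONE_CODES["ZG"]
    if tissue_mask is not None:
        tissue_mask = np.asarray(tissue_mask, dtype=bool)
        zones[(r > 1.0) & tissue_mask] = ZONE_CODES["ZG"]
        zones[~tissue_mask] = ZONE_CODES["outside"]
    return ZoneMap(zones=zones, bands=b, fit=fit)


def coverage_by_zone(zone_map: ZoneMap, mask: SectionMask) -> CoverageReport:
    """Percent of each zone's pixels covered by particles.

    Empty zones report NaN coverage (undefined), not zero.
    """
    if zone_map.zones.shape != mask.tissue.shape:
        raise ValueError("zone map and masks have different shapes")
    zone_pixels, particle_pixels, coverage = {}, {}, {}
    for zone in ZONES:
        code = ZONE_CODES[zone]
        in_zone = zone_map.zones == code
        nz = int(in_zone.sum())
        np_in = int((in_zone & mask.particles).sum())
        zone_pixels[zone] = nz
        particle_pixels[zone] = np_in
        coverage[zone] = (100.0 * np_in / nz) if nz > 0 else float("nan")
    return CoverageReport(zone_pixels=zone_pixels, particle_pixels=particle_pixels,
                          coverage_percent=coverage)


def analyze_section(mask: SectionMask, bands: tuple = DEFAULT_BANDS) -> CoverageReport:
    """Full per-section pipeline: ellipse fit, zone labels, coverage."""
    fit = fit_ellipse_moments(mask)
    zones = assign_zones(fit, mask.tissue.shape, bands=bands, tissue_mask=mask.tissue)
    return coverage_by_zone(zones, mask)
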