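"""Segmentation of fruiting bodies from plate images and trait measurement.

The processing chain mirrors a standard Fiji particle-analysis workflow for
starvation-plate photographs of *Myxococcus xanthus* developmental spots:

1. convert the grey-scale image to 8-bit,
2. mask dust artefacts and restrict analysis to the spotted-population ROI,
3. threshold the ROI histogram with the Triangle (Zack) algorithm,
4. label connected components and drop particles smaller than 20 px^2,
5. measure, per retained fruiting body, its area (px^2), mean grey value
   ("density") and grey-value standard deviation ("density heterogeneity"),
6. summarise each plate as a count plus the three per-plate medians.

Density is reported as the raw mean grey value.  With dark objects on a
bright background a LOWER value therefore means a denser (darker) fruiting
body; pass ``invert_density=True`` to ``measure_plate`` to report
``255 - mean`` instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import filters, measure, morphology

__all__ = [
    "PlateImage",
    "FruitingBodyRegion",
    "TraitRecord",
    "TRAIT_COLUMNS",
    "convert_to_8bit",
    "triangle_threshold",
    "circular_roi",
    "detect_spot_roi",
    "segment_plate",
    "measure_plate",
    "records_to_frame",
    "aggregate_traits",
]

#: Trait columns of the plate-level table, in canonical order.
TRAIT_COLUMNS = ["fb_count", "fb_area_med_px2", "fb_density_med", "fb_hetero_med"]


@dataclass
class PlateImage:
    """One grey-scale plate photograph plus its ROI and dust masks.

    Parameters
    ----------
    pixels
        2-D integer image; 8-bit (values in [0, 255]) after conversion.
    roi_mask
        Boolean mask of the spotted-population area; must be non-empty.
    dust_mask
        Boolean mask of pixels to exclude (imaging dust).  Optional; an
        all-``False`` mask means no dust.
    meta
        Identifiers (treatment, population_id, cycle, assay_replicate, ...).
    """

    pixels: np.ndarray
    roi_mask: np.ndarray
    dust_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        if self.dust_mask is None:
            self.dust_mask = np.zeros(self.pixels.shape, dtype=bool)
        self.dust_mask = np.asarray(self.dust_mask, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"plate image must be single-channel 2-D, got {self.pixels.ndim} axes"
            )
        if self.roi_mask.shape != self.pixels.shape:
            raise ValueError("roi_mask shape does not match pixels")
        if self.dust_mask.shape != self.pixels.shape:
            raise ValueError("dust_mask shape does not match pixels")


@dataclass
class FruitingBodyRegion:
    """One segmented particle: pixel set, area and grey-value statistics."""

    label: int
    pixel_coords: np.ndarray  # (n, 2) array of 0-based (row, col)
    area_px2: int
    density: float  # mean grey value of member pixels
    heterogeneity: float  # population SD of member grey values
    centroid: tuple[float, float] = (math.nan, math.nan)


@dataclass
class TraitRecord:
    """Plate-level morphology: fruiting-body count plus three medians.

    Medians are NaN ("flagged missing") when the plate produced no
    fruiting bodies; the count is still a valid 0.
    """

    treatment: str
    population_id: str
    cycle: int
    assay_replicate: str
    fb_count: int
    fb_area_med: float
    fb_density_med: float
    fb_hetero_med: float


def convert_to_8bit(image: np.ndarray) -> np.ndarray:
    """Convert an 8- or 16-bit grey image to 8-bit.

    8-bit input is returned unchanged.  16-bit input is linearly rescaled
    from its observed [min, max] range to [0, 255] with half-up rounding;
    a constant 16-bit image maps to all zeros (degenerate range).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(
            f"expected single-channel grey image, got {image.ndim}-D input "
            f"with {image.shape[-1] if image.ndim == 3 else '?'} channels"
        )
    if not np.issubdtype(image.dtype, np.integer):
        raise ValueError(f"expected integer image, got dtype {image.dtype}")
    if image.dtype == np.uint8:
        return image
    if image.dtype.itemsize * 8 != 16 or np.issubdtype(image.dtype, np.signedinteger):
        # allow 8-bit values stored in wider dtypes
        if image.min() >= 0 and image.max() <= 255:
            return image.astype(np.uint8)
        if image.dtype.itemsize * 8 != 16:
            raise ValueError(f"unsupported bit depth for dtype {image.dtype}")
    lo = int(image.min())
    hi = int(image.max())
    if hi == lo:
        return np.zeros(image.shape, dtype=np.uint8)
    scaled = (image.astype(np.float64) - lo) * 255.0 / (hi - lo)
    return np.floor(scaled + 0.5).astype(np.uint8)  # round half-up


def triangle_threshold(histogram: Sequence[int] | np.ndarray) -> int:
    """Triangle (Zack-Gruber-Spinelli) threshold of a 256-bin histogram.

    A chord is drawn from the histogram peak (maximum-count bin) to the
    farthest non-empty bin; the threshold is the bin between them whose
    histogram point lies at maximal perpendicular distance from that chord.
    Ties are broken toward the peak.  The geometry is computed directly for
    either tail orientation, which is equivalent to the classical
    reflect-apply-map-back formulation.

    Returns the threshold bin index; for dark objects the foreground is
    ``pixels <= threshold``.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("histogram must have exactly 256 bins")
    if np.any(hist < 0):
        raise ValueError("histogram counts must be non-negative")
    nonzero = np.flatnonzero(hist)
    if nonzero.size < 2:
        raise ValueError("degenerate histogram: fewer than two non-empty bins")

    peak = int(np.argmax(hist))
    # farthest non-empty bin from the peak; on an exact tie prefer the dark side
    lo, hi = nonzero[0], nonzero[-1]
    tail = int(lo if (peak - lo) >= (hi - peak) else hi)
    if tail == peak:  # peak sits at one extreme; tail is the other
        tail = int(hi if peak == lo else lo)

    step = 1 if tail > peak else -1
    candidates = np.arange(peak + step, tail, step)
    if candidates.size == 0:
        return peak
    # perpendicular distance of (b, h[b]) from the chord peak->tail
    dx = float(tail - peak)
    dy = hist[tail] - hist[peak]
    norm = math.hypot(dx, dy)
    dist = np.abs(dy * (candidates - peak) - dx * (hist[candidates] - hist[peak])) / norm
    best = float(dist.max())
    # tie-break toward the peak: candidates are ordered peak -> tail
    idx = int(np.flatnonzero(dist >= best - 1e-12)[0])
    return int(candidates[idx])


def circular_roi(
    shape: tuple[int, int], center: tuple[float, float], radius: float
) -> np.ndarray:
    """Boolean mask of a filled circle (0-based row/col center, radius in px)."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def detect_spot_roi(pixels: np.ndarray, sigma: float = 5.0) -> np.ndarray:
    """Automatic spot ROI: blur, Otsu split, largest component, convex hull.

    A convenience for images without a user-supplied ROI; a manually
    specified circle is the reproducible alternative.
    """
    blurred = filters.gaussian(pixels.astype(np.float64), sigma=sigma)
    thr = filters.threshold_otsu(blurred)
    # the spot is the brighter of the two Otsu classes on these plates
    fg = blurred >= thr
    labels = measure.label(fg, connectivity=2)
    if labels.max() == 0:
        raise ValueError("automatic ROI detection found no spot")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return morphology.convex_hull_image(labels == largest)


def segment_plate(
    plate: PlateImage,
    polarity: str = "dark_objects",
    min_area_px2: int = 20,
    connectivity: int = 8,
) -> list[FruitingBodyRegion]:
    """Segment fruiting bodies on an 8-bit plate image.

    The histogram is computed only over ROI pixels not under the dust mask,
    thresholded with the Triangle algorithm, and the foreground (the dark
    side of the threshold for ``dark_objects``) is labelled into connected
    components within the ROI.  Components smaller than ``min_area_px2``
    are dropped; a component of exactly ``min_area_px2`` pixels is retained
    ("smaller than" is strict).  Density and heterogeneity are measured on
    the original 8-bit grey values of each retained region.

    Returns an empty list when no particle survives the filter (a valid
    outcome: some evolved populations form almost no fruiting bodies).
    """
    if polarity not in ("dark_objects", "bright_objects"):
        raise ValueError(f"unknown polarity {polarity!r}")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    pixels = plate.pixels
    if pixels.dtype != np.uint8:
        raise ValueError("plate must be 8-bit; call convert_to_8bit first")
    valid = plate.roi_mask & ~plate.dust_mask
    if not plate.roi_mask.any():
        raise ValueError("empty ROI: no spotted-population area to segment")
    if not valid.any():
        raise ValueError("ROI fully covered by dust mask")

    hist = np.bincount(pixels[valid].ravel(), minlength=256)
    thr = triangle_threshold(hist)
    peak = int(np.argmax(hist))
    # The threshold must fall on the object side of the background mode;
    # otherwise the histogram has no object class (e.g. a blank spot whose
    # longer noise tail happens to lie on the opposite side) and the plate
    # is object-free.
    if polarity == "dark_objects":
        if thr >= peak:
            return []
        foreground = pixels <= thr
    else:
        if thr <= peak:
            return []
        foreground = pixels >= thr
    foreground &= valid

    labels = measure.label(foreground, connectivity=1 if connectivity == 4 else 2)
    regions: list[FruitingBodyRegion] = []
    for props in measure.regionprops(labels, intensity_image=pixels):
        if props.area < min_area_px2:
            continue
        values = pixels[tuple(props.coords.T)].astype(np.float64)
        regions.append(
            FruitingBodyRegion(
                label=int(props.label),
                pixel_coords=props.coords.copy(),
                area_px2=int(props.area),
                density=float(values.mean()),
                heterogeneity=float(values.std(ddof=0)),
                centroid=(float(props.centroid[0]), float(props.centroid[1])),
            )
        )
    return regions


def measure_plate(
    regions: Iterable[FruitingBodyRegion],
    meta: Mapping[str, object],
    invert_density: bool = False,
) -> TraitRecord:
    """Summarise one plate's regions into the four-trait record.

    The three per-region measurements are summarised by their plate median
    (mean of the central pair for an even number of regions).  A plate with
    zero fruiting bodies keeps ``fb_count == 0`` and NaN medians.
    """
    regions = list(regions)
    if regions:
        areas = np.array([r.area_px2 for r in regions], dtype=np.float64)
        densities = np.array([r.density for r in regions])
        heteros = np.array([r.heterogeneity for r in regions])
        if invert_density:
            densities = 255.0 - densities
        area_med = float(np.median(areas))
        dens_med = float(np.median(densities))
        het_med = float(np.median(heteros))
    else:
        area_med = dens_med = het_med = math.nan
    return TraitRecord(
        treatment=str(meta.get("treatment", "")),
        population_id=str(meta.get("population_id", "")),
        cycle=int(meta.get("cycle", 0)),
        assay_replicate=str(meta.get("assay_replicate", "")),
        fb_count=len(regions),
        fb_area_med=area_med,
        fb_density_med=dens_med,
        fb_hetero_med=het_med,
    )


def records_to_frame(records: Iterable[TraitRecord]) -> pd.DataFrame:
    """Stack trait records into the canonical ``traits.csv`` table."""
    rows = [
        {
            "assay_id": r.assay_replicate,
            "cycle": r.cycle,
            "treatment": r.treatment,
            "population_id": r.population_id,
            "fb_count": r.fb_count,
            "fb_area_med_px2": r.fb_area_med,
            "fb_density_med": r.fb_density_med,
            "fb_hetero_med": r.fb_hetero_med,
            "n_regions_used": r.fb_count,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def aggregate_traits(
    table: pd.DataFrame,
    level: str = "treatment",
    category_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Two-stage replicate averaging of the plate-level trait table.

    Stage 1 averages trait values across the replicate populations of each
    group within each assay replicate; stage 2 averages the per-assay group
    means across assays and attaches the s.e.m. across assays.  Missing
    medians from zero-fruiting-body plates are omitted pairwise, so the
    effective number of assays can differ between traits; it is reported as
    ``n_assays``.  Groups with no surviving populations are simply absent
    from the output, never reported as zero.

    Parameters
    ----------
    table
        ``traits.csv``-shaped frame (one row per plate); rows must share a
        cycle or carry a ``cycle`` column to group on.
    level
        ``"population"``, ``"treatment"`` or ``"category"``.
    category_map
        Required for ``level="category"``: treatment -> category label.
    """
    levels = {"population": "population_id", "treatment": "treatment", "category": None}
    if level not in levels:
        raise ValueError(f"unknown aggregation level {level!r}")
    df = table.copy()
    if level == "category":
        if category_map is None:
            raise ValueError("category_map is required for category-level aggregation")
        df["category"] = df["treatment"].map(dict(category_map))
        if df["category"].isna().any():
            missing = sorted(df.loc[df["category"].isna(), "treatment"].unique())
            raise ValueError(f"treatments without a category: {missing}")
        group_col = "category"
    else:
        group_col = levels[level]

    keys = ["cycle", group_col] if "cycle" in df.columns else [group_col]
    per_assay = df.groupby(keys + ["assay_id"], observed=True)[TRAIT_COLUMNS].mean()
    agg = per_assay.groupby(level=keys, observed=True).agg(["mean", "sem", "count"])

    out = []
    for trait in TRAIT_COLUMNS:
        sub = agg[trait].reset_index()
        sub.insert(len(keys), "trait", trait)
        sub = sub.rename(columns={"count": "n_assays", "sem": "sem"})
        out.append(sub)
    result = pd.concat(out, ignore_index=True)
    result = result.rename(columns={group_col: "group"})
    return result
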