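"""Pixel-level compartmentalization and exposure-normalized intensity scoring.

Quantifies a target protein (here caveolin-1) separately in the stromal and
epithelial compartments of a multiplex immunofluorescence tissue-microarray
core.  Compartments are defined by marker logic rather than cell
segmentation:

* **epithelium** — pancytokeratin-positive pixels;
* **stroma** — vimentin-positive pixels that are pancytokeratin-negative and
  lie near a DAPI-positive nucleus.  Pixels positive for both vimentin and
  pancytokeratin are assigned to epithelium, since vimentin can also stain
  tumor epithelial cells.

The compartment score is the AQUA-style quantity

    score = scale * (sum of target intensity over the mask / mask area)
                  * (reference_exposure / target_exposure)

i.e. mean target intensity per unit area, normalized for camera exposure
time so it is proportional to protein concentration (molecules per unit
area) in arbitrary units.  Only the whole-cell ("overall") score is
computed; nuclear/cytoplasmic sub-scores are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.filters import threshold_otsu
from skimage.morphology import disk, remove_small_objects

CHANNELS = ("dapi", "vimentin", "panck", "cav1")

#: exposure time (ms) that scores are normalized to
REFERENCE_EXPOSURE_MS = 100.0

#: default multiplier mapping mean normalized intensity (0-1) to score units;
#: chosen so typical tissue concentrations land in the 100-300 range
DEFAULT_SCORE_SCALE = 500.0

ROI_CLASSES = (
    "tumor_stroma",
    "tumor_epithelium",
    "benign_stroma",
    "benign_epithelium",
    "adjacent_normal",
)


class InvalidImageError(ValueError):
    """Raised when a multiplex core image violates its contract."""


@dataclass
class MultiplexCoreImage:
    """One TMA core: four co-registered fluorescence channels.

    Channels are non-negative float arrays on a nominal 0-1 intensity scale
    with identical shapes; ``exposure_ms`` records the camera exposure used
    for each channel (required for score normalization).
    """

    channels: dict[str, np.ndarray]
    exposure_ms: dict[str, float]
    core_id: str = ""
    subject_id: str = ""
    roi_class: str = "tumor_stroma"

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise InvalidImageError(f"missing channels: {missing}")
        shapes = {c: np.asarray(self.channels[c]).shape for c in CHANNELS}
        if len(set(shapes.values())) != 1:
            raise InvalidImageError(f"channel shapes differ: {shapes}")
        for c in CHANNELS:
            arr = np.asarray(self.channels[c], dtype=float)
            if arr.ndim != 2:
                raise InvalidImageError(f"channel {c!r} is not 2-D")
            if np.any(arr < 0):
                raise InvalidImageError(f"channel {c!r} has negative intensities")
            self.channels[c] = arr
            exp = self.exposure_ms.get(c)
            if exp is None or not exp > 0:
                raise InvalidImageError(f"exposure for {c!r} must be > 0, got {exp}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels["dapi"].shape


@dataclass
class SegmentationParams:
    """Positivity thresholds and stroma-association rules.

    threshold_method maps each channel to ``"otsu"`` (data-driven, default)
    or ``"fixed"`` (use ``fixed_thresholds[channel]``).  A vimentin+ pixel
    only counts as stroma if a DAPI-positive nucleus lies within
    ``nucleus_association_radius`` pixels (DAPI is nuclear while vimentin is
    cytoplasmic, so they rarely share pixels).  Connected regions smaller
    than ``min_region_px`` are dropped from each mask.
    """

    threshold_method: dict[str, str] = field(default_factory=dict)
    fixed_thresholds: dict[str, float] = field(default_factory=dict)
    nucleus_association_radius: int = 10
    min_region_px: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_association_radius < 0:
            raise ValueError("nucleus_association_radius must be >= 0")
        if self.min_region_px < 0:
            raise ValueError("min_region_px must be >= 0")
        for c, m in self.threshold_method.items():
            if m not in ("otsu", "fixed"):
                raise ValueError(f"unknown threshold method {m!r} for channel {c!r}")
            if m == "fixed" and c not in self.fixed_thresholds:
                raise ValueError(f"fixed threshold requested but not given for {c!r}")


@dataclass
class CompartmentMasks:
    """Disjoint boolean pixel sets for the stroma and epithelium compartments."""

    stroma: np.ndarray
    epithelium: np.ndarray
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stroma = np.asarray(self.stroma, dtype=bool)
        self.epithelium = np.asarray(self.epithelium, dtype=bool)
        if self.stroma.shape != self.epithelium.shape:
            raise ValueError("mask shapes differ")
        if np.any(self.stroma & self.epithelium):
            raise ValueError("stroma and epithelium masks overlap")

    def mask_for(self, compartment: str) -> np.ndarray:
        if compartment not in ("stroma", "epithelium"):
            raise ValueError(f"unknown compartment {compartment!r}")
        return self.stroma if compartment == "stroma" else self.epithelium


@dataclass
class AquaScore:
    """Exposure-normalized intensity-per-area score for one compartment.

    ``value`` is None when the compartment mask was empty (a missing score,
    never zero).
    """

    value: float | None
    compartment: str
    area_px: int

    @property
    def missing(self) -> bool:
        return self.value is None


def _positive(channel: np.ndarray, name: str, params: SegmentationParams) -> tuple[np.ndarray, float]:
    """Threshold one channel into a positivity mask; returns (mask, threshold)."""
    method = params.threshold_method.get(name, "otsu")
    if method == "fixed":
        thr = float(params.fixed_thresholds[name])
    else:
        if np.all(channel == channel.flat[0]):
            # constant channel: Otsu is undefined; warn and call nothing positive
            warnings.warn(f"channel {name!r} is constant; {name} mask is empty")
            return np.zeros_like(channel, dtype=bool), float("inf")
        thr = float(threshold_otsu(channel))
    return channel > thr, thr


def build_compartment_masks(
    image: MultiplexCoreImage, params: SegmentationParams | None = None
) -> CompartmentMasks:
    """Derive disjoint stroma/epithelium compartment masks by marker logic.

    epithelium = panCK+.  stroma = vimentin+ AND panCK- AND within
    ``nucleus_association_radius`` px of a DAPI+ pixel.  The panCK exclusion
    means a vimentin+/panCK+ pixel belongs to epithelium only, so the masks
    are disjoint by construction.  With zero DAPI signal the stroma mask is
    empty regardless of vimentin.
    """
    params = params or SegmentationParams()
    dapi_pos, t_dapi = _positive(image.channels["dapi"], "dapi", params)
    vim_pos, t_vim = _positive(image.channels["vimentin"], "vimentin", params)
    panck_pos, t_panck = _positive(image.channels["panck"], "panck", params)

    if params.nucleus_association_radius > 0:
        near_nucleus = binary_dilation(dapi_pos, structure=disk(params.nucleus_association_radius))
    else:
        near_nucleus = dapi_pos

    epithelium = panck_pos
    stroma = vim_pos & ~panck_pos & near_nucleus

    if params.min_region_px > 0:
        stroma = remove_small_objects(stroma, max_size=params.min_region_px - 1)
        epithelium = remove_small_objects(epithelium, max_size=params.min_region_px - 1)

    return CompartmentMasks(
        stroma=stroma,
        epithelium=epithelium,
        thresholds={"dapi": t_dapi, "vimentin": t_vim, "panck": t_panck},
    )


def compute_aqua_score(
    image: MultiplexCoreImage,
    masks: CompartmentMasks,
    compartment: str,
    scale: float = DEFAULT_SCORE_SCALE,
    reference_exposure_ms: float = REFERENCE_EXPOSURE_MS,
) -> AquaScore:
    """Compute the whole-cell AQUA-style score for one compartment.

    score = scale * (sum target intensity over mask / area) *
    (reference exposure / target exposure).  An empty mask yields a missing
    score (``value=None``), never zero.
    """
    mask = masks.mask_for(compartment)
    area = int(mask.sum())
    if area == 0:
        warnings.warn(f"empty {compartment} mask; score is missing")
        return AquaScore(value=None, compartment=compartment, area_px=0)
    cav1 = image.channels["cav1"]
    mean_intensity = float(cav1[mask].sum()) / area
    value = scale * mean_intensity * (reference_exposure_ms / image.exposure_ms["cav1"])
    return AquaScore(value=value, compartment=compartment, area_px=area)


def aggregate_duplicate_cores(scores: list[AquaScore | float | None]) -> tuple[float | None, int]:
    """Mean of the non-missing duplicate-core scores for one subject x ROI.

    Duplicate cores are sampled to absorb tissue heterogeneity; the subject's
    record is their arithmetic mean.  Returns ``(mean, n_cores_used)``;
    ``(None, 0)`` if every duplicate is missing.
    """
    values = []
    for s in scores:
        v = s.value if isinstance(s, AquaScore) else s
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        values.append(float(v))
    if not values:
        return None, 0
    return float(np.mean(values)), len(values)


def dichotomize_if(values) -> tuple[np.ndarray, float]:
    """Split immunofluorescence scores at their median: high (>= median) vs low.

    Ties at the median are labelled high.  Missing values stay missing.
    Returns (labels array of 'low'/'high'/NaN, cutoff used).
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2:
        raise ValueError("need at least 2 non-missing values to dichotomize")
    cutoff = float(np.median(finite))
    labels = np.where(arr >= cutoff, "high", "low").astype(object)
    labels[~np.isfinite(arr)] = None
    return labels, cutoff
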