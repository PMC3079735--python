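"""Cell-region segmentation and the area-ratio remodeling score.

The score quantifies how tumor-cell clusters change the labeled matrix
around them, entirely within one field:

1. On a per-layer maximum projection (0-225 scale), every pixel is binned
   as *high* (90-225, closed lower bound) or *low* (< 90) intensity.
2. Inside a region, the *area ratio* is (# high pixels) / (# low pixels).
3. The *remodeling score* is ``100 x ratio_cell / ratio_devoid``, the
   percent difference of the cell-containing area's ratio relative to the
   adjacent cell-devoid area (= 100 when the cells change nothing).

Scores below 100 mean local matrix degradation (a protease-driven,
OVCAR5-like phenotype); scores above 100 mean local accumulation /
contraction of matrix toward the cells (a ROCK-dependent, OVCAR10-like
phenotype).

Cell regions are delineated from the nuclei (DAPI) channel.  The manual
procedure — tracing around nuclei-defined cell clumps — is automated as:
Otsu-threshold the nuclei projection, drop specks, group nearby nuclei into
clumps, take each clump's convex hull and dilate it outward (the traced
"circumvention").  A buffer ring separates the cell region from the scored
cell-devoid region so halo signal contaminates neither.  Users who trace
manually can supply polygons instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import convex_hull_image, disk, remove_small_objects

from .errors import EmptyMaskError, ParameterError
from .layers import LAYERS, LayerPartition, max_projection
from .stacks import MATRIX_CHANNELS, ImageStack

#: Closed high-intensity bin on the 0-225 scale.
HIGH_RANGE = (90.0, 225.0)

#: Neutral-band half width for phenotype calls, in score-percent units.
#: Calibrated once as 3x the across-seed standard deviation of the
#: top-layer score under the no-remodeling (null) simulation defaults; see
#: :func:`calibrate_neutral_margin`.
DEFAULT_NEUTRAL_MARGIN = 35.0


@dataclass
class RegionMask:
    """Binary partition of a field into cell-containing and cell-devoid areas.

    The two masks are disjoint; their union need not cover the field (a
    buffer ring may separate them).
    """

    cell_mask: np.ndarray
    devoid_mask: np.ndarray
    provenance: str = "auto"

    def __post_init__(self) -> None:
        if self.cell_mask.shape != self.devoid_mask.shape:
            raise ParameterError("cell and devoid masks must share one shape")
        if np.any(self.cell_mask & self.devoid_mask):
            raise ParameterError("cell and devoid masks overlap")


@dataclass
class RemodelingScore:
    """The area-ratio score of one (layer, channel) projection."""

    layer: str
    channel: str
    ratio_cell: float
    ratio_devoid: float
    score_percent: float
    n_high_cell: int
    n_low_cell: int
    n_high_devoid: int
    n_low_devoid: int
    smoothing_applied: bool = False


@dataclass
class PhenotypeCall:
    """Classification of a field's remodeling behavior."""

    label: str  # degrader | accumulator | neutral
    deciding_layer: str
    margin: float
    top_score: float


# ---------------------------------------------------------------------------
# segmentation


def segment_cell_region(
    nuclei_projection: np.ndarray,
    pixel_size_um: float = 0.5,
    min_blob_area: int = 30,
    dilation_radius_um: float = 3.0,
    buffer_um: float = 10.0,
    clump_link_um: float = 4.0,
) -> RegionMask:
    """Delineate cell-containing vs cell-devoid areas from a nuclei projection.

    Nuclei are Otsu-thresholded, blobs smaller than ``min_blob_area`` pixels
    discarded, and blobs within ``clump_link_um`` of each other grouped into
    one clump.  Each clump is enclosed by the convex hull of its nuclei,
    dilated outward by ``dilation_radius_um`` — the automated counterpart of
    manually tracing around a cell clump.  The cell-devoid mask is the rest
    of the field minus a ``buffer_um`` exclusion ring around the cell mask.
    """
    img = np.asarray(nuclei_projection, dtype=float)
    if img.ndim != 2:
        raise ParameterError("nuclei projection must be a 2D image")
    if float(img.max()) <= 0 or np.ptp(img) == 0:
        raise EmptyMaskError("no nuclei signal detected in the field")
    thr = threshold_otsu(img)
    blobs = img > thr
    blobs = remove_small_objects(blobs, max_size=int(min_blob_area) - 1)
    if not blobs.any():
        raise EmptyMaskError("no nuclei blobs above the minimum area")

    link_px = max(int(round(clump_link_um / pixel_size_um)), 1)
    clumps = label(binary_dilation(blobs, structure=disk(link_px)))
    cell = np.zeros_like(blobs)
    for lab in range(1, clumps.max() + 1):
        members = blobs & (clumps == lab)
        if members.any():
            cell |= convex_hull_image(members)
    dil_px = max(int(round(dilation_radius_um / pixel_size_um)), 1)
    cell = binary_dilation(cell, structure=disk(dil_px))

    buf_px = max(int(round(buffer_um / pixel_size_um)), 1)
    devoid = ~binary_dilation(cell, structure=disk(buf_px))
    if not devoid.any():
        raise EmptyMaskError("cell clumps plus buffer cover the entire field")
    return RegionMask(cell_mask=cell, devoid_mask=devoid, provenance="auto")


def region_from_polygons(
    field_shape: tuple[int, int],
    polygons,
    pixel_size_um: float = 0.5,
    buffer_um: float = 10.0,
) -> RegionMask:
    """Build a region mask from manually traced cell-clump polygons.

    ``polygons`` is a list of vertex lists in pixel coordinates (origin
    top-left, x rightward, y downward), each given as ``(x, y)`` pairs.
    """
    cell = np.zeros(field_shape, dtype=bool)
    for verts in polygons:
        pts = np.asarray(verts, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ParameterError("each polygon needs >= 3 (x, y) vertices")
        cell |= polygon2mask(field_shape, pts[:, ::-1])  # (x,y) -> (row, col)
    if not cell.any():
        raise EmptyMaskError("polygons enclose no pixels")
    buf_px = max(int(round(buffer_um / pixel_size_um)), 1)
    devoid = ~binary_dilation(cell, structure=disk(buf_px))
    if not devoid.any():
        raise EmptyMaskError("polygons plus buffer cover the entire field")
    return RegionMask(cell_mask=cell, devoid_mask=devoid, provenance="manual-polygon")


# ---------------------------------------------------------------------------
# the area-ratio statistic


def _ratio_counts(projection, mask, high_range, smoothing):
    values = np.asarray(projection, dtype=float)[mask]
    if values.size == 0:
        raise EmptyMaskError("region mask selects no pixels")
    lo, hi = high_range
    n_high = int(np.count_nonzero((values >= lo) & (values <= hi)))
    n_low = int(values.size - n_high)
    if smoothing == "auto":
        smooth = n_high == 0 or n_low == 0
    else:
        smooth = bool(smoothing)
    if smooth:
        ratio = (n_high + 0.5) / (n_low + 0.5)
    else:
        if n_low == 0:
            raise ParameterError(
                "low-intensity bin is empty; enable smoothing to score this region"
            )
        ratio = n_high / n_low
    return ratio, n_high, n_low, smooth


def area_ratio(
    projection: np.ndarray,
    mask: np.ndarray,
    high_range: tuple[float, float] = HIGH_RANGE,
    smoothing="auto",
) -> float:
    """High/low intensity area ratio of a region on a 0-225 projection.

    ``ratio = (# pixels with 90 <= v <= 225) / (# pixels with v < 90)``;
    the lower bound is closed (a pixel at exactly 90 is high).  With
    smoothing on, 0.5 is added to each count — the guard against an empty
    low bin; ``"auto"`` (default) applies it only when a count is zero.
    """
    ratio, *_ = _ratio_counts(projection, np.asarray(mask, bool), high_range, smoothing)
    return ratio


def remodeling_score(
    projection: np.ndarray,
    region: RegionMask,
    high_range: tuple[float, float] = HIGH_RANGE,
    smoothing="auto",
    layer: str = "",
    channel: str = "",
) -> RemodelingScore:
    """Percent difference of the cell-region ratio relative to the devoid one.

    ``score = 100 x ratio_cell / ratio_devoid``; 100 means no cell-induced
    change.  If either region triggers the zero-count smoothing guard, both
    ratios are computed with smoothing so they stay comparable.
    """
    mask_c = np.asarray(region.cell_mask, bool)
    mask_d = np.asarray(region.devoid_mask, bool)
    rc, hc, lc, sc = _ratio_counts(projection, mask_c, high_range, smoothing)
    rd, hd, ld, sd_ = _ratio_counts(projection, mask_d, high_range, smoothing)
    if (sc or sd_) and not (sc and sd_):
        rc = (hc + 0.5) / (lc + 0.5)
        rd = (hd + 0.5) / (ld + 0.5)
        sc = sd_ = True
    if rd == 0:
        rc, rd = (hc + 0.5) / (lc + 0.5), (hd + 0.5) / (ld + 0.5)
        sc = sd_ = True
    return RemodelingScore(
        layer=layer,
        channel=channel,
        ratio_cell=rc,
        ratio_devoid=rd,
        score_percent=100.0 * rc / rd,
        n_high_cell=hc,
        n_low_cell=lc,
        n_high_devoid=hd,
        n_low_devoid=ld,
        smoothing_applied=bool(sc or sd_),
    )


def score_stack(
    stack: ImageStack,
    partition: LayerPartition,
    region: RegionMask,
    channels=MATRIX_CHANNELS,
    high_range: tuple[float, float] = HIGH_RANGE,
    smoothing="auto",
) -> list[RemodelingScore]:
    """Score every (layer, matrix channel) of a scaled stack: 6 per field.

    Each layer's planes are collapsed by maximum projection before the
    area-ratio score is computed.
    """
    scores: list[RemodelingScore] = []
    for layer_name in LAYERS:
        planes = partition.planes(layer_name)
        for ch in channels:
            proj = max_projection(stack, ch, planes)
            scores.append(
                remodeling_score(
                    proj, region, high_range, smoothing,
                    layer=layer_name, channel=ch,
                )
            )
    return scores


def normalize_to_control(
    scores: list[RemodelingScore],
    control: list[RemodelingScore],
) -> dict[int, float]:
    """Express scores relative to the untreated control's bottom layer (=100).

    Per channel, every score is divided by the control's bottom-layer mean
    score and multiplied by 100, so the untreated bottom maps to exactly
    100.  Returns ``{index in `scores`: normalized value}``.
    """
    factors: dict[str, float] = {}
    for ch in {s.channel for s in scores}:
        vals = [
            s.score_percent for s in control if s.layer == "bottom" and s.channel == ch
        ]
        if not vals:
            raise ParameterError(
                f"control provides no bottom-layer score for channel {ch!r}"
            )
        mean = float(np.mean(vals))
        if mean == 0:
            raise ParameterError(f"control bottom-layer mean is zero for {ch!r}")
        factors[ch] = mean
    return {
        i: 100.0 * s.score_percent / factors[s.channel] for i, s in enumerate(scores)
    }


def classify_phenotype(
    scores: list[RemodelingScore],
    neutral_margin: float = DEFAULT_NEUTRAL_MARGIN,
) -> PhenotypeCall:
    """Call the remodeling phenotype from the top-layer score.

    The top layer is the deciding layer — it is where the two phenotypes
    separate most.  The mean top-layer score (over available matrix
    channels) below ``100 - margin`` calls a degrader; above
    ``100 + margin`` an accumulator; otherwise neutral.
    """
    if neutral_margin <= 0:
        raise ParameterError("neutral_margin must be positive")
    top = [s.score_percent for s in scores if s.layer == "top"]
    if not top:
        raise ParameterError("no top-layer score available (deciding layer)")
    val = float(np.mean(top))
    if val < 100.0 - neutral_margin:
        lab = "degrader"
    elif val > 100.0 + neutral_margin:
        lab = "accumulator"
    else:
        lab = "neutral"
    return PhenotypeCall(
        label=lab, deciding_layer="top", margin=neutral_margin, top_score=val
    )


def calibrate_neutral_margin(params=None, n_seeds: int = 20, seed: int = 0) -> float:
    """Recompute the neutral margin as 3x the null top-layer score SD.

    Runs ``n_seeds`` no-remodeling simulations with the generator defaults
    (or the given params with phenotype forced to ``"none"``), scores each,
    and returns three times the standard deviation of the top-layer mean
    score across seeds.
    """
    from dataclasses import replace

    from .layers import detect_layers
    from .simulate import SimulationParams, simulate_matrix_stack
    from .stacks import rescale_to_225

    base = params if params is not None else SimulationParams()
    tops = []
    for i in range(n_seeds):
        p = replace(base, phenotype="none", seed=seed + i)
        stack, _ = simulate_matrix_stack(p)
        scaled = rescale_to_225(stack, "fixed-range", lo=0.0, hi=225.0)
        part = detect_layers(scaled)
        region = segment_cell_region(
            max_projection(scaled, "nuclei"), pixel_size_um=p.pixel_size_um
        )
        scores = score_stack(scaled, part, region)
        tops.append(np.mean([s.score_percent for s in scores if s.layer == "top"]))
    return 3.0 * float(np.std(tops, ddof=1))


# ---------------------------------------------------------------------------
# time-lapse intensity tracking


def timelapse_change(
    series,
    region: RegionMask,
):
    """Mean-intensity trajectories of the cell and devoid regions over days.

    ``series`` is a list of ``(day, image)`` pairs over one consistently
    tracked field, where each image is a 2D fluorescence field (e.g. a
    widefield matrix image, or a depth-collapsed stack).  Returns a dict
    with per-day means per region and day-over-day percent change.
    """
    if len(series) < 2:
        raise ParameterError("need at least 2 timepoints")
    shape = np.asarray(series[0][1]).shape
    days, cell_means, devoid_means = [], [], []
    for day, img in series:
        arr = np.asarray(img, dtype=float)
        if arr.shape != shape:
            raise ParameterError(
                f"field size changed between days: {arr.shape} vs {shape}"
            )
        days.append(int(day))
        cell_means.append(float(arr[region.cell_mask].mean()))
        devoid_means.append(float(arr[region.devoid_mask].mean()))
    cm = np.asarray(cell_means)
    dm = np.asarray(devoid_means)
    with np.errstate(divide="ignore", invalid="ignore"):
        cell_pct = 100.0 * np.diff(cm) / cm[:-1]
        devoid_pct = 100.0 * np.diff(dm) / dm[:-1]
    return {
        "days": days,
        "cell_mean": cm,
        "devoid_mean": dm,
        "cell_pct_change": cell_pct,
        "devoid_pct_change": devoid_pct,
    }


def widefield_image(stack: ImageStack, channel: str = "tmp") -> np.ndarray:
    """Collapse a stack to a 2D widefield-like image (mean over depth).

    Widefield epifluorescence integrates signal across depth, so the z-mean
    is the closest stack-derived stand-in for the time-lapse images.
    """
    return stack.channel(channel).mean(axis=0)
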