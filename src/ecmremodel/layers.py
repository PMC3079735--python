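"""Maximum-intensity projections, orthogonal reslices, and layer detection.

A z-stack is partitioned into *top*, *middle* and *bottom* layers by
fibronectin stain-positive coverage, scanning from the topmost plane (index
0) downward:

* **top** — the first plane on which at least 20% of the field is
  stain-positive, plus one additional plane below;
* **bottom** — the first plane (at or below the top plane) on which
  staining covers essentially the entire field, plus one additional plane
  above;
* **middle** — the one (odd span) or two (even span) halfway planes of the
  span from the top plane to the bottom plane.

"Entire field" is operationalized as coverage >= ``full_coverage`` (default
0.995), because noisy fields never reach exactly 1.0.  When no plane reaches
full coverage — which heavily degraded matrices can legitimately cause —
the bottom falls back to the deepest plane attaining the maximum coverage
(plus one above) and the partition is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoMatrixError, ParameterError
from .stacks import ImageStack

#: Default stain-positive cutoff on the 0-225 scale, unified with the
#: high/low scoring bin edge.
POSITIVE_THRESHOLD = 90.0


@dataclass
class LayerPartition:
    """Plane-index sets labeling the top / middle / bottom of a stack."""

    top_planes: tuple[int, int]
    middle_planes: tuple[int, ...]
    bottom_planes: tuple[int, int]
    span: tuple[int, int]
    positive_threshold: float
    coverage_curve: np.ndarray
    bottom_fallback: bool = False

    def planes(self, layer: str) -> tuple[int, ...]:
        try:
            return {
                "top": self.top_planes,
                "middle": self.middle_planes,
                "bottom": self.bottom_planes,
            }[layer]
        except KeyError:
            raise ParameterError(f"unknown layer {layer!r}") from None

    def as_dict(self) -> dict:
        return {
            "top": list(self.top_planes),
            "middle": list(self.middle_planes),
            "bottom": list(self.bottom_planes),
            "span": list(self.span),
            "positive_threshold": self.positive_threshold,
            "coverage_curve": [float(c) for c in self.coverage_curve],
            "bottom_fallback": self.bottom_fallback,
        }


LAYERS = ("top", "middle", "bottom")


def coverage_profile(
    stack: ImageStack | np.ndarray,
    channel: str = "fibronectin",
    positive_threshold: float = POSITIVE_THRESHOLD,
) -> np.ndarray:
    """Per-plane fraction of stain-positive pixels (value >= threshold)."""
    arr = stack.channel(channel) if isinstance(stack, ImageStack) else np.asarray(stack)
    if arr.ndim != 3 or arr.shape[0] == 0:
        raise ParameterError("expected a non-empty (z, y, x) array")
    return (arr >= positive_threshold).mean(axis=(1, 2))


def partition_from_coverage(
    coverage: np.ndarray,
    top_coverage: float = 0.20,
    full_coverage: float = 0.995,
    positive_threshold: float = POSITIVE_THRESHOLD,
) -> LayerPartition:
    """Apply the top/middle/bottom rules to a per-plane coverage curve."""
    cov = np.asarray(coverage, dtype=float)
    n = len(cov)
    if n < 2:
        raise ParameterError("need at least 2 planes to partition layers")

    above = np.nonzero(cov >= top_coverage)[0]
    if len(above) == 0:
        raise NoMatrixError(
            f"no plane reaches {top_coverage:.0%} stain-positive coverage"
        )
    t = int(above[0])
    top = (t, t + 1) if t + 1 < n else (t - 1, t)

    fallback = False
    full = np.nonzero(cov[t:] >= full_coverage)[0]
    if len(full) > 0:
        b = t + int(full[0])
    else:
        tail = cov[t:]
        b = t + int(np.nonzero(tail >= tail.max() - 1e-12)[0][-1])
        fallback = True
    bottom = (b - 1, b) if b - 1 >= 0 else (b, b + 1)

    start, end = t, b
    if end < start:  # bottom rule satisfied on the top plane itself
        start, end = end, start
    length = end - start + 1
    if length % 2 == 1:
        middle: tuple[int, ...] = ((start + end) // 2,)
    else:
        middle = ((start + end) // 2, (start + end) // 2 + 1)

    return LayerPartition(
        top_planes=top,
        middle_planes=middle,
        bottom_planes=bottom,
        span=(start, end),
        positive_threshold=positive_threshold,
        coverage_curve=cov,
        bottom_fallback=fallback,
    )


def detect_layers(
    stack: ImageStack,
    channel: str = "fibronectin",
    positive_threshold: float = POSITIVE_THRESHOLD,
    top_coverage: float = 0.20,
    full_coverage: float = 0.995,
) -> LayerPartition:
    """Detect the top/middle/bottom layer partition of a scaled stack."""
    cov = coverage_profile(stack, channel, positive_threshold)
    return partition_from_coverage(
        cov, top_coverage, full_coverage, positive_threshold
    )


def max_projection(
    stack: ImageStack | np.ndarray,
    channel: str | None = None,
    planes=None,
) -> np.ndarray:
    """Per-pixel maximum-intensity projection over the listed planes.

    ``planes=None`` projects over all focal planes.
    """
    arr = (
        stack.channel(channel)
        if isinstance(stack, ImageStack)
        else np.asarray(stack)
    )
    if planes is None:
        planes = range(arr.shape[0])
    idx = list(planes)
    if len(idx) == 0:
        raise ParameterError("plane list must be non-empty")
    if min(idx) < 0 or max(idx) >= arr.shape[0]:
        raise ParameterError(f"plane indices {idx} out of range for {arr.shape[0]}")
    return arr[idx].max(axis=0)


def orthogonal_reslice(
    stack: ImageStack,
    channel: str,
    line: int,
    thickness_um: float = 10.0,
) -> np.ndarray:
    """90-degree (XZ) reslice: maximum over a band of rows around ``line``.

    For each ``(x, z)`` the value is the maximum over the image rows within
    ``thickness_um`` centered on the given y-row.  Output shape is
    ``(n_planes, x)`` with z increasing downward, matching the top-first
    plane convention.
    """
    arr = stack.channel(channel)
    nz, h, w = arr.shape
    if not 0 <= line < h:
        raise ParameterError(f"row {line} outside field of height {h}")
    half_px = 0.5 * thickness_um / stack.pixel_size_um
    if 2 * half_px < 1.0:
        raise ParameterError(
            f"thickness {thickness_um} um is less than one pixel row"
        )
    lo = max(int(np.ceil(line - half_px)), 0)
    hi = min(int(np.floor(line + half_px)), h - 1)
    return arr[:, lo : hi + 1, :].max(axis=1)
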