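"""Core 3D multi-channel stack containers and multi-page TIFF I/O.

An :class:`ImageStack` holds one 3D intensity array per named channel,
indexed ``(z, y, x)`` with plane index 0 the *topmost* plane (farthest from
the substrate); "below" always means increasing plane index.  Downstream
scoring operates on a :class:`ScaledStack`, whose intensities live on the
closed 0–225 pseudo-color scale on which all thresholds (the stain-positive
cutoff and the high/low bin edge at 90) are defined.

Stacks are persisted as multi-page TIFF with axes ``ZCYX`` and channel
names, z-spacing and pixel size recorded in the shaped-TIFF metadata, so a
written stack round-trips losslessly through :func:`read_stack`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import DimensionError, FormatError, ParameterError

#: Channel roles used by the full scoring pipeline.
CHANNEL_ROLES = ("nuclei", "fibronectin", "tmp")

#: Channels that carry labeled matrix signal (scored channels).
MATRIX_CHANNELS = ("tmp", "fibronectin")

#: Top of the pseudo-color intensity scale.
SCALE_MAX = 225.0


@dataclass
class ImageStack:
    """A z-ordered set of 2D multi-channel intensity planes.

    Parameters
    ----------
    channels
        Mapping from channel name to a ``(z, y, x)`` float array of
        non-negative intensities.  All channels must share one shape.
    z_spacing_um
        Physical spacing between consecutive planes, in micrometers.
    pixel_size_um
        Lateral pixel size, in micrometers.
    z_orientation
        Always ``"top-first"``: plane index 0 is the topmost plane.
    """

    channels: dict[str, np.ndarray]
    z_spacing_um: float = 0.5
    pixel_size_um: float = 0.5
    z_orientation: str = "top-first"

    def __post_init__(self) -> None:
        if not self.channels:
            raise DimensionError("stack must contain at least one channel")
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        ref = next(iter(shapes.values()))
        if len(ref) != 3:
            raise DimensionError(f"channel arrays must be (z, y, x); got shape {ref}")
        for name, shape in shapes.items():
            if shape != ref:
                raise DimensionError(
                    f"channel {name!r} has shape {shape}, expected {ref}"
                )
        if not self.z_spacing_um > 0:
            raise ParameterError("z_spacing_um must be positive")
        if not self.pixel_size_um > 0:
            raise ParameterError("pixel_size_um must be positive")
        for name, arr in self.channels.items():
            if not np.all(np.isfinite(arr)):
                raise DimensionError(f"channel {name!r} contains non-finite values")
            if np.any(arr < 0):
                raise DimensionError(f"channel {name!r} contains negative intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        """The common ``(z, y, x)`` shape of every channel."""
        return next(iter(self.channels.values())).shape

    @property
    def n_planes(self) -> int:
        return self.shape[0]

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise FormatError(f"stack has no channel {name!r}") from None


@dataclass
class ScaledStack(ImageStack):
    """An :class:`ImageStack` whose intensities lie on the closed 0–225 scale.

    ``scale_params[name]`` records the raw ``(lo, hi)`` interval that was
    affinely mapped onto ``[0, 225]`` for each channel.
    """

    scale_params: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        for name, arr in self.channels.items():
            if np.any(arr > SCALE_MAX):
                raise DimensionError(
                    f"channel {name!r} exceeds the 0-{SCALE_MAX:g} scale"
                )


def rescale_to_225(
    stack: ImageStack,
    mode: str = "global-minmax",
    lo: float | None = None,
    hi: float | None = None,
) -> ScaledStack:
    """Map every channel onto the closed 0–225 pseudo-color scale.

    Two modes are supported:

    ``"global-minmax"``
        Each channel is mapped with ``lo, hi`` equal to its own min and max
        over the whole stack.  A constant channel maps to all zeros (the
        conservative degenerate-range rule: no spurious high-intensity area).
    ``"fixed-range"``
        One explicit ``(lo, hi)`` interval, shared by all channels, is mapped
        onto ``[0, 225]`` with clipping.  This is the mode to use when stacks
        of one experiment must stay mutually comparable (share the interval
        taken from the untreated control).

    The map is affine and order-preserving: ``v -> 225 * (v - lo) / (hi - lo)``
    clipped to ``[0, 225]``.
    """
    if mode not in ("global-minmax", "fixed-range"):
        raise ParameterError(f"unknown rescale mode {mode!r}")
    if mode == "fixed-range":
        if lo is None or hi is None:
            raise ParameterError("fixed-range mode requires lo and hi")
        if not hi > lo:
            raise ParameterError(f"fixed-range requires hi > lo, got ({lo}, {hi})")

    out: dict[str, np.ndarray] = {}
    params: dict[str, tuple[float, float]] = {}
    for name, arr in stack.channels.items():
        if mode == "global-minmax":
            c_lo = float(arr.min())
            c_hi = float(arr.max())
            if c_hi <= c_lo:  # constant channel -> all zeros
                out[name] = np.zeros_like(arr, dtype=np.float64)
                params[name] = (c_lo, c_lo)
                continue
        else:
            c_lo, c_hi = float(lo), float(hi)  # type: ignore[arg-type]
        scaled = SCALE_MAX * (arr.astype(np.float64) - c_lo) / (c_hi - c_lo)
        out[name] = np.clip(scaled, 0.0, SCALE_MAX)
        params[name] = (c_lo, c_hi)
    return ScaledStack(
        channels=out,
        z_spacing_um=stack.z_spacing_um,
        pixel_size_um=stack.pixel_size_um,
        z_orientation=stack.z_orientation,
        scale_params=params,
    )


def write_stack(stack: ImageStack, path) -> str:
    """Write a stack as a multi-page TIFF (axes ``ZCYX``) with metadata.

    Channel names, z-spacing and pixel size travel in the shaped-TIFF
    metadata, so :func:`read_stack` can restore the stack without a channel
    map.  Integer and float32/float64 data round-trip losslessly.
    """
    names = stack.channel_names
    data = np.stack([stack.channels[n] for n in names], axis=1)  # (z, c, y, x)
    tifffile.imwrite(
        str(path),
        data,
        photometric="minisblack",
        metadata={
            "axes": "ZCYX",
            "ecm_channels": list(names),
            "z_spacing_um": stack.z_spacing_um,
            "pixel_size_um": stack.pixel_size_um,
        },
    )
    return str(path)


def read_stack(
    path,
    channel_map: dict[str, int] | None = None,
    z_spacing_um: float | None = None,
    pixel_size_um: float | None = None,
) -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_stack` or a plain one.

    Parameters
    ----------
    path
        A multi-page TIFF whose data reshape to ``(z, c, y, x)`` or
        ``(z, y, x)``.
    channel_map
        Mapping from channel role to channel-axis index.  Required for files
        without embedded channel names; when given it must cover all three
        roles ``nuclei``, ``fibronectin`` and ``tmp``.  ``None`` uses the
        names embedded at write time.
    z_spacing_um, pixel_size_um
        Physical calibration.  These come from configuration, never from
        guesswork on the file; when omitted, embedded metadata (if present)
        is used, else the 0.5 um acquisition defaults.
    """
    try:
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            meta = {}
            if tif.shaped_metadata:
                meta = dict(tif.shaped_metadata[0])
    except (OSError, ValueError, IndexError) as exc:
        raise FormatError(f"cannot read TIFF {path!r}: {exc}") from exc

    if data.ndim == 3:
        data = data[:, None, :, :]
    if data.ndim != 4:
        raise DimensionError(
            f"expected pages reshaping to (z, c, y, x); got ndim={data.ndim}"
        )
    n_chan = data.shape[1]

    if channel_map is None:
        names = meta.get("ecm_channels")
        if names is None:
            raise FormatError(
                "file carries no embedded channel names; pass channel_map"
            )
        if len(names) != n_chan:
            raise FormatError(
                f"metadata lists {len(names)} channels but file has {n_chan}"
            )
        mapping = {str(n): i for i, n in enumerate(names)}
    else:
        missing = [r for r in CHANNEL_ROLES if r not in channel_map]
        if missing:
            raise FormatError(
                "channel_map must assign every role; missing: " + ", ".join(missing)
            )
        bad = {r: i for r, i in channel_map.items() if not 0 <= i < n_chan}
        if bad:
            raise FormatError(
                f"channel_map indices out of range for {n_chan} channels: {bad}"
            )
        mapping = dict(channel_map)

    channels = {name: data[:, idx].astype(np.float64) for name, idx in mapping.items()}
    return ImageStack(
        channels=channels,
        z_spacing_um=float(
            z_spacing_um if z_spacing_um is not None else meta.get("z_spacing_um", 0.5)
        ),
        pixel_size_um=float(
            pixel_size_um
            if pixel_size_um is not None
            else meta.get("pixel_size_um", 0.5)
        ),
    )


def stack_config_from_json(path) -> dict:
    """Load a channel-map/calibration config (JSON) for :func:`read_stack`."""
    with open(path) as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("stack config must be a JSON object")
    return cfg
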