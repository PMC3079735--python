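"""Synthetic 3D fluorescently-labeled matrix cultures with known ground truth.

The generator emulates the phenomenology of fibroblast-derived 3D matrices
colonized by ovarian tumor-cell clusters, at the level the area-ratio score
can see:

* two matrix channels (``tmp`` — bulk-labeled total matrix protein — and
  ``fibronectin``) carrying an anisotropic fiber mesh whose per-plane
  stain-positive coverage tapers toward the top of the stack and saturates
  at the bottom;
* a ``nuclei`` channel with ellipsoidal nuclei confined to circular cell
  cluster footprints, rendered on a small set of reference planes;
* two remodeling transforms applied inside the cluster footprint:
  a *degrader* that multiplicatively depletes matrix signal (optionally
  strongest in the top planes), and an *accumulator/contractor* that
  amplifies signal under the clusters, depletes a surrounding annulus so a
  stated fraction of the moved signal is conserved, and deposits part of
  the moved signal apically on the top planes;
* a day-0/7/10 time series in which the remodeling effect grows
  monotonically on a seed-fixed field, mirroring repeated imaging of
  preselected fields.

Every stack is deterministic given ``(params, seed)``.

The fiber mesh is built from random straight segments with a Gaussian
cross-section — not a fibrillogenesis model; the score only needs realistic
coverage statistics.  Per-plane coverage is imposed exactly by quantile
thresholding of a shared (z-persistent) texture, so low-coverage "holes"
line up across planes as they do in a real matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse, line

from .errors import GeometryError, ParameterError
from .stacks import MATRIX_CHANNELS, ImageStack

#: Default per-plane stain-positive coverage, topmost plane first.
DEFAULT_Z_PROFILE = (
    0.05, 0.10, 0.25, 0.40, 0.55, 0.68,
    0.80, 0.89, 0.95, 0.98, 0.995, 0.995,
)

#: Intensity floor for stain-positive pixels and ceiling for negatives on the
#: raw scale; the gap keeps additive noise from flipping coverage.
_POS_FLOOR = 100.0
_NEG_CEIL = 80.0


@dataclass(frozen=True)
class Cluster:
    """One circular cell-cluster footprint (pixel coordinates)."""

    center: tuple[float, float]  # (y, x)
    radius: float


@dataclass(frozen=True)
class SimulationParams:
    """Full specification of one synthetic matrix-culture experiment.

    Parameters
    ----------
    field_shape
        ``(y, x)`` field size in pixels.
    n_planes
        Number of focal planes; plane 0 is the topmost.
    fiber_density
        Expected fiber segments per 100x100 px used for the persistent mesh.
        High densities give a spatially homogeneous mesh, which is what the
        within-field cell/devoid comparison assumes.
    fiber_intensity_mean, fiber_intensity_sd
        Target mean/spread of stain-positive pixel intensities (raw scale,
        which coincides with the 0-225 scoring scale).
    z_profile
        Per-plane stain-positive coverage fractions, non-decreasing from top
        toward bottom; ``None`` uses :data:`DEFAULT_Z_PROFILE` resampled to
        ``n_planes``.
    clusters
        Explicit cluster footprints, or ``None`` to place ``n_clusters``
        non-overlapping clusters at seed-determined positions.
    n_clusters, cluster_radius_range
        Geometry of auto-placed clusters.
    n_nuclei_per_cluster
        Nuclei rendered inside each footprint.
    phenotype
        ``"none"``, ``"degrader"`` or ``"accumulator"``.
    effect_size
        Multiplicative factor: depletion factor ``0 < f < 1`` for a
        degrader, concentration factor ``f > 1`` for an accumulator.
        ``None`` selects the phenotype default (0.3 / 3.0).
    apical_fraction
        Accumulator only: fraction of the moved signal deposited on the top
        planes above the cluster footprint.
    conserve_fraction
        Accumulator only: fraction of the concentration gain removed from
        the surrounding annulus (1.0 = pure redistribution).
    depth_tau_planes
        E-folding depth (in planes, measured from the matrix onset) of the
        remodeling strength, making both degradation and annulus depletion
        strongest near the top of the matrix.  ``None`` uses
        ``n_planes / 4``; ``inf`` gives a depth-uniform effect.
    noise_sd
        Additive Gaussian noise (truncated at 0) on every channel.
    timepoints, effect_timescale
        Imaging days and the per-day effect scaling for
        :func:`simulate_timecourse`.
    seed
        Integer RNG seed; identical seed + params give identical stacks.
    """

    field_shape: tuple[int, int] = (256, 256)
    n_planes: int = 12
    fiber_density: float = 150.0
    fiber_intensity_mean: float = 140.0
    fiber_intensity_sd: float = 25.0
    z_profile: tuple[float, ...] | None = None
    clusters: tuple[Cluster, ...] | None = None
    n_clusters: int = 3
    cluster_radius_range: tuple[float, float] = (30.0, 42.0)
    n_nuclei_per_cluster: int = 15
    phenotype: str = "none"
    effect_size: float | None = None
    apical_fraction: float = 0.5
    conserve_fraction: float = 1.0
    depth_tau_planes: float | None = None
    noise_sd: float = 3.0
    timepoints: tuple[int, ...] = (0, 7, 10)
    effect_timescale: tuple[float, ...] = (0.0, 0.6, 1.0)
    seed: int = 0
    pixel_size_um: float = 0.5
    z_spacing_um: float = 0.5

    def resolved_z_profile(self) -> np.ndarray:
        if self.z_profile is not None:
            prof = np.asarray(self.z_profile, dtype=float)
            if len(prof) != self.n_planes:
                raise ParameterError(
                    f"z_profile has {len(prof)} entries for {self.n_planes} planes"
                )
        else:
            base = np.asarray(DEFAULT_Z_PROFILE)
            xp = np.linspace(0.0, 1.0, len(base))
            prof = np.interp(np.linspace(0.0, 1.0, self.n_planes), xp, base)
        if np.any(prof < 0) or np.any(prof > 1):
            raise ParameterError("z_profile values must lie in [0, 1]")
        if np.any(np.diff(prof) < -1e-12):
            raise ParameterError(
                "z_profile must be non-decreasing from top toward bottom"
            )
        return prof

    def resolved_effect_size(self) -> float:
        if self.phenotype == "none":
            return 1.0
        if self.effect_size is not None:
            f = float(self.effect_size)
        else:
            f = 0.3 if self.phenotype == "degrader" else 3.0
        _check_effect(self.phenotype, f)
        return f

    def validate(self) -> None:
        if self.phenotype not in ("none", "degrader", "accumulator"):
            raise ParameterError(f"unknown phenotype {self.phenotype!r}")
        if self.n_planes < 2:
            raise ParameterError("need at least 2 planes")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if len(self.timepoints) != len(self.effect_timescale):
            raise ParameterError("timepoints and effect_timescale lengths differ")
        self.resolved_z_profile()
        self.resolved_effect_size()


@dataclass
class GroundTruth:
    """Known truth accompanying one simulated stack."""

    cell_mask: np.ndarray  # 2D bool, true = inside a cluster footprint
    phenotype: str
    effect_size: float
    clusters: tuple[Cluster, ...]
    #: expected sign of (cell score - 100) per layer; 0 = no change
    layer_direction: dict[str, int] = field(default_factory=dict)


def _check_effect(phenotype: str, f: float) -> None:
    if phenotype == "degrader" and not 0.0 < f <= 1.0:
        raise ParameterError(f"degrader effect_size must be in (0, 1]; got {f}")
    if phenotype == "accumulator" and not f >= 1.0:
        raise ParameterError(f"accumulator effect_size must be >= 1; got {f}")


# ---------------------------------------------------------------------------
# fiber texture


def _fiber_texture(shape, n_fibers, rng, length_mean=20.0, length_sd=7.0, sigma=1.0):
    """Sum of random line segments, Gaussian-blurred into a fiber mesh.

    Fibers are drawn on a padded canvas and cropped so the statistics are
    stationary all the way to the field border.
    """
    h, w = shape
    pad = int(length_mean + 3 * length_sd)
    ph, pw = h + 2 * pad, w + 2 * pad
    # keep the in-field density equal to n_fibers / (h * w)
    n_total = int(round(n_fibers * ph * pw / (h * w)))
    canvas = np.zeros((ph, pw), dtype=np.float64)
    lengths = np.clip(rng.normal(length_mean, length_sd, n_total), 6.0, None)
    angles = rng.uniform(0.0, np.pi, n_total)
    ys = rng.uniform(0, ph, n_total)
    xs = rng.uniform(0, pw, n_total)
    amps = rng.lognormal(0.0, 0.4, n_total)
    for y0, x0, ang, ln, amp in zip(ys, xs, angles, lengths, amps):
        dy = 0.5 * ln * np.sin(ang)
        dx = 0.5 * ln * np.cos(ang)
        r0 = int(np.clip(round(y0 - dy), 0, ph - 1))
        c0 = int(np.clip(round(x0 - dx), 0, pw - 1))
        r1 = int(np.clip(round(y0 + dy), 0, ph - 1))
        c1 = int(np.clip(round(x0 + dx), 0, pw - 1))
        rr, cc = line(r0, c0, r1, c1)
        canvas[rr, cc] += amp
    return gaussian_filter(canvas, sigma)[pad : pad + h, pad : pad + w]


def _coverage_mapped_plane(tex, coverage, i_mean, i_sd=25.0):
    """Map a texture onto raw intensities with an exact stain-positive fraction.

    Pixels above the ``1 - coverage`` quantile become positives on
    ``[_POS_FLOOR, 225]``-ish intensities; the rest are compressed below
    ``_NEG_CEIL``.  The gap between the two bands keeps small additive noise
    from moving pixels across the stain-positive threshold (90).
    """
    if coverage <= 0.0:
        v = tex.max() + 1.0
    elif coverage >= 1.0:
        v = tex.min()
    else:
        # k-th largest value, so the positive fraction is >= coverage by count
        k = int(np.ceil(coverage * tex.size))
        v = np.partition(tex.ravel(), tex.size - k)[tex.size - k]
    pos = tex >= v
    plane = np.zeros_like(tex)
    if pos.any():
        spread = tex[pos] - v
        std = max(float(spread.std()), 1e-9)
        vals = i_mean + i_sd * (spread - spread.mean()) / std
        plane[pos] = np.maximum(vals, _POS_FLOOR)
    neg = ~pos
    if neg.any():
        depth = v - tex[neg]
        dmax = max(float(depth.max()), 1e-9)
        plane[neg] = _NEG_CEIL * (1.0 - depth / dmax)
    return np.clip(plane, 0.0, 225.0)


# ---------------------------------------------------------------------------
# geometry


def _auto_clusters(params: SimulationParams, rng) -> tuple[Cluster, ...]:
    h, w = params.field_shape
    lo, hi = params.cluster_radius_range
    if 2 * (lo + 2) >= min(h, w):
        raise GeometryError(
            f"clusters of radius >= {lo} cannot fit in a {h}x{w} field"
        )
    placed: list[Cluster] = []
    for _ in range(2000):
        if len(placed) == params.n_clusters:
            break
        r = float(rng.uniform(lo, hi))
        cy = float(rng.uniform(r + 2, h - r - 2))
        cx = float(rng.uniform(r + 2, w - r - 2))
        ok = all(
            np.hypot(cy - c.center[0], cx - c.center[1]) > r + c.radius + 30
            for c in placed
        )
        if ok:
            placed.append(Cluster((cy, cx), r))
    if len(placed) < params.n_clusters:
        raise GeometryError(
            f"could not place {params.n_clusters} non-overlapping clusters "
            f"of radius {lo}-{hi} in a {h}x{w} field"
        )
    return tuple(placed)


def _cluster_mask(shape, clusters) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros(shape, dtype=bool)
    for c in clusters:
        cy, cx = c.center
        if not (c.radius <= cy <= h - c.radius and c.radius <= cx <= w - c.radius):
            raise GeometryError(
                f"cluster at {c.center} with radius {c.radius} exceeds the "
                f"{h}x{w} field"
            )
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= c.radius**2
    return mask


def _draw_nuclei(shape, clusters, n_per_cluster, rng) -> np.ndarray:
    img = np.zeros(shape, dtype=np.float64)
    for c in clusters:
        cy, cx = c.center
        for _ in range(n_per_cluster):
            rho = c.radius * 0.92 * np.sqrt(rng.uniform())
            phi = rng.uniform(0, 2 * np.pi)
            ny, nx = cy + rho * np.sin(phi), cx + rho * np.cos(phi)
            r_minor = rng.uniform(3.0, 4.5)
            r_major = rng.uniform(5.0, 7.0)
            rot = rng.uniform(0, np.pi)
            rr, cc = ellipse(ny, nx, r_major, r_minor, shape=shape, rotation=rot)
            img[rr, cc] = np.maximum(img[rr, cc], rng.normal(195.0, 12.0))
    return np.clip(gaussian_filter(img, 0.8), 0.0, 225.0)


# ---------------------------------------------------------------------------
# public generators


def simulate_matrix_stack(
    params: SimulationParams,
) -> tuple[ImageStack, GroundTruth]:
    """Generate one synthetic labeled-matrix stack plus its ground truth.

    The matrix channels share one persistent fiber mesh (plus a small
    per-plane perturbation) thresholded per plane to the coverage profile;
    the nuclei channel is rendered on a reference band of planes near 60%
    depth.  If ``params.phenotype`` is not ``"none"``, the corresponding
    remodeling transform is applied at full effect.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.field_shape
    profile = params.resolved_z_profile()

    n_base = max(int(params.fiber_density * h * w / 1e4), 8)
    base = _fiber_texture((h, w), n_base, rng)
    # pixel-scale speckle, persistent across planes and channels: breaks ties
    # for the quantile thresholds and disperses the low-intensity "holes" so
    # region counts behave binomially instead of patch-wise
    base += 0.80 * base.std() * rng.standard_normal((h, w))

    clusters = (
        params.clusters if params.clusters is not None else _auto_clusters(params, rng)
    )
    cell_mask = _cluster_mask((h, w), clusters)

    channels: dict[str, np.ndarray] = {}
    for ch in MATRIX_CHANNELS:
        planes = np.empty((params.n_planes, h, w), dtype=np.float64)
        for z in range(params.n_planes):
            extra = _fiber_texture((h, w), max(n_base // 8, 4), rng)
            tex = base + 0.12 * extra
            planes[z] = _coverage_mapped_plane(
                tex, profile[z], params.fiber_intensity_mean,
                params.fiber_intensity_sd,
            )
        channels[ch] = planes

    nuclei = np.zeros((params.n_planes, h, w), dtype=np.float64)
    ref0 = int(round(0.55 * (params.n_planes - 1)))
    ref_planes = [p for p in (ref0, ref0 + 1) if p < params.n_planes]
    nuclei_img = _draw_nuclei((h, w), clusters, params.n_nuclei_per_cluster, rng)
    for p in ref_planes:
        nuclei[p] = nuclei_img
    channels["nuclei"] = nuclei

    truth = GroundTruth(
        cell_mask=cell_mask,
        phenotype=params.phenotype,
        effect_size=params.resolved_effect_size(),
        clusters=tuple(clusters),
        layer_direction=_expected_directions(params.phenotype),
    )

    stack = ImageStack(
        channels=channels,
        z_spacing_um=params.z_spacing_um,
        pixel_size_um=params.pixel_size_um,
    )

    if params.phenotype != "none":
        onset = np.nonzero(profile >= 0.20)[0]
        stack = apply_remodeling(
            stack,
            truth,
            params.phenotype,
            truth.effect_size,
            apical_fraction=params.apical_fraction,
            conserve_fraction=params.conserve_fraction,
            depth_tau_planes=(
                params.depth_tau_planes
                if params.depth_tau_planes is not None
                else params.n_planes / 4.0
            ),
            depth_origin=int(onset[0]) if len(onset) else 0,
        )

    if params.noise_sd > 0:
        noisy = {}
        for name, arr in stack.channels.items():
            noisy[name] = np.clip(
                arr + rng.normal(0.0, params.noise_sd, arr.shape), 0.0, None
            )
        stack = ImageStack(
            channels=noisy,
            z_spacing_um=stack.z_spacing_um,
            pixel_size_um=stack.pixel_size_um,
        )
    return stack, truth


def _expected_directions(phenotype: str) -> dict[str, int]:
    if phenotype == "degrader":
        return {"top": -1, "middle": -1, "bottom": -1}
    if phenotype == "accumulator":
        return {"top": +1, "middle": +1, "bottom": +1}
    return {"top": 0, "middle": 0, "bottom": 0}


def _depth_weights(nz: int, tau: float | None, origin: int) -> np.ndarray:
    """Per-plane effect weights, 1 at the matrix top and decaying with depth.

    ``origin`` is the plane index where the matrix proper begins (the 20%
    coverage onset); planes above it get full weight.  ``tau=None`` (or inf)
    means depth-uniform weights.
    """
    if tau is None or np.isinf(tau):
        return np.ones(nz)
    zs = np.arange(nz, dtype=float)
    return np.exp(-np.maximum(zs - origin, 0.0) / float(tau))


def _waterfill(demand: float, caps: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Split ``demand`` over planes as ``min(lam * w * cap, cap)``, summing
    to ``demand`` (or to total capacity when the demand exceeds it)."""
    caps = np.asarray(caps, dtype=float)
    wc = weights * caps
    if demand >= caps.sum():
        return caps.copy()
    lo, hi = 0.0, 1.0
    while np.minimum(hi * wc, caps).sum() < demand:
        hi *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.minimum(mid * wc, caps).sum() < demand:
            lo = mid
        else:
            hi = mid
    return np.minimum(hi * wc, caps)


def apply_remodeling(
    stack: ImageStack,
    truth: GroundTruth,
    phenotype: str,
    effect_size: float,
    apical_fraction: float = 0.0,
    conserve_fraction: float = 1.0,
    depth_tau_planes: float | None = None,
    n_apical_planes: int = 3,
    depth_origin: int = 0,
) -> ImageStack:
    """Apply one remodeling transform to the matrix channels of a stack.

    *Degrader* — multiplies intensities inside the cluster footprint by the
    depletion factor ``f`` on every plane.  With ``depth_tau_planes`` set,
    the depletion strength decays with depth below ``depth_origin`` (the
    plane where the matrix proper begins) so the effect is strongest in the
    top planes; the per-plane factor is ``1 - (1 - f) * w_z`` with
    ``w_z = exp(-(z - origin)/tau)`` below the origin.  ``None`` applies
    ``f`` uniformly at every plane.

    *Accumulator* — multiplies intensities inside the footprint by the
    concentration factor ``f`` (attenuated with depth by the same
    ``w_z`` profile: contraction acts where the cells sit, near the matrix
    top); removes ``conserve_fraction`` of the gain
    from an annulus surrounding the footprint (multiplicative down-scaling,
    allocated across planes preferentially near the matrix top, never below
    a plane's available signal); and deposits ``apical_fraction`` of the
    removed signal on the top ``n_apical_planes`` planes over the footprint,
    proportionally to the signal already there (matrix is pulled up along
    existing fibers, so truly dark pixels stay dark).  With
    ``conserve_fraction = 1`` and ``apical_fraction = 0`` the field total is
    preserved exactly.

    The nuclei channel is never touched.  Intensities are not re-clipped
    here; mapping back onto the 0-225 scale is the job of
    :func:`ecmremodel.stacks.rescale_to_225`.
    """
    if phenotype not in ("degrader", "accumulator"):
        raise ParameterError(f"unknown phenotype {phenotype!r}")
    _check_effect(phenotype, effect_size)
    f = float(effect_size)
    mask = truth.cell_mask
    nz = stack.n_planes
    out = {name: arr.copy() for name, arr in stack.channels.items()}

    if phenotype == "degrader":
        weights = _depth_weights(nz, depth_tau_planes, depth_origin)
        factors = 1.0 - (1.0 - f) * weights
        for ch in MATRIX_CHANNELS:
            arr = out[ch]
            for z in range(nz):
                arr[z][mask] *= factors[z]
        return ImageStack(out, stack.z_spacing_um, stack.pixel_size_um)

    # accumulator
    from scipy.ndimage import binary_dilation
    from skimage.morphology import disk

    inner = binary_dilation(mask, structure=disk(8))
    annulus = binary_dilation(mask, structure=disk(40)) & ~inner
    weights = _depth_weights(nz, depth_tau_planes, depth_origin)
    factors = 1.0 + (f - 1.0) * weights
    for ch in MATRIX_CHANNELS:
        arr = out[ch]
        gain = 0.0
        for z in range(nz):
            gain += (factors[z] - 1.0) * float(arr[z][mask].sum())
            arr[z][mask] *= factors[z]
        removed = 0.0
        if conserve_fraction > 0 and gain > 0 and annulus.any():
            caps = np.array([float(arr[z][annulus].sum()) for z in range(nz)])
            take = _waterfill(conserve_fraction * gain, caps, weights)
            for z in range(nz):
                if caps[z] > 0 and take[z] > 0:
                    arr[z][annulus] *= 1.0 - take[z] / caps[z]
            removed = float(take.sum())
        if apical_fraction > 0 and removed > 0:
            n_top = min(n_apical_planes, nz)
            w = np.linspace(2.0, 1.0, n_top)
            w /= w.sum()
            for i in range(n_top):
                plane_sum = float(arr[i][mask].sum())
                if plane_sum > 0:
                    arr[i][mask] *= 1.0 + apical_fraction * removed * w[i] / plane_sum
    return ImageStack(out, stack.z_spacing_um, stack.pixel_size_um)


def simulate_timecourse(
    params: SimulationParams,
) -> list[tuple[int, ImageStack]]:
    """Simulate repeated imaging of one seed-fixed field over culture days.

    The same field geometry and fiber mesh (identical seed) underlie every
    timepoint; the remodeling effect is scaled per day by
    ``params.effect_timescale`` (non-decreasing; day 0 customarily 0), as
    when preselected fields are re-imaged on days 0, 7 and 10.
    """
    params.validate()
    if not params.timepoints:
        raise ParameterError("timepoints must be non-empty")
    scaling = np.asarray(params.effect_timescale, dtype=float)
    if np.any(np.diff(scaling) < 0):
        raise ParameterError("effect_timescale must be non-decreasing over days")
    if np.any(scaling < 0) or np.any(scaling > 1):
        raise ParameterError("effect_timescale values must lie in [0, 1]")

    f_full = params.resolved_effect_size()
    series: list[tuple[int, ImageStack]] = []
    for day, s in zip(params.timepoints, scaling):
        if params.phenotype == "none" or s == 0.0:
            day_params = replace(params, phenotype="none")
        else:
            if params.phenotype == "degrader":
                f_day = 1.0 - s * (1.0 - f_full)
            else:
                f_day = 1.0 + s * (f_full - 1.0)
            day_params = replace(params, effect_size=f_day)
        stack, _ = simulate_matrix_stack(day_params)
        series.append((int(day), stack))
    return series


# ---------------------------------------------------------------------------
# presets


def preset(name: str, seed: int = 0, **overrides) -> SimulationParams:
    """Named parameter presets for the two observed remodeling phenotypes.

    ``"null"`` — no remodeling; ``"ovcar5_like"`` — protease-driven matrix
    degrader; ``"ovcar10_like"`` — contraction-driven matrix accumulator.
    """
    base = dict(seed=seed)
    if name == "null":
        base.update(phenotype="none")
    elif name == "ovcar5_like":
        base.update(phenotype="degrader", effect_size=0.3)
    elif name == "ovcar10_like":
        base.update(phenotype="accumulator", effect_size=3.0)
    else:
        raise ParameterError(f"unknown preset {name!r}")
    base.update(overrides)
    return SimulationParams(**base)
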