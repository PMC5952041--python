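"""Synthetic arched-tract phantom and synthetic rater tables.

The phantom emulates the imaging situation the dissection protocol was
built for: a thin (~2 mm diameter) white-matter tube that arches through
~180 degrees in the mid-sagittal plane — anterior end at the level of the
anterior commissure, apex over the inter-thalamic adhesion, posterior end
at the pineal level — embedded in isotropic CSF-like background, with
fornix-like distractor tubes close enough to contaminate a gate-based
dissection.  Ground truth (centerline, per-structure masks, landmarks and
closed-form tensor metrics) is carried alongside so every downstream module
can be tested without scan data.

Default geometry: 64^3 grid of 1 mm voxels; semicircular arc of radius
9.6 mm (arc length pi*R = 30.16 mm, matching the ~30 mm tract; chord
19.2 mm = anterior-posterior landmark distance); tube radius 1.0 mm
(diameter 2.0 mm, within the 1.5-2.5 mm cadaveric range); tube eigenvalues
(1.41e-3, 0.98e-3, 0.98e-3) mm^2/s, i.e. AD/RD at the reported tract means;
background mean diffusivity 3.0e-3 mm^2/s (free-water-like).  Voxels whose
centre falls within half a voxel of the tube surface receive a
volume-weighted mix of tube and background tensors, reproducing the
partial-volume FA collapse expected for a CSF-bathed tract.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from . import shbasis
from .metrics import eigen_metrics
from .space import AffineGrid, FODField, TensorField

DEG = np.pi / 180.0

#: per-metric means used by the rater-table simulator, anchored at the
#: reported tract-level values (length mm, volume mm^3, diffusivities mm^2/s)
DEFAULT_METRIC_MEANS = {
    "length_mm": 29.8,
    "volume_mm3": 129.0,
    "fa": 0.253,
    "md": 0.00112,
    "ad": 0.00141,
    "rd": 0.00098,
    "cl": 0.243,
    "cp": 0.145,
    "cs": 0.612,
}


# ---------------------------------------------------------------------------
# geometry specs


@dataclass(frozen=True)
class TubeSpec:
    """A tube around either a circular-arc or straight-segment centerline."""

    name: str
    kind: str  # "arc" | "line"
    radius: float = 1.0  # tube radius, mm
    eigenvalues: tuple[float, float, float] = (1.41e-3, 0.98e-3, 0.98e-3)
    # arc parameters: circle centre, circle radius, angular range (radians);
    # the circle lies in a plane x = const, parametrized
    # (cx, cy + rho*cos(theta), cz + rho*sin(theta))
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rho: float = 0.0
    theta_range: tuple[float, float] = (0.0, np.pi)
    # line parameters
    a: tuple[float, float, float] = (0.0, 0.0, 0.0)
    b: tuple[float, float, float] = (0.0, 0.0, 1.0)


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 1.0  # mm, isotropic
    arc_radius: float = 9.6  # mm -> arc length pi*R = 30.16 mm
    tube_radius: float = 1.0  # mm -> 2.0 mm diameter
    tract_eigenvalues: tuple[float, float, float] = (1.41e-3, 0.98e-3, 0.98e-3)
    background_md: float = 3.0e-3  # mm^2/s, CSF-like isotropic
    background_fod_amplitude: float = 0.05  # below the 0.1 tracking floor
    sh_order: int = 8
    kernel_kappa: float = 15.0  # single-fibre kernel sharpness
    bilateral: bool = False  # two para-sagittal arcs merging at the apex
    bilateral_offset: float = 1.2  # mm, lateral half-separation of the arcs
    partial_volume_shell: bool = True  # mix tube/background at the surface
    distractors: str | list[TubeSpec] = "default"
    rng_seed: int = 0

    def __post_init__(self):
        lam = self.tract_eigenvalues
        if not (lam[0] >= lam[1] >= lam[2] > 0):
            raise ValueError("tract eigenvalues must be sorted descending, > 0")
        if self.tube_radius < self.voxel_size / 2:
            raise ValueError("tube radius must be at least half a voxel")
        extent = min(self.grid_shape) * self.voxel_size
        if self.arc_radius + self.tube_radius + 2 * self.voxel_size > extent / 2:
            raise ValueError("arc does not fit inside the grid with a 2-voxel margin")


@dataclass
class Landmarks:
    """Anatomical fixed points driving gate construction (world mm, RAS+)."""

    ac_apex: np.ndarray  # uppermost anterior commissure
    pineal_apex: np.ndarray  # most superior pineal point
    thalamus_mid: np.ndarray  # mid-thalamus / inter-thalamic adhesion centre
    has_ita: bool = True

    def __post_init__(self):
        self.ac_apex = np.asarray(self.ac_apex, dtype=float)
        self.pineal_apex = np.asarray(self.pineal_apex, dtype=float)
        self.thalamus_mid = np.asarray(self.thalamus_mid, dtype=float)
        # anterior is +y in RAS+
        if not (self.ac_apex[1] > self.thalamus_mid[1] > self.pineal_apex[1]):
            raise ValueError(
                "landmark ordering violated: need AC anterior to mid-thalamus "
                "anterior to pineal along y"
            )


@dataclass
class PhantomTruth:
    grid: AffineGrid
    centerline: np.ndarray  # (M, 3) world mm along the arc
    tract_mask: np.ndarray  # voxels at least half inside the tube
    tracking_mask: np.ndarray  # any anisotropic content (seeding support)
    landmarks: Landmarks
    expected_metrics: dict[str, float]
    arc_length: float  # mm
    arc_center: np.ndarray
    arc_radius: float
    tube_radius: float
    distractor_masks: dict[str, np.ndarray] = dfield(default_factory=dict)
    weights: dict[str, np.ndarray] = dfield(default_factory=dict)
    tangents: dict[str, np.ndarray] = dfield(default_factory=dict)


# ---------------------------------------------------------------------------
# distance / tangent fields


def _arc_distance(points, center, rho, theta_range):
    """Distance to an arc centerline and unit tangents at nearest points.

    The tube is truncated flush at the arc's angular ends (it models a
    tract *segment*): points beyond the end planes get infinite distance,
    so tracking terminates at the caps instead of following a rounded
    end-cap ball past them.
    """
    p = np.asarray(points, dtype=float)
    c = np.asarray(center, dtype=float)
    dy, dz = p[:, 1] - c[1], p[:, 2] - c[2]
    theta = np.arctan2(dz, dy)
    t0, t1 = theta_range
    # map into [t0, t0 + 2*pi) then clamp to the arc's angular span
    theta = np.mod(theta - t0, 2 * np.pi) + t0
    theta_cl = np.clip(theta, t0, t1)
    on_arc = theta <= t1
    radial = np.hypot(dy, dz)
    d = np.full(len(p), np.inf)
    d[on_arc] = np.sqrt((p[on_arc, 0] - c[0]) ** 2 + (radial[on_arc] - rho) ** 2)
    tang = np.zeros_like(p)
    tang[:, 1] = -np.sin(theta_cl)
    tang[:, 2] = np.cos(theta_cl)
    return d, tang


def _line_distance(points, a, b):
    p = np.asarray(points, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    L = np.linalg.norm(ab)
    u = ab / L
    t = np.clip((p - a) @ u, 0.0, L)
    nearest = a[None, :] + t[:, None] * u[None, :]
    d = np.linalg.norm(p - nearest, axis=1)
    tang = np.broadcast_to(u, p.shape).copy()
    return d, tang


def tube_weights(spec: PhantomSpec, tube: TubeSpec, points: np.ndarray):
    """Partial-volume weight in [0, 1] and tangent field for one tube.

    Weight ramps linearly from 1 at (radius - voxel/2) to 0 at
    (radius + voxel/2): the volume-weighted tube fraction of each voxel.
    """
    if tube.kind == "arc":
        d, tang = _arc_distance(points, tube.center, tube.rho, tube.theta_range)
    elif tube.kind == "line":
        d, tang = _line_distance(points, tube.a, tube.b)
    else:
        raise ValueError(f"unknown tube kind {tube.kind!r}")
    if spec.partial_volume_shell:
        w = np.clip((tube.radius + spec.voxel_size / 2 - d) / spec.voxel_size, 0.0, 1.0)
    else:
        w = (d <= tube.radius).astype(float)
    return w, tang


# ---------------------------------------------------------------------------
# field assembly


def _tensor_from_tangent(tangents: np.ndarray, lam) -> np.ndarray:
    """Axially oriented tensors T = lam2*I + (lam1-lam2)*t t^T (+ planar term).

    For a general sorted triple the second axis is chosen in the plane
    orthogonal to the tangent; for the axially symmetric default
    (lam2 == lam3) the choice is irrelevant.
    """
    l1, l2, l3 = lam
    t = tangents / np.linalg.norm(tangents, axis=-1, keepdims=True)
    # build an orthonormal complement
    a = np.where(np.abs(t[:, :1]) < 0.9, [[1.0, 0, 0]], [[0, 1.0, 0]])
    e2 = np.cross(t, a)
    e2 /= np.linalg.norm(e2, axis=-1, keepdims=True)
    e3 = np.cross(t, e2)
    T = (
        l1 * t[:, :, None] * t[:, None, :]
        + l2 * e2[:, :, None] * e2[:, None, :]
        + l3 * e3[:, :, None] * e3[:, None, :]
    )
    return T


def _default_distractors(spec: PhantomSpec, center, z0) -> list[TubeSpec]:
    """Fornix-body-like dorsal arc plus two crus-like oblique lateral tubes."""
    x0, yc = center[0], center[1]
    R = spec.arc_radius
    lam = spec.tract_eigenvalues
    fornix = TubeSpec(
        name="fornix_body",
        kind="arc",
        radius=spec.tube_radius,
        eigenvalues=lam,
        center=(x0, yc, z0),
        rho=R + 3.5,
        theta_range=(-25 * DEG, 205 * DEG),
    )
    # half-integer lateral offset: a 1 mm tube centred on a voxel plane
    # digitizes to a degenerate single-column mask
    crus = [
        TubeSpec(
            name=f"fornix_crus_{side}",
            kind="line",
            radius=spec.tube_radius,
            eigenvalues=lam,
            a=(x0 + s * 4.5, yc - 10.6, z0 - 6.0),
            b=(x0 + s * 4.5, yc + 1.0, z0 + 14.0),
        )
        for side, s in (("left", -1), ("right", +1))
    ]
    return [fornix] + crus


def _sm_tubes(spec: PhantomSpec, center, z0) -> list[TubeSpec]:
    tubes = []
    offsets = (
        (-spec.bilateral_offset, +spec.bilateral_offset) if spec.bilateral else (0.0,)
    )
    for i, dx in enumerate(offsets):
        tubes.append(
            TubeSpec(
                name="sm" if not spec.bilateral else f"sm_{i}",
                kind="arc",
                radius=spec.tube_radius,
                eigenvalues=spec.tract_eigenvalues,
                center=(center[0] + dx, center[1], z0),
                rho=spec.arc_radius,
                theta_range=(0.0, np.pi),
            )
        )
    return tubes


def _assemble_fields(spec: PhantomSpec, tubes: list[TubeSpec], grid: AffineGrid):
    """Blend tube and background tensors/FODs over the whole grid."""
    shape = grid.shape
    ii, jj, kk = np.indices(shape)
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    pts = grid.voxel_to_world(vox)
    n = len(pts)

    weights = np.zeros((len(tubes), n))
    tangents = np.zeros((len(tubes), n, 3))
    for t, tube in enumerate(tubes):
        weights[t], tangents[t] = tube_weights(spec, tube, pts)
    owner = np.argmax(weights, axis=0)
    w = weights[owner, np.arange(n)]

    bg = spec.background_md * np.eye(3)
    tensors = np.broadcast_to(bg, (n, 3, 3)).copy()
    order = spec.sh_order
    coeffs = np.tile(
        shbasis.isotropic_coeffs(spec.background_fod_amplitude, order), (n, 1)
    )
    active = w > 0
    if active.any():
        idx = np.nonzero(active)[0]
        tang = tangents[owner[idx], idx]
        for t, tube in enumerate(tubes):
            sel = idx[owner[idx] == t]
            if not len(sel):
                continue
            T = _tensor_from_tangent(tangents[t, sel], tube.eigenvalues)
            wv = w[sel][:, None, None]
            tensors[sel] = wv * T + (1 - wv) * bg
            peak = shbasis.single_peak_coeffs(tangents[t, sel], order, spec.kernel_kappa)
            iso = shbasis.isotropic_coeffs(spec.background_fod_amplitude, order)
            coeffs[sel] = w[sel][:, None] * peak + (1 - w[sel][:, None]) * iso

    from .space import matrix_to_tensor6

    comp = matrix_to_tensor6(tensors).reshape(shape + (6,))
    sh = coeffs.reshape(shape + (-1,))
    full = np.ones(shape, dtype=bool)
    tracking = (w >= spec.background_fod_amplitude + 1e-12).reshape(shape)
    per_tube_w = {tube.name: weights[t].reshape(shape) for t, tube in enumerate(tubes)}
    per_tube_t = {tube.name: tangents[t] for t, tube in enumerate(tubes)}
    tensor_field = TensorField(grid, comp, full)
    fod_field = FODField(grid, sh, tracking.copy())
    return tensor_field, fod_field, per_tube_w, per_tube_t, tracking


def _phantom_grid(spec: PhantomSpec) -> AffineGrid:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = spec.voxel_size
    return AffineGrid(spec.grid_shape, aff)


def build_arc_phantom(spec: PhantomSpec | None = None):
    """Build the arched-tract phantom without distractors.

    Returns ``(TensorField, FODField, PhantomTruth)``.  Deterministic: the
    geometry is analytic and the seed only parametrizes downstream table
    simulation.
    """
    spec = spec or PhantomSpec()
    grid = _phantom_grid(spec)
    nx, ny, nz = spec.grid_shape
    vx = spec.voxel_size
    # centre on a voxel so the mid-sagittal plane and the arc's end plane
    # contain voxel centres: fully-interior voxels then carry the exact
    # tube tensor and the flush-truncated ends keep their bottom voxel row
    center = np.array([(nx // 2) * vx, (ny // 2) * vx, 0.0])
    z0 = (nz // 2 - int(round(spec.arc_radius / (2 * vx)))) * vx
    center[2] = z0

    tubes = _sm_tubes(spec, center, z0)
    tensor_field, fod_field, wmap, tmap, tracking = _assemble_fields(spec, tubes, grid)

    R = spec.arc_radius
    theta = np.linspace(0.0, np.pi, int(np.ceil(np.pi * R / 0.05)) + 1)
    centerline = np.column_stack(
        [
            np.full_like(theta, center[0]),
            center[1] + R * np.cos(theta),
            z0 + R * np.sin(theta),
        ]
    )
    landmarks = Landmarks(
        ac_apex=np.array([center[0], center[1] + R, z0]),
        pineal_apex=np.array([center[0], center[1] - R, z0 - vx]),
        thalamus_mid=np.array([center[0], center[1], z0 + R - 2.0]),
        has_ita=True,
    )
    sm_w = np.zeros(grid.shape)
    for tube in tubes:
        sm_w = np.maximum(sm_w, wmap[tube.name])
    truth = PhantomTruth(
        grid=grid,
        centerline=centerline,
        tract_mask=sm_w >= 0.5,
        tracking_mask=tracking,
        landmarks=landmarks,
        expected_metrics=eigen_metrics(np.asarray(spec.tract_eigenvalues)),
        arc_length=np.pi * R,
        arc_center=center,
        arc_radius=R,
        tube_radius=spec.tube_radius,
        weights={"sm": sm_w},
        tangents={},
    )
    return tensor_field, fod_field, truth


def build_distractors(spec: PhantomSpec, truth: PhantomTruth):
    """Rebuild the phantom fields with distractor tubes overlaid.

    Returns ``(TensorField, FODField, PhantomTruth)`` where the truth now
    records one mask per distractor.  Raises if any distractor overlaps more
    than 20% of the tract tube volume (the dissection would be ill-posed).
    """
    if spec.distractors == "none" or spec.distractors == []:
        return None
    grid = truth.grid
    center, z0 = truth.arc_center, truth.arc_center[2]
    if spec.distractors == "default":
        extra = _default_distractors(spec, center, z0)
    else:
        extra = list(spec.distractors)
    tubes = _sm_tubes(spec, center, z0) + extra
    tensor_field, fod_field, wmap, tmap, tracking = _assemble_fields(spec, tubes, grid)

    sm_vox = int(truth.tract_mask.sum())
    masks = {}
    for tube in extra:
        m = wmap[tube.name] >= 0.5
        overlap = int((m & truth.tract_mask).sum())
        if overlap > 0.2 * sm_vox:
            raise ValueError(
                f"distractor {tube.name!r} overlaps {overlap}/{sm_vox} tract voxels"
            )
        masks[tube.name] = m
    new_truth = PhantomTruth(
        grid=grid,
        centerline=truth.centerline,
        tract_mask=truth.tract_mask,
        tracking_mask=tracking,
        landmarks=truth.landmarks,
        expected_metrics=truth.expected_metrics,
        arc_length=truth.arc_length,
        arc_center=truth.arc_center,
        arc_radius=truth.arc_radius,
        tube_radius=truth.tube_radius,
        distractor_masks=masks,
        weights={**truth.weights, **{t.name: wmap[t.name] for t in extra}},
        tangents={},
    )
    return tensor_field, fod_field, new_truth


def build_phantom(spec: PhantomSpec | None = None, with_distractors: bool = True):
    """One-call phantom: arc (+ default distractors) fields and ground truth."""
    spec = spec or PhantomSpec()
    tensor_field, fod_field, truth = build_arc_phantom(spec)
    if with_distractors and spec.distractors not in ("none", []):
        tensor_field, fod_field, truth = build_distractors(spec, truth)
    return tensor_field, fod_field, truth


def build_line_phantom(
    a,
    b,
    grid_shape=(40, 40, 40),
    voxel_size: float = 1.0,
    tube_radius: float = 1.0,
    eigenvalues=(1.41e-3, 0.98e-3, 0.98e-3),
    partial_volume_shell: bool = False,
    background_fod_amplitude: float = 0.05,
):
    """A single straight tube from ``a`` to ``b`` in isotropic background.

    Returns ``(TensorField, FODField, tube_mask, weights)``; handy for
    tracking-termination and digitized-cylinder-volume tests where the
    analytic geometry is trivial.
    """
    spec = PhantomSpec(
        grid_shape=tuple(grid_shape),
        voxel_size=voxel_size,
        arc_radius=min(grid_shape) * voxel_size / 4,  # unused; satisfies bounds
        tube_radius=tube_radius,
        tract_eigenvalues=tuple(eigenvalues),
        partial_volume_shell=partial_volume_shell,
        background_fod_amplitude=background_fod_amplitude,
        distractors="none",
    )
    grid = _phantom_grid(spec)
    tube = TubeSpec(name="tube", kind="line", radius=tube_radius,
                    eigenvalues=tuple(eigenvalues), a=tuple(a), b=tuple(b))
    tensor_field, fod_field, wmap, _, tracking = _assemble_fields(spec, [tube], grid)
    w = wmap["tube"]
    return tensor_field, fod_field, w >= 0.5, w


# ---------------------------------------------------------------------------
# synthetic rater / subject tables

AGE_MEAN, AGE_SD = 29.58, 13.03  # cohort age distribution
ETIV_MEAN, ETIV_SD = 1.45e6, 1.2e5  # mm^3


def _covariates(n_subjects: int, rng: np.random.Generator):
    # ages stay untruncated Gaussian so correlation structure is exact
    age = rng.normal(AGE_MEAN, AGE_SD, n_subjects)
    gender = np.arange(n_subjects) % 2  # balanced 0/1
    etiv = rng.normal(ETIV_MEAN, ETIV_SD, n_subjects) + 5e4 * (gender - 0.5)
    return age, gender, etiv


def simulate_rater_tables(
    n_subjects: int,
    icc_target: float,
    metric_means: dict[str, float] | None = None,
    rng_seed: int = 0,
    n_raters: int = 2,
    subject_cv: float = 0.10,
    age_slope: dict[str, float] | None = None,
    noise_sd_override: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Two-rater (or k-rater) long-format metric table with known ICC.

    Each metric value is subject effect + rater noise with variance ratio
    sigma_s^2 / (sigma_s^2 + sigma_e^2) = ``icc_target``; total SD per metric
    is ``subject_cv`` times its mean.  ``age_slope`` (units of metric per
    year) moves part of the subject variance onto age, for
    partial-correlation recovery tests.  Covariates are constant across a
    subject's rows.
    """
    if not (0.0 < icc_target < 1.0):
        raise ValueError("icc_target must be strictly inside (0, 1)")
    if n_subjects < 5:
        raise ValueError("need at least 5 subjects")
    means = dict(DEFAULT_METRIC_MEANS if metric_means is None else metric_means)
    age_slope = age_slope or {}
    noise_sd_override = noise_sd_override or {}
    rng = np.random.default_rng(rng_seed)
    age, gender, etiv = _covariates(n_subjects, rng)

    rows = {
        "subject": np.repeat(np.arange(n_subjects), n_raters),
        "rater": np.tile(np.arange(1, n_raters + 1), n_subjects),
    }
    for metric, mu in means.items():
        sigma = subject_cv * (abs(mu) if mu != 0 else 1.0)
        var_s = icc_target * sigma**2
        var_e = (1 - icc_target) * sigma**2
        slope = age_slope.get(metric, 0.0)
        var_from_age = slope**2 * AGE_SD**2
        if var_from_age > var_s:
            raise ValueError(f"age slope for {metric!r} exceeds subject variance")
        subj = slope * (age - AGE_MEAN) + rng.normal(
            0.0, np.sqrt(var_s - var_from_age), n_subjects
        )
        sd_e = noise_sd_override.get(metric, np.sqrt(var_e))
        noise = rng.normal(0.0, sd_e, (n_subjects, n_raters))
        rows[metric] = (mu + subj[:, None] + noise).ravel()
    rows["age"] = np.repeat(age, n_raters)
    rows["gender"] = np.repeat(gender, n_raters)
    rows["etiv"] = np.repeat(etiv, n_raters)
    return pd.DataFrame(rows)


def simulate_group_table(
    n_subjects: int,
    rng_seed: int = 0,
    metric: str = "rd",
    metric_mean: float = 0.00098,
    metric_cv: float = 0.10,
    partial_r_age: float = 0.0,
    gender_effect: float = 0.0,
    etiv_slope_sd: float = 0.3,
) -> pd.DataFrame:
    """Per-subject (rater-averaged) table with exact population structure.

    The metric is built as gender effect + an eTIV component + a latent
    age-linked factor, such that the population partial correlation between
    metric and age controlling (gender, eTIV) is exactly ``partial_r_age``
    and the marginal gender effect (male - female) is ``gender_effect``.
    """
    if not (-1.0 < partial_r_age < 1.0):
        raise ValueError("partial_r_age must lie in (-1, 1)")
    rng = np.random.default_rng(rng_seed)
    age, gender, etiv = _covariates(n_subjects, rng)
    w_age = (age - AGE_MEAN) / AGE_SD  # independent of gender/eTIV noise
    sigma = metric_cv * abs(metric_mean)
    eps = rng.normal(0.0, 1.0, n_subjects)
    value = (
        metric_mean
        + gender_effect * (gender - 0.5)
        + etiv_slope_sd * sigma * (etiv - ETIV_MEAN) / ETIV_SD
        + sigma * (partial_r_age * w_age + np.sqrt(1 - partial_r_age**2) * eps)
    )
    return pd.DataFrame(
        {
            "subject": np.arange(n_subjects),
            metric: value,
            "age": age,
            "gender": gender,
            "etiv": etiv,
        }
    )
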