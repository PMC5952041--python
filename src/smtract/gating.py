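"""Boolean-gate virtual dissection of the arched epithalamic tract.

The protocol places three landmark-driven gates (Boolean regions of
interest) on whole-brain streamlines:

* an anterior **OR** gate: an axial slab at the uppermost anterior
  commissure, its rectangle starting just anterior to the commissure and
  extending posteriorly;
* a posterior **OR** gate: an axial slab at the slice immediately *above*
  the most superior pineal point, extending from mid-thalamus level back
  over the pineal and laterally over the pineal stalks;
* a mid **AND** gate: a coronal slab at the inter-thalamic adhesion /
  mid-thalamus, tall enough to cover the tract's arch.

Streamlines are retained if they cross at least one OR gate, every AND
gate and no NOT gate (set semantics; order irrelevant).  Declarative NOT
templates replace the manual cleanup step: a coronal pair with margins
anterior and posterior to the tract region, and an axial pair isolating
fornix-crus-like fibres bilaterally.  Retained streamlines are then *split*
— clipped to the portion travelling between the anterior and posterior
gates, with endpoints interpolated exactly onto the gate mid-planes.

All gates are axis-aligned boxes (slab interval along the plane normal x
in-plane rectangle), with half-open ``[lo, hi)`` intervals; gate membership
is an exact segment-box intersection test.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield, replace

import numpy as np

from .phantom import Landmarks  # canonical landmark container
from .space import AffineGrid
from .tracking import Tractogram, Streamline, TrackingParams, whole_brain_track
from .metrics import TractStats, tract_mean_metrics

PLANE_NORMAL = {"axial": 2, "coronal": 1, "sagittal": 0}


# ---------------------------------------------------------------------------
# gates


@dataclass(frozen=True)
class Gate:
    """An oriented rectangular slab ROI with a Boolean role."""

    role: str  # "SEED_OR" | "AND" | "NOT"
    plane: str  # "axial" | "coronal" | "sagittal"
    slab: tuple[float, float]  # [lo, hi) along the plane normal, world mm
    rect: tuple[tuple[float, float], tuple[float, float]]  # in-plane [lo, hi)
    label: str = ""

    def __post_init__(self):
        if self.role not in ("SEED_OR", "AND", "NOT"):
            raise ValueError(f"unknown gate role {self.role!r}")
        if self.plane not in PLANE_NORMAL:
            raise ValueError(f"unknown plane {self.plane!r}")
        if not self.slab[1] > self.slab[0]:
            raise ValueError("slab thickness must be positive")
        (u0, u1), (v0, v1) = self.rect
        if not (u1 > u0 and v1 > v0):
            raise ValueError("rectangle area must be positive")

    @property
    def normal_axis(self) -> int:
        return PLANE_NORMAL[self.plane]

    @property
    def plane_axes(self) -> tuple[int, int]:
        return tuple(a for a in (0, 1, 2) if a != self.normal_axis)  # type: ignore[return-value]

    @property
    def midplane(self) -> float:
        return 0.5 * (self.slab[0] + self.slab[1])

    def box(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.empty(3)
        hi = np.empty(3)
        lo[self.normal_axis], hi[self.normal_axis] = self.slab
        (u, v) = self.plane_axes
        (lo[u], hi[u]), (lo[v], hi[v]) = self.rect
        return lo, hi

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Half-open box membership of world points."""
        p = np.atleast_2d(points)
        lo, hi = self.box()
        return ((p >= lo) & (p < hi)).all(axis=1)


def _boxes_overlap(a: Gate, b: Gate) -> bool:
    alo, ahi = a.box()
    blo, bhi = b.box()
    return bool(np.all(np.maximum(alo, blo) < np.minimum(ahi, bhi)))


@dataclass
class GateProtocol:
    or_gates: list[Gate]
    and_gates: list[Gate] = dfield(default_factory=list)
    not_gates: list[Gate] = dfield(default_factory=list)
    split_between: tuple[str, str] | None = None  # (anterior, posterior) labels

    def __post_init__(self):
        labels = {g.label for g in self.all_gates()}
        if self.split_between is not None:
            for lab in self.split_between:
                if lab not in labels:
                    raise ValueError(f"split_between references unknown gate {lab!r}")
        for ng in self.not_gates:
            for g in list(self.or_gates) + list(self.and_gates):
                if _boxes_overlap(ng, g):
                    raise ValueError(
                        f"NOT gate {ng.label!r} overlaps selection gate {g.label!r}"
                    )

    def all_gates(self) -> list[Gate]:
        return list(self.or_gates) + list(self.and_gates) + list(self.not_gates)

    def gate(self, label: str) -> Gate:
        for g in self.all_gates():
            if g.label == label:
                return g
        raise KeyError(label)


# ---------------------------------------------------------------------------
# membership and crossings


def streamline_crosses_gate(points: np.ndarray, gate: Gate) -> bool:
    """True iff the polyline intersects the gate's slab-rectangle box.

    Exact segment/axis-aligned-box intersection (slab clipping), equivalent
    to membership of the densely resampled polyline in the limit.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    lo, hi = gate.box()
    if bool(((p >= lo) & (p < hi)).all(axis=1).any()):
        return True
    if len(p) < 2:
        return False
    p0, p1 = p[:-1], p[1:]
    d = p1 - p0
    tmin = np.zeros(len(p0))
    tmax = np.ones(len(p0))
    ok = np.ones(len(p0), dtype=bool)
    for a in range(3):
        da = d[:, a]
        pa = p0[:, a]
        parallel = np.abs(da) < 1e-300
        inside_par = (pa >= lo[a]) & (pa < hi[a])
        ok &= ~parallel | inside_par
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (lo[a] - pa) / da
            t2 = (hi[a] - pa) / da
        tlo = np.minimum(t1, t2)
        thi = np.maximum(t1, t2)
        nonpar = ~parallel
        tmin = np.where(nonpar, np.maximum(tmin, tlo), tmin)
        tmax = np.where(nonpar, np.minimum(tmax, thi), tmax)
    return bool((ok & (tmin <= tmax)).any())


def midplane_crossings(
    points: np.ndarray, gate: Gate, restrict_rect: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Crossings of the gate's slab mid-plane along a polyline.

    Returns (positions, crossing_points) where a position ``s`` means the
    crossing occurs at parametric coordinate ``s`` along the polyline
    (vertex i at s = i).  A vertex lying exactly on the plane counts as a
    crossing.  With ``restrict_rect`` only crossings whose in-plane
    coordinates fall inside the gate rectangle are returned.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    n = gate.normal_axis
    f = p[:, n] - gate.midplane
    pos_list = []
    pts_list = []
    on_plane = np.nonzero(f == 0.0)[0]
    for i in on_plane:
        pos_list.append(float(i))
        pts_list.append(p[i])
    if len(p) > 1:
        f0, f1 = f[:-1], f[1:]
        sign_change = (f0 * f1) < 0
        for i in np.nonzero(sign_change)[0]:
            t = f0[i] / (f0[i] - f1[i])
            q = p[i] + t * (p[i + 1] - p[i])
            q[n] = gate.midplane  # exact by construction
            pos_list.append(float(i) + float(t))
            pts_list.append(q)
    if not pos_list:
        return np.empty(0), np.empty((0, 3))
    order = np.argsort(pos_list)
    pos = np.asarray(pos_list)[order]
    pts = np.asarray(pts_list)[order]
    if restrict_rect:
        u, v = gate.plane_axes
        (u0, u1), (v0, v1) = gate.rect
        keep = (pts[:, u] >= u0) & (pts[:, u] < u1) & (pts[:, v] >= v0) & (pts[:, v] < v1)
        pos, pts = pos[keep], pts[keep]
    return pos, pts


def apply_protocol(t: Tractogram, p: GateProtocol) -> Tractogram:
    """Retain streamlines crossing >=1 OR gate, all AND gates, no NOT gate.

    Pure set semantics; an empty result is returned with a warning flag in
    the provenance, not raised.
    """
    kept = []
    for s in t.streamlines:
        pts = s.points
        if p.or_gates and not any(
            streamline_crosses_gate(pts, g) for g in p.or_gates
        ):
            continue
        if any(not streamline_crosses_gate(pts, g) for g in p.and_gates):
            continue
        if any(streamline_crosses_gate(pts, g) for g in p.not_gates):
            continue
        kept.append(s)
    prov = dict(t.provenance)
    prov["selection"] = {
        "n_input": len(t.streamlines),
        "n_retained": len(kept),
        "empty_warning": len(kept) == 0,
    }
    return Tractogram(streamlines=kept, grid_ref=t.grid_ref, provenance=prov)


def split_between_gates(
    t: Tractogram, anterior: Gate, posterior: Gate
) -> tuple[Tractogram, dict]:
    """Clip each streamline to its span between the two boundary gates.

    Keeps the maximal contiguous sub-polyline from the first crossing of the
    anterior gate's mid-plane (within its rectangle) to the last crossing of
    the posterior gate's mid-plane; endpoints are interpolated exactly onto
    the planes.  Streamlines not crossing both gates are dropped (counted);
    a streamline crossing either plane more than 4 times is kept but
    flagged as a loop suspect.
    """
    out = []
    dropped = 0
    flagged = 0
    for s in t.streamlines:
        pts = s.points
        pos_a, xyz_a = midplane_crossings(pts, anterior)
        pos_p, xyz_p = midplane_crossings(pts, posterior)
        if len(pos_a) == 0 or len(pos_p) == 0:
            dropped += 1
            continue
        # orient so travel goes anterior gate -> posterior gate
        if pos_a.min() > pos_p.max():
            n = len(pts) - 1
            pts = pts[::-1]
            pos_a, xyz_a = n - pos_a[::-1], xyz_a[::-1]
            pos_p, xyz_p = n - pos_p[::-1], xyz_p[::-1]
        sa, qa = pos_a[0], xyz_a[0]
        later = pos_p >= sa
        if not later.any():
            dropped += 1
            continue
        sp, qp = pos_p[later][-1], xyz_p[later][-1]
        if len(pos_a) > 4 or len(pos_p) > 4:
            flagged += 1
        i0 = int(np.ceil(sa))
        i1 = int(np.floor(sp))
        mid = pts[i0 : i1 + 1]
        pieces = []
        if len(mid) == 0 or not np.allclose(qa, mid[0]):
            pieces.append(qa[None])
        pieces.append(mid)
        if len(mid) == 0 or not np.allclose(qp, mid[-1]):
            pieces.append(qp[None])
        new_pts = np.vstack(pieces)
        if len(new_pts) < 2:
            dropped += 1
            continue
        out.append(Streamline(points=new_pts, seed_index=0))
    prov = dict(t.provenance)
    info = {"n_input": len(t.streamlines), "n_split": len(out),
            "n_dropped": dropped, "n_loop_flagged": flagged}
    prov["split"] = info
    return Tractogram(streamlines=out, grid_ref=t.grid_ref, provenance=prov), info


# ---------------------------------------------------------------------------
# protocol construction


@dataclass(frozen=True)
class GateExtents:
    """Rectangle extents of the three landmark gates (mm).

    The protocol fixes gate *positions* from landmarks; extents are
    qualitative in the source protocol ("extended broadly posteriorly") and
    therefore live here as configuration.
    """

    slab_thickness: float | None = None  # None -> one voxel
    anterior_margin: float = 1.0  # rect starts this far anterior to the AC
    anterior_depth: float = 10.0  # posterior extent of the anterior rect
    anterior_halfwidth: float = 8.0
    posterior_overshoot: float = 4.0  # posterior to the pineal apex
    posterior_halfwidth: float = 6.0
    and_below: float = 4.0  # rect below the mid-thalamus point
    and_above: float = 10.0  # rect above it (total height 14 mm)
    and_halfwidth: float = 10.0


@dataclass(frozen=True)
class NotTemplateConfig:
    """Extents of the declarative NOT-gate cleanup templates (mm)."""

    coronal_margin_anterior: float = 2.0
    # posterior margin clears the posterior OR gate's overshoot rectangle
    coronal_margin_posterior: float = 4.0
    coronal_thickness: float = 2.0
    crus_drop: float = 3.0  # top of the axial pair below the AC slice
    crus_thickness: float = 1.0
    crus_inner: float = 2.0  # lateral rect from inner to outer offset
    crus_outer: float = 12.0


def _grid_world_bounds(grid: AffineGrid) -> tuple[np.ndarray, np.ndarray]:
    shape = np.asarray(grid.shape, dtype=float)
    corners = np.array(
        [[x, y, z] for x in (-0.5, shape[0] - 0.5)
         for y in (-0.5, shape[1] - 0.5) for z in (-0.5, shape[2] - 0.5)]
    )
    w = grid.voxel_to_world(corners)
    return w.min(axis=0), w.max(axis=0)


def build_sm_protocol(
    landmarks: Landmarks,
    grid: AffineGrid,
    extents: GateExtents | None = None,
) -> GateProtocol:
    """Three-gate protocol from the anatomical fixed points.

    Anterior axial OR gate at the AC apex slice; posterior axial OR gate at
    the slice immediately above the pineal apex; coronal AND gate at the
    mid-thalamus.  Raises if the landmark ordering is violated (enforced by
    ``Landmarks``) or a gate falls outside the grid.
    """
    ex = extents or GateExtents()
    vz = float(grid.voxel_size[2])
    vy = float(grid.voxel_size[1])
    tz = ex.slab_thickness if ex.slab_thickness is not None else vz
    ty = ex.slab_thickness if ex.slab_thickness is not None else vy
    ac, pineal, thal = landmarks.ac_apex, landmarks.pineal_apex, landmarks.thalamus_mid

    anterior = Gate(
        role="SEED_OR",
        plane="axial",
        slab=(ac[2] - tz / 2, ac[2] + tz / 2),
        rect=(
            (ac[0] - ex.anterior_halfwidth, ac[0] + ex.anterior_halfwidth),
            (ac[1] - ex.anterior_depth, ac[1] + ex.anterior_margin),
        ),
        label="anterior_or",
    )
    post_z = pineal[2] + vz  # the slice above the pineal apex
    posterior = Gate(
        role="SEED_OR",
        plane="axial",
        slab=(post_z - tz / 2, post_z + tz / 2),
        rect=(
            (pineal[0] - ex.posterior_halfwidth, pineal[0] + ex.posterior_halfwidth),
            (pineal[1] - ex.posterior_overshoot, thal[1]),
        ),
        label="posterior_or",
    )
    mid_and = Gate(
        role="AND",
        plane="coronal",
        slab=(thal[1] - ty / 2, thal[1] + ty / 2),
        rect=(
            (thal[0] - ex.and_halfwidth, thal[0] + ex.and_halfwidth),
            (thal[2] - ex.and_below, thal[2] + ex.and_above),
        ),
        label="mid_and",
    )
    wlo, whi = _grid_world_bounds(grid)
    for g in (anterior, posterior, mid_and):
        lo, hi = g.box()
        if (lo[g.normal_axis] < wlo[g.normal_axis]) or (
            hi[g.normal_axis] > whi[g.normal_axis]
        ):
            raise ValueError(f"gate {g.label!r} slab falls outside the grid")
    return GateProtocol(
        or_gates=[anterior, posterior],
        and_gates=[mid_and],
        split_between=("anterior_or", "posterior_or"),
    )


def not_templates(
    landmarks: Landmarks,
    grid: AffineGrid,
    names: tuple[str, ...] = ("coronal_pair", "fornix_crus_pair"),
    config: NotTemplateConfig | None = None,
) -> list[Gate]:
    """Named NOT-gate template sets built from the landmarks.

    ``coronal_pair``: whole-plane coronal slabs with margins anterior and
    posterior to the tract region — removes anything travelling beyond the
    tract's anterior-posterior span (fornix body and similar).
    ``fornix_crus_pair``: an axial pair below the AC slice with bilateral
    lateral rectangles — removes descending crus-like fibres.
    """
    cfg = config or NotTemplateConfig()
    ac, pineal = landmarks.ac_apex, landmarks.pineal_apex
    wlo, whi = _grid_world_bounds(grid)
    gates: list[Gate] = []
    if "coronal_pair" in names:
        full_xz = ((wlo[0], whi[0]), (wlo[2], whi[2]))
        gates.append(
            Gate(
                role="NOT",
                plane="coronal",
                slab=(
                    ac[1] + cfg.coronal_margin_anterior,
                    ac[1] + cfg.coronal_margin_anterior + cfg.coronal_thickness,
                ),
                rect=full_xz,
                label="not_coronal_anterior",
            )
        )
        gates.append(
            Gate(
                role="NOT",
                plane="coronal",
                slab=(
                    pineal[1] - cfg.coronal_margin_posterior - cfg.coronal_thickness,
                    pineal[1] - cfg.coronal_margin_posterior,
                ),
                rect=full_xz,
                label="not_coronal_posterior",
            )
        )
    if "fornix_crus_pair" in names:
        slab = (ac[2] - cfg.crus_drop - cfg.crus_thickness, ac[2] - cfg.crus_drop)
        full_y = (wlo[1], whi[1])
        for side, s in (("left", -1), ("right", +1)):
            x0 = ac[0] + s * cfg.crus_inner
            x1 = ac[0] + s * cfg.crus_outer
            gates.append(
                Gate(
                    role="NOT",
                    plane="axial",
                    slab=slab,
                    rect=((min(x0, x1), max(x0, x1)), full_y),
                    label=f"not_crus_{side}",
                )
            )
    return gates


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class SMPipelineResult:
    tract: Tractogram
    stats: TractStats | None
    protocol: GateProtocol
    counts: dict
    empty: bool


def sm_pipeline(
    field,
    mask: np.ndarray,
    landmarks: Landmarks,
    params_low: TrackingParams,
    params_high: TrackingParams,
    not_config: NotTemplateConfig | None = None,
    extents: GateExtents | None = None,
    tensor_field=None,
    not_names: tuple[str, ...] = ("coronal_pair", "fornix_crus_pair"),
    weighting: str = "point",
) -> SMPipelineResult:
    """Two-pass dissection mirroring the scout/final workflow.

    A low-fidelity scout tractogram validates gate placement (its retention
    counts are logged, then it is discarded); the saved gates are re-applied
    to the high-fidelity tractogram, which is split between the boundary
    gates and summarized.  ``tensor_field`` supplies the diffusion metrics
    when tracking runs on an FOD field.
    """
    grid = field.grid
    protocol = build_sm_protocol(landmarks, grid, extents)
    nots = not_templates(landmarks, grid, names=not_names, config=not_config)
    protocol = GateProtocol(
        or_gates=protocol.or_gates,
        and_gates=protocol.and_gates,
        not_gates=nots,
        split_between=protocol.split_between,
    )
    counts: dict = {}

    low = whole_brain_track(field, mask, params_low)
    low_sel = apply_protocol(low, protocol)
    counts["low_fidelity"] = {
        "n_whole_brain": len(low),
        "n_retained": len(low_sel),
    }
    # the scout tractogram is discarded; only the saved gates carry over
    high = whole_brain_track(field, mask, params_high)
    high_sel = apply_protocol(high, protocol)
    split, sinfo = split_between_gates(
        high_sel,
        protocol.gate(protocol.split_between[0]),
        protocol.gate(protocol.split_between[1]),
    )
    counts["high_fidelity"] = {
        "n_whole_brain": len(high),
        "n_or_retained": len(high_sel),
        "n_span_retained": sinfo["n_split"],
        "n_split_dropped": sinfo["n_dropped"],
        "n_loop_flagged": sinfo["n_loop_flagged"],
    }
    empty = len(split) == 0
    stats = None
    tfield = tensor_field
    from .space import TensorField as _TF

    if tfield is None and isinstance(field, _TF):
        tfield = field
    if not empty and tfield is not None:
        stats = tract_mean_metrics(split.point_arrays(), tfield, weighting=weighting)
    return SMPipelineResult(
        tract=split, stats=stats, protocol=protocol, counts=counts, empty=empty
    )
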