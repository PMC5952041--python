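"""Tract dimensions and tensor-derived diffusion metrics.

Scalar metrics follow the standard definitions on the sorted eigenvalues
λ1 ≥ λ2 ≥ λ3 of the diffusion tensor:

    MD = (λ1 + λ2 + λ3) / 3            AD = λ1         RD = (λ2 + λ3) / 2
    FA = sqrt(1/2) * sqrt(((λ1-λ2)^2 + (λ2-λ3)^2 + (λ1-λ3)^2)
                          / (λ1^2 + λ2^2 + λ3^2))

Westin shape measures use the λ1-normalized convention, under which they
sum to one pointwise:

    C_L = (λ1 - λ2) / λ1    C_P = (λ2 - λ3) / λ1    C_S = λ3 / λ1

(The trace-normalized variant is available via ``westin_norm="trace"``.)
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .space import AffineGrid, TensorField, eigensystems

METRIC_NAMES = ("fa", "md", "ad", "rd", "cl", "cp", "cs")


@dataclass(frozen=True)
class TractStats:
    """Per-tract summary: dimensions plus mean diffusion metrics."""

    mean_length: float  # mm
    volume: float  # mm^3
    fa: float
    md: float  # mm^2/s
    ad: float
    rd: float
    cl: float
    cp: float
    cs: float
    n_streamlines: int
    weighting: str = "point"

    def as_dict(self) -> dict:
        return asdict(self)


def eigen_metrics(lams: np.ndarray, westin_norm: str = "lambda1") -> dict[str, np.ndarray]:
    """FA/MD/AD/RD and Westin C_L/C_P/C_S from sorted eigenvalue triples.

    Accepts a single triple or an (N, 3) batch; eigenvalues must be sorted
    descending and not all zero.
    """
    lam = np.atleast_2d(np.asarray(lams, dtype=float))
    if lam.shape[-1] != 3:
        raise ValueError("expected eigenvalue triples")
    if np.any(np.diff(lam, axis=-1) > 1e-12):
        raise ValueError("eigenvalues must be sorted descending")
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    sq = l1**2 + l2**2 + l3**2
    if np.any(sq == 0):
        raise ValueError("all-zero eigenvalue triple has undefined metrics")
    md = lam.mean(axis=-1)
    ad = l1
    rd = (l2 + l3) / 2.0
    fa = np.sqrt(0.5 * ((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2) / sq)
    if westin_norm == "lambda1":
        cl = (l1 - l2) / l1
        cp = (l2 - l3) / l1
        cs = l3 / l1
    elif westin_norm == "trace":
        tr = l1 + l2 + l3
        cl = (l1 - l2) / tr
        cp = 2 * (l2 - l3) / tr
        cs = 3 * l3 / tr
    else:
        raise ValueError("westin_norm must be 'lambda1' or 'trace'")
    out = {"fa": fa, "md": md, "ad": ad, "rd": rd, "cl": cl, "cp": cp, "cs": cs}
    if np.asarray(lams).ndim == 1:
        out = {k: float(v[0]) for k, v in out.items()}
    return out


def streamline_length(points: np.ndarray) -> float:
    """Sum of Euclidean segment lengths of a polyline (mm)."""
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or len(p) < 2:
        raise ValueError("streamline needs at least 2 points")
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


def visited_voxels(streamlines, grid: AffineGrid) -> np.ndarray:
    """Unique voxel indices containing at least one streamline point."""
    if not len(streamlines):
        return np.empty((0, 3), dtype=int)
    pts = np.vstack([np.asarray(s) for s in streamlines])
    vox = np.rint(grid.world_to_voxel(pts)).astype(int)
    inside = (vox >= 0).all(axis=1) & (vox < np.asarray(grid.shape)).all(axis=1)
    return np.unique(vox[inside], axis=0)


def tract_volume(streamlines, grid: AffineGrid) -> float:
    """Pass-through volume: unique visited voxels x voxel volume (mm^3)."""
    if not len(streamlines):
        raise ValueError("empty tractogram has no volume")
    voxel_volume = float(np.prod(grid.voxel_size))
    return len(visited_voxels(streamlines, grid)) * voxel_volume


def tract_mean_metrics(
    streamlines,
    field: TensorField,
    weighting: str = "point",
    westin_norm: str = "lambda1",
    max_outside_frac: float = 0.05,
) -> TractStats:
    """Tract-average metrics from the tensor field under the tract.

    ``point`` weighting averages over every streamline vertex; ``voxel``
    weighting averages one sample per unique visited voxel (at its centre).
    """
    streamlines = list(streamlines)
    if not streamlines:
        raise ValueError("empty tractogram")
    if weighting == "point":
        samples = np.vstack([np.asarray(s) for s in streamlines])
    elif weighting == "voxel":
        samples = field.grid.voxel_to_world(visited_voxels(streamlines, field.grid))
    else:
        raise ValueError("weighting must be 'point' or 'voxel'")
    ok = field.support(samples)
    frac_out = 1.0 - ok.mean()
    if frac_out > max_outside_frac:
        bad = np.nonzero(~ok)[0]
        raise ValueError(
            f"{frac_out:.1%} of samples outside tensor support "
            f"(first offenders at rows {bad[:5].tolist()})"
        )
    six = field.interpolate6(samples[ok], check_support=False)
    lam, _ = eigensystems(six)
    lam = np.clip(lam, 0.0, None)
    m = eigen_metrics(lam, westin_norm=westin_norm)
    lengths = [streamline_length(s) for s in streamlines]
    return TractStats(
        mean_length=float(np.mean(lengths)),
        volume=tract_volume(streamlines, field.grid),
        fa=float(np.mean(m["fa"])),
        md=float(np.mean(m["md"])),
        ad=float(np.mean(m["ad"])),
        rd=float(np.mean(m["rd"])),
        cl=float(np.mean(m["cl"])),
        cp=float(np.mean(m["cp"])),
        cs=float(np.mean(m["cs"])),
        n_streamlines=len(streamlines),
        weighting=weighting,
    )
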