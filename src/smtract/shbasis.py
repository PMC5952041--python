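"""Real symmetric (even-order) spherical-harmonic basis and peak machinery.

Fibre orientation distributions (FODs) are antipodally symmetric spherical
functions, so only even harmonic orders carry signal.  The basis used
throughout is the real, orthonormal, even-order basis with coefficients
ordered as (l, m) for l = 0, 2, ..., order and m = -l..l:

    m < 0 :  sqrt(2) * N_l|m| * P_l^|m|(cos theta) * sin(|m| phi)
    m = 0 :  N_l0    * P_l^0 (cos theta)
    m > 0 :  sqrt(2) * N_lm  * P_l^m (cos theta) * cos(m phi)

with N_lm the full orthonormalization constant (Condon-Shortley phase kept,
as in :func:`scipy.special.lpmv`).  The ordering identifier below is written
into every sidecar file; a mismatching identifier is a hard error, because a
silently mismatched basis is the classic failure mode of SH pipelines.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import gammaln, lpmv
from scipy.spatial import cKDTree

#: identifier recorded in file metadata for this basis + ordering
REAL_SYM_BASIS_ID = "real-sym-em-v1"

DEFAULT_N_DIRECTIONS = 724


def n_coeffs(order: int) -> int:
    """Number of coefficients of an even-only basis of maximum order."""
    if order < 0 or order % 2:
        raise ValueError(f"SH order must be even and non-negative, got {order}")
    return (order + 1) * (order + 2) // 2


def order_from_ncoeffs(nc: int) -> int:
    order = int(np.rint((np.sqrt(8 * nc + 1) - 3) / 2))
    if n_coeffs(order) != nc:
        raise ValueError(f"{nc} is not a valid even-order SH coefficient count")
    return order


def lm_arrays(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Degree and order index arrays, matching the coefficient ordering."""
    ls, ms = [], []
    for l in range(0, order + 1, 2):
        for m in range(-l, l + 1):
            ls.append(l)
            ms.append(m)
    return np.asarray(ls), np.asarray(ms)


@lru_cache(maxsize=8)
def _basis_tables(order: int):
    """Cached (l, m, |m|, normalization) arrays for one order."""
    ls, ms = lm_arrays(order)
    am = np.abs(ms)
    norm = np.sqrt(
        (2 * ls + 1)
        / (4 * np.pi)
        * np.exp(gammaln(ls - am + 1) - gammaln(ls + am + 1))
    )
    pos, neg = ms > 0, ms < 0
    return ls, ms, am, norm, pos, neg


def sh_basis(dirs: np.ndarray, order: int) -> np.ndarray:
    """Evaluate the real even-order basis at unit direction(s).

    Parameters
    ----------
    dirs : (..., 3) array of unit vectors.
    order : maximum (even) harmonic order.

    Returns
    -------
    (..., n_coeffs) design matrix B with amplitude(d) = B @ coeffs.
    """
    arr = np.asarray(dirs, dtype=float)
    d = np.atleast_2d(arr)
    ls, ms, am, norm, pos, neg = _basis_tables(order)
    z = np.clip(d[..., 2], -1.0, 1.0)
    phi = np.arctan2(d[..., 1], d[..., 0])
    # associated Legendre, broadcast over (coeff, point)
    P = lpmv(am[:, None], ls[:, None], z[None, :])
    B = norm[:, None] * P
    B[pos] *= np.sqrt(2.0) * np.cos(ms[pos, None] * phi[None, :])
    B[neg] *= np.sqrt(2.0) * np.sin(am[neg, None] * phi[None, :])
    out = B.T
    if arr.ndim == 1:
        return out[0]
    return out


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """n roughly uniform unit vectors on the upper hemisphere (z >= 0)."""
    i = np.arange(n) + 0.5
    z = i / n  # (0, 1)
    phi = np.pi * (1 + np.sqrt(5.0)) * i
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def symmetric_sphere(n_total: int = DEFAULT_N_DIRECTIONS) -> np.ndarray:
    """Antipodally symmetric direction sample (default 724 = 2 x 362)."""
    if n_total % 2:
        raise ValueError("antipodally symmetric set needs an even count")
    half = fibonacci_hemisphere(n_total // 2)
    return np.vstack([half, -half])


def sphere_neighbors(dirs: np.ndarray, k: int = 6) -> np.ndarray:
    """Index array (n, k) of each direction's k nearest angular neighbours."""
    tree = cKDTree(dirs)
    _, idx = tree.query(dirs, k=k + 1)
    return idx[:, 1:]


class SphereSampler:
    """Precomputed direction set + basis matrix for fast peak extraction."""

    def __init__(self, order: int, n_directions: int = DEFAULT_N_DIRECTIONS):
        self.order = order
        self.dirs = symmetric_sphere(n_directions)
        self.B = sh_basis(self.dirs, order)  # (n, C)
        self.neighbors = sphere_neighbors(self.dirs)
        # mean nearest-neighbour spacing, used to cap refinement steps
        cosang = np.einsum("ij,ij->i", self.dirs, self.dirs[self.neighbors[:, 0]])
        self.spacing_rad = float(np.mean(np.arccos(np.clip(cosang, -1, 1))))

    def amplitudes(self, coeffs: np.ndarray) -> np.ndarray:
        return self.B @ coeffs

    def local_maxima(self, amps: np.ndarray, floor: float) -> np.ndarray:
        """Indices of strict-or-tied local maxima with amplitude >= floor."""
        is_max = amps >= amps[self.neighbors].max(axis=1)
        return np.nonzero(is_max & (amps >= floor))[0]


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


def _tangent_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = _cross3(d, a)
    u /= np.linalg.norm(u)
    return u, _cross3(d, u)


def refine_peak(
    coeffs: np.ndarray,
    d0: np.ndarray,
    order: int,
    step_rad: float = 0.035,
    iters: int = 2,
    max_total_rad: float = 0.12,
) -> tuple[np.ndarray, float]:
    """Hill-climb a coarse peak direction on the continuous sphere.

    Each iteration fits a quadratic to amplitudes at the current direction
    and four tangent-plane offsets, and moves to its stationary point
    (clamped).  Returns the refined unit direction and its amplitude.
    """
    d = np.asarray(d0, dtype=float)
    d = d / np.linalg.norm(d)
    best_d, best_amp = d, -np.inf
    total = 0.0
    for _ in range(iters):
        u, v = _tangent_frame(d)
        h = step_rad
        probes = np.stack([d, d + h * u, d - h * u, d + h * v, d - h * v])
        probes /= np.linalg.norm(probes, axis=1, keepdims=True)
        a = sh_basis(probes, order) @ coeffs
        i = int(np.argmax(a))
        if a[i] > best_amp:
            best_d, best_amp = probes[i], float(a[i])
        # central differences on the tangent plane
        gu = (a[1] - a[2]) / (2 * h)
        gv = (a[3] - a[4]) / (2 * h)
        huu = (a[1] - 2 * a[0] + a[2]) / h**2
        hvv = (a[3] - 2 * a[0] + a[4]) / h**2
        du = dv = 0.0
        if huu < 0 and hvv < 0:
            du, dv = -gu / huu, -gv / hvv
        else:  # fall back to a fixed-size ascent step
            g = np.hypot(gu, gv)
            if g > 0:
                du, dv = step_rad * gu / g, step_rad * gv / g
        move = np.hypot(du, dv)
        cap = min(2 * step_rad, max_total_rad - total)
        if move > cap or cap <= 0:
            if cap <= 0:
                break
            du, dv = du * cap / move, dv * cap / move
            move = cap
        d = d + du * u + dv * v
        d /= np.linalg.norm(d)
        total += move
    amp = float(sh_basis(d, order) @ coeffs)
    if amp > best_amp:
        best_d, best_amp = d, amp
    return best_d, best_amp


def axial_kernel_legendre(order: int, kappa: float = 15.0) -> np.ndarray:
    """Legendre coefficients a_l (even l) of the single-fibre kernel.

    The kernel is the antipodally symmetric profile exp(-kappa*(1-t^2)) of
    the angle cosine t to the fibre axis; a_l = (2l+1)/2 * int A(t) P_l(t) dt
    by Gauss-Legendre quadrature.  Returned for l = 0, 2, ..., order.
    """
    t, w = np.polynomial.legendre.leggauss(64)
    A = np.exp(-kappa * (1 - t**2))
    out = []
    for l in range(0, order + 1, 2):
        P = np.polynomial.legendre.Legendre.basis(l)(t)
        out.append((2 * l + 1) / 2.0 * np.sum(w * A * P))
    return np.asarray(out)


def single_peak_coeffs(
    peak_dirs: np.ndarray, order: int, kappa: float = 15.0
) -> np.ndarray:
    """SH coefficients of a unit-peak-amplitude single-fibre FOD.

    By the addition theorem, an axially symmetric function sum_l a_l P_l(u.d)
    has real-basis coefficients c_lm(u) = a_l * 4*pi/(2l+1) * Y_lm(u).
    Coefficients are scaled so the amplitude at the peak direction is 1.0
    (the tracking threshold of 0.1 then has a meaningful scale).
    """
    a_l = axial_kernel_legendre(order, kappa)
    peak_amp = a_l.sum()  # P_l(1) = 1
    ls, _ = lm_arrays(order)
    per_coeff = (a_l / peak_amp)[(ls // 2)] * 4 * np.pi / (2 * ls + 1)
    Y = sh_basis(peak_dirs, order)
    return per_coeff * Y


def isotropic_coeffs(amplitude: float, order: int) -> np.ndarray:
    """Coefficients of a constant spherical function of given amplitude."""
    c = np.zeros(n_coeffs(order))
    c[0] = amplitude * np.sqrt(4 * np.pi)  # Y00 = 1/sqrt(4 pi)
    return c
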