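"""Spherical geometry, quadrature, harmonics and orientation distributions.

Internal numerical toolbox shared by the signal simulators and the
model fitters.  Conventions:

* directions are unit 3-vectors in image space (x, y, z),
* spherical harmonics are the real, even-order basis customary in
  diffusion MRI (Descoteaux ordering: for each even l, m = -l..l),
* orientation distribution functions (ODFs) are densities on the full
  sphere normalised so that their integral over S^2 equals 1.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import eval_legendre, hyp1f1, sph_harm_y

__all__ = [
    "fibonacci_sphere",
    "fibonacci_hemisphere",
    "sphere_quadrature",
    "sh_degrees",
    "n_sh_coeffs",
    "real_sh_basis",
    "watson_density",
    "watson_normalization",
    "bingham_density",
    "bingham_normalization",
    "bingham_normalization_series",
    "rotation_to",
]


def fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform deterministic point set on the full sphere, shape (n, 3)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """n near-uniform directions with non-negative z (antipodally unique)."""
    pts = fibonacci_sphere(2 * n)
    pts = pts[pts[:, 2] >= 0]
    if len(pts) > n:
        pts = pts[:n]
    elif len(pts) < n:  # pragma: no cover - parity fallback
        extra = fibonacci_sphere(2 * n + 1)
        extra = extra[extra[:, 2] >= 0]
        pts = extra[:n]
    return pts


def rotation_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping the +z axis onto ``axis`` (unit vector)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(np.dot(z, axis))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


@lru_cache(maxsize=16)
def _gl_grid(n_theta: int, n_phi: int):
    x, w = np.polynomial.legendre.leggauss(n_theta)  # x = cos(theta)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    ct = np.repeat(x, n_phi)
    st = np.sqrt(1.0 - ct**2)
    cp = np.tile(np.cos(phi), n_theta)
    sp_ = np.tile(np.sin(phi), n_theta)
    pts = np.column_stack([st * cp, st * sp_, ct])
    wts = np.repeat(w, n_phi) * (2.0 * np.pi / n_phi)
    return pts, wts


def sphere_quadrature(n_theta: int = 60, n_phi: int = 60, pole: np.ndarray | None = None):
    """Product Gauss-Legendre x trapezoid quadrature over S^2.

    Returns (points (N,3), weights (N,)); the weights sum to 4*pi.  When
    ``pole`` is given the grid is rotated so the dense polar clustering
    sits on that axis, which keeps sharply concentrated ODFs resolved.
    """
    pts, wts = _gl_grid(int(n_theta), int(n_phi))
    if pole is not None:
        pts = pts @ rotation_to(pole).T
    return pts, wts


def sh_degrees(lmax: int) -> np.ndarray:
    """Per-coefficient degree l for the even real SH basis up to lmax."""
    out = []
    for l in range(0, lmax + 1, 2):
        out.extend([l] * (2 * l + 1))
    return np.array(out)


def n_sh_coeffs(lmax: int) -> int:
    return (lmax + 1) * (lmax + 2) // 2


def real_sh_basis(points: np.ndarray, lmax: int) -> np.ndarray:
    """Real even-order SH design matrix, shape (n_points, n_sh_coeffs(lmax)).

    Column ordering is (l, m) with l = 0, 2, ..., lmax and m = -l..l.
    Orthonormal on the sphere: sum_i w_i Y_a(x_i) Y_b(x_i) = delta_ab for
    an exact quadrature.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    norms = np.linalg.norm(points, axis=1, keepdims=True)
    points = points / np.where(norms > 0, norms, 1.0)
    theta = np.arccos(np.clip(points[:, 2], -1.0, 1.0))
    phi = np.arctan2(points[:, 1], points[:, 0])
    cols = []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * y.imag)
            elif m == 0:
                cols.append(y.real)
            else:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * y.real)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Orientation distributions
# ---------------------------------------------------------------------------

def watson_normalization(kappa: float) -> float:
    """Integral of exp(kappa * (mu.n)^2) over the sphere: 4*pi*M(1/2,3/2,kappa)."""
    if kappa < 0:
        raise ValueError("Watson concentration must be non-negative")
    return 4.0 * np.pi * float(hyp1f1(0.5, 1.5, kappa))


def watson_density(points: np.ndarray, mu: np.ndarray, kappa: float) -> np.ndarray:
    """Watson ODF values at ``points`` (antipodally symmetric, integral 1)."""
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    c2 = (np.atleast_2d(points) @ mu) ** 2
    # exponent shifted by kappa for overflow safety; the shift cancels in
    # the normalisation M(1/2,3/2,kappa)*exp(-kappa) = M(1,3/2,-kappa) route
    return np.exp(kappa * (c2 - 1.0)) / (watson_normalization(kappa) * np.exp(-kappa))


def bingham_normalization_series(kappa1: float, kappa2: float, nmax: int = 400, tol: float = 1e-14) -> float:
    """Sphere integral of exp(k1 x^2 + k2 y^2) by the Dirichlet-moment series.

    On the uniform sphere (x^2, y^2, z^2) ~ Dirichlet(1/2,1/2,1/2), so the
    integral equals 4*pi * sum_{i,j} (1/2)_i (1/2)_j / ((3/2)_{i+j} i! j!)
    k1^i k2^j.  Entire series; used as the independent oracle for moderate
    concentrations.
    """
    total = 0.0
    for i in range(nmax):
        # term_i0 = (1/2)_i k1^i / ((3/2)_i i!)
        ti = 1.0
        for a in range(i):
            ti *= (0.5 + a) * kappa1 / ((1.5 + a) * (a + 1))
        row = 0.0
        tij = ti
        for j in range(nmax):
            if j > 0:
                tij *= (0.5 + j - 1) * kappa2 * 1.0 / ((1.5 + i + j - 1) * j)
            row += tij
            if j > 2 and abs(tij) < tol * max(abs(row), 1.0):
                break
        total += row
        if i > 2 and abs(ti) < tol * max(abs(total), 1.0):
            break
    return 4.0 * np.pi * total


@lru_cache(maxsize=256)
def bingham_normalization(kappa1: float, kappa2: float) -> float:
    """Sphere integral of exp(-k1 (e1.n)^2 - k2 (e2.n)^2), by dense quadrature.

    This is the Bingham-NODDI convention: the two concentration
    parameters suppress probability along the two axes perpendicular to
    the fiber orientation, so kappa1 = kappa2 = kappa recovers the
    Watson distribution with concentration kappa about the fiber axis.
    """
    if kappa2 > kappa1 or kappa2 < 0:
        raise ValueError("require kappa1 >= kappa2 >= 0")
    pts, wts = sphere_quadrature(128, 128)
    # canonical perpendicular axes: e1 = x, e2 = y (fiber along z)
    expo = -kappa1 * pts[:, 0] ** 2 - kappa2 * pts[:, 1] ** 2
    return float(np.sum(wts * np.exp(expo)))


def bingham_density(points: np.ndarray, axes: np.ndarray, kappa1: float, kappa2: float) -> np.ndarray:
    """Bingham ODF values at ``points`` (antipodally symmetric, integral 1).

    ``axes`` is a 3x3 orthonormal frame whose column 0 is the fiber
    orientation; columns 1 and 2 carry the suppression exponents kappa1
    and kappa2 (kappa1 >= kappa2 >= 0, so dispersion fans preferentially
    toward column 2).
    """
    axes = np.asarray(axes, dtype=float)
    pts = np.atleast_2d(points)
    c1 = (pts @ axes[:, 1]) ** 2
    c2 = (pts @ axes[:, 2]) ** 2
    norm = bingham_normalization(float(kappa1), float(kappa2))
    return np.exp(-kappa1 * c1 - kappa2 * c2) / norm


def frame_from(mu: np.ndarray, psi: float = 0.0) -> np.ndarray:
    """Orthonormal frame with first column ``mu``; ``psi`` rotates the
    secondary axis within the plane orthogonal to mu."""
    R = rotation_to(mu)
    e2 = R @ np.array([np.cos(psi), np.sin(psi), 0.0])
    mu = np.asarray(mu, float) / np.linalg.norm(mu)
    e3 = np.cross(mu, e2)
    return np.column_stack([mu, e2, e3])
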