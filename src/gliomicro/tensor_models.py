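"""Diffusion tensor and kurtosis tensor fitting; FA/MD/AD/RD, AK/MK/RK, AWF.

Both fits are weighted linear least squares on log-signals with weights
taken as the squared predicted signals from an ordinary least-squares
pre-pass (the standard two-step WLLS that removes the log-transform bias
gradient).  The kurtosis signal model is, per direction g,

    ln S(b)/S(0) = -b D_app(g) + (1/6) b^2 D_app(g)^2 K_app(g)

with D_app the quadratic form of the rank-2 tensor D and
D_app^2 K_app the quartic form of a rank-4 tensor V; the stored
dimensionless kurtosis tensor is W = V / MD^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._sphere import fibonacci_sphere, rotation_to
from .protocol_io import GradientScheme

__all__ = [
    "TensorFit", "KurtosisFit",
    "fit_dti", "dti_metrics", "fit_dki", "dki_metrics", "awf_from_kurtosis",
    "DTIEstimator", "DKIEstimator",
]

# index pairs for the 6 unique elements of D (xx, yy, zz, xy, xz, yz)
_D_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
_D_MULT = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])

# index quadruples for the 15 unique elements of a fully symmetric rank-4
# tensor, with multinomial multiplicities
_W_IDX = [
    (0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 2, 2),
    (0, 0, 0, 1), (0, 0, 0, 2), (0, 1, 1, 1), (1, 1, 1, 2), (0, 2, 2, 2), (1, 2, 2, 2),
    (0, 0, 1, 1), (0, 0, 2, 2), (1, 1, 2, 2),
    (0, 0, 1, 2), (0, 1, 1, 2), (0, 1, 2, 2),
]
_W_MULT = np.array([1, 1, 1, 4, 4, 4, 4, 4, 4, 6, 6, 6, 12, 12, 12], dtype=float)

#: soft bounds on directional kurtosis (clip + flag, not a constrained solver)
K_APP_MIN = -3.0 / 7.0
K_APP_MAX = 10.0


def _design_d(scheme: GradientScheme) -> np.ndarray:
    g = scheme.bvecs
    cols = [g[:, i] * g[:, j] for (i, j) in _D_IDX]
    return np.column_stack(cols) * _D_MULT


def _design_w(scheme: GradientScheme) -> np.ndarray:
    g = scheme.bvecs
    cols = [g[:, i] * g[:, j] * g[:, k] * g[:, l] for (i, j, k, l) in _W_IDX]
    return np.column_stack(cols) * _W_MULT


def _to_matrix(d6: np.ndarray) -> np.ndarray:
    out = np.zeros(d6.shape[:-1] + (3, 3))
    for n, (i, j) in enumerate(_D_IDX):
        out[..., i, j] = d6[..., n]
        out[..., j, i] = d6[..., n]
    return out


def quadratic_form(d6: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """D_app along each direction; d6 (..., 6), dirs (M, 3) -> (..., M)."""
    design = np.column_stack([dirs[:, i] * dirs[:, j] for (i, j) in _D_IDX]) * _D_MULT
    return d6 @ design.T


def quartic_form(w15: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    design = np.column_stack(
        [dirs[:, i] * dirs[:, j] * dirs[:, k] * dirs[:, l] for (i, j, k, l) in _W_IDX]
    ) * _W_MULT
    return w15 @ design.T


@dataclass
class TensorFit:
    D: np.ndarray          # (..., 6) unique elements, um^2/ms
    eigenvalues: np.ndarray  # (..., 3) descending
    eigenvectors: np.ndarray  # (..., 3, 3), columns match eigenvalues
    lnS0: np.ndarray
    n_clamped: int = 0

    @property
    def tensor(self) -> np.ndarray:
        return _to_matrix(self.D)


@dataclass
class KurtosisFit:
    D: np.ndarray           # (..., 6)
    W: np.ndarray           # (..., 15), dimensionless (V / MD^2)
    lnS0: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_clamped: int = 0
    degenerate: np.ndarray | None = None  # lambda1 ~ lambda2 tie flags

    @property
    def md(self) -> np.ndarray:
        return self.D[..., :3].mean(axis=-1)

    def k_app(self, dirs: np.ndarray, clip: bool = True) -> np.ndarray:
        """Directional kurtosis K_app(g) = V_app / D_app^2."""
        d_app = quadratic_form(self.D, dirs)
        v_app = quartic_form(self.W, dirs) * (self.md[..., None] ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            k = np.where(d_app > 1e-12, v_app / np.maximum(d_app, 1e-12) ** 2, 0.0)
        return np.clip(k, K_APP_MIN, K_APP_MAX) if clip else k


def _wlls(design: np.ndarray, logs: np.ndarray) -> np.ndarray:
    """Two-step WLLS; logs shape (..., N), returns (..., P)."""
    beta_ols = np.linalg.lstsq(design, logs.reshape(-1, logs.shape[-1]).T, rcond=None)[0].T
    w = np.exp(design @ beta_ols.T).T ** 2  # squared predicted signals, (V, N)
    out = np.empty_like(beta_ols)
    for v in range(beta_ols.shape[0]):
        aw = design * w[v][:, None]
        out[v] = np.linalg.solve(design.T @ aw, aw.T @ logs.reshape(-1, logs.shape[-1])[v])
    return out.reshape(logs.shape[:-1] + (design.shape[1],))


def _prep_signals(signals: np.ndarray, n_meas: int):
    sig = np.asarray(signals, dtype=float)
    flat = np.atleast_2d(sig.reshape(-1, n_meas))
    n_clamped = int(np.sum(flat <= 0))
    floor = max(flat.max() * 1e-8, 1e-12)
    return np.maximum(flat, floor), n_clamped, sig.shape[:-1]


def fit_dti(signals: np.ndarray, scheme: GradientScheme, b_max: float = 1.3) -> TensorFit:
    """WLLS diffusion-tensor fit on the b=0 and low-b (<= b_max ms/um^2) data."""
    mask = scheme.bvals <= b_max
    sub_b = scheme.bvals[mask]
    if np.all(sub_b == 0):
        raise ValueError("cannot fit a tensor from b=0 data only")
    if mask.sum() < 7:
        raise ValueError(f"need >= 7 usable measurements, got {int(mask.sum())}")
    flat, n_clamped, shape = _prep_signals(np.asarray(signals)[..., mask], int(mask.sum()))
    g = scheme.bvecs[mask]
    design = np.column_stack([np.ones(mask.sum()),
                              -sub_b[:, None] * (np.column_stack(
                                  [g[:, i] * g[:, j] for (i, j) in _D_IDX]) * _D_MULT)])
    beta = _wlls(design, np.log(flat))
    d6 = beta[..., 1:]
    evals, evecs = np.linalg.eigh(_to_matrix(d6))
    order = np.argsort(evals, axis=-1)[..., ::-1]
    evals = np.take_along_axis(evals, order, axis=-1)
    evecs = np.take_along_axis(evecs, order[..., None, :], axis=-1)
    return TensorFit(D=d6.reshape(shape + (6,)), eigenvalues=evals.reshape(shape + (3,)),
                     eigenvectors=evecs.reshape(shape + (3, 3)),
                     lnS0=beta[..., 0].reshape(shape), n_clamped=n_clamped)


def dti_metrics(fit: TensorFit) -> dict:
    """FA, MD, AD, RD from sorted eigenvalues (FA := 0 for a null tensor)."""
    l1, l2, l3 = (fit.eigenvalues[..., i] for i in range(3))
    denom = l1**2 + l2**2 + l3**2
    num = (l1 - l2) ** 2 + (l1 - l3) ** 2 + (l2 - l3) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.where(denom > 0, np.sqrt(np.maximum(num, 0) / np.maximum(2 * denom, 1e-300)), 0.0)
    return {"FA": np.clip(fa, 0.0, 1.0), "MD": (l1 + l2 + l3) / 3.0,
            "AD": l1, "RD": (l2 + l3) / 2.0}


def fit_dki(signals: np.ndarray, scheme: GradientScheme) -> KurtosisFit:
    """WLLS fit of the 22-parameter log-quadratic kurtosis model."""
    if len(scheme.nonzero_shells) < 2:
        raise ValueError("kurtosis fit needs at least two nonzero shells")
    if len(scheme) < 22:
        raise ValueError("kurtosis fit needs at least 22 measurements")
    flat, n_clamped, shape = _prep_signals(signals, len(scheme))
    b = scheme.bvals
    design = np.column_stack([np.ones(len(scheme)),
                              -b[:, None] * _design_d(scheme),
                              (b[:, None] ** 2 / 6.0) * _design_w(scheme)])
    beta = _wlls(design, np.log(flat))
    d6 = beta[..., 1:7]
    v15 = beta[..., 7:]
    md = d6[..., :3].mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        w15 = v15 / np.maximum(md[..., None] ** 2, 1e-300)
    evals, evecs = np.linalg.eigh(_to_matrix(d6))
    order = np.argsort(evals, axis=-1)[..., ::-1]
    evals = np.take_along_axis(evals, order, axis=-1)
    evecs = np.take_along_axis(evecs, order[..., None, :], axis=-1)
    degen = (evals[..., 0] - evals[..., 1]) < 1e-6 * np.maximum(np.abs(evals[..., 0]), 1e-12)
    return KurtosisFit(D=d6.reshape(shape + (6,)), W=w15.reshape(shape + (15,)),
                       lnS0=beta[..., 0].reshape(shape),
                       eigenvalues=evals.reshape(shape + (3,)),
                       eigenvectors=evecs.reshape(shape + (3, 3)),
                       n_clamped=n_clamped, degenerate=degen.reshape(shape))


def dki_metrics(fit: KurtosisFit, n_dirs: int = 250, n_radial: int = 64) -> dict:
    """AK/MK/RK from directional kurtosis.

    MK averages K_app over a dense uniform direction set; AK evaluates it
    along the principal eigenvector; RK averages over directions in the
    plane perpendicular to it.  For a degenerate tensor (lambda1 ~
    lambda2) the principal direction falls back to the fixed
    eigendecomposition ordering and the voxel is flagged.
    """
    if n_dirs < 100:
        raise ValueError("n_dirs must be >= 100 for a stable spherical mean")
    dirs = fibonacci_sphere(n_dirs)
    mk = fit.k_app(dirs).mean(axis=-1)

    e1 = fit.eigenvectors[..., :, 0]
    flat_e1 = e1.reshape(-1, 3)
    flat_d = fit.D.reshape(-1, 6)
    flat_w = fit.W.reshape(-1, 15)
    md = flat_d[:, :3].mean(axis=-1)
    ak = np.empty(len(flat_e1))
    rk = np.empty(len(flat_e1))
    ang = 2 * np.pi * np.arange(n_radial) / n_radial
    circle = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(n_radial)])
    for v in range(len(flat_e1)):
        sub = KurtosisFit(D=flat_d[v], W=flat_w[v], lnS0=np.zeros(()),
                          eigenvalues=np.zeros(3), eigenvectors=np.eye(3))
        ak[v] = sub.k_app(flat_e1[v][None, :])[0]
        perp = circle @ rotation_to(flat_e1[v]).T
        rk[v] = sub.k_app(perp).mean()
    shape = fit.D.shape[:-1]
    return {"MK": mk.reshape(shape), "AK": ak.reshape(shape), "RK": rk.reshape(shape)}


def awf_from_kurtosis(fit: KurtosisFit, n_dirs: int = 724) -> np.ndarray:
    """WMTI axonal water fraction: AWF = K_max / (K_max + 3).

    K_max is the maximum directional kurtosis over a dense uniform
    direction set; negative maxima clamp AWF to 0 (flag via return of the
    exact zero).
    """
    dirs = fibonacci_sphere(n_dirs)
    k_max = fit.k_app(dirs).max(axis=-1)
    k_max = np.maximum(k_max, 0.0)
    return k_max / (k_max + 3.0)


# ---------------------------------------------------------------------------
# Estimator-style wrappers
# ---------------------------------------------------------------------------

class _VoxelEstimator:
    """Minimal sklearn-style surface for voxel-batch model fits:
    ``fit(X)`` on an (n_voxels, n_measurements) array, fitted attributes
    with trailing underscores, ``get_params``/``set_params``."""

    _param_names: tuple = ()

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self


class DTIEstimator(_VoxelEstimator):
    """Diffusion-tensor model over a voxel batch."""

    _param_names = ("scheme", "b_max")

    def __init__(self, scheme: GradientScheme, b_max: float = 1.3):
        self.scheme = scheme
        self.b_max = b_max

    def fit(self, X: np.ndarray, y=None) -> "DTIEstimator":
        self.fit_ = fit_dti(X, self.scheme, b_max=self.b_max)
        self.maps_ = dti_metrics(self.fit_)
        return self

    def transform(self, X=None) -> np.ndarray:
        return np.column_stack([self.maps_[k] for k in ("FA", "MD", "AD", "RD")])


class DKIEstimator(_VoxelEstimator):
    """Diffusion-kurtosis model (plus WMTI axonal water fraction)."""

    _param_names = ("scheme", "n_dirs")

    def __init__(self, scheme: GradientScheme, n_dirs: int = 250):
        self.scheme = scheme
        self.n_dirs = n_dirs

    def fit(self, X: np.ndarray, y=None) -> "DKIEstimator":
        self.fit_ = fit_dki(X, self.scheme)
        self.maps_ = dki_metrics(self.fit_, n_dirs=self.n_dirs)
        self.maps_["AWF"] = awf_from_kurtosis(self.fit_)
        return self

    def transform(self, X=None) -> np.ndarray:
        return np.column_stack([self.maps_[k] for k in ("AK", "MK", "RK", "AWF")])
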