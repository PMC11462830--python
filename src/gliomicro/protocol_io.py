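"""Acquisition scheme, image / gradient-table / ROI / clinical-table I/O.

All coordinate and format conventions of the package live here:

* b-values are stored internally in ms/um^2 (1000 s/mm^2 = 1 ms/um^2);
  the unit conversion from the scanner-side s/mm^2 happens in exactly one
  function, :func:`bval_si_to_internal`.
* Diffusivities elsewhere in the package are in um^2/ms so that b*D is
  dimensionless and O(1).
* Gradient directions use the FSL image-space dialect (3-row ``bvec``
  text files); no reorientation is applied — phantoms are generated in
  the same frame.
* Masks are 0-based label images on the NIfTI voxel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from ._sphere import fibonacci_hemisphere

__all__ = [
    "GradientScheme",
    "DWIDataset",
    "ROISet",
    "ClinicalTable",
    "build_scheme",
    "paper_scheme",
    "load_dwi",
    "save_dwi",
    "place_circular_rois",
    "bval_si_to_internal",
]

#: clinical-table columns expected by the cohort statistics stage
CLINICAL_COLUMNS = [
    "patient_id", "group", "age", "gender", "midline_invasion",
    "lesion_location", "lesion_size", "lesion_margin",
    "histological_class", "who_grade", "therapy",
]


def bval_si_to_internal(bvals_si) -> np.ndarray:
    """Convert b-values from s/mm^2 to the internal ms/um^2 unit.

    This is the only place in the package where the factor 1000 appears.
    """
    return np.asarray(bvals_si, dtype=float) / 1000.0


@dataclass(frozen=True)
class GradientScheme:
    """Multi-shell gradient table.

    Attributes
    ----------
    bvals : (N,) float, ms/um^2
    bvecs : (N, 3) float, unit vectors for nonzero shells (zero rows on b0)
    shell_id : (N,) int, index into ``shell_bvals``
    shell_bvals : (S,) float, shell centroid b-values, ascending
    beta : (N,) float, b-tensor shape; 1.0 for linear tensor encoding
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    shell_id: np.ndarray
    shell_bvals: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        nz = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("non-unit bvec on a diffusion-weighted measurement")

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.shell_bvals[self.shell_id] == 0

    def shell_mask(self, b: float, tol: float = 1e-9) -> np.ndarray:
        return np.abs(self.shell_bvals[self.shell_id] - b) <= tol

    @property
    def nonzero_shells(self) -> np.ndarray:
        return self.shell_bvals[self.shell_bvals > 0]

    def subset(self, mask: np.ndarray) -> "GradientScheme":
        bv = self.bvals[mask]
        return build_scheme(bv * 1000.0, self.bvecs[mask], shell_tolerance=1.0)


def build_scheme(bvals_si, bvecs, shell_tolerance: float = 50.0, beta=None) -> GradientScheme:
    """Assemble a :class:`GradientScheme` from scanner-unit inputs.

    Parameters
    ----------
    bvals_si : (N,) b-values in s/mm^2.
    bvecs : (N, 3) gradient directions (renormalised; arbitrary scale on b0).
    shell_tolerance : clustering tolerance in s/mm^2 for shell grouping.
    beta : optional per-measurement b-tensor shape (default 1.0, LTE).
    """
    bvals_si = np.asarray(bvals_si, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    if bvecs.ndim != 2 or bvecs.shape[1] != 3 or len(bvals_si) != len(bvecs):
        raise ValueError("bvals and bvecs must have matching lengths (N and Nx3)")
    if np.any(bvals_si < 0):
        raise ValueError("negative b-value")
    norms = np.linalg.norm(bvecs, axis=1)
    nz = bvals_si > 0
    if np.any(norms[nz] == 0):
        raise ValueError("zero-norm bvec on a nonzero-b measurement")
    unit = np.zeros_like(bvecs)
    good = norms > 0
    unit[good] = bvecs[good] / norms[good, None]

    # greedy centroid clustering of b-values within tolerance
    order = np.argsort(bvals_si)
    centroids: list[list[float]] = []
    assign = np.zeros(len(bvals_si), dtype=int)
    for idx in order:
        b = bvals_si[idx]
        if centroids and b - np.mean(centroids[-1]) <= shell_tolerance:
            centroids[-1].append(b)
            assign[idx] = len(centroids) - 1
        else:
            centroids.append([b])
            assign[idx] = len(centroids) - 1
    shell_bvals_si = np.array([np.mean(c) for c in centroids])
    # b0 shell snaps to exactly zero when it contains only zeros
    shell_bvals_si[np.isclose(shell_bvals_si, 0.0)] = 0.0
    beta = np.ones(len(bvals_si)) if beta is None else np.asarray(beta, dtype=float)
    return GradientScheme(
        bvals=bval_si_to_internal(bvals_si),
        bvecs=unit,
        shell_id=assign,
        shell_bvals=bval_si_to_internal(shell_bvals_si),
        beta=beta,
    )


def paper_scheme(n_dirs: int = 25, bvals_si=(1250.0, 2500.0), n_b0: int = 1) -> GradientScheme:
    """The acquisition protocol used throughout: b = 0, 1250, 2500 s/mm^2
    with 25 uniformly distributed directions per nonzero shell."""
    dirs = fibonacci_hemisphere(n_dirs)
    bv = [0.0] * n_b0 + [b for b in bvals_si for _ in range(n_dirs)]
    vecs = np.vstack([np.zeros((n_b0, 3))] + [dirs for _ in bvals_si])
    return build_scheme(np.array(bv), vecs)


@dataclass
class DWIDataset:
    """A 4D diffusion-weighted volume with its gradient scheme."""

    signal: np.ndarray  # (X, Y, Z, N), float, >= 0
    scheme: GradientScheme
    voxel_size: tuple = (1.875, 1.875, 3.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4 or self.signal.shape[3] != len(self.scheme):
            raise ValueError(
                f"signal 4th dimension ({self.signal.shape[-1] if self.signal.ndim == 4 else 'n/a'}) "
                f"must equal scheme length ({len(self.scheme)})"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")


def load_dwi(image_path, bval_path, bvec_path, shell_tolerance: float = 50.0) -> DWIDataset:
    """Read a NIfTI volume plus FSL-dialect bval/bvec text files."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # FSL writes 3 rows x N columns
    scheme = build_scheme(bvals, bvecs, shell_tolerance=shell_tolerance)
    if data.ndim != 4 or data.shape[3] != len(scheme):
        raise ValueError("image and gradient table lengths differ")
    zooms = img.header.get_zooms()[:3]
    return DWIDataset(signal=data, scheme=scheme, voxel_size=tuple(float(z) for z in zooms),
                      affine=np.asarray(img.affine))


def save_dwi(dataset: DWIDataset, image_path, bval_path, bvec_path) -> None:
    """Write NIfTI + FSL bval/bvec (b-values back in s/mm^2, 3-row bvecs)."""
    affine = dataset.affine.copy()
    img = nib.Nifti1Image(dataset.signal.astype(np.float32), affine)
    img.header.set_zooms(tuple(dataset.voxel_size) + (1.0,))
    nib.save(img, str(image_path))
    np.savetxt(bval_path, (dataset.scheme.bvals * 1000.0)[None, :], fmt="%.6g")
    np.savetxt(bvec_path, dataset.scheme.bvecs.T, fmt="%.9f")


def save_mask(mask: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


@dataclass
class ROISet:
    """Tumor ROIs plus the contralateral white-matter reference ROI."""

    tumor_rois: list  # list of boolean arrays, one per ROI
    reference_roi: np.ndarray | None = None
    diameter_mm: float = 6.0

    def __post_init__(self):
        for i, roi in enumerate(self.tumor_rois):
            if not np.any(roi):
                raise ValueError(f"tumor ROI {i} is empty")
            if self.reference_roi is not None and np.any(roi & self.reference_roi):
                raise ValueError(f"tumor ROI {i} overlaps the reference ROI")

    @property
    def union(self) -> np.ndarray:
        out = np.zeros_like(self.tumor_rois[0], dtype=bool)
        for roi in self.tumor_rois:
            out |= roi
        return out


def place_circular_rois(mask_shape, centers, diameter_mm: float = 6.0,
                        voxel_size=(1.875, 1.875, 3.0),
                        reference_center=None) -> ROISet:
    """In-plane circular ROIs of a given physical diameter.

    Each center is a 0-based (i, j, k) voxel index; the ROI is the set of
    voxels in slice k whose in-plane center distance to the ROI center is
    at most diameter/2 (always at least the center voxel itself).
    """
    mask_shape = tuple(mask_shape)
    radius = diameter_mm / 2.0

    def _disc(center):
        i0, j0, k0 = center
        if not (0 <= i0 < mask_shape[0] and 0 <= j0 < mask_shape[1] and 0 <= k0 < mask_shape[2]):
            raise ValueError(f"ROI center {center} outside volume {mask_shape}")
        ii, jj = np.meshgrid(np.arange(mask_shape[0]), np.arange(mask_shape[1]), indexing="ij")
        d2 = ((ii - i0) * voxel_size[0]) ** 2 + ((jj - j0) * voxel_size[1]) ** 2
        disc = d2 <= radius**2
        mask = np.zeros(mask_shape, dtype=bool)
        mask[:, :, int(k0)] = disc
        mask[int(i0), int(j0), int(k0)] = True
        return mask

    rois = [_disc(c) for c in centers]
    ref = _disc(reference_center) if reference_center is not None else None
    return ROISet(tumor_rois=rois, reference_roi=ref, diameter_mm=diameter_mm)


class ClinicalTable:
    """Per-patient clinical and routine-MRI characteristics.

    Thin wrapper over a pandas DataFrame enforcing the expected columns;
    ``group`` is binary ('recurrence' / 'non-recurrence') and
    ``who_grade`` may be missing (coded as NaN / 'unknown').
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in ("patient_id", "group") if c not in df.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        groups = set(df["group"].unique())
        if not groups <= {"recurrence", "non-recurrence"}:
            raise ValueError(f"group labels must be binary, got {groups}")
        self.df = df.reset_index(drop=True)

    def __len__(self):
        return len(self.df)

    @property
    def labels(self) -> np.ndarray:
        """1 for recurrence, 0 for non-recurrence."""
        return (self.df["group"] == "recurrence").to_numpy(dtype=int)

    @classmethod
    def from_csv(cls, path) -> "ClinicalTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)
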