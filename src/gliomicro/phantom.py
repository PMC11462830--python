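"""Forward simulation of multi-compartment diffusion signals and synthetic
two-group cohorts with known ground truth.

The tissue model is the three-compartment standard model of white matter:
an intra-neurite stick (zero perpendicular diffusivity), an extra-neurite
axially symmetric Gaussian (zeppelin) with independent parallel and
perpendicular diffusivities, and an isotropic free-water ball.  The stick
and zeppelin are dispersed by a Watson or Bingham orientation
distribution via spherical quadrature (pole-aligned Gauss-Legendre grid).

Two cohort generators emulate the study population of 25 non-recurrence
and 23 recurrence lower-grade-glioma patients:

* a *feature-level* cohort draws the 21 per-patient ROI metrics directly
  from a per-group effect table (fast path for the statistics and
  OPLS-DA stages), and
* a *signal-level* cohort builds small 4D volumes whose tumor and
  contralateral white-matter ROI voxels are simulated from ground-truth
  microstructure (end-to-end path).

The "paper-like" effect table encodes, for each metric, the direction of
the recurrence-group shift and a standardized effect size chosen so that
the metric's single-feature discriminability matches the reported
per-metric ROC AUC (d = sqrt(2) * Phi^-1(AUC)); metrics reported as
non-significant get zero effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm

from ._sphere import (
    bingham_density,
    frame_from,
    sphere_quadrature,
    watson_density,
)
from .protocol_io import (
    ClinicalTable,
    DWIDataset,
    GradientScheme,
    ROISet,
    place_circular_rois,
)

__all__ = [
    "MicrostructureTruth",
    "CohortConfig",
    "Cohort",
    "simulate_signal",
    "add_rician_noise",
    "make_cohort",
    "noddi_truth",
    "paper_effect_table",
    "METRICS",
]

#: canonical metric names, grouped by reconstruction model family
METRIC_FAMILIES = {
    "AFD": ["AFD_max", "AFD_sum", "AFD_total"],
    "DTI": ["AD", "MD", "RD", "FA"],
    "DKI": ["AK", "MK", "RK", "AWF"],
    "BinNODDI": ["Bin_ICVF", "Bin_ODI", "DAI"],
    "NODDI": ["ICVF", "ODI"],
    "SMI": ["Da", "De_par", "De_perp", "f", "fw"],
}
METRICS = [m for fam in METRIC_FAMILIES.values() for m in fam]


@dataclass
class MicrostructureTruth:
    """Ground-truth compartment parameters for one voxel.

    Fractions are absolute signal fractions (f_intra + f_iso <= 1, the
    remainder is extra-neurite); diffusivities in um^2/ms.
    """

    f_intra: float = 0.5
    f_iso: float = 0.1
    Da: float = 2.0
    De_par: float = 1.5
    De_perp: float = 0.6
    d_iso: float = 3.0
    odf_kind: str = "watson"  # watson | bingham | delta
    kappa1: float = 4.0
    kappa2: float = 4.0
    mu: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    psi: float = 0.0  # secondary-axis angle for Bingham fanning plane
    S0: float = 1.0

    def __post_init__(self):
        if not (0 <= self.f_intra <= 1 and 0 <= self.f_iso <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.f_intra + self.f_iso > 1 + 1e-12:
            raise ValueError("f_intra + f_iso exceeds 1")
        if not (self.Da >= 0 and self.De_par >= self.De_perp >= 0):
            raise ValueError("require Da >= 0 and De_par >= De_perp >= 0")
        mu = np.asarray(self.mu, dtype=float)
        n = np.linalg.norm(mu)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("mu must be a unit vector")
        self.mu = mu / n
        if self.odf_kind not in ("watson", "bingham", "delta"):
            raise ValueError(f"unknown odf_kind {self.odf_kind!r}")
        if self.kappa1 < self.kappa2 or self.kappa2 < 0:
            raise ValueError("require kappa1 >= kappa2 >= 0")


def noddi_truth(vic: float, viso: float, odi: float, mu=(0, 0, 1.0),
                d_par: float = 1.7, d_iso: float = 3.0, s0: float = 1.0) -> MicrostructureTruth:
    """Truth under the Watson-NODDI coupled parameterization.

    Intra and extra parallel diffusivities are tied to ``d_par`` and the
    extra-neurite perpendicular diffusivity follows the tortuosity rule
    De_perp = d_par * (1 - vic), with vic the intra fraction of the
    non-isotropic space.
    """
    kappa = 0.0 if odi >= 1 else 1.0 / np.tan(np.pi / 2.0 * odi)
    return MicrostructureTruth(
        f_intra=(1 - viso) * vic,
        f_iso=viso,
        Da=d_par,
        De_par=d_par,
        De_perp=d_par * (1 - vic),
        d_iso=d_iso,
        odf_kind="watson",
        kappa1=kappa,
        kappa2=kappa,
        mu=np.asarray(mu, dtype=float),
        S0=s0,
    )


def _odf_values(truth: MicrostructureTruth, points: np.ndarray) -> np.ndarray:
    if truth.odf_kind == "watson":
        return watson_density(points, truth.mu, truth.kappa1)
    frame = frame_from(truth.mu, truth.psi)
    return bingham_density(points, frame, truth.kappa1, truth.kappa2)


def simulate_signal(truth: MicrostructureTruth, scheme: GradientScheme,
                    n_theta: int = 60, n_phi: int = 60) -> np.ndarray:
    """Noise-free signal for one voxel under the three-compartment model.

    The stick and zeppelin kernels are convolved with the ODF by
    Gauss-Legendre quadrature with the dense polar band aligned to the
    principal orientation; S(b=0) equals S0 exactly.
    """
    b = scheme.bvals
    g = scheme.bvecs
    f_ec = 1.0 - truth.f_intra - truth.f_iso
    e_iso = np.exp(-b * truth.d_iso)

    if truth.odf_kind == "delta":
        c2 = (g @ truth.mu) ** 2
        e_ic = np.exp(-b * truth.Da * c2)
        e_ec = np.exp(-b * (truth.De_perp + (truth.De_par - truth.De_perp) * c2))
    else:
        pts, wts = sphere_quadrature(n_theta, n_phi, pole=truth.mu)
        odf_w = wts * _odf_values(truth, pts)  # integrates to ~1
        odf_w = odf_w / odf_w.sum()  # exact normalisation on the grid
        c2 = (g @ pts.T) ** 2  # (N, Q)
        e_ic = np.exp(-(b[:, None] * truth.Da) * c2) @ odf_w
        delta = truth.De_par - truth.De_perp
        e_ec = np.exp(-b[:, None] * (truth.De_perp + delta * c2)) @ odf_w

    s = truth.S0 * (truth.f_intra * e_ic + f_ec * e_ec + truth.f_iso * e_iso)
    # b = 0 rows are exactly S0 regardless of quadrature
    s[b == 0] = truth.S0
    return s


def add_rician_noise(signal: np.ndarray, snr: float | None, s0: float = 1.0,
                     rng=None, seed: int | None = None) -> np.ndarray:
    """Rician magnitude noise: |signal + N(0, sigma) + i N(0, sigma)| with
    sigma = s0 / snr.  ``snr=None`` (or inf) returns the input unchanged."""
    if snr is None or np.isinf(snr):
        return np.asarray(signal, dtype=float).copy()
    if snr <= 0:
        raise ValueError("snr must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    sigma = s0 / snr
    sig = np.asarray(signal, dtype=float)
    re = sig + rng.normal(0.0, sigma, sig.shape)
    im = rng.normal(0.0, sigma, sig.shape)
    return np.hypot(re, im)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: reported single-metric AUC (discriminability target) and direction of the
#: recurrence-group shift; direction 0 marks metrics reported non-significant.
_PAPER_EFFECTS = {
    # metric: (baseline mean, SD, AUC, direction)
    "AFD_max": (0.30, 0.08, 0.805, +1),
    "AFD_sum": (0.45, 0.12, 0.722, +1),
    "AFD_total": (0.55, 0.15, 0.774, +1),
    "AD": (1.60, 0.25, 0.682, -1),
    "MD": (1.30, 0.20, 0.744, -1),
    "RD": (1.15, 0.20, 0.762, -1),
    "FA": (0.22, 0.06, 0.732, +1),
    "AK": (0.55, 0.12, 0.736, +1),
    "MK": (0.60, 0.12, 0.767, +1),
    "RK": (0.65, 0.15, 0.744, +1),
    "AWF": (0.25, 0.06, 0.703, +1),
    "Bin_ICVF": (0.35, 0.08, 0.751, +1),
    "Bin_ODI": (0.45, 0.10, 0.5, 0),
    "DAI": (0.30, 0.10, 0.5, 0),
    "ICVF": (0.35, 0.08, 0.750, +1),
    "ODI": (0.45, 0.10, 0.5, 0),
    "Da": (2.00, 0.30, 0.5, 0),
    "De_par": (1.80, 0.30, 0.624, +1),
    "De_perp": (0.90, 0.15, 0.885, -1),
    "f": (0.30, 0.08, 0.683, +1),
    "fw": (0.25, 0.08, 0.830, -1),
}


def paper_effect_table() -> pd.DataFrame:
    """Per-metric group means and SDs for the paper-like preset.

    The recurrence mean is baseline + direction * d * SD with
    d = sqrt(2) * Phi^-1(AUC), so each metric's two-group separability
    matches its reported ROC AUC.
    """
    rows = []
    fam_of = {m: f for f, ms in METRIC_FAMILIES.items() for m in ms}
    for metric, (mean0, sd, auc, direction) in _PAPER_EFFECTS.items():
        d = np.sqrt(2.0) * _norm.ppf(auc) if direction != 0 else 0.0
        rows.append({
            "metric": metric,
            "family": fam_of[metric],
            "mean_nonrec": mean0,
            "mean_rec": mean0 + direction * d * sd,
            "sd": sd,
            "effect_d": direction * d,
            "direction": direction,
        })
    return pd.DataFrame(rows).set_index("metric")


def null_effect_table() -> pd.DataFrame:
    tab = paper_effect_table()
    tab["mean_rec"] = tab["mean_nonrec"]
    tab["effect_d"] = 0.0
    tab["direction"] = 0
    return tab


@dataclass
class CohortConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults mirror the study: 25 non-recurrence / 23 recurrence
    patients; effect directions and sizes from the reported per-metric
    ROC AUCs.  ``rho_global`` / ``rho_family`` set the shared-variance
    fractions of a patient-level severity latent and per-model-family
    latents (strong within-family, weak cross-family correlation, as in
    the reported correlation heatmap).
    """

    n_nonrec: int = 25
    n_rec: int = 23
    preset: str = "paper-like"  # paper-like | null
    level: str = "features"  # features | signals
    snr: float = 30.0
    seed: int = 0
    rho_global: float = 0.15
    rho_family: float = 0.35
    effect_table: pd.DataFrame | None = None
    # signal-level options
    n_rois: int = 5
    volume_shape: tuple = (16, 16, 3)
    voxel_size: tuple = (1.875, 1.875, 3.0)
    s0: float = 500.0

    def resolved_effects(self) -> pd.DataFrame:
        if self.effect_table is not None:
            tab = self.effect_table
            if (tab["sd"] <= 0).any():
                raise ValueError("effect-table SDs must be positive")
            return tab
        if self.preset == "paper-like":
            return paper_effect_table()
        if self.preset == "null":
            return null_effect_table()
        raise ValueError(f"unknown preset {self.preset!r}")


@dataclass
class Cohort:
    clinical: ClinicalTable
    features: pd.DataFrame | None = None
    datasets: dict | None = None  # patient_id -> (DWIDataset, ROISet)
    effects: pd.DataFrame | None = None

    @property
    def labels(self) -> np.ndarray:
        return self.clinical.labels

    @property
    def X(self) -> np.ndarray:
        return self.features[METRICS].to_numpy()


def _draw_clinical(rng: np.random.Generator, n_nonrec: int, n_rec: int) -> ClinicalTable:
    """Clinical covariates with the per-group category frequencies of the
    study cohort (used only for descriptive Table-1-style output)."""
    spec = {
        # column: (categories, probs nonrec, probs rec)
        "gender": (["male", "female"], [14 / 25, 11 / 25], [10 / 23, 13 / 23]),
        "midline_invasion": (["yes", "no"], [7 / 25, 18 / 25], [6 / 23, 17 / 23]),
        "lesion_location": (["frontal", "non-frontal"], [11 / 25, 14 / 25], [12 / 23, 11 / 23]),
        "lesion_size": (["<6cm", ">=6cm"], [9 / 25, 16 / 25], [13 / 23, 10 / 23]),
        "lesion_margin": (["sharp", "blurred"], [19 / 25, 6 / 25], [9 / 23, 14 / 23]),
        "histological_class": (["astrocytoma", "oligodendroglioma", "unclear"],
                               [18 / 25, 3 / 25, 4 / 25], [16 / 23, 6 / 23, 1 / 23]),
        "who_grade": (["II", "III", "unknown"], [11 / 25, 14 / 25, 0.0],
                      [17 / 23, 5 / 23, 1 / 23]),
        "therapy": (["chemo+radio", "chemo", "radio", "not-clear"],
                    [10 / 25, 2 / 25, 7 / 25, 6 / 25], [16 / 23, 1 / 23, 5 / 23, 1 / 23]),
    }
    rows = []
    for g, n, age_mu, age_sd in (("non-recurrence", n_nonrec, 40.17, 11.87),
                                 ("recurrence", n_rec, 43.16, 12.53)):
        for i in range(n):
            row = {"patient_id": f"{'R' if g == 'recurrence' else 'N'}{i:03d}",
                   "group": g, "age": float(np.round(rng.normal(age_mu, age_sd), 1))}
            for col, (cats, p0, p1) in spec.items():
                p = np.array(p1 if g == "recurrence" else p0, dtype=float)
                p = p / p.sum()
                row[col] = rng.choice(cats, p=p)
            rows.append(row)
    return ClinicalTable(pd.DataFrame(rows))


def _draw_features(rng: np.random.Generator, cfg: CohortConfig,
                   clinical: ClinicalTable, effects: pd.DataFrame) -> pd.DataFrame:
    rho_g, rho_f = cfg.rho_global, cfg.rho_family
    if rho_g + rho_f >= 1:
        raise ValueError("latent variance fractions must sum below 1")
    fams = sorted(METRIC_FAMILIES)
    rows = []
    for _, pat in clinical.df.iterrows():
        rec = pat["group"] == "recurrence"
        u = rng.normal()
        v = {f: rng.normal() for f in fams}
        row = {"patient_id": pat["patient_id"], "group": pat["group"]}
        for metric in METRICS:
            e = effects.loc[metric]
            mean = e["mean_rec"] if rec else e["mean_nonrec"]
            load = e["direction"] if e["direction"] != 0 else 1.0
            z = (load * (np.sqrt(rho_g) * u + np.sqrt(rho_f) * v[e["family"]])
                 + np.sqrt(1 - rho_g - rho_f) * rng.normal())
            row[metric] = mean + e["sd"] * z
        rows.append(row)
    return pd.DataFrame(rows)


# ground-truth tissue distributions for the signal-level cohort; the
# recurrence group has denser, less watery tissue (higher stick fraction,
# lower free water and extra-neurite perpendicular diffusivity)
_SIGNAL_TRUTH = {
    "non-recurrence": dict(f_intra=0.30, f_iso=0.25, De_par=1.70, De_perp=0.95, kappa=1.6),
    "recurrence": dict(f_intra=0.40, f_iso=0.17, De_par=1.85, De_perp=0.75, kappa=1.6),
}
_WM_TRUTH = dict(f_intra=0.55, f_iso=0.03, De_par=1.70, De_perp=0.50, kappa=8.0)


def _simulate_patient(rng: np.random.Generator, cfg: CohortConfig, group: str,
                      scheme: GradientScheme):
    shape = cfg.volume_shape
    centers = [(3 + 2 * r, 3 + ((3 * r) % 7), shape[2] // 2) for r in range(cfg.n_rois)]
    rois = place_circular_rois(shape, centers, 6.0, cfg.voxel_size,
                               reference_center=(shape[0] - 3, shape[1] - 3, shape[2] // 2))
    base = _SIGNAL_TRUTH["non-recurrence" if cfg.preset == "null" else group]
    sig = np.full(shape + (len(scheme),), cfg.s0 * 0.05)

    def _vox_truth(params, jitter):
        f_i = float(np.clip(params["f_intra"] + jitter * rng.normal(0, 0.03), 0.02, 0.9))
        f_w = float(np.clip(params["f_iso"] + jitter * rng.normal(0, 0.03), 0.0, 0.98 - f_i))
        de_par = float(np.clip(params["De_par"] + jitter * rng.normal(0, 0.05), 0.8, 2.8))
        de_perp = float(np.clip(params["De_perp"] + jitter * rng.normal(0, 0.05), 0.1, de_par))
        kap = float(np.clip(params["kappa"] * np.exp(jitter * rng.normal(0, 0.1)), 0.05, 50))
        mu = rng.normal(size=3)
        mu /= np.linalg.norm(mu)
        return MicrostructureTruth(f_intra=f_i, f_iso=f_w, Da=2.0, De_par=de_par,
                                   De_perp=de_perp, odf_kind="watson",
                                   kappa1=kap, kappa2=kap, mu=mu, S0=cfg.s0)

    for roi in rois.tumor_rois:
        for idx in zip(*np.nonzero(roi)):
            sig[idx] = simulate_signal(_vox_truth(base, 1.0), scheme, n_theta=24, n_phi=24)
    for idx in zip(*np.nonzero(rois.reference_roi)):
        sig[idx] = simulate_signal(_vox_truth(_WM_TRUTH, 0.3), scheme, n_theta=24, n_phi=24)
    noisy = add_rician_noise(sig, cfg.snr, s0=cfg.s0, rng=rng)
    affine = np.diag(list(cfg.voxel_size) + [1.0])
    return DWIDataset(signal=noisy, scheme=scheme, voxel_size=cfg.voxel_size, affine=affine), rois


def make_cohort(config: CohortConfig, scheme: GradientScheme | None = None) -> Cohort:
    """Generate a two-group synthetic cohort (see module docstring).

    Deterministic under ``config.seed``.
    """
    effects = config.resolved_effects()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2718]))
    clinical = _draw_clinical(rng, config.n_nonrec, config.n_rec)
    if config.level == "features":
        feats = _draw_features(rng, config, clinical, effects)
        return Cohort(clinical=clinical, features=feats, effects=effects)
    if config.level != "signals":
        raise ValueError(f"unknown cohort level {config.level!r}")
    if scheme is None:
        from .protocol_io import paper_scheme
        scheme = paper_scheme()
    datasets = {}
    for _, pat in clinical.df.iterrows():
        datasets[pat["patient_id"]] = _simulate_patient(rng, config, pat["group"], scheme)
    return Cohort(clinical=clinical, datasets=datasets, effects=effects)
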