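"""Synthetic CT phantoms and patient cohorts with known ground truth.

The phantom is a "candy-cane" thoracic aorta: a half-torus arch (radius
``arch_radius_mm``) joined to a straight descending cylinder, embedded in a
CT grid together with two ellipsoidal lungs whose lowest axial plane plays
the role of the diaphragm.  Voxels inside the lumen carry a linear contrast
trend along the vessel plus an optional periodic fluctuation and Gaussian
noise:

    I(s) = I0 + g * s + A * sin(2 * pi * f * s / 100) + N(0, sigma^2)

where ``s`` is the arc-length position normalised to 0-100 % between the
aortic root and the diaphragm plane.  The descending tube continues a short
distance below the diaphragm (an abdominal stub) so that truncation at the
lowest lung plane is a real operation, exactly as for a segmented scan.

The cohort generator draws the three enhancement markers (mean intensity,
proximal intensity, contrast gradient) from distributions shaped like the
observed histograms (bimodal intensities, left-skewed gradient), attaches
correlated anatomical confounders, and draws binary outcomes from a
logistic model with known coefficients, so selection and estimation
behaviour can be verified against the generating truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq
from scipy.special import expit

from .volume import CtVolume, SegmentationMask

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
    "OUTCOME_NAMES",
    "OUTCOME_PREVALENCE",
    "GRADIENT_EFFECT_PER_UNIT",
    "CONFOUNDER_NAMES",
    "PARAMETER_NAMES",
]

# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Geometry and intensity law of the candy-cane aorta phantom.

    All lengths in millimetres, intensities in Hounsfield units.  The
    defaults give a thoracic aorta of about 246 mm (half-torus of radius
    40 mm plus a 120 mm descending segment) with a 12 mm lumen radius,
    sampled on an isotropic 1.5 mm grid.
    """

    voxel_spacing_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    grid_shape: tuple[int, int, int] = (100, 96, 144)
    arch_radius_mm: float = 40.0
    lumen_radius_mm: float = 12.0
    descending_length_mm: float = 120.0
    intensity_intercept_hu: float = 350.0
    intensity_slope_hu_per_pct: float = -0.8
    fluctuation_amplitude_hu: float = 20.0
    fluctuation_cycles: float = 5.0
    noise_sd_hu: float = 5.0
    background_hu: float = 40.0
    lung_hu: float = -800.0
    seed: int = 0
    # Length of descending tube kept below the diaphragm so that
    # truncation at the lowest lung plane removes a nonempty piece.
    subdiaphragm_mm: float = 15.0

    def validate(self) -> None:
        sp = np.asarray(self.voxel_spacing_mm, float)
        if np.any(sp <= 0):
            raise ValueError("voxel spacing must be positive")
        if self.lumen_radius_mm < 2.0 * sp.max():
            raise ValueError(
                f"lumen radius {self.lumen_radius_mm} mm is below twice the "
                f"maximum voxel spacing {sp.max()} mm; the tube is not resolvable"
            )
        for name in ("arch_radius_mm", "descending_length_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fluctuation_amplitude_hu", "noise_sd_hu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class PhantomTruth:
    """Analytic ground truth of a generated phantom (the test oracle)."""

    true_centerline: np.ndarray  # (N, 3) world mm, root -> diaphragm
    true_intercept_hu: float
    true_slope_hu_per_pct: float
    true_length_mm: float
    startingpoint_vox: tuple[int, int, int]
    endpoint_vox: tuple[int, int, int]
    truncation_plane_index: int

    def to_json(self, path) -> None:
        d = asdict(self)
        d["true_centerline"] = np.asarray(self.true_centerline).tolist()
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "PhantomTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["true_centerline"] = np.asarray(d["true_centerline"], float)
        d["startingpoint_vox"] = tuple(d["startingpoint_vox"])
        d["endpoint_vox"] = tuple(d["endpoint_vox"])
        return cls(**d)


def _candy_cane_curve(spec: PhantomSpec, dz: float):
    """Analytic centerline of the phantom in world mm.

    Returns (points, arc, geometry) where ``arc`` is cumulative arc length
    and ``geometry`` carries the key positions used for masks and truth.
    """
    dx, dy, _ = spec.voxel_spacing_mm
    nx, ny, nz = spec.grid_shape
    R, r = spec.arch_radius_mm, spec.lumen_radius_mm

    # Snap the tube axis and arch centre to voxel centres.
    x0 = round((nx - 1) / 2) * dx
    yc = round((ny - 1) / 2) * dy
    k_bottom = 3
    z_stub_bottom = k_bottom * dz
    k_diaphragm = k_bottom + int(round(spec.subdiaphragm_mm / dz))
    z_d = k_diaphragm * dz
    zc = z_d + spec.descending_length_mm  # arch hinge (start/end of half-torus)

    step = min(spec.voxel_spacing_mm) / 2.0
    # Half-torus arch: theta 0 (ascending root, anterior) -> pi (posterior).
    n_arch = max(int(math.ceil(math.pi * R / step)), 8)
    theta = np.linspace(0.0, math.pi, n_arch + 1)
    arch = np.stack(
        [np.full_like(theta, x0), yc + R * np.cos(theta), zc + R * np.sin(theta)], axis=1
    )
    # Straight descending segment down to the sub-diaphragm stub bottom.
    n_desc = max(int(math.ceil((zc - z_stub_bottom) / step)), 4)
    zdesc = np.linspace(zc, z_stub_bottom, n_desc + 1)[1:]
    desc = np.stack([np.full_like(zdesc, x0), np.full_like(zdesc, yc - R), zdesc], axis=1)

    pts = np.concatenate([arch, desc], axis=0)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    geometry = dict(x0=x0, yc=yc, zc=zc, z_d=z_d, z_stub_bottom=z_stub_bottom,
                    k_diaphragm=k_diaphragm, thoracic_length=math.pi * R + (zc - z_d))
    return pts, arc, geometry


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[CtVolume, SegmentationMask, SegmentationMask, PhantomTruth]:
    """Build the phantom volume, aorta mask, lung mask and ground truth."""
    spec.validate()
    dx, dy, dz = spec.voxel_spacing_mm
    nx, ny, nz = spec.grid_shape
    R, r = spec.arch_radius_mm, spec.lumen_radius_mm

    pts, arc, geo = _candy_cane_curve(spec, dz)
    x0, yc, zc, z_d = geo["x0"], geo["yc"], geo["zc"], geo["z_d"]
    thoracic_len = geo["thoracic_length"]
    s_pct = arc / thoracic_len * 100.0  # exceeds 100 in the abdominal stub

    # Grid extents the tube and lungs must respect.
    xmax, ymax, zmax = (nx - 1) * dx, (ny - 1) * dy, (nz - 1) * dz
    checks = {
        "arch apex (superior)": zc + R + r <= zmax,
        "arch anterior extent": yc + R + r <= ymax,
        "arch posterior extent": yc - R - r >= 0,
        "tube lateral extent": (x0 - r >= 0) and (x0 + r <= xmax),
        # the end cap of the stub may be clipped at the grid edge, like a
        # real field of view; the curve itself must stay inside
        "stub inferior extent": geo["z_stub_bottom"] >= 0,
    }
    for name, ok in checks.items():
        if not ok:
            raise ValueError(f"phantom geometry exceeds the grid: {name}")

    affine = np.diag([dx, dy, dz, 1.0])

    # Rasterise the curve, then use the Euclidean distance transform to find
    # every voxel within one lumen radius of it (and its nearest curve point,
    # which carries the arc position for the intensity law).
    curve_vox = np.rint(pts / np.array([dx, dy, dz])).astype(int)
    curve_vox = np.clip(curve_vox, 0, np.array([nx, ny, nz]) - 1)
    seedgrid = np.ones((nx, ny, nz), dtype=bool)
    seedgrid[curve_vox[:, 0], curve_vox[:, 1], curve_vox[:, 2]] = False
    s_at_curve = np.zeros((nx, ny, nz), dtype=float)
    s_at_curve[curve_vox[:, 0], curve_vox[:, 1], curve_vox[:, 2]] = s_pct
    dist, (ii, jj, kk) = ndimage.distance_transform_edt(
        seedgrid, sampling=(dx, dy, dz), return_indices=True
    )
    lumen = dist <= r

    # Flat cut of the ascending root: the tube must not extend below the
    # level of the aortic root on the anterior side, otherwise the lowest
    # two-component plane would sit inside the spherical end cap.
    zw = np.arange(nz) * dz
    yw = np.arange(ny) * dy
    below_root = zw[None, None, :] < zc - 1e-9
    anterior = yw[None, :, None] > yc
    lumen &= ~(below_root & anterior)

    s_vox = s_at_curve[ii, jj, kk]

    # Lungs: two ellipsoids whose lowest plane defines the diaphragm.
    k_d = geo["k_diaphragm"]
    lung_a, lung_b, lung_c = 28.0, 45.0, 55.0
    lung_dx = round(45.0 / dx) * dx
    lz = k_d * dz - 0.45 * dz + lung_c  # bottom 0.45 voxel below plane k_d
    if lz + lung_c > zmax or yc - 5.0 + lung_b > ymax or x0 + lung_dx + lung_a > xmax:
        raise ValueError("phantom geometry exceeds the grid: lung extent")
    xw = np.arange(nx) * dx
    lungs = np.zeros((nx, ny, nz), dtype=bool)
    for cx in (x0 - lung_dx, x0 + lung_dx):
        e = (
            ((xw[:, None, None] - cx) / lung_a) ** 2
            + ((yw[None, :, None] - (yc - 5.0)) / lung_b) ** 2
            + ((zw[None, None, :] - lz) / lung_c) ** 2
        )
        lungs |= e < 1.0
    lungs &= ~lumen

    rng = np.random.default_rng(spec.seed)
    vol = np.full((nx, ny, nz), spec.background_hu, dtype=np.float32)
    vol[lungs] = spec.lung_hu
    s_l = s_vox[lumen]
    intensity = (
        spec.intensity_intercept_hu
        + spec.intensity_slope_hu_per_pct * s_l
        + spec.fluctuation_amplitude_hu
        * np.sin(2.0 * math.pi * spec.fluctuation_cycles * s_l / 100.0)
    )
    if spec.noise_sd_hu > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd_hu, size=s_l.shape)
    vol[lumen] = intensity

    # Ground truth.  The starting point is the root centre on the first
    # axial plane at or above the root level; the endpoint the descending
    # tube centre on the diaphragm plane (= lowest lung-containing plane).
    k_trunc = int(np.flatnonzero(lungs.any(axis=(0, 1)))[0])
    k_start = int(math.ceil(zc / dz - 1e-9))
    start_vox = (int(round(x0 / dx)), int(round((yc + R) / dy)), k_start)
    end_vox = (int(round(x0 / dx)), int(round((yc - R) / dy)), k_trunc)
    thoracic = s_pct <= 100.0 + 1e-9
    truth = PhantomTruth(
        true_centerline=pts[thoracic],
        true_intercept_hu=spec.intensity_intercept_hu,
        true_slope_hu_per_pct=spec.intensity_slope_hu_per_pct,
        true_length_mm=thoracic_len,
        startingpoint_vox=start_vox,
        endpoint_vox=end_vox,
        truncation_plane_index=k_trunc,
    )
    return (
        CtVolume(vol, affine),
        SegmentationMask(lumen, affine),
        SegmentationMask(lungs, affine),
        truth,
    )


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

PARAMETER_NAMES = ["mean_intensity", "proximal_intensity", "contrast_gradient"]
CONFOUNDER_NAMES = [
    "lung_volume_l",
    "aorta_length_mm",
    "aorta_volume_ml",
    "aorta_diameter_mm",
    "contrast_delay_s",
]

OUTCOME_NAMES = [
    "hospital_admission",
    "icu_admission",
    "oxygen_therapy",
    "pain_medication",
    "reperfusion_therapy",
    "vasopressor_therapy",
    "recurrent_vte",
    "pe_rehospitalization",
    "pe_related_death",
    "dyspnea",
    "chest_pain",
    "functional_impairment",
]

# Observed prevalences in a 93-patient acute-PE cohort (counts / 93).
OUTCOME_PREVALENCE = {
    "hospital_admission": 54 / 93,
    "icu_admission": 7 / 93,
    "oxygen_therapy": 23 / 93,
    "pain_medication": 6 / 93,
    "reperfusion_therapy": 4 / 93,
    "vasopressor_therapy": 3 / 93,
    "recurrent_vte": 1 / 93,
    "pe_rehospitalization": 8 / 93,
    "pe_related_death": 2 / 93,
    "dyspnea": 21 / 93,
    "chest_pain": 10 / 93,
    "functional_impairment": 21 / 93,
}

# Default true log-odds effect of the raw contrast gradient (HU/%) on each
# outcome.  The five short-term outcomes carry the reported per-10-unit
# coefficients divided by 10; the rest are null.
GRADIENT_EFFECT_PER_UNIT = {name: 0.0 for name in OUTCOME_NAMES}
GRADIENT_EFFECT_PER_UNIT.update(
    {
        "icu_admission": -0.0656,
        "oxygen_therapy": -0.0347,
        "reperfusion_therapy": -0.0931,
        "vasopressor_therapy": -0.0855,
        "pe_related_death": -0.0698,
    }
)

# (mu, sigma, loading on the intensity latent, loading on the gradient)
_CONFOUNDER_MODEL = {
    "lung_volume_l": (5.0, 1.2, -0.40, -0.08),
    "aorta_length_mm": (230.0, 25.0, -0.35, -0.20),
    "aorta_volume_ml": (180.0, 40.0, -0.45, -0.20),
    "aorta_diameter_mm": (31.0, 3.0, -0.42, -0.20),
    "contrast_delay_s": (20.0, 4.0, 0.27, -0.05),
}


@dataclass
class CohortSpec:
    """Generating model of a synthetic patient cohort.

    ``gradient_effect_per_unit`` is the log-odds change per 1 HU/% of the
    raw contrast gradient; the conventional reporting scale multiplies it
    by 10.  Outcome intercepts are solved so that the expected prevalence
    matches ``prevalences`` under the generated gradient distribution,
    unless explicit ``logit_intercepts`` are given.
    """

    n_patients: int = 93
    outcome_names: tuple[str, ...] = tuple(OUTCOME_NAMES)
    prevalences: dict | None = None
    logit_intercepts: dict | None = None
    gradient_effect_per_unit: dict | None = None
    confounder_correlations: dict | None = None
    missing_rate: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 10:
            raise ValueError("n_patients must be at least 10")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        for d in (self.prevalences, self.logit_intercepts, self.gradient_effect_per_unit):
            if d is not None:
                vals = np.asarray(list(d.values()), dtype=float)
                if not np.all(np.isfinite(vals)):
                    raise ValueError("cohort spec contains non-finite values")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


# Marker distributions: a two-component Gaussian mixture for the intensity
# level (bimodal, like the observed histograms) and a negated, shifted
# log-normal for the gradient (left-skewed, mode around -4 HU/%).
_GRADIENT_SHIFT = 2.0
_GRADIENT_LOG_MEDIAN = math.log(8.0)
_GRADIENT_LOG_SD = 0.5
_PROXIMAL_MODES = ((320.0, 30.0), (430.0, 30.0))


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a synthetic cohort; returns (table, generating truth)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    gradient = _GRADIENT_SHIFT - rng.lognormal(_GRADIENT_LOG_MEDIAN, _GRADIENT_LOG_SD, n)
    comp = rng.integers(0, 2, n)
    mu = np.where(comp == 0, _PROXIMAL_MODES[0][0], _PROXIMAL_MODES[1][0])
    sd = np.where(comp == 0, _PROXIMAL_MODES[0][1], _PROXIMAL_MODES[1][1])
    proximal = rng.normal(mu, sd)
    mean_int = proximal - 40.0 + rng.normal(0.0, 15.0, n)

    z_m = (mean_int - mean_int.mean()) / mean_int.std()
    z_g = (gradient - gradient.mean()) / gradient.std()
    corr_override = spec.confounder_correlations or {}
    table = {
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "mean_intensity": mean_int,
        "proximal_intensity": proximal,
        "contrast_gradient": gradient,
    }
    for name, (mu_c, sd_c, rho_m, rho_g) in _CONFOUNDER_MODEL.items():
        if name in corr_override:
            rho_m = float(corr_override[name])
        resid = max(1.0 - rho_m**2 - rho_g**2, 0.0)
        table[name] = mu_c + sd_c * (
            rho_m * z_m + rho_g * z_g + math.sqrt(resid) * rng.normal(size=n)
        )

    prev = dict(OUTCOME_PREVALENCE)
    prev.update(spec.prevalences or {})
    beta = dict(GRADIENT_EFFECT_PER_UNIT)
    beta.update(spec.gradient_effect_per_unit or {})

    intercepts = {}
    for name in spec.outcome_names:
        b = float(beta.get(name, 0.0))
        if spec.logit_intercepts and name in spec.logit_intercepts:
            a = float(spec.logit_intercepts[name])
        else:
            p_target = float(prev.get(name, 0.1))
            a = brentq(lambda a_: expit(a_ + b * gradient).mean() - p_target, -30.0, 30.0)
        intercepts[name] = a
        table[name] = rng.binomial(1, expit(a + b * gradient)).astype(float)

    # High-risk clinical markers, negatively coupled to the gradient
    # (steeper decline -> more likely marker-positive).
    for name, b_m, p_m in (
        ("hemodynamic_instability", -0.12, 5 / 93),
        ("rvlv_gt1", -0.10, 44 / 93),
    ):
        a = brentq(lambda a_: expit(a_ + b_m * gradient).mean() - p_m, -30.0, 30.0)
        table[name] = rng.binomial(1, expit(a + b_m * gradient)).astype(float)

    df = pd.DataFrame(table)

    # Missingness: completely at random, one blanked outcome cell per
    # affected patient, so the expected number of incomplete rows is
    # n * missing_rate.
    if spec.missing_rate > 0:
        incomplete = rng.random(n) < spec.missing_rate
        cols = list(spec.outcome_names)
        for i in np.flatnonzero(incomplete):
            df.loc[i, cols[rng.integers(0, len(cols))]] = np.nan

    truth = {
        "logit_intercepts": intercepts,
        "gradient_effect_per_unit": beta,
        "prevalences": prev,
    }
    return df, truth
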