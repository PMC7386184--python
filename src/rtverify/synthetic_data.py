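"""Seeded synthetic case generators.

Two families of cases feed the verification pipeline:

* *Phantom mode* — triplets (primary-TPS map, secondary-TPS map,
  measurement map) on an unwrapped cylindrical diode layout.  Both TPS
  maps share the underlying planned field; the measurement additionally
  carries a spatially correlated systematic model error (the shared
  TPS-vs-reality discrepancy) plus independent per-diode noise.  With
  the defaults this makes the TPS-vs-TPS comparison (pattern 1) agree
  better than either TPS-vs-measurement comparison (patterns 2 and 3).

* *Patient mode* — a lung-like HU volume with a spherical tumor, margin
  -derived targets (iGTV + 3 mm -> ITV, + 5 mm -> PTV), a primary dose
  grid normalized so the PTV D95 equals the prescription, and a
  secondary dose grid perturbed by a density-dependent model: dose is
  suppressed where HU is low and the removed energy is redistributed
  into the surrounding low-density tissue, giving negative target DEs
  and positive lung VEs.

Determinism: every generator consumes a single ``numpy.random.default_rng``
seeded from the spec, and the order of draws is fixed (documented in each
function), so identical specs give bit-identical cases on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .comparison_metrics import DetectorMap
from .dose_model import (
    CTVolume,
    DoseGrid,
    GeometryError,
    Structure,
    StructureSet,
    expand_margin,
    rasterize_structure,
)
from .dvh_verification import cumulative_dvh, dose_at_volume

__all__ = [
    "PhantomCaseSpec",
    "PatientCaseSpec",
    "DetectorSpec",
    "PhantomCase",
    "PatientCase",
    "make_phantom_case",
    "make_patient_case",
    "sample_cylinder",
    "known_shift_case",
    "phantom_cohort_specs",
    "patient_cohort_specs",
]


@dataclass(frozen=True)
class DetectorSpec:
    """Regular cylindrical diode lattice (unwrapped rows x columns)."""

    n_axial: int = 21
    n_azimuth: int = 66
    diode_spacing: float = 10.0  # mm, axial pitch
    cylinder_radius: float = 105.0  # mm

    def __post_init__(self):
        if self.diode_spacing <= 0 or self.cylinder_radius <= 0:
            raise ValueError("detector spacing and radius must be > 0")


@dataclass(frozen=True)
class PhantomCaseSpec:
    seed: int = 0
    detector: DetectorSpec = field(default_factory=DetectorSpec)
    n_arc_lobes: int = 4
    max_dose_gy: float = 2.0
    tps_discrepancy_sd: float = 2.0  # % of max dose, pattern-1 scale
    model_error_sd: float = 3.2  # % of max, shared TPS-vs-reality systematic
    measurement_noise_sd: float = 1.2  # % of max, independent diode noise
    stps_model_fraction: float = 0.15  # share of the systematic the sTPS captures
    tps_corr_mm: float = 35.0  # correlation length of the TPS discrepancy
    model_corr_mm: float = 45.0  # correlation length of the systematic
    case_scale_sd: float = 0.55  # lognormal sigma of per-case error rescaling

    def __post_init__(self):
        for name in ("tps_discrepancy_sd", "model_error_sd", "measurement_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PatientCaseSpec:
    seed: int = 0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)  # default calc grid 2.0 mm
    lung_radius_mm: float = 48.0
    lung_hu_mean: float = -700.0
    lung_hu_sd: float = 40.0
    tumor_hu_mean: float = -150.0
    tumor_hu_sd: float = 30.0
    tumor_radius_mm: float = 12.0
    itv_margin_mm: float = 3.0
    ptv_margin_mm: float = 5.0
    prescription_gy: float = 50.0  # default regimen: 50 Gy in 4 fractions
    fractions: int = 4
    penumbra_sigma_mm: float = 7.0
    bath_fraction: float = 0.10  # arc entrance/exit low-dose bath level
    bath_range_mm: float = 25.0
    heterogeneity_sd: float = 0.03
    body_hu_sd: float = 25.0
    density_coupling: float = 0.10  # strength of low-HU dose suppression
    hu_reference: float = 0.0  # HU at which the suppression starts
    hu_scale: float = 700.0  # HU drop over which it saturates
    redistribution_gain: float = 1.4
    redistribution_sigma_mm: float = 12.0

    def __post_init__(self):
        if self.tumor_radius_mm <= 0 or self.lung_radius_mm <= 0:
            raise ValueError("radii must be > 0")
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be > 0")
        if self.itv_margin_mm < 0 or self.ptv_margin_mm < 0:
            raise ValueError("margins must be >= 0")


class PhantomCase(NamedTuple):
    ptps: DetectorMap
    stps: DetectorMap
    measurement: DetectorMap
    spec: PhantomCaseSpec


class PatientCase(NamedTuple):
    ct: CTVolume
    structures: StructureSet
    ptps: DoseGrid
    stps: DoseGrid
    isocenter_mm: tuple[float, float, float]
    spec: PatientCaseSpec


# ---------------------------------------------------------------------------
# Phantom mode
# ---------------------------------------------------------------------------


def _smooth_field(rng, shape, sigma_px) -> np.ndarray:
    """Unit-variance correlated field; periodic along the column axis."""
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma=sigma_px, mode=("reflect", "wrap"))
    sd = f.std()
    return f / sd if sd > 0 else f


def make_phantom_case(spec: PhantomCaseSpec) -> PhantomCase:
    """Generate one phantom-mode triplet.

    Draw order: (1) lobe geometry/amplitudes, (2) per-case error-scale
    factors, (3) TPS discrepancy field, (4) systematic model-error
    field, (5) diode noise.
    """
    rng = np.random.default_rng(spec.seed)
    det = spec.detector
    n_r, n_c = det.n_axial, det.n_azimuth
    arc = 2 * math.pi * det.cylinder_radius / n_c

    rows = np.arange(n_r)[:, None] * det.diode_spacing
    cols = np.arange(n_c)[None, :] * arc
    period = n_c * arc

    # (1) base field: sum of smooth lobes, periodic in azimuth
    base = np.zeros((n_r, n_c))
    for _ in range(max(1, spec.n_arc_lobes)):
        r0 = rng.uniform(0.2, 0.8) * (n_r - 1) * det.diode_spacing
        c0 = rng.uniform(0, period)
        sig_r = rng.uniform(25.0, 60.0)
        sig_c = rng.uniform(35.0, 90.0)
        amp = rng.uniform(0.5, 1.0)
        dc = np.abs(cols - c0)
        dc = np.minimum(dc, period - dc)  # cyclic distance along the arc
        base += amp * np.exp(-((rows - r0) ** 2) / (2 * sig_r**2) - dc**2 / (2 * sig_c**2))
    base += 0.02 * base.max()
    base *= spec.max_dose_gy / base.max()
    bmax = base.max()

    # (2) per-case rescaling so a cohort spreads its passing rates
    s_tps, s_model, s_noise = np.exp(rng.normal(0.0, spec.case_scale_sd, size=3))

    # errors concentrate where there is dose
    weight = 0.25 + 0.75 * base / bmax

    # (3) TPS-vs-TPS discrepancy (smooth)
    sig_tps = (spec.tps_corr_mm / det.diode_spacing, spec.tps_corr_mm / arc)
    e_tps = _smooth_field(rng, (n_r, n_c), sig_tps) * weight
    e_tps *= spec.tps_discrepancy_sd * s_tps / 100.0 * bmax

    # (4) shared systematic model error (reality vs both TPSs)
    sig_m = (spec.model_corr_mm / det.diode_spacing, spec.model_corr_mm / arc)
    e_model = _smooth_field(rng, (n_r, n_c), sig_m) * weight
    e_model *= spec.model_error_sd * s_model / 100.0 * bmax

    # (5) independent diode noise
    noise = rng.standard_normal((n_r, n_c)) * (
        spec.measurement_noise_sd * s_noise / 100.0 * bmax
    )

    mk = lambda v: DetectorMap(np.clip(v, 0, None), det.diode_spacing, det.cylinder_radius)
    # the secondary TPS tracks a fraction of the true systematic, so the
    # sTPS-vs-measurement comparison comes out slightly better than
    # pTPS-vs-measurement and its fail points overlap pattern 1's
    return PhantomCase(
        ptps=mk(base),
        stps=mk(base + e_tps + spec.stps_model_fraction * e_model),
        measurement=mk(base + e_model + noise),
        spec=spec,
    )


def sample_cylinder(grid: DoseGrid, detector: DetectorSpec) -> DetectorMap:
    """Trilinearly sample a 3-D dose grid on a cylinder surface.

    The cylinder axis runs along z through the grid center; rows are
    centered axially.  Column j sits at azimuth ``theta = 2*pi*j/n``,
    with column 0 toward +x: sample position
    ``(z_i, yc + r*sin(theta), xc + r*cos(theta))``.
    """
    ext = grid.extent()
    zc = 0.5 * (ext[0][0] + ext[0][1])
    yc = 0.5 * (ext[1][0] + ext[1][1])
    xc = 0.5 * (ext[2][0] + ext[2][1])

    z = zc + (np.arange(detector.n_axial) - (detector.n_axial - 1) / 2) * detector.diode_spacing
    theta = 2 * math.pi * np.arange(detector.n_azimuth) / detector.n_azimuth
    r = detector.cylinder_radius

    zz, tt = np.meshgrid(z, theta, indexing="ij")
    pts = np.stack(
        [zz.ravel(), yc + r * np.sin(tt).ravel(), xc + r * np.cos(tt).ravel()], axis=1
    )
    for a in range(3):
        if pts[:, a].min() < ext[a][0] - 1e-9 or pts[:, a].max() > ext[a][1] + 1e-9:
            raise GeometryError("detector cylinder does not fit inside the dose grid")
    coords = ((pts - np.asarray(grid.origin)) / np.asarray(grid.spacing)).T
    vals = ndimage.map_coordinates(grid.values, coords, order=1, mode="nearest")
    return DetectorMap(
        vals.reshape(detector.n_axial, detector.n_azimuth),
        detector.diode_spacing,
        detector.cylinder_radius,
    )


# ---------------------------------------------------------------------------
# Patient mode
# ---------------------------------------------------------------------------


def _sphere_contours(center_zyx, radius, z_positions, n_vertices=64):
    """Circle polygons approximating a sphere on the given slices."""
    contours = []
    ang = 2 * math.pi * np.arange(n_vertices) / n_vertices
    for z in z_positions:
        dz = z - center_zyx[0]
        if abs(dz) >= radius:
            continue
        r_slice = math.sqrt(radius**2 - dz**2)
        poly = np.column_stack(
            [center_zyx[1] + r_slice * np.sin(ang), center_zyx[2] + r_slice * np.cos(ang)]
        )
        contours.append((float(z), poly))
    return contours


def make_patient_case(spec: PatientCaseSpec) -> PatientCase:
    """Generate one patient-mode case.

    Draw order: (1) lung HU texture, (2) tumor HU texture, (3) dose
    heterogeneity field.  The primary dose is a target-conformal field
    (flat inside the PTV, Gaussian penumbra outside) rescaled so the PTV
    D95 equals the prescription; the secondary dose applies the
    density-coupled suppression/redistribution model to the primary.
    """
    nz, ny, nx = spec.grid_shape
    sp = spec.spacing
    origin = (0.0, 0.0, 0.0)
    center = tuple((n - 1) / 2 * s for n, s in zip(spec.grid_shape, sp))

    if spec.tumor_radius_mm + spec.itv_margin_mm + spec.ptv_margin_mm >= spec.lung_radius_mm:
        raise ValueError("tumor plus margins exceeds the lung extent")

    rng = np.random.default_rng(spec.seed)
    zz = origin[0] + sp[0] * np.arange(nz)
    yy = origin[1] + sp[1] * np.arange(ny)
    xx = origin[2] + sp[2] * np.arange(nx)
    gz, gy, gx = np.meshgrid(zz, yy, xx, indexing="ij")
    r2 = (gz - center[0]) ** 2 + (gy - center[1]) ** 2 + (gx - center[2]) ** 2
    in_lung = r2 <= spec.lung_radius_mm**2
    in_tumor = r2 <= spec.tumor_radius_mm**2

    # (1)-(2) CT: water body, noisy lung, noisy tumor
    sigma_px = tuple(4.0 / s for s in sp)
    lung_tex = ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape), sigma_px)
    lung_tex /= max(lung_tex.std(), 1e-12)
    tumor_tex = ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape), sigma_px)
    tumor_tex /= max(tumor_tex.std(), 1e-12)

    hu = spec.body_hu_sd * lung_tex  # mild soft-tissue texture around water
    hu[in_lung] = spec.lung_hu_mean + spec.lung_hu_sd * lung_tex[in_lung]
    hu[in_tumor] = spec.tumor_hu_mean + spec.tumor_hu_sd * tumor_tex[in_tumor]
    hu = np.clip(hu, -1000.0, 3000.0)
    ct = CTVolume(hu, origin, sp)

    # structures as planar contours (iGTV, lung, cord, external)
    igtv = Structure(
        "iGTV", "iGTV", _sphere_contours(center, spec.tumor_radius_mm, zz)
    )
    lung_struct = Structure("lung", "lung", _sphere_contours(center, spec.lung_radius_mm, zz))
    cord_y = center[1] + spec.lung_radius_mm + 8.0
    cord_contours = []
    ang = 2 * math.pi * np.arange(24) / 24
    for z in zz:
        poly = np.column_stack(
            [cord_y + 5.0 * np.sin(ang), center[2] + 5.0 * np.cos(ang)]
        )
        cord_contours.append((float(z), poly))
    cord = Structure("spinal_cord", "spinal_cord", cord_contours)
    lo_y, hi_y = yy[0] - sp[1] / 2, yy[-1] + sp[1] / 2
    lo_x, hi_x = xx[0] - sp[2] / 2, xx[-1] + sp[2] / 2
    ext_contours = [
        (float(z), np.array([[lo_y, lo_x], [lo_y, hi_x], [hi_y, hi_x], [hi_y, lo_x]]))
        for z in zz
    ]
    external = Structure("external", "external", ext_contours)
    structures = StructureSet([igtv, lung_struct, cord, external])

    # PTV for dose shaping: iGTV + 3 mm -> ITV, + 5 mm -> PTV
    igtv_mask = rasterize_structure(igtv, ct)
    itv_mask = expand_margin(igtv_mask, spec.itv_margin_mm)
    ptv_mask = expand_margin(itv_mask, spec.ptv_margin_mm)

    # (3) primary dose: conformal plateau + Gaussian penumbra + heterogeneity
    dist_out = ndimage.distance_transform_edt(~ptv_mask.flags, sampling=sp)
    dose = np.exp(-(dist_out**2) / (2 * spec.penumbra_sigma_mm**2))
    dose += spec.bath_fraction * np.exp(-dist_out / spec.bath_range_mm)
    het = ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape), sigma_px)
    het /= max(het.std(), 1e-12)
    dose *= 1.0 + spec.heterogeneity_sd * het
    dose = np.clip(dose, 0.0, None)

    ptps = DoseGrid(dose, origin, sp)
    d95 = dose_at_volume(cumulative_dvh(ptps, ptv_mask, 0.001), 95)
    ptps = DoseGrid(dose * spec.prescription_gy / d95, origin, sp)

    # secondary dose: low-HU suppression with energy redistribution
    stps = DoseGrid(
        _density_perturbation(ptps.values, hu, spec), origin, sp, frame_id=ptps.frame_id
    )
    return PatientCase(ct, structures, ptps, stps, center, spec)


def _density_perturbation(dose: np.ndarray, hu: np.ndarray, spec: PatientCaseSpec) -> np.ndarray:
    """Suppress dose in low-density voxels and redistribute it outward.

    f(HU) rises linearly from 0 at ``hu_reference`` and saturates at 1 a
    further ``hu_scale`` HU down, so the suppression grows as density
    falls.  The removed energy is blurred outward and deposited with a
    weight that saturates at moderately low density: anywhere in lung
    the deposit weight is ~1 (so the suppression, not the add-back,
    carries the HU dependence), while dense soft tissue receives
    essentially nothing.
    """
    if spec.density_coupling == 0:
        return dose.copy()
    f = np.clip((spec.hu_reference - hu) / spec.hu_scale, 0.0, 1.0)
    removed = spec.density_coupling * f * dose
    sigma_px = tuple(spec.redistribution_sigma_mm / s for s in spec.spacing)
    halo = ndimage.gaussian_filter(removed, sigma_px) * spec.redistribution_gain
    deposit = np.clip((f - 0.3) / 0.4, 0.0, 1.0)
    return np.clip(dose - removed + halo * deposit, 0.0, None)


def known_shift_case(base_case: PatientCase, shift_percent: float) -> PatientCase:
    """Replace the secondary grid by an exact uniform rescale of the
    primary: sTPS = pTPS * (1 + shift/100).  Recovery harness for DE."""
    if shift_percent <= -100:
        raise ValueError("shift must be > -100%")
    factor = 1.0 + shift_percent / 100.0
    stps = DoseGrid(
        base_case.ptps.values * factor,
        base_case.ptps.origin,
        base_case.ptps.spacing,
        frame_id=base_case.ptps.frame_id,
    )
    return base_case._replace(stps=stps)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def phantom_cohort_specs(n: int = 20, seed: int = 0, **overrides) -> list[PhantomCaseSpec]:
    """n independent phantom specs with per-case seeds derived from one seed."""
    ss = np.random.SeedSequence(seed)
    return [
        replace(PhantomCaseSpec(seed=int(child.generate_state(1)[0])), **overrides)
        for child in ss.spawn(n)
    ]


def patient_cohort_specs(n: int = 20, seed: int = 0, **overrides) -> list[PatientCaseSpec]:
    """n patient specs with varied tumor size and HU statistics.

    Tumor radius ~ U(8, 18) mm and lung/tumor HU means vary across
    cases, so cohort covariates (PTV size, mean/SD HU in PTV) have the
    spread the correlation analysis expects.
    """
    ss = np.random.SeedSequence(seed)
    specs = []
    for child in ss.spawn(n):
        rng = np.random.default_rng(child)
        specs.append(
            replace(
                PatientCaseSpec(
                    seed=int(child.generate_state(1)[0]),
                    tumor_radius_mm=float(rng.uniform(8.0, 18.0)),
                    lung_hu_mean=float(rng.uniform(-850.0, -500.0)),
                    tumor_hu_mean=float(rng.uniform(-350.0, 0.0)),
                    lung_hu_sd=float(rng.uniform(25.0, 60.0)),
                ),
                **overrides,
            )
        )
    return specs
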