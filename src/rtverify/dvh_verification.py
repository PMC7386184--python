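"""Patient-geometry verification: DVHs, dose-volume indices, dosimetric
and volumetric error metrics with tolerance levels, correlation analysis
and paired significance testing.

Error conventions: DE = (D_sTPS - D_pTPS) / D_pTPS * 100 and
VE = (V_sTPS - V_pTPS) / V_pTPS * 100, so a secondary system that
reports less dose than the primary yields a negative DE.  The tolerance
level of an index over a cohort is its mean +/- sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .dose_model import DoseGrid, VoxelMask, point_dose

__all__ = [
    "DVH",
    "TargetIndices",
    "DvhIndexSet",
    "ErrorRecord",
    "CorrelationResult",
    "cumulative_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "dvh_index_set",
    "dosimetric_error",
    "volume_error",
    "tolerance_level",
    "correlation_analysis",
    "paired_t_test",
    "classify_correlation",
]

DEFAULT_BIN_WIDTH_GY = 0.01


@dataclass
class DVH:
    """Cumulative dose-volume curve for one structure.

    ``cumulative_volume[i]`` is the fraction of the structure receiving
    at least ``dose_bins[i]`` Gy; bins are uniform left edges starting
    at 0, the curve starts at 1 and ends at 0.
    """

    structure_label: str
    dose_bins: np.ndarray
    cumulative_volume: np.ndarray
    total_volume_cm3: float

    def __post_init__(self):
        self.dose_bins = np.asarray(self.dose_bins, dtype=np.float64)
        self.cumulative_volume = np.asarray(self.cumulative_volume, dtype=np.float64)
        if self.dose_bins.shape != self.cumulative_volume.shape:
            raise ValueError("bin/volume arrays must match")
        if np.any(np.diff(self.cumulative_volume) > 1e-12):
            raise ValueError("cumulative volume must be non-increasing")

    @property
    def bin_width(self) -> float:
        return float(self.dose_bins[1] - self.dose_bins[0])


def cumulative_dvh(dose: DoseGrid, mask: VoxelMask, bin_width: float = DEFAULT_BIN_WIDTH_GY) -> DVH:
    """Exact voxel-counting cumulative DVH (no intra-voxel interpolation)."""
    if dose.values.shape != mask.flags.shape:
        raise ValueError("dose grid and mask are on different geometries")
    doses = dose.values[mask.flags]
    if doses.size == 0:
        raise ValueError("empty structure mask")
    dmax = float(doses.max())
    n_bins = int(np.ceil(dmax / bin_width)) + 2
    edges = np.arange(n_bins) * bin_width
    sorted_d = np.sort(doses)
    # fraction receiving >= edge: voxels with dose >= edge
    n_below = np.searchsorted(sorted_d, edges, side="left")
    cum = (doses.size - n_below) / doses.size
    total = mask.voxel_count * float(np.prod(mask.spacing)) / 1000.0
    return DVH(mask.frame_id, edges, cum, total)


def dose_at_volume(dvh: DVH, p: float) -> float:
    """D_p%: minimum dose received by the hottest p% of the structure,
    linearly interpolated between DVH bins."""
    if not (0 < p <= 100):
        raise ValueError("volume percentage must be in (0, 100]")
    frac = p / 100.0
    cum, bins = dvh.cumulative_volume, dvh.dose_bins
    if frac > cum[0]:
        return float(bins[0])
    # last index where cum >= frac; interpolate down to the next bin
    i = int(np.max(np.nonzero(cum >= frac)[0]))
    c0, c1 = cum[i], cum[i + 1]
    if c0 == c1:
        return float(bins[i])
    t = (c0 - frac) / (c0 - c1)
    return float(bins[i] + t * (bins[i + 1] - bins[i]))


def volume_at_dose(dvh: DVH, d: float) -> float:
    """V_d: percentage of structure volume receiving >= d Gy."""
    if d < 0:
        raise ValueError("dose must be >= 0")
    bins, cum = dvh.dose_bins, dvh.cumulative_volume
    if d <= bins[0]:
        return 100.0 * float(cum[0])
    if d >= bins[-1]:
        return 100.0 * float(cum[-1])
    return 100.0 * float(np.interp(d, bins, cum))


@dataclass
class TargetIndices:
    """D-indices for one target structure, all in Gy."""

    D99: float
    D95: float
    Dmean: float
    D2: float
    Dmax: float

    def __post_init__(self):
        eps = 1e-9
        if not (self.D99 <= self.D95 + eps and self.D95 <= self.D2 + eps and self.D2 <= self.Dmax + eps):
            raise ValueError("target D-index ordering D99 <= D95 <= D2 <= Dmax violated")

    def as_dict(self) -> dict[str, float]:
        return {"D99": self.D99, "D95": self.D95, "Dmean": self.Dmean, "D2": self.D2, "Dmax": self.Dmax}


@dataclass
class DvhIndexSet:
    """All verification indices for one dose grid on one patient geometry.

    Missing structures leave their entries absent (``None``) rather than
    silently zero.
    """

    targets: dict[str, TargetIndices] = field(default_factory=dict)  # iGTV, PTV
    lung_V20Gy: float | None = None  # % of lung volume
    lung_V10Gy: float | None = None
    lung_V5Gy: float | None = None
    lung_Dmean: float | None = None  # Gy
    lung_volume_cm3: float | None = None
    cord_Dmax: float | None = None  # Gy
    isocenter_dose: float | None = None  # Gy

    def __post_init__(self):
        vs = (self.lung_V5Gy, self.lung_V10Gy, self.lung_V20Gy)
        if all(v is not None for v in vs):
            if not (vs[0] + 1e-9 >= vs[1] >= vs[2] - 1e-9):
                raise ValueError("lung volume ordering V5 >= V10 >= V20 violated")

    def flat(self) -> dict[str, float | None]:
        out: dict[str, float | None] = {"isocenter_dose": self.isocenter_dose}
        for label, t in self.targets.items():
            for k, v in t.as_dict().items():
                out[f"{label}_{k}"] = v
        out.update(
            {
                "lung_V20Gy": self.lung_V20Gy,
                "lung_V10Gy": self.lung_V10Gy,
                "lung_V5Gy": self.lung_V5Gy,
                "lung_Dmean": self.lung_Dmean,
                "cord_Dmax": self.cord_Dmax,
            }
        )
        return out


def _target_indices(dose: DoseGrid, mask: VoxelMask, bin_width: float) -> TargetIndices:
    dvh = cumulative_dvh(dose, mask, bin_width)
    vals = dose.values[mask.flags]
    dmax = float(vals.max())
    # bin interpolation can overshoot the hottest voxel by < one bin width
    return TargetIndices(
        D99=min(dose_at_volume(dvh, 99), dmax),
        D95=min(dose_at_volume(dvh, 95), dmax),
        Dmean=float(vals.mean()),
        D2=min(dose_at_volume(dvh, 2), dmax),
        Dmax=dmax,
    )


def dvh_index_set(
    dose: DoseGrid,
    masks: Mapping[str, VoxelMask],
    isocenter_mm: Sequence[float] | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH_GY,
) -> DvhIndexSet:
    """Compute the full verification index set for one dose grid.

    ``masks`` maps role names (iGTV, PTV, lung, spinal_cord) to voxel
    masks on the dose grid's geometry.  The lung used for V-indices is
    the lung mask minus the iGTV mask (normal lung tissue).
    """
    out = DvhIndexSet()
    for label in ("iGTV", "PTV"):
        if label in masks and masks[label].flags.any():
            out.targets[label] = _target_indices(dose, masks[label], bin_width)
    if "lung" in masks and masks["lung"].flags.any():
        lung = masks["lung"]
        if "iGTV" in masks:
            lung = lung.minus(masks["iGTV"])
        if lung.flags.any():
            dvh = cumulative_dvh(dose, lung, bin_width)
            out.lung_V20Gy = volume_at_dose(dvh, 20.0)
            out.lung_V10Gy = volume_at_dose(dvh, 10.0)
            out.lung_V5Gy = volume_at_dose(dvh, 5.0)
            out.lung_Dmean = float(dose.values[lung.flags].mean())
            out.lung_volume_cm3 = lung.volume_cm3
    if "spinal_cord" in masks and masks["spinal_cord"].flags.any():
        out.cord_Dmax = float(dose.values[masks["spinal_cord"].flags].max())
    if isocenter_mm is not None:
        out.isocenter_dose = point_dose(dose, isocenter_mm)
    return out


def dosimetric_error(d_stps: float, d_ptps: float) -> float:
    """DE (%) = (D_sTPS - D_pTPS) / D_pTPS * 100; negative when the
    secondary system reports less dose."""
    if d_ptps <= 0:
        raise ValueError("primary-TPS dose must be > 0")
    return (d_stps - d_ptps) / d_ptps * 100.0


def volume_error(v_stps: float, v_ptps: float) -> float:
    """VE (%) = (V_sTPS - V_pTPS) / V_pTPS * 100."""
    if v_ptps <= 0:
        raise ValueError("primary-TPS volume must be > 0")
    return (v_stps - v_ptps) / v_ptps * 100.0


@dataclass
class ErrorRecord:
    """Per-case DE/VE values in %, keyed by index name."""

    case_id: str
    DE: dict[str, float] = field(default_factory=dict)
    VE: dict[str, float] = field(default_factory=dict)


# dose-valued indices get a DE; volume-valued lung indices get a VE.
DE_INDEX_NAMES = (
    "isocenter_dose",
    "iGTV_D99",
    "iGTV_D95",
    "iGTV_Dmean",
    "iGTV_D2",
    "iGTV_Dmax",
    "PTV_D99",
    "PTV_D95",
    "PTV_Dmean",
    "PTV_D2",
    "PTV_Dmax",
    "cord_Dmax",
)
VE_INDEX_NAMES = ("lung_V20Gy", "lung_V10Gy", "lung_V5Gy", "lung_Dmean")


def error_record(
    ptps_indices: DvhIndexSet, stps_indices: DvhIndexSet, case_id: str = ""
) -> ErrorRecord:
    """Build the DE/VE record comparing secondary vs primary index sets."""
    p_flat, s_flat = ptps_indices.flat(), stps_indices.flat()
    rec = ErrorRecord(case_id=case_id)
    for name in DE_INDEX_NAMES:
        p, s = p_flat.get(name), s_flat.get(name)
        if p is not None and s is not None and p > 0:
            rec.DE[name] = dosimetric_error(s, p)
    for name in VE_INDEX_NAMES:
        p, s = p_flat.get(name), s_flat.get(name)
        if p is not None and s is not None and p > 0:
            rec.VE[name] = volume_error(s, p)
    return rec


def tolerance_level(errors: Sequence[float]) -> tuple[float, float]:
    """Cohort tolerance interval (mean - SD, mean + SD), sample SD (n-1)."""
    vals = np.asarray(errors, dtype=float)
    if vals.size < 2:
        raise ValueError("tolerance level needs at least 2 values")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return (mean - sd, mean + sd)


def classify_correlation(cc: float) -> str:
    """Strength classes on |CC|: <0.4 weak, [0.4, 0.8) moderate, >=0.8 strong."""
    a = abs(cc)
    if a >= 0.8:
        return "strong"
    if a >= 0.4:
        return "moderate"
    return "weak"


@dataclass(frozen=True)
class CorrelationResult:
    cc: float | None
    covariate_label: str
    strength: str
    p_value: float | None = None
    undefined: bool = False


def correlation_analysis(
    de_values: Sequence[float], covariates: Mapping[str, Sequence[float]]
) -> list[CorrelationResult]:
    """Pearson correlation of a DE series against each covariate series
    (PTV size, mean HU in PTV, SD of HU in PTV, ...)."""
    de = np.asarray(de_values, dtype=float)
    if de.size < 3:
        raise ValueError("correlation needs n >= 3")
    out = []
    for label, cov in covariates.items():
        x = np.asarray(cov, dtype=float)
        if x.size != de.size:
            raise ValueError(f"covariate {label!r} length mismatch")
        if np.std(de) == 0 or np.std(x) == 0:
            out.append(CorrelationResult(None, label, "undefined", undefined=True))
            continue
        r = stats.pearsonr(de, x)
        out.append(CorrelationResult(float(r.statistic), label, classify_correlation(r.statistic), float(r.pvalue)))
    return out


def paired_t_test(ptps_values: Sequence[float], stps_values: Sequence[float]):
    """Two-sided paired t-test p-value with a degenerate-case marker.

    Returns ``(p_value, significant)``; when the paired differences have
    zero variance the test is degenerate and ``(None, None)`` is
    returned instead of a number.
    """
    p = np.asarray(ptps_values, dtype=float)
    s = np.asarray(stps_values, dtype=float)
    if p.shape != s.shape or p.size < 2:
        raise ValueError("paired t-test needs equal-length samples, n >= 2")
    diffs = s - p
    if np.std(diffs, ddof=1) == 0:
        return None, None
    res = stats.ttest_rel(s, p)
    return float(res.pvalue), bool(res.pvalue < 0.05)
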