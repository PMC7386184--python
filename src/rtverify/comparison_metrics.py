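"""Point-wise dose comparison: dose-difference and gamma-index maps,
passing rates under a low-isodose threshold, and fail-point extraction.

Both 3-D dose grids and 2-D unwrapped cylindrical detector maps are
supported; detector maps are periodic along the azimuth (column) axis,
so the gamma distance search wraps around.

Normalization follows the global-difference convention: differences are
expressed in percent of a single normalization dose, by default the
maximum of the reference distribution, and only points where the
reference exceeds ``low_dose_threshold`` (default 10%) of that
normalization are evaluated.

The gamma search lattice is the evaluated distribution upsampled by an
integer per-axis factor ``ceil(spacing / (interp_step_fraction * distance
criterion))`` so every reference sample lies exactly on the lattice; the
exhaustive search covers lattice points within ``search_radius_factor *
distance_criterion``.  :func:`gamma_brute_force` re-derives the same
minimum per point with its own interpolation — it exists as an
independent oracle and shares no code with the optimized path beyond
the lattice definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from .dose_model import DoseGrid, GeometryError

__all__ = [
    "ComparisonCriteria",
    "ComparisonMap",
    "FailPointSet",
    "DetectorMap",
    "normalization_dose",
    "dose_difference_map",
    "gamma_map",
    "gamma_brute_force",
    "passing_rate",
    "extract_fail_points",
    "compare_on_detector",
    "parse_criteria",
    "DEFAULT_CRITERIA",
]


@dataclass(frozen=True)
class ComparisonCriteria:
    """A single comparison criterion (e.g. DD3% or gamma 3%/2 mm)."""

    dose_criterion: float  # % of normalization dose
    distance_criterion: float | None = None  # mm; None for pure dose difference
    mode: Literal["dose_difference", "gamma"] = "dose_difference"
    low_dose_threshold: float = 0.10  # fraction of normalization dose

    def __post_init__(self):
        if self.dose_criterion <= 0:
            raise ValueError("dose criterion must be > 0")
        if self.mode == "gamma" and (
            self.distance_criterion is None or self.distance_criterion <= 0
        ):
            raise ValueError("gamma mode needs a positive distance criterion")
        if not (0 <= self.low_dose_threshold < 1):
            raise ValueError("low-dose threshold must be in [0, 1)")

    @property
    def name(self) -> str:
        d = f"{self.dose_criterion:g}"
        if self.mode == "gamma":
            return f"g{d}%/{self.distance_criterion:g}mm"
        return f"DD{d}%"


def parse_criteria(spec: str) -> ComparisonCriteria:
    """Parse short criterion names: ``dd3``, ``dd5``, ``g2/2``, ``g3/2``, ``g3/3``."""
    s = spec.strip().lower()
    if s.startswith("dd"):
        return ComparisonCriteria(dose_criterion=float(s[2:]))
    if s.startswith("g"):
        dose, dist = s[1:].split("/")
        return ComparisonCriteria(
            dose_criterion=float(dose), distance_criterion=float(dist), mode="gamma"
        )
    raise ValueError(f"unrecognized criterion {spec!r}")


DEFAULT_CRITERIA = tuple(parse_criteria(s) for s in ("dd3", "dd5", "g2/2", "g3/2", "g3/3"))


@dataclass
class DetectorMap:
    """Dose samples on an unwrapped cylinder.

    Rows run along the cylinder axis (axial position), columns along the
    azimuth; column 0 is azimuth 0 and the column axis is periodic.
    ``diode_spacing`` is the axial pitch in mm; the azimuthal pitch is
    the arc length ``2*pi*radius / n_columns``.
    """

    values: np.ndarray
    diode_spacing: float
    cylinder_radius: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("detector map must be 2-D (axial x azimuth)")
        if self.diode_spacing <= 0 or self.cylinder_radius <= 0:
            raise ValueError("diode spacing and cylinder radius must be > 0")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("detector doses must be finite and >= 0")

    @property
    def arc_spacing(self) -> float:
        return 2.0 * math.pi * self.cylinder_radius / self.values.shape[1]

    @property
    def spacing(self) -> tuple[float, float]:
        return (self.diode_spacing, self.arc_spacing)

    def same_layout(self, other: "DetectorMap") -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.diode_spacing, other.diode_spacing)
            and math.isclose(self.cylinder_radius, other.cylinder_radius)
        )


@dataclass
class ComparisonMap:
    """Per-point comparison result on the reference layout.

    ``values`` is the dose difference in % of the normalization dose
    (mode ``dose_difference``) or the dimensionless gamma value;
    ``evaluated`` marks points above the low-dose threshold (and valid).
    """

    values: np.ndarray
    evaluated: np.ndarray
    criteria: ComparisonCriteria
    spacing: tuple[float, ...]
    wrap: tuple[bool, ...]
    norm_dose: float
    reference_label: str = "reference"
    evaluated_label: str = "evaluated"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.evaluated = np.asarray(self.evaluated, dtype=bool)
        if self.values.shape != self.evaluated.shape:
            raise ValueError("values/evaluated shape mismatch")

    @property
    def pass_mask(self) -> np.ndarray:
        limit = self.criteria.dose_criterion if self.criteria.mode == "dose_difference" else 1.0
        return self.evaluated & (self.values <= limit + 1e-12)

    def to_frame(self) -> pd.DataFrame:
        """Flat CSV-ready view: index, position (mm), value, evaluated, pass."""
        idx = np.arange(self.values.size)
        multi = np.unravel_index(idx, self.values.shape)
        cols = {"index": idx}
        for a, ax_idx in enumerate(multi):
            cols[f"position_mm_axis{a}"] = ax_idx * self.spacing[a]
        cols["value"] = self.values.ravel()
        cols["evaluated"] = self.evaluated.ravel()
        cols["pass"] = self.pass_mask.ravel()
        return pd.DataFrame(cols)


@dataclass
class FailPointSet:
    """Indices (flat, on the reference layout) failing a criterion."""

    indices: frozenset[int]
    criterion: ComparisonCriteria
    n_evaluated: int

    def __post_init__(self):
        self.indices = frozenset(int(i) for i in self.indices)
        if len(self.indices) > self.n_evaluated:
            raise ValueError("cannot have more fail points than evaluated points")

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _dist_layout(dist):
    """(values, spacing per axis, wrap per axis, valid mask) for a grid or map."""
    if isinstance(dist, DoseGrid):
        valid = dist.valid if dist.valid is not None else np.ones(dist.shape, bool)
        return dist.values, tuple(dist.spacing), (False, False, False), valid
    if isinstance(dist, DetectorMap):
        return dist.values, dist.spacing, (False, True), np.ones(dist.values.shape, bool)
    raise TypeError(f"expected DoseGrid or DetectorMap, got {type(dist).__name__}")


def _check_same_layout(ref, ev):
    if isinstance(ref, DoseGrid) and isinstance(ev, DoseGrid):
        if not ref.same_geometry(ev):
            raise GeometryError("dose grids differ in geometry; resample first")
    elif isinstance(ref, DetectorMap) and isinstance(ev, DetectorMap):
        if not ref.same_layout(ev):
            raise GeometryError("detector layouts differ")
    else:
        raise TypeError("reference and evaluated must be the same kind of distribution")


def normalization_dose(reference) -> float:
    """Global normalization dose: the maximum of the reference distribution."""
    values, *_ = _dist_layout(reference)
    if values.size == 0:
        raise ValueError("empty reference distribution")
    vmax = float(values.max())
    if vmax <= 0:
        raise ValueError("all-zero reference distribution has no normalization dose")
    return vmax


def dose_difference_map(
    reference, evaluated, criteria: ComparisonCriteria, norm: float | None = None
) -> ComparisonMap:
    """Global absolute dose-difference map in % of the normalization dose."""
    _check_same_layout(reference, evaluated)
    r_vals, spacing, wrap, r_valid = _dist_layout(reference)
    e_vals, _, _, e_valid = _dist_layout(evaluated)
    norm = normalization_dose(reference) if norm is None else float(norm)
    values = np.abs(e_vals - r_vals) / norm * 100.0
    eval_mask = (r_vals >= criteria.low_dose_threshold * norm) & r_valid & e_valid
    return ComparisonMap(values, eval_mask, criteria, spacing, wrap, norm)


def passing_rate(cmap: ComparisonMap) -> float:
    """Percentage of evaluated points passing the criterion."""
    n_eval = int(cmap.evaluated.sum())
    if n_eval == 0:
        raise ValueError("no evaluated points above the low-dose threshold")
    return 100.0 * int(cmap.pass_mask.sum()) / n_eval


def extract_fail_points(cmap: ComparisonMap, criteria: ComparisonCriteria | None = None) -> FailPointSet:
    """Flat indices of evaluated points that fail the criterion."""
    if criteria is not None and criteria != cmap.criteria:
        raise ValueError("criteria do not match the map they produced")
    fails = np.flatnonzero(cmap.evaluated.ravel() & ~cmap.pass_mask.ravel())
    return FailPointSet(frozenset(fails.tolist()), cmap.criteria, int(cmap.evaluated.sum()))


# ---------------------------------------------------------------------------
# Gamma search
# ---------------------------------------------------------------------------


def _lattice_factors(spacing, dist_crit: float, step_fraction: float):
    """Integer per-axis upsampling factors and resulting fine steps."""
    target = step_fraction * dist_crit
    factors = tuple(max(1, math.ceil(s / target - 1e-9)) for s in spacing)
    fine_steps = tuple(s / f for s, f in zip(spacing, factors))
    return factors, fine_steps


def _fine_lattice(values: np.ndarray, factors, wrap):
    """Upsample by trilinear interpolation onto the integer-refined lattice.

    Non-periodic axes get ``(n-1)*f + 1`` samples spanning the original
    extent; periodic axes get ``n*f`` samples covering one full period.
    """
    shape = values.shape
    axes = []
    fine_shape = []
    for n, f, w in zip(shape, factors, wrap):
        m = n * f if w else (n - 1) * f + 1
        axes.append(np.arange(m) / f)
        fine_shape.append(m)
    mesh = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([m.ravel() for m in mesh])
    mode = "grid-wrap" if any(wrap) else "nearest"
    fine = ndimage.map_coordinates(values, coords, order=1, mode=mode)
    return fine.reshape(fine_shape)


def _search_offsets(fine_steps, radius_mm: float):
    """All integer fine-lattice offsets within the search sphere, plus
    their squared physical distances, sorted by distance."""
    ranges = [int(math.floor(radius_mm / fs + 1e-9)) for fs in fine_steps]
    grids = np.meshgrid(*[np.arange(-r, r + 1) for r in ranges], indexing="ij")
    offsets = np.stack([g.ravel() for g in grids], axis=1)
    d2 = np.zeros(offsets.shape[0])
    for a, fs in enumerate(fine_steps):
        d2 += (offsets[:, a] * fs) ** 2
    keep = d2 <= radius_mm**2 + 1e-9
    offsets, d2 = offsets[keep], d2[keep]
    order = np.argsort(d2, kind="stable")
    return offsets[order], d2[order]


def _gamma_values(
    ref_vals: np.ndarray,
    eval_vals: np.ndarray,
    spacing,
    wrap,
    eval_mask: np.ndarray,
    delta_d: float,
    dist_crit: float,
    search_radius_factor: float,
    step_fraction: float,
) -> np.ndarray:
    """Optimized gamma: shared fine lattice, offsets processed in order of
    increasing distance with pruning once the distance term alone exceeds
    the worst remaining per-point best."""
    factors, fine_steps = _lattice_factors(spacing, dist_crit, step_fraction)
    fine = _fine_lattice(eval_vals, factors, wrap)
    fine_flat = fine.ravel()
    fine_shape = fine.shape
    strides = np.array(
        [int(np.prod(fine_shape[a + 1 :])) for a in range(len(fine_shape))], dtype=np.int64
    )

    pts = np.argwhere(eval_mask)
    out = np.full(ref_vals.shape, np.nan)
    if pts.size == 0:
        return out
    ref_at = ref_vals[tuple(pts.T)]
    base = pts * np.asarray(factors, dtype=np.int64)  # fine index of each ref point

    offsets, d2 = _search_offsets(fine_steps, search_radius_factor * dist_crit)
    dist_term = d2 / dist_crit**2

    # offset 0 is first: initialize with the pure dose-difference gamma
    best = ((fine_flat[(base * strides).sum(axis=1)] - ref_at) / delta_d) ** 2

    n_pts = base.shape[0]
    chunk = max(1, int(2_000_000 // max(n_pts, 1)))
    i = 1
    fine_dims = np.asarray(fine_shape, dtype=np.int64)
    while i < offsets.shape[0]:
        if dist_term[i] >= best.max() - 1e-15:
            break
        j = min(i + chunk, offsets.shape[0])
        # only points that can still improve need this shell
        active = np.flatnonzero(best > dist_term[i])
        idx = base[active, :, None] + offsets[i:j].T[None, :, :]  # (na, ndim, m)
        valid = np.ones((active.size, j - i), dtype=bool)
        flat = np.zeros((active.size, j - i), dtype=np.int64)
        for a in range(len(fine_shape)):
            ia = idx[:, a, :]
            if wrap[a]:
                ia = np.mod(ia, fine_dims[a])
            else:
                valid &= (ia >= 0) & (ia < fine_dims[a])
                ia = np.clip(ia, 0, fine_dims[a] - 1)
            flat += ia * strides[a]
        g2 = ((fine_flat[flat] - ref_at[active, None]) / delta_d) ** 2 + dist_term[i:j][None, :]
        g2 = np.where(valid, g2, np.inf)
        best[active] = np.minimum(best[active], g2.min(axis=1))
        i = j

    out[tuple(pts.T)] = np.sqrt(best)
    return out


def gamma_map(
    reference,
    evaluated,
    criteria: ComparisonCriteria,
    search_radius_factor: float = 3.0,
    interp_step_fraction: float = 0.1,
    norm: float | None = None,
) -> ComparisonMap:
    """Generalized gamma map with global dose normalization.

    gamma(r_ref) = min over search points r of
    sqrt(((D_eval(r) - D_ref(r_ref)) / dose_crit)^2 + (|r - r_ref| / dist_crit)^2)
    over the fine lattice within ``search_radius_factor * dist_crit``.
    """
    if criteria.mode != "gamma":
        raise ValueError("criteria.mode must be 'gamma'")
    if interp_step_fraction >= 1:
        import warnings

        warnings.warn("interp_step_fraction >= 1 gives a coarse gamma search", stacklevel=2)
    _check_same_layout(reference, evaluated)
    r_vals, spacing, wrap, r_valid = _dist_layout(reference)
    e_vals, _, _, e_valid = _dist_layout(evaluated)
    norm = normalization_dose(reference) if norm is None else float(norm)
    eval_mask = (r_vals >= criteria.low_dose_threshold * norm) & r_valid & e_valid

    delta_d = criteria.dose_criterion / 100.0 * norm
    values = _gamma_values(
        r_vals,
        e_vals,
        spacing,
        wrap,
        eval_mask,
        delta_d,
        criteria.distance_criterion,
        search_radius_factor,
        interp_step_fraction,
    )
    values = np.where(eval_mask, values, 0.0)
    return ComparisonMap(values, eval_mask, criteria, spacing, wrap, norm)


def _trilinear_at(values: np.ndarray, frac_idx: np.ndarray, wrap) -> np.ndarray:
    """Hand-rolled multilinear interpolation at fractional indices.

    ``frac_idx`` is (m, ndim); periodic axes wrap, others must be in
    range.  Used only by the brute-force oracle so it stays independent
    of scipy's interpolators.
    """
    ndim = values.ndim
    lo = np.floor(frac_idx).astype(np.int64)
    t = frac_idx - lo
    out = np.zeros(frac_idx.shape[0])
    for corner in range(2**ndim):
        w = np.ones(frac_idx.shape[0])
        idx = []
        for a in range(ndim):
            bit = (corner >> a) & 1
            ia = lo[:, a] + bit
            w = w * (t[:, a] if bit else 1.0 - t[:, a])
            if wrap[a]:
                ia = np.mod(ia, values.shape[a])
            else:
                ia = np.clip(ia, 0, values.shape[a] - 1)
            idx.append(ia)
        out += w * values[tuple(idx)]
    return out


def gamma_brute_force(
    reference,
    evaluated,
    criteria: ComparisonCriteria,
    search_radius_factor: float = 3.0,
    interp_step_fraction: float = 0.1,
    norm: float | None = None,
) -> np.ndarray:
    """Brute-force gamma oracle: per reference point, exhaustively
    minimize over every fine-lattice search position with independent
    interpolation.  Returns the gamma array (NaN where not evaluated).
    """
    if criteria.mode != "gamma":
        raise ValueError("criteria.mode must be 'gamma'")
    _check_same_layout(reference, evaluated)
    r_vals, spacing, wrap, r_valid = _dist_layout(reference)
    e_vals, _, _, e_valid = _dist_layout(evaluated)
    norm = normalization_dose(reference) if norm is None else float(norm)
    eval_mask = (r_vals >= criteria.low_dose_threshold * norm) & r_valid & e_valid

    dist_crit = criteria.distance_criterion
    delta_d = criteria.dose_criterion / 100.0 * norm
    factors, fine_steps = _lattice_factors(spacing, dist_crit, interp_step_fraction)
    offsets, d2 = _search_offsets(fine_steps, search_radius_factor * dist_crit)
    dist_term = d2 / dist_crit**2

    shape = np.asarray(r_vals.shape)
    out = np.full(r_vals.shape, np.nan)
    for pt in np.argwhere(eval_mask):
        cand = pt[None, :] * np.asarray(factors) + offsets  # fine-lattice indices
        frac = cand / np.asarray(factors, dtype=np.float64)  # original-grid index coords
        ok = np.ones(cand.shape[0], dtype=bool)
        for a in range(len(shape)):
            if not wrap[a]:
                ok &= (frac[:, a] >= 0) & (frac[:, a] <= shape[a] - 1)
        dose = _trilinear_at(e_vals, frac[ok], wrap)
        g2 = ((dose - r_vals[tuple(pt)]) / delta_d) ** 2 + dist_term[ok]
        out[tuple(pt)] = math.sqrt(g2.min())
    return out


def compare_on_detector(
    reference: DetectorMap,
    evaluated: DetectorMap,
    criteria: ComparisonCriteria,
    **gamma_kwargs,
) -> ComparisonMap:
    """DD or gamma analysis on unwrapped cylindrical detector maps; the
    azimuth axis is treated as periodic in the gamma distance search."""
    if not isinstance(reference, DetectorMap) or not isinstance(evaluated, DetectorMap):
        raise TypeError("compare_on_detector expects DetectorMap inputs")
    if not reference.same_layout(evaluated):
        raise GeometryError("mismatched detector layouts")
    if criteria.mode == "gamma":
        return gamma_map(reference, evaluated, criteria, **gamma_kwargs)
    return dose_difference_map(reference, evaluated, criteria)
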