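"""Heavy-ion dosimetry: fluence/LET/dose conversion and beam-range geometry.

Absorbed dose for a monoenergetic, unidirectional ion beam traversing thin
tissue is the product of particle fluence and linear energy transfer (LET),

    D [Gy] = Phi [/cm^2] * LET [keV/um] * 1.0e7 [um cm^2 / kg] * 1.602e-16 [J/keV]

which is the standard track-segment dose formula.  The module also provides
a parametric depth-LET (Bragg) profile pinned to four measurable constants
(surface LET, peak LET, range, peak width), a Bragg-Kleeman range estimate
for ions in water, and ray-cast geometry that determines which part of an
oval body cross-section a beam of given range irradiates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "BeamSpec",
    "DepthLETProfile",
    "CrossSection",
    "IrradiationPlan",
    "fluence_to_dose",
    "dose_to_fluence",
    "parametric_bragg_profile",
    "ion_range_water",
    "irradiated_mask",
    "fraction_irradiated",
    "beam_from_dict",
    "plan_from_dict",
]

#: keV -> J times um*cm^2/kg unit bridge; the two constants of the dose formula.
_KEV_TO_J = 1.602e-16
_UNIT_BRIDGE = 1.0e7

Direction = Literal["dorsal", "ventral", "lateral-left", "lateral-right"]
_DIRECTIONS = ("dorsal", "ventral", "lateral-left", "lateral-right")


@dataclass(frozen=True)
class BeamSpec:
    """Constants of an accelerated ion beam.

    Parameters
    ----------
    ion_label:
        Human-readable species tag, e.g. ``"12C6+"``.
    mass_number, atomic_number:
        A and Z of the ion.
    energy_per_nucleon:
        Specific kinetic energy in MeV/u.
    surface_let:
        LET at the body surface, keV/um.
    dose_rate_min, dose_rate_max:
        Delivered dose-rate interval, Gy/s.
    """

    ion_label: str
    mass_number: int
    atomic_number: int
    energy_per_nucleon: float
    surface_let: float
    dose_rate_min: float = 0.0
    dose_rate_max: float = 0.0

    def __post_init__(self) -> None:
        if self.mass_number < 1 or self.atomic_number < 1:
            raise ValueError("mass_number and atomic_number must be positive")
        if self.atomic_number > self.mass_number:
            raise ValueError("atomic_number cannot exceed mass_number")
        if self.energy_per_nucleon < 0:
            raise ValueError("energy_per_nucleon must be >= 0")
        if self.surface_let <= 0:
            raise ValueError("surface_let must be > 0")
        if self.dose_rate_min < 0 or self.dose_rate_max < 0:
            raise ValueError("dose rates must be >= 0")
        if self.dose_rate_min > self.dose_rate_max:
            raise ValueError("dose_rate_min must be <= dose_rate_max")


@dataclass(frozen=True)
class DepthLETProfile:
    """LET as a function of depth in water-equivalent tissue.

    ``depths`` (mm) is strictly increasing and starts at 0; ``let_values``
    (keV/um) is zero beyond ``range_mm``.  ``let_at`` interpolates linearly
    and returns 0 past the range.
    """

    depths: np.ndarray
    let_values: np.ndarray
    range_mm: float

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        lets = np.asarray(self.let_values, dtype=float)
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "let_values", lets)
        if depths.ndim != 1 or depths.size < 2:
            raise ValueError("need at least two depth samples")
        if depths[0] != 0.0 or np.any(np.diff(depths) <= 0):
            raise ValueError("depths must be strictly increasing from 0")
        if lets.shape != depths.shape:
            raise ValueError("let_values must match depths in length")
        if np.any(lets < 0):
            raise ValueError("LET values must be >= 0")
        if self.range_mm <= 0:
            raise ValueError("range_mm must be > 0")
        if np.any(lets[depths > self.range_mm] != 0.0):
            raise ValueError("LET must be 0 beyond range_mm")

    def let_at(self, depth_mm: float | np.ndarray) -> float | np.ndarray:
        """Linearly interpolated LET (keV/um) at a depth in mm; 0 past range."""
        d = np.asarray(depth_mm, dtype=float)
        out = np.interp(d, self.depths, self.let_values, left=self.let_values[0], right=0.0)
        out = np.where(d > self.range_mm, 0.0, out)
        return float(out) if np.isscalar(depth_mm) else out

    @property
    def peak_depth_mm(self) -> float:
        return float(self.depths[int(np.argmax(self.let_values))])

    @property
    def peak_let(self) -> float:
        return float(np.max(self.let_values))

    def to_csv(self, path) -> None:
        """Write the profile as two-column CSV (depth_mm, let_kev_um)."""
        arr = np.column_stack([self.depths, self.let_values])
        np.savetxt(path, arr, delimiter=",", header="depth_mm,let_kev_um", comments="")

    @classmethod
    def from_csv(cls, path) -> "DepthLETProfile":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        depths, lets = arr[:, 0], arr[:, 1]
        nz = np.nonzero(lets > 0)[0]
        range_mm = float(depths[nz[-1]]) if nz.size else float(depths[-1])
        return cls(depths=depths, let_values=lets, range_mm=range_mm)


@dataclass(frozen=True)
class CrossSection:
    """Transverse body cross-section, dorsal side up (row 0 side).

    Either an axis-aligned ellipse (``half_width_mm``, ``half_height_mm``)
    or a simple closed ``polygon_mm`` of (y, x) vertices in mm with y
    increasing ventrally from the dorsal-most extent.
    """

    half_width_mm: float | None = None
    half_height_mm: float | None = None
    polygon_mm: Sequence[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.polygon_mm is None:
            if self.half_width_mm is None or self.half_height_mm is None:
                raise ValueError("give half_width_mm/half_height_mm or polygon_mm")
            if self.half_width_mm <= 0 or self.half_height_mm <= 0:
                raise ValueError("ellipse half-axes must be positive")
        else:
            poly = np.asarray(self.polygon_mm, dtype=float)
            if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
                raise ValueError("polygon needs >= 3 (y, x) vertices")
            if _polygon_self_intersects(poly):
                raise ValueError("polygon must be simple (non-self-intersecting)")

    @property
    def height_mm(self) -> float:
        if self.polygon_mm is None:
            return 2.0 * self.half_height_mm  # type: ignore[operator]
        poly = np.asarray(self.polygon_mm, dtype=float)
        return float(poly[:, 0].max() - poly[:, 0].min())

    @property
    def width_mm(self) -> float:
        if self.polygon_mm is None:
            return 2.0 * self.half_width_mm  # type: ignore[operator]
        poly = np.asarray(self.polygon_mm, dtype=float)
        return float(poly[:, 1].max() - poly[:, 1].min())

    def contains(self, y_mm: np.ndarray, x_mm: np.ndarray) -> np.ndarray:
        """Boolean membership for points given in the section's mm frame.

        The frame has its origin at the dorsal-left corner of the bounding
        box: y grows ventrally, x to the right.
        """
        if self.polygon_mm is None:
            a = self.half_width_mm
            b = self.half_height_mm
            return ((x_mm - a) / a) ** 2 + ((y_mm - b) / b) ** 2 <= 1.0
        from shapely import contains_xy
        from shapely.geometry import Polygon

        poly = np.asarray(self.polygon_mm, dtype=float)
        shifted = poly - poly.min(axis=0)
        geom = Polygon(shifted[:, ::-1])  # shapely wants (x, y)
        hit = contains_xy(geom.buffer(1e-12), np.ravel(x_mm), np.ravel(y_mm))
        return hit.reshape(np.shape(y_mm))


def _polygon_self_intersects(poly: np.ndarray) -> bool:
    """Brute-force segment intersection check for small polygons."""
    n = poly.shape[0]
    segs = [(poly[i], poly[(i + 1) % n]) for i in range(n)]

    def cross2(u, v):
        return u[0] * v[1] - u[1] * v[0]

    def crosses(p1, p2, p3, p4):
        d1 = cross2(p4 - p3, p1 - p3)
        d2 = cross2(p4 - p3, p2 - p3)
        d3 = cross2(p2 - p1, p3 - p1)
        d4 = cross2(p2 - p1, p4 - p1)
        return (d1 * d2 < 0) and (d3 * d4 < 0)

    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through the wrap
            if crosses(*segs[i], *segs[j]):
                return True
    return False


@dataclass(frozen=True)
class IrradiationPlan:
    """Beam entry direction, range in tissue and prescribed dose."""

    direction: Direction
    range_mm: float
    dose_gy: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}")
        if self.range_mm <= 0:
            raise ValueError("range_mm must be > 0")
        if self.dose_gy < 0:
            raise ValueError("dose_gy must be >= 0")


def fluence_to_dose(fluence: float, let: float) -> float:
    """Absorbed dose (Gy) from particle fluence (/cm^2) and LET (keV/um).

    Implements ``D = Phi * LET * 1.0e7 * 1.602e-16`` exactly; linear in both
    arguments.
    """
    if fluence < 0:
        raise ValueError("fluence must be >= 0")
    if let <= 0:
        raise ValueError("LET must be > 0")
    return fluence * let * _UNIT_BRIDGE * _KEV_TO_J


def dose_to_fluence(dose: float, let: float) -> float:
    """Particle fluence (/cm^2) delivering ``dose`` (Gy) at the given LET."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if let <= 0:
        raise ValueError("LET must be > 0")
    return dose / (let * _UNIT_BRIDGE * _KEV_TO_J)


def parametric_bragg_profile(
    range_mm: float,
    surface_let: float,
    peak_let: float,
    peak_width_mm: float,
    n_points: int = 2001,
) -> DepthLETProfile:
    """Fit-free depth-LET profile pinned to four beam constants.

    The profile interpolates between the measured surface LET and the Bragg
    peak: an entry plateau rising as a power law in residual range (pinned to
    ``surface_let`` at depth 0 and to half the peak just before the peak),
    topped by a Gaussian of FWHM ``peak_width_mm`` centered at
    ``range_mm - peak_width_mm / 2`` so the maximum equals ``peak_let``
    exactly; the distal side falls off as the same Gaussian and is cut to 0
    beyond the range (the distal dose edge of a monoenergetic beam is sharp
    on the sampling scale used here).
    """
    if not (0 < peak_width_mm < range_mm):
        raise ValueError("need 0 < peak_width_mm < range_mm")
    if not (0 < surface_let < peak_let):
        raise ValueError("need 0 < surface_let < peak_let")
    if n_points < 16:
        raise ValueError("n_points too small to resolve the peak")

    mu = range_mm - peak_width_mm / 2.0
    sigma = peak_width_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    # Sampling grid: uniform plus a refined band across the (narrow) peak,
    # with mu itself included so the maximum is pinned exactly.
    base = np.linspace(0.0, range_mm, n_points)
    fine = np.linspace(max(0.0, mu - 3 * peak_width_mm), range_mm, n_points // 4)
    depths = np.unique(np.concatenate([base, fine, [mu]]))

    # Plateau exponent chosen so the plateau alone reaches peak/2 at mu.
    resid = range_mm - depths
    resid_at_mu = peak_width_mm / 2.0
    p = np.log(0.5 * peak_let / surface_let) / np.log(range_mm / resid_at_mu)
    with np.errstate(divide="ignore"):
        plateau = surface_let * (range_mm / np.maximum(resid, resid_at_mu)) ** p
    gauss = np.exp(-0.5 * ((depths - mu) / sigma) ** 2)

    # plateau(mu) = peak/2 by construction, so the Gaussian tops up the rest.
    amplitude = peak_let - 0.5 * peak_let
    lets = np.where(depths <= mu, plateau + amplitude * gauss, peak_let * gauss)
    lets[depths.searchsorted(mu)] = peak_let

    # Append an explicit zero sample just past the range for interpolation.
    eps = range_mm * 1e-9
    depths = np.append(depths, range_mm + eps)
    lets = np.append(lets, 0.0)
    return DepthLETProfile(depths=depths, let_values=lets, range_mm=range_mm)


#: Bragg-Kleeman coefficients for protons in water: R[cm] = alpha * E[MeV]^p.
_BK_ALPHA_CM = 0.0022
_BK_P = 1.77


def ion_range_water(
    energy_per_nucleon: float, mass_number: int, atomic_number: int
) -> float:
    """Approximate CSDA range (mm) of an ion in water.

    Uses the Bragg-Kleeman power law for protons, ``R_p = 0.0022 E^1.77`` cm,
    scaled by ``A / Z^2`` (ions of equal velocity share the proton's range per
    unit A/Z^2).  Accuracy is of order +/-15%; a transport-code range is the
    reference where available.
    """
    if mass_number < 1 or atomic_number < 1:
        raise ValueError("mass_number and atomic_number must be positive")
    if energy_per_nucleon < 0:
        raise ValueError("energy_per_nucleon must be >= 0")
    proton_range_cm = _BK_ALPHA_CM * energy_per_nucleon**_BK_P
    return proton_range_cm * (mass_number / atomic_number**2) * 10.0


def irradiated_mask(
    cross_section: CrossSection,
    plan: IrradiationPlan,
    grid_resolution: float,
) -> np.ndarray:
    """Boolean mask of the irradiated part of a body cross-section.

    The beam is a parallel ray bundle entering from ``plan.direction``.  A
    pixel (center) is irradiated iff it lies inside the cross-section and its
    depth along the beam axis, measured from the entry surface on that ray,
    is <= ``plan.range_mm`` (closed interval, so the mask is monotone in
    range).  Row 0 is the dorsal side.
    """
    if grid_resolution <= 0:
        raise ValueError("grid_resolution must be > 0")
    h_mm = cross_section.height_mm
    w_mm = cross_section.width_mm
    n_rows = max(1, int(np.ceil(h_mm / grid_resolution)))
    n_cols = max(1, int(np.ceil(w_mm / grid_resolution)))
    y = (np.arange(n_rows) + 0.5) * grid_resolution
    x = (np.arange(n_cols) + 0.5) * grid_resolution
    yy, xx = np.meshgrid(y, x, indexing="ij")
    inside = cross_section.contains(yy, xx)
    if not inside.any():
        raise ValueError("cross-section is empty on this grid")

    # Orient so the beam travels down increasing row index, ray per column.
    flips: dict[str, int] = {"dorsal": 0, "ventral": 1, "lateral-left": 2, "lateral-right": 3}
    mode = flips[plan.direction]
    work = inside
    if mode == 1:
        work = inside[::-1, :]
    elif mode == 2:
        work = inside.T
    elif mode == 3:
        work = inside.T[::-1, :]

    rows = np.arange(work.shape[0])[:, None]
    has_entry = work.any(axis=0)
    entry = np.where(has_entry, work.argmax(axis=0), 0)
    depth_mm = (rows - entry[None, :]) * grid_resolution
    irr = work & (depth_mm <= plan.range_mm) & has_entry[None, :]

    if mode == 1:
        irr = irr[::-1, :]
    elif mode == 2:
        irr = irr.T
    elif mode == 3:
        irr = irr[::-1, :].T
    return irr


def beam_from_dict(cfg: dict) -> BeamSpec:
    """Build a :class:`BeamSpec` from a config mapping with unit-bearing keys.

    Expected keys: ``ion_label``, ``mass_number``, ``atomic_number``,
    ``energy_mev_per_u``, ``surface_let_kev_um``, optional
    ``dose_rate_gy_s_min`` / ``dose_rate_gy_s_max``.
    """
    return BeamSpec(
        ion_label=cfg["ion_label"],
        mass_number=int(cfg["mass_number"]),
        atomic_number=int(cfg["atomic_number"]),
        energy_per_nucleon=float(cfg["energy_mev_per_u"]),
        surface_let=float(cfg["surface_let_kev_um"]),
        dose_rate_min=float(cfg.get("dose_rate_gy_s_min", 0.0)),
        dose_rate_max=float(cfg.get("dose_rate_gy_s_max", 0.0)),
    )


def plan_from_dict(cfg: dict) -> IrradiationPlan:
    """Build an :class:`IrradiationPlan` from ``direction`` / ``range_mm`` / ``dose_gy``."""
    return IrradiationPlan(
        direction=cfg["direction"],
        range_mm=float(cfg["range_mm"]),
        dose_gy=float(cfg.get("dose_gy", 0.0)),
    )


def fraction_irradiated(organ_mask: np.ndarray, irradiated: np.ndarray) -> float:
    """Fraction of organ pixels lying inside the irradiated region."""
    organ = np.asarray(organ_mask, dtype=bool)
    irr = np.asarray(irradiated, dtype=bool)
    if organ.shape != irr.shape:
        raise ValueError("masks must share the same grid")
    n_organ = int(organ.sum())
    if n_organ == 0:
        raise ValueError("organ mask is empty")
    return float((organ & irr).sum() / n_organ)
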