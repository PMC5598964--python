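"""Hierarchical liver-lobule geometry.

The liver is modelled as a large number of identical hexagonal lobules.
Each hexagon is replaced by a disc of equal area and, by six-fold symmetry,
only one sector is constructed explicitly.  Starting from the periphery,
sinusoids run toward the central vein and merge pairwise, producing a
hierarchy of levels: within a level the sinusoid radius shrinks linearly to
the minimal radius ``R_sin``; at a merge the flow doubles and the radius
jumps back up.  The construction is driven by four measured lengths (lobule
radius, minimal sinusoid radius, lobule thickness and hepatocyte radius)
and by packing constraints between hepatocyte plates.

Internal units: lengths in micrometres (um), volumes in litres (L), flows in
L/h, surfaces in dm^2.  Conversions: 1 L = 1e15 um^3, 1 dm^2 = 1e10 um^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

UM3_PER_L = 1e15
UM2_PER_DM2 = 1e10

#: half opening angle of a hexagon sector (60 degrees)
THETA0 = np.pi / 3.0

_MAX_LEVELS = 64


class GeometryError(ValueError):
    """Raised when lobule parameters produce an implausible construction."""


@dataclass(frozen=True)
class LobuleParams:
    """Physiological dimensions of a liver lobule and whole-liver scalars.

    Parameters
    ----------
    lobule_radius
        Hexagon (circumscribed) radius of a lobule, um.
    min_sinusoid_radius
        Minimal sinusoid radius reached at the downstream end of every
        level, um.
    lobule_thickness
        Thickness of the lobule slab, um.  Must exceed one hepatocyte
        plate width, otherwise no blood channel remains.
    hepatocyte_radius
        Radius of a hepatocyte, um.  The plate width is twice this value.
    liver_volume
        Whole-liver volume, L.
    liver_blood_flow
        Whole-liver blood flow, L/h.
    cell_volume
        Hepatocyte volume, uL per 1e6 cells.
    liver_mass
        Liver mass in g, used only to report cells per gram.
    """

    lobule_radius: float = 790.57
    min_sinusoid_radius: float = 3.65
    lobule_thickness: float = 25.0
    hepatocyte_radius: float = 8.49
    liver_volume: float = 1.69
    liver_blood_flow: float = 87.0
    cell_volume: float = 4.0
    liver_mass: float = 1800.0

    @property
    def plate_width(self) -> float:
        """Hepatocyte plate width e = 2 R_H, um."""
        return 2.0 * self.hepatocyte_radius

    def __post_init__(self) -> None:
        for name in ("lobule_radius", "min_sinusoid_radius",
                     "lobule_thickness", "hepatocyte_radius",
                     "liver_volume", "liver_blood_flow", "cell_volume",
                     "liver_mass"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be > 0")
        if self.lobule_thickness <= self.plate_width:
            raise GeometryError(
                "lobule_thickness must exceed the hepatocyte plate width "
                "(2*hepatocyte_radius); no blood channel cross-section left")


@dataclass
class LobuleGeometry:
    """Constructed sinusoid hierarchy with derived whole-liver quantities.

    Levels are numbered in flow order: level 1 is the furthest from the
    central vein (periphery), level ``n_levels`` drains into it.
    ``theta[k-1]`` is the half-angle associated with level k, i.e. the
    construction angle ``theta_{n-k+1}``.
    """

    params: LobuleParams
    n_levels: int
    disc_radius: float                      # R_Circle, um
    outputs_x: np.ndarray                   # raw x_0..x_n from the centre, um
    plates_y: np.ndarray                    # raw y_0..y_n from the centre, um
    level_lengths: np.ndarray               # L_1..L_n in flow order, um
    cum_lengths: np.ndarray                 # [0, L_1, L_1+L_2, ...], um
    theta: np.ndarray                       # per-level angle, rad
    lobule_volume: float = 0.0              # um^3
    n_lobules: float = 0.0
    blood_volume: float = 0.0               # mL
    hepatocyte_volume: float = 0.0          # mL
    exchange_surface: float = 0.0           # dm^2
    n_cells: float = 0.0
    cells_per_gram: float = 0.0
    _level_counts: np.ndarray = field(default_factory=lambda: np.array([]))

    # ------------------------------------------------------------------
    # profile helpers
    # ------------------------------------------------------------------
    @property
    def total_length(self) -> float:
        """Total sinusoid path length from periphery to central vein, um."""
        return float(self.cum_lengths[-1])

    @property
    def lobule_flow(self) -> float:
        """Blood flow through a single lobule, L/h."""
        return self.params.liver_blood_flow / self.n_lobules

    def sinusoids_per_lobule(self, level: int) -> int:
        """Number of parallel sinusoids of ``level`` (1-based) per lobule."""
        return 6 * 2 ** (self.n_levels - level)

    def level_of(self, x) -> np.ndarray:
        """1-based level index containing path position ``x`` (um)."""
        x = np.asarray(x, dtype=float)
        self._check_range(x)
        # boundaries belong to the upstream level, except x = 0
        idx = np.searchsorted(self.cum_lengths[1:-1], x, side="left") + 1
        return np.where(x == 0.0, 1, idx)

    def _check_range(self, x: np.ndarray) -> None:
        if np.any(x < 0) or np.any(x > self.total_length + 1e-9):
            raise ValueError(
                f"position outside the sinusoid path [0, {self.total_length:.2f}] um")

    def _local(self, x):
        """Return (level array, local coordinate within the level)."""
        lev = self.level_of(x)
        x = np.asarray(x, dtype=float)
        return lev, x - self.cum_lengths[lev - 1]

    def radius_at(self, x) -> np.ndarray:
        """Sinusoid radius R(x), um.

        Within a level the radius decreases linearly to ``R_sin`` at the
        downstream end; it jumps upward across a merge.
        """
        lev, xloc = self._local(x)
        L = self.level_lengths[lev - 1]
        th = self.theta[lev - 1]
        return self.params.min_sinusoid_radius + (L - xloc) * np.tan(th)

    def flow_at(self, x) -> np.ndarray:
        """Blood flow of a single sinusoid at ``x``, L/h (constant per level)."""
        lev, _ = self._local(x)
        counts = np.array([self.sinusoids_per_lobule(int(k)) for k in np.atleast_1d(lev)])
        q = self.lobule_flow / counts
        return q if np.ndim(x) else float(q[0])

    def cross_section_at(self, x, kind: str = "rect") -> np.ndarray:
        """Sinusoid cross-section area, um^2.

        ``kind='rect'`` uses the rectangular channel R(x)(e_L - 2 R_H)
        consistent with the elementary blood volume; ``kind='circular'``
        uses pi R(x)^2 (kept as a sensitivity option).
        """
        r = self.radius_at(x)
        if kind == "rect":
            return r * (self.params.lobule_thickness - 2 * self.params.hepatocyte_radius)
        if kind == "circular":
            return np.pi * r ** 2
        raise ValueError("kind must be 'rect' or 'circular'")

    def velocity_at(self, x, kind: str = "rect") -> np.ndarray:
        """Average blood velocity, um/h: per-sinusoid flow over cross-section."""
        q = np.asarray(self.flow_at(x), dtype=float) * UM3_PER_L
        return q / self.cross_section_at(x, kind=kind)

    # ------------------------------------------------------------------
    # blood <-> hepatocyte exchange ratios
    # ------------------------------------------------------------------
    def alpha_b_to_h(self, x) -> np.ndarray:
        """Exchange surface per unit blood volume, 1/um."""
        r = self.radius_at(x)
        lev, _ = self._local(x)
        cos_t = np.cos(self.theta[lev - 1])
        eL = self.params.lobule_thickness
        gap = eL - 2 * self.params.hepatocyte_radius
        return (2 * r + gap * cos_t) / (r * gap)

    def alpha_h_to_b(self, x) -> np.ndarray:
        """Exchange surface per unit hepatocyte volume, 1/um."""
        r = self.radius_at(x)
        lev, _ = self._local(x)
        cos_t = np.cos(self.theta[lev - 1])
        eL = self.params.lobule_thickness
        gap = eL - 2 * self.params.hepatocyte_radius
        rh = self.params.hepatocyte_radius
        return (2 * r + gap * cos_t) / (rh * (2 * r + eL * cos_t))

    # ------------------------------------------------------------------
    # closed-form elementary integrals (per single sinusoid, local coords)
    # ------------------------------------------------------------------
    def _int_radius(self, level: int, a: float, b: float) -> float:
        """Integral of R over [a, b] of a level (local coordinates), um^2."""
        L = self.level_lengths[level - 1]
        th = self.theta[level - 1]
        rs = self.params.min_sinusoid_radius
        return rs * (b - a) + 0.5 * np.tan(th) * ((L - a) ** 2 - (L - b) ** 2)

    def segment_blood_volume(self, level: int, a: float, b: float) -> float:
        """Blood volume of one sinusoid segment, um^3 (dV_b = 2 R (e_L - 2R_H) dx)."""
        gap = self.params.lobule_thickness - 2 * self.params.hepatocyte_radius
        return 2.0 * gap * self._int_radius(level, a, b)

    def segment_hepatocyte_volume(self, level: int, a: float, b: float) -> float:
        """Hepatocyte volume flanking one segment, um^3
        (dV_h = 2 R_H (2 R + e_L cos(theta)) dx)."""
        th = self.theta[level - 1]
        eL = self.params.lobule_thickness
        rh = self.params.hepatocyte_radius
        return 2.0 * rh * (2.0 * self._int_radius(level, a, b)
                           + eL * np.cos(th) * (b - a))

    def segment_exchange_surface(self, level: int, a: float, b: float) -> float:
        """Blood-hepatocyte contact surface of one segment, um^2
        (dS = 2 (2 R + (e_L - 2R_H) cos(theta)) dx)."""
        th = self.theta[level - 1]
        gap = self.params.lobule_thickness - 2 * self.params.hepatocyte_radius
        return 2.0 * (2.0 * self._int_radius(level, a, b)
                      + gap * np.cos(th) * (b - a))


def build_lobule(params: LobuleParams | None = None) -> LobuleGeometry:
    """Construct the sinusoid hierarchy from physiological dimensions.

    The hexagon is replaced by a disc of equal area; hepatocyte plates and
    sinusoid outputs are placed iteratively outward, halving the opening
    angle at every generation, until the next output would fall outside the
    disc.  Levels are then renumbered so that level 1 is at the periphery,
    and level lengths follow ``L_k = min(y_{n-k+1}, R_circle) - x_{n-k}``,
    the disc radius truncating the outermost level.
    """
    if params is None:
        params = LobuleParams()
    rs = params.min_sinusoid_radius
    half_plate = params.plate_width / 2.0

    # disc of same area as the hexagon: pi R_circle^2 = (3 sqrt(3)/2) R_lobule^2
    r_circle = params.lobule_radius * np.sqrt(1.5 * np.sqrt(3.0) / np.pi)

    def theta_k(k: int) -> float:
        return THETA0 / 2.0 ** k

    xs = [rs / np.tan(theta_k(1)) + half_plate / np.sin(theta_k(1))]
    ys = [rs / np.sin(theta_k(1)) + half_plate / np.tan(theta_k(1))]
    if xs[0] > r_circle:
        raise GeometryError("lobule too small: no sinusoid level fits in the disc")

    k = 0
    while xs[k] <= r_circle:
        k += 1
        if k > _MAX_LEVELS:
            raise GeometryError(
                "placement loop did not terminate; implausible lobule parameters")
        xs.append(rs / np.tan(theta_k(k + 1)) + half_plate / np.sin(theta_k(k + 1)))
        ys.append(rs / np.sin(theta_k(k + 1)) + half_plate / np.tan(theta_k(k + 1)))
    n = k

    xs = np.asarray(xs)
    ys = np.asarray(ys)
    # flow-ordered lengths: level 1 at the periphery
    lengths = np.array([min(ys[n - k + 1], r_circle) - xs[n - k]
                        for k in range(1, n + 1)])
    if np.any(lengths <= 0):
        raise GeometryError("non-positive level length; implausible parameters")
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    theta = np.array([theta_k(n - k + 1) for k in range(1, n + 1)])

    geom = LobuleGeometry(
        params=params, n_levels=n, disc_radius=r_circle,
        outputs_x=xs, plates_y=ys, level_lengths=lengths,
        cum_lengths=cum, theta=theta,
    )
    geom._level_counts = np.array([geom.sinusoids_per_lobule(k)
                                   for k in range(1, n + 1)])
    return derived_quantities(geom, params)


def derived_quantities(geom: LobuleGeometry, params: LobuleParams) -> LobuleGeometry:
    """Populate whole-liver volumes, exchange surface and cell counts.

    All per-level integrals are polynomials in x and are evaluated in
    closed form; no numerical quadrature is involved.
    """
    geom.lobule_volume = np.pi * geom.disc_radius ** 2 * params.lobule_thickness
    geom.n_lobules = params.liver_volume * UM3_PER_L / geom.lobule_volume

    vb = vh = sx = 0.0
    for k in range(1, geom.n_levels + 1):
        count = geom.sinusoids_per_lobule(k)
        L = geom.level_lengths[k - 1]
        vb += count * geom.segment_blood_volume(k, 0.0, L)
        vh += count * geom.segment_hepatocyte_volume(k, 0.0, L)
        sx += count * geom.segment_exchange_surface(k, 0.0, L)

    geom.blood_volume = vb * geom.n_lobules / UM3_PER_L * 1e3        # mL
    geom.hepatocyte_volume = vh * geom.n_lobules / UM3_PER_L * 1e3   # mL
    geom.exchange_surface = sx * geom.n_lobules / UM2_PER_DM2        # dm^2
    # cell_volume is uL per 1e6 cells -> cells = V_h[uL] / V_cell * 1e6
    geom.n_cells = geom.hepatocyte_volume * 1e3 / params.cell_volume * 1e6
    geom.cells_per_gram = geom.n_cells / params.liver_mass
    return geom
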