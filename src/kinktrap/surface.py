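"""Geometric charge model of the two-layer lamellar film.

The film that templates the DNA is a two-layer system: a highly ordered
epitaxial lamellar sublayer of rod-like amphiphiles packed side by side
(each lamella presents two parallel rows of positive terminal amines,
~4 nm apart, with the lamellar pattern repeating at ~7 nm), and above
it a poorly ordered granular adlayer of polydisperse oligomers of the
same molecule.  The sublayer makes the surface charge one-dimensionally
periodic; the adlayer perturbs but does not erase that pattern.

Coordinates are 2D in-plane nm.  Rows run along the x-axis; the
template repeats along y.  The DNA rides at a fixed closest-approach
height above the charge plane, which enters all screened distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import k0, k1

from .electrostatics import DivergentTorqueError, ElectrostaticParams

__all__ = [
    "LamellarTemplate",
    "GrainField",
    "SurfaceChargeField",
    "build_template",
    "sample_adlayer",
    "lateral_force_at",
    "incommensurability_ratio",
]

GA_MOLECULE_LENGTH_NM = 4.0  # fixed short grain dimension
AMINES_PER_MOLECULE = 2      # two terminal amino groups per molecule


@dataclass
class LamellarTemplate:
    """One-dimensionally periodic lamellar charge pattern.

    ``period`` is the lamellar repeat (~7 nm); each lamella carries two
    amine rows ``row_pair_separation`` (~4 nm) apart, so row offsets
    along y are {0, 4, 7, 11, 14, ...} at defaults.  ``orientation`` is
    the row direction in the laboratory frame; with ``sixfold`` set the
    allowed orientations form the 60-degree-symmetric epitaxial set.
    """

    period: float = 7.0
    row_pair_separation: float = 4.0
    b_row: float = 0.53
    orientation: float = 0.0
    sixfold: bool = False
    extent: float = 300.0

    def __post_init__(self) -> None:
        if not 0 < self.row_pair_separation < self.period:
            raise ValueError("need 0 < row_pair_separation < period")
        if self.b_row <= 0 or self.extent <= 0:
            raise ValueError("b_row and extent must be positive")

    def allowed_orientations(self) -> np.ndarray:
        """Sixfold-symmetric orientation set (degrees) when epitaxial."""
        if not self.sixfold:
            return np.array([self.orientation])
        return (self.orientation + 60.0 * np.arange(6)) % 360.0

    def row_offsets(self, half_width: float | None = None) -> np.ndarray:
        """Transverse row positions (nm) covering +-half_width."""
        if half_width is None:
            half_width = self.extent
        k = np.arange(math.floor(-half_width / self.period) - 1,
                      math.ceil(half_width / self.period) + 2)
        offsets = np.sort(np.concatenate(
            [k * self.period, k * self.period + self.row_pair_separation]))
        return offsets[(offsets >= -half_width - self.period)
                       & (offsets <= half_width + self.period)]

    def charge_positions(self, half_width: float | None = None) -> np.ndarray:
        """Discrete amine charge coordinates, array of (x, y, q)."""
        if half_width is None:
            half_width = self.extent
        xs = np.arange(-half_width + self.b_row / 2, half_width, self.b_row)
        rows = self.row_offsets(half_width)
        x = np.tile(xs, len(rows))
        y = np.repeat(rows, len(xs))
        return np.stack([x, y, np.ones_like(x)], axis=1)


def build_template(period: float = 7.0, row_pair_separation: float = 4.0,
                   b_row: float = 0.53, orientation: float = 0.0,
                   extent: float = 300.0, sixfold: bool = False) -> LamellarTemplate:
    return LamellarTemplate(period=period, row_pair_separation=row_pair_separation,
                            b_row=b_row, orientation=orientation,
                            sixfold=sixfold, extent=extent)


@dataclass
class GrainField:
    """Polydisperse oligomer grains of the adlayer.

    Each grain is (center_x, center_y, aggregation_number, orientation,
    charge_e); the short grain dimension is fixed at the molecular
    length (~4 nm), the long one scales with the aggregation number.
    Grain charge is two terminal amines per constituent molecule.
    """

    grains: np.ndarray  # columns: x, y, n_agg, orientation_deg, charge_e
    seed: int = 0

    def __post_init__(self) -> None:
        self.grains = np.atleast_2d(np.asarray(self.grains, dtype=float))
        if self.grains.size and self.grains.shape[1] != 5:
            raise ValueError("grains need 5 columns (x, y, n, orient, q)")

    @property
    def aggregation_numbers(self) -> np.ndarray:
        return self.grains[:, 2].astype(int) if self.grains.size else np.array([], int)

    def charge_positions(self) -> np.ndarray:
        if not self.grains.size:
            return np.empty((0, 3))
        return np.stack([self.grains[:, 0], self.grains[:, 1],
                         self.grains[:, 4]], axis=1)


def sample_adlayer(density: float, extent: float = 300.0,
                   size_range: tuple[int, int] = (2, 10),
                   seed: int = 0, charged: bool = True) -> GrainField:
    """Draw a reproducible random grain field.

    ``density`` is grains per nm^2 over the square of half-size
    ``extent``; aggregation numbers are uniform integers over
    ``size_range``; grain charge is 2 e per molecule (or zero for an
    uncharged adlayer).
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    rng = np.random.default_rng(seed)
    area = (2 * extent) ** 2
    n = rng.poisson(density * area)
    if n == 0:
        return GrainField(np.empty((0, 5)), seed=seed)
    xy = rng.uniform(-extent, extent, size=(n, 2))
    n_agg = rng.integers(size_range[0], size_range[1] + 1, size=n)
    orient = rng.uniform(0.0, 180.0, size=n)
    q = AMINES_PER_MOLECULE * n_agg if charged else np.zeros(n)
    return GrainField(np.stack([xy[:, 0], xy[:, 1], n_agg.astype(float),
                                orient, q.astype(float)], axis=1), seed=seed)


class SurfaceChargeField:
    """Combined screened field of the lamellar sublayer and grain adlayer.

    Evaluations are per unit (1 e) probe charge at height ``h`` above
    the charge plane, scaled by the condensation factor of ``params``;
    energies in pN nm, forces in pN.  The template contribution uses the
    screened line-charge potential ``2 l_B kT lambda K0(rho/L_D)``
    (exact for a uniform row, and indistinguishable from the discrete
    sum at amine spacings well below the screening length); grains are
    summed as discrete Yukawa point charges.
    """

    def __init__(self, template: LamellarTemplate | None = None,
                 grains: GrainField | None = None,
                 params: ElectrostaticParams | None = None,
                 height: float = 1.0):
        if template is None and grains is None:
            raise ValueError("at least one surface layer must be present")
        self.template = template
        self.grains = grains
        self.params = params if params is not None else ElectrostaticParams()
        self.height = height
        self._grain_tree = None
        self._grain_grid = None
        if grains is not None and grains.grains.size:
            self._grain_tree = cKDTree(grains.grains[:, :2])

    # -- template fast path -------------------------------------------------

    def _row_line_density(self) -> float:
        return 1.0 / self.template.b_row

    def _template_rows_near(self, y: np.ndarray) -> np.ndarray:
        """Row offsets within the screening reach of the probe points."""
        reach = 8.0 * self.params.L_D
        lo, hi = float(np.min(y)) - reach, float(np.max(y)) + reach
        rows = self.template.row_offsets(max(abs(lo), abs(hi)))
        return rows[(rows >= lo) & (rows <= hi)]

    def template_energy(self, y: np.ndarray) -> np.ndarray:
        """Screened probe energy (pN nm) vs transverse position; < 0 near rows."""
        p = self.params
        y = np.atleast_1d(np.asarray(y, dtype=float))
        rows = self._template_rows_near(y)
        dy = y[:, None] - rows[None, :]
        rho = np.sqrt(dy ** 2 + self.height ** 2)
        u = -2.0 * p.k_C * p.l_B * p.kT * self._row_line_density() \
            * k0(rho / p.L_D)
        return u.sum(axis=1)

    def template_transverse_force(self, y: np.ndarray) -> np.ndarray:
        """In-plane force component along +y (pN per unit probe charge)."""
        p = self.params
        y = np.atleast_1d(np.asarray(y, dtype=float))
        rows = self._template_rows_near(y)
        dy = y[:, None] - rows[None, :]
        rho = np.sqrt(dy ** 2 + self.height ** 2)
        f = -2.0 * p.k_C * p.l_B * p.kT * self._row_line_density() \
            * k1(rho / p.L_D) / p.L_D * (dy / rho)
        return f.sum(axis=1)

    # -- grain contribution -------------------------------------------------

    GRID_SPACING = 0.5  # nm; fine against both L_D and the probe height
    GRID_THRESHOLD = 200  # use the gridded field above this grain count

    def _build_grain_grid(self):
        """Pre-tabulate the grain energy/force on a grid (large fields).

        Dense adlayers make per-point pairwise sums the bottleneck of
        trapping simulations; a 0.5-nm bilinear grid reproduces the
        smooth screened field to well below a percent.
        """
        from scipy.interpolate import RegularGridInterpolator

        p = self.params
        g = self.grains.grains
        cut = 6.0 * p.L_D
        ext = float(np.max(np.abs(g[:, :2]))) + cut
        h = self.GRID_SPACING
        xs = np.arange(-ext, ext + h / 2, h)
        ys = xs.copy()
        U = np.zeros((len(ys), len(xs)))
        for x0, y0, _, _, q in g:
            i0 = np.searchsorted(xs, x0 - cut)
            i1 = np.searchsorted(xs, x0 + cut)
            j0 = np.searchsorted(ys, y0 - cut)
            j1 = np.searchsorted(ys, y0 + cut)
            dx = xs[i0:i1] - x0
            dy = ys[j0:j1] - y0
            r = np.sqrt(dx[None, :] ** 2 + dy[:, None] ** 2 + self.height ** 2)
            U[j0:j1, i0:i1] -= (p.k_C * p.l_B * p.kT * q
                                * np.exp(-r / p.L_D) / r)
        gy, gx = np.gradient(U, h)
        mk = lambda arr: RegularGridInterpolator(
            (ys, xs), arr, method="linear", bounds_error=False, fill_value=0.0)
        self._grain_grid = (mk(U), mk(-gx), mk(-gy))

    def _grain_terms(self, pts: np.ndarray):
        if (self._grain_tree is not None
                and len(self.grains.grains) > self.GRID_THRESHOLD):
            if self._grain_grid is None:
                self._build_grain_grid()
            fU, fFx, fFy = self._grain_grid
            q = pts[:, ::-1]  # interpolators take (y, x)
            return fU(q), np.stack([fFx(q), fFy(q)], axis=1)
        return self._grain_terms_exact(pts)

    def _grain_terms_exact(self, pts: np.ndarray):
        p = self.params
        cut = 6.0 * p.L_D
        energies = np.zeros(len(pts))
        forces = np.zeros((len(pts), 2))
        if self._grain_tree is None:
            return energies, forces
        g = self.grains.grains
        for i, pt in enumerate(pts):
            idx = self._grain_tree.query_ball_point(pt, cut)
            if not idx:
                continue
            d = g[idx, :2] - pt[None, :]
            r = np.sqrt(np.sum(d ** 2, axis=1) + self.height ** 2)
            q = g[idx, 4]
            w = p.k_C * p.l_B * p.kT * q
            energies[i] = -np.sum(w * np.exp(-r / p.L_D) / r)
            fmag = w * np.exp(-r / p.L_D) * (1.0 / r ** 2 + 1.0 / (r * p.L_D))
            forces[i] = np.sum(fmag[:, None] * d / r[:, None], axis=0)
        return energies, forces

    # -- public evaluation --------------------------------------------------

    def site_energy(self, points: np.ndarray) -> np.ndarray:
        """Screened adsorption energy (pN nm) of unit probe charges in-plane."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        u = np.zeros(len(pts))
        if self.template is not None:
            u += self.template_energy(pts[:, 1])
        if self._grain_tree is not None:
            ug, _ = self._grain_terms(pts)
            u += ug
        return u

    def in_plane_force(self, points: np.ndarray) -> np.ndarray:
        """In-plane attraction force vectors (pN) on unit probe charges."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        f = np.zeros((len(pts), 2))
        if self.template is not None:
            f[:, 1] += self.template_transverse_force(pts[:, 1])
        if self._grain_tree is not None:
            _, fg = self._grain_terms(pts)
            f += fg
        return f


def lateral_force_at(point: Sequence[float], direction_normal: Sequence[float],
                     field: SurfaceChargeField, brute: bool = False) -> float:
    """Signed in-plane force component (pN) at a point, from discrete charges.

    Sums screened Yukawa forces from every discrete surface charge
    within ``6 L_D`` of the point (or from all charges when ``brute``)
    and projects the resultant onto ``direction_normal``; attraction
    toward a nearby row is positive when the normal points at it.
    """
    p = field.params
    pt = np.asarray(point, dtype=float)
    n = np.asarray(direction_normal, dtype=float)
    n = n / np.linalg.norm(n)
    charges = []
    if field.template is not None:
        reach = field.template.extent
        c = field.template.charge_positions(reach)
        charges.append(c)
    if field.grains is not None and field.grains.grains.size:
        charges.append(field.grains.charge_positions())
    allq = np.vstack(charges)
    d = allq[:, :2] - pt[None, :]
    dist2 = np.sum(d ** 2, axis=1)
    if not brute:
        keep = dist2 <= (6.0 * p.L_D) ** 2
        allq, d, dist2 = allq[keep], d[keep], dist2[keep]
    r = np.sqrt(dist2 + field.height ** 2)
    fmag = (p.k_C * p.l_B * p.kT * allq[:, 2]
            * np.exp(-r / p.L_D) * (1.0 / r ** 2 + 1.0 / (r * p.L_D)))
    fvec = np.sum(fmag[:, None] * d / r[:, None], axis=0)
    return float(fvec @ n)


DEFAULT_ADLAYER_DENSITY = 0.015  # grains/nm^2: incomplete granular adlayer


def two_layer_film(params: ElectrostaticParams | None = None,
                   extent: float = 350.0,
                   adlayer_density: float = DEFAULT_ADLAYER_DENSITY,
                   seed: int = 0, height: float = 1.0,
                   **template_kwargs) -> SurfaceChargeField:
    """The standard AL/L film: lamellar sublayer plus granular adlayer.

    The epitaxial lamellar template supplies the periodic row charges;
    the polydisperse grain adlayer adds the random local charge
    imbalances that bend the DNA at the low scale.  This is the default
    surface for trapping simulations of "projected" conformations.
    """
    template = LamellarTemplate(extent=extent, **template_kwargs)
    grains = sample_adlayer(adlayer_density, extent=extent, seed=seed)
    return SurfaceChargeField(template=template, grains=grains,
                              params=params, height=height)


def incommensurability_ratio(theta_deg: float, W_L: float = 7.0,
                             p_DNA: float = 3.57,
                             tol: float = 1e-3) -> tuple[float, bool]:
    """Ratio of the surface charge period to the DNA period along the contact.

    ``W_L / (p_DNA * sin(theta))`` is generally non-integer and depends
    on the tilt, so the perturbation pattern along the DNA is aperiodic
    (frustrated).  Returns the ratio and a flag marking near-integer
    (commensurate) values.
    """
    if theta_deg == 0:
        raise DivergentTorqueError("contact period diverges at theta = 0")
    if not 0 < theta_deg <= 90:
        raise ValueError("theta must lie in (0, 90] degrees")
    ratio = W_L / (p_DNA * math.sin(math.radians(theta_deg)))
    return ratio, abs(ratio - round(ratio)) < tol
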