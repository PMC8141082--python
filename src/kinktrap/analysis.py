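"""Statistics of traced DNA contours.

The workhorse quantity is the mean-square end-to-end distance
``<R^2(L)>`` as a function of curvilinear separation ``L``, averaged
over all point pairs separated by ``L`` along each traced contour and
pooled across molecules, on a 25-nm grid.  Compared against the
worm-like-chain reference laws

    2D freely equilibrated:  <R^2> = 4PL [1 - (2P/L)(1 - exp(-L/2P))]
    projected (3D -> 2D):    <R^2> = (2/3) * 2PL [1 - (P/L)(1 - exp(-L/P))]

it classifies surface conformations as equilibrated, close to
projected, or anomalously compact (below the projected limit, the
signature of surface-induced low-scale bending), and supports weighted
least-squares estimation of the effective persistence length.

Local operations detect kinks (sites where the tangent turn implies a
curvature radius at or below the ~3.5 nm kink threshold), build
segment-length histograms, measure longitudinal height-profile minima
spacings (the electrostatic compression pattern) and quantify the
sixfold orientational anisotropy of extended segments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize_scalar
from scipy.signal import argrelmin

__all__ = [
    "ContourTrace",
    "MsedCurve",
    "KinkCall",
    "FitResult",
    "mean_square_end_to_end",
    "wlc_theory_curve",
    "fit_persistence_length",
    "classify_conformation",
    "detect_kinks",
    "kink_linear_density",
    "segment_length_histogram",
    "profile_minima_spacings",
    "orientation_anisotropy",
    "extended_segments",
]


@dataclass
class ContourTrace:
    """An ordered digitized contour of one molecule (nm)."""

    molecule_id: str
    points: np.ndarray
    point_spacing: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if len(self.points) < 3:
            raise ValueError("a trace needs at least 3 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("repeated consecutive points: arc length not monotone")
        if self.point_spacing is None:
            self.point_spacing = float(np.median(seg))

    @property
    def arc_lengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc_lengths[-1])

    def resample(self, spacing: float) -> np.ndarray:
        """Linear interpolation of the polyline at uniform arc spacing."""
        s = self.arc_lengths
        # guard against float jitter in the total arc length (e.g. after
        # a rigid rotation) flipping the inclusion of the last grid point
        n = int(math.floor(s[-1] / spacing * (1 + 1e-9)))
        grid = np.arange(n + 1) * spacing
        grid = np.minimum(grid, s[-1])
        x = np.interp(grid, s, self.points[:, 0])
        y = np.interp(grid, s, self.points[:, 1])
        return np.stack([x, y], axis=1)


@dataclass
class MsedCurve:
    """<R^2(L)> on a uniform arc-separation grid with counts and SEs."""

    L_grid: np.ndarray
    R2: np.ndarray
    n_pairs: np.ndarray
    se: np.ndarray
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.L_grid = np.asarray(self.L_grid, dtype=float)
        self.R2 = np.asarray(self.R2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs)
        self.se = np.asarray(self.se, dtype=float)
        if np.any(np.diff(self.L_grid) <= 0):
            raise ValueError("L grid must be strictly increasing")
        if np.any(self.R2 < 0):
            raise ValueError("R^2 must be non-negative")
        if np.any(self.R2 > self.L_grid ** 2 * (1 + 1e-9)):
            raise ValueError("R^2(L) cannot exceed L^2")


@dataclass
class KinkCall:
    trace_id: str
    arc_position: float
    angle_deg: float
    radius_nm: float

    def __post_init__(self) -> None:
        if not 0.0 < self.angle_deg < 180.0:
            raise ValueError("kink angle must lie in (0, 180) degrees")
        if self.radius_nm <= 0:
            raise ValueError("curvature radius must be positive")


@dataclass
class FitResult:
    P_eff: float
    ci: tuple[float, float]
    kind: str
    converged: bool
    classification: str | None = None


# ---------------------------------------------------------------------------
# <R^2(L)>


def mean_square_end_to_end(traces: list[ContourTrace], step: float = 25.0,
                           resample_spacing: float | None = None) -> MsedCurve:
    """Pooled mean-square end-to-end distance on a ``step``-nm grid.

    Each contour is resampled by linear interpolation at a fine uniform
    arc spacing; for every grid separation ``L`` (from ``step`` up to
    the longest trace) the squared chord distance is averaged over all
    point pairs at that arc separation, pooled over molecules with
    pair-count weights.  Standard errors come from the between-molecule
    scatter of per-molecule means, since pairs within one molecule are
    strongly correlated.  Traces shorter than two grid steps are
    excluded with a warning.
    """
    if not traces:
        raise ValueError("no traces supplied")
    usable = []
    for t in traces:
        if t.length < 2 * step:
            warnings.warn(f"trace {t.molecule_id} shorter than {2*step} nm; excluded")
        else:
            usable.append(t)
    if not usable:
        raise ValueError("no trace long enough for the requested grid")

    max_len = max(t.length for t in usable)
    L_grid = np.arange(step, max_len + step / 2, step)
    sums = np.zeros(len(L_grid))
    counts = np.zeros(len(L_grid), dtype=int)
    per_mol: list[dict[int, tuple[float, int]]] = []

    for t in usable:
        h = resample_spacing or min(t.point_spacing, step / 10)
        pts = t.resample(h)
        mol: dict[int, tuple[float, int]] = {}
        for gi, L in enumerate(L_grid):
            k = int(round(L / h))
            if k < 1 or k >= len(pts):
                continue
            if abs(k * h - L) > step / 2:
                continue
            d = pts[k:] - pts[:-k]
            r2 = np.sum(d ** 2, axis=1)
            sums[gi] += r2.sum()
            counts[gi] += len(r2)
            mol[gi] = (float(r2.mean()), len(r2))
        per_mol.append(mol)

    keep = counts > 0
    R2 = np.where(keep, sums / np.maximum(counts, 1), np.nan)
    se = np.zeros(len(L_grid))
    for gi in range(len(L_grid)):
        vals = np.array([m[gi][0] for m in per_mol if gi in m])
        if len(vals) > 1:
            se[gi] = vals.std(ddof=1) / math.sqrt(len(vals))
        elif len(vals) == 1:
            se[gi] = np.nan
    return MsedCurve(L_grid[keep], R2[keep], counts[keep], se[keep],
                     metadata={"pooling": "pairs pooled across molecules",
                               "n_molecules": len(usable), "step": step})


def wlc_theory_curve(P: float, kind: str, L_grid: np.ndarray) -> MsedCurve:
    """Worm-like-chain reference <R^2(L)> for a given persistence length.

    ``equilibrated2d``: in-plane relaxed chain, 4PL asymptote.
    ``projected``: orthogonal projection of the 3D chain, (4/3)PL
    asymptote.  Both tend to L^2 in the stiff limit.
    """
    if P <= 0:
        raise ValueError("persistence length must be positive")
    L = np.asarray(L_grid, dtype=float)
    if kind == "equilibrated2d":
        R2 = 4.0 * P * L * (1.0 - (2.0 * P / L) * (1.0 - np.exp(-L / (2.0 * P))))
    elif kind == "projected":
        R2 = (2.0 / 3.0) * 2.0 * P * L * (1.0 - (P / L) * (1.0 - np.exp(-L / P)))
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    return MsedCurve(L, R2, np.zeros(len(L), int), np.zeros(len(L)),
                     metadata={"kind": kind, "P": P})


def fit_persistence_length(curve: MsedCurve, kind: str = "equilibrated2d",
                           L_max: float | None = None) -> FitResult:
    """Weighted least-squares persistence length from an <R^2(L)> curve.

    Minimises ``sum_i (R2_i - theory(P, L_i))^2 / se_i^2`` over P; the
    confidence interval comes from the curvature of the objective at
    the minimum (local Gaussian approximation).  Points with zero pair
    count or beyond ``L_max`` are ignored.
    """
    mask = np.asarray(curve.n_pairs) > 0
    if L_max is not None:
        mask &= curve.L_grid <= L_max
    L = curve.L_grid[mask]
    R2 = curve.R2[mask]
    se = curve.se[mask]
    if len(L) < 5:
        raise ValueError("need at least 5 populated grid points to fit")
    w = np.where(np.isfinite(se) & (se > 0), 1.0 / np.maximum(se, 1e-12) ** 2, 0.0)
    if not np.any(w > 0):
        w = np.ones_like(L)

    def chi2(P: float) -> float:
        th = wlc_theory_curve(P, kind, L).R2
        return float(np.sum(w * (R2 - th) ** 2))

    res = minimize_scalar(chi2, bounds=(1.0, 2000.0), method="bounded",
                          options={"xatol": 1e-4})
    P_hat = float(res.x)
    # CI from the numerical curvature of chi^2
    h = max(1e-3 * P_hat, 1e-3)
    d2 = (chi2(P_hat + h) - 2 * chi2(P_hat) + chi2(P_hat - h)) / h ** 2
    sigma = math.sqrt(2.0 / d2) if d2 > 0 else float("inf")
    return FitResult(P_hat, (P_hat - 1.96 * sigma, P_hat + 1.96 * sigma),
                     kind, bool(res.success))


def classify_conformation(curve: MsedCurve, P: float) -> str:
    """Compare a measured curve to the two reference laws.

    ``equilibrated`` when within 3 SE of the 2D-equilibrated law at
    every populated point; ``close_to_projected`` when within 3 SE of
    the projected law or lying between the two laws; ``subprojected``
    when below the projected law by more than 3 SE at at least half of
    the grid; ``unclassified`` otherwise (or with fewer than 3 points).
    """
    mask = np.asarray(curve.n_pairs) >= 0
    L = curve.L_grid[mask]
    R2 = curve.R2[mask]
    se = np.where(np.isfinite(curve.se[mask]) & (curve.se[mask] > 0),
                  curve.se[mask], 0.0)
    if len(L) < 3:
        return "unclassified"
    eq = wlc_theory_curve(P, "equilibrated2d", L).R2
    pr = wlc_theory_curve(P, "projected", L).R2
    tol = 3.0 * se
    if np.all(np.abs(R2 - eq) <= np.maximum(tol, 1e-9 * eq)):
        return "equilibrated"
    within_proj = np.abs(R2 - pr) <= np.maximum(tol, 1e-9 * pr)
    between = (R2 <= eq + tol) & (R2 >= pr - tol)
    if np.all(within_proj | between):
        return "close_to_projected"
    below = R2 < pr - tol
    if np.count_nonzero(below) >= len(L) / 2:
        return "subprojected"
    return "unclassified"


# ---------------------------------------------------------------------------
# kinks


def detect_kinks(trace: ContourTrace, window: float = 4.0,
                 angle_threshold: float = 60.0,
                 radius_threshold: float = 3.5,
                 angle_window: float = 2.0) -> list[KinkCall]:
    """Find sharp discontinuous bends along a contour.

    Tangents are estimated as chords over ``window`` nm on each side of
    every resampled point; a kink is called where the turn angle
    reaches ``angle_threshold`` or where the implied osculating radius
    ``window / (2 sin(angle/2))`` falls to ``radius_threshold``
    (~3.5 nm, the critical kink radius).  Calls are non-maximum
    suppressed to one per ``window``.  The reported bend angle is
    re-measured with the finer ``angle_window`` chord, which carries
    much less thermal bending noise than the detection window.
    """
    if trace.point_spacing > window / 2:
        raise ValueError("point spacing must be at most half the window")
    h = min(trace.point_spacing, window / 4)
    pts = trace.resample(h)
    if len(pts) < 5:
        warnings.warn("trace too short for kink detection")
        return []
    k = max(1, int(round(window / h)))

    def turn_angles(kk: int) -> np.ndarray:
        before = pts[kk:-kk] - pts[:-2 * kk]
        after = pts[2 * kk:] - pts[kk:-kk]
        dot = np.sum(before * after, axis=1)
        cross = before[:, 0] * after[:, 1] - before[:, 1] * after[:, 0]
        return np.abs(np.arctan2(cross, dot))

    if len(pts) < 2 * k + 1:
        warnings.warn("trace too short for kink detection")
        return []
    ang = turn_angles(k)
    with np.errstate(divide="ignore"):
        radius = window / (2.0 * np.sin(ang / 2.0))
    hit = (np.degrees(ang) >= angle_threshold) | (radius <= radius_threshold)
    idx = np.nonzero(hit)[0]
    if idx.size == 0:
        return []

    # non-maximum suppression: strongest call wins within one window
    order = idx[np.argsort(-ang[idx])]
    chosen: list[int] = []
    for i in order:
        if all(abs(i - j) * h >= window for j in chosen):
            chosen.append(i)
    chosen.sort()

    kf = max(1, int(round(angle_window / h)))
    fine = turn_angles(kf) if len(pts) >= 2 * kf + 1 else ang
    calls = []
    for i in chosen:
        center = i + k  # index into pts
        fi = min(max(center - kf, 0), len(fine) - 1)
        a_deg = float(np.degrees(fine[fi]))
        a_deg = min(max(a_deg, 1e-6), 180.0 - 1e-6)
        r = float(window / (2.0 * math.sin(max(ang[i], 1e-9) / 2.0)))
        calls.append(KinkCall(trace.molecule_id, float(center * h), a_deg, r))
    return calls


def kink_linear_density(trace: ContourTrace, calls: list[KinkCall],
                        P: float = 53.0) -> float:
    """Kinks per persistence length along one contour."""
    L = trace.length
    if L <= 0:
        raise ValueError("trace has zero length")
    return len(calls) / L * P


# ---------------------------------------------------------------------------
# histograms, profiles, anisotropy


def segment_length_histogram(values, bin_width: float = 1.0):
    """Histogram of segment lengths with the mode bin.

    Returns ``(edges, counts, mode_bin)`` where ``mode_bin`` is the
    (low, high) interval of the most populated bin.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError("need at least 10 values for a histogram")
    lo = math.floor(values.min() / bin_width) * bin_width
    hi = math.ceil(values.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    counts, edges = np.histogram(values, bins=edges)
    m = int(np.argmax(counts))
    return edges, counts, (float(edges[m]), float(edges[m + 1]))


def profile_minima_spacings(arc: np.ndarray, height: np.ndarray,
                            smoothing: float = 1.0,
                            d_DNA: float = 2.0) -> np.ndarray:
    """Arc distances between adjacent height minima of a longitudinal profile.

    The profile is Gaussian-smoothed (``smoothing`` in nm) before local
    minima are located; heights must lie within the physical band
    (0, d_DNA].  A flat profile yields no spacings (with a warning).
    """
    arc = np.asarray(arc, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(height <= 0) or np.any(height > d_DNA):
        raise ValueError("profile heights must lie in (0, d_DNA]")
    dx = float(np.median(np.diff(arc)))
    sm = gaussian_filter1d(height, max(smoothing / dx, 1e-9))
    if np.ptp(sm) < 1e-12:
        warnings.warn("flat profile: no minima found")
        return np.array([])
    (mins,) = argrelmin(sm, order=max(1, int(round(1.0 / dx))))
    if len(mins) < 3:
        warnings.warn("fewer than 3 minima after smoothing")
        return np.array([]) if len(mins) < 2 else np.diff(arc[mins])
    return np.diff(arc[mins])


def extended_segments(trace: ContourTrace, max_turn_deg: float = 20.0,
                      min_length: float = 20.0) -> list[tuple[float, float]]:
    """Maximal straight runs of a contour: (orientation_deg, length_nm).

    A run extends while every turn angle between successive segments
    stays below ``max_turn_deg``; runs shorter than ``min_length`` are
    dropped.  Orientations are modulo 180 degrees.
    """
    pts = trace.resample(min(trace.point_spacing, 2.0))
    d = np.diff(pts, axis=0)
    phi = np.arctan2(d[:, 1], d[:, 0])
    dphi = np.abs(np.degrees(np.arctan2(np.sin(np.diff(phi)), np.cos(np.diff(phi)))))
    seg_len = np.linalg.norm(d, axis=1)
    breaks = np.concatenate([[0], np.nonzero(dphi >= max_turn_deg)[0] + 1,
                             [len(d)]])
    out = []
    for s, e in zip(breaks[:-1], breaks[1:]):
        if e <= s:
            continue
        length = float(seg_len[s:e].sum())
        if length >= min_length:
            vec = pts[e] - pts[s]
            out.append((float(np.degrees(np.arctan2(vec[1], vec[0])) % 180.0),
                        length))
    return out


def orientation_anisotropy(traces: list[ContourTrace], n_fold: int = 6,
                           max_turn_deg: float = 20.0,
                           min_length: float = 20.0,
                           n_permutations: int = 0,
                           seed: int = 0):
    """n-fold circular order parameter of extended-segment orientations.

    Score = ``|sum_k w_k exp(i n phi_k)| / sum_k w_k`` over pooled
    extended segments with length weights ``w_k``; 1 for perfect n-fold
    alignment, ~0 for isotropy.  With ``n_permutations > 0`` an
    isotropic Monte Carlo null (same weights, uniform random
    orientations) yields a p-value for the observed score.
    """
    segs = []
    for t in traces:
        segs.extend(extended_segments(t, max_turn_deg, min_length))
    if len(segs) < 100:
        raise ValueError("need at least 100 pooled segment orientations")
    phi = np.radians([s[0] for s in segs])
    w = np.array([s[1] for s in segs])

    def score_of(angles: np.ndarray) -> float:
        z = np.sum(w * np.exp(1j * n_fold * angles))
        return float(np.abs(z) / np.sum(w))

    score = score_of(phi)
    if n_permutations <= 0:
        return score
    rng = np.random.default_rng(seed)
    null = np.array([score_of(rng.uniform(0.0, math.pi, size=len(phi)))
                     for _ in range(n_permutations)])
    p = (1 + np.count_nonzero(null >= score)) / (n_permutations + 1)
    return score, float(p), null
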