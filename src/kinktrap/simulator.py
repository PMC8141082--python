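"""Kinkable worm-like-chain conformations on a periodically charged surface.

Three reference ensembles bracket what a surface-adsorbed DNA trace can
look like:

* *2D freely equilibrated* -- the chain relaxed in-plane; discretised as
  Gaussian turn angles of variance ``a/P`` per segment, giving the 2D
  tangent correlation length ``2P`` and the mean-square end-to-end
  distance ``4PL[1 - (2P/L)(1 - exp(-L/2P))]``.
* *projected* -- a 3D worm-like chain flattened orthogonally onto the
  plane without re-equilibration, the classical picture of kinetic
  trapping; its in-plane mean-square end-to-end distance is 2/3 of the
  3D value.
* *kinetically trapped on a lamellar template* -- the chain is laid down
  segment by segment in the screened field of the periodic surface
  charges.  Already-adsorbed segments never move (kinetic trapping);
  each new segment locally trades bending energy against the surface
  energy, and wherever the accumulated lateral bending torque exceeds
  the critical torque a discrete kink (85-105 degrees, fixed energy
  ~7 kT) is inserted.  This produces conformations more compact than
  the projected baseline, oversaturated with kinks at row crossings.

A separate geometric generator reproduces the confined zigzag shapes of
template-directed DNA trapped between the two charged rows of one
lamella, where each undulation segment spans the row gap and terminates
in a kink/anti-kink pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Literal

import numpy as np

from .surface import SurfaceChargeField

__all__ = [
    "SimulationConfig",
    "ChainConformation",
    "generate_wlc_2d",
    "generate_wlc_3d_projected",
    "wlc2d_ensemble",
    "wlc3d_projected_ensemble",
    "trap_on_surface",
    "trap_ensemble",
    "confined_zigzag_chain",
    "twist_variance",
    "classify_anomalies",
    "stored_energy_density",
    "open_bp_probability_per_persistence",
]

DNA_RISE_NM = 0.34


@dataclass
class SimulationConfig:
    """Chain and trapping-protocol parameters (nm, pN, kT units).

    ``P`` is the bending persistence length, ``C`` the low-force
    torsional persistence length, ``F_p`` the tension scale ("several
    pN") above which a torsionally stressed pinned interval can collapse
    into a plectoneme, and ``F_u`` the ~10 pN unzipping threshold that
    separates linear elasticity from large structural rearrangement.
    Trapping-protocol knobs: ``max_deflection`` bounds the per-segment
    angular search, ``torque_window`` is the arc length over which the
    lateral torque is accumulated before testing the kink criterion,
    and ``trap_temperature`` scales thermal resampling during
    deposition (0 = pure quench).
    """

    P: float = 53.0
    L: float = 900.0
    a: float = 1.0
    d_DNA: float = 2.0
    p_DNA: float = 3.57
    C: float = 100.0
    F_p: float = 3.0
    F_u: float = 10.0
    E_K: float = 7.0
    seed: int = 0
    max_deflection: float = 0.6
    n_candidates: int = 25
    torque_window: float = 10.0
    lookahead: float = 5.0
    trap_temperature: float = 0.0
    kink_angle_range: tuple[float, float] = (85.0, 105.0)
    pin_distance: float = 1.0

    def __post_init__(self) -> None:
        if self.a > self.P / 10:
            raise ValueError("segment length must satisfy a <= P/10")
        if self.L < 2 * self.a:
            raise ValueError("contour length must cover at least two segments")
        for name in ("F_p", "F_u", "C", "E_K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ChainConformation:
    """A discretised DNA contour with per-site stress bookkeeping.

    ``points`` are ordered in-plane positions (nm); ``spacing`` is the
    segment length for fixed-spacing chains (None when steps vary, e.g.
    after 3D->2D projection).  ``kinks`` holds (site index, kink angle
    in degrees, formation torque in pN nm); ``twist_register`` holds
    (start, end, residual twist in rad) per pinned interval;
    ``anomalies`` holds classified plectoneme/bubble spans.
    """

    points: np.ndarray
    spacing: float | None = None
    kinks: list = dc_field(default_factory=list)
    site_labels: np.ndarray | None = None
    twist_register: list = dc_field(default_factory=list)
    anomalies: list = dc_field(default_factory=list)
    stress: dict = dc_field(default_factory=dict)
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if self.site_labels is None:
            self.site_labels = np.full(len(self.points), "plain", dtype="<U5")
        self.validate()

    def validate(self) -> None:
        if self.spacing is not None:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            if seg.size and np.max(np.abs(seg - self.spacing)) > 1e-6 * max(1.0, self.spacing):
                raise ValueError("consecutive point spacing deviates from a")
        for _, angle, *_ in self.kinks:
            if not 0.0 < angle < 180.0:
                raise ValueError(f"kink angle {angle} outside (0, 180) degrees")
        spans = sorted((a["span"] for a in self.anomalies), key=lambda s: s[0])
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("anomaly spans overlap")

    @property
    def tangent_angles(self) -> np.ndarray:
        d = np.diff(self.points, axis=0)
        return np.arctan2(d[:, 1], d[:, 0])

    @property
    def contour_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    @property
    def end_to_end_sq(self) -> float:
        return float(np.sum((self.points[-1] - self.points[0]) ** 2))


# ---------------------------------------------------------------------------
# reference ensembles


def _points_from_angles(phi: np.ndarray, a: float) -> np.ndarray:
    """Cumulate unit steps of length a; phi has shape (n_chains, n_steps)."""
    dx = a * np.cos(phi)
    dy = a * np.sin(phi)
    pts = np.zeros((phi.shape[0], phi.shape[1] + 1, 2))
    pts[:, 1:, 0] = np.cumsum(dx, axis=1)
    pts[:, 1:, 1] = np.cumsum(dy, axis=1)
    return pts


def _wlc2d_points(rng: np.random.Generator, n_chains: int, P: float,
                  L: float, a: float) -> np.ndarray:
    n_steps = int(round(L / a))
    phi0 = rng.uniform(0.0, 2 * math.pi, size=(n_chains, 1))
    turns = rng.normal(0.0, math.sqrt(a / P), size=(n_chains, n_steps - 1))
    phi = phi0 + np.concatenate(
        [np.zeros((n_chains, 1)), np.cumsum(turns, axis=1)], axis=1)
    return _points_from_angles(phi, a)


def generate_wlc_2d(P: float, L: float, a: float = 1.0,
                    seed: int = 0) -> ChainConformation:
    """One 2D freely equilibrated worm-like chain.

    Gaussian turn angles of variance ``a/P`` per step give the in-plane
    tangent correlation ``exp(-s/2P)`` and hence the 2D-equilibrated
    mean-square end-to-end law with large-L slope ``4P``.
    """
    if a > P / 10:
        raise ValueError("segment length must satisfy a <= P/10")
    rng = np.random.default_rng(seed)
    pts = _wlc2d_points(rng, 1, P, L, a)[0]
    return ChainConformation(pts, spacing=a,
                             metadata={"kind": "equilibrated2d", "P": P,
                                       "L": L, "a": a, "seed": seed})


def wlc2d_ensemble(n_molecules: int, P: float, L: float, a: float = 1.0,
                   seed: int = 0) -> list[ChainConformation]:
    rng = np.random.default_rng(seed)
    pts = _wlc2d_points(rng, n_molecules, P, L, a)
    return [ChainConformation(pts[i], spacing=a,
                              metadata={"kind": "equilibrated2d", "P": P,
                                        "L": L, "a": a, "seed": seed,
                                        "molecule": i})
            for i in range(n_molecules)]


def _wlc3d_points(rng: np.random.Generator, n_chains: int, P: float,
                  L: float, a: float) -> np.ndarray:
    """3D worm-like chains with tangent correlation exp(-s/P)."""
    n_steps = int(round(L / a))
    t = rng.normal(size=(n_chains, 3))
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    pts = np.zeros((n_chains, n_steps + 1, 3))
    sigma = math.sqrt(2 * a / P)  # polar bending angle per step
    for i in range(n_steps):
        pts[:, i + 1] = pts[:, i] + a * t
        beta = rng.normal(0.0, sigma, size=n_chains)
        psi = rng.uniform(0.0, 2 * math.pi, size=n_chains)
        # orthonormal frame transverse to each tangent
        ref = np.where(np.abs(t[:, 2:3]) < 0.9,
                       np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))
        e1 = np.cross(t, ref)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(t, e1)
        t = (np.cos(beta)[:, None] * t
             + np.sin(beta)[:, None] * (np.cos(psi)[:, None] * e1
                                        + np.sin(psi)[:, None] * e2))
        t /= np.linalg.norm(t, axis=1, keepdims=True)
    return pts


def generate_wlc_3d_projected(P: float, L: float, a: float = 1.0,
                              seed: int = 0) -> ChainConformation:
    """A 3D worm-like chain orthogonally projected onto the surface plane.

    The projected in-plane coordinates keep the 3D arc parameterisation
    (step lengths shrink under projection), the classical model of a
    kinetically trapped conformation; ``metadata['end_to_end_sq_3d']``
    preserves the pre-projection value, whose ensemble mean is 3/2 of
    the projected one.
    """
    rng = np.random.default_rng(seed)
    p3 = _wlc3d_points(rng, 1, P, L, a)[0]
    chain = ChainConformation(p3[:, :2], spacing=None,
                              metadata={"kind": "projected", "P": P, "L": L,
                                        "a": a, "seed": seed})
    chain.metadata["end_to_end_sq_3d"] = float(np.sum((p3[-1] - p3[0]) ** 2))
    return chain


def wlc3d_projected_ensemble(n_molecules: int, P: float, L: float,
                             a: float = 1.0, seed: int = 0) -> list[ChainConformation]:
    rng = np.random.default_rng(seed)
    p3 = _wlc3d_points(rng, n_molecules, P, L, a)
    chains = []
    for i in range(n_molecules):
        c = ChainConformation(p3[i][:, :2], spacing=None,
                              metadata={"kind": "projected", "P": P, "L": L,
                                        "a": a, "seed": seed, "molecule": i})
        c.metadata["end_to_end_sq_3d"] = float(np.sum((p3[i][-1] - p3[i][0]) ** 2))
        chains.append(c)
    return chains


# ---------------------------------------------------------------------------
# kinetic trapping on a charged surface


def _turn_angles(chain: ChainConformation) -> np.ndarray:
    phi = chain.tangent_angles
    d = np.diff(phi)
    return np.arctan2(np.sin(d), np.cos(d))  # wrap to (-pi, pi]


def trap_on_surface(chain0: ChainConformation, field: SurfaceChargeField,
                    cfg: SimulationConfig, seed: int = 0) -> ChainConformation:
    """Deposit a chain sequentially in the screened surface field.

    One-pass sequential adsorption from one chain end.  Segment ``i``
    arrives carrying the turn angle of the input conformation (the
    quenched shape of the incoming coil); the realised turn angle
    minimises local energy = harmonic bending about that quenched angle
    (stiffness ``kT P / a``) plus the screened surface energy of the new
    site, over a bounded candidate grid.  Already-placed segments are
    never revisited.  With ``trap_temperature > 0`` the candidate is
    Boltzmann-sampled instead of minimised; at zero surface charge the
    input conformation is reproduced exactly.

    The lateral force transverse to the chain is accumulated into a
    running torque over the trailing ``torque_window``; when it reaches
    the critical torque ``tau_K`` the segment's turn is replaced by a
    discrete kink (85-105 deg, oriented with the torque), the formation
    torque is recorded and the stress accumulator resets.  Contour
    length is conserved throughout.
    """
    if field is None:
        raise ValueError("a surface charge field is required")
    p = field.params
    rng = np.random.default_rng(seed)
    a = cfg.a
    phi_all = chain0.tangent_angles
    if chain0.spacing is None:
        # variable-spacing input (projected chain): keep its turn sequence
        turns0 = _turn_angles(chain0)
    else:
        turns0 = _turn_angles(chain0)
    n_steps = len(phi_all)
    q_site = p.q_DNA * a  # probe charge of one segment, e

    kappa = p.kT * cfg.P / a  # pN nm per rad^2
    deltas = np.linspace(-cfg.max_deflection, cfg.max_deflection, cfg.n_candidates)
    window_n = max(2, int(round(cfg.torque_window / a)))

    period = field.template.period if field.template is not None else None
    pts = np.zeros((n_steps + 1, 2))
    pts[0, 0] = 0.0
    pts[0, 1] = rng.uniform(0.0, period) if period else 0.0
    phi = float(phi_all[0])
    pts[1] = pts[0] + a * np.array([math.cos(phi), math.sin(phi)])

    f_buf = np.zeros(window_n)
    torque_tr = np.zeros(n_steps + 1)
    tension_tr = np.zeros(n_steps + 1)
    kinks: list[tuple[int, float, float]] = []
    zero_field_energy = False
    # a kink strands the chain crossing the rows; the anti-kink of the
    # pair re-aligns it when it reaches the next row
    pending_antikink: tuple[float, float] | None = None  # (sign, torque)

    def _row_distance(pt: np.ndarray) -> float:
        if period is None:
            return math.inf
        sep = field.template.row_pair_separation
        ym = pt[1] % period
        return min(abs(ym), abs(ym - sep), abs(ym - period), abs(ym + sep - period))

    look_n = max(1, int(round(cfg.lookahead / a)))
    for i in range(1, n_steps):
        turn0 = turns0[i - 1]
        cand_phi = phi + turn0 + deltas
        steps = np.stack([np.cos(cand_phi), np.sin(cand_phi)], axis=1)
        # the stiff leading section of the incoming coil feels the field
        # over a short horizon ahead, not just at the next site
        m = np.arange(1, look_n + 1)[None, :, None]
        look_pts = pts[i][None, None, :] + a * m * steps[:, None, :]
        u_all = field.site_energy(look_pts.reshape(-1, 2)).reshape(
            len(deltas), look_n)
        u_surf = q_site * u_all.mean(axis=1)
        cand_pts = look_pts[:, 0, :]
        energy = 0.5 * kappa * deltas ** 2 + u_surf
        if cfg.trap_temperature > 0:
            w = np.exp(-(energy - energy.min()) / (p.kT * cfg.trap_temperature))
            j = rng.choice(len(deltas), p=w / w.sum())
        else:
            j = int(np.argmin(energy))
        if np.ptp(u_surf) == 0.0:
            zero_field_energy = True
            j = int(np.argmin(np.abs(deltas)))  # exact quench: keep input turn
        phi = cand_phi[j]
        new_pt = cand_pts[j]

        # lateral stress bookkeeping at the new site
        fvec = q_site * field.in_plane_force(new_pt[None, :])[0]
        tangent = np.array([math.cos(phi), math.sin(phi)])
        normal = np.array([-tangent[1], tangent[0]])
        f_perp = float(fvec @ normal)
        f_par = float(fvec @ tangent)
        f_buf = np.roll(f_buf, 1)
        # inside a trough the transverse force is a confining restoring
        # oscillation already relieved by smooth bending; unidirectional
        # kink-driving torque builds up only while crossing between rows
        f_buf[0] = f_perp if _row_distance(new_pt) >= cfg.pin_distance else 0.0
        levers = a * np.arange(1, window_n + 1)
        tau = float(np.dot(f_buf, levers))
        torque_tr[i + 1] = tau
        tension_tr[i + 1] = abs(f_par)

        if abs(tau) >= p.tau_K:
            kink_deg = rng.uniform(*cfg.kink_angle_range)
            phi = float(phi - (turn0 + deltas[j])
                        + math.copysign(math.radians(kink_deg), tau))
            new_pt = pts[i] + a * np.array([math.cos(phi), math.sin(phi)])
            kinks.append((i, kink_deg, abs(tau)))
            f_buf[:] = 0.0
            pending_antikink = (-math.copysign(1.0, tau), abs(tau))
        elif (pending_antikink is not None
              and _row_distance(new_pt) < cfg.pin_distance
              and abs(math.sin(phi)) > 0.5):
            # the paired anti-kink: the crossing segment re-attaches
            # along the row it has just reached
            sign, pair_tau = pending_antikink
            kink_deg = rng.uniform(*cfg.kink_angle_range)
            phi = float(phi + sign * math.radians(kink_deg))
            new_pt = pts[i] + a * np.array([math.cos(phi), math.sin(phi)])
            kinks.append((i, kink_deg, pair_tau))
            f_buf[:] = 0.0
            pending_antikink = None
        pts[i + 1] = new_pt

    chain = ChainConformation(pts, spacing=a, kinks=kinks,
                              metadata={"kind": "trapped", "P": cfg.P,
                                        "L": n_steps * a, "a": a, "seed": seed,
                                        "zero_field": zero_field_energy})
    chain.stress = {"torque": torque_tr, "tension": tension_tr,
                    "unzip": np.zeros(n_steps + 1)}
    _annotate_trapped(chain, field, cfg, rng)
    return chain


def _annotate_trapped(chain: ChainConformation, field: SurfaceChargeField,
                      cfg: SimulationConfig, rng: np.random.Generator) -> None:
    """Assign B/S labels, pinned intervals, twist registers and unzip stress."""
    pts = chain.points
    n = len(pts)
    labels = np.full(n, "plain", dtype="<U5")
    turns = np.abs(np.concatenate([[0.0], _turn_angles(chain), [0.0]]))
    sigma = math.sqrt(cfg.a / cfg.P)
    kink_idx = {k[0] for k in chain.kinks}
    labels[np.nonzero(turns >= 6 * sigma)[0]] = "B"
    for i in kink_idx:
        labels[i] = "B"

    tmpl = field.template
    if tmpl is not None:
        offs = np.array([0.0, tmpl.row_pair_separation])
        ymod = np.mod(pts[:, 1], tmpl.period)
        row_dist = np.min(np.abs(ymod[:, None] - np.concatenate(
            [offs, offs + tmpl.period, offs - tmpl.period])[None, :]), axis=1)
        pinned = row_dist < cfg.pin_distance
        stretched = pinned & (turns < 2 * sigma)
        labels[stretched & (labels == "plain")] = "S"

        # unzip stress: opposing pulls when the chain sits between the
        # two rows of one lamella, per strand (half the site charge)
        p = field.params
        mid = (ymod > cfg.pin_distance) & (ymod < tmpl.row_pair_separation
                                           - cfg.pin_distance)
        q_strand = 0.5 * p.q_DNA * cfg.a
        unzip = np.zeros(n)
        if np.any(mid):
            d_left = ymod[mid]
            d_right = tmpl.row_pair_separation - ymod[mid]
            for d in (d_left, d_right):
                rho = np.sqrt(d ** 2 + field.height ** 2)
                f = (2.0 * p.k_C * p.l_B * p.kT / tmpl.b_row
                     * _k1(rho / p.L_D) / p.L_D * (d / rho))
                unzip[mid] += q_strand * f
        chain.stress["unzip"] = unzip

        # pinned intervals between anchored runs carry a quenched
        # residual twist inherited from bulk fluctuations
        anchors = np.nonzero(pinned)[0]
        if anchors.size >= 2:
            gaps = np.nonzero(np.diff(anchors) > 1)[0]
            for g in gaps:
                i0, i1 = int(anchors[g]), int(anchors[g + 1])
                s12 = (i1 - i0) * cfg.a
                dtheta = rng.normal(0.0, math.sqrt(s12 / cfg.C))
                chain.twist_register.append((i0, i1, float(dtheta)))
    chain.site_labels = labels


def _k1(x):
    from scipy.special import k1 as _bessel_k1
    return _bessel_k1(x)


def trap_ensemble(n_molecules: int, field: SurfaceChargeField,
                  cfg: SimulationConfig, seed: int = 0,
                  base_kind: Literal["projected", "equilibrated2d"] = "projected",
                  orientations: tuple[float, ...] | None = None) -> list[ChainConformation]:
    """Trap an ensemble; optionally rotate traces to sixfold template domains.

    Each molecule lands on a template domain whose row direction cycles
    through ``orientations`` (degrees); the trapped trace is rotated
    into the laboratory frame accordingly.
    """
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_molecules * 2)
    if base_kind == "projected":
        bases = wlc3d_projected_ensemble(n_molecules, cfg.P, cfg.L, cfg.a,
                                         seed=int(child[0].generate_state(1)[0] % 2**31))
    else:
        bases = wlc2d_ensemble(n_molecules, cfg.P, cfg.L, cfg.a,
                               seed=int(child[0].generate_state(1)[0] % 2**31))
    chains = []
    for i, base in enumerate(bases):
        mseed = int(child[n_molecules + i].generate_state(1)[0] % 2**31)
        c = trap_on_surface(base, field, cfg, seed=mseed)
        if orientations:
            ang = math.radians(orientations[i % len(orientations)])
            R = np.array([[math.cos(ang), -math.sin(ang)],
                          [math.sin(ang), math.cos(ang)]])
            c.points = c.points @ R.T
            c.metadata["template_orientation"] = math.degrees(ang)
        chains.append(c)
    return chains


# ---------------------------------------------------------------------------
# confined zigzag (template-directed, theta = 0)


def confined_zigzag_chain(row_separation: float = 4.0,
                          vertex_angle_range: tuple[float, float] = (85.0, 105.0),
                          n_segments: int = 20, a: float = 1.0,
                          seed: int = 0) -> ChainConformation:
    """Geometric zigzag of DNA confined between two charged rows.

    A purely geometric model of the observed confined shapes (no
    energetic derivation exists for the instability at zero tilt): each
    straight segment spans the row gap ``W`` as a chord, successive
    segments alternate sides, and every vertex is a kink.  A vertex
    angle ``v`` gives segment length ``W / sin((180 - v)/2)`` and a
    tangent turn of ``180 - v`` degrees.  Vertex angles are drawn
    uniformly from ``vertex_angle_range``.
    """
    if row_separation <= 0:
        raise ValueError("row separation must be positive")
    if n_segments < 2:
        raise ValueError("need at least two segments")
    lo, hi = vertex_angle_range
    if not (0.0 < lo <= hi < 180.0):
        raise ValueError("vertex angles must lie in (0, 180)")
    rng = np.random.default_rng(seed)
    vertices = rng.uniform(lo, hi, size=n_segments - 1)
    half = np.radians((180.0 - vertices) / 2.0)
    # first segment tilt drawn like the others
    first_v = rng.uniform(lo, hi)
    alpha0 = math.radians((180.0 - first_v) / 2.0)

    verts = [np.array([0.0, 0.0])]
    seg_lengths = []
    sign = 1.0
    alpha = alpha0
    for k in range(n_segments):
        length = row_separation / math.sin(alpha)
        seg_lengths.append(length)
        dx = length * math.cos(alpha)
        verts.append(verts[-1] + np.array([dx, sign * row_separation]))
        sign = -sign
        if k < n_segments - 1:
            alpha = float(half[k])
    verts = np.array(verts)

    # resample the polyline at arc spacing a, keeping the vertices exact
    pts = [verts[0]]
    kinks = []
    arc = 0.0
    for k in range(n_segments):
        seg = verts[k + 1] - verts[k]
        length = seg_lengths[k]
        direction = seg / length
        n_pts = max(1, int(math.floor(length / a)))
        for m in range(1, n_pts + 1):
            pts.append(verts[k] + direction * min(m * a, length))
        if not np.allclose(pts[-1], verts[k + 1]):
            pts.append(verts[k + 1])
        if k < n_segments - 1:
            kinks.append((len(pts) - 1, 180.0 - float(vertices[k]), float("nan")))
        arc += length
    chain = ChainConformation(np.array(pts), spacing=None, kinks=kinks,
                              metadata={"kind": "zigzag",
                                        "row_separation": row_separation,
                                        "vertex_angles": vertices.tolist(),
                                        "segment_lengths": seg_lengths,
                                        "seed": seed})
    return chain


# ---------------------------------------------------------------------------
# twist, anomalies, energetics


def twist_variance(S12: float, C: float = 100.0) -> float:
    """Variance (rad^2) of the quenched twist over a pinned interval.

    Thermal twist fluctuations of a segment of curvilinear length
    ``S12`` in solution have variance ``S12 / C`` with ``C`` the
    low-force torsional persistence length; the value is frozen in at
    adsorption.
    """
    if C <= 0:
        raise ValueError("torsional persistence length must be positive")
    if S12 < 0:
        raise ValueError("interval length must be non-negative")
    return S12 / C


def classify_anomalies(chain: ChainConformation,
                       cfg: SimulationConfig) -> ChainConformation:
    """Flag collapsed plectonemes and melting bubbles from stored stress.

    A pinned interval whose tension reaches ``F_p`` while its quenched
    residual twist exceeds the thermal scale ``sqrt(S12/C)`` is labelled
    a collapsed plectoneme.  A site pulled apart by opposing row
    attractions at or above ``F_u`` (and not already inside a plectoneme
    span) seeds a melting bubble whose separated strands stick to the
    opposite rows of the lamella.  Anomaly spans never overlap.
    """
    if not chain.stress:
        raise ValueError("stress fields are not populated")
    chain.anomalies = []
    tension = chain.stress.get("tension")
    unzip = chain.stress.get("unzip")
    occupied = np.zeros(len(chain.points), dtype=bool)

    for (i0, i1, dtheta) in chain.twist_register:
        s12 = (i1 - i0) * (chain.spacing or cfg.a)
        if s12 <= 0:
            continue
        t = float(np.max(tension[i0:i1 + 1])) if tension is not None else 0.0
        if t >= cfg.F_p and abs(dtheta) > math.sqrt(twist_variance(s12, cfg.C)):
            chain.anomalies.append({"type": "plectoneme", "span": (i0, i1),
                                    "metadata": {"tension_pN": t,
                                                 "twist_rad": dtheta}})
            occupied[i0:i1 + 1] = True

    if unzip is not None:
        hot = np.nonzero((unzip >= cfg.F_u) & ~occupied)[0]
        if hot.size:
            breaks = np.nonzero(np.diff(hot) > 1)[0]
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks, [hot.size - 1]])
            sep = chain.metadata.get("row_separation", 4.0)
            for s, e in zip(starts, ends):
                i0, i1 = int(hot[s]), int(hot[e])
                chain.anomalies.append(
                    {"type": "bubble", "span": (i0, i1),
                     "metadata": {"strand_separation_nm": float(np.clip(sep, 4.0, 5.0)),
                                  "peak_unzip_pN": float(np.max(unzip[i0:i1 + 1]))}})
    chain.validate()
    return chain


def stored_energy_density(chain: ChainConformation,
                          cfg: SimulationConfig) -> float:
    """Elastic energy stored in kinks, in kT per persistence length.

    (kinks per persistence length) x (kink energy).  A kink-saturated
    template-directed chain (~10 kinks per P at ~7 kT each) stores ~70
    kT per P, about two orders of magnitude above the ~kT per P of a
    freely relaxed worm-like chain.
    """
    L = chain.contour_length
    if L <= 0:
        return 0.0
    return len(chain.kinks) / (L / cfg.P) * cfg.E_K


def open_bp_probability_per_persistence(p_per_bp: float = 1e-5,
                                        P: float = 53.0,
                                        rise: float = DNA_RISE_NM) -> float:
    """Convert an open-base-pair probability per bp to per persistence length.

    With ~155 bp per persistence length (P = 53 nm at 0.34 nm rise),
    10^-5 per bp becomes ~1.5 x 10^-3 per persistence length -- the
    solution baseline against which the several-kinks-per-P density of
    trapped DNA is about three orders of magnitude higher.
    """
    if p_per_bp < 0 or P <= 0 or rise <= 0:
        raise ValueError("inputs must be positive (probability non-negative)")
    return p_per_bp * P / rise
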