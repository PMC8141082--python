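"""Seeded synthetic fixtures and plain-text trace/profile I/O.

Real inputs to the contour pipeline are digitized traces — ordered
(x, y) point tables per molecule, in nm — and longitudinal height
profiles.  This module generates statistically faithful stand-ins for
every conformation class the surface produces (2D-equilibrated,
projected, template-trapped, confined zigzag) plus quasi-periodic
height profiles with ~8-nm depressions at 1/3–2/3 of the DNA diameter,
and ships each fixture with its ground truth (planted kink positions
and angles, generating persistence length, template orientation) so
detector recall and parameter recovery are directly testable.

Formats are plain TSV/CSV: traces as ``molecule_id, point_index, x_nm,
y_nm``; profiles as ``arc_nm, height_nm``.  All generation is
deterministic per seed and every output directory carries a metadata
JSON with the seed and a config hash.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import ContourTrace
from .electrostatics import ElectrostaticParams
from .simulator import (ChainConformation, SimulationConfig,
                        confined_zigzag_chain, trap_ensemble, wlc2d_ensemble,
                        wlc3d_projected_ensemble)
from .surface import two_layer_film

__all__ = [
    "FixtureSpec",
    "make_trace_fixture",
    "make_height_profile",
    "read_traces",
    "write_traces",
    "read_profile",
    "chains_to_traces",
    "plant_kinks",
]

TRACE_COLUMNS = ["molecule_id", "point_index", "x_nm", "y_nm"]
FIXTURE_KINDS = ("equilibrated2d", "projected", "trapped", "zigzag",
                 "height_profile")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic fixture.

    ``kind`` selects the generator; chain parameters (P, L, a) apply to
    the polymer kinds, ``noise`` is an isotropic Gaussian positional
    jitter (nm) emulating tracing error, and ``template`` configures
    the lamellar surface for trapped fixtures.
    """

    kind: str
    seed: int
    n_molecules: int = 1
    P: float = 53.0
    L: float = 900.0
    a: float = 1.0
    noise: float = 0.0
    row_separation: float = 4.0
    vertex_angle_range: tuple[float, float] = (85.0, 105.0)
    n_segments: int = 20
    orientations: tuple[float, ...] | None = None
    planted_kinks: int = 0
    kink_angle_range: tuple[float, float] = (85.0, 105.0)
    ionic_strength_M: float = 0.002
    extra: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.seed is None:
            raise ValueError("a seed is mandatory for fixtures")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be at least 1")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# trace I/O


def write_traces(traces: list[ContourTrace], path: str | Path) -> None:
    """Write traces as TSV with columns molecule_id, point_index, x_nm, y_nm."""
    rows = []
    for t in traces:
        for i, (x, y) in enumerate(t.points):
            rows.append((t.molecule_id, i, x, y))
    df = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_traces(path: str | Path) -> list[ContourTrace]:
    """Read a trace TSV; orders points by index and validates every row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns {missing} in {path}")
    for col in ("point_index", "x_nm", "y_nm"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"non-numeric {col} at line {line} of {path}")
        df[col] = pd.to_numeric(df[col])
    if df[["molecule_id", "point_index"]].duplicated().any():
        dup = df[df[["molecule_id", "point_index"]].duplicated()].iloc[0]
        raise ValueError(f"duplicate point index {dup['point_index']} for "
                         f"molecule {dup['molecule_id']}")
    traces = []
    for mid, grp in df.groupby("molecule_id", sort=True):
        grp = grp.sort_values("point_index")
        traces.append(ContourTrace(str(mid),
                                   grp[["x_nm", "y_nm"]].to_numpy(float)))
    return traces


def read_profile(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if not {"arc_nm", "height_nm"} <= set(df.columns):
        raise ValueError(f"profile {path} needs arc_nm and height_nm columns")
    return df["arc_nm"].to_numpy(float), df["height_nm"].to_numpy(float)


def chains_to_traces(chains: list[ChainConformation],
                     noise: float = 0.0, seed: int = 0,
                     prefix: str = "mol") -> list[ContourTrace]:
    """Convert simulated conformations to traces, with optional jitter."""
    rng = np.random.default_rng(seed)
    out = []
    for i, c in enumerate(chains):
        pts = c.points.copy()
        if noise > 0:
            pts = pts + rng.normal(0.0, noise, size=pts.shape)
        out.append(ContourTrace(f"{prefix}{i:04d}", pts))
    return out


# ---------------------------------------------------------------------------
# planted kinks


def plant_kinks(chain: ChainConformation, n_kinks: int,
                angle_range: tuple[float, float] = (85.0, 105.0),
                seed: int = 0, min_separation: float = 20.0) -> ChainConformation:
    """Insert discrete kinks at random sites of a smooth chain.

    The chain is rebuilt from its turn-angle sequence with extra
    discrete turns (random sign, angle uniform in ``angle_range``) at
    ``n_kinks`` sites separated by at least ``min_separation`` nm and
    away from the ends; planted positions and angles go to
    ``chain.kinks`` as ground truth.
    """
    if chain.spacing is None:
        raise ValueError("planting requires a fixed-spacing chain")
    rng = np.random.default_rng(seed)
    a = chain.spacing
    phi = chain.tangent_angles
    n = len(phi)
    margin = int(round(min_separation / a))
    candidates = np.arange(margin, n - margin)
    sites: list[int] = []
    rng.shuffle(candidates)
    for c in candidates:
        if all(abs(c - s) * a >= min_separation for s in sites):
            sites.append(int(c))
        if len(sites) == n_kinks:
            break
    if len(sites) < n_kinks:
        raise ValueError("chain too short for the requested kink count")
    sites.sort()
    turns = np.diff(phi)
    extra = np.zeros_like(phi)
    kinks = []
    for s in sites:
        ang = rng.uniform(*angle_range) * rng.choice([-1.0, 1.0])
        extra[s] = math.radians(ang)
        kinks.append((s, abs(ang), float("nan")))
    new_phi = phi[0] + np.concatenate([[0.0], np.cumsum(turns)]) \
        + np.cumsum(extra)
    pts = np.zeros((n + 1, 2))
    pts[1:, 0] = np.cumsum(a * np.cos(new_phi))
    pts[1:, 1] = np.cumsum(a * np.sin(new_phi))
    out = ChainConformation(pts, spacing=a, kinks=kinks,
                            metadata=dict(chain.metadata, planted=True,
                                          plant_seed=seed))
    return out


# ---------------------------------------------------------------------------
# fixture generation


def _generate_chains(spec: FixtureSpec) -> list[ChainConformation]:
    if spec.kind == "equilibrated2d":
        chains = wlc2d_ensemble(spec.n_molecules, spec.P, spec.L, spec.a,
                                seed=spec.seed)
    elif spec.kind == "projected":
        chains = wlc3d_projected_ensemble(spec.n_molecules, spec.P, spec.L,
                                          spec.a, seed=spec.seed)
    elif spec.kind == "trapped":
        params = ElectrostaticParams.from_ionic_strength(spec.ionic_strength_M)
        field = two_layer_film(params=params, extent=max(300.0, spec.L),
                               seed=spec.seed)
        cfg = SimulationConfig(P=spec.P, L=spec.L, a=spec.a, seed=spec.seed)
        chains = trap_ensemble(spec.n_molecules, field, cfg, seed=spec.seed,
                               orientations=spec.orientations)
    elif spec.kind == "zigzag":
        ss = np.random.SeedSequence(spec.seed)
        seeds = [int(s.generate_state(1)[0] % 2**31)
                 for s in ss.spawn(spec.n_molecules)]
        chains = [confined_zigzag_chain(spec.row_separation,
                                        spec.vertex_angle_range,
                                        spec.n_segments, spec.a, seed=s)
                  for s in seeds]
    else:
        raise ValueError(f"{spec.kind} is not a trace fixture kind")
    if spec.planted_kinks:
        planted = []
        ss = np.random.SeedSequence(spec.seed + 1)
        seeds = [int(s.generate_state(1)[0] % 2**31)
                 for s in ss.spawn(len(chains))]
        for c, s in zip(chains, seeds):
            planted.append(plant_kinks(c, spec.planted_kinks,
                                       spec.kink_angle_range, seed=s))
        chains = planted
    return chains


def make_trace_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Generate a trace fixture with ground truth and metadata.

    Writes ``traces.tsv``, ``truth.csv`` (per-molecule ground truth:
    generating P, planted/inserted kinks with site, arc position and
    angle, template orientation, zigzag segment lengths) and
    ``metadata.json`` (seed, config hash, file list).  Deterministic
    per seed: identical specs produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chains = _generate_chains(spec)
    traces = chains_to_traces(chains, noise=spec.noise, seed=spec.seed + 7)

    truth_rows = []
    for i, c in enumerate(chains):
        mid = f"mol{i:04d}"
        base = {"molecule_id": mid, "P_nm": spec.P,
                "kind": spec.kind,
                "template_orientation_deg":
                    c.metadata.get("template_orientation", ""),
                }
        if c.kinks:
            for (site, angle, torque) in c.kinks:
                spacing = c.spacing if c.spacing else spec.a
                truth_rows.append(dict(base, kink_site=site,
                                       kink_arc_nm=site * spacing,
                                       kink_angle_deg=angle,
                                       kink_torque_pNnm=torque))
        else:
            truth_rows.append(dict(base, kink_site="", kink_arc_nm="",
                                   kink_angle_deg="", kink_torque_pNnm=""))
        if spec.kind == "zigzag":
            for r in truth_rows[::-1]:
                if r["molecule_id"] == mid:
                    r["segment_lengths_nm"] = ";".join(
                        f"{x:.4f}" for x in c.metadata["segment_lengths"])
                    break

    write_traces(traces, out / "traces.tsv")
    pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)
    meta = {"spec": asdict(spec), "seed": spec.seed,
            "config_hash": spec.config_hash(),
            "files": ["traces.tsv", "truth.csv"]}
    (out / "metadata.json").write_text(json.dumps(meta, indent=2,
                                                  default=str) + "\n")
    return meta


def make_height_profile(out_path: str | Path | None = None,
                        period: float = 8.0, d_DNA: float = 2.0,
                        low: float | None = None, high: float | None = None,
                        noise: float = 0.0, length: float = 400.0,
                        dx: float = 0.25, seed: int = 0):
    """Quasi-periodic longitudinal height profile of compressed DNA.

    Minima near ``low`` (default d_DNA/3) repeat at ``period`` (~8 nm,
    the inter-depression spacing where the DNA crosses charged rows);
    maxima near ``high`` (default 2 d_DNA/3).  Additive Gaussian noise
    of scale ``noise`` nm emulates measurement roughness.  Returns
    ``(arc, height, truth)`` and optionally writes a CSV plus truth
    metadata JSON next to it.
    """
    low = d_DNA / 3.0 if low is None else low
    high = 2.0 * d_DNA / 3.0 if high is None else high
    if not 0 < low < high <= d_DNA:
        raise ValueError("need 0 < low < high <= d_DNA")
    rng = np.random.default_rng(seed)
    arc = np.arange(0.0, length + dx / 2, dx)
    mid = (low + high) / 2.0
    amp = (high - low) / 2.0
    height = mid - amp * np.cos(2 * math.pi * arc / period)
    if noise > 0:
        height = height + rng.normal(0.0, noise, size=len(arc))
        height = np.clip(height, 1e-3, d_DNA)
    truth = {"period_nm": period, "low_nm": low, "high_nm": high,
             "noise_nm": noise, "seed": seed}
    if out_path is not None:
        out_path = Path(out_path)
        pd.DataFrame({"arc_nm": arc, "height_nm": height}).to_csv(
            out_path, index=False, float_format="%.6f")
        out_path.with_suffix(".truth.json").write_text(
            json.dumps(truth, indent=2) + "\n")
    return arc, height, truth
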