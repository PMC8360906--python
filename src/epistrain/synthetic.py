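"""Synthetic pseudo-experimental datasets.

Stand-ins for the confocal-derived measurements: traced apical polygons
around a hyper-contractile cluster (with junction-localisation jitter),
exponential-saturation recoil traces with additive noise, and division
events with a configurable angular bias toward the cluster.  Every
generator is a deterministic function of ``master_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mechanics import simulate_cluster_tissue
from .params import MechanicalParams
from .recoil import RecoilTrace
from .shape import DivisionEvent
from .tracing import tissue_to_tracing

DEFAULT_RECOIL_GROUPS = {
    # amplitude scale per experimental group: hyper-contractile clusters
    # recoil roughly twice as far as controls; k identical across groups
    "GFP": 1.0,
    "kRasV12": 2.0,
    "cMYC": 1.0,
    "wild_type": 1.3,
}


@dataclass
class RecoilParams:
    d0: float = 10.0  # pre-ablation vertex separation (um)
    amplitude: float = 1.0  # base recoil amplitude D (um)
    rate: float = 0.1  # relaxation rate k (1/s); resolvable at 4 s frames
    noise_sigma: float = 0.05  # additive measurement noise (um)
    dt: float = 4.0  # frame interval (s)
    n_points: int = 16  # post-ablation frames (~1 min movie)
    n_baseline: int = 2  # pre-ablation frames
    n_traces: int = 10  # traces per group


@dataclass
class DivisionParams:
    rate_percent_per_min: float = 0.2
    kappa: float = 0.0  # angular concentration toward the cluster (0 = uniform)
    n_cells: int = 100
    duration_min: float = 30.0
    out_of_plane_fraction: float = 0.1
    cluster_radius: float = 1.0
    field_radius: float = 4.0


@dataclass
class SyntheticConfig:
    """Study conditions for all three generators."""

    true_increment: float = 0.09
    n_pseudo_embryos: int = 5
    vertex_jitter_sigma: float = 0.02  # fraction of mean edge length
    n_cells: int = 300
    cluster_size: int = 19
    relax_tol: float = 1e-6
    master_seed: int = 0
    params: MechanicalParams = field(default_factory=MechanicalParams)
    recoil: RecoilParams = field(default_factory=RecoilParams)
    divisions: DivisionParams = field(default_factory=DivisionParams)

    def __post_init__(self):
        if self.vertex_jitter_sigma < 0:
            raise ValueError("vertex_jitter_sigma must be >= 0")
        if self.recoil.noise_sigma < 0:
            raise ValueError("recoil noise_sigma must be >= 0")
        if self.divisions.rate_percent_per_min < 0:
            raise ValueError("division rate must be >= 0")


def derived_seed(master_seed: int, *stream) -> int:
    """Deterministic 31-bit child seed for a named random stream."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, stream)])
    return int(ss.generate_state(1)[0] % (2**31))


def synth_tracings(config: SyntheticConfig) -> pd.DataFrame:
    """Pseudo-experimental tracing table.

    Each pseudo-embryo is an independent simulated tissue at
    ``true_increment``, exported as traced polygons with isotropic Gaussian
    junction jitter of ``vertex_jitter_sigma`` times the mean edge length.
    """
    frames = []
    params = config.params.with_increment(config.true_increment)
    for i in range(config.n_pseudo_embryos):
        tissue_seed = derived_seed(config.master_seed, 1, i)
        tissue = simulate_cluster_tissue(
            config.n_cells,
            tissue_seed,
            params,
            cluster_size=config.cluster_size,
            relax_tol=config.relax_tol,
        )
        jitter_rng = np.random.default_rng(derived_seed(config.master_seed, 2, i))
        frames.append(
            tissue_to_tracing(
                tissue,
                embryo_id=f"embryo{i:02d}",
                jitter_sigma=config.vertex_jitter_sigma,
                rng=jitter_rng if config.vertex_jitter_sigma > 0 else None,
            )
        )
    return pd.concat(frames, ignore_index=True)


def synth_recoil(config: SyntheticConfig, groups: dict = None) -> pd.DataFrame:
    """Synthetic recoil traces, one block of rows per trace.

    Each trace is d(t) = d0 + D (1 - exp(-k t)) + N(0, sigma^2) sampled
    every ``dt`` seconds, preceded by baseline frames at the pre-ablation
    separation; ``groups`` maps group name to amplitude scale.
    """
    if groups is None:
        groups = DEFAULT_RECOIL_GROUPS
    rp = config.recoil
    rows = []
    for g_idx, (group, scale) in enumerate(sorted(groups.items())):
        for j in range(rp.n_traces):
            rng = np.random.default_rng(
                derived_seed(config.master_seed, 3, g_idx, j)
            )
            t_pre = -rp.dt * np.arange(rp.n_baseline, 0, -1)
            t_post = rp.dt * np.arange(rp.n_points)
            t = np.concatenate([t_pre, t_post])
            d = np.where(
                t < 0,
                rp.d0,
                rp.d0 + scale * rp.amplitude * (1.0 - np.exp(-rp.rate * np.maximum(t, 0.0))),
            )
            d = d + (rng.normal(0.0, rp.noise_sigma, t.shape) if rp.noise_sigma > 0 else 0.0)
            for ti, di in zip(t, d):
                rows.append(
                    {
                        "trace_id": f"{group}_{j:02d}",
                        "group": group,
                        "time_s": float(ti),
                        "distance": float(di),
                    }
                )
    return pd.DataFrame(rows)


def recoil_traces_from_frame(df: pd.DataFrame):
    """Parse a recoil table into RecoilTrace objects (one per trace_id)."""
    traces = []
    for (tid, group), grp in df.groupby(["trace_id", "group"], sort=True):
        grp = grp.sort_values("time_s")
        traces.append(
            RecoilTrace(
                time_s=grp["time_s"].to_numpy(dtype=float),
                distance=grp["distance"].to_numpy(dtype=float),
                group=str(group),
                trace_id=tid,
            )
        )
    return traces


def _sample_axis_angles(rng: np.random.Generator, n: int, kappa: float) -> np.ndarray:
    """Axis angles (degrees, relative to the cluster direction) in [0, 90].

    Axial von Mises: the doubled angle 2*theta is von Mises(0, kappa);
    kappa = 0 degenerates to a uniform distribution on [0, 90].
    """
    if kappa == 0:
        return rng.uniform(0.0, 90.0, n)
    doubled = rng.vonmises(0.0, kappa, n)
    theta = np.degrees(doubled / 2.0) % 180.0
    return np.minimum(theta, 180.0 - theta)


def synth_divisions(config: SyntheticConfig):
    """Synthetic division events around a circular cluster at the origin.

    Event count is Poisson with mean rate/100 * n_cells * duration; axis
    angles relative to the cluster direction follow an axial von Mises law
    with concentration ``kappa``.  Returns (events, table) where ``events``
    are in-plane :class:`DivisionEvent` objects and ``table`` records every
    event including out-of-plane ones.
    """
    dp = config.divisions
    rng = np.random.default_rng(derived_seed(config.master_seed, 4))
    mean_events = dp.rate_percent_per_min / 100.0 * dp.n_cells * dp.duration_min
    n_events = rng.poisson(mean_events)
    events = []
    rows = []
    angles = _sample_axis_angles(rng, n_events, dp.kappa)
    for i in range(n_events):
        radius = rng.uniform(dp.cluster_radius * 1.05, dp.field_radius)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        centroid = radius * np.array([np.cos(phi), np.sin(phi)])
        # reference direction: toward the nearest cluster-boundary point,
        # i.e. toward the origin for a circular cluster
        ref = np.degrees(np.arctan2(-centroid[1], -centroid[0]))
        sign = rng.choice([-1.0, 1.0])
        axis_deg = np.radians(ref + sign * angles[i])
        axis = np.array([np.cos(axis_deg), np.sin(axis_deg)])
        in_plane = bool(rng.random() >= dp.out_of_plane_fraction)
        time_min = float(rng.uniform(0.0, dp.duration_min))
        rows.append(
            {
                "time_min": time_min,
                "x": float(centroid[0]),
                "y": float(centroid[1]),
                "axis_x": float(axis[0]),
                "axis_y": float(axis[1]),
                "in_plane": in_plane,
            }
        )
        if in_plane:
            events.append(
                DivisionEvent(
                    time_min=time_min,
                    cell_centroid=centroid,
                    daughter_axis=axis,
                    in_plane=True,
                )
            )
    table = pd.DataFrame(
        rows, columns=["time_min", "x", "y", "axis_x", "axis_y", "in_plane"]
    )
    return events, table
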