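"""Ground-truth-labelled simulators of aggregation movies.

Three frame-iterative growth engines emulate the morphology classes seen
in protein-aggregation SMLM experiments:

* **isotropic** — radially symmetric spherulite-like accretion: each frame
  a Uniform{0..30} number of points is sampled from a Gaussian KDE
  refitted to all current points, with the bandwidth growing linearly in
  time, ``bandwidth = ((f - f_start)/(f_end - f_start) * f_end + 1) * 10``
  nm.
* **random** (steric hindrance) — Monte-Carlo growth where candidate
  points drawn around recently added points are accepted in order of
  lowest steric hindrance ``sum(exp(-d^2))``, producing branched
  asymmetric structures.
* **fibril** — a directed diffusion scheme: thin, elongating, occasionally
  branching polylines with Gaussian step lengths and turn angles.

Movies place several assemblies (possibly overlapping) in a 40 × 40 µm
field of view with randomly drawn onset/end frames, then append uniform
or heterogeneous (noise-seed) background noise.  Every generator is a
pure function of its parameters and RNG: a fixed seed reproduces the
output exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IsotropicGrowthParams",
    "StericGrowthParams",
    "FibrilGrowthParams",
    "MovieSpec",
    "SimulatedMovie",
    "isotropic_bandwidth",
    "steric_hindrance",
    "simulate_isotropic",
    "simulate_steric",
    "simulate_fibril",
    "simulate_sparse_structure",
    "apply_blinking",
    "add_noise",
    "assemble_movie",
    "interpolate_pair",
    "morph_sequence",
    "reverse_time",
]

NOISE_ID = -1


# --------------------------------------------------------------------- params


@dataclass(frozen=True)
class IsotropicGrowthParams:
    frame_start: int = 0
    frame_end: int = 100
    points_per_frame: tuple[int, int] = (0, 30)  # inclusive uniform range
    bandwidth_unit: float = 10.0  # nm, the factor multiplying the growth law

    def bandwidth(self, frame: int) -> float:
        f0, f1 = self.frame_start, self.frame_end
        if f1 <= f0:
            raise ValueError("frame_end must exceed frame_start")
        return ((frame - f0) / (f1 - f0) * f1 + 1.0) * self.bandwidth_unit


@dataclass(frozen=True)
class StericGrowthParams:
    frame_start: int = 0
    frame_end: int = 100
    candidate_sigma: float = 100.0  # nm; the working unit of the unit Gaussian
    points_per_frame_mean: float = 10.0  # Poisson mean of accepted candidates
    neighborhood: int = 50  # candidates come from / hindrance sums over last <= 50 points


@dataclass(frozen=True)
class FibrilGrowthParams:
    frame_start: int = 0
    frame_end: int = 100
    points_per_step_mean: float = 1.0  # Poisson mean per active branch per frame
    step_mean: float = 100.0  # nm
    step_sd: float = 20.0  # nm
    turn_sd: float = np.pi / 4
    branch_prob: float = 0.005
    max_branches: int = 3
    branch_angle_offset: float = np.pi / 4
    branch_angle_sd: float = np.pi / 16


@dataclass(frozen=True)
class MovieSpec:
    """Study conditions for one simulated movie."""

    fov: tuple[float, float] = (40_000.0, 40_000.0)  # nm
    n_assemblies: dict = field(default_factory=lambda: {"isotropic": 10})
    max_frames: int = 400
    start_window: int = 300  # onsets drawn in the first `start_window` frames
    min_lifetime: int = 100  # frames
    noise_mode: str = "uniform"  # uniform | heterogeneous | none
    noise_amount: float = 0.3  # uniform mode: noise points as fraction of signal
    sparse_n_points: int = 4  # detections per structure for sparse classes
    seed: int = 0

    def __post_init__(self):
        if self.start_window + self.min_lifetime > self.max_frames:
            raise ValueError("start_window + min_lifetime must not exceed max_frames")


@dataclass
class SimulatedMovie:
    """A labelled localization table plus its generating ground truth."""

    table: pd.DataFrame  # x, y, t, assembly_id, class
    spec: MovieSpec
    ground_truth: pd.DataFrame  # assembly_id, class, onset, end, origin_x, origin_y

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def manifest(self) -> dict:
        return {
            "spec": asdict(self.spec),
            "ground_truth": self.ground_truth.to_dict(orient="records"),
        }

    def save(self, csv_path, manifest_path=None) -> None:
        self.to_csv(csv_path)
        if manifest_path is not None:
            with open(manifest_path, "w") as fh:
                json.dump(self.manifest(), fh, indent=2)


# -------------------------------------------------------------- growth engines


def isotropic_bandwidth(frame, frame_start, frame_end, unit=10.0):
    """Linear-in-time KDE bandwidth law for isotropic growth (nm)."""
    return IsotropicGrowthParams(frame_start, frame_end, bandwidth_unit=unit).bandwidth(frame)


def simulate_isotropic(params: IsotropicGrowthParams, rng: np.random.Generator) -> pd.DataFrame:
    """Grow one isotropic assembly around the origin; returns x, y, t (nm, frames)."""
    lo, hi = params.points_per_frame
    pts = [np.zeros(2)]
    frames = [params.frame_start]
    for f in range(params.frame_start, params.frame_end + 1):
        bw = params.bandwidth(f)
        k = int(rng.integers(lo, hi + 1))
        if k == 0:
            continue
        base = np.asarray(pts)
        centers = base[rng.integers(0, len(base), size=k)]
        new = centers + rng.normal(0.0, bw, size=(k, 2))
        pts.extend(new)
        frames.extend([f] * k)
    return pd.DataFrame({"x": [p[0] for p in pts], "y": [p[1] for p in pts], "t": frames})


def steric_hindrance(distances) -> float:
    """Steric hindrance of a candidate: sum(exp(-d^2)) over nearby points."""
    d = np.asarray(distances, float)
    return float(np.sum(np.exp(-(d**2))))


def simulate_steric(params: StericGrowthParams, rng: np.random.Generator) -> pd.DataFrame:
    """Grow one steric-hindrance ("random") assembly around the origin."""
    u = params.candidate_sigma  # working unit in nm
    pts = [np.zeros(2)]
    frames = [params.frame_start]
    for f in range(params.frame_start, params.frame_end + 1):
        recent = np.asarray(pts[-params.neighborhood:])
        cand = recent + rng.normal(0.0, u, size=recent.shape)
        # hindrance in working units against the same recent neighbourhood
        d2 = np.sum((cand[:, None, :] - recent[None, :, :]) ** 2, axis=-1) / u**2
        hindrance = np.exp(-d2).sum(axis=1)
        k = min(int(rng.poisson(params.points_per_frame_mean)), len(cand))
        if k == 0:
            continue
        accepted = cand[np.argsort(hindrance, kind="stable")[:k]]
        pts.extend(accepted)
        frames.extend([f] * k)
    return pd.DataFrame({"x": [p[0] for p in pts], "y": [p[1] for p in pts], "t": frames})


def simulate_fibril(
    params: FibrilGrowthParams, rng: np.random.Generator, n_points: int | None = None
) -> pd.DataFrame:
    """Grow one (possibly branching) fibril from the origin.

    ``n_points`` optionally caps the total number of points (used by the
    sparse protocol); growth then stops once the cap is reached.
    """
    start_dir = rng.uniform(0.0, 2 * np.pi)
    # each branch: [tip_x, tip_y, direction]
    branches = [[0.0, 0.0, start_dir]]
    n_branch_events = 0
    xs, ys, frames = [0.0], [0.0], [params.frame_start]
    for f in range(params.frame_start, params.frame_end + 1):
        if n_points is not None and len(xs) >= n_points:
            break
        for b in list(branches):
            k = int(rng.poisson(params.points_per_step_mean))
            for _ in range(k):
                if n_points is not None and len(xs) >= n_points:
                    break
                direction = rng.normal(b[2], params.turn_sd)
                step = rng.normal(params.step_mean, params.step_sd)
                b[0] += np.cos(direction) * step
                b[1] += np.sin(direction) * step
                b[2] = direction
                xs.append(b[0])
                ys.append(b[1])
                frames.append(f)
                if (
                    n_branch_events < params.max_branches
                    and rng.random() < params.branch_prob
                ):
                    side = 1.0 if rng.random() < 0.5 else -1.0
                    new_dir = rng.normal(
                        direction + side * params.branch_angle_offset,
                        params.branch_angle_sd,
                    )
                    branches.append([b[0], b[1], new_dir])
                    n_branch_events += 1
    return pd.DataFrame({"x": xs, "y": ys, "t": frames})


def simulate_sparse_structure(
    kind: str, n_points: int, rng: np.random.Generator, n_frames: int = 400
) -> pd.DataFrame:
    """One sparse nanostructure: a short fibril or a rotated Gaussian ellipse.

    Sparse fibrils use the fibril engine with a mean elongation of 20 nm
    (SD 5 nm) and consecutive frames; ellipses draw x ~ N(0, 10^2),
    y ~ N(0, 20^2) nm, apply a random rotation, and assign uniformly
    random frames (emulating static SMLM acquisitions).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if kind == "fibril":
        params = FibrilGrowthParams(
            frame_start=0,
            frame_end=10 * n_points,
            step_mean=20.0,
            step_sd=5.0,
        )
        out = simulate_fibril(params, rng, n_points=n_points)
        out["t"] = np.arange(len(out))
        return out
    if kind == "ellipse":
        xy = np.column_stack([rng.normal(0, 10.0, n_points), rng.normal(0, 20.0, n_points)])
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        xy = xy @ rot.T
        t = rng.integers(0, n_frames, size=n_points)
        return pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "t": t})
    raise ValueError(f"unknown sparse structure kind {kind!r}")


# ------------------------------------------------------------------ corruption


def apply_blinking(structure: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Replace each ground-truth point by 1–6 displaced blinking detections.

    Each detection is displaced by a Gaussian localization error whose
    sigma is itself drawn from LogNormal(mean=3, sigma=0.28) on the log
    scale (median ≈ 20 nm).  The original points are not kept.
    """
    if len(structure) == 0:
        raise ValueError("structure must be non-empty")
    rows = []
    for _, row in structure.iterrows():
        k = int(rng.integers(1, 7))
        sigmas = rng.lognormal(3.0, 0.28, size=k)
        dx = rng.normal(0.0, sigmas)
        dy = rng.normal(0.0, sigmas)
        for j in range(k):
            r = row.copy()
            r["x"] = row["x"] + dx[j]
            r["y"] = row["y"] + dy[j]
            rows.append(r)
    return pd.DataFrame(rows).reset_index(drop=True)


def add_noise(
    movie: SimulatedMovie,
    mode: str | None = None,
    amount: float | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedMovie:
    """Append background-noise rows (assembly_id = -1) to a movie.

    ``uniform`` noise is uniform in x, y over the field of view and in t
    over the movie; ``amount`` is the noise count as a fraction of the
    signal count.  ``heterogeneous`` noise places 5–25 noise seeds
    uniformly in the FOV, each contributing 20–50 Gaussian points
    (sigma 320 nm) that are further displaced by a radial magnitude
    ~ N(20000, 100^2) nm along a uniformly random direction, clipped to
    the FOV; frames are drawn uniformly.  Non-noise rows are never
    modified.
    """
    spec = movie.spec
    mode = spec.noise_mode if mode is None else mode
    amount = spec.noise_amount if amount is None else amount
    if mode == "none" or (mode == "uniform" and amount == 0):
        return movie
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    w, h = spec.fov
    if mode == "uniform":
        n_signal = int((movie.table["assembly_id"] != NOISE_ID).sum())
        n = int(round(amount * n_signal))
        x = rng.uniform(0, w, n)
        y = rng.uniform(0, h, n)
    elif mode == "heterogeneous":
        n_seeds = int(rng.integers(5, 26))
        xs, ys = [], []
        for _ in range(n_seeds):
            ox, oy = rng.uniform(0, w), rng.uniform(0, h)
            m = int(rng.integers(20, 51))
            px = ox + rng.normal(0, 320.0, m)
            py = oy + rng.normal(0, 320.0, m)
            mag = rng.normal(20_000.0, 100.0, m)
            ang = rng.uniform(0, 2 * np.pi, m)
            xs.append(px + mag * np.cos(ang))
            ys.append(py + mag * np.sin(ang))
        x = np.clip(np.concatenate(xs), 0, w)
        y = np.clip(np.concatenate(ys), 0, h)
        n = len(x)
    else:
        raise ValueError(f"unknown noise mode {mode!r}")
    noise = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "t": rng.integers(0, spec.max_frames, n),
            "assembly_id": NOISE_ID,
            "class": "noise",
        }
    )
    table = pd.concat([movie.table, noise], ignore_index=True)
    return SimulatedMovie(table=table, spec=spec, ground_truth=movie.ground_truth)


# --------------------------------------------------------------- movie builder

_ENGINES = {"isotropic", "random", "fibril", "sparse_fibril", "ellipse"}


def _grow(cls: str, onset: int, end: int, rng: np.random.Generator, spec: MovieSpec):
    if cls == "isotropic":
        return simulate_isotropic(IsotropicGrowthParams(onset, end), rng)
    if cls == "random":
        return simulate_steric(StericGrowthParams(onset, end), rng)
    if cls == "fibril":
        return simulate_fibril(FibrilGrowthParams(onset, end), rng)
    if cls == "sparse_fibril":
        out = simulate_sparse_structure("fibril", spec.sparse_n_points, rng)
        out["t"] = out["t"] + onset
        return out
    if cls == "ellipse":
        out = simulate_sparse_structure("ellipse", spec.sparse_n_points, rng, spec.max_frames)
        return out
    raise ValueError(f"unknown assembly class {cls!r}; known: {sorted(_ENGINES)}")


def assemble_movie(spec: MovieSpec, rng: np.random.Generator | None = None) -> SimulatedMovie:
    """Build one labelled movie from a :class:`MovieSpec`.

    Assemblies are placed at uniformly random origins in the FOV with
    onset frames drawn in the first ``start_window`` frames and lifetimes
    of at least ``min_lifetime`` frames; spatial overlap between
    assemblies is permitted (and expected).  Noise is appended per the
    spec's noise mode.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    w, h = spec.fov
    tables, gt = [], []
    aid = 0
    for cls, count in spec.n_assemblies.items():
        for _ in range(count):
            onset = int(rng.integers(0, spec.start_window))
            end = int(rng.integers(onset + spec.min_lifetime, spec.max_frames))
            origin = rng.uniform([0, 0], [w, h])
            pts = _grow(cls, onset, end, rng, spec)
            pts["x"] += origin[0]
            pts["y"] += origin[1]
            pts["assembly_id"] = aid
            pts["class"] = cls
            tables.append(pts)
            gt.append(
                {
                    "assembly_id": aid,
                    "class": cls,
                    "onset": int(pts["t"].min()),
                    "end": int(pts["t"].max()),
                    "origin_x": origin[0],
                    "origin_y": origin[1],
                }
            )
            aid += 1
    table = pd.concat(tables, ignore_index=True)
    movie = SimulatedMovie(table=table, spec=spec, ground_truth=pd.DataFrame(gt))
    return add_noise(movie, rng=rng)


# ---------------------------------------------------- dynamic morphology tools


def interpolate_pair(a, b, fraction: float, rng: np.random.Generator | None = None):
    """Linearly interpolate between two centred point sets.

    Points are matched by minimum-cost assignment on pairwise distances
    after centroid alignment; the smaller set is padded by seeded
    resampling.  ``fraction`` 0 returns ``a`` exactly, 1 returns ``b``.
    """
    from scipy.optimize import linear_sum_assignment
    from scipy.spatial.distance import cdist

    if rng is None:
        rng = np.random.default_rng(0)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    n = max(len(a), len(b))
    if len(a) < n:
        a = np.vstack([a, a[rng.integers(0, len(a), n - len(a))]])
    if len(b) < n:
        b = np.vstack([b, b[rng.integers(0, len(b), n - len(b))]])
    rows, cols = linear_sum_assignment(cdist(a, b))
    return (1 - fraction) * a[rows] + fraction * b[cols]


def morph_sequence(structures, n_interp: int, rng: np.random.Generator | None = None):
    """Intermediate point sets morphing through a list of structures.

    For each consecutive pair, ``n_interp`` intermediates are constructed
    at fractions strictly between 0 and 1, giving
    ``(len(structures) - 1) * n_interp`` point sets in total (90
    structures with 100 interpolants each yield 8900).
    """
    if len(structures) < 2:
        raise ValueError("need at least 2 structures to morph between")
    if rng is None:
        rng = np.random.default_rng(0)
    fractions = np.linspace(0.0, 1.0, n_interp + 2)[1:-1]
    out = []
    for a, b in zip(structures[:-1], structures[1:]):
        for f in fractions:
            out.append(interpolate_pair(a, b, f, rng))
    return out


def reverse_time(movie: SimulatedMovie) -> SimulatedMovie:
    """Reverse the time axis: t -> max(t) - t; supports shrinking-structure studies."""
    if "t" not in movie.table.columns:
        raise ValueError("movie has no time axis to reverse")
    tmax = int(movie.table["t"].max())
    table = movie.table.copy()
    table["t"] = tmax - table["t"]
    gt = movie.ground_truth.copy()
    if {"onset", "end"} <= set(gt.columns):
        onset, end = gt["onset"].copy(), gt["end"].copy()
        gt["onset"] = tmax - end
        gt["end"] = tmax - onset
    return SimulatedMovie(table=table, spec=movie.spec, ground_truth=gt)
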