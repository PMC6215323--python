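"""Directional statistics for cell migration tracks.

Per cell: forward migration index (FMI) parallel and perpendicular to the
oxygen gradient, mean velocity, path length, net displacement.  Per
population: weighted angular histogram of final positions, centre-of-mass
displacement, and rank-based (Kruskal-Wallis) group comparison.

Sign convention: the gradient frame's unit vector points toward HIGHER
oxygen, so cells moving toward hypoxia have negative FMI_parallel.  The
convention is configurable by flipping the vector.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


@dataclass
class Track:
    """One cell's trajectory: strictly increasing times (min), positions (um)."""

    track_id: str | int
    t_min: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        n = len(self.t_min)
        if not (len(self.x_um) == len(self.y_um) == n):
            raise ValidationError(f"track {self.track_id}: ragged frame arrays")
        if n < 2:
            raise ValidationError(f"track {self.track_id}: needs >= 2 frames")
        if not np.all(np.diff(self.t_min) > 0):
            raise ValidationError(
                f"track {self.track_id}: time stamps must be strictly increasing"
            )
        for name, arr in (("t", self.t_min), ("x", self.x_um), ("y", self.y_um)):
            if not np.isfinite(arr).all():
                raise ValidationError(
                    f"track {self.track_id}: non-finite {name} coordinate"
                )

    def __len__(self) -> int:
        return len(self.t_min)

    @property
    def positions(self) -> np.ndarray:
        """(n_frames, 2) array of xy positions."""
        return np.column_stack([self.x_um, self.y_um])

    @property
    def steps(self) -> np.ndarray:
        return np.diff(self.positions, axis=0)

    @property
    def path_length(self) -> float:
        """Total migration path length (um)."""
        return float(np.linalg.norm(self.steps, axis=1).sum())

    @property
    def net_displacement(self) -> np.ndarray:
        """Final minus initial position (um)."""
        return self.positions[-1] - self.positions[0]

    @property
    def duration_min(self) -> float:
        return float(self.t_min[-1] - self.t_min[0])


class TrackSet:
    """An ordered collection of tracks, optionally labelled by population."""

    def __init__(self, tracks: Iterable[Track], name: str | None = None):
        self.tracks: list[Track] = list(tracks)
        self.name = name

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def __getitem__(self, i: int) -> Track:
        return self.tracks[i]

    def labels(self) -> list[str | None]:
        return [t.label for t in self.tracks]

    def subset(self, label: str) -> "TrackSet":
        return TrackSet([t for t in self.tracks if t.label == label], name=label)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.tracks:
            frame_idx = np.arange(len(tr))
            rows.append(
                pd.DataFrame(
                    {
                        "track_id": tr.track_id,
                        "frame": frame_idx,
                        "t_min": tr.t_min,
                        "x_um": tr.x_um,
                        "y_um": tr.y_um,
                        "label": tr.label if tr.label is not None else "",
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, name: str | None = None) -> "TrackSet":
        tracks = []
        for tid, grp in frame.groupby("track_id", sort=True):
            grp = grp.sort_values("t_min")
            label = None
            if "label" in grp.columns:
                raw = grp["label"].iloc[0]
                label = None if (pd.isna(raw) or raw == "") else str(raw)
            tracks.append(
                Track(
                    track_id=tid,
                    t_min=grp["t_min"].to_numpy(),
                    x_um=grp["x_um"].to_numpy(),
                    y_um=grp["y_um"].to_numpy(),
                    label=label,
                )
            )
        return cls(tracks, name=name)


@dataclass(frozen=True)
class GradientFrame:
    """Reference frame for directional statistics.

    ``direction`` is the unit vector along INCREASING oxygen; positive
    FMI_parallel therefore means net migration toward higher O2.  The
    perpendicular axis is the 90-degree counterclockwise rotation.
    """

    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (2,) or not math.isclose(float(np.linalg.norm(d)), 1.0, rel_tol=1e-9):
            raise ValidationError("gradient direction must be a 2D unit vector")
        object.__setattr__(self, "direction", d)

    @property
    def perpendicular(self) -> np.ndarray:
        gx, gy = self.direction
        return np.array([-gy, gx])

    @classmethod
    def from_axis(cls, axis: str = "x", sign: int = 1) -> "GradientFrame":
        if axis not in ("x", "y") or sign not in (1, -1):
            raise ValidationError("axis must be 'x'|'y' and sign +1|-1")
        vec = {"x": [1.0, 0.0], "y": [0.0, 1.0]}[axis]
        return cls(np.asarray(vec) * sign)


def offset_to_origin(track: Track) -> Track:
    """Translate a track so its first frame sits at (0, 0)."""
    return replace(
        track, x_um=track.x_um - track.x_um[0], y_um=track.y_um - track.y_um[0]
    )


def fmi(track: Track, frame: GradientFrame) -> tuple[float, float]:
    """Forward migration index parallel/perpendicular to the gradient.

    Net displacement projected on the gradient direction (and its 90-degree
    rotation) divided by the total path length; each component is signed and
    bounded by 1 in magnitude.  A track with zero path length has no defined
    direction and yields (nan, nan) with a warning.
    """
    length = track.path_length
    if length == 0:
        warnings.warn(
            f"track {track.track_id} has zero path length; FMI undefined",
            stacklevel=2,
        )
        return (math.nan, math.nan)
    net = track.net_displacement
    return (
        float(net @ frame.direction) / length,
        float(net @ frame.perpendicular) / length,
    )


def mean_velocity(track: Track) -> float:
    """Total path length divided by elapsed time (um/min)."""
    if track.duration_min <= 0:
        raise ValidationError(f"track {track.track_id}: zero duration")
    return track.path_length / track.duration_min


def com_displacement(tracks: TrackSet | Sequence[Track]) -> np.ndarray:
    """Centre-of-mass displacement: mean final minus mean initial position (um)."""
    tracks = list(tracks)
    if not tracks:
        raise ValidationError("com_displacement requires at least one track")
    finals = np.array([t.positions[-1] for t in tracks])
    initials = np.array([t.positions[0] for t in tracks])
    return finals.mean(axis=0) - initials.mean(axis=0)


@dataclass
class AngularHistogram:
    """Distance-weighted histogram of final-position angles.

    Each motile cell contributes weight d_i / mean(d) to the bin holding
    its net-displacement angle (counterclockwise from +x), so the weights
    sum to the number of contributing cells.
    """

    bin_edges_deg: np.ndarray
    weights: np.ndarray
    n_contributing: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_deg": self.bin_edges_deg[:-1],
                "bin_end_deg": self.bin_edges_deg[1:],
                "weight": self.weights,
            }
        )


def weighted_angular_histogram(
    tracks: TrackSet | Sequence[Track], n_bins: int = 8
) -> AngularHistogram:
    """Weighted angular histogram of net displacements.

    Bins are [k*360/n, (k+1)*360/n) degrees measured counterclockwise from
    +x.  Cells with zero net displacement have no angle; they contribute
    nothing and are excluded from the mean distance.
    """
    tracks = list(tracks)
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    if not tracks:
        raise ValidationError("histogram requires at least one track")
    nets = np.array([t.net_displacement for t in tracks])
    dist = np.linalg.norm(nets, axis=1)
    motile = dist > 0
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    weights = np.zeros(n_bins)
    if not motile.any():
        warnings.warn("all cells immobile; angular histogram is empty", stacklevel=2)
        return AngularHistogram(edges, weights, 0)
    mean_d = dist[motile].mean()
    angles = np.degrees(np.arctan2(nets[motile, 1], nets[motile, 0])) % 360.0
    bins = np.minimum((angles / (360.0 / n_bins)).astype(int), n_bins - 1)
    np.add.at(weights, bins, dist[motile] / mean_d)
    return AngularHistogram(edges, weights, int(motile.sum()))


def summarize_tracks(
    tracks: TrackSet | Sequence[Track], frame: GradientFrame
) -> pd.DataFrame:
    """Per-cell migration summary table.

    Columns: track_id, label, fmi_parallel, fmi_perpendicular,
    mean_velocity_um_min, path_length_um, net_displacement_um.
    """
    rows = []
    for tr in tracks:
        par, perp = fmi(tr, frame) if tr.path_length > 0 else (math.nan, math.nan)
        rows.append(
            {
                "track_id": tr.track_id,
                "label": tr.label,
                "fmi_parallel": par,
                "fmi_perpendicular": perp,
                "mean_velocity_um_min": mean_velocity(tr),
                "path_length_um": tr.path_length,
                "net_displacement_um": float(np.linalg.norm(tr.net_displacement)),
            }
        )
    return pd.DataFrame(rows)


def aggregate_conditions(
    summaries: Mapping[str, pd.DataFrame],
    value_cols: Sequence[str] = ("fmi_parallel", "fmi_perpendicular", "mean_velocity_um_min"),
    mode: str = "per_cell",
    experiment_col: str = "experiment",
) -> pd.DataFrame:
    """Aggregate per-cell summaries into one row per condition.

    ``mode='per_cell'`` pools all cells; ``mode='per_experiment'`` first
    averages within each replicate experiment and then across replicates
    (requires an ``experiment`` column).  Both orders are offered because
    they weight replicates differently.
    """
    if mode not in ("per_cell", "per_experiment"):
        raise ValidationError("mode must be 'per_cell' or 'per_experiment'")
    rows = []
    for cond, df in summaries.items():
        if mode == "per_experiment":
            if experiment_col not in df.columns:
                raise ValidationError(
                    f"per_experiment aggregation needs a {experiment_col!r} column"
                )
            df = df.groupby(experiment_col, as_index=False)[list(value_cols)].mean()
        row: dict[str, object] = {"condition": cond, "n": len(df)}
        for col in value_cols:
            vals = df[col].dropna()
            row[f"{col}_mean"] = vals.mean()
            row[f"{col}_sem"] = vals.sem() if len(vals) > 1 else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def local_response(
    tracks: TrackSet | Sequence[Track],
    o2_at: Callable[[float, float], float] | tuple[np.ndarray, np.ndarray],
    frame: GradientFrame | None = None,
    axis: str = "x",
) -> pd.DataFrame:
    """Single-cell migration behaviour versus local oxygen.

    ``o2_at`` is either a callable ``(x_um, y_um) -> %O2`` or a pair of
    arrays ``(positions_um, o2_percent)`` interpolated linearly along the
    chosen axis.  Oxygen is sampled at each cell's (un-offset) initial
    position; positions outside the profile support are flagged missing.
    One row per track: track_id, o2_percent, fmi_parallel,
    mean_velocity_um_min, valid.
    """
    frame = frame or GradientFrame.from_axis("x")
    tracks = list(tracks)
    if callable(o2_at):
        sample = lambda x, y: float(o2_at(x, y))
    else:
        pos, o2 = (np.asarray(a, dtype=float) for a in o2_at)
        order = np.argsort(pos)
        pos, o2 = pos[order], o2[order]

        def sample(x: float, y: float) -> float:
            c = x if axis == "x" else y
            if c < pos[0] or c > pos[-1]:
                return math.nan
            return float(np.interp(c, pos, o2))

    rows = []
    for tr in tracks:
        x0, y0 = tr.positions[0]
        local = sample(x0, y0)
        par, _ = fmi(tr, frame) if tr.path_length > 0 else (math.nan, math.nan)
        rows.append(
            {
                "track_id": tr.track_id,
                "o2_percent": local,
                "fmi_parallel": par,
                "mean_velocity_um_min": mean_velocity(tr),
                "valid": math.isfinite(local),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class KruskalResult:
    h: float
    df: int
    p: float


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalResult:
    """Kruskal-Wallis rank test with tie correction.

    H = [12 / (N(N+1)) * sum R_j^2 / n_j - 3(N+1)] / (1 - sum(t^3 - t)/(N^3 - N))
    with R_j the rank sum of group j and t the sizes of tied groups; the
    p-value uses the chi-square approximation with k-1 degrees of freedom.
    When every observation is identical the tie correction denominator
    vanishes; that degenerate case is reported as H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValidationError("every group must be nonempty")
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    if n_total < 3:
        raise ValidationError("need at least 3 observations in total")
    k = len(groups)
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_term / (n_total**3 - n_total)
    if denom <= 0:  # all observations identical
        return KruskalResult(0.0, k - 1, 1.0)
    h /= denom
    h = max(h, 0.0)  # guard tiny negative from roundoff
    p = float(stats.chi2.sf(h, k - 1))
    return KruskalResult(float(h), k - 1, p)


def kruskal_wallis_permutation(
    groups: Sequence[Sequence[float]], max_n: int = 10, mid_p: bool = False
) -> float:
    """Exact permutation p-value of the Kruskal-Wallis H statistic.

    Enumerates every assignment of the pooled observations to the group
    sizes; feasible only for small samples (total N <= ``max_n``).  Serves
    as a small-sample reference for the chi-square approximation.  With
    ``mid_p`` the probability mass exactly at the observed H counts half —
    the usual continuity correction when comparing a discrete null against
    a continuous approximation.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    if len(pooled) > max_n:
        raise ValidationError(f"permutation test limited to N <= {max_n}")
    h_obs = kruskal_wallis(groups).h
    n_ge = 0
    n_eq = 0
    total = 0
    for perm in itertools.permutations(range(len(pooled))):
        arranged = pooled[list(perm)]
        split = []
        start = 0
        for s in sizes:
            split.append(arranged[start:start + s])
            start += s
        h = kruskal_wallis(split).h
        if h >= h_obs - 1e-12:
            n_ge += 1
            if abs(h - h_obs) < 1e-9:
                n_eq += 1
        total += 1
    if mid_p:
        return (n_ge - 0.5 * n_eq) / total
    return n_ge / total


def pairwise_kruskal(
    samples: Mapping[str, Sequence[float]], reference: str
) -> pd.DataFrame:
    """Kruskal-Wallis of each condition against a reference condition.

    One row per non-reference condition with H, df and p; no multiple-
    testing correction is applied.
    """
    if reference not in samples:
        raise ValidationError(f"reference condition {reference!r} not present")
    rows = []
    for cond, values in samples.items():
        if cond == reference:
            continue
        res = kruskal_wallis([samples[reference], values])
        rows.append({"condition": cond, "reference": reference,
                     "h": res.h, "df": res.df, "p": res.p})
    return pd.DataFrame(rows)
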