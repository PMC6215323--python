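"""Synthetic migration tracks and quenched-fluorescence images.

The wet-lab inputs of an oxygen-gradient migration experiment are (a)
manually tracked cell trajectories and (b) fluorescence images of an
oxygen-sensitive dye.  This module generates both with the statistical
structure the analysis assumes, so the whole pipeline is testable without
any experimental data.

Tracks follow a biased persistent random walk: each step direction is a
von Mises draw whose natural parameter is the vector sum of a bias term
(concentration ``kappa`` toward the gradient axis) and a persistence term
(toward the previous step direction), and step speeds are lognormal.  This
is deliberately the simplest model exposing both persistence and taxis; it
is test scaffolding, not a biological claim.

Defaults mirror the experimental sampling: 50 cells per condition, imaged
every 10 min over a 390 min (6.5 h) tracking window — the stable-gradient
portion of a 24 h experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from .errors import ValidationError
from .oximetry import forward_intensity
from .track_stats import Track, TrackSet

#: the four experimental conditions: bulk cancer cells and CSC-enriched
#: populations, each with and without an oxygen gradient
DEFAULT_CONDITIONS = (
    "bulk_no_gradient",
    "csc_no_gradient",
    "bulk_gradient",
    "csc_gradient",
)


@dataclass(frozen=True)
class WalkParams:
    """Biased persistent random-walk settings.

    bias_kappa
        von Mises concentration of step directions toward
        ``bias_direction_deg``; 0 means no directional bias.
    persistence
        Circular correlation of successive step directions in [0, 1);
        0 means uncorrelated steps.
    speed_mean_um_min / speed_sd_um_min
        Mean and spread of the per-step lognormal speed distribution.
    """

    n_cells: int = 50
    frame_interval_min: float = 10.0
    duration_min: float = 390.0
    speed_mean_um_min: float = 0.5
    speed_sd_um_min: float = 0.25
    bias_kappa: float = 0.0
    bias_direction_deg: float = 0.0
    persistence: float = 0.0
    start_box_um: tuple[tuple[float, float], tuple[float, float]] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if self.frame_interval_min <= 0 or self.duration_min <= 0:
            raise ValidationError("frame interval and duration must be positive")
        if self.duration_min < self.frame_interval_min:
            raise ValidationError("duration shorter than one frame interval")
        if self.bias_kappa < 0:
            raise ValidationError("bias_kappa must be >= 0")
        if not 0 <= self.persistence < 1:
            raise ValidationError("persistence must lie in [0, 1)")
        if self.speed_mean_um_min <= 0 or self.speed_sd_um_min < 0:
            raise ValidationError("speed mean must be > 0 and sd >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_min / self.frame_interval_min))


def kappa_from_persistence(rho: float) -> float:
    """von Mises concentration giving mean resultant length ``rho``.

    Inverts rho = I1(kappa)/I0(kappa) with the standard piecewise
    approximation (Best & Fisher); exact at rho = 0.
    """
    if not 0 <= rho < 1:
        raise ValidationError("rho must lie in [0, 1)")
    if rho < 0.53:
        return 2 * rho + rho**3 + 5 * rho**5 / 6
    if rho < 0.85:
        return -0.4 + 1.39 * rho + 0.43 / (1 - rho)
    return 1.0 / (rho**3 - 4 * rho**2 + 3 * rho)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    if sd == 0:
        return np.log(mean), 0.0
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def generate_tracks(
    params: WalkParams,
    rng: np.random.Generator | None = None,
    kappa_at: "Callable[[float, float], float] | None" = None,
) -> TrackSet:
    """Simulate a set of biased persistent random-walk tracks.

    Reproducible given ``params.seed``; each track has
    ``duration/interval + 1`` frames.  Step direction draws combine the
    directional bias and the previous step direction as von Mises natural
    parameters, so bias_kappa = 0 with persistence = 0 gives an isotropic
    walk, and very large bias_kappa gives near-straight tracks along the
    bias axis.

    ``kappa_at`` optionally makes the bias strength depend on position
    (e.g. on local oxygen via a measured profile): it is evaluated at each
    cell's current position before every step and overrides
    ``params.bias_kappa``.  Returned values must be >= 0.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_cells
    n_steps = params.n_steps
    bias_rad = np.radians(params.bias_direction_deg)
    bias_unit = np.array([np.cos(bias_rad), np.sin(bias_rad)])
    bias_vec = params.bias_kappa * bias_unit
    kappa_p = kappa_from_persistence(params.persistence)
    mu_ln, sigma_ln = _lognormal_params(
        params.speed_mean_um_min, params.speed_sd_um_min
    )

    if params.start_box_um is None:
        pos = np.zeros((n, 2))
    else:
        (x0, x1), (y0, y1) = params.start_box_um
        pos = np.column_stack(
            [rng.uniform(x0, x1, size=n), rng.uniform(y0, y1, size=n)]
        )

    positions = np.empty((n_steps + 1, n, 2))
    positions[0] = pos
    prev_dir: np.ndarray | None = None  # (n, 2) unit vectors
    for step in range(n_steps):
        if kappa_at is not None:
            kappas = np.array(
                [kappa_at(x, y) for x, y in positions[step]], dtype=float
            )
            if (kappas < 0).any() or not np.isfinite(kappas).all():
                raise ValidationError(
                    "kappa_at must return finite non-negative bias strengths"
                )
            eta = kappas[:, None] * bias_unit
        else:
            eta = np.broadcast_to(bias_vec, (n, 2)).copy()
        if prev_dir is not None and kappa_p > 0:
            eta = eta + kappa_p * prev_dir
        conc = np.linalg.norm(eta, axis=1)
        center = np.where(conc > 0, np.arctan2(eta[:, 1], eta[:, 0]), 0.0)
        theta = rng.vonmises(center, conc)
        if sigma_ln > 0:
            speeds = rng.lognormal(mu_ln, sigma_ln, size=n)
        else:
            speeds = np.full(n, params.speed_mean_um_min)
        prev_dir = np.column_stack([np.cos(theta), np.sin(theta)])
        positions[step + 1] = (
            positions[step] + (speeds * params.frame_interval_min)[:, None] * prev_dir
        )

    t = np.arange(n_steps + 1) * params.frame_interval_min
    tracks = [
        Track(
            track_id=i,
            t_min=t,
            x_um=positions[:, i, 0],
            y_um=positions[:, i, 1],
        )
        for i in range(n)
    ]
    return TrackSet(tracks)


def generate_condition_set(
    bias_by_condition: Mapping[str, float] | None = None,
    base: WalkParams = WalkParams(seed=0),
    mixed: bool = False,
    populations: tuple[str, str] = ("BULK", "CSC"),
) -> dict[str, TrackSet]:
    """Generate labelled track sets for the four experimental conditions.

    ``bias_by_condition`` maps each condition name to its directional bias
    kappa (default: the four standard conditions, gradient conditions
    biased toward lower oxygen along -x with kappa = 1).  In mixed mode the
    two population labels are interleaved 1:1 within each condition,
    emulating co-seeded strains.
    """
    if bias_by_condition is None:
        bias_by_condition = {
            "bulk_no_gradient": 0.0,
            "csc_no_gradient": 0.0,
            "bulk_gradient": 1.0,
            "csc_gradient": 1.0,
        }
    if len(bias_by_condition) != 4:
        raise ValidationError("expected exactly four condition labels")
    children = np.random.SeedSequence(base.seed).spawn(len(bias_by_condition))
    out: dict[str, TrackSet] = {}
    for (cond, kappa), seq in zip(bias_by_condition.items(), children):
        params = replace(base, bias_kappa=float(kappa))
        ts = generate_tracks(params, rng=np.random.default_rng(seq))
        for i, tr in enumerate(ts):
            tr.label = populations[i % 2] if mixed else cond
        ts.name = cond
        out[cond] = ts
    return out


@dataclass(frozen=True)
class ImagingParams:
    """Forward model settings for synthetic quenched-fluorescence stacks.

    ``o2_field`` is the true oxygen field: a 1D profile along the gradient
    axis (broadcast across the image height) or a full 2D array matching
    ``shape``.  Noise is additive Gaussian with standard deviation
    ``noise_sd_frac * i0``, drawn independently per pixel and per image.
    """

    o2_field: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 21.0, 120))
    i0: float = 1000.0
    kq: float = 0.05
    noise_sd_frac: float = 0.0
    shape: tuple[int, int] = (80, 120)
    n_images: int = 10
    c_ambient: float = 21.0
    gradient_axis: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.i0 <= 0 or self.kq <= 0:
            raise ValidationError("i0 and kq must be positive")
        if self.noise_sd_frac < 0:
            raise ValidationError("noise_sd_frac must be >= 0")
        if self.n_images < 1:
            raise ValidationError("n_images must be >= 1")

    def field_2d(self) -> np.ndarray:
        arr = np.asarray(self.o2_field, dtype=float)
        if arr.ndim == 1:
            if self.gradient_axis == 1:
                if len(arr) != self.shape[1]:
                    raise ValidationError("1D o2_field length must match image width")
                return np.broadcast_to(arr, self.shape).copy()
            if len(arr) != self.shape[0]:
                raise ValidationError("1D o2_field length must match image height")
            return np.broadcast_to(arr[:, None], self.shape).copy()
        if arr.shape != self.shape:
            raise ValidationError("2D o2_field shape must match image shape")
        return arr


@dataclass
class ImageBundle:
    """Calibration and measurement stacks, each (n_images, H, W)."""

    stack_0pct: np.ndarray
    stack_ambient: np.ndarray
    stack_gradient: np.ndarray


def generate_images(params: ImagingParams) -> ImageBundle:
    """Generate 0 %, ambient, and gradient image stacks from the
    Stern-Volmer forward model I = I0 / (1 + Kq [O2]) with independent
    additive noise per image; fully determined by ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    sd = params.noise_sd_frac * params.i0
    n = params.n_images

    def stack(o2: np.ndarray | float) -> np.ndarray:
        clean = np.broadcast_to(
            forward_intensity(o2, params.i0, params.kq), params.shape
        )
        stk = np.repeat(clean[None, :, :], n, axis=0).astype(float)
        if sd > 0:
            stk = stk + rng.normal(0.0, sd, size=stk.shape)
        return stk

    return ImageBundle(
        stack_0pct=stack(0.0),
        stack_ambient=stack(params.c_ambient),
        stack_gradient=stack(params.field_2d()),
    )
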