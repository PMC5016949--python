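"""Synthetic two-colour locus-tracking data.

The generator emulates the statistical structure of 3D live-cell videos
of two fluorescently tagged chromosomal loci: a tethered pair whose
inter-locus vector undergoes confined (mean-reverting) relative motion,
imaged through two colour channels that each add Gaussian localisation
noise, with a constant residual chromatic offset on the red channel.

The inter-locus vector and the pair's midpoint are modelled as
independent stationary Ornstein-Uhlenbeck processes, discretised with
the exact conditional update

    x(t + dt) = rho * x(t) + s * sqrt(1 - rho^2) * N(0, 1),
    rho = exp(-dt / theta),

so the stationary per-axis SD ``s`` and the autocorrelation time
``theta`` are exact at any frame interval.  Stationary initialisation
means every frame is a draw from the equilibrium distribution.

For a 3D isotropic Gaussian vector with per-axis SD s, the magnitude is
Maxwell-distributed with mean 2*s*sqrt(2/pi) and variance s^2*(3-8/pi);
these closed forms anchor the package's test oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CellVideo, FRAME_COLUMNS, StrainSpec, ValidationError

ANISOTROPY_MODES = ("isotropic", "fixed-direction")
CELL_DISTRIBUTIONS = ("lognormal", "fixed")

#: mean of the Maxwell distribution per unit per-axis SD
MAXWELL_MEAN = 2.0 * math.sqrt(2.0 / math.pi)
#: variance of the Maxwell distribution per unit per-axis variance
MAXWELL_VAR = 3.0 - 8.0 / math.pi


@dataclass
class SimulationConfig:
    """Parameters of the synthetic video generator.

    Lengths in nm, times in seconds.  Defaults describe a reporter pair
    roughly 70 kb apart: stationary per-axis SD 150 nm gives a mean 3D
    separation of ~240 nm, relaxing on a ~20 s timescale, imaged once
    per second through a 5 um Z-stack with 27.9 nm per-axis localisation
    noise in each channel.
    """

    sigma: float = 150.0            # stationary per-axis SD of the inter-locus vector (nm)
    theta: float = 20.0             # relaxation time of the inter-locus vector (s)
    frame_interval: float = 1.0     # time between Z-stacks (s)
    n_frames: int = 60              # frames per video
    noise_sd: float = 27.9          # per-axis localisation noise per channel (nm)
    channel_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)  # added to red (nm)
    centre_sigma: float = 200.0     # confinement SD of the pair midpoint (nm)
    centre_theta: float = 20.0      # relaxation time of the midpoint (s)
    stack_range: tuple[float, float] = (0.0, 5000.0)  # axial imaging bounds (nm)
    intensity_mean_green: float = 40.0
    intensity_sd_green: float = 8.0
    intensity_mean_red: float = 50.0
    intensity_sd_red: float = 10.0
    contrast_mean_green: float = 20.0
    contrast_sd_green: float = 3.0
    contrast_mean_red: float = 20.0
    contrast_sd_red: float = 3.0
    anisotropy_mode: str = "isotropic"
    inheritance_coefficient: float = 0.0  # in [0,1]; 1 = daughter copies mother
    between_cell_cv: float = 0.4          # CV of the between-cell mean-separation distribution
    between_cell_distribution: str = "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        self.channel_offset = tuple(float(v) for v in self.channel_offset)
        self.stack_range = tuple(float(v) for v in self.stack_range)
        numeric = [self.sigma, self.theta, self.frame_interval, self.noise_sd,
                   self.centre_sigma, self.centre_theta, self.between_cell_cv,
                   self.inheritance_coefficient, *self.channel_offset, *self.stack_range,
                   self.intensity_mean_green, self.intensity_sd_green,
                   self.intensity_mean_red, self.intensity_sd_red,
                   self.contrast_mean_green, self.contrast_sd_green,
                   self.contrast_mean_red, self.contrast_sd_red]
        if not all(math.isfinite(v) for v in numeric):
            raise ValidationError("non-finite value in simulation config")
        if self.sigma < 0 or self.centre_sigma < 0:
            raise ValidationError("sigma and centre_sigma must be >= 0")
        if self.theta <= 0 or self.centre_theta <= 0:
            raise ValidationError("theta and centre_theta must be > 0")
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be > 0")
        if self.n_frames < 2:
            raise ValidationError("n_frames must be >= 2")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0.0 <= self.inheritance_coefficient <= 1.0:
            raise ValidationError("inheritance_coefficient must be in [0, 1]")
        if self.between_cell_cv < 0:
            raise ValidationError("between_cell_cv must be >= 0")
        if self.anisotropy_mode not in ANISOTROPY_MODES:
            raise ValidationError(f"anisotropy_mode must be one of {ANISOTROPY_MODES}")
        if self.between_cell_distribution not in CELL_DISTRIBUTIONS:
            raise ValidationError(f"between_cell_distribution must be one of {CELL_DISTRIBUTIONS}")
        if self.stack_range[1] <= self.stack_range[0]:
            raise ValidationError("stack_range must be an increasing (z_min, z_max) pair")

    @property
    def mean_separation(self) -> float:
        """Stationary mean 3D inter-locus distance in the noiseless limit (nm)."""
        return MAXWELL_MEAN * self.sigma


def _ou_path(rng: np.random.Generator, n: int, dt: float, sigma: float,
             theta: float, shape: tuple[int, ...] = ()) -> np.ndarray:
    """Stationary OU sample path(s): exact conditional discretisation."""
    out = np.empty((n, *shape))
    out[0] = rng.normal(0.0, sigma, size=shape)
    if n > 1:
        rho = math.exp(-dt / theta)
        innov_sd = sigma * math.sqrt(1.0 - rho * rho)
        innovations = rng.normal(0.0, 1.0, size=(n - 1, *shape))
        for i in range(1, n):
            out[i] = rho * out[i - 1] + innov_sd * innovations[i - 1]
    return out


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    norm = np.linalg.norm(v)
    while norm == 0.0:  # pragma: no cover - probability zero
        v = rng.normal(size=3)
        norm = np.linalg.norm(v)
    return v / norm


def _covariates(rng: np.random.Generator, config: SimulationConfig, n: int):
    cov = {}
    for ch in ("green", "red"):
        mean_i = getattr(config, f"intensity_mean_{ch}")
        sd_i = getattr(config, f"intensity_sd_{ch}")
        mean_c = getattr(config, f"contrast_mean_{ch}")
        sd_c = getattr(config, f"contrast_sd_{ch}")
        cov[f"intensity_{ch}"] = np.clip(rng.normal(mean_i, sd_i, size=n), 0.1, None)
        cov[f"contrast_{ch}"] = np.clip(rng.normal(mean_c, sd_c, size=n), 0.1, None)
    return cov


def _assemble_video(config: SimulationConfig, rng: np.random.Generator,
                    green: np.ndarray, red: np.ndarray, *,
                    video_id: str, cell_id: str, strain_id: str,
                    role: str = "unpaired", pair_id: str | None = None) -> CellVideo:
    n = len(green)
    times = np.arange(n, dtype=float) * config.frame_interval
    cov = _covariates(rng, config, n)
    frames = pd.DataFrame({
        "time_s": times,
        "x_nm_green": green[:, 0], "y_nm_green": green[:, 1], "z_nm_green": green[:, 2],
        "intensity_green": cov["intensity_green"], "contrast_green": cov["contrast_green"],
        "x_nm_red": red[:, 0], "y_nm_red": red[:, 1], "z_nm_red": red[:, 2],
        "intensity_red": cov["intensity_red"], "contrast_red": cov["contrast_red"],
    })[FRAME_COLUMNS]
    return CellVideo(
        video_id=video_id, cell_id=cell_id, strain_id=strain_id,
        role=role, pair_id=pair_id, frame_interval=config.frame_interval,
        stack_range=config.stack_range, frames=frames,
    )


def _simulate_tracks(config: SimulationConfig, rng: np.random.Generator,
                     sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """True green/red positions (without localisation noise or offset)."""
    n, dt = config.n_frames, config.frame_interval
    centre = _ou_path(rng, n, dt, config.centre_sigma, config.centre_theta, shape=(3,))
    z_mid = 0.5 * (config.stack_range[0] + config.stack_range[1])
    centre[:, 2] += z_mid
    vec = _ou_path(rng, n, dt, sigma, config.theta, shape=(3,))
    if config.anisotropy_mode == "fixed-direction":
        # direction pinned per video; magnitude keeps the isotropic
        # (Maxwell) marginal by construction
        direction = _random_unit_vector(rng)
        vec = np.linalg.norm(vec, axis=1)[:, None] * direction[None, :]
    green = centre - 0.5 * vec
    red = centre + 0.5 * vec
    return green, red


def _observe(config: SimulationConfig, rng: np.random.Generator,
             green: np.ndarray, red: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Add per-channel localisation noise and the red chromatic offset."""
    offset = np.asarray(config.channel_offset, dtype=float)
    green_obs = green + rng.normal(0.0, config.noise_sd, size=green.shape)
    red_obs = red + rng.normal(0.0, config.noise_sd, size=red.shape) + offset
    return green_obs, red_obs


def simulate_pair_video(config: SimulationConfig, seed: int, *,
                        video_id: str = "v000", cell_id: str | None = None,
                        strain_id: str = "strain0", role: str = "unpaired",
                        pair_id: str | None = None,
                        sigma: float | None = None) -> CellVideo:
    """Simulate one two-colour video of a tethered locus pair.

    ``sigma`` overrides the config's stationary scale for this video
    (used for cell-specific mean separations in population simulations).
    Identical (config, seed) reproduce byte-identical output.
    """
    rng = np.random.default_rng(seed)
    green, red = _simulate_tracks(config, rng, config.sigma if sigma is None else sigma)
    green_obs, red_obs = _observe(config, rng, green, red)
    return _assemble_video(config, rng, green_obs, red_obs,
                           video_id=video_id, cell_id=cell_id or video_id,
                           strain_id=strain_id, role=role, pair_id=pair_id)


def simulate_colocalising_videos(config: SimulationConfig, n_videos: int,
                                 seed: int) -> list[CellVideo]:
    """Simulate the colocalising control strain: true separation is zero.

    A single spot is bound by both fluorophores, so the green and red
    observations differ only by localisation noise and the channel
    offset.  Used downstream to estimate fine alignment offsets and the
    residual measurement error.
    """
    if n_videos < 1:
        raise ValidationError("n_videos must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_videos)
    videos = []
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        n, dt = config.n_frames, config.frame_interval
        centre = _ou_path(rng, n, dt, config.centre_sigma, config.centre_theta, shape=(3,))
        centre[:, 2] += 0.5 * (config.stack_range[0] + config.stack_range[1])
        green_obs, red_obs = _observe(config, rng, centre, centre.copy())
        videos.append(_assemble_video(
            config, rng, green_obs, red_obs,
            video_id=f"coloc{i:03d}", cell_id=f"coloc_cell{i:03d}",
            strain_id="colocalising"))
    return videos


def _draw_cell_mean(config: SimulationConfig, rng: np.random.Generator) -> float:
    """Cell-specific mean 3D separation, drawn from the between-cell law."""
    mu = config.mean_separation
    if config.between_cell_distribution == "fixed" or config.between_cell_cv == 0.0:
        return mu
    s2 = math.log1p(config.between_cell_cv ** 2)
    return float(rng.lognormal(math.log(mu) - 0.5 * s2, math.sqrt(s2)))


def simulate_population(config: SimulationConfig, strain_specs: list[StrainSpec],
                        n_cells: int, fraction_paired: float,
                        seed: int) -> list[CellVideo]:
    """Simulate a cell population with mother/daughter lineage structure.

    Each cell draws its own mean separation from the between-cell
    distribution (log-normal by default), emulating the cell-to-cell
    heterogeneity seen in real locus-tracking data.  For a related pair,

        daughter_mean = k * mother_mean + (1 - k) * fresh_draw,

    with k = ``config.inheritance_coefficient``: k=1 copies the mother's
    configuration exactly, k=0 erases it.  ``fraction_paired`` of the
    cells (rounded down to whole pairs) are emitted as mother/daughter
    pairs sharing a ``pair_id``; the rest are unpaired.  Strains cycle
    through ``strain_specs``.
    """
    if not strain_specs:
        raise ValidationError("strain_specs must not be empty")
    if not 0.0 <= fraction_paired <= 1.0:
        raise ValidationError("fraction_paired must be in [0, 1]")
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    n_pairs = int(n_cells * fraction_paired) // 2
    n_unpaired = n_cells - 2 * n_pairs
    master = np.random.SeedSequence(seed)
    draw_rng = np.random.default_rng(master.spawn(1)[0])
    video_streams = iter(master.spawn(n_cells))
    scale = MAXWELL_MEAN  # mean separation per unit per-axis SD
    k = config.inheritance_coefficient
    videos: list[CellVideo] = []

    def _make(index, role, pair_id, strain, mean_sep):
        vid = f"v{index:04d}"
        return simulate_pair_video(
            config, next(video_streams), video_id=vid, cell_id=f"cell{index:04d}",
            strain_id=strain.strain_id, role=role, pair_id=pair_id,
            sigma=mean_sep / scale)

    index = 0
    for p in range(n_pairs):
        strain = strain_specs[p % len(strain_specs)]
        mother_mean = _draw_cell_mean(config, draw_rng)
        daughter_mean = k * mother_mean + (1.0 - k) * _draw_cell_mean(config, draw_rng)
        pair_id = f"p{p:04d}"
        videos.append(_make(index, "mother", pair_id, strain, mother_mean))
        index += 1
        videos.append(_make(index, "daughter", pair_id, strain, daughter_mean))
        index += 1
    for u in range(n_unpaired):
        strain = strain_specs[(n_pairs + u) % len(strain_specs)]
        videos.append(_make(index, "unpaired", None, strain, _draw_cell_mean(config, draw_rng)))
        index += 1
    return videos
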