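"""Synthetic data generation with known ground truth.

Everything the downstream pipeline consumes — dwell-time samples, single-molecule
movie stacks, two-channel mitotic cell images, and spike-in read-count tables —
can be generated here with the generating parameters recorded, so that every
analysis stage can be validated by parameter recovery.

The kinetic model is a two-state mixture: each molecule is either a transient
("fast") or a stable ("slow") binder, its bound lifetime is exponential with the
component's dissociation rate, and an independent exponential photobleaching
clock can truncate the observation.  The observable dwell is the minimum of the
two clocks, discretized to the camera's frame interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "KineticConfig",
    "MovieConfig",
    "GroundTruth",
    "CellImageConfig",
    "SpikeInSimConfig",
    "simulate_dwell_times",
    "simulate_movie",
    "simulate_cell_image",
    "simulate_spikein_counts",
]


class InvalidConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class KineticConfig:
    """Two-component dissociation kinetics with photobleaching.

    Parameters
    ----------
    frac_fast : float
        Fraction of molecules in the fast (transient, non-specific) component.
    k_fast, k_slow : float
        Dissociation rates of the two components, 1/s.  ``k_fast >= k_slow``.
    k_bleach : float
        Single-step photobleach rate of the fluorophore, 1/s.
    frame_interval : float
        Camera frame interval in seconds (0.2 s at the nominal 5 Hz).
    n_frames : int
        Movie length in frames (nominally 1000).
    n_molecules : int
        Number of bound molecules to simulate in a movie.
    seed : int
        Seed for the simulation's random generator.
    """

    frac_fast: float = 0.3
    k_fast: float = 1.0
    k_slow: float = 0.1
    k_bleach: float = 0.05
    frame_interval: float = 0.2
    n_frames: int = 1000
    n_molecules: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_fast <= 1.0:
            raise InvalidConfigError(f"frac_fast must be in [0, 1], got {self.frac_fast}")
        if self.k_slow <= 0:
            raise InvalidConfigError(f"k_slow must be > 0, got {self.k_slow}")
        if self.frac_fast > 0 and self.k_fast < self.k_slow:
            raise InvalidConfigError(
                f"k_fast ({self.k_fast}) must be >= k_slow ({self.k_slow}) when frac_fast > 0"
            )
        if self.k_bleach < 0:
            raise InvalidConfigError(f"k_bleach must be >= 0, got {self.k_bleach}")
        if self.frame_interval <= 0:
            raise InvalidConfigError(f"frame_interval must be > 0, got {self.frame_interval}")


@dataclass(frozen=True)
class MovieConfig:
    """Rendering parameters for a synthetic slow-tracking movie.

    Bound molecules appear as immobile diffraction-limited Gaussian spots;
    free molecules mostly blur out under the long exposure and are rendered
    only with probability ``p_detect_free`` per frame at diffusing positions.
    """

    width: int = 128
    height: int = 128
    pixel_size: float = 0.16  # um / pixel
    psf_sigma: float = 1.2  # pixels
    background_mean: float = 100.0
    background_sd: float = 10.0
    spot_amplitude: float = 80.0  # peak above background; SNR = amplitude / background_sd
    diffusion_free: float = 2.0  # um^2/s for the free population
    p_detect_free: float = 0.05
    n_free: int = 0
    edge_margin: int = 8  # bound molecules placed at least this many px from the border
    kinetic: KineticConfig = field(default_factory=KineticConfig)

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise InvalidConfigError(f"psf_sigma must be > 0, got {self.psf_sigma}")
        if self.spot_amplitude <= 0:
            raise InvalidConfigError(f"spot_amplitude must be > 0, got {self.spot_amplitude}")
        if not 0.0 <= self.p_detect_free <= 1.0:
            raise InvalidConfigError(f"p_detect_free must be in [0, 1], got {self.p_detect_free}")


@dataclass
class GroundTruth:
    """Per-molecule, per-frame truth for a simulated movie.

    Attributes
    ----------
    intervals : pandas.DataFrame
        One row per bound molecule: molecule_id, start_frame, end_frame
        (inclusive), bleach-limited flag, censored flag (still bound at the
        final frame), component label, x_px, y_px.
    renderings : pandas.DataFrame
        One row per rendered spot: molecule_id, frame, x_px, y_px, state
        ('bound' or 'free'), component.
    """

    intervals: pd.DataFrame
    renderings: pd.DataFrame

    def spots_in_frame(self, frame: int) -> pd.DataFrame:
        return self.renderings[self.renderings["frame"] == frame]


@dataclass(frozen=True)
class CellImageConfig:
    """A mitotic cell as an ellipse with an interior chromatin ellipse.

    ``chromatin_to_cell_ratio`` is the ratio of the mean TF-channel intensity
    over chromatin to the whole-cell mean, so the true enrichment score is
    log2 of this ratio.
    """

    shape: tuple[int, int] = (256, 256)
    cell_center: tuple[float, float] = (128.0, 128.0)
    cell_axes: tuple[float, float] = (80.0, 60.0)
    chromatin_center: tuple[float, float] = (128.0, 128.0)
    chromatin_axes: tuple[float, float] = (40.0, 28.0)
    cell_mean: float = 200.0
    chromatin_to_cell_ratio: float = 2.0
    noise_sd: float = 10.0
    h2b_level: float = 300.0
    background_level: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chromatin_to_cell_ratio <= 0:
            raise InvalidConfigError(
                f"chromatin_to_cell_ratio must be > 0, got {self.chromatin_to_cell_ratio}"
            )
        # chromatin ellipse must fit inside the cell ellipse (sufficient check:
        # bounding offsets plus axes within the cell axes)
        dy = abs(self.chromatin_center[0] - self.cell_center[0])
        dx = abs(self.chromatin_center[1] - self.cell_center[1])
        if dy + self.chromatin_axes[0] > self.cell_axes[0] or dx + self.chromatin_axes[1] > self.cell_axes[1]:
            raise InvalidConfigError("chromatin region must lie inside the cell region")


@dataclass(frozen=True)
class SpikeInSimConfig:
    """Per-sample fly (D. melanogaster) spike-in read counts.

    ``samples`` is a list of (name, condition, fly_fraction) tuples where
    condition is 'asynchronous' or 'mitotic'; exactly one sample is the
    asynchronous reference.  ``constant`` is the arbitrary scaling constant
    (100 000 for a 10% spike-in; 200 000 for 20%).
    """

    samples: tuple[tuple[str, str, float], ...]
    total_reads: int = 10_000_000
    constant: int = 100_000
    reference: str | None = None  # default: first asynchronous sample
    deterministic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        conditions = {c for _, c, _ in self.samples}
        if not conditions <= {"asynchronous", "mitotic"}:
            raise InvalidConfigError(f"unknown conditions: {conditions - {'asynchronous', 'mitotic'}}")
        for name, _, frac in self.samples:
            if not 0.0 < frac < 1.0:
                raise InvalidConfigError(f"fly fraction for {name!r} must be in (0, 1), got {frac}")
        ref = self.resolve_reference()
        if ref is None:
            raise InvalidConfigError("no asynchronous reference sample in config")

    def resolve_reference(self) -> str | None:
        if self.reference is not None:
            for name, cond, _ in self.samples:
                if name == self.reference and cond == "asynchronous":
                    return name
            return None
        for name, cond, _ in self.samples:
            if cond == "asynchronous":
                return name
        return None


# ---------------------------------------------------------------------------
# dwell times
# ---------------------------------------------------------------------------

def simulate_dwell_times(
    config: KineticConfig,
    n: int,
    seed: int | None = None,
    *,
    min_intervals: int = 1,
    discretize: bool = True,
) -> pd.DataFrame:
    """Draw observed dwell times from the two-component bleaching model.

    Each molecule draws a component (fast with probability ``frac_fast``), a
    bound lifetime ~ Exponential(k_component), and a bleach time
    ~ Exponential(k_bleach); the observed dwell is the minimum of the two.
    With ``discretize=True`` the dwell is floored to a whole number of frame
    intervals and molecules observed for fewer than ``min_intervals``
    intervals (i.e. fewer than ``min_intervals + 1`` frames) are dropped, as
    they would be below the minimum track length.

    Returns a DataFrame with columns ``duration`` (s), ``n_intervals`` and
    ``component`` ('fast'/'slow'); only the surviving molecules are returned.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    is_fast = rng.random(n) < config.frac_fast
    rates = np.where(is_fast, config.k_fast, config.k_slow)
    lifetime = rng.exponential(1.0 / rates)
    if config.k_bleach > 0:
        bleach = rng.exponential(1.0 / config.k_bleach, size=n)
        observed = np.minimum(lifetime, bleach)
    else:
        observed = lifetime
    component = np.where(is_fast, "fast", "slow")
    if discretize:
        n_intervals = np.floor(observed / config.frame_interval).astype(int)
        keep = n_intervals >= min_intervals
        duration = n_intervals * config.frame_interval
        out = pd.DataFrame(
            {
                "duration": duration[keep],
                "n_intervals": n_intervals[keep],
                "component": component[keep],
            }
        )
    else:
        out = pd.DataFrame(
            {
                "duration": observed,
                "n_intervals": np.floor(observed / config.frame_interval).astype(int),
                "component": component,
            }
        )
    out.index.name = "molecule_id"
    return out


def survival_model(t: np.ndarray, config: KineticConfig) -> np.ndarray:
    """Analytic survival S(t) of the observed dwell under the config.

    S(t) = frac_fast * exp(-(k_fast + k_bleach) t)
         + (1 - frac_fast) * exp(-(k_slow + k_bleach) t).
    """
    t = np.asarray(t, dtype=float)
    kb = config.k_bleach
    return config.frac_fast * np.exp(-(config.k_fast + kb) * t) + (
        1.0 - config.frac_fast
    ) * np.exp(-(config.k_slow + kb) * t)


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------

def _render_spots(frame: np.ndarray, xs, ys, amplitude: float, sigma: float) -> None:
    """Add 2-D Gaussian spots (in place). Positions are (row=y, col=x) pixels."""
    h, w = frame.shape
    half = int(np.ceil(4 * sigma))
    for x, y in zip(xs, ys):
        r0, r1 = max(0, int(y) - half), min(h, int(y) + half + 1)
        c0, c1 = max(0, int(x) - half), min(w, int(x) + half + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        frame[r0:r1, c0:c1] += amplitude * np.exp(
            -((rr - y) ** 2 + (cc - x) ** 2) / (2.0 * sigma**2)
        )


def simulate_movie(config: MovieConfig, seed: int | None = None):
    """Render a slow-tracking movie and return ``(stack, GroundTruth)``.

    ``stack`` is a float32 array of shape (n_frames, height, width).  Bound
    molecules are immobile Gaussian spots for the duration of their bound
    interval; the interval starts at a uniformly random frame and ends at
    unbinding, bleaching, or the end of the movie (then flagged censored).
    After the interval ends the molecule is no longer rendered — an unbound
    molecule blurs out within a single 200 ms exposure.  An optional free
    population diffuses and is rendered with probability ``p_detect_free``
    per frame.
    """
    kin = config.kinetic
    rng = np.random.default_rng(kin.seed if seed is None else seed)
    n_frames = kin.n_frames
    h, w = config.height, config.width
    m = config.edge_margin

    n_mol = kin.n_molecules
    interval_rows = []
    render_rows = []
    if n_mol > 0:
        is_fast = rng.random(n_mol) < kin.frac_fast
        rates = np.where(is_fast, kin.k_fast, kin.k_slow)
        lifetime = rng.exponential(1.0 / rates)
        if kin.k_bleach > 0:
            bleach = rng.exponential(1.0 / kin.k_bleach, size=n_mol)
        else:
            bleach = np.full(n_mol, np.inf)
        observed = np.minimum(lifetime, bleach)
        n_intervals = np.floor(observed / kin.frame_interval).astype(int)
        start = rng.integers(0, n_frames, size=n_mol)
        x = rng.uniform(m, w - m, size=n_mol)
        y = rng.uniform(m, h - m, size=n_mol)
        for i in range(n_mol):
            end = start[i] + n_intervals[i]
            censored = end >= n_frames
            end = min(end, n_frames - 1)
            interval_rows.append(
                {
                    "molecule_id": i,
                    "start_frame": int(start[i]),
                    "end_frame": int(end),
                    "bleached": bool(bleach[i] < lifetime[i]),
                    "censored": bool(censored),
                    "component": "fast" if is_fast[i] else "slow",
                    "x_px": x[i],
                    "y_px": y[i],
                }
            )
            for f in range(int(start[i]), int(end) + 1):
                render_rows.append((i, f, x[i], y[i], "bound", "fast" if is_fast[i] else "slow"))

    # free population: pure random walk, rarely rendered
    if config.n_free > 0:
        step_sd = np.sqrt(2.0 * config.diffusion_free * kin.frame_interval) / config.pixel_size
        fx = rng.uniform(0, w, size=config.n_free)
        fy = rng.uniform(0, h, size=config.n_free)
        for f in range(n_frames):
            fx = np.mod(fx + rng.normal(0, step_sd, config.n_free), w)
            fy = np.mod(fy + rng.normal(0, step_sd, config.n_free), h)
            visible = rng.random(config.n_free) < config.p_detect_free
            for j in np.nonzero(visible)[0]:
                render_rows.append((n_mol + j, f, fx[j], fy[j], "free", "free"))

    renderings = pd.DataFrame(
        render_rows, columns=["molecule_id", "frame", "x_px", "y_px", "state", "component"]
    )
    intervals = pd.DataFrame(
        interval_rows,
        columns=[
            "molecule_id",
            "start_frame",
            "end_frame",
            "bleached",
            "censored",
            "component",
            "x_px",
            "y_px",
        ],
    )

    # density check: warn when spots are too crowded to track unambiguously
    if len(intervals):
        per_frame = renderings.groupby("frame").size()
        mean_spots = float(per_frame.mean())
        if mean_spots > 1:
            area = h * w
            mean_nn = 0.5 / np.sqrt(mean_spots / area)  # Poisson-process expectation
            if mean_nn < 2 * config.psf_sigma:
                logger.warning(
                    "spot density high: mean nearest-neighbor distance %.2f px < 2*psf_sigma; "
                    "tracking may be ambiguous",
                    mean_nn,
                )

    stack = rng.normal(config.background_mean, config.background_sd, size=(n_frames, h, w)).astype(
        np.float32
    )
    for f, grp in renderings.groupby("frame"):
        _render_spots(stack[f], grp["x_px"].to_numpy(), grp["y_px"].to_numpy(),
                      config.spot_amplitude, config.psf_sigma)

    return stack, GroundTruth(intervals=intervals, renderings=renderings)


# ---------------------------------------------------------------------------
# cell images
# ---------------------------------------------------------------------------

def _ellipse_mask(shape, center, axes) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def simulate_cell_image(config: CellImageConfig):
    """Build a two-channel mitotic cell image with a known enrichment score.

    Channel 1 (H2B marker) is bright only over the chromatin region.  Channel
    2 (HaloTag-TF) has mean ``cell_mean * chromatin_to_cell_ratio`` over
    chromatin and a compensating level over the rest of the cell so that the
    whole-cell mean is exactly ``cell_mean``; the true enrichment score is
    log2(chromatin_to_cell_ratio).

    Returns ``(image, masks, true_score)`` where ``image`` has shape
    (2, H, W) with channel 0 = H2B and channel 1 = Halo, and ``masks`` is a
    dict with boolean 'cell' and 'chromatin' arrays.
    """
    rng = np.random.default_rng(config.seed)
    cell = _ellipse_mask(config.shape, config.cell_center, config.cell_axes)
    chromatin = _ellipse_mask(config.shape, config.chromatin_center, config.chromatin_axes)
    chromatin &= cell

    n_cell = cell.sum()
    n_chrom = chromatin.sum()
    n_rest = n_cell - n_chrom
    ratio = config.chromatin_to_cell_ratio
    chrom_level = config.cell_mean * ratio
    if n_rest > 0:
        rest_level = (config.cell_mean * n_cell - chrom_level * n_chrom) / n_rest
    else:
        rest_level = 0.0
    if rest_level < 0:
        raise InvalidConfigError(
            "chromatin_to_cell_ratio too large for the chromatin/cell area ratio: "
            "the compensating outside-chromatin level would be negative"
        )

    halo = np.full(config.shape, config.background_level, dtype=float)
    halo[cell] = rest_level
    halo[chromatin] = chrom_level
    h2b = np.full(config.shape, config.background_level, dtype=float)
    h2b[chromatin] = config.h2b_level
    if config.noise_sd > 0:
        halo += rng.normal(0, config.noise_sd, config.shape)
        h2b += rng.normal(0, config.noise_sd, config.shape)

    image = np.stack([h2b, halo]).astype(np.float32)
    masks = {"cell": cell, "chromatin": chromatin}
    return image, masks, float(np.log2(ratio))


# ---------------------------------------------------------------------------
# spike-in counts
# ---------------------------------------------------------------------------

def simulate_spikein_counts(config: SpikeInSimConfig) -> pd.DataFrame:
    """Draw per-sample fly-aligned read counts.

    Counts are Binomial(total_reads, fly_fraction) per sample, or the exact
    expectation in deterministic mode.  The returned table carries the scaling
    constant and the reference-sample flag; scaling values themselves are
    computed downstream by :func:`mitodwell.spikein.compute_scaling`.
    """
    rng = np.random.default_rng(config.seed)
    ref = config.resolve_reference()
    rows = []
    for name, cond, frac in config.samples:
        if config.deterministic:
            fly = int(round(config.total_reads * frac))
        else:
            fly = int(rng.binomial(config.total_reads, frac))
        rows.append(
            {
                "sample": name,
                "condition": cond,
                "fly_reads": fly,
                "constant": config.constant,
                "is_reference": name == ref,
            }
        )
    return pd.DataFrame(rows)
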