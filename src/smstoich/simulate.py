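"""Synthetic single-molecule data with complete ground truth.

Three kinds of synthetic data are produced, mirroring the three experimental
readouts the analysis modules quantify:

* photobleaching movies/traces — immobile diffraction-limited spots carrying
  one or two fluorophores that bleach stochastically (single-exponential,
  no blinking), on a noisy constant background;
* kinetic movies — complexes that appear as Poisson events, persist for
  exponentially distributed lifetimes and vanish (assembly/disassembly of
  oligomeric signalling scaffolds seen by TIRF);
* two-channel single-cell time series — a nuclear:cytoplasmic translocation
  ratio that rises to a single peak and decays, plus a transcriptional
  reporter channel that rises sigmoidally after a delay.

Every generator returns the ground truth needed to score the downstream
estimators (true positions, fluorophore counts, bleach frames, lifetimes,
peak times), and is deterministic given its seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass


import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.special import erf

__all__ = [
    "MovieConfig",
    "PopulationSpec",
    "NfkbCellParams",
    "CellTimeSeries",
    "simulate_trace",
    "simulate_movie",
    "simulate_reference_field",
    "simulate_kinetic_movie",
    "simulate_nfkb_series",
    "simulate_nfkb_cohort",
    "peak_amplitude",
    "background_sd_for_snr",
    "movie_size_for",
    "write_movie",
    "write_ground_truth",
    "write_config_sidecar",
]

_UINT16_MAX = 65535


@dataclass(frozen=True)
class MovieConfig:
    """Geometry, optics and noise of a simulated TIRF acquisition.

    Intensities are in arbitrary detector units (ADU); no camera gain model
    is applied, so ``intensity_per_fluorophore`` is the integrated flux one
    fluorophore contributes per frame.
    """

    width_px: int = 320
    height_px: int = 320
    n_frames: int = 400
    frame_interval_s: float = 0.035
    psf_sigma_px: float = 1.2
    background_mean: float = 2000.0
    background_sd: float = 400.0
    intensity_per_fluorophore: float = 20000.0
    shot_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px, self.n_frames) < 1:
            raise ValueError("image dimensions and frame count must be >= 1")
        if not (self.psf_sigma_px > 0):
            raise ValueError("psf_sigma_px must be positive")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")
        for name in ("frame_interval_s", "background_mean", "background_sd",
                     "intensity_per_fluorophore", "psf_sigma_px"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class PopulationSpec:
    """Mixed monomer/dimer spot population with partial labeling."""

    n_spots: int = 1000
    dimer_fraction: float = 0.22
    labeling_efficiency: float = 1.0
    bleach_rate_per_frame: float = 0.01

    def __post_init__(self) -> None:
        for name in ("dimer_fraction", "labeling_efficiency", "bleach_rate_per_frame"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_spots < 0:
            raise ValueError("n_spots must be >= 0")


@dataclass(frozen=True)
class NfkbCellParams:
    """Per-cell parameters of the translocation/reporter generator.

    The green-channel nuclear:cytoplasmic ratio follows a fixed-width pulse
    ``baseline + (peak-baseline) * exp(-(t-tp)^2 / (2 w^2))`` whose maximum
    is exactly at ``t_peak_min``; the width ``w`` (``pulse_width_min``) does
    not scale with the peak time, as first-translocation peaks have a
    characteristic duration set by import/export kinetics, not by when they
    occur. The red reporter rises as a logistic from 1x to
    ``reporter_fold``x its initial level, centred well after
    ``reporter_delay_min``. Noise is multiplicative Gaussian.
    """

    t_peak_min: float = 30.0
    peak_ratio: float = 2.5
    baseline_ratio: float = 1.0
    reporter_fold: float = 3.0
    reporter_delay_min: float = 60.0
    noise_sd: float = 0.05
    sampling_interval_min: float = 3.0
    pulse_width_min: float = 12.0
    reporter_rise_tau_min: float = 30.0

    def __post_init__(self) -> None:
        if not (self.t_peak_min > 0):
            raise ValueError("t_peak_min must be > 0")
        if not (self.baseline_ratio > 0):
            raise ValueError("baseline_ratio must be > 0")
        if self.reporter_fold < 1:
            raise ValueError("reporter_fold must be >= 1")
        if self.peak_ratio < self.baseline_ratio:
            raise ValueError("peak_ratio must be >= baseline_ratio")
        if self.noise_sd < 0 or self.sampling_interval_min <= 0:
            raise ValueError("noise_sd >= 0 and sampling_interval_min > 0 required")


@dataclass
class CellTimeSeries:
    """Per-cell channel means over time (minutes); the substrate of the
    translocation analysis."""

    cell_id: str
    t_min: np.ndarray
    nuclear_green: np.ndarray
    cytoplasm_green: np.ndarray
    red_reporter: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.t_min)
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        arrs = (self.nuclear_green, self.cytoplasm_green, self.red_reporter, self.valid)
        if any(len(a) != n for a in arrs):
            raise ValueError("all channels must have the same length")
        if n > 1 and not np.all(np.diff(self.t_min) > 0):
            raise ValueError("timepoints must be strictly increasing")


# ---------------------------------------------------------------------------
# photobleaching traces


def _bleach_frames(rng: np.random.Generator, n: int, rate: float, n_frames: int) -> np.ndarray:
    """Frame at which each fluorophore goes dark (geometric law, support 1..).

    A fluorophore with bleach frame ``b`` contributes signal on frames
    ``0..b-1``; values are clipped to ``n_frames`` meaning "survived the
    whole movie".
    """
    if n == 0:
        return np.empty(0, dtype=int)
    if rate <= 0:
        return np.full(n, n_frames, dtype=int)
    b = rng.geometric(rate, size=n)
    return np.minimum(b, n_frames).astype(int)


def simulate_trace(
    n_fluorophores: int,
    intensity_per_fluor: float = 10000.0,
    bleach_rate: float = 0.01,
    noise_sd: float = 0.0,
    n_frames: int = 400,
    seed: int | np.random.Generator = 0,
):
    """Simulate one spot's intensity trajectory.

    Returns ``(values, bleach_frames)`` where ``values[t]`` is
    (number of fluorophores surviving at frame t) x ``intensity_per_fluor``
    plus additive Gaussian noise, and ``bleach_frames`` is the ground-truth
    first dark frame of each fluorophore (== ``n_frames`` if it never
    bleached within the movie).
    """
    if n_fluorophores < 0:
        raise ValueError("n_fluorophores must be >= 0")
    if not (0.0 <= bleach_rate <= 1.0):
        raise ValueError("bleach_rate must be in [0, 1]")
    for name, v in (("intensity_per_fluor", intensity_per_fluor),
                    ("noise_sd", noise_sd)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bleach = _bleach_frames(rng, n_fluorophores, bleach_rate, n_frames)
    t = np.arange(n_frames)
    surviving = (t[:, None] < bleach[None, :]).sum(axis=1) if n_fluorophores else np.zeros(n_frames)
    values = surviving * float(intensity_per_fluor)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n_frames)
    return values.astype(float), bleach


# ---------------------------------------------------------------------------
# image rendering


def _pixel_gaussian(x0: float, y0: float, sigma: float, halfwidth: int):
    """Pixel-integrated 2-D Gaussian patch of unit total flux.

    Pixel centres sit at integer coordinates (origin top-left, x = column);
    the value in pixel (i, j) is the Gaussian mass falling inside the unit
    square around it, so the patch sum equals the flux captured by the
    window (≈1 for halfwidth >= 4 sigma).
    """
    cx, cy = int(round(x0)), int(round(y0))
    xs = np.arange(cx - halfwidth, cx + halfwidth + 1)
    ys = np.arange(cy - halfwidth, cy + halfwidth + 1)
    s = sigma * math.sqrt(2.0)
    fx = 0.5 * (erf((xs + 0.5 - x0) / s) - erf((xs - 0.5 - x0) / s))
    fy = 0.5 * (erf((ys + 0.5 - y0) / s) - erf((ys - 0.5 - y0) / s))
    return cx, cy, np.outer(fy, fx)


def peak_amplitude(config: MovieConfig) -> float:
    """Brightest-pixel value of one centred fluorophore (ADU), used to
    define SNR = peak_amplitude / background_sd."""
    a = float(erf(0.5 / (config.psf_sigma_px * math.sqrt(2.0))))
    return config.intensity_per_fluorophore * a * a


def background_sd_for_snr(config: MovieConfig, snr: float) -> float:
    """Background sd giving the requested single-fluorophore peak SNR."""
    if snr <= 0:
        raise ValueError("snr must be > 0")
    return peak_amplitude(config) / snr


def movie_size_for(n_spots: int, min_separation_px: float, margin_px: float,
                   jitter_px: float = 0.5) -> int:
    """Side length (px) of a square field that fits ``n_spots`` on the
    jittered placement grid used by :func:`simulate_movie`."""
    pitch = min_separation_px + 2.0 * jitter_px
    per_side = int(math.ceil(math.sqrt(n_spots)))
    return int(math.ceil((per_side - 1) * pitch + 2 * (margin_px + jitter_px) + 2))


def _place_spots(rng, n, width, height, min_sep, margin, jitter=0.5):
    """Random spot positions >= min_sep apart and >= margin from edges.

    Positions are drawn on a jittered grid (pitch = min_sep + 2*jitter),
    which guarantees the separation constraint at any density the field can
    geometrically hold.
    """
    if n == 0:
        return np.empty(0), np.empty(0)
    pitch = min_sep + 2.0 * jitter
    lo = margin + jitter
    nx = int((width - 1 - 2 * lo) // pitch) + 1
    ny = int((height - 1 - 2 * lo) // pitch) + 1
    if nx < 1 or ny < 1 or nx * ny < n:
        raise ValueError(
            f"cannot place {n} spots >= {min_sep:.2f} px apart in a "
            f"{width}x{height} field (capacity {max(nx, 0) * max(ny, 0)})"
        )
    cells = rng.choice(nx * ny, size=n, replace=False)
    gx = lo + (cells % nx) * pitch
    gy = lo + (cells // nx) * pitch
    x = gx + rng.uniform(-jitter, jitter, size=n)
    y = gy + rng.uniform(-jitter, jitter, size=n)
    return x, y


def _background_stack(rng, config: MovieConfig) -> np.ndarray:
    stack = np.empty((config.n_frames, config.height_px, config.width_px), dtype=np.float32)
    for t in range(config.n_frames):
        stack[t] = config.background_mean + rng.normal(
            0.0, config.background_sd, size=(config.height_px, config.width_px)
        ) if config.background_sd > 0 else config.background_mean
    return stack


def _finalize_stack(rng, stack: np.ndarray, config: MovieConfig) -> np.ndarray:
    if config.shot_noise:
        stack = rng.poisson(np.clip(stack, 0, None)).astype(np.float32)
    return np.clip(np.rint(stack), 0, _UINT16_MAX).astype(np.uint16)


def _add_spot(stack, x, y, sigma, flux, t0, t1):
    """Add ``flux`` ADU of pixel-integrated Gaussian at (x, y) on frames
    [t0, t1)."""
    if t1 <= t0:
        return
    hw = int(math.ceil(5 * sigma))
    cx, cy, patch = _pixel_gaussian(x, y, sigma, hw)
    h, w = stack.shape[1:]
    y0, y1 = max(0, cy - hw), min(h, cy + hw + 1)
    x0, x1 = max(0, cx - hw), min(w, cx + hw + 1)
    sub = patch[y0 - (cy - hw): y1 - (cy - hw), x0 - (cx - hw): x1 - (cx - hw)]
    stack[t0:t1, y0:y1, x0:x1] += (flux * sub).astype(np.float32)


def simulate_movie(
    config: MovieConfig,
    pop: PopulationSpec,
    min_separation_px: float | None = None,
):
    """Render a photobleaching movie of an immobile monomer/dimer mixture.

    Each spot is a monomer (1 subunit) with probability ``1 - dimer_fraction``
    or a dimer (2 subunits); each subunit is labeled independently with
    probability ``labeling_efficiency`` and each labeled fluorophore bleaches
    with a per-frame probability ``bleach_rate_per_frame``. Returns
    ``(stack_uint16, truth)`` where ``truth`` is a DataFrame with one row per
    spot (including invisible, zero-label spots): spot_id, x, y,
    true_subunits, n_labeled, bleach_frames (";"-joined first dark frames).
    """
    rng = np.random.default_rng(config.seed)
    sigma = config.psf_sigma_px
    min_sep = 4.0 * sigma if min_separation_px is None else float(min_separation_px)
    margin = 3.0 * sigma
    x, y = _place_spots(rng, pop.n_spots, config.width_px, config.height_px, min_sep, margin)

    is_dimer = rng.random(pop.n_spots) < pop.dimer_fraction
    subunits = np.where(is_dimer, 2, 1)
    n_labeled = rng.binomial(subunits, pop.labeling_efficiency)

    stack = _background_stack(rng, config)
    rows = []
    for i in range(pop.n_spots):
        bleach = _bleach_frames(rng, int(n_labeled[i]), pop.bleach_rate_per_frame,
                                config.n_frames)
        for b in bleach:
            _add_spot(stack, x[i], y[i], sigma, config.intensity_per_fluorophore, 0, int(b))
        rows.append({
            "spot_id": i,
            "x": x[i],
            "y": y[i],
            "true_subunits": int(subunits[i]),
            "n_labeled": int(n_labeled[i]),
            "bleach_frames": ";".join(str(int(b)) for b in sorted(bleach)),
        })
    truth = pd.DataFrame(rows, columns=["spot_id", "x", "y", "true_subunits",
                                        "n_labeled", "bleach_frames"])
    return _finalize_stack(rng, stack, config), truth


def simulate_reference_field(
    config: MovieConfig,
    n_spots: int,
    copies: int = 2,
    min_separation_px: float | None = None,
):
    """Render one frame of a calibration standard: ``n_spots`` immobile
    spots each carrying exactly ``copies`` fluorophores (e.g. the
    surface-attached dimeric-GFP standard at ``copies=2``).

    Returns ``(stack_uint16 (1, H, W), truth)`` with truth columns
    spot_id, x, y, copies.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    rng = np.random.default_rng(config.seed)
    sigma = config.psf_sigma_px
    min_sep = 4.0 * sigma if min_separation_px is None else float(min_separation_px)
    x, y = _place_spots(rng, n_spots, config.width_px, config.height_px,
                        min_sep, 3.0 * sigma)
    cfg1 = MovieConfig(**{**vars(config), "n_frames": 1})
    stack = _background_stack(rng, cfg1)
    for i in range(n_spots):
        _add_spot(stack, x[i], y[i], sigma,
                  copies * config.intensity_per_fluorophore, 0, 1)
    truth = pd.DataFrame({"spot_id": np.arange(n_spots), "x": x, "y": y,
                          "copies": copies})
    return _finalize_stack(rng, stack, cfg1), truth


def simulate_kinetic_movie(
    config: MovieConfig,
    appearance_rate: float,
    mean_lifetime_frames: float,
    copies_per_complex: int = 6,
    seed: int | None = None,
    min_separation_px: float | None = None,
):
    """Render a movie of complexes appearing and vanishing.

    New complexes appear per frame as Poisson(``appearance_rate``) events at
    random positions (>= 4 sigma from any currently visible complex), persist
    for an exponentially distributed lifetime rounded to whole frames
    (minimum 1), then vanish. Each complex carries ``copies_per_complex``
    fluorophores; photobleaching is neglected on these short, sparsely
    sampled acquisitions (disappearance is the lifetime itself). Returns
    ``(stack_uint16, truth)`` with truth columns complex_id, x, y,
    appear_frame, lifetime_frames, disappear_frame (first frame no longer
    visible), copies.
    """
    if appearance_rate < 0 or mean_lifetime_frames < 0:
        raise ValueError("rates must be >= 0")
    if copies_per_complex < 1:
        raise ValueError("copies_per_complex must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sigma = config.psf_sigma_px
    min_sep = 4.0 * sigma if min_separation_px is None else float(min_separation_px)
    margin = 3.0 * sigma

    stack = _background_stack(rng, config)
    rows = []
    active: list[tuple[float, float, int]] = []  # (x, y, disappear_frame)
    cid = 0
    for t in range(config.n_frames):
        active = [a for a in active if a[2] > t]
        for _ in range(rng.poisson(appearance_rate)):
            pos = _sample_free_position(rng, config, margin, min_sep, active)
            if pos is None:
                continue  # field momentarily saturated; skip this event
            if mean_lifetime_frames > 0:
                life = max(1, int(round(rng.exponential(mean_lifetime_frames))))
            else:
                life = 1
            end = min(t + life, config.n_frames)
            _add_spot(stack, pos[0], pos[1], sigma,
                      copies_per_complex * config.intensity_per_fluorophore, t, end)
            active.append((pos[0], pos[1], t + life))
            rows.append({"complex_id": cid, "x": pos[0], "y": pos[1],
                         "appear_frame": t, "lifetime_frames": life,
                         "disappear_frame": t + life, "copies": copies_per_complex})
            cid += 1
    truth = pd.DataFrame(rows, columns=["complex_id", "x", "y", "appear_frame",
                                        "lifetime_frames", "disappear_frame", "copies"])
    return _finalize_stack(rng, stack, config), truth


def _sample_free_position(rng, config, margin, min_sep, active, max_tries=200):
    lo_x, hi_x = margin, config.width_px - 1 - margin
    lo_y, hi_y = margin, config.height_px - 1 - margin
    if hi_x <= lo_x or hi_y <= lo_y:
        raise ValueError("field too small for the PSF margin")
    for _ in range(max_tries):
        px = rng.uniform(lo_x, hi_x)
        py = rng.uniform(lo_y, hi_y)
        if all((px - a[0]) ** 2 + (py - a[1]) ** 2 >= min_sep ** 2 for a in active):
            return px, py
    return None


# ---------------------------------------------------------------------------
# NF-kB translocation / reporter series


def _ratio_curve(t: np.ndarray, p: NfkbCellParams) -> np.ndarray:
    pulse = np.exp(-((t - p.t_peak_min) ** 2) / (2.0 * p.pulse_width_min ** 2))
    return p.baseline_ratio + (p.peak_ratio - p.baseline_ratio) * pulse


def _reporter_curve(t: np.ndarray, p: NfkbCellParams) -> np.ndarray:
    tau = p.reporter_rise_tau_min
    t_mid = p.reporter_delay_min + 3.0 * tau
    s = 0.5 * (1.0 + np.tanh((t - t_mid) / tau))
    return 1.0 + (p.reporter_fold - 1.0) * s


def simulate_nfkb_series(
    params: NfkbCellParams,
    duration_min: float = 900.0,
    seed: int | np.random.Generator = 0,
    cell_id: str = "cell0",
    emit_images: bool = False,
    image_size: int = 64,
):
    """Simulate one cell's translocation + reporter time series.

    Returns a :class:`CellTimeSeries`; with ``emit_images=True`` returns
    ``(series, stack, nucleus_mask, cytoplasm_mask)`` where ``stack`` has
    shape (T, 2, H, W) with channel 0 = green, channel 1 = red, and the
    masks are the rendering ground truth (so segmentation is testable
    separately from everything downstream).
    """
    if duration_min < params.t_peak_min:
        raise ValueError("duration must cover t_peak_min")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(0.0, duration_min + 1e-9, params.sampling_interval_min)
    ratio = _ratio_curve(t, params)
    red = _reporter_curve(t, params)

    cyt0, red0 = 100.0, 100.0
    cyt = np.full_like(t, cyt0)
    nuc = ratio * cyt0
    rep = red * red0
    if params.noise_sd > 0:
        nuc = nuc * (1.0 + rng.normal(0.0, params.noise_sd, size=t.size))
        cyt = cyt * (1.0 + rng.normal(0.0, params.noise_sd, size=t.size))
        rep = rep * (1.0 + rng.normal(0.0, params.noise_sd, size=t.size))
    series = CellTimeSeries(cell_id, t, nuc, cyt, rep)
    if not emit_images:
        return series

    h = w = image_size
    yy, xx = np.mgrid[0:h, 0:w]
    cy = cx = (h - 1) / 2.0
    cell = (yy - cy) ** 2 + (xx - cx) ** 2 <= (0.42 * h) ** 2
    nucleus = (yy - cy - 0.08 * h) ** 2 + (xx - cx) ** 2 <= (0.16 * h) ** 2
    nucleus &= cell
    cyto = cell & ~nucleus
    stack = np.zeros((t.size, 2, h, w), dtype=np.float32)
    for i in range(t.size):
        g = np.full((h, w), 10.0, dtype=np.float32)
        g[cyto] = cyt[i]
        g[nucleus] = nuc[i]
        r = np.full((h, w), 10.0, dtype=np.float32)
        r[cell] = rep[i]
        if params.noise_sd > 0:
            g *= 1.0 + rng.normal(0.0, params.noise_sd, size=(h, w)).astype(np.float32)
            r *= 1.0 + rng.normal(0.0, params.noise_sd, size=(h, w)).astype(np.float32)
        stack[i, 0] = g
        stack[i, 1] = r
    return series, stack, nucleus, cyto


def simulate_nfkb_cohort(
    n_cells: int,
    seed: int = 0,
    duration_min: float = 900.0,
    t_peak_range: tuple[float, float] = (15.0, 120.0),
    peak_ratio_range: tuple[float, float] = (1.8, 3.0),
    baseline_ratio: float = 1.0,
    reporter_fold_range: tuple[float, float] = (1.5, 6.0),
    reporter_delay_min: float = 60.0,
    noise_sd: float = 0.05,
    sampling_interval_min: float = 3.0,
    fold_link: str | None = None,
):
    """Simulate a cohort of cells; returns ``(series_list, truth_df)``.

    ``fold_link='inverse'`` makes the reporter fold a decreasing function of
    the peak time (cells translocating faster induce more reporter), the
    relationship the rank-correlation analysis is designed to detect;
    ``None`` draws fold independently (a null cohort).
    """
    rng = np.random.default_rng(seed)
    series, rows = [], []
    lo, hi = t_peak_range
    flo, fhi = reporter_fold_range
    for i in range(n_cells):
        t_peak = rng.uniform(lo, hi)
        if fold_link == "inverse":
            frac = (hi - t_peak) / (hi - lo) if hi > lo else 0.5
            fold = flo + (fhi - flo) * frac * (1.0 + rng.normal(0.0, 0.02))
            fold = max(1.0, fold)
        elif fold_link is None:
            fold = rng.uniform(flo, fhi)
        else:
            raise ValueError(f"unknown fold_link: {fold_link!r}")
        params = NfkbCellParams(
            t_peak_min=t_peak,
            peak_ratio=rng.uniform(*peak_ratio_range),
            baseline_ratio=baseline_ratio,
            reporter_fold=fold,
            reporter_delay_min=reporter_delay_min,
            noise_sd=noise_sd,
            sampling_interval_min=sampling_interval_min,
        )
        series.append(simulate_nfkb_series(params, duration_min, rng, cell_id=f"cell{i}"))
        rows.append({"cell_id": f"cell{i}", "t_peak_min": t_peak,
                     "peak_ratio": params.peak_ratio, "reporter_fold": fold})
    return series, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# output


def write_movie(path, stack: np.ndarray) -> None:
    """Write a movie as multi-frame 16-bit grayscale TIFF."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16))


def write_ground_truth(path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, index=False)


def write_config_sidecar(path, *configs) -> None:
    """Echo generator parameters to a YAML sidecar next to the data."""
    blob = {}
    for c in configs:
        if dataclasses.is_dataclass(c):
            blob[type(c).__name__] = dataclasses.asdict(c)
        else:
            blob.update(dict(c))
    with open(path, "w") as fh:
        yaml.safe_dump(blob, fh, sort_keys=True)
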