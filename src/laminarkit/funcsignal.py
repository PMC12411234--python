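"""Phase-encoded BOLD analysis: run averaging, Fourier response amplitude,
calibrated depth-response profiles, 1-D pRF fitting and RLC eigenvector
centrality."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.stats import gamma as gamma_dist

from .errors import DesignError, NormalizationError
from .laminar import N_DEPTHS, LayerCompartments

__all__ = [
    "PhaseEncodedSeries",
    "DepthResponseProfile",
    "PRFFit",
    "average_phase_runs",
    "fourier_amplitude",
    "calibrated_depth_profile",
    "peak_decay_metrics",
    "fit_prf_1d",
    "noise_ceiling",
    "ecm_rlc",
    "canonical_hrf",
]

#: movement-artifact frequency cutoff (Hz): lower frequencies are excluded
FREQ_CUTOFF_HZ = 0.005

#: hemodynamic-delay compensation applied to time-reversed runs (seconds)
HEMODYNAMIC_SHIFT_S = 4.0

#: fraction of superficial depths excluded from depth-response metrics
SUPERFICIAL_EXCLUDE_FRACTION = 0.2


@dataclass
class PhaseEncodedSeries:
    """Per-vertex BOLD run with cycle metadata."""

    samples: np.ndarray  # (vertices, timepoints)
    tr: float  # s
    n_cycles: int
    cycle_length: float  # s
    direction: str = "forward"  # forward | reverse
    mean_brightness: float = 100.0
    rest_pre_s: float = 0.0  # rest block before stimulation
    rest_post_s: float = 0.0  # rest block after stimulation

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.tr <= 0:
            raise ValueError("TR must be > 0")
        if self.direction not in ("forward", "reverse"):
            raise ValueError("direction must be 'forward' or 'reverse'")
        expected = (
            self.n_cycles * self.cycle_length + self.rest_pre_s + self.rest_post_s
        ) / self.tr
        if abs(self.n_timepoints - expected) > 1e-6:
            raise DesignError(
                f"{self.n_timepoints} timepoints inconsistent with "
                f"{self.n_cycles} cycles x {self.cycle_length}s "
                f"(+{self.rest_pre_s + self.rest_post_s}s rest) at TR={self.tr}s"
            )

    @property
    def n_timepoints(self) -> int:
        return self.samples.shape[1]

    def stimulation_window(self) -> "PhaseEncodedSeries":
        """Copy restricted to the stimulation cycles (rest blocks cropped)."""
        if self.rest_pre_s == 0 and self.rest_post_s == 0:
            return self
        a = int(round(self.rest_pre_s / self.tr))
        b = self.n_timepoints - int(round(self.rest_post_s / self.tr))
        return replace(
            self, samples=self.samples[:, a:b], rest_pre_s=0.0, rest_post_s=0.0
        )


@dataclass
class DepthResponseProfile:
    """Calibrated 21-depth response curve with peak/decay metrics."""

    amplitude: np.ndarray  # % signal change per depth
    normalized: np.ndarray  # min-max normalized, in [0, 1]
    rest_normalized: np.ndarray
    calibrated: np.ndarray
    peak_metric: float = np.nan
    decay_metric: float = np.nan


@dataclass
class PRFFit:
    mu: float
    sigma: float
    beta: float
    baseline: float
    r2: float
    nr2: float = np.nan
    noise_ceiling: float = np.nan
    degenerate: bool = False


def average_phase_runs(
    forward: PhaseEncodedSeries, reverse: PhaseEncodedSeries
) -> PhaseEncodedSeries:
    """Average a forward and a reverse run after mirroring the reverse run.

    The reverse run is time-reversed, circularly shifted forward by the
    hemodynamic-delay compensation (4 s = two TRs at TR 2 s), and averaged
    timepoint by timepoint with the forward run.
    """
    if forward.direction != "forward" or reverse.direction != "reverse":
        raise ValueError("pass one forward and one reverse run, in that order")
    if forward.samples.shape != reverse.samples.shape:
        raise ValueError("runs must have matching shapes")
    if forward.tr != reverse.tr or forward.n_cycles != reverse.n_cycles:
        raise ValueError("runs must share TR and cycle structure")
    shift = int(round(HEMODYNAMIC_SHIFT_S / forward.tr))
    mirrored = np.roll(reverse.samples[:, ::-1], shift, axis=1)
    avg = 0.5 * (forward.samples + mirrored)
    return replace(
        forward,
        samples=avg,
        mean_brightness=0.5 * (forward.mean_brightness + reverse.mean_brightness),
    )


def fourier_amplitude(
    series: PhaseEncodedSeries,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-vertex response amplitude (%), phase and F-ratio at the stimulus bin.

    The stimulus frequency bin equals the number of stimulation cycles.  The
    noise set comprises bins at or above the 0.005 Hz movement cutoff up to
    Nyquist, excluding the stimulus bin and its first two harmonics.  The
    percent amplitude applies the x2 (negative frequencies) * x2
    (peak-to-peak) / N / brightness * 100 chain to the DFT magnitude.
    """
    series = series.stimulation_window()
    if series.n_cycles < 2:
        raise ValueError("need at least 2 stimulation cycles")
    if series.mean_brightness <= 0:
        raise ValueError("mean brightness must be > 0")
    x = series.samples
    n = series.n_timepoints
    spec = np.fft.rfft(x, axis=1)
    freqs = np.fft.rfftfreq(n, d=series.tr)
    stim_bin = series.n_cycles
    included = np.flatnonzero(freqs >= FREQ_CUTOFF_HZ)
    if stim_bin not in included:
        raise ValueError("stimulus bin falls outside the included frequency range")
    harmonics = {stim_bin, 2 * stim_bin, 3 * stim_bin}
    noise_bins = np.array([k for k in included if k not in harmonics])
    if noise_bins.size == 0:
        raise ValueError("no noise bins available for the F-ratio")

    power = np.abs(spec) ** 2
    stim_power = power[:, stim_bin]
    noise_power = power[:, noise_bins].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_ratio = np.where(noise_power > 0, stim_power / noise_power, np.inf)
        f_ratio = np.where(stim_power == 0, 0.0, f_ratio)

    amplitude = (
        np.abs(spec[:, stim_bin]) * 2.0 * 2.0 / n / series.mean_brightness * 100.0
    )
    phase = np.angle(spec[:, stim_bin])
    return amplitude, phase, f_ratio


def _minmax(x: np.ndarray) -> np.ndarray:
    rng = x.max() - x.min()
    if rng == 0:
        raise NormalizationError("profile has zero range; cannot min-max normalize")
    return (x - x.min()) / rng


def calibrated_depth_profile(
    task_profile: np.ndarray,
    rest_profile: np.ndarray,
    epsilon: float = 0.05,
    mode: str = "divide",
) -> DepthResponseProfile:
    """Min-max normalize task and rest depth curves, then calibrate the task
    curve by the rest curve to control for baseline fluctuations.

    ``divide`` (default): calibrated = (task_n + eps) / (rest_n + eps), with
    eps expressed as a fraction of the (unit) normalized rest range so that
    identical curves calibrate to a constant 1.  ``subtract`` is available as
    an alternative operator.
    """
    task_profile = np.asarray(task_profile, dtype=float)
    rest_profile = np.asarray(rest_profile, dtype=float)
    if task_profile.shape != (N_DEPTHS,) or rest_profile.shape != (N_DEPTHS,):
        raise ValueError(f"profiles must have length {N_DEPTHS}")
    tn = _minmax(task_profile)
    rn = _minmax(rest_profile)
    if mode == "divide":
        cal = (tn + epsilon) / (rn + epsilon)
    elif mode == "subtract":
        cal = tn - rn
    else:
        raise ValueError(f"unknown calibration mode {mode!r}")
    return DepthResponseProfile(task_profile, tn, rn, cal)


def peak_decay_metrics(
    profile: DepthResponseProfile, compartments: LayerCompartments
) -> tuple[float, float]:
    """Area-under-curve peak and decay metrics of the calibrated depth curve.

    The most superficial 20% of depths is excluded (superficial veins).  The
    peak metric is the trapezoidal AUC of (calibrated - median) over the
    middle compartment; the decay metric is the mean of the AUCs of
    (median - calibrated) over the outer and inner flanks, each clipped at 0.
    """
    cal = np.asarray(profile.calibrated, dtype=float)
    depth_frac = np.arange(N_DEPTHS) / (N_DEPTHS - 1)
    retained = np.flatnonzero(depth_frac >= SUPERFICIAL_EXCLUDE_FRACTION)
    med = np.median(cal[retained])

    def auc(indices: np.ndarray, sign: float) -> float:
        idx = np.intersect1d(indices, retained)
        if idx.size < 2:
            return 0.0
        y = sign * (cal[idx] - med)
        return float(np.trapezoid(y, depth_frac[idx]))

    middle = compartments.depth_indices("middle")
    outer = compartments.depth_indices("outer")
    inner = compartments.depth_indices("inner")
    if np.intersect1d(middle, retained).size == 0:
        raise ValueError("middle compartment does not overlap retained depths")
    peak = auc(middle, +1.0)
    decay = float(np.mean([max(auc(outer, -1.0), 0.0), max(auc(inner, -1.0), 0.0)]))
    profile.peak_metric = peak
    profile.decay_metric = decay
    return peak, decay


def save_series_h5(series: PhaseEncodedSeries, path) -> None:
    """Write a series to HDF5 (dataset ``data`` + metadata attributes)."""
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=series.samples)
        d.attrs.update(
            tr=series.tr,
            n_cycles=series.n_cycles,
            cycle_length=series.cycle_length,
            direction=series.direction,
            mean_brightness=series.mean_brightness,
            rest_pre_s=series.rest_pre_s,
            rest_post_s=series.rest_post_s,
        )


def load_series_h5(path) -> PhaseEncodedSeries:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["data"]
        a = d.attrs
        return PhaseEncodedSeries(
            d[...],
            tr=float(a["tr"]),
            n_cycles=int(a["n_cycles"]),
            cycle_length=float(a["cycle_length"]),
            direction=str(a["direction"]),
            mean_brightness=float(a["mean_brightness"]),
            rest_pre_s=float(a.get("rest_pre_s", 0.0)),
            rest_post_s=float(a.get("rest_post_s", 0.0)),
        )


def canonical_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR (peak 6 s, undershoot 16 s,
    undershoot ratio 1/6), normalized to unit peak."""
    t = np.arange(0, duration, tr)
    peak = gamma_dist.pdf(t, 6.0)
    under = gamma_dist.pdf(t, 16.0)
    h = peak - under / 6.0
    return h / h.max()


def _prf_prediction(
    mu: float, sigma: float, aperture: np.ndarray, space: np.ndarray, hrf: np.ndarray
) -> np.ndarray:
    rf = np.exp(-0.5 * ((space - mu) / sigma) ** 2)
    drive = aperture @ rf
    pred = np.convolve(drive, hrf)[: len(drive)]
    return pred


def fit_prf_1d(
    timecourse: np.ndarray,
    aperture: np.ndarray,
    space: np.ndarray,
    tr: float = 2.0,
    hrf: np.ndarray | None = None,
    bounds: tuple[float, float] = (-1.25, 1.25),
    grid_step: float = 0.05,
    ceiling: float | None = None,
) -> PRFFit:
    """Two-stage coarse-to-fine 1-D Gaussian pRF fit.

    Coarse stage: grid search over (mu, sigma) in [-1.25, 1.25] x (0, 1.25]
    maximizing the correlation between the observed series and the
    HRF-convolved prediction.  Fine stage: Nelder-Mead refinement from the
    coarse optimum.  Beta and baseline follow by least squares; R^2 is the
    squared correlation, nR^2 = R^2 / noise ceiling when a ceiling is given.
    """
    timecourse = np.asarray(timecourse, dtype=float)
    if not np.all(np.isfinite(timecourse)):
        raise ValueError("timecourse contains non-finite values")
    aperture = np.atleast_2d(np.asarray(aperture, dtype=float))
    space = np.asarray(space, dtype=float)
    if aperture.shape[0] != len(timecourse):
        raise ValueError("aperture rows must match timecourse length")
    if hrf is None:
        hrf = canonical_hrf(tr)

    # z-score + linear detrend of the observed series
    t_idx = np.arange(len(timecourse))
    y = timecourse - np.polyval(np.polyfit(t_idx, timecourse, 1), t_idx)
    sd = y.std()
    y = y / sd if sd > 0 else y

    def neg_corr(params: np.ndarray) -> float:
        mu, sigma = params
        if not (bounds[0] <= mu <= bounds[1]) or not (0 < sigma <= bounds[1]):
            return 2.0
        pred = _prf_prediction(mu, sigma, aperture, space, hrf)
        ps = pred.std()
        if ps == 0:
            return 2.0
        r = float(np.corrcoef(y, pred)[0, 1])
        return -r

    mus = np.arange(bounds[0], bounds[1] + grid_step / 2, grid_step)
    sigmas = np.arange(grid_step, bounds[1] + grid_step / 2, grid_step)
    best = (np.inf, 0.0, sigmas[0])
    for mu in mus:
        for sigma in sigmas:
            v = neg_corr(np.array([mu, sigma]))
            if v < best[0]:
                best = (v, mu, sigma)
    if best[0] >= 2.0:
        return PRFFit(0.0, sigmas[0], 0.0, float(y.mean()), 0.0, degenerate=True)

    res = minimize(
        neg_corr,
        x0=np.array([best[1], best[2]]),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-8},
    )
    mu, sigma = (res.x if res.fun <= best[0] else np.array([best[1], best[2]]))
    sigma = float(np.clip(sigma, 1e-6, bounds[1]))

    pred = _prf_prediction(float(mu), sigma, aperture, space, hrf)
    design = np.column_stack([pred, np.ones_like(pred)])
    (beta, baseline), *_ = np.linalg.lstsq(design, y, rcond=None)
    r = float(np.corrcoef(y, pred)[0, 1])
    r2 = r * r
    fit = PRFFit(float(mu), sigma, float(beta), float(baseline), r2)
    if ceiling is not None:
        fit.noise_ceiling = ceiling
        fit.nr2 = r2 / ceiling if ceiling > 0 else np.nan
    return fit


def noise_ceiling(half1: np.ndarray, half2: np.ndarray) -> float:
    """Spearman-Brown prophecy ceiling from split-half reliability."""
    half1 = np.asarray(half1, dtype=float)
    half2 = np.asarray(half2, dtype=float)
    if half1.shape != half2.shape:
        raise ValueError("halves must have equal length")
    if half1.std() == 0 or half2.std() == 0:
        raise ValueError("constant half; reliability undefined")
    r = float(np.corrcoef(half1, half2)[0, 1])
    return max(0.0, 2.0 * r / (1.0 + r)) if r > -1.0 else 0.0


def ecm_rlc(
    timeseries: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000
) -> np.ndarray:
    """Eigenvector centrality on the rectified-correlation adjacency.

    Adjacency = max(0, Pearson r) with zero diagonal; the centrality is the
    principal eigenvector obtained by power iteration, nonnegative and of
    unit Euclidean norm.
    """
    x = np.atleast_2d(np.asarray(timeseries, dtype=float))
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 vertices")
    sds = x.std(axis=1)
    if np.any(sds == 0):
        raise ValueError("constant timecourse present; correlation undefined")
    a = np.corrcoef(x)
    np.fill_diagonal(a, 0.0)
    a = np.maximum(a, 0.0)
    if not a.any():
        warnings.warn("all-zero adjacency; returning uniform centrality")
        return np.full(n, 1.0 / np.sqrt(n))
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        w = a @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            warnings.warn("power iteration collapsed; returning uniform centrality")
            return np.full(n, 1.0 / np.sqrt(n))
        w /= norm
        if np.linalg.norm(w - v) < tol:
            v = w
            break
        v = w
    return v
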