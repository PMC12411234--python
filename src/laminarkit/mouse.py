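"""Calcium-trace quantification, movement-state labeling, double-vs-single
stimulation response classification and depth-binned histological densities."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import filtfilt, firwin
from scipy.stats import ttest_ind

__all__ = [
    "CalciumTraces",
    "HistoSection",
    "delta_f_over_f",
    "label_movement_epochs",
    "classify_double_vs_single",
    "bin_depth_density",
]

SAMPLING_HZ = 30.0
FIR_ORDER = 60
FIR_CUTOFF_HZ = 1.0
BASELINE_PERCENTILE = 5.0

#: intermovement intervals shorter than this are relabeled as movement
GAP_MERGE_S = 0.5


@dataclass
class CalciumTraces:
    """Fluorescence matrix (neurons x timepoints) with stimulus metadata."""

    fluorescence: np.ndarray
    fs: float = SAMPLING_HZ
    onsets: dict[str, np.ndarray] = field(default_factory=dict)  # condition -> s

    def __post_init__(self):
        self.fluorescence = np.atleast_2d(np.asarray(self.fluorescence, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be > 0")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence contains non-finite values")
        duration = self.fluorescence.shape[1] / self.fs
        for cond, t in self.onsets.items():
            t = np.asarray(t, dtype=float)
            if t.size and (t.min() < 0 or t.max() >= duration):
                raise ValueError(f"onsets for {cond!r} fall outside the record")
            self.onsets[cond] = t

    @property
    def n_neurons(self) -> int:
        return self.fluorescence.shape[0]


@dataclass
class HistoSection:
    """Marker-cell depth positions in a section, normalized 0 (surface) to 1
    (white matter), with layer demarcation fractions."""

    positions: np.ndarray
    marker: str  # PV | Iba1
    dapi_positions: np.ndarray
    demarcations: tuple[float, ...] = (0.30, 0.45)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.dapi_positions = np.asarray(self.dapi_positions, dtype=float)
        for arr, label in ((self.positions, "marker"), (self.dapi_positions, "DAPI")):
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValueError(f"{label} positions must lie in [0, 1]")
        if len(self.dapi_positions) < len(self.positions):
            raise ValueError("DAPI count must be at least the marker count")
        if list(self.demarcations) != sorted(self.demarcations) or not all(
            0 < d < 1 for d in self.demarcations
        ):
            raise ValueError("demarcations must be ordered fractions in (0, 1)")


def delta_f_over_f(
    traces: CalciumTraces,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron dF/F with a percentile baseline.

    F0 is the 5th percentile of the 1 Hz low-pass (zero-phase, 60th-order
    FIR) filtered trace; dF/F = (F - F0) / F0.  Neurons with F0 <= 0 are
    flagged (returned mask False) and their rows set to NaN.
    """
    f = traces.fluorescence
    if f.shape[1] <= 3 * FIR_ORDER:
        raise ValueError("trace shorter than filter padding requirement")
    taps = firwin(FIR_ORDER + 1, FIR_CUTOFF_HZ, fs=traces.fs)
    smoothed = filtfilt(taps, [1.0], f, axis=1)
    f0 = np.percentile(smoothed, BASELINE_PERCENTILE, axis=1)
    valid = f0 > 0
    dff = np.full_like(f, np.nan)
    dff[valid] = (f[valid] - f0[valid, None]) / f0[valid, None]
    return dff, valid


def label_movement_epochs(
    speed: np.ndarray,
    fs: float = SAMPLING_HZ,
    threshold: float = 0.5,
    gap_merge_s: float = GAP_MERGE_S,
) -> np.ndarray:
    """Boolean whisker-pad movement mask.

    A frame is movement iff instantaneous speed, 0.25 Hz low-pass filtered
    speed and the average speed over a 1 s centered window are all at or
    above the threshold (0.5 cm/s).  Intermovement gaps shorter than 500 ms
    are then relabeled as movement.
    """
    speed = np.asarray(speed, dtype=float)
    if np.any(speed < 0):
        raise ValueError("speed must be nonnegative")
    n = len(speed)

    inst = speed >= threshold

    taps = firwin(FIR_ORDER + 1, 0.25, fs=fs)
    pad = min(3 * FIR_ORDER, n - 1)
    lowpass = filtfilt(taps, [1.0], speed, padlen=pad) >= threshold

    win = max(1, int(round(fs)))
    kernel = np.ones(win) / win
    window_avg = np.convolve(speed, kernel, mode="same") >= threshold

    mask = inst & lowpass & window_avg

    # merge short intermovement gaps
    gap_frames = int(round(gap_merge_s * fs))
    out = mask.copy()
    i = 0
    while i < n:
        if not out[i]:
            j = i
            while j < n and not out[j]:
                j += 1
            interior = i > 0 and j < n  # gap flanked by movement on both sides
            if interior and (j - i) < gap_frames:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def _evoked_amplitudes(
    dff_row: np.ndarray,
    onsets_s: np.ndarray,
    fs: float,
    pre_s: float,
    post_s: float,
) -> np.ndarray:
    amps = []
    n = len(dff_row)
    for t in onsets_s:
        k = int(round(t * fs))
        pre = dff_row[max(0, k - int(pre_s * fs)) : k]
        post = dff_row[k : min(n, k + int(post_s * fs))]
        if len(pre) and len(post):
            amps.append(post.mean() - pre.mean())
    return np.asarray(amps)


def classify_double_vs_single(
    dff: np.ndarray,
    onsets_double: np.ndarray,
    onsets_single: np.ndarray,
    fs: float = SAMPLING_HZ,
    alpha: float = 0.05,
    pre_s: float = 1.0,
    post_s: float = 1.0,
    min_trials: int = 5,
) -> tuple[np.ndarray, dict[str, float], int]:
    """Per-neuron double-vs-single response class and class proportions.

    Trial-wise evoked amplitude = mean dF/F 0-1 s post-onset minus the 1 s
    pre-onset mean.  A Welch test at ``alpha`` decides: additive when double
    > single, reduced when double < single, unchanged otherwise.  Neurons
    with too few trials or NaN traces are excluded (count returned).
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    if len(onsets_double) < min_trials or len(onsets_single) < min_trials:
        raise ValueError(f"need at least {min_trials} trials per condition")

    classes = np.full(dff.shape[0], "", dtype=object)
    excluded = 0
    for i, row in enumerate(dff):
        if not np.all(np.isfinite(row)):
            classes[i] = "excluded"
            excluded += 1
            continue
        a_d = _evoked_amplitudes(row, onsets_double, fs, pre_s, post_s)
        a_s = _evoked_amplitudes(row, onsets_single, fs, pre_s, post_s)
        if len(a_d) < min_trials or len(a_s) < min_trials:
            classes[i] = "excluded"
            excluded += 1
            continue
        if np.allclose(a_d, a_d[0]) and np.allclose(a_s, a_s[0]):
            # noiseless degenerate case: compare means directly
            if np.isclose(a_d.mean(), a_s.mean()):
                classes[i] = "unchanged"
            else:
                classes[i] = "additive" if a_d.mean() > a_s.mean() else "reduced"
            continue
        t, p = ttest_ind(a_d, a_s, equal_var=False)
        if p < alpha:
            classes[i] = "additive" if a_d.mean() > a_s.mean() else "reduced"
        else:
            classes[i] = "unchanged"

    kept = classes != "excluded"
    n_kept = int(kept.sum())
    props = {
        c: float((classes[kept] == c).sum() / n_kept) if n_kept else np.nan
        for c in ("additive", "reduced", "unchanged")
    }
    return classes, props, excluded


def bin_depth_density(
    section: HistoSection, n_bins: int = 10, layer_width: float = 1.0
) -> dict:
    """Depth histogram plus per-layer densities and percent-of-DAPI.

    Layer area is approximated as (demarcated depth span x ``layer_width``),
    matching density normalization 'to the area for the given demarcated
    cortical depths'.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    counts, edges = np.histogram(section.positions, bins=n_bins, range=(0.0, 1.0))

    bounds = (0.0, *section.demarcations, 1.0)
    layers = ["outer", "middle", "inner"][: len(bounds) - 1]
    density, percent, layer_counts = {}, {}, {}
    for name, lo, hi in zip(layers, bounds[:-1], bounds[1:]):
        inc_hi = hi == 1.0
        in_layer = (section.positions >= lo) & (
            (section.positions <= hi) if inc_hi else (section.positions < hi)
        )
        in_dapi = (section.dapi_positions >= lo) & (
            (section.dapi_positions <= hi) if inc_hi else (section.dapi_positions < hi)
        )
        c = int(in_layer.sum())
        d = int(in_dapi.sum())
        layer_counts[name] = c
        density[name] = c / ((hi - lo) * layer_width)
        percent[name] = 100.0 * c / d if d else 0.0
    return {
        "bin_counts": counts,
        "bin_edges": edges,
        "layer_counts": layer_counts,
        "density": density,
        "percent_of_dapi": percent,
    }
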