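"""Behavioral analysis: adaptive staircase thresholds, d-prime, two-point
discrimination, skin-indentation conversion and precision-grip scoring."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import StaircaseError

__all__ = [
    "TrialLog",
    "SkinModel",
    "MONOFILAMENT_FORCES_G",
    "staircase_threshold",
    "dprime",
    "two_point_threshold",
    "skin_indentation",
    "grip_time_on_target",
]

#: Semmes-Weinstein monofilament set (grams-force)
MONOFILAMENT_FORCES_G = (
    0.008, 0.02, 0.04, 0.07, 0.16, 0.4, 0.6, 1.0, 1.4, 2.0, 4.0, 6.0,
)


def log10_tenth_mg(force_g: np.ndarray | float) -> np.ndarray | float:
    """Force in grams -> log10 of force in 1/10 milligram units."""
    return np.log10(np.asarray(force_g, dtype=float) * 10_000.0)


@dataclass
class TrialLog:
    """Chronological psychophysics trial sequence."""

    intensity: np.ndarray  # stimulus intensity per trial (task units)
    response: np.ndarray  # correctness (0/1) or choice per trial
    staircase: np.ndarray | None = None  # staircase id per trial
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.response = np.asarray(self.response)
        if len(self.intensity) != len(self.response):
            raise ValueError("intensity and response must have equal length")
        if self.staircase is None:
            self.staircase = np.zeros(len(self.intensity), dtype=int)
        else:
            self.staircase = np.asarray(self.staircase, dtype=int)

    def __len__(self) -> int:
        return len(self.intensity)

    @classmethod
    def from_tsv(cls, path) -> "TrialLog":
        df = pd.read_csv(path, sep="\t")
        return cls(
            df["intensity"].to_numpy(),
            df["response"].to_numpy(),
            df["staircase"].to_numpy() if "staircase" in df else None,
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "trial": np.arange(len(self)),
                "staircase": self.staircase,
                "intensity": self.intensity,
                "response": self.response,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SkinModel:
    """Force -> indentation power-law constants (fixed as printed)."""

    A: float = 0.2368  # N
    b: float = 2.0696
    delta_ref: float = 1.00  # mm


def _reversal_mask(log: TrialLog) -> np.ndarray:
    """Trials at which the response flips correct<->incorrect within their
    staircase (the first flip after the initial run included)."""
    correct = np.asarray(log.response, dtype=float) > 0.5
    rev = np.zeros(len(log), dtype=bool)
    for sc in np.unique(log.staircase):
        idx = np.flatnonzero(log.staircase == sc)
        c = correct[idx]
        rev[idx[1:]] = c[1:] != c[:-1]
    return rev


def staircase_threshold(
    log: TrialLog,
    window: int = 10,
    max_trials: int = 100,
    stop_window: int = 30,
    ladder_step: float | None = None,
) -> float:
    """Detection threshold from a 3-down/1-up staircase log.

    Threshold = mean stimulus intensity across reversal points within the
    final ``window`` trials.  The stop rule (sd of intensity over the last
    ``stop_window`` trials at most one ladder step, or ``max_trials``
    reached) is validated with a warning when violated.
    """
    n = len(log)
    if n < window:
        raise StaircaseError(f"log has {n} trials; need at least {window}")
    if ladder_step is not None and n < max_trials:
        tail_sd = float(np.std(log.intensity[-stop_window:]))
        if n < stop_window or tail_sd > ladder_step:
            warnings.warn(
                "stop rule not satisfied: run shorter than the maximum with "
                "intensity sd above one ladder step over the last trials"
            )
    rev = _reversal_mask(log)
    final = np.zeros(n, dtype=bool)
    final[-window:] = True
    sel = rev & final
    if not sel.any():
        raise StaircaseError(
            "no reversal within the final trials; collect a longer run"
        )
    return float(log.intensity[sel].mean())


def dprime(
    hits: float,
    false_alarms: float,
    n_signal: int,
    n_noise: int,
    fa_floor: float = 0.1,
) -> float:
    """Sensitivity index d' = z(hit) - z(false alarm).

    A zero false-alarm rate is replaced by ``fa_floor`` (0.1 by default);
    rates of exactly 0/1 elsewhere are clamped by the 1/(2n) correction.
    """
    if n_signal <= 0 or n_noise <= 0:
        raise ValueError("trial counts must be > 0")
    if not (0 <= hits <= 1 and 0 <= false_alarms <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if false_alarms == 0:
        false_alarms = fa_floor
    elif false_alarms == 1:
        false_alarms = 1 - 1 / (2 * n_noise)
    if hits == 1:
        hits = 1 - 1 / (2 * n_signal)
    elif hits == 0:
        hits = 1 / (2 * n_signal)
    return float(norm.ppf(hits) - norm.ppf(false_alarms))


def two_point_threshold(
    spacings: np.ndarray, responses: np.ndarray
) -> tuple[float, dict]:
    """2PD threshold from a logit fit of P('two pins') on pin spacing.

    Returns the spacing at fitted P = 0.5 and a diagnostics dict (slope,
    intercept, separation flag).  A fit that never crosses 50% within the
    tested range yields NaN with a warning.
    """
    import statsmodels.api as sm

    spacings = np.asarray(spacings, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if len(np.unique(spacings)) < 2:
        raise ValueError("need at least 2 distinct pin spacings")

    x = sm.add_constant(spacings)
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(responses, x, family=sm.families.Binomial()).fit()
            intercept, slope = fit.params
        except Exception:
            separated = True
            intercept, slope = np.nan, np.nan
    if not separated and (not np.isfinite(slope) or abs(slope) > 1e3):
        separated = True
    info = {"intercept": intercept, "slope": slope, "separated": separated}

    if separated or slope == 0:
        warnings.warn("degenerate logistic fit; no finite 2PD threshold")
        return float("nan"), info
    threshold = -intercept / slope
    if not (spacings.min() <= threshold <= spacings.max()):
        warnings.warn("fitted 50% point lies outside the tested spacing range")
        return float("nan"), info
    return float(threshold), info


def skin_indentation(
    force_n: float,
    model: SkinModel = SkinModel(),
    amplification: float = 3.0,
    literal: bool = False,
) -> tuple[float, float]:
    """Convert a detection-threshold force (N) to skin indentation (mm).

    Default power-law reading: delta = (F/A)**(1/b) * delta_ref, so F = A
    maps to the reference indentation.  The literal product reading
    (F/A)*(1/b)*delta_ref is available behind ``literal`` but is not
    physically meaningful.  Returns (delta, amplified stimulation amplitude).
    """
    if force_n <= 0:
        raise ValueError("force must be > 0")
    if literal:
        delta = (force_n / model.A) * (1.0 / model.b) * model.delta_ref
    else:
        delta = (force_n / model.A) ** (1.0 / model.b) * model.delta_ref
    return float(delta), float(amplification * delta)


def grip_time_on_target(
    force: np.ndarray,
    target: np.ndarray,
    fs: float = 100.0,
    band_fraction: float = 0.025,
) -> float:
    """Seconds the applied force stays within +-2.5% of the target force."""
    force = np.asarray(force, dtype=float)
    target = np.asarray(target, dtype=float)
    if force.shape != target.shape:
        raise ValueError("force and target traces must have equal length")
    within = np.abs(force - target) <= band_fraction * np.abs(target)
    return float(within.sum() / fs)
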