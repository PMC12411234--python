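"""Synthetic cortical phantoms and observers.

Every generator is a pure function of its spec plus seed (bit-reproducible)
and emits the ground truth alongside the data, so every analysis module can
be exercised closed-loop without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .funcsignal import PhaseEncodedSeries, canonical_hrf
from .laminar import N_DEPTHS, N_RETAINED, DepthProfileField, ThicknessRecord
from .mouse import CalciumTraces
from .psychophys import TrialLog
from .surface import SurfaceMesh

__all__ = [
    "COHORT_PARAMS",
    "PhantomSpec",
    "Septum",
    "PhaseDesign",
    "COHORT1_DESIGN",
    "COHORT2_DESIGN",
    "Psychometric",
    "gen_cortex_phantom",
    "gen_depth_profiles",
    "gen_phase_encoded_bold",
    "simulate_staircase",
    "staircase_convergence_point",
    "simulate_2pd_block",
    "gen_calcium_traces",
]

#: cohort-level generating parameters: thickness means/sd (mm) and qT1
#: plateau means (ms).  The outer qT1 plateau is a free phantom choice.
COHORT_PARAMS = {
    "younger": {
        "total_mm": 2.06,
        "total_sd": 0.07,
        "middle_mm": 0.56,
        "inner_mm": 1.10,
        "qt1_outer": 2000.0,
        "qt1_middle": 1874.4,
        "qt1_inner": 1636.3,
    },
    "older": {
        "total_mm": 1.94,
        "total_sd": 0.08,
        "middle_mm": 0.85,
        "inner_mm": 0.69,
        "qt1_outer": 1950.0,
        "qt1_middle": 1783.2,
        "qt1_inner": 1547.6,
    },
}


@dataclass(frozen=True)
class Septum:
    """Low-myelin septum: a ridge of elevated qT1 at middle depths."""

    y_mm: float  # inferior->superior position on the strip
    amplitude_ms: float = 100.0
    width_mm: float = 1.5  # Gaussian sigma


@dataclass
class PhantomSpec:
    """Specification of a rectangular cortical strip phantom."""

    cohort: str = "younger"
    pitch_mm: float = 0.5  # vertex spacing
    width_mm: float = 20.0  # anterior->posterior extent (x axis)
    length_mm: float = 40.0  # inferior->superior extent (y axis)
    face_fraction: float = 0.3  # inferior strip fraction labeled face
    thickness_sd_mm: float | None = None  # default: cohort table value
    vertex_noise_sd_ms: float = 30.0  # per-vertex, per-depth qT1 noise
    # spatial correlation lengths of the qT1 noise: myelin content drifts
    # slowly along the inferior->superior (path) axis and varies on a finer
    # scale anterior->posterior, decorrelating neighbouring paths
    noise_corr_ap_mm: float = 0.5
    noise_corr_is_mm: float = 8.0
    transition_width: float = 0.7  # plateau transition sigma, depth-index units
    septa: tuple[Septum, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.cohort not in COHORT_PARAMS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.thickness_sd_mm is None:
            self.thickness_sd_mm = COHORT_PARAMS[self.cohort]["total_sd"]

    def spans(self) -> tuple[float, float, float]:
        """Generating (outer, middle, inner) depth-fraction spans."""
        p = COHORT_PARAMS[self.cohort]
        outer = p["total_mm"] - p["middle_mm"] - p["inner_mm"]
        return (
            outer / p["total_mm"],
            p["middle_mm"] / p["total_mm"],
            p["inner_mm"] / p["total_mm"],
        )


@dataclass
class PhantomResult:
    mesh: SurfaceMesh
    profiles: DepthProfileField
    labels: dict[str, int]
    thickness: ThicknessRecord
    truth: dict


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _base_profile(spec: PhantomSpec) -> tuple[np.ndarray, float, float]:
    """Noise-free 21-depth qT1 profile with plateau transitions centered at
    the generating boundary fractions (on the retained 19-depth grid)."""
    p = COHORT_PARAMS[spec.cohort]
    s_outer, s_middle, _ = spec.spans()
    c1 = (s_outer) * (N_RETAINED - 1)
    c2 = (s_outer + s_middle) * (N_RETAINED - 1)
    i = np.arange(N_DEPTHS, dtype=float)
    w = spec.transition_width
    prof = (
        p["qt1_outer"]
        + (p["qt1_middle"] - p["qt1_outer"]) * _sigmoid((i - c1) / w)
        + (p["qt1_inner"] - p["qt1_middle"]) * _sigmoid((i - c2) / w)
    )
    return prof, s_outer, s_outer + s_middle


def gen_depth_profiles(
    spec: PhantomSpec, n_vertices: int, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    """(n_vertices x 21) noisy qT1 profiles plus generating ground truth."""
    base, b1f, b2f = _base_profile(spec)
    noise = rng.normal(0.0, spec.vertex_noise_sd_ms, size=(n_vertices, N_DEPTHS))
    truth = {"b1_frac": b1f, "b2_frac": b2f, "base_profile": base}
    return base[None, :] + noise, truth


def gen_laminar_cohort(
    cohort: str,
    n_subjects: int,
    seed: int = 0,
    thickness_sd_mm: float = 0.05,
    n_vertices: int = 50,
    vertex_noise_sd_ms: float = 30.0,
) -> dict:
    """Lightweight per-subject laminar data for closed-loop recovery tests.

    Each subject contributes a vertex-averaged 21-depth qT1 profile and a
    total thickness drawn around the cohort mean.  Returns the per-subject
    profiles, totals and the generating ground truth (spans, boundaries).
    """
    spec = PhantomSpec(
        cohort=cohort,
        thickness_sd_mm=thickness_sd_mm,
        vertex_noise_sd_ms=vertex_noise_sd_ms,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    p = COHORT_PARAMS[cohort]
    profiles, totals = [], []
    truth = None
    for _ in range(n_subjects):
        profs, truth = gen_depth_profiles(spec, n_vertices, rng)
        profiles.append(profs.mean(axis=0))
        totals.append(rng.normal(p["total_mm"], thickness_sd_mm))
    s_outer, s_middle, s_inner = spec.spans()
    truth = dict(truth)
    truth.update(
        {
            "spans": (s_outer, s_middle, s_inner),
            "total_mean_mm": p["total_mm"],
            "outer_mean_mm": p["total_mm"] * s_outer,
            "middle_mean_mm": p["middle_mm"],
            "inner_mean_mm": p["inner_mm"],
        }
    )
    return {
        "profiles": np.asarray(profiles),
        "totals": np.asarray(totals),
        "truth": truth,
    }


def _strip_mesh(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, int, int]:
    nx = int(round(spec.width_mm / spec.pitch_mm)) + 1
    ny = int(round(spec.length_mm / spec.pitch_mm)) + 1
    gx, gy = np.meshgrid(
        np.arange(nx) * spec.pitch_mm, np.arange(ny) * spec.pitch_mm, indexing="ij"
    )
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(nx * ny)])
    tris = []
    for ix in range(nx - 1):
        for iy in range(ny - 1):
            a = ix * ny + iy
            b = (ix + 1) * ny + iy
            tris.append([a, b, a + 1])
            tris.append([b, b + 1, a + 1])
    return verts, np.asarray(tris, dtype=np.intp), nx, ny


#: label codes used on phantom strips
LABELS = {
    "face": 1, "thumb": 2, "index": 3, "middle_finger": 4, "ring": 5, "little": 6,
}


def _smooth_field(rng, n, scale=0.1):
    x = rng.normal(0, 1, n)
    # crude spatial smoothing by a moving average in index order
    k = np.ones(25) / 25
    return scale * np.convolve(x, k, mode="same")


def gen_cortex_phantom(spec: PhantomSpec) -> PhantomResult:
    """Rectangular cortical strip with labels, depth profiles and overlays.

    Overlays: ``label``, ``qt1_mid`` (mean qT1 over middle-compartment
    depths, the signal used for border detection), plus smooth synthetic
    ``ecm``/``qsm``/``nqsm``/``pqsm``/``aqsm`` fields for featurization.
    Septa are injected as Gaussian ridges of elevated qT1 across the middle
    depths; their positions are recorded in the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    verts, tris, nx, ny = _strip_mesh(spec)
    n = len(verts)
    y = verts[:, 1]

    for s in spec.septa:
        if not (0 <= s.y_mm <= spec.length_mm):
            raise ValueError(f"septum at y={s.y_mm} mm lies outside the mesh")

    profiles, truth = gen_depth_profiles(spec, n, rng)
    if spec.noise_corr_ap_mm > 0 or spec.noise_corr_is_mm > 0:
        # replace iid vertex noise by a spatially smooth field (same sd):
        # qT1 noise on real surfaces is correlated, not white
        from scipy.ndimage import gaussian_filter

        base = truth["base_profile"]
        noise = (profiles - base[None, :]).reshape(nx, ny, N_DEPTHS)
        sig = (
            spec.noise_corr_ap_mm / spec.pitch_mm,
            spec.noise_corr_is_mm / spec.pitch_mm,
            0,
        )
        noise = gaussian_filter(noise, sigma=sig, mode="nearest")
        sd = noise.std()
        if sd > 0:
            noise *= spec.vertex_noise_sd_ms / sd
        profiles = base[None, :] + noise.reshape(n, N_DEPTHS)
    b1f, b2f = truth["b1_frac"], truth["b2_frac"]
    b1 = int(round(b1f * (N_RETAINED - 1)))
    b2 = int(round(b2f * (N_RETAINED - 1)))
    middle_idx = np.arange(b1, b2 + 1)

    septum_field = np.zeros(n)
    for s in spec.septa:
        septum_field += s.amplitude_ms * np.exp(
            -0.5 * ((y - s.y_mm) / s.width_mm) ** 2
        )
    profiles[:, middle_idx] += septum_field[:, None]

    # labels: inferior face band, then five equal finger bands
    labels = np.zeros(n, dtype=float)
    face_end = spec.face_fraction * spec.length_mm
    labels[y < face_end] = LABELS["face"]
    finger_names = ["thumb", "index", "middle_finger", "ring", "little"]
    band = (spec.length_mm - face_end) / len(finger_names)
    for k, name in enumerate(finger_names):
        lo = face_end + k * band
        sel = (y >= lo) & (y < lo + band if k < 4 else y <= spec.length_mm)
        labels[sel] = LABELS[name]

    qt1_mid = profiles[:, middle_idx].mean(axis=1)
    overlays = {
        "label": labels,
        "qt1_mid": qt1_mid,
        "ecm": np.abs(_smooth_field(rng, n, 0.1)) + 0.1,
        "qsm": _smooth_field(rng, n, 0.01),
        "nqsm": -np.abs(_smooth_field(rng, n, 0.01)),
        "pqsm": np.abs(_smooth_field(rng, n, 0.01)),
        "aqsm": np.abs(_smooth_field(rng, n, 0.012)),
    }
    mesh = SurfaceMesh(verts, tris, overlays)

    p = COHORT_PARAMS[spec.cohort]
    total = float(rng.normal(p["total_mm"], spec.thickness_sd_mm))
    s_outer, s_middle, s_inner = spec.spans()
    thickness = ThicknessRecord(
        total, total * s_outer, total * s_middle, total * s_inner
    )
    truth.update(
        {
            "septa_y_mm": [s.y_mm for s in spec.septa],
            "septum_amplitude_ms": [s.amplitude_ms for s in spec.septa],
            "path_noise_sd_ms": spec.vertex_noise_sd_ms / np.sqrt(len(middle_idx)),
            "total_thickness_mm": total,
            "spans": (s_outer, s_middle, s_inner),
            "face_end_mm": face_end,
            "seed": spec.seed,
            "grid_shape": (nx, ny),
        }
    )
    return PhantomResult(
        mesh, DepthProfileField(profiles), dict(LABELS), thickness, truth
    )


# ---------------------------------------------------------------------------
# phase-encoded BOLD
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseDesign:
    """Arithmetic of one phase-encoded run."""

    tr: float
    n_cycles: int
    cycle_s: float
    n_positions: int
    rest_pre_s: float = 0.0
    rest_post_s: float = 0.0

    def __post_init__(self):
        from .errors import DesignError

        total = self.n_cycles * self.cycle_s + self.rest_pre_s + self.rest_post_s
        if abs(total / self.tr - round(total / self.tr)) > 1e-9:
            raise DesignError(
                f"run duration {total}s is not a whole number of TRs ({self.tr}s)"
            )

    @property
    def n_volumes(self) -> int:
        total = self.n_cycles * self.cycle_s + self.rest_pre_s + self.rest_post_s
        return int(round(total / self.tr))


#: five-finger localizer: 20 cycles, five fingertips x 5.12 s, TR 2 s
COHORT1_DESIGN = PhaseDesign(tr=2.0, n_cycles=20, cycle_s=25.6, n_positions=5)

#: two-finger response profile: eight 32 s cycles + 32 s rest before/after
COHORT2_DESIGN = PhaseDesign(
    tr=2.0, n_cycles=8, cycle_s=32.0, n_positions=4, rest_pre_s=32.0,
    rest_post_s=32.0,
)


def _depth_gain(middle_center_frac: float, peak_gain: float) -> np.ndarray:
    frac = np.arange(N_DEPTHS) / (N_DEPTHS - 1)
    return 1.0 + (peak_gain - 1.0) * np.exp(
        -0.5 * ((frac - middle_center_frac) / 0.12) ** 2
    )


def _ar1(rng, shape, sd, rho=0.4):
    eps = rng.normal(0, sd, size=shape)
    out = np.empty_like(eps)
    out[..., 0] = eps[..., 0]
    for t in range(1, shape[-1]):
        out[..., t] = rho * out[..., t - 1] + eps[..., t]
    return out


def gen_phase_encoded_bold(
    design: PhaseDesign,
    cohort: str = "younger",
    preferred_position: int = 0,
    depth_peak_gain: float | None = None,
    middle_center_frac: float = 0.35,
    noise_sd: float = 0.0,
    ar_rho: float = 0.4,
    brightness: float = 100.0,
    response_amplitude: float = 2.0,
    seed: int = 0,
) -> dict:
    """Forward/reverse phase-encoded runs + rest run for one depth column.

    Rows of each series are the 21 cortical depths of a single surface
    location tuned to ``preferred_position``.  The traveling-wave drive is a
    per-cycle boxcar over stimulus positions convolved with the canonical
    HRF, scaled by a depth gain peaking at the middle compartment (stronger
    for the older cohort), on top of a brightness offset with additive AR(1)
    noise.  Returns forward, reverse and rest series plus the ground truth.
    """
    rng = np.random.default_rng(seed)
    if depth_peak_gain is None:
        depth_peak_gain = 2.0 if cohort == "younger" else 2.6
    n_stim_vols = int(round(design.n_cycles * design.cycle_s / design.tr))

    def drive_for(order: np.ndarray) -> np.ndarray:
        # per-volume active stimulus position (cycle need not align to TR)
        t = (np.arange(n_stim_vols) + 0.5) * design.tr
        phase = (t % design.cycle_s) / design.cycle_s
        slot = np.minimum(
            (phase * design.n_positions).astype(int), design.n_positions - 1
        )
        stim = (np.asarray(order)[slot] == preferred_position).astype(float)
        hrf = canonical_hrf(design.tr)
        resp = np.convolve(stim, hrf)[: len(stim)]
        pre = np.zeros(int(round(design.rest_pre_s / design.tr)))
        post = np.zeros(int(round(design.rest_post_s / design.tr)))
        return np.concatenate([pre, resp, post])

    forward_order = np.arange(design.n_positions)
    gains = _depth_gain(middle_center_frac, depth_peak_gain)

    def build(drive: np.ndarray, direction: str) -> PhaseEncodedSeries:
        clean = brightness + response_amplitude * gains[:, None] * drive[None, :]
        noisy = clean + (
            _ar1(rng, clean.shape, noise_sd, ar_rho) if noise_sd > 0 else 0.0
        )
        return PhaseEncodedSeries(
            noisy,
            tr=design.tr,
            n_cycles=design.n_cycles,
            cycle_length=design.cycle_s,
            direction=direction,
            mean_brightness=brightness,
            rest_pre_s=design.rest_pre_s,
            rest_post_s=design.rest_post_s,
        )

    forward = build(drive_for(forward_order), "forward")
    reverse = build(drive_for(forward_order[::-1]), "reverse")
    rest_samples = brightness + (
        _ar1(rng, (N_DEPTHS, design.n_volumes), noise_sd, ar_rho)
        if noise_sd > 0
        else np.zeros((N_DEPTHS, design.n_volumes))
    )
    rest = PhaseEncodedSeries(
        rest_samples,
        tr=design.tr,
        n_cycles=design.n_cycles,
        cycle_length=design.cycle_s,
        direction="forward",
        mean_brightness=brightness,
        rest_pre_s=design.rest_pre_s,
        rest_post_s=design.rest_post_s,
    )
    truth = {
        "depth_gain": gains,
        "preferred_position": preferred_position,
        "n_volumes": design.n_volumes,
        "seed": seed,
    }
    return {"forward": forward, "reverse": reverse, "rest": rest, "truth": truth}


# ---------------------------------------------------------------------------
# behavioral observers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Psychometric:
    """Logistic observer with guess and lapse rates."""

    threshold: float
    slope: float
    guess: float = 0.5
    lapse: float = 0.0

    def p_correct(self, x: np.ndarray | float) -> np.ndarray | float:
        from scipy.special import expit

        core = expit(self.slope * (np.asarray(x, float) - self.threshold))
        return self.guess + (1.0 - self.guess - self.lapse) * core


def staircase_convergence_point(obs: Psychometric, target: float = 0.794) -> float:
    """Intensity at which the observer is correct with the 3-down/1-up
    convergence probability (0.5^(1/3) ~ 79.4%)."""
    from scipy.optimize import brentq

    lo = obs.threshold - 50.0 / max(obs.slope, 1e-9)
    hi = obs.threshold + 50.0 / max(obs.slope, 1e-9)
    if obs.p_correct(lo) > target or obs.p_correct(hi) < target:
        raise ValueError("target probability unreachable for this observer")
    return float(brentq(lambda x: obs.p_correct(x) - target, lo, hi))


def simulate_staircase(
    obs: Psychometric,
    ladder: np.ndarray,
    start_indices: tuple[int, int],
    seed: int = 0,
    max_trials: int = 100,
    stop_window: int = 30,
) -> TrialLog:
    """Simulate a session of two interleaved 3-down/1-up staircases.

    ``ladder`` is the ascending intensity ladder (task units); the two
    staircases start at ``start_indices`` and are interleaved in an order
    randomized per session.  The session stops when the intensity sd over
    the last ``stop_window`` trials is at most one (median) ladder step, or
    at ``max_trials``.
    """
    rng = np.random.default_rng(seed)
    ladder = np.asarray(ladder, dtype=float)
    step = float(np.median(np.diff(ladder)))
    levels = list(start_indices)
    streak = [0, 0]
    intensities, responses, which = [], [], []
    while len(intensities) < max_trials:
        sc = int(rng.integers(0, 2))
        x = ladder[levels[sc]]
        correct = rng.random() < obs.p_correct(x)
        intensities.append(x)
        responses.append(int(correct))
        which.append(sc)
        if correct:
            streak[sc] += 1
            if streak[sc] == 3:
                levels[sc] = max(0, levels[sc] - 1)
                streak[sc] = 0
        else:
            levels[sc] = min(len(ladder) - 1, levels[sc] + 1)
            streak[sc] = 0
        if len(intensities) >= stop_window:
            if np.std(intensities[-stop_window:]) <= step:
                break
    return TrialLog(
        np.asarray(intensities),
        np.asarray(responses),
        np.asarray(which),
        extras={"ladder": ladder, "seed": seed},
    )


def simulate_2pd_block(
    obs: Psychometric,
    spacings: np.ndarray,
    n_reps: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate 'two pins' responses over a spacing ladder.

    The observer's psychometric gives P('two pins'); guess should be set to
    the false-alarm tendency (e.g. 0.05) and 1-lapse to the asymptote.
    """
    rng = np.random.default_rng(seed)
    x = np.repeat(np.asarray(spacings, dtype=float), n_reps)
    p = obs.p_correct(x)
    return x, (rng.random(len(x)) < p).astype(int)


# ---------------------------------------------------------------------------
# calcium traces
# ---------------------------------------------------------------------------


def _indicator_kernel(fs: float, rise_s: float = 0.05, decay_s: float = 0.4):
    t = np.arange(0, 2.0, 1.0 / fs)
    k = (1 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    return k / k.max()


def gen_calcium_traces(
    n_neurons: int = 50,
    duration_s: float = 600.0,
    fs: float = 30.0,
    baseline: float = 100.0,
    noise_frac: float = 0.1,
    spontaneous_rate_hz: float = 0.05,
    single_amplitude: float = 0.5,
    double_ratio_additive: float = 1.5,
    double_ratio_reduced: float = 0.5,
    mixture: tuple[float, float, float] = (0.6, 0.2, 0.2),
    isi_range_s: tuple[float, float] = (6.0, 20.0),
    seed: int = 0,
) -> tuple[CalciumTraces, np.ndarray, dict]:
    """GCaMP-like traces with double/single stimulation conditions.

    ``mixture`` gives the (additive, reduced, unchanged) neuron proportions;
    additive neurons respond to double stimulation with
    ``double_ratio_additive`` x their single response, and so on.  Also
    returns a synchronized synthetic whisker-pad speed trace with movement
    bouts and the ground-truth class per neuron.
    """
    rng = np.random.default_rng(seed)
    n_t = int(round(duration_s * fs))
    t_axis = np.arange(n_t) / fs

    # interleaved condition onsets at randomized ISIs
    onsets = {"double": [], "single": []}
    t, flip = 5.0, 0
    while t < duration_s - 3.0:
        onsets["double" if flip == 0 else "single"].append(t)
        flip ^= 1
        t += rng.uniform(*isi_range_s)
    onsets = {k: np.asarray(v) for k, v in onsets.items()}

    classes = rng.choice(
        ["additive", "reduced", "unchanged"], size=n_neurons, p=mixture
    )
    ratio = {
        "additive": double_ratio_additive,
        "reduced": double_ratio_reduced,
        "unchanged": 1.0,
    }
    kernel = _indicator_kernel(fs)
    f = np.empty((n_neurons, n_t))
    for i in range(n_neurons):
        events = np.zeros(n_t)
        n_spont = rng.poisson(spontaneous_rate_hz * duration_s)
        for ts in rng.uniform(0, duration_s, n_spont):
            events[int(ts * fs) % n_t] += rng.uniform(0.2, 0.6)
        for cond, amp in (
            ("single", single_amplitude),
            ("double", single_amplitude * ratio[classes[i]]),
        ):
            for ts in onsets[cond]:
                k = int(ts * fs)
                if k < n_t:
                    events[k] += amp * rng.uniform(0.8, 1.2)
        signal = np.convolve(events, kernel)[:n_t]
        f[i] = baseline * (1.0 + signal) + rng.normal(
            0, noise_frac * baseline, n_t
        )

    # whisker-pad speed: resting noise plus movement bouts
    speed = np.abs(rng.normal(0.0, 0.05, n_t))
    n_bouts = max(1, int(duration_s / 60))
    bout_starts = rng.uniform(0, duration_s - 5, n_bouts)
    for bs in bout_starts:
        a, b = int(bs * fs), int((bs + rng.uniform(1, 3)) * fs)
        speed[a:b] += rng.uniform(0.6, 1.5)

    traces = CalciumTraces(f, fs=fs, onsets=onsets)
    truth = {
        "classes": classes,
        "onsets": onsets,
        "bout_starts_s": bout_starts,
        "seed": seed,
    }
    return traces, speed, truth
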