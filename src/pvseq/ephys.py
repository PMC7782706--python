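"""Intrinsic electrophysiology feature extraction from patch-clamp sweeps.

Ten canonical parameters are computed per cell: three passive (input
resistance, series resistance, capacitance, from a small voltage-clamp test
step) and seven active (firing threshold, dF/dI slope, spike-train
attenuation, sag, and AP amplitude / half-width / symmetry, from a family of
1.5 s current-clamp steps).  Base width and trough amplitude are emitted as
auxiliary columns.

Unit conventions: time in ms, voltage in mV, current in pA, resistance in
MOhm, capacitance in pF.  Note mV / MOhm = nA, hence the factor 1000 when
currents are expressed in pA.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

logger = logging.getLogger(__name__)

LN4 = math.log(4.0)


@dataclass
class VoltageClampStep:
    """A voltage-clamp test step and the recorded current transient."""

    delta_mv: float
    onset_ms: float
    offset_ms: float
    time_ms: np.ndarray
    current_pa: np.ndarray


@dataclass
class CurrentClampStep:
    """A square current injection and the recorded membrane voltage."""

    i_inj_pa: float
    onset_ms: float
    offset_ms: float
    time_ms: np.ndarray
    voltage_mv: np.ndarray

    @property
    def duration_s(self) -> float:
        return (self.offset_ms - self.onset_ms) / 1000.0


@dataclass
class SweepSet:
    """All clamp recordings for one cell, with protocol timing."""

    sampling_rate_hz: float
    vc_step: VoltageClampStep | None = None
    cc_steps: list[CurrentClampStep] = field(default_factory=list)

    def __post_init__(self):
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        self.cc_steps = sorted(self.cc_steps, key=lambda s: s.i_inj_pa)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz


FEATURE_NAMES = (
    "input_resistance_mohm",
    "series_resistance_mohm",
    "capacitance_pf",
    "firing_threshold_pa",
    "df_di_hz_per_pa",
    "attenuation_ratio",
    "sag_mv",
    "ap_amplitude_mv",
    "ap_half_width_ms",
    "ap_symmetry",
)

AUX_NAMES = ("ap_base_width_ms", "ap_trough_mv")


@dataclass
class EphysFeatures:
    """The ten named intrinsic parameters (NaN where undefined) + auxiliaries."""

    input_resistance_mohm: float = math.nan
    series_resistance_mohm: float = math.nan
    capacitance_pf: float = math.nan
    firing_threshold_pa: float = math.nan
    df_di_hz_per_pa: float = math.nan
    attenuation_ratio: float = math.nan
    sag_mv: float = math.nan
    ap_amplitude_mv: float = math.nan
    ap_half_width_ms: float = math.nan
    ap_symmetry: float = math.nan
    ap_base_width_ms: float = math.nan
    ap_trough_mv: float = math.nan
    flags: dict = field(default_factory=dict)

    def as_dict(self, include_aux: bool = True) -> dict[str, float]:
        out = {name: getattr(self, name) for name in FEATURE_NAMES}
        if include_aux:
            out.update({name: getattr(self, name) for name in AUX_NAMES})
        return out


# ---------------------------------------------------------------- passive

def _vc_baseline(step: VoltageClampStep) -> float:
    pre = step.time_ms < step.onset_ms
    if not pre.any():
        return 0.0
    return float(np.median(step.current_pa[pre]))


def _vc_steady_state(step: VoltageClampStep, steady_fraction: float = 0.2) -> float:
    """Baseline-subtracted current over the last ``steady_fraction`` of the step."""
    t0 = step.offset_ms - steady_fraction * (step.offset_ms - step.onset_ms)
    window = (step.time_ms >= t0) & (step.time_ms < step.offset_ms)
    return float(np.mean(step.current_pa[window])) - _vc_baseline(step)


def series_resistance(sweeps: SweepSet, peak_window_ms: float = 5.0) -> float:
    """R_s = dV / I_peak, from the initial maximum of the current transient.

    The peak is the extreme baseline-subtracted current within the first
    ``peak_window_ms`` after step onset.
    """
    step = sweeps.vc_step
    if step is None:
        return math.nan
    window = (step.time_ms >= step.onset_ms) & (step.time_ms <= step.onset_ms + peak_window_ms)
    trace = step.current_pa[window] - _vc_baseline(step)
    i_peak = trace[np.argmax(np.abs(trace))]
    if i_peak == 0:
        return math.nan
    return step.delta_mv / i_peak * 1000.0


def input_resistance(sweeps: SweepSet, steady_fraction: float = 0.2) -> float:
    """R_in from the steady-state current, with the series resistance partitioned out.

    The steady-state current through the pipette sees R_s and R_in in series
    (I_ss = dV / (R_s + R_in)), so the membrane input resistance is the total
    steady-state resistance minus R_s.
    """
    step = sweeps.vc_step
    if step is None:
        return math.nan
    i_ss = _vc_steady_state(step, steady_fraction)
    if abs(i_ss) < 1e-9:
        logger.warning("input_resistance: steady-state current below noise floor")
        return math.nan
    r_total = step.delta_mv / i_ss * 1000.0
    r_s = series_resistance(sweeps)
    if math.isnan(r_s):
        return r_total
    return r_total - r_s


def capacitance(
    sweeps: SweepSet,
    steady_fraction: float = 0.2,
    correct_for_series: bool = True,
) -> float:
    """Membrane capacitance from the charge of the voltage-clamp transient.

    Q = integral of (I(t) - I_ss) over the step; the raw estimate is
    C_raw = Q / dV.  Because the command step divides across R_s and the
    membrane, only dV * R_in / (R_s + R_in) appears across the capacitor and
    the transient current is likewise attenuated, so C_raw underestimates C
    by (R_in / (R_s + R_in))^2.  With ``correct_for_series`` (default) the
    estimate is rescaled by the measured resistances.
    """
    step = sweeps.vc_step
    if step is None:
        return math.nan
    in_step = (step.time_ms >= step.onset_ms) & (step.time_ms < step.offset_ms)
    i_ss = _vc_steady_state(step, steady_fraction)
    trans = step.current_pa[in_step] - _vc_baseline(step) - i_ss
    q_pa_ms = float(np.trapezoid(trans, step.time_ms[in_step]))  # pA*ms = fC
    c_raw = q_pa_ms / step.delta_mv  # fC / mV = pF
    if c_raw < 0:
        logger.warning("capacitance: negative charge integral, flagged")
        return math.nan
    if correct_for_series:
        r_s = series_resistance(sweeps)
        r_in = input_resistance(sweeps, steady_fraction)
        if r_s > 0 and r_in > 0:
            c_raw *= ((r_s + r_in) / r_in) ** 2
    return c_raw


# ---------------------------------------------------------------- spikes

def detect_aps(
    time_ms: np.ndarray,
    voltage_mv: np.ndarray,
    dvdt_threshold: float = 20.0,
    refractory_ms: float = 1.0,
) -> dict:
    """Detect action potentials by a dV/dt threshold crossing.

    An AP onset is where dV/dt first exceeds ``dvdt_threshold`` (V/s, i.e.
    mV/ms) after at least ``refractory_ms`` since the previous onset.  For
    each AP the peak (max V before the next onset) and the trough (min V
    after the peak, before the next onset) are recorded.

    Returns a dict with ``onset_idx``, ``onset_t``, ``peak_idx``, ``peak_v``,
    ``trough_idx``, ``trough_v`` arrays (empty when no spikes).
    """
    empty = {k: np.array([]) for k in
             ("onset_idx", "onset_t", "peak_idx", "peak_v", "trough_idx", "trough_v")}
    if len(voltage_mv) < 3:
        return empty
    dt = float(np.median(np.diff(time_ms)))
    dvdt = np.gradient(voltage_mv, dt)
    above = dvdt >= dvdt_threshold
    crossings = np.flatnonzero(above & ~np.roll(above, 1))
    crossings = crossings[crossings > 0]
    onsets = []
    last = -math.inf
    for idx in crossings:
        if time_ms[idx] - last >= refractory_ms:
            onsets.append(idx)
            last = time_ms[idx]
    if not onsets:
        return empty
    onsets = np.asarray(onsets)
    bounds = np.append(onsets[1:], len(voltage_mv))
    peak_idx, peak_v, trough_idx, trough_v = [], [], [], []
    for start, end in zip(onsets, bounds):
        seg = voltage_mv[start:end]
        p = start + int(np.argmax(seg))
        peak_idx.append(p)
        peak_v.append(voltage_mv[p])
        after = voltage_mv[p:end]
        t = p + int(np.argmin(after))
        trough_idx.append(t)
        trough_v.append(voltage_mv[t])
    return {
        "onset_idx": onsets,
        "onset_t": time_ms[onsets],
        "peak_idx": np.asarray(peak_idx),
        "peak_v": np.asarray(peak_v),
        "trough_idx": np.asarray(trough_idx),
        "trough_v": np.asarray(trough_v),
    }


@dataclass
class FICurve:
    """Firing frequency (Hz) as a function of injected current (pA)."""

    currents_pa: np.ndarray
    frequencies_hz: np.ndarray

    def __post_init__(self):
        self.currents_pa = np.asarray(self.currents_pa, dtype=float)
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        if not np.all(np.diff(self.currents_pa) > 0):
            raise ValueError("FICurve currents must be strictly increasing")
        if (self.frequencies_hz < 0).any():
            raise ValueError("FICurve frequencies must be >= 0")


def fi_curve(sweeps: SweepSet, dvdt_threshold: float = 20.0) -> FICurve:
    """Build the F-I curve from the current-clamp family (spike count / duration)."""
    currents, freqs = [], []
    for step in sweeps.cc_steps:
        in_step = (step.time_ms >= step.onset_ms) & (step.time_ms < step.offset_ms)
        aps = detect_aps(step.time_ms[in_step], step.voltage_mv[in_step], dvdt_threshold)
        currents.append(step.i_inj_pa)
        freqs.append(len(aps["onset_idx"]) / step.duration_s)
    return FICurve(np.asarray(currents), np.asarray(freqs))


def _logistic(i, fmax, i0, s):
    return fmax / (1.0 + np.exp(-(i - i0) / s))


def fit_logistic_fi(fi: FICurve) -> tuple[float, float, float]:
    """Least-squares fit of F(I) = Fmax / (1 + exp(-(I - I0)/s)).

    Initialized from data quantiles; bounded so Fmax and s stay positive.
    """
    i, f = fi.currents_pa, fi.frequencies_hz
    if np.count_nonzero(f) < 1 or len(i) < 4:
        raise ValueError("need >= 4 points with at least one nonzero frequency")
    fmax0 = max(f.max(), 1.0)
    half = fmax0 / 2.0
    i0_0 = float(i[np.argmin(np.abs(f - half))])
    span = max(i.max() - i.min(), 1.0)
    p0 = (fmax0, i0_0, span / 10.0)
    bounds = ([1e-6, i.min() - 10 * span, 1e-6], [10 * fmax0, i.max() + 10 * span, 10 * span])
    popt, _ = curve_fit(_logistic, i, f, p0=p0, bounds=bounds, maxfev=20000)
    return tuple(float(v) for v in popt)


def chord_threshold(fmax: float, i0: float, s: float) -> float:
    """X-intercept of the chord through the 20% and 80% points of the sigmoid.

    The crossings are found numerically on the fitted curve; for a symmetric
    logistic this equals I0 - (5/3) ln(4) s in closed form.
    """
    def crossing(level: float) -> float:
        f = lambda i: _logistic(i, fmax, i0, s) - level * fmax
        lo, hi = i0 - 50 * s, i0 + 50 * s
        return brentq(f, lo, hi)

    i20, i80 = crossing(0.2), crossing(0.8)
    slope = (0.8 * fmax - 0.2 * fmax) / (i80 - i20)
    return i20 - 0.2 * fmax / slope


def firing_threshold(fi: FICurve) -> float:
    """Firing threshold (pA) via the logistic fit and its 20-80% chord."""
    try:
        fmax, i0, s = fit_logistic_fi(fi)
    except (ValueError, RuntimeError) as exc:
        logger.warning("firing_threshold: %s", exc)
        return math.nan
    return chord_threshold(fmax, i0, s)


def df_di(fi: FICurve, window_start_pa: float = 50.0, window_len_pa: float = 250.0) -> float:
    """OLS slope of F over [I_first_spiking + 50, I_first_spiking + 300] pA."""
    spiking = fi.currents_pa[fi.frequencies_hz > 0]
    if len(spiking) == 0:
        return math.nan
    lo = spiking[0] + window_start_pa
    hi = lo + window_len_pa
    mask = (fi.currents_pa >= lo) & (fi.currents_pa <= hi)
    if mask.sum() < 2:
        logger.warning("df_di: fewer than 2 F-I points in [%g, %g] pA", lo, hi)
        return math.nan
    return float(np.polyfit(fi.currents_pa[mask], fi.frequencies_hz[mask], 1)[0])


def attenuation(sweeps: SweepSet, dvdt_threshold: float = 20.0) -> float:
    """First/last AP amplitude ratio on the maximal current step (>1 = decline).

    Amplitude = peak voltage minus the voltage at the dV/dt threshold
    crossing of that AP.
    """
    if not sweeps.cc_steps:
        return math.nan
    step = sweeps.cc_steps[-1]
    aps = detect_aps(step.time_ms, step.voltage_mv, dvdt_threshold)
    if len(aps["onset_idx"]) < 2:
        return math.nan
    amp = aps["peak_v"] - step.voltage_mv[aps["onset_idx"]]
    return float(amp[0] / amp[-1])


def sag(
    sweeps: SweepSet,
    i_sag_pa: float = -150.0,
    min_window_ms: tuple[float, float] = (750.0, 1000.0),
    steady_window_ms: tuple[float, float] = (1500.0, 2250.0),
) -> float:
    """Sag amplitude on the -150 pA step.

    sag = median V over the steady window minus the minimum V over the early
    window; window times are relative to step onset and config-overridable.
    """
    step = next((s for s in sweeps.cc_steps if s.i_inj_pa == i_sag_pa), None)
    if step is None:
        return math.nan
    t = step.time_ms - step.onset_ms
    early = (t >= min_window_ms[0]) & (t <= min_window_ms[1])
    late = (t >= steady_window_ms[0]) & (t <= steady_window_ms[1])
    if not early.any() or not late.any():
        logger.warning("sag: measurement windows fall outside the recorded step")
        return math.nan
    return float(np.median(step.voltage_mv[late]) - np.min(step.voltage_mv[early]))


def _interp_crossing(t: np.ndarray, v: np.ndarray, level: float, rising: bool) -> float:
    """Linearly interpolated time at which v crosses level."""
    if rising:
        idx = np.flatnonzero((v[:-1] < level) & (v[1:] >= level))
    else:
        idx = np.flatnonzero((v[:-1] >= level) & (v[1:] < level))
    if len(idx) == 0:
        return math.nan
    i = idx[0] if rising else idx[-1]
    frac = (level - v[i]) / (v[i + 1] - v[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def ap_shape(
    sweeps: SweepSet,
    dvdt_threshold: float = 20.0,
    min_aps: int = 3,
    pre_ms: float = 2.0,
    post_ms: float = 4.0,
    amplitude_mode: str = "peak_to_trough",
) -> dict[str, float]:
    """Average AP waveform metrics from the first trace with >= 3 APs.

    All APs of the chosen trace are aligned on their peak sample and
    averaged.  Linear segments are fit to (i) the pre-AP baseline, (ii) the
    20-80% rising phase, and (iii) the 80-20% falling phase of the averaged
    waveform.  Reported metrics:

    * ``ap_amplitude_mv`` — peak minus trough (or peak minus baseline with
      ``amplitude_mode="peak_to_baseline"``)
    * ``ap_half_width_ms`` — width at half of (peak - baseline)
    * ``ap_base_width_ms`` — width at the baseline level
    * ``ap_symmetry`` — (t_peak - t_rise20) / (t_fall20 - t_rise20)
    * ``ap_trough_mv`` — trough minus baseline (negative = after-hyperpolarizing)
    """
    nan = {k: math.nan for k in
           ("ap_amplitude_mv", "ap_half_width_ms", "ap_base_width_ms",
            "ap_symmetry", "ap_trough_mv")}
    chosen = None
    for step in sweeps.cc_steps:
        aps = detect_aps(step.time_ms, step.voltage_mv, dvdt_threshold)
        if len(aps["onset_idx"]) >= min_aps:
            chosen = (step, aps)
            break
    if chosen is None:
        logger.warning("ap_shape: no trace with >= %d APs; excluded", min_aps)
        return nan
    step, aps = chosen
    dt = step.time_ms[1] - step.time_ms[0]
    w_pre = int(round(pre_ms / dt))
    w_post = int(round(post_ms / dt))
    segments = []
    for p in aps["peak_idx"]:
        if p - w_pre < 0 or p + w_post >= len(step.voltage_mv):
            continue
        segments.append(step.voltage_mv[p - w_pre: p + w_post + 1])
    if len(segments) < min_aps:
        return nan
    avg = np.mean(segments, axis=0)
    t = (np.arange(len(avg)) - w_pre) * dt  # peak at t = 0

    base_n = max(int(round(0.5 / dt)), 1)  # first 0.5 ms of the window
    baseline = float(np.polyval(np.polyfit(t[:base_n], avg[:base_n], 1), t[base_n - 1]))
    peak_i = int(np.argmax(avg))
    peak = float(avg[peak_i])
    trough = float(np.min(avg[peak_i:]))
    amp_bp = peak - baseline
    if amp_bp <= 0:
        return nan

    rise_t, rise_v = t[: peak_i + 1], avg[: peak_i + 1]
    fall_t, fall_v = t[peak_i:], avg[peak_i:]
    t_rise20 = _interp_crossing(rise_t, rise_v, baseline + 0.2 * amp_bp, rising=True)
    t_fall20 = _interp_crossing(fall_t, fall_v, baseline + 0.2 * amp_bp, rising=False)
    t_half_up = _interp_crossing(rise_t, rise_v, baseline + 0.5 * amp_bp, rising=True)
    t_half_down = _interp_crossing(fall_t, fall_v, baseline + 0.5 * amp_bp, rising=False)
    t_base_up = _interp_crossing(rise_t, rise_v, baseline, rising=True)
    t_base_down = _interp_crossing(fall_t, fall_v, baseline, rising=False)

    symmetry = math.nan
    if not (math.isnan(t_rise20) or math.isnan(t_fall20)) and t_fall20 > t_rise20:
        symmetry = (0.0 - t_rise20) / (t_fall20 - t_rise20)
    amplitude = peak - trough if amplitude_mode == "peak_to_trough" else amp_bp
    return {
        "ap_amplitude_mv": amplitude,
        "ap_half_width_ms": t_half_down - t_half_up,
        "ap_base_width_ms": t_base_down - t_base_up,
        "ap_symmetry": symmetry,
        "ap_trough_mv": trough - baseline,
    }


# ---------------------------------------------------------------- compose

def extract_features(sweeps: SweepSet, **kwargs) -> EphysFeatures:
    """Compute all ten intrinsic parameters for one cell.

    Undefined features (missing protocol pieces, too few spikes) come back as
    NaN with a note in ``flags``; partial input never raises.
    """
    feats = EphysFeatures()
    if sweeps.vc_step is not None:
        feats.series_resistance_mohm = series_resistance(sweeps)
        feats.input_resistance_mohm = input_resistance(sweeps)
        feats.capacitance_pf = capacitance(sweeps)
    else:
        feats.flags["passive"] = "no voltage-clamp step"
    if sweeps.cc_steps:
        try:
            fi = fi_curve(sweeps)
            feats.firing_threshold_pa = firing_threshold(fi)
            feats.df_di_hz_per_pa = df_di(fi)
        except ValueError as exc:
            feats.flags["fi"] = str(exc)
        feats.attenuation_ratio = attenuation(sweeps)
        feats.sag_mv = sag(sweeps)
        shape = ap_shape(sweeps)
        for key, val in shape.items():
            setattr(feats, key, val)
    else:
        feats.flags["active"] = "no current-clamp steps"
    return feats
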