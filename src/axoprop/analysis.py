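"""Measurement procedures on recorded or simulated traces.

Implements the quantities reported for layer-5 pyramidal neurons:

* AP propagation: per-site event times (first prominent peak of dV/dt for
  voltage traces, or of the inward action current), delays relative to the
  somatic dV/dt maximum, and forward/backward conduction velocities from a
  two-segment linear fit of the delay-distance profile with a free breakpoint
  (the initiation zone).
* Persistent Na+ current: linear leak subtraction on voltage-ramp traces,
  conversion to conductance, and Boltzmann fits of the normalized G-V curve
  (half-activation voltage V1/2 and slope factor k).
* Firing gain: mean instantaneous frequency per current step and the linear
  F-I slope (Hz/nA) over suprathreshold steps.
* Passive properties: input resistance from the steady-state voltage
  deflection and membrane time constant from a monoexponential fit to the
  off-transient.
* EPSP shape: peak, baseline-corrected time integral, decay time constant,
  and the set-level integral-vs-peak slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .traces import Channel, TraceSet

__all__ = [
    "VelocityEstimate",
    "BoltzmannFit",
    "GainFit",
    "PassiveFit",
    "EpspMetrics",
    "detect_ap_and_align",
    "align_average",
    "delay_distance_profile",
    "fit_propagation_velocities",
    "extract_inap_gv",
    "fit_boltzmann",
    "fi_curve",
    "fit_gain",
    "passive_properties",
    "epsp_metrics",
    "integral_peak_slope",
]

AXONAL_REGIONS = ("ais_proximal", "ais_middle", "ais_distal", "internode", "node")


# ---------------------------------------------------------------------------
# event detection and alignment
# ---------------------------------------------------------------------------


def _first_prominent_peak(t: np.ndarray, y: np.ndarray, min_frac: float) -> float | None:
    """Time of the first local maximum of y reaching `min_frac` of its global
    maximum, refined by quadratic (parabolic) sub-sample interpolation."""
    ymax = y.max()
    if not np.isfinite(ymax):
        return None
    peaks, _ = find_peaks(y, height=min_frac * ymax)
    i = int(peaks[0]) if len(peaks) else int(np.argmax(y))
    if 0 < i < len(y) - 1:
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        den = y0 - 2 * y1 + y2
        if den != 0:
            return float(t[i] - 0.5 * (y2 - y0) / den * (t[1] - t[0]))
    return float(t[i])


def detect_ap_and_align(
    trace: Channel | np.ndarray,
    time: np.ndarray | None = None,
    mode: str = "dvdt_max",
    *,
    t_from: float = 0.0,
    min_amplitude: float = 20.0,
    peak_frac: float = 0.5,
) -> list[float]:
    """Reference event time(s) in one sweep.

    mode 'dvdt_max': time of the (first prominent) maximum of dV/dt -- the
    standard alignment point for somatic APs.  mode 'onset_threshold': first
    upward crossing of -20 mV.  For action-current channels the extremum of
    the inward (negative) current is used instead of dV/dt.

    A flat/subthreshold trace yields an empty list, not an error.

    Events occurring before `t_from` (e.g. during the stimulus artifact) are
    excluded from the search.
    """
    if isinstance(trace, Channel):
        y = trace.samples
        t = time if time is not None else np.arange(len(y), dtype=float)
        is_current = trace.quantity in ("I_membrane", "I_clamp")
    else:
        y = np.asarray(trace, dtype=float)
        if time is None:
            raise ValueError("time grid required for bare arrays")
        t = np.asarray(time, dtype=float)
        is_current = False
    sel = t >= t_from
    t, y = t[sel], y[sel]
    if len(t) < 3:
        return []

    if is_current:
        sig = -(y - np.median(y))  # inward peak of the action current
        if sig.max() <= 0:
            return []
        ev = _first_prominent_peak(t, sig, peak_frac)
        return [ev] if ev is not None else []

    if y.max() - y.min() < min_amplitude:
        return []
    if mode == "dvdt_max":
        dv = np.gradient(y, t)
        ev = _first_prominent_peak(t, dv, peak_frac)
        return [ev] if ev is not None else []
    if mode == "onset_threshold":
        thr = -20.0
        above = y >= thr
        idx = np.where(~above[:-1] & above[1:])[0]
        out = []
        for i in idx:
            frac = (thr - y[i]) / (y[i + 1] - y[i])
            out.append(float(t[i] + frac * (t[1] - t[0])))
        return out
    raise ValueError(f"unknown mode {mode!r}")


def align_average(
    sweeps: Sequence[np.ndarray],
    time: np.ndarray,
    events: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Average sweeps after aligning each to its event time.

    Returns (relative time grid, averaged waveform); the grid is centered on
    the event (t = 0 at alignment point).  Sweeps are shifted by linear
    interpolation onto the common grid.
    """
    if len(sweeps) != len(events):
        raise ValueError("one event time per sweep required")
    dt = time[1] - time[0]
    rel = time - time[len(time) // 2]
    acc = np.zeros_like(rel)
    for y, ev in zip(sweeps, events):
        acc += np.interp(rel + ev, time, y, left=y[0], right=y[-1])
    return rel, acc / len(sweeps)


# ---------------------------------------------------------------------------
# propagation velocity
# ---------------------------------------------------------------------------


@dataclass
class VelocityEstimate:
    """Forward/backward conduction velocities from a delay-distance profile."""

    initiation_um: float
    backward_m_per_s: float  # proximal (soma-ward) branch; NaN if undetermined
    forward_m_per_s: float  # distal branch; NaN if undetermined
    points: np.ndarray = field(repr=False)  # (distance um, delay ms)
    residual_ms2: float = 0.0

    @property
    def ratio(self) -> float:
        return self.backward_m_per_s / self.forward_m_per_s


def delay_distance_profile(
    traceset: TraceSet,
    soma_channel: str = "V_soma",
    *,
    t_from: float | None = None,
    max_distance: float | None = None,
    min_amplitude: float = 2.0,
) -> np.ndarray:
    """Per-site (distance um, delay ms) pairs relative to the somatic
    dV/dt-max time.  Negative delay = site leads the soma.

    Uses all axonal channels with distance metadata; action-current channels
    are timed by their inward peak, voltage channels by the first prominent
    dV/dt peak.  `t_from` excludes the stimulus window from the event search
    (defaults to the end of the pulse recorded in the trace-set metadata).

    `min_amplitude` (mV) is a floor on the voltage excursion a channel must
    show to be timed.  The default (2 mV) times the passing wavefront even at
    sites whose local membrane does not fire a full spike, which is what the
    loose-patch action-current measurement effectively does; raise it to
    restrict the profile to actively spiking sites.
    """
    if t_from is None:
        pulse = traceset.meta.get("pulse", {})
        t_from = float(pulse.get("t_start", 0.0)) + float(pulse.get("duration_ms", 0.0))
    soma = traceset[soma_channel]
    ref = detect_ap_and_align(soma, traceset.time, t_from=t_from)
    if not ref:
        raise ValueError("no somatic AP found for alignment")
    tref = ref[0]
    pts = []
    for ch in traceset.channels:
        if ch.name == soma_channel or ch.region not in AXONAL_REGIONS:
            continue
        if np.isnan(ch.distance):
            raise ValueError(f"channel {ch.name!r} lacks distance metadata")
        if max_distance is not None and ch.distance > max_distance:
            continue
        ev = detect_ap_and_align(ch, traceset.time, t_from=t_from,
                                 min_amplitude=min_amplitude)
        if ev:
            pts.append((ch.distance, ev[0] - tref))
    if len(pts) < 3:
        raise ValueError("need >= 3 axonal sites with detected events")
    return np.array(sorted(pts))


def fit_propagation_velocities(profile: np.ndarray) -> VelocityEstimate:
    """Two-segment linear fit of delay vs distance with a free breakpoint.

    The breakpoint (initiation zone) is found by grid search over all splits
    between adjacent sites, minimizing the total squared residual of the two
    independent least-squares lines; ties break toward the proximal (AIS-ward)
    candidate.  Velocities are the inverse slopes (um/ms converted to m/s):
    proximal branch = backward velocity, distal branch = forward velocity.
    A side with < 2 points leaves that velocity undetermined (NaN).
    """
    pts = np.asarray(profile, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 4:
        raise ValueError("profile must be (n >= 4) x 2 [distance, delay]")
    pts = pts[np.argsort(pts[:, 0])]
    x, y = pts[:, 0], pts[:, 1]
    n = len(x)

    best = None
    for b in range(1, n - 2):  # left = [0..b], right = [b+1..]
        xl, yl = x[: b + 1], y[: b + 1]
        xr, yr = x[b + 1 :], y[b + 1 :]
        pl = np.polyfit(xl, yl, 1)
        pr = np.polyfit(xr, yr, 1)
        sse = float(
            ((np.polyval(pl, xl) - yl) ** 2).sum()
            + ((np.polyval(pr, xr) - yr) ** 2).sum()
        )
        if best is None or sse < best[0] - 1e-15:
            best = (sse, b, pl, pr)
    sse, b, pl, pr = best

    def vel(slope):  # slope ms/um -> m/s
        return float("inf") if slope == 0 else 1e-3 / abs(slope)

    vb = vel(pl[0]) if b + 1 >= 2 else float("nan")
    vf = vel(pr[0]) if n - b - 1 >= 2 else float("nan")
    return VelocityEstimate(
        initiation_um=float(0.5 * (x[b] + x[b + 1])),
        backward_m_per_s=vb,
        forward_m_per_s=vf,
        points=pts,
        residual_ms2=sse,
    )


# ---------------------------------------------------------------------------
# persistent Na+ current: G-V extraction and Boltzmann fit
# ---------------------------------------------------------------------------


@dataclass
class BoltzmannFit:
    vhalf: float  # mV
    k: float  # mV
    gmax: float  # same units as the input conductance
    rmse: float
    extrapolated: bool = False


def extract_inap_gv(
    traceset: TraceSet,
    *,
    current_channel: str = "I_clamp",
    command_channel: str = "Vcmd",
    leak_window: tuple[float, float] = (-70.0, -65.0),
    e_na: float | None = None,
    v_max: float | None = -10.0,
    refine_leak: bool = True,
    normalize: bool = True,
) -> np.ndarray:
    """Normalized conductance-voltage curve of the ramp-evoked persistent
    Na+ current.

    A line is fitted to the current over the subthreshold `leak_window` of
    command voltage and subtracted (this also removes the constant capacitive
    current of a linear ramp); the remaining inward current is converted to
    conductance via G = I / (V - E_Na) and normalized to its plateau (median
    of the top 10% voltage range below `v_max`).

    Because the activation foot is not strictly zero inside the leak window,
    a plain leak fit over-subtracts and biases the curve leftward; when
    `refine_leak` is true the leak line is therefore re-estimated by a joint
    least-squares fit of (linear leak + Boltzmann Na current) over the whole
    analyzed span, seeded by the window fit.  At zero noise the joint fit
    recovers the exact decomposition.

    Returns an (n, 2) array of (V mV, G/Gmax).
    """
    i = traceset[current_channel].samples
    v = traceset[command_channel].samples
    if np.any(np.diff(v) < 0):
        raise ValueError("command voltage must be non-decreasing")
    if e_na is None:
        e_na = float(traceset.meta.get("ena_mV", 91.1))
    ramp = np.diff(v).max() > 0
    if not ramp:
        raise ValueError("command voltage is constant; not a ramp")
    sel_rising = np.gradient(v) > 0
    v, i = v[sel_rising], i[sel_rising]

    w = (v >= leak_window[0]) & (v <= leak_window[1])
    if w.sum() < 2:
        raise ValueError("leak window contains < 2 samples")
    keep = v <= v_max if v_max is not None else np.ones_like(v, dtype=bool)

    slope, icpt = np.polyfit(v[w], i[w], 1)
    if refine_leak:
        def full_model(vv, a, b, vhalf, k, gmax):
            return a + b * vv + gmax / (1.0 + np.exp(-(vv - vhalf) / k)) * (
                vv - e_na)

        vk, ik = v[keep], i[keep]
        # provisional curve from the window fit seeds the joint fit
        prov = (ik - (slope * vk + icpt)) / (vk - e_na)
        plateau0 = float(np.median(prov[vk >= vk.max() - 0.1 * (vk.max() - vk.min())]))
        vhalf0 = float(vk[np.argmin(np.abs(prov - 0.5 * plateau0))])
        try:
            popt, _ = curve_fit(
                full_model, vk, ik,
                p0=(icpt, slope, vhalf0, 5.0, max(plateau0, 1e-9)),
                bounds=([-np.inf, -np.inf, vk.min(), 0.5, 0.0],
                        [np.inf, np.inf, vk.max(), 30.0, np.inf]),
                maxfev=20000,
            )
            icpt, slope = popt[0], popt[1]
        except RuntimeError:
            pass  # no resolvable Na component; keep the window leak fit
    i_sub = i - (slope * v + icpt)
    v, i_sub = v[keep], i_sub[keep]
    drive = v - e_na
    g = i_sub / drive  # inward current / negative drive -> positive G
    if not normalize:
        return np.column_stack([v, g])
    vspan = v.max() - v.min()
    plateau_sel = v >= v.max() - 0.1 * vspan
    plateau = float(np.median(g[plateau_sel]))
    if plateau <= 0:
        plateau = max(g.max(), 1e-12)
    return np.column_stack([v, g / plateau])


def fit_boltzmann(gv: np.ndarray, *, p0: tuple | None = None) -> BoltzmannFit:
    """Least-squares Boltzmann fit G/Gmax = gmax / (1 + exp(-(V - V1/2)/k)).

    A curve that does not span both tails (min > 10% or max < 90% of the
    plateau) is fitted anyway but flagged ``extrapolated``.
    """
    gv = np.asarray(gv, dtype=float)
    v, g = gv[:, 0], gv[:, 1]

    def boltz(vv, vhalf, k, gmax):
        return gmax / (1.0 + np.exp(-(vv - vhalf) / k))

    if p0 is None:
        gmax0 = float(np.percentile(g, 95))
        half = gmax0 / 2
        vhalf0 = float(v[np.argmin(np.abs(g - half))])
        p0 = (vhalf0, 5.0, gmax0)
    popt, _ = curve_fit(boltz, v, g, p0=p0, maxfev=20000)
    vhalf, k, gmax = (float(p) for p in popt)
    if k < 0:  # enforce activation orientation of the fitted curve
        k, vhalf = -k, vhalf
    resid = g - boltz(v, *popt)
    extrap = bool(g.min() > 0.1 * gmax or g.max() < 0.9 * gmax)
    return BoltzmannFit(
        vhalf=vhalf, k=k, gmax=gmax,
        rmse=float(np.sqrt(np.mean(resid**2))),
        extrapolated=extrap,
    )


# ---------------------------------------------------------------------------
# F-I gain
# ---------------------------------------------------------------------------


@dataclass
class GainFit:
    slope_hz_per_na: float
    intercept_hz: float
    rheobase_na: float  # lowest amplitude that evoked >= 1 spike (NaN if none)
    points: np.ndarray = field(repr=False)  # (I nA, f Hz) used in the fit


def _spike_times(t: np.ndarray, v: np.ndarray, thr: float = 0.0) -> np.ndarray:
    """Upward threshold crossings, linearly interpolated between samples."""
    above = v >= thr
    idx = np.where(~above[:-1] & above[1:])[0]
    frac = (thr - v[idx]) / (v[idx + 1] - v[idx])
    return t[idx] + frac * (t[1] - t[0])


def fi_curve(
    traceset: TraceSet,
    *,
    window: tuple[float, float] | None = None,
    spike_threshold: float = 0.0,
) -> list[tuple[float, float, int]]:
    """Mean instantaneous frequency per current step.

    For each sweep, spikes are upward crossings of `spike_threshold` within
    the pulse window and the frequency is the mean of reciprocal interspike
    intervals.  Returns (amplitude nA, frequency Hz or NaN, spike count) per
    sweep; sweeps with < 2 spikes get NaN frequency but keep their count for
    rheobase bookkeeping.
    """
    amps = traceset.meta.get("amplitudes_nA")
    if amps is None:
        raise ValueError("trace set lacks 'amplitudes_nA' metadata")
    if window is None:
        window = tuple(traceset.meta.get("pulse_ms", (traceset.time[0], traceset.time[-1])))
    t = traceset.time
    out = []
    for sweep, amp in enumerate(amps):
        chans = [c for c in traceset.channels if c.sweep == sweep and c.quantity == "V"]
        if not chans:
            raise ValueError(f"no voltage channel for sweep {sweep}")
        v = chans[0].samples
        st = _spike_times(t, v, spike_threshold)
        st = st[(st >= window[0]) & (st <= window[1])]
        if len(st) >= 2:
            f = float(np.mean(1.0 / np.diff(st)) * 1e3)  # ms -> Hz
        else:
            f = float("nan")
        out.append((float(amp), f, int(len(st))))
    return out


def fit_gain(points: Iterable[tuple]) -> GainFit:
    """Linear F-I gain over suprathreshold steps (those with a frequency).

    Subthreshold (zero-spike) steps do not influence the fitted slope.
    """
    pts = [(p[0], p[1]) + ((p[2],) if len(p) > 2 else (2,)) for p in points]
    with_spike = [p[0] for p in pts if p[2] >= 1]
    rheo = min(with_spike) if with_spike else float("nan")
    xy = np.array([(i, f) for i, f, _ in pts if np.isfinite(f)])
    if len(xy) < 2:
        raise ValueError("need >= 2 suprathreshold steps with >= 2 spikes")
    slope, icpt = np.polyfit(xy[:, 0], xy[:, 1], 1)
    return GainFit(
        slope_hz_per_na=float(slope),
        intercept_hz=float(icpt),
        rheobase_na=float(rheo),
        points=xy,
    )


# ---------------------------------------------------------------------------
# passive properties
# ---------------------------------------------------------------------------


@dataclass
class PassiveFit:
    r_in_mohm: float
    tau_m_ms: float
    spike_contaminated: bool = False


def passive_properties(
    traceset_or_trace,
    amplitude_na: float | None = None,
    *,
    window: tuple[float, float] | None = None,
    channel: str | None = None,
) -> PassiveFit:
    """Input resistance and membrane time constant from a hyperpolarizing step.

    R_in = steady-state voltage deflection / current amplitude (the last 10%
    of the pulse vs the pre-pulse baseline).  tau_m is a monoexponential fit
    to the off-transient following the end of the pulse.  Spikes anywhere in
    the trace set the `spike_contaminated` flag.
    """
    ts = traceset_or_trace
    if isinstance(ts, TraceSet):
        ch = ts[channel] if channel else ts.select(quantity="V")[0]
        t, v = ts.time, ch.samples
        if amplitude_na is None:
            amps = ts.meta.get("amplitudes_nA")
            sweep = ch.sweep or 0
            amplitude_na = float(amps[sweep]) if amps else None
        if window is None:
            window = tuple(ts.meta.get("pulse_ms", ()))
    else:
        raise TypeError("pass a TraceSet")
    if amplitude_na is None or amplitude_na == 0:
        raise ValueError("step amplitude required")
    if not window:
        raise ValueError("pulse window required (trace meta 'pulse_ms' or window=)")
    t0, t1 = window

    contaminated = bool(v.max() > 0.0)
    base = v[t < t0]
    if len(base) < 2:
        raise ValueError("no pre-pulse baseline")
    v0 = float(base.mean())
    ss_sel = (t >= t1 - 0.1 * (t1 - t0)) & (t < t1)
    dv_ss = float(v[ss_sel].mean() - v0)
    r_in = dv_ss / amplitude_na  # mV/nA = MOhm

    off = t >= t1
    toff, voff = t[off], v[off]

    def mono(tt, a, tau):
        return v0 + a * np.exp(-(tt - t1) / tau)

    tau0 = max((t1 - t0) / 10.0, t[1] - t[0])
    popt, _ = curve_fit(mono, toff, voff, p0=(dv_ss, tau0), maxfev=10000)
    return PassiveFit(
        r_in_mohm=float(r_in),
        tau_m_ms=float(abs(popt[1])),
        spike_contaminated=contaminated,
    )


# ---------------------------------------------------------------------------
# EPSP metrics
# ---------------------------------------------------------------------------


@dataclass
class EpspMetrics:
    peak_mv: float
    integral_mv_ms: float
    decay_tau_ms: float
    baseline_mv: float


def epsp_metrics(
    time: np.ndarray,
    v: np.ndarray,
    *,
    stim_time: float,
    baseline_window: float = 2.0,
    noise_floor: float = 0.2,
) -> EpspMetrics | None:
    """Peak, baseline-corrected integral and decay tau of one EPSP.

    The baseline is the mean over `baseline_window` ms before `stim_time`.
    The integral is the trapezoid of (V - baseline) from the stimulus to the
    end of the trace.  Decay tau is a monoexponential fit from the peak
    onward.  Returns None when the peak is below `noise_floor` mV.
    """
    t = np.asarray(time, dtype=float)
    v = np.asarray(v, dtype=float)
    base_sel = (t >= stim_time - baseline_window) & (t < stim_time)
    if base_sel.sum() < 2:
        raise ValueError("baseline window precedes the recorded trace")
    base = float(v[base_sel].mean())
    after = t >= stim_time
    ta, va = t[after], v[after] - base
    ipk = int(np.argmax(va))
    peak = float(va[ipk])
    if peak < noise_floor:
        return None
    integral = float(np.trapezoid(va, ta))

    td, vd = ta[ipk:], va[ipk:]

    def mono(tt, a, tau):
        return a * np.exp(-(tt - td[0]) / tau)

    popt, _ = curve_fit(mono, td, vd, p0=(peak, max(ta[-1] - ta[ipk], 1.0) / 3),
                        maxfev=10000)
    return EpspMetrics(
        peak_mv=peak,
        integral_mv_ms=integral,
        decay_tau_ms=float(abs(popt[1])),
        baseline_mv=base,
    )


def integral_peak_slope(metrics: Sequence[EpspMetrics]) -> float:
    """Slope (mV*ms per mV) of the EPSP integral-vs-peak relation.

    For a family with a shared decay time constant the relation is linear
    through the origin with slope e*tau; activity-dependent broadening of
    large EPSPs steepens it.  Fitted by least squares through the origin.
    """
    ms = [m for m in metrics if m is not None]
    if len(ms) < 2:
        raise ValueError("need >= 2 EPSPs")
    x = np.array([m.peak_mv for m in ms])
    y = np.array([m.integral_mv_ms for m in ms])
    return float((x @ y) / (x @ x))
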