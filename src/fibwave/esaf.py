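"""Event-synchronous adaptive QRST cancellation.

During AF the surface ECG is the sum of a large beat-locked ventricular
waveform (QRST) and the low-amplitude continuous atrial fibrillatory
activity.  The event-synchronous adaptive filter (ESAF) learns the R-locked
ventricular waveform as the impulse response of an FIR filter driven by an
impulse train synchronized to the R peaks: a normalized-LMS adaptation
minimizes the residual power, the converged kernel is the average-like QRST
template, and the residual is the ventricular-cancelled atrial signal.

Because the reference is sparse (one unit impulse per beat), each sample's
regressor contains at most a handful of nonzero taps — one per beat whose
kernel window covers that sample — so adaptation touches one kernel tap per
(beat, offset) pair and overlapping beats are least-squares-split
automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, firwin as sig_firwin

from .preprocessing import ImpulseTrain, RPeakSeries

__all__ = [
    "EsafConfig",
    "AtrialSignal",
    "esaf_cancel",
    "template_subtract_oracle",
    "qrst_suppression_db",
]


@dataclass(frozen=True)
class EsafConfig:
    """ESAF tuning.

    The kernel spans [-kernel_pre, +kernel_post] s around each R peak.  The
    defaults cover Q onset through the T end *plus* the slow tails that the
    1 Hz high-pass edge smears onto the QRST — tails the kernel must learn
    or they leak into the atrial residual.  ``step_size`` scales a
    stochastic-approximation (harmonically decreasing) normalized-LMS step:
    each tap's k-th update uses step_size/k, so at step_size=1 the kernel
    converges to the plain R-locked beat average, the minimum-variance
    estimate a fixed number of beats allows.  The final sweep emits the
    residual with the near-converged kernel.
    """

    kernel_pre: float = 0.35
    kernel_post: float = 0.60
    step_size: float = 1.0
    n_passes: int = 3
    kernel_smooth_hz: float | None = 36.0

    def __post_init__(self) -> None:
        if not (0 < self.step_size < 2):
            raise ValueError("step_size must lie in (0, 2)")
        if self.n_passes < 1:
            raise ValueError("n_passes must be >= 1")
        if self.kernel_pre < 0 or self.kernel_post <= 0:
            raise ValueError("kernel span must be positive")


@dataclass
class AtrialSignal:
    """Ventricular-cancelled (atrial) waveform plus the learned QRST kernel."""

    samples: np.ndarray
    fs: float
    lead: str = ""
    qrst_kernel: np.ndarray = field(default_factory=lambda: np.zeros(0))
    warnings: list[str] = field(default_factory=list)


def _active_taps(
    positions: np.ndarray, L: int, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Enumerate (sample, tap) pairs where the sparse regressor is nonzero.

    For an impulse at advanced position p, tap k is active at sample p+k.
    Returns sample indices, tap indices, and the boundaries of groups of
    equal sample index (so multi-beat overlaps can be updated jointly).
    """
    samp = (positions[:, None] + np.arange(L)[None, :]).ravel()
    taps = np.tile(np.arange(L), positions.size)
    ok = (samp >= 0) & (samp < n)
    samp, taps = samp[ok], taps[ok]
    order = np.argsort(samp, kind="stable")
    samp, taps = samp[order], taps[order]
    # group boundaries: starts of runs of equal sample index
    if samp.size:
        starts = np.flatnonzero(np.r_[True, np.diff(samp) > 0])
        starts = np.r_[starts, samp.size]
    else:
        starts = np.array([0])
    return samp, taps, starts


def esaf_cancel(
    filtered_lead: np.ndarray,
    train: ImpulseTrain,
    cfg: EsafConfig = EsafConfig(),
    lead: str = "",
) -> AtrialSignal:
    """Cancel the beat-locked QRST waveform; return the atrial residual.

    The reference is the impulse train advanced by ``kernel_pre`` so a
    causal FIR kernel of length round((kernel_pre+kernel_post)*fs) spans
    [-kernel_pre, +kernel_post] around each R.  NLMS sweeps adapt the
    kernel; the last sweep emits residual = primary - kernel convolved with
    the advanced train.  Samples outside every kernel window are returned
    unchanged (the reference is zero there).
    """
    d = np.asarray(filtered_lead, dtype=float)
    n = d.size
    fs = train.fs
    if train.positions.size == 0:
        raise ValueError("cannot cancel without beats: impulse train is empty")

    warnings: list[str] = []
    if train.positions.size < 5:
        warnings.append(f"only {train.positions.size} beats; ESAF may be under-trained")

    L = int(round((cfg.kernel_pre + cfg.kernel_post) * fs))
    adv = train.positions - int(round(cfg.kernel_pre * fs))
    if train.positions.size > 1:
        min_rr = int(np.diff(train.positions).min())
        if L >= min_rr:
            warnings.append(
                f"kernel span {L} samples >= min RR {min_rr}: overlapping beats"
            )

    samp, taps, starts = _active_taps(adv, L, n)
    w = np.zeros(L)
    counts = np.zeros(L)
    n_groups = starts.size - 1
    for p in range(cfg.n_passes):
        for g in range(n_groups):
            s0, s1 = starts[g], starts[g + 1]
            i = samp[s0]
            ks = taps[s0:s1]
            e = d[i] - w[ks].sum()
            counts[ks] += 1.0
            # harmonically decreasing normalized step; overlapping beats
            # share the error equally (least-squares splitting)
            w[ks] += cfg.step_size * e / ((s1 - s0) * counts[ks])

    if cfg.kernel_smooth_hz is not None and w.size > 8:
        w = _smooth_kernel(w, fs, cfg.kernel_smooth_hz)

    # residual: primary minus the learned kernel placed at every beat;
    # samples outside all kernel windows pass through untouched
    y = np.zeros(n)
    for p_adv in adv:
        s = max(0, -p_adv)
        e_ = min(L, n - p_adv)
        if e_ > s:
            y[p_adv + s : p_adv + e_] += w[s:e_]
    residual = d - y

    return AtrialSignal(samples=residual, fs=fs, lead=lead, qrst_kernel=w,
                        warnings=warnings)


def _smooth_kernel(w: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    """Band-limit the learned kernel to the primary's own passband.

    The primary input is band-limited before cancellation, so the true
    R-locked template is too; tap-estimation noise above the passband is
    pure variance and is removed by a symmetric (zero-phase) FIR low-pass.
    """
    numtaps = min(int(5.5 * fs / 14.0) | 1, (w.size // 2) * 2 - 1)
    taps = sig_firwin(numtaps, cutoff_hz, fs=fs, window="blackman")
    h = numtaps // 2
    wp = np.pad(w, (h, h), mode="reflect")
    return fftconvolve(wp, taps, mode="valid")


def template_subtract_oracle(
    filtered_lead: np.ndarray,
    peaks: RPeakSeries,
    window: tuple[float, float] = (0.25, 0.45),
) -> np.ndarray:
    """Average-beat subtraction: the brute-force reference for the ESAF.

    Computes the plain mean of R-locked segments over beats whose windows
    fit inside the record, and subtracts it at every such beat.  Valid only
    for non-overlapping beat windows (rejected otherwise); intended for
    tests, not production use.
    """
    x = np.asarray(filtered_lead, dtype=float)
    pre, post = window
    fs = peaks.fs
    a = int(round(pre * fs))
    b = int(round(post * fs))
    if len(peaks) < 2:
        raise ValueError("average-beat subtraction needs at least 2 beats")
    if np.any(np.diff(peaks.indices) < a + b):
        raise ValueError("beat windows overlap; oracle requires non-overlapping beats")
    segs = []
    usable = []
    for r in peaks.indices:
        if r - a >= 0 and r + b <= x.size:
            segs.append(x[r - a : r + b])
            usable.append(r)
    if len(segs) < 2:
        raise ValueError("fewer than 2 complete beat windows in record")
    template = np.mean(segs, axis=0)
    out = x.copy()
    for r in usable:
        out[r - a : r + b] -= template
    return out


def qrst_suppression_db(
    original: np.ndarray,
    residual: np.ndarray,
    peaks: RPeakSeries,
    window: tuple[float, float] = (0.25, 0.45),
    cap_db: float = 60.0,
) -> tuple[float, list[str]]:
    """Ventricular suppression achieved by cancellation, in dB.

    Beat-window power of the original over beat-window power of the
    residual, each first reduced by the signal's own out-of-window mean
    power (an estimate of the atrial+noise floor), so the ratio reflects
    the ventricular component.  Returns ``(dB, flags)``; a zero or
    floor-level residual numerator is capped at ``cap_db``.
    """
    x = np.asarray(original, dtype=float)
    r = np.asarray(residual, dtype=float)
    if len(peaks) < 1:
        raise ValueError("need at least one beat")
    fs = peaks.fs
    a, b = int(round(window[0] * fs)), int(round(window[1] * fs))
    mask = np.zeros(x.size, dtype=bool)
    for p in peaks.indices:
        mask[max(0, p - a) : min(x.size, p + b)] = True

    flags: list[str] = []

    def vent_power(sig: np.ndarray) -> float:
        inside = float(np.mean(sig[mask] ** 2)) if mask.any() else 0.0
        outside = float(np.mean(sig[~mask] ** 2)) if (~mask).any() else 0.0
        return max(inside - outside, 0.0)

    p_orig = vent_power(x)
    p_res = vent_power(r)
    if p_res <= 0 or p_orig <= 0:
        flags.append("floor-limited suppression estimate (capped)")
        return (cap_db if p_orig > 0 else 0.0), flags
    db = 10.0 * np.log10(p_orig / p_res)
    if db > cap_db:
        flags.append("suppression capped")
        db = cap_db
    return float(db), flags
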