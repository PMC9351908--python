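"""Per-lead complexity parameters of the atrial (fibrillatory) signal.

Five parameters summarize f-wave organization per lead:

* **FWA** (uV) — fibrillatory-wave amplitude: mean successive
  peak-to-trough of the atrial signal (time domain);
* **DF** (Hz) — dominant frequency: location of the largest spectral peak
  in the 3-12 Hz fibrillatory band;
* **OI** — organization index: fraction of 3-25 Hz power concentrated in
  ±0.5 Hz windows around the DF and its harmonics;
* **SE** (nats) — spectral entropy of the normalized 3-12 Hz spectrum;
* **SampEn** — sample entropy of the (decimated) atrial waveform.

SE depends on the spectral binning (here a 0.1 Hz grid over 3-12 Hz, 91
bins, natural log, so 0 <= SE <= ln 91 ~= 4.51) and SampEn on (m, r, fs);
absolute values of both are comparable only under matching conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import decimate, find_peaks, savgol_filter, welch

from .esaf import AtrialSignal, EsafConfig, esaf_cancel, qrst_suppression_db
from .io import EcgEpoch
from .preprocessing import build_impulse_train, detect_r_peaks, wavelet_bandlimit

__all__ = [
    "SpectralSummary",
    "ComplexityRow",
    "SampEnConfig",
    "compute_fwa",
    "estimate_spectrum",
    "compute_df",
    "compute_oi",
    "compute_se",
    "compute_sampen",
    "analyze_epoch",
    "DF_BAND",
    "OI_BAND",
]

DF_BAND = (3.0, 12.0)   # fibrillatory-rate search band, Hz
OI_BAND = (3.0, 25.0)   # band retained for OI harmonics, Hz
SPECTRAL_RESOLUTION = 0.1  # Hz grid for the display spectrum


@dataclass
class SpectralSummary:
    freqs: np.ndarray
    psd: np.ndarray
    band: tuple[float, float] = DF_BAND
    resolution: float = SPECTRAL_RESOLUTION

    def __post_init__(self) -> None:
        if np.any(self.psd < 0):
            raise ValueError("psd must be nonnegative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    def band_mask(self, band: tuple[float, float] | None = None) -> np.ndarray:
        lo, hi = band if band is not None else self.band
        return (self.freqs >= lo - 1e-9) & (self.freqs <= hi + 1e-9)


@dataclass
class SampEnConfig:
    m: int = 2
    r_frac: float = 0.2
    resample_fs: float = 250.0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not (0 < self.r_frac < 1):
            raise ValueError("r_frac must lie in (0, 1)")


@dataclass
class ComplexityRow:
    """One lead's five complexity parameters plus quality flags."""

    lead: str
    fwa: float
    df: float
    oi: float
    se: float
    sampen: float
    quality: dict = field(default_factory=dict)


def compute_fwa(
    atrial: AtrialSignal | np.ndarray,
    fs: float | None = None,
    min_sep_s: float = 0.04,
    smooth_s: float = 0.02,
    prominence_frac: float = 1.0,
) -> tuple[float, dict]:
    """Fibrillatory-wave amplitude: mean successive peak-to-trough, in uV.

    The signal is lightly smoothed (Savitzky-Golay over ``smooth_s``, which
    keeps the fibrillatory band at unity gain), alternating local extrema at
    least ``min_sep_s`` apart and with prominence >= ``prominence_frac`` x SD
    are detected (the prominence floor keeps cancellation-residual ripple
    from diluting the estimate), and FWA is the mean absolute difference
    between successive extrema.  Returns ``(fwa_uV, flags)``; fewer than 4
    extrema sets ``unreliable``.
    """
    x, fs = _coerce(atrial, fs)
    if x.size < 2 * fs:
        raise ValueError("need at least 2 s of signal for FWA")
    wl = int(round(smooth_s * fs)) | 1
    xs = savgol_filter(x, wl, polyorder=3) if wl > 3 else x
    sd = float(np.std(xs))
    flags: dict = {}
    if sd == 0:
        return 0.0, {"unreliable": True, "n_extrema": 0}
    dist = max(1, int(round(min_sep_s * fs)))
    prom = prominence_frac * sd
    peaks, _ = find_peaks(xs, distance=dist, prominence=prom)
    troughs, _ = find_peaks(-xs, distance=dist, prominence=prom)
    idx = np.sort(np.concatenate([peaks, troughs]))
    flags["n_extrema"] = int(idx.size)
    if idx.size < 4:
        flags["unreliable"] = True
    if idx.size < 2:
        return 0.0, flags
    return float(np.mean(np.abs(np.diff(xs[idx])))), flags


def estimate_spectrum(
    atrial: AtrialSignal | np.ndarray, fs: float | None = None
) -> SpectralSummary:
    """Welch power spectrum on a 0.1 Hz grid (2-s Hann segments, 50% overlap,
    zero-padded)."""
    x, fs = _coerce(atrial, fs)
    if x.size < 4 * fs:
        raise ValueError("need at least 4 s of signal for the spectrum")
    nperseg = int(round(2 * fs))
    nfft = int(round(fs / SPECTRAL_RESOLUTION))
    freqs, psd = welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, nfft=nfft
    )
    return SpectralSummary(freqs=freqs, psd=psd)


def compute_df(spec: SpectralSummary) -> tuple[float, dict]:
    """Dominant frequency: argmax of the PSD in the 3-12 Hz band.

    Ties break toward the lower frequency.  If the in-band spectrum is
    (numerically) empty, or the in-band peak is dwarfed by out-of-band
    power (no fibrillatory component in band), the value is flagged invalid
    and returned as NaN.
    """
    m = spec.band_mask(DF_BAND)
    if not m.any():
        raise ValueError("spectrum does not cover the 3-12 Hz DF band")
    in_psd = spec.psd[m]
    flags: dict = {}
    peak = in_psd.max()
    total_peak = spec.psd.max()
    if peak <= 0 or (total_peak > 0 and peak < 0.05 * total_peak):
        return float("nan"), {"df_invalid": True}
    df = float(spec.freqs[m][int(np.argmax(in_psd))])
    return df, flags


def compute_oi(
    spec: SpectralSummary, df: float, half_width: float = 0.6, n_harmonics: int = 4
) -> tuple[float, dict]:
    """Organization index: harmonic-window power fraction.

    Power within ±``half_width`` Hz of k*DF (k = 1..``n_harmonics``,
    k*DF <= 25 Hz) divided by the total 3-25 Hz power, clipped to [0, 1].
    The default half-width (0.6 Hz) just covers the mainlobe of the 2-s
    Hann Welch segments, so a pure tone scores ~1 while the windows stay
    narrow relative to the harmonic spacing.
    """
    if not np.isfinite(df):
        return float("nan"), {"oi_invalid": True}
    band = spec.band_mask(OI_BAND)
    # rectangle-rule sums: the harmonic-window mask is non-contiguous, so a
    # trapezoid over the selected freqs would bridge the gaps
    total = float(spec.psd[band].sum())
    if total <= 0:
        return float("nan"), {"oi_invalid": True}
    harm = np.zeros_like(spec.freqs, dtype=bool)
    for k in range(1, n_harmonics + 1):
        fk = k * df
        if fk > OI_BAND[1]:
            break
        harm |= np.abs(spec.freqs - fk) <= half_width + 1e-9
    num = float(spec.psd[harm & band].sum())
    return float(np.clip(num / total, 0.0, 1.0)), {}


def compute_se(spec: SpectralSummary) -> tuple[float, dict]:
    """Spectral entropy (nats) of the normalized 3-12 Hz spectrum.

    p_i = psd_i / sum(psd) over the 91-bin 0.1 Hz grid; SE = -sum p ln p
    with 0 ln 0 := 0.  Ranges from 0 (single bin) to ln(n_bins) (flat).
    """
    m = spec.band_mask(DF_BAND)
    p = spec.psd[m].astype(float)
    tot = p.sum()
    if tot <= 0:
        return float("nan"), {"se_invalid": True}
    p = p / tot
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum() + 0.0), {}


def sampen_max_bins(spec_or_nbins=None) -> float:
    """ln(n_bins) upper bound of SE on the default 91-bin grid."""
    return float(np.log(91))


def compute_sampen(
    atrial: AtrialSignal | np.ndarray,
    cfg: SampEnConfig = SampEnConfig(),
    fs: float | None = None,
) -> tuple[float, dict]:
    """Sample entropy of the (anti-aliased, decimated) atrial waveform.

    SampEn(m, r) = -ln(A/B) where B counts pairs of length-``m`` templates
    within Chebyshev distance ``r`` (self-matches excluded) and A the same
    for length m+1; r = ``r_frac`` x SD of the decimated signal.  A constant
    signal returns 0 by convention; B = 0 is flagged undefined; A = 0 is
    returned as -ln(1/B) (the largest estimable value) and flagged.
    """
    x, fs0 = _coerce(atrial, fs)
    q = max(1, int(round(fs0 / cfg.resample_fs)))
    if x.size // q < 100:
        raise ValueError(f"resampled length {x.size // q} < 100; SampEn unreliable")
    if np.all(x == x[0]):
        return 0.0, {"constant_signal": True}
    y = decimate(x, q, ftype="fir", zero_phase=True) if q > 1 else x.astype(float)
    n = y.size
    sd = float(np.std(y))
    if sd == 0:
        return 0.0, {"constant_signal": True}
    r = max(cfg.r_frac * sd, np.finfo(float).eps * sd)
    m = cfg.m

    a, b = _match_counts(y, m, r)
    flags: dict = {}
    if b == 0:
        return float("nan"), {"sampen_undefined": True}
    if a == 0:
        flags["sampen_capped"] = True
        return float(-np.log(1.0 / b)), flags
    return float(-np.log(a / b)), flags


def _match_counts(y: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Template-match counts (A for m+1, B for m), Chebyshev distance,
    ordered pairs i != j, both template sets restricted to the n-m first
    start positions so A/B is a conditional probability."""
    n = y.size
    nt = n - m  # number of (m+1)-templates; m-templates use the same starts
    emb_m = np.lib.stride_tricks.sliding_window_view(y, m)[:nt]
    emb_m1 = np.lib.stride_tricks.sliding_window_view(y, m + 1)
    b_total = 0
    a_total = 0
    chunk = 256
    for s in range(0, nt, chunk):
        e = min(s + chunk, nt)
        dm = np.abs(emb_m[s:e, None, :] - emb_m[None, :, :]).max(axis=2)
        dm1 = np.abs(emb_m1[s:e, None, :] - emb_m1[None, :, :]).max(axis=2)
        bm = dm <= r
        am = dm1 <= r
        # exclude self-matches
        idx = np.arange(s, e)
        bm[np.arange(e - s), idx] = False
        am[np.arange(e - s), idx] = False
        b_total += int(bm.sum())
        a_total += int(am.sum())
    return a_total, b_total


def _coerce(atrial, fs: float | None) -> tuple[np.ndarray, float]:
    if isinstance(atrial, AtrialSignal):
        return np.asarray(atrial.samples, dtype=float), atrial.fs
    if fs is None:
        raise ValueError("fs required when passing a bare array")
    return np.asarray(atrial, dtype=float), float(fs)


def analyze_epoch(
    epoch: EcgEpoch,
    esaf_cfg: EsafConfig = EsafConfig(),
    sampen_cfg: SampEnConfig = SampEnConfig(),
    r_lead: str = "II",
) -> list[ComplexityRow]:
    """Run the full per-lead pipeline: band-limit, detect R peaks (on
    ``r_lead``), build the impulse train, cancel QRST, compute the five
    parameters.  Deterministic: the same epoch yields identical rows."""
    filtered = {l: wavelet_bandlimit(epoch.samples[l], epoch.fs) for l in epoch.leads}
    try:
        ref = epoch.lead(r_lead)
        ref_name = r_lead
    except KeyError:
        ref_name = epoch.leads[0]
    ref_filtered = wavelet_bandlimit(epoch.lead(ref_name), epoch.fs)
    peaks = detect_r_peaks(ref_filtered, epoch.fs)
    train = build_impulse_train(peaks, epoch.n_samples)

    rows: list[ComplexityRow] = []
    for l in epoch.leads:
        try:
            atr = esaf_cancel(filtered[l], train, esaf_cfg, lead=l)
        except ValueError as exc:
            raise ValueError(f"lead {l}: {exc}") from exc
        supp_db, supp_flags = qrst_suppression_db(
            filtered[l], atr.samples, peaks,
            window=(esaf_cfg.kernel_pre, esaf_cfg.kernel_post),
        )
        fwa, f_fwa = compute_fwa(atr)
        spec = estimate_spectrum(atr)
        df, f_df = compute_df(spec)
        oi, f_oi = compute_oi(spec, df)
        se, f_se = compute_se(spec)
        sampen, f_samp = compute_sampen(atr, sampen_cfg)
        quality = {
            "n_beats": len(peaks),
            "suppression_db": round(supp_db, 2),
            **f_fwa, **f_df, **f_oi, **f_se, **f_samp,
        }
        if atr.warnings:
            quality["esaf_warnings"] = list(atr.warnings)
        rows.append(ComplexityRow(lead=l, fwa=fwa, df=df, oi=oi, se=se,
                                  sampen=sampen, quality=quality))
    return rows
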