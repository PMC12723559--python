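"""Power-spectral EEG biomarkers.

Implements the resting-state feature set used throughout the analysis:

* Welch power spectral density (2-s Hann windows, 50% overlap).
* Spectral parameterization: iterative decomposition of the PSD (in log10
  power) into an aperiodic 1/f component — vertical ``offset`` and
  ``exponent`` — plus up to three Gaussian periodic peaks with bandwidth
  clamped to [2, 6] Hz, in the 3–30 Hz fit range.
* Band AUC (trapezoidal power integral over θ/α/β bands) and the closed
  form area under the fitted aperiodic curve ("1/f AUC").
* Wavelet (Morlet) spectrogram oscillation-event detection with
  per-frequency median normalization, suprathreshold bounding boxes, box
  merging, and per-event wave heights from the band-filtered signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from scipy.optimize import curve_fit

__all__ = [
    "PowerSpectrum",
    "AperiodicFit",
    "SpectralPeak",
    "OscillationEvent",
    "FeatureVector",
    "BANDS",
    "welch_psd",
    "parameterize_spectrum",
    "band_auc",
    "aperiodic_auc",
    "detect_events",
    "extract_features",
]

#: Conventional band edges (Hz) consistent with a 3-30 Hz fit window.
BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 12.0), "beta": (12.0, 30.0)}


@dataclass
class PowerSpectrum:
    """One-sided PSD: frequencies (Hz) and power density (μV²/Hz)."""

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass(frozen=True)
class AperiodicFit:
    """Aperiodic (1/f) component: P(f) = 10^offset * f^-exponent."""

    offset: float  # log10 power at 1 Hz
    exponent: float

    def evaluate(self, f: np.ndarray) -> np.ndarray:
        """Power density of the aperiodic component at frequencies ``f``."""
        return 10.0**self.offset * np.asarray(f, dtype=float) ** (-self.exponent)


@dataclass(frozen=True)
class SpectralPeak:
    """Gaussian periodic peak above the aperiodic component (log power)."""

    center_frequency: float  # Hz
    amplitude: float  # log10-power height above the aperiodic fit
    bandwidth: float  # Hz (2x Gaussian SD)


@dataclass(frozen=True)
class OscillationEvent:
    """A suprathreshold time-frequency event."""

    band: str
    t_start: float  # s
    t_stop: float
    f_low: float  # Hz
    f_high: float
    peak_frequency: float
    peak_power: float  # in units of the frequency's median power
    wave_height: float  # nV, peak-to-trough of band-filtered signal


@dataclass
class FeatureVector:
    """The four EEG features used for mechanism classification."""

    offset: float
    exponent: float
    peak_cf: float  # Hz; NaN if no periodic peak was detected
    aperiodic_auc: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.offset, self.exponent, self.peak_cf, self.aperiodic_auc]
        )


def welch_psd(trace, window_s: float = 2.0) -> PowerSpectrum:
    """Welch PSD with Hann windows of ``window_s`` seconds, 50% overlap.

    A 2-s window gives 0.5 Hz frequency resolution. ``trace`` is any object
    with ``values`` (μV) and ``fs`` (Hz) attributes.
    """
    values = np.asarray(trace.values, dtype=float)
    nperseg = int(round(window_s * trace.fs))
    if values.size < nperseg:
        raise ValueError("trace shorter than one Welch window")
    f, p = signal.welch(
        values,
        fs=trace.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )
    return PowerSpectrum(frequencies=f, power=p)


def _gaussian(f, height, cf, sd):
    return height * np.exp(-0.5 * ((f - cf) / sd) ** 2)


def _robust_aperiodic(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    """Linear aperiodic fit in log-log space, down-weighting peak regions.

    First pass ordinary least squares; second pass refits on the points
    whose positive residual is below one residual SD, so narrowband peaks
    do not drag the fit up.
    """
    slope, intercept = np.polyfit(logf, logp, 1)
    resid = logp - (intercept + slope * logf)
    keep = resid <= max(np.std(resid), 1e-12)
    if keep.sum() >= 3:
        slope, intercept = np.polyfit(logf[keep], logp[keep], 1)
    return intercept, -slope  # offset, exponent


def parameterize_spectrum(
    ps: PowerSpectrum,
    f_range: tuple = (3.0, 30.0),
    max_peaks: int = 3,
    bw_limits: tuple = (2.0, 6.0),
    relative_threshold: float = 2.0,
    min_height: float = 0.0,
) -> tuple[AperiodicFit, list]:
    """Decompose a PSD into aperiodic and periodic components.

    Iterative fit in log10-power vs linear-frequency space: (1) robust
    aperiodic fit; (2) peak detection on the flattened spectrum, largest
    first, accepting peaks above ``relative_threshold`` x residual SD and
    ``min_height``; (3) joint Gaussian refit with bandwidth clamped to
    ``bw_limits``; (4) aperiodic refit on the peak-subtracted spectrum.
    Peaks are returned sorted by amplitude, largest first.
    """
    sel = (ps.frequencies >= f_range[0]) & (ps.frequencies <= f_range[1])
    f = ps.frequencies[sel]
    p = ps.power[sel]
    if f.size < 5:
        raise ValueError("spectrum does not cover the fit range")
    if np.any(p <= 0):
        raise ValueError("non-positive power in fit range")
    logf = np.log10(f)
    logp = np.log10(p)
    sd_lo, sd_hi = bw_limits[0] / 2.0, bw_limits[1] / 2.0

    offset, exponent = _robust_aperiodic(logf, logp)
    flat = logp - (offset - exponent * logf)

    # iterative peak guesses on the flattened spectrum
    guesses = []
    work = flat.copy()
    for _ in range(max_peaks):
        i = int(np.argmax(work))
        height = work[i]
        if height <= max(relative_threshold * np.std(work), min_height):
            break
        cf = f[i]
        # half-height width on the working spectrum
        half = height / 2.0
        lo = i
        while lo > 0 and work[lo] > half:
            lo -= 1
        hi = i
        while hi < work.size - 1 and work[hi] > half:
            hi += 1
        fwhm = max(f[hi] - f[lo], 1e-6)
        sd = float(np.clip(fwhm / 2.355, sd_lo, sd_hi))
        guesses.append((height, cf, sd))
        work = work - _gaussian(f, height, cf, sd)

    peaks: list[SpectralPeak] = []
    if guesses:

        def multi_gauss(x, *params):
            y = np.zeros_like(x)
            for k in range(0, len(params), 3):
                y = y + _gaussian(x, params[k], params[k + 1], params[k + 2])
            return y

        p0, lob, hib = [], [], []
        for h, cf, sd in guesses:
            p0 += [h, cf, sd]
            lob += [0.0, f_range[0], sd_lo]
            hib += [np.inf, f_range[1], sd_hi]
        try:
            popt, _ = curve_fit(
                multi_gauss, f, flat, p0=p0, bounds=(lob, hib), maxfev=5000
            )
        except RuntimeError:
            popt = np.array([v for g in guesses for v in g])
        for k in range(0, len(popt), 3):
            h, cf, sd = popt[k : k + 3]
            if h > 0:
                peaks.append(
                    SpectralPeak(
                        center_frequency=float(cf),
                        amplitude=float(h),
                        bandwidth=float(2.0 * sd),
                    )
                )
        periodic = multi_gauss(f, *popt)
        offset, exponent = _robust_aperiodic(logf, logp - periodic)

    peaks.sort(key=lambda pk: pk.amplitude, reverse=True)
    return AperiodicFit(offset=float(offset), exponent=float(exponent)), peaks


def band_auc(ps: PowerSpectrum, band: tuple) -> float:
    """Trapezoidal integral of power density over ``band = (low, high)`` Hz.

    Band edges are interpolated onto the frequency grid, so adjacent bands
    sharing an edge add exactly: AUC(a,b) + AUC(b,c) = AUC(a,c).
    """
    lo, hi = band
    if hi <= lo:
        raise ValueError("band must satisfy low < high")
    f, p = ps.frequencies, ps.power
    if lo < f[0] or hi > f[-1]:
        raise ValueError("band outside the spectrum's frequency range")
    grid = f[(f > lo) & (f < hi)]
    fx = np.concatenate(([lo], grid, [hi]))
    px = np.interp(fx, f, p)
    return float(np.trapezoid(px, fx))


def aperiodic_auc(fit: AperiodicFit, f_range: tuple = (3.0, 30.0)) -> float:
    """Closed-form area under the aperiodic curve over ``f_range``.

    ∫ 10^offset f^-χ df = 10^offset (f2^(1-χ) - f1^(1-χ)) / (1-χ) for
    χ ≠ 1, and 10^offset ln(f2/f1) for χ = 1.
    """
    f1, f2 = f_range
    a = 10.0**fit.offset
    chi = fit.exponent
    if abs(chi - 1.0) < 1e-12:
        return float(a * math.log(f2 / f1))
    return float(a * (f2 ** (1.0 - chi) - f1 ** (1.0 - chi)) / (1.0 - chi))


def _morlet_spectrogram(
    values: np.ndarray, fs: float, freqs: np.ndarray, n_cycles: float = 7.0
) -> np.ndarray:
    """Complex Morlet wavelet power, rows = frequencies."""
    out = np.empty((freqs.size, values.size))
    for i, f0 in enumerate(freqs):
        sigma_t = n_cycles / (2.0 * np.pi * f0)
        half = int(np.ceil(4.0 * sigma_t * fs))
        t = np.arange(-half, half + 1) / fs
        w = np.exp(2j * np.pi * f0 * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
        w /= np.sqrt(np.sum(np.abs(w) ** 2))
        conv = signal.fftconvolve(values, w, mode="same")
        out[i] = np.abs(conv) ** 2
    return out


def _merge_boxes(boxes: list, overlap: float) -> list:
    """Merge bounding boxes whose fractional overlap (relative to the
    smaller box) is at least ``overlap``; iterate to a fixed point."""
    boxes = list(boxes)
    merged = True
    while merged:
        merged = False
        out = []
        while boxes:
            b = boxes.pop()
            for k, o in enumerate(out):
                dt = min(b[1], o[1]) - max(b[0], o[0])
                df = min(b[3], o[3]) - max(b[2], o[2])
                if dt > 0 and df > 0:
                    inter = dt * df
                    a1 = (b[1] - b[0]) * (b[3] - b[2])
                    a2 = (o[1] - o[0]) * (o[3] - o[2])
                    if inter >= overlap * min(a1, a2):
                        out[k] = (
                            min(b[0], o[0]),
                            max(b[1], o[1]),
                            min(b[2], o[2]),
                            max(b[3], o[3]),
                            max(b[4], o[4]),
                            b[5] if b[4] >= o[4] else o[5],
                        )
                        merged = True
                        break
            else:
                out.append(b)
        boxes = out
        if not merged:
            return boxes
    return boxes


def detect_events(
    trace,
    median_threshold: float = 4.0,
    fmin: float = 1.0,
    fmax: float = 100.0,
    fstep: float = 0.5,
    box_overlap: float = 0.5,
    min_cycles: float = 3.0,
    min_peak_ratio: float = 40.0,
    n_cycles: float = 7.0,
) -> list:
    """Detect oscillation events in a Morlet spectrogram.

    The spectrogram (``fmin``–``fmax`` Hz in ``fstep`` steps) is normalized
    per frequency row by its median power; connected suprathreshold regions
    (> ``median_threshold``) become time-frequency bounding boxes, boxes
    overlapping by ≥ ``box_overlap`` of the smaller box are merged, and
    events shorter than ``min_cycles`` cycles at their peak frequency are
    discarded, as are events whose peak power stays below ``min_peak_ratio``
    x the median (a two-threshold hysteresis: the median threshold defines
    the event's extent, the peak criterion rejects the ubiquitous weak
    blobs that median-thresholded colored noise produces). Each event gets a band label by peak frequency and a wave
    height: the peak-to-trough amplitude of the zero-phase band-filtered
    signal inside the event window, in nV.
    """
    values = np.asarray(trace.values, dtype=float)
    fs = trace.fs
    if values.size < int(fs):
        raise ValueError("trace too short for event analysis")
    fmax = min(fmax, 0.45 * fs)
    freqs = np.arange(fmin, fmax + fstep / 2, fstep)
    power = _morlet_spectrogram(values, fs, freqs, n_cycles=n_cycles)
    med = np.median(power, axis=1, keepdims=True)
    med[med <= 0] = np.finfo(float).tiny
    norm = power / med

    above = norm > median_threshold
    labels, n_lab = ndimage.label(above)
    if n_lab == 0:
        return []
    boxes = []
    objects = ndimage.find_objects(labels)
    for sl in objects:
        fsl, tsl = sl
        sub = norm[sl]
        pk = float(sub.max())
        pf_i, pt_i = np.unravel_index(int(np.argmax(sub)), sub.shape)
        boxes.append(
            (
                tsl.start / fs,
                tsl.stop / fs,
                freqs[fsl.start],
                freqs[fsl.stop - 1],
                pk,
                freqs[fsl.start + pf_i],
            )
        )
    boxes = _merge_boxes(boxes, box_overlap)

    events = []
    for t0, t1, flo, fhi, pk, pf in boxes:
        if (t1 - t0) * pf < min_cycles or pk < min_peak_ratio:
            continue
        band = None
        for name, (blo, bhi) in BANDS.items():
            if blo <= pf < bhi:
                band = name
                break
        if band is None:
            continue
        blo, bhi = BANDS[band]
        sos = signal.butter(4, [blo, bhi], btype="bandpass", fs=fs, output="sos")
        filt = signal.sosfiltfilt(sos, values)
        i0, i1 = int(t0 * fs), max(int(t1 * fs), int(t0 * fs) + 2)
        seg = filt[i0:i1]
        height_nv = float((seg.max() - seg.min()) * 1000.0)  # μV → nV
        events.append(
            OscillationEvent(
                band=band,
                t_start=float(t0),
                t_stop=float(t1),
                f_low=float(flo),
                f_high=float(fhi),
                peak_frequency=float(pf),
                peak_power=pk,
                wave_height=height_nv,
            )
        )
    events.sort(key=lambda e: e.t_start)
    return events


def extract_features(trace, f_range: tuple = (3.0, 30.0)) -> FeatureVector:
    """Extract the 4-feature EEG vector: offset, exponent, peak CF, 1/f AUC.

    Peak CF is the center frequency of the maximum-amplitude periodic
    peak; if no peak is detected it is NaN (imputed downstream by the
    mechanism decoder).
    """
    ps = welch_psd(trace)
    fit, peaks = parameterize_spectrum(ps, f_range=f_range)
    cf = peaks[0].center_frequency if peaks else float("nan")
    return FeatureVector(
        offset=fit.offset,
        exponent=fit.exponent,
        peak_cf=cf,
        aperiodic_auc=aperiodic_auc(fit, f_range),
    )
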