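"""Circuit-function statistics: rates, signal detection, decoding, effect sizes.

Measures how well a microcircuit's stimulus response can be read out
against its ongoing baseline activity:

* Baseline firing-rate distribution — Pyr population rate in a 40 ms
  window slid in 1 ms steps over a 3 s pre-stimulus period.
* Recurrent-response rate distribution — one Pyr population rate per
  stimulus trial in the 10-50 ms post-stimulus window.
* Signal-detection error — percent overlap of the two rate distributions
  (histogram intersection on shared bins), with a bootstrap interval.
* Decoding accuracy — per-trial per-neuron spike-count vectors from
  baseline vs. response windows classified by an ANN or linear SVM over
  repeated train/test splits.
* Cohen's d (pooled-SD standardized mean difference) and equal-variance
  two-sample t tests for group comparisons across randomized circuits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RateDistribution",
    "OverlapResult",
    "baseline_rate_distribution",
    "recurrent_rate_distribution",
    "detection_error",
    "decoding_accuracy",
    "cohens_d",
    "compare_conditions",
]


@dataclass
class RateDistribution:
    """Sample of Pyr population firing rates (Hz) with window metadata."""

    rates: np.ndarray
    window_ms: float
    step_ms: float | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class OverlapResult:
    """Percent overlap of two rate distributions with bootstrap CI."""

    overlap_pct: float
    boot_mean: float
    ci_low: float
    ci_high: float
    n_boot: int


def _pyr_spike_times(spikes) -> tuple[np.ndarray, int]:
    mask = spikes.population_mask("Pyr")[spikes.neuron_ids]
    n_pyr = int(spikes.population_mask("Pyr").sum())
    return np.sort(spikes.times_ms[mask]), n_pyr


def baseline_rate_distribution(
    spikes,
    window_ms: float = 40.0,
    step_ms: float = 1.0,
    span_ms: float = 3000.0,
    t_end_ms: float | None = None,
) -> RateDistribution:
    """Sliding-window Pyr population rate over the pre-stimulus period.

    Windows of ``window_ms`` slide in ``step_ms`` steps over the
    ``span_ms`` interval ending at the first stimulus (or at ``t_end_ms``).
    Rate = spike count / (n_Pyr x window length).
    """
    if t_end_ms is None:
        t_end_ms = (
            float(spikes.stim_times_ms[0])
            if spikes.stim_times_ms.size
            else spikes.duration_ms
        )
    t0 = t_end_ms - span_ms
    if t0 < 0:
        raise ValueError("insufficient pre-stimulus span")
    times, n_pyr = _pyr_spike_times(spikes)
    # per-ms binning + moving sum gives every window position exactly
    n_bins = int(round(span_ms / step_ms))
    counts, _ = np.histogram(times, bins=n_bins, range=(t0, t_end_ms))
    w = int(round(window_ms / step_ms))
    csum = np.concatenate(([0], np.cumsum(counts)))
    win_counts = csum[w:] - csum[:-w]
    rates = win_counts / (n_pyr * window_ms * 1e-3)
    return RateDistribution(rates=rates, window_ms=window_ms, step_ms=step_ms)


def recurrent_rate_distribution(
    spikes, window_ms: tuple = (10.0, 50.0)
) -> RateDistribution:
    """Per-trial Pyr population rate in a fixed post-stimulus window."""
    if spikes.stim_times_ms.size == 0:
        raise ValueError("spike data carries no stimulus markers")
    times, n_pyr = _pyr_spike_times(spikes)
    lo, hi = window_ms
    dur_s = (hi - lo) * 1e-3
    rates = [
        np.sum((times >= t + lo) & (times < t + hi)) / (n_pyr * dur_s)
        for t in spikes.stim_times_ms
    ]
    return RateDistribution(rates=np.asarray(rates), window_ms=hi - lo)


def _hist_overlap(x: np.ndarray, y: np.ndarray, edges: np.ndarray) -> float:
    px, _ = np.histogram(x, bins=edges)
    py, _ = np.histogram(y, bins=edges)
    px = px / px.sum()
    py = py / py.sum()
    return 100.0 * float(np.minimum(px, py).sum())


def _shared_edges(x: np.ndarray, y: np.ndarray, min_bins: int = 10) -> np.ndarray:
    pooled = np.concatenate([x, y])
    lo, hi = pooled.min(), pooled.max()
    if hi <= lo:
        hi = lo + 1e-9
    iqr = np.subtract(*np.percentile(pooled, [75, 25]))
    if iqr > 0:
        width = 2.0 * iqr / pooled.size ** (1.0 / 3.0)  # Freedman–Diaconis
        n_bins = max(min_bins, int(np.ceil((hi - lo) / width)))
    else:
        n_bins = min_bins
    return np.linspace(lo, hi, n_bins + 1)


def detection_error(
    baseline: RateDistribution,
    recurrent: RateDistribution,
    n_boot: int = 1000,
    seed: int = 0,
) -> OverlapResult:
    """Percent overlap between baseline and response rate distributions.

    Both samples are histogrammed on shared equal-width bins spanning the
    pooled range (Freedman-Diaconis count, floor 10); the overlap is
    100 x Σ_bins min(p̂_b, p̂_r). High overlap means the response is hard
    to detect against baseline. Bootstrap resampling of both samples gives
    a mean and 95% interval.
    """
    x, y = baseline.rates, recurrent.rates
    if x.size == 0 or y.size == 0:
        raise ValueError("empty rate distribution")
    edges = _shared_edges(x, y)
    point = _hist_overlap(x, y, edges)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        xb = rng.choice(x, size=x.size, replace=True)
        yb = rng.choice(y, size=y.size, replace=True)
        boots[b] = _hist_overlap(xb, yb, edges)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return OverlapResult(
        overlap_pct=point,
        boot_mean=float(boots.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
    )


def spike_count_vectors(
    spikes,
    baseline_window_ms: float = 50.0,
    response_window_ms: tuple = (25.0, 75.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial per-Pyr-neuron spike-count vectors for decoding.

    For each stimulus trial, counts per Pyr neuron in the 50 ms baseline
    window immediately pre-stimulus (label 0 / noise) and in the
    post-stimulus response window (label 1 / signal). Returns (X, y).
    """
    if spikes.stim_times_ms.size == 0:
        raise ValueError("spike data carries no stimulus markers")
    pyr_ids = np.flatnonzero(spikes.population_mask("Pyr"))
    id_map = {int(n): k for k, n in enumerate(pyr_ids)}
    mask = spikes.population_mask("Pyr")[spikes.neuron_ids]
    t = spikes.times_ms[mask]
    nid = spikes.neuron_ids[mask]
    X, y = [], []
    rlo, rhi = response_window_ms
    for t0 in spikes.stim_times_ms:
        for (a, b), label in (((t0 - baseline_window_ms, t0), 0), ((t0 + rlo, t0 + rhi), 1)):
            sel = (t >= a) & (t < b)
            v = np.zeros(pyr_ids.size)
            for n in nid[sel]:
                v[id_map[int(n)]] += 1
            X.append(v)
            y.append(label)
    return np.asarray(X), np.asarray(y)


def decoding_accuracy(
    spikes=None,
    classifier: str = "svm",
    n_perm: int = 100,
    train_frac: float = 0.7,
    seed: int = 0,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
) -> np.ndarray:
    """Baseline-vs-response decoding accuracy over random splits (%).

    Spike-count vectors (from ``spikes`` or given directly as ``X, y``)
    are split 70/30 (stratified) ``n_perm`` times; a classifier is trained
    on each split and scored on its test set. ``classifier`` is ``"svm"``
    (linear kernel, C=1) or ``"ann"`` (single 20-unit ReLU hidden layer).
    Returns the sample of test accuracies in percent.
    """
    from sklearn.model_selection import StratifiedShuffleSplit
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC

    if X is None or y is None:
        X, y = spike_count_vectors(spikes)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("need at least two trials of each class")
    splitter = StratifiedShuffleSplit(
        n_splits=n_perm, train_size=train_frac, random_state=seed
    )
    accs = np.empty(n_perm)
    for k, (tr, te) in enumerate(splitter.split(X, y)):
        if classifier == "svm":
            clf = SVC(kernel="linear", C=1.0)
        elif classifier == "ann":
            clf = MLPClassifier(
                hidden_layer_sizes=(20,),
                max_iter=500,
                random_state=k,
            )
        else:
            raise ValueError(f"unknown classifier {classifier!r}")
        clf.fit(X[tr], y[tr])
        accs[k] = clf.score(X[te], y[te]) * 100.0
    return accs


def cohens_d(x, y) -> float:
    """Standardized mean difference (comparison − reference) / pooled SD.

    Pooled SD uses the (Nx−1)σx² + (Ny−1)σy² over Nx+Ny−2 form. The sign
    convention is (second argument − first argument): with x = reference
    (e.g. middle-aged) and y = comparison (e.g. older), a negative d means
    the quantity decreases with aging.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("need at least two observations per sample")
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    diff = y.mean() - x.mean()
    if pooled_var == 0:
        if diff == 0:
            return 0.0
        raise ZeroDivisionError("zero pooled variance with unequal means")
    return float(diff / np.sqrt(pooled_var))


def compare_conditions(x, y, alpha: float = 0.05, d_threshold: float = 0.5) -> dict:
    """Equal-variance two-sample t test plus Cohen's d for one metric.

    ``x`` is the reference sample (middle-aged), ``y`` the comparison.
    ``significant`` flags p < alpha together with |d| > d_threshold.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, p = stats.ttest_ind(y, x, equal_var=True)
    try:
        d = cohens_d(x, y)
    except ZeroDivisionError:
        d = float("inf") if y.mean() > x.mean() else float("-inf")
    return {
        "t": float(t),
        "p": float(p),
        "d": d,
        "significant": bool(p < alpha and abs(d) > d_threshold),
    }
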