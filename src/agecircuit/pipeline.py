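"""Five-condition aging experiment orchestrator.

Runs the full analysis for each condition (middle_age, older, inhib_loss,
nmda_loss, spine_loss) over ``n_circuits`` randomized circuits:

1. derive the condition's aging profile and build the circuit;
2. simulate resting (baseline) activity, forward-model the EEG, and
   extract spectral biomarkers (offset, exponent, peak CF, 1/f AUC, band
   AUCs, oscillation-event wave heights);
3. simulate the brief-stimulus protocol and compute baseline/recurrent
   rates plus the distribution-overlap signal-detection error;
4. simulate the stronger stimulus and compute spike-count decoding
   accuracy;
5. compare every metric against middle_age (equal-variance t test +
   Cohen's d).

Results are plain pandas DataFrames writable as CSV/JSON; column names
carry units. All stages are deterministic in the experiment seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as fm
from . import spectral as sf
from .aging_parameters import CONDITION_LABELS, make_profile
from .eeg_forward import FourSphereModel, project_dipole
from .microcircuit import (
    CircuitConfig,
    brief_stimulus,
    build_circuit,
    simulate,
    strong_stimulus,
)

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "feature_dataset"]

#: metric column -> description with units and window definition
COLUMN_DOC = {
    "condition": "condition label",
    "circuit": "circuit index within condition",
    "baseline_rate_hz": "mean Pyr rate, 3 s pre-stimulus (Hz)",
    "recurrent_rate_hz": "mean Pyr rate 10-50 ms post brief stimulus across trials (Hz)",
    "strong_recurrent_rate_hz": "mean Pyr rate 25-75 ms post strong stimulus across trials (Hz)",
    "detection_error_pct": "overlap of baseline (40 ms/1 ms sliding) and recurrent rate distributions (%)",
    "decoding_accuracy_pct": "mean test accuracy, baseline vs 25-75 ms response spike-count vectors (%)",
    "offset_log10_uv2": "aperiodic offset, log10 EEG power at 1 Hz",
    "exponent": "aperiodic 1/f exponent (3-30 Hz fit)",
    "peak_cf_hz": "center frequency of largest periodic peak (Hz; NaN if none)",
    "aperiodic_auc": "area under aperiodic fit, 3-30 Hz (μV²·Hz-normalized)",
    "theta_auc": "PSD area 4-8 Hz (μV²-scale)",
    "alpha_auc": "PSD area 8-12 Hz",
    "beta_auc": "PSD area 12-30 Hz",
    "theta_wave_height_nv": "mean θ oscillation-event peak-to-trough (nV; NaN if no events)",
    "alpha_wave_height_nv": "mean α oscillation-event peak-to-trough (nV)",
    "beta_wave_height_nv": "mean β oscillation-event peak-to-trough (nV)",
}


@dataclass
class ExperimentConfig:
    """Study design parameters for one experiment batch."""

    circuit: CircuitConfig = field(default_factory=lambda: CircuitConfig(n_total=1000))
    years: float = 20.0
    n_circuits: int = 20
    baseline_duration_ms: float = 28000.0
    n_trials: int = 20
    stim_start_ms: float = 3500.0
    stim_interval_ms: float = 500.0
    decoder_classifier: str = "svm"
    decoder_n_perm: int = 100
    detect_oscillation_events: bool = True
    eeg_model: FourSphereModel = field(default_factory=FourSphereModel)
    dipole_pos_mm: tuple = (0.0, 0.0, 78.0)
    electrode_pos_mm: tuple = (0.0, 0.0, 90.0)


@dataclass
class ExperimentReport:
    """Per-circuit metric table plus group statistics vs middle_age."""

    results: pd.DataFrame
    group_stats: pd.DataFrame
    column_doc: dict = field(default_factory=lambda: dict(COLUMN_DOC))

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(out / "condition_results.csv", index=False)
        self.group_stats.to_csv(out / "group_stats.csv", index=False)
        summary = {
            "column_doc": self.column_doc,
            "medians": {
                cond: g.median(numeric_only=True).to_dict()
                for cond, g in self.results.groupby("condition")
            },
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))


def _circuit_seeds(base_seed: int, cond_idx: int, i: int) -> tuple[int, int, int, int]:
    ss = np.random.SeedSequence([int(base_seed), cond_idx, i])
    a, b, c, d = ss.generate_state(4)
    mod = 2**31 - 1
    return int(a % mod), int(b % mod), int(c % mod), int(d % mod)


def run_condition_circuit(
    cfg: ExperimentConfig, label: str, index: int, base_seed: int
) -> dict:
    """Run all stages for one randomized circuit of one condition."""
    cond_idx = CONDITION_LABELS.index(label)
    s_build, s_base, s_brief, s_strong = _circuit_seeds(base_seed, cond_idx, index)
    profile = make_profile(label, years=cfg.years)
    circuit = build_circuit(cfg.circuit, profile, seed=s_build)
    row: dict = {"condition": label, "circuit": index}

    # resting activity → EEG → spectral biomarkers
    spikes, dipole = simulate(circuit, cfg.baseline_duration_ms, seed=s_base)
    eeg = project_dipole(
        dipole, cfg.eeg_model, cfg.dipole_pos_mm, cfg.electrode_pos_mm
    )
    ps = sf.welch_psd(eeg)
    fit, peaks = sf.parameterize_spectrum(ps)
    row["offset_log10_uv2"] = fit.offset
    row["exponent"] = fit.exponent
    row["peak_cf_hz"] = peaks[0].center_frequency if peaks else np.nan
    row["aperiodic_auc"] = sf.aperiodic_auc(fit)
    for band, edges in sf.BANDS.items():
        row[f"{band}_auc"] = sf.band_auc(ps, edges)
    if cfg.detect_oscillation_events:
        events = sf.detect_events(eeg)
        for band in sf.BANDS:
            hs = [e.wave_height for e in events if e.band == band]
            row[f"{band}_wave_height_nv"] = float(np.mean(hs)) if hs else np.nan

    # brief stimulus → rates + signal-detection error
    dur = cfg.stim_start_ms + cfg.n_trials * cfg.stim_interval_ms
    spikes_b, _ = simulate(
        circuit,
        dur,
        stimulus=brief_stimulus(),
        n_trials=cfg.n_trials,
        stim_start_ms=cfg.stim_start_ms,
        stim_interval_ms=cfg.stim_interval_ms,
        seed=s_brief,
    )
    base_dist = fm.baseline_rate_distribution(spikes_b)
    rec_dist = fm.recurrent_rate_distribution(spikes_b)
    row["baseline_rate_hz"] = float(base_dist.rates.mean())
    row["recurrent_rate_hz"] = float(rec_dist.rates.mean())
    row["detection_error_pct"] = fm.detection_error(
        base_dist, rec_dist, seed=s_brief
    ).overlap_pct

    # strong stimulus → decoding accuracy
    spikes_s, _ = simulate(
        circuit,
        dur,
        stimulus=strong_stimulus(),
        n_trials=cfg.n_trials,
        stim_start_ms=cfg.stim_start_ms,
        stim_interval_ms=cfg.stim_interval_ms,
        seed=s_strong,
    )
    rec_s = fm.recurrent_rate_distribution(spikes_s, window_ms=(25.0, 75.0))
    row["strong_recurrent_rate_hz"] = float(rec_s.rates.mean())
    accs = fm.decoding_accuracy(
        spikes_s,
        classifier=cfg.decoder_classifier,
        n_perm=cfg.decoder_n_perm,
        seed=s_strong,
    )
    row["decoding_accuracy_pct"] = float(accs.mean())
    return row


def run_experiment(
    cfg: ExperimentConfig,
    conditions=CONDITION_LABELS,
    seed: int = 0,
    on_error: str = "record",
) -> ExperimentReport:
    """Run the full multi-condition experiment.

    A failing stage for one circuit is recorded (row of NaNs with an
    ``error`` note) rather than aborting the batch, unless
    ``on_error="raise"``.
    """
    rows = []
    for label in conditions:
        for i in range(cfg.n_circuits):
            try:
                rows.append(run_condition_circuit(cfg, label, i, seed))
            except Exception as exc:  # noqa: BLE001 - batch robustness
                if on_error == "raise":
                    raise
                rows.append({"condition": label, "circuit": i, "error": str(exc)})
    results = pd.DataFrame(rows)

    stats_rows = []
    metric_cols = [
        c
        for c in results.columns
        if c not in ("condition", "circuit", "error") and results[c].dtype.kind == "f"
    ]
    if "middle_age" in set(results["condition"]):
        ref = results[results["condition"] == "middle_age"]
        for label in conditions:
            if label == "middle_age":
                continue
            comp = results[results["condition"] == label]
            for col in metric_cols:
                x = ref[col].dropna().to_numpy()
                y = comp[col].dropna().to_numpy()
                if x.size < 2 or y.size < 2:
                    continue
                st = fm.compare_conditions(x, y)
                stats_rows.append(
                    {
                        "condition": label,
                        "metric": col,
                        "middle_age_mean": x.mean(),
                        "condition_mean": y.mean(),
                        **st,
                    }
                )
    group_stats = pd.DataFrame(stats_rows)
    return ExperimentReport(results=results, group_stats=group_stats)


def feature_dataset(report: ExperimentReport) -> tuple[np.ndarray, list]:
    """EEG feature matrix + condition labels for the mechanism decoder.

    Returns (X, labels): X is (n, 4) with columns offset, exponent,
    peak CF (NaN allowed) and 1/f AUC — one row per circuit.
    """
    cols = ["offset_log10_uv2", "exponent", "peak_cf_hz", "aperiodic_auc"]
    df = report.results
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"report lacks spectral feature column(s): {missing}")
    usable = df.dropna(subset=["offset_log10_uv2", "exponent", "aperiodic_auc"])
    present = set(usable["condition"])
    absent = [lb for lb in CONDITION_LABELS if lb not in present]
    if absent:
        raise ValueError(f"report is missing condition(s): {absent}")
    X = usable[cols].to_numpy(dtype=float)
    labels = usable["condition"].tolist()
    return X, labels
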