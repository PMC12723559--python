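"""Reduced four-population spiking cortical microcircuit.

A conductance-based leaky integrate-and-fire network standing in for a
morphologically detailed layer-2/3 model: 80% pyramidal (Pyr) neurons and
three interneuron classes (5% SST, 7% PV, 8% VIP), wired with the
canonical motif (Pyr→all, SST→Pyr apical, PV→Pyr basal, VIP→SST, VIP→PV).
Excitatory synapses carry AMPA + NMDA components (double-exponential
kinetics, Jahr-Stevens Mg block on NMDA), inhibitory synapses GABA_A.
Each neuron receives an independent excitatory Ornstein-Uhlenbeck (OU)
conductance emulating background synaptic bombardment, producing irregular
baseline firing of Pyr cells around ~1 Hz.

Aging mechanisms enter through an :class:`~agecircuit.aging_parameters.AgingProfile`:
interneuron counts scale by survival fractions, NMDA conductances onto Pyr
(recurrent and stimulus) scale by the NMDA multiplier, Pyr→Pyr connection
probability by the spine-loss multiplier, and Pyr leak conductance and
capacitance by the passive multiplier.

The network also emits an EEG-proxy current-dipole trace: the sum of Pyr
synaptic currents weighted by a signed depth offset per synapse class
(SST inhibition and OU drive on the apical side, recurrent/stimulus
excitation and PV inhibition on the basal side).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .aging_parameters import AgingProfile

__all__ = [
    "POP_NAMES",
    "CircuitConfig",
    "SynapseKinetics",
    "OUDrive",
    "StimulusEntry",
    "StimulusSpec",
    "SpikeData",
    "DipoleTrace",
    "Circuit",
    "build_circuit",
    "simulate",
    "brief_stimulus",
    "strong_stimulus",
    "replay_dipole",
]

POP_NAMES = ("Pyr", "SST", "PV", "VIP")
_PYR, _SST, _PV, _VIP = 0, 1, 2, 3


@dataclass(frozen=True)
class SynapseKinetics:
    """Rise/decay time constants (ms) per receptor and NMDA Mg-block."""

    nmda_rise: float = 2.0
    nmda_decay: float = 65.0
    ampa_rise: float = 0.3
    ampa_decay: float = 3.0
    gaba_rise: float = 1.0
    gaba_decay: float = 10.0
    mg_conc_factor: float = 0.28  # [Mg]/3.57 at 1 mM, Jahr-Stevens
    mg_slope: float = 0.062  # 1/mV

    def __post_init__(self) -> None:
        for rec in ("nmda", "ampa", "gaba"):
            if getattr(self, f"{rec}_rise") >= getattr(self, f"{rec}_decay"):
                raise ValueError(f"{rec}: tau_rise must be < tau_decay")


@dataclass(frozen=True)
class OUDrive:
    """Per-population excitatory OU conductance drive (nS)."""

    mean: float
    sd: float
    tau: float = 5.0  # ms
    reversal: float = 0.0  # mV


def _default_conn_prob() -> np.ndarray:
    # rows = presynaptic population, cols = postsynaptic; canonical motif
    p = np.zeros((4, 4))
    p[_PYR] = [0.15, 0.20, 0.20, 0.20]
    p[_SST, _PYR] = 0.25
    p[_PV, _PYR] = 0.30
    p[_VIP, _SST] = 0.30
    p[_VIP, _PV] = 0.30
    return p


def _default_w_ampa() -> np.ndarray:
    w = np.zeros((4, 4))
    w[_PYR] = [0.35, 0.10, 1.50, 0.10]
    return w


def _default_w_nmda() -> np.ndarray:
    w = np.zeros((4, 4))
    w[_PYR] = [1.00, 0.10, 0.15, 0.10]
    return w


def _default_w_gaba() -> np.ndarray:
    w = np.zeros((4, 4))
    w[_SST, _PYR] = 6.0
    w[_PV, _PYR] = 8.0
    w[_VIP, _SST] = 0.5
    w[_VIP, _PV] = 0.5
    return w


@dataclass(frozen=True)
class CircuitConfig:
    """Structural and dynamical parameters of the reduced microcircuit.

    Connection probabilities and peak conductances are 4x4 tables in
    population order (Pyr, SST, PV, VIP), presynaptic rows. Neuron
    parameters are per-population tuples in the same order.
    """

    n_total: int = 1000
    proportions: tuple = (0.80, 0.05, 0.07, 0.08)
    conn_prob: np.ndarray = field(default_factory=_default_conn_prob)
    w_ampa: np.ndarray = field(default_factory=_default_w_ampa)  # nS peak
    w_nmda: np.ndarray = field(default_factory=_default_w_nmda)
    w_gaba: np.ndarray = field(default_factory=_default_w_gaba)
    # membrane: capacitance pF, leak nS, leak reversal, threshold, reset (mV), refractory ms
    capacitance: tuple = (150.0, 100.0, 100.0, 80.0)
    g_leak: tuple = (7.5, 5.0, 10.0, 5.0)
    e_leak: tuple = (-70.0, -65.0, -67.0, -65.0)
    v_thresh: tuple = (-50.0, -47.0, -47.5, -47.0)
    v_reset: tuple = (-60.0, -57.0, -57.0, -57.0)
    t_refrac: tuple = (3.0, 2.0, 1.5, 2.0)
    # spike-frequency adaptation: conductance increment per spike (nS) and
    # decay time (ms); adaptation terminates stimulus-evoked reverberation
    adapt_b: tuple = (0.12, 0.05, 0.0, 0.05)
    adapt_tau: tuple = (250.0, 150.0, 150.0, 150.0)
    e_adapt: float = -90.0  # mV
    ou: tuple = (
        OUDrive(1.50, 1.65),
        OUDrive(1.60, 1.00),
        OUDrive(0.60, 0.60),
        OUDrive(0.90, 0.80),
    )
    kinetics: SynapseKinetics = field(default_factory=SynapseKinetics)
    e_exc: float = 0.0  # mV
    e_inh: float = -80.0
    dt: float = 0.05  # ms
    dipole_fs: float = 2000.0  # Hz, decimated output rate
    # signed depth offsets (μm) per synaptic current class on Pyr neurons
    z_basal: float = -150.0
    z_apical_sst: float = 300.0
    z_ou: float = 150.0
    stim_nmda_ratio: float = 2.0  # NMDA:AMPA peak ratio of stimulus synapses
    # somatic efficacy of stimulus synapses: the protocol's conductances are
    # dendritic values; on a point neuron they are scaled down to emulate
    # dendritic attenuation
    stim_gain: float = 0.3
    # common alpha-band drive to Pyr neurons: a noise-driven damped resonator
    # modulating the OU conductance coherently across cells, emulating the
    # rhythmic (thalamocortical) input that a reduced L2/3 network does not
    # generate intrinsically
    alpha_freq: float = 10.0  # Hz
    alpha_damping: float = 0.15  # relative damping ζ (bandwidth ≈ 2ζf)
    alpha_gain: float = 0.25  # nS per unit-variance resonator state
    #: network size at which the conductance tables are calibrated;
    #: recurrent weights scale by weight_ref_n / n_total so the mean input
    #: per neuron is invariant to the simulated circuit size
    weight_ref_n: int = 1000

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("population proportions must sum to 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class StimulusEntry:
    """Stimulation of one target population."""

    pop: str
    n_targets: int
    delay_ms: tuple  # (lo, hi) uniform per-neuron delay after stimulus onset
    gmax_ns: float
    n_syn: int = 1


@dataclass(frozen=True)
class StimulusSpec:
    """A stimulus protocol: entries per target population."""

    name: str
    entries: tuple

    def entry_for(self, pop: str) -> StimulusEntry | None:
        for e in self.entries:
            if e.pop == pop:
                return e
        return None


def brief_stimulus() -> StimulusSpec:
    """Brief feedforward stimulus: basal excitation of 55 Pyr (4 nS,
    2-4 ms delay), 35 PV (2 nS, 2-2.5 ms), and two VIP phases — early
    (65 cells, 2.8 nS, 2-2.5 ms) and late (80 cells, 2.2 nS, 7-12 ms)."""
    return StimulusSpec(
        name="brief",
        entries=(
            StimulusEntry("Pyr", 55, (2.0, 4.0), 4.0),
            StimulusEntry("PV", 35, (2.0, 2.5), 2.0),
            StimulusEntry("VIP_early", 65, (2.0, 2.5), 2.8),
            StimulusEntry("VIP_late", 80, (7.0, 12.0), 2.2),
        ),
    )


def strong_stimulus() -> StimulusSpec:
    """Stronger, de-correlated stimulus promoting recurrent activity:
    PV stimulation removed (less feedforward inhibition), VIP conductances
    doubled (more disinhibition), and Pyr excitation prolonged
    (2-22 ms delays, doubled synapse count, 2 nS)."""
    return StimulusSpec(
        name="strong",
        entries=(
            StimulusEntry("Pyr", 55, (2.0, 22.0), 2.0, n_syn=2),
            StimulusEntry("VIP_early", 65, (2.0, 2.5), 5.6),
            StimulusEntry("VIP_late", 80, (7.0, 12.0), 4.4),
        ),
    )


@dataclass
class SpikeData:
    """Spike times (ms) with population labels and stimulus markers."""

    times_ms: np.ndarray
    neuron_ids: np.ndarray
    pop_idx: np.ndarray  # per-neuron population index into POP_NAMES
    duration_ms: float
    stim_times_ms: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_neurons(self) -> int:
        return self.pop_idx.size

    def population_mask(self, pop: str) -> np.ndarray:
        return self.pop_idx == POP_NAMES.index(pop)

    def population_spikes(self, pop: str) -> np.ndarray:
        """Spike times of all neurons in one population, sorted."""
        mask = self.population_mask(pop)[self.neuron_ids]
        return np.sort(self.times_ms[mask])

    def population_rate(self, pop: str, t0: float = 0.0, t1: float | None = None) -> float:
        """Mean per-neuron firing rate (Hz) of a population in [t0, t1)."""
        t1 = self.duration_ms if t1 is None else t1
        st = self.population_spikes(pop)
        n = int(self.population_mask(pop).sum())
        if n == 0 or t1 <= t0:
            return 0.0
        count = int(np.sum((st >= t0) & (st < t1)))
        return count / n / ((t1 - t0) * 1e-3)

    def isi_cv(self, pop: str = "Pyr") -> float:
        """Mean coefficient of variation of inter-spike intervals across
        neurons of a population (neurons with ≥ 3 spikes)."""
        mask = self.population_mask(pop)
        cvs = []
        for nid in np.flatnonzero(mask):
            t = np.sort(self.times_ms[self.neuron_ids == nid])
            if t.size >= 3:
                isi = np.diff(t)
                if isi.mean() > 0:
                    cvs.append(isi.std() / isi.mean())
        return float(np.mean(cvs)) if cvs else float("nan")


@dataclass
class DipoleTrace:
    """Current-dipole moment time series (nA·μm) along the depth axis."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dipole trace contains non-finite samples")


@dataclass
class Circuit:
    """A realized network: neuron arrays and connectivity matrices."""

    config: CircuitConfig
    profile: AgingProfile
    seed: int
    pop_idx: np.ndarray  # (N,) int32
    counts: dict
    W_ampa: np.ndarray  # (N, N) presyn rows, peak nS
    W_nmda: np.ndarray
    W_gabaA: np.ndarray  # SST→Pyr (apical)
    W_gabaB: np.ndarray  # other GABA (basal / interneuron targets)
    capacitance: np.ndarray
    g_leak: np.ndarray
    e_leak: np.ndarray
    v_thresh: np.ndarray
    v_reset: np.ndarray
    refrac_ms: np.ndarray
    ou_mean: np.ndarray
    ou_sd: np.ndarray
    ou_tau: np.ndarray
    adapt_b: np.ndarray
    adapt_tau: np.ndarray

    @property
    def n_neurons(self) -> int:
        return self.pop_idx.size

    def neurons_of(self, pop: str) -> np.ndarray:
        return np.flatnonzero(self.pop_idx == POP_NAMES.index(pop))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def build_circuit(config: CircuitConfig, profile: AgingProfile, seed: int) -> Circuit:
    """Instantiate a randomized circuit under an aging profile.

    Interneuron counts are scaled by survival fractions (round half up,
    floored at one cell with a warning); NMDA conductances onto Pyr by the
    NMDA multiplier; Pyr→Pyr connection probability by the spine-loss
    multiplier; Pyr leak and capacitance by the passive multiplier.
    Connectivity is Bernoulli per ordered pair, no self-connections,
    deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    base_counts = [_round_half_up(p * config.n_total) for p in config.proportions]
    # population order (Pyr, SST, PV, VIP)
    survival = [1.0, profile.sst_survival, profile.pv_survival, profile.vip_survival]
    counts = {}
    for k, name in enumerate(POP_NAMES):
        c = _round_half_up(base_counts[k] * survival[k])
        if c < 1:
            warnings.warn(f"{name} count scaled below 1; flooring at 1")
            c = 1
        counts[name] = c
    n = sum(counts.values())
    pop_idx = np.concatenate(
        [np.full(counts[name], k, dtype=np.int32) for k, name in enumerate(POP_NAMES)]
    )

    conn_p = np.array(config.conn_prob, dtype=float).copy()
    conn_p[_PYR, _PYR] *= profile.pyr_pyr_connection_multiplier

    wscale = config.weight_ref_n / config.n_total
    w_ampa = np.array(config.w_ampa, dtype=float) * wscale
    w_gaba = np.array(config.w_gaba, dtype=float) * wscale
    w_nmda = np.array(config.w_nmda, dtype=float) * wscale
    w_nmda[:, _PYR] *= profile.nmda_multiplier

    W_ampa = np.zeros((n, n))
    W_nmda = np.zeros((n, n))
    W_gabaA = np.zeros((n, n))
    W_gabaB = np.zeros((n, n))
    slices = {}
    off = 0
    for k, name in enumerate(POP_NAMES):
        slices[k] = slice(off, off + counts[name])
        off += counts[name]
    for pre in range(4):
        for post in range(4):
            p = conn_p[pre, post]
            if p <= 0:
                continue
            sl_pre, sl_post = slices[pre], slices[post]
            mask = rng.random((sl_pre.stop - sl_pre.start, sl_post.stop - sl_post.start)) < p
            if pre == post:
                np.fill_diagonal(mask, False)
            if w_ampa[pre, post] > 0:
                W_ampa[sl_pre, sl_post] = mask * w_ampa[pre, post]
            if w_nmda[pre, post] > 0:
                W_nmda[sl_pre, sl_post] = mask * w_nmda[pre, post]
            if w_gaba[pre, post] > 0:
                if pre == _SST and post == _PYR:
                    W_gabaA[sl_pre, sl_post] = mask * w_gaba[pre, post]
                else:
                    W_gabaB[sl_pre, sl_post] = mask * w_gaba[pre, post]

    per = lambda tup: np.array([tup[k] for k in pop_idx], dtype=float)
    capacitance = per(config.capacitance)
    g_leak = per(config.g_leak)
    pyr_mask = pop_idx == _PYR
    capacitance[pyr_mask] *= profile.passive_multiplier
    g_leak[pyr_mask] *= profile.passive_multiplier

    return Circuit(
        config=config,
        profile=profile,
        seed=seed,
        pop_idx=pop_idx,
        counts=counts,
        W_ampa=W_ampa,
        W_nmda=W_nmda,
        W_gabaA=W_gabaA,
        W_gabaB=W_gabaB,
        capacitance=capacitance,
        g_leak=g_leak,
        e_leak=per(config.e_leak),
        v_thresh=per(config.v_thresh),
        v_reset=per(config.v_reset),
        refrac_ms=per(config.t_refrac),
        ou_mean=per(tuple(o.mean for o in config.ou)),
        ou_sd=per(tuple(o.sd for o in config.ou)),
        ou_tau=per(tuple(o.tau for o in config.ou)),
        adapt_b=per(config.adapt_b),
        adapt_tau=per(config.adapt_tau),
    )


def _dexp_norm(tau_r: float, tau_d: float) -> float:
    """Peak normalization for a difference-of-exponentials conductance."""
    tp = tau_r * tau_d / (tau_d - tau_r) * math.log(tau_d / tau_r)
    return 1.0 / (math.exp(-tp / tau_d) - math.exp(-tp / tau_r))


@njit(cache=True)
def _run_network(
    n_steps,
    dt,
    seed,
    C,
    gL,
    EL,
    Vth,
    Vres,
    ref_steps,
    ou_mean,
    ou_sd,
    ou_a,
    ou_b,
    ad_b,
    ad_decay,
    e_adapt,
    Wa,
    Wn,
    WgA,
    WgB,
    is_pyr,
    fa_d,
    fa_r,
    fn_d,
    fn_r,
    fg_d,
    fg_r,
    na,
    nn,
    ng,
    e_exc,
    e_inh,
    mg_b,
    mg_k,
    stim_step,
    stim_neuron,
    stim_ga,
    stim_gn,
    alpha_w,
    alpha_zeta,
    alpha_gain,
    z_bas,
    z_api,
    z_ou,
    decim,
    dipole_out,
    spike_t,
    spike_i,
):
    np.random.seed(seed)
    n = C.size
    V = EL.copy()
    g_ou = ou_mean.copy()
    a_d = np.zeros(n)
    a_r = np.zeros(n)
    nm_d = np.zeros(n)
    nm_r = np.zeros(n)
    gA_d = np.zeros(n)
    gA_r = np.zeros(n)
    gB_d = np.zeros(n)
    gB_r = np.zeros(n)
    g_adapt = np.zeros(n)
    refrac = np.zeros(n, dtype=np.int64)
    spiked = np.empty(n, dtype=np.int64)
    n_spiked = 0
    n_spikes = 0
    max_spikes = spike_t.size
    sp = 0  # stimulus event pointer
    m_stim = stim_step.size
    dip_acc = 0.0
    dip_count = 0
    out_i = 0
    ax = 0.0  # alpha resonator state (unit variance)
    av = 0.0
    a_sig = math.sqrt(4.0 * alpha_zeta * alpha_w**3)

    for step in range(n_steps):
        # common alpha-band drive (shared across Pyr cells)
        anoise = np.random.standard_normal()
        av += dt * (-2.0 * alpha_zeta * alpha_w * av - alpha_w * alpha_w * ax) \
            + a_sig * math.sqrt(dt) * anoise
        ax += dt * av
        g_alpha = alpha_gain * ax
        # OU conductance (exact discretization), floored at 0 when applied
        xi = np.random.standard_normal(n)
        for i in range(n):
            g_ou[i] = ou_mean[i] + (g_ou[i] - ou_mean[i]) * ou_a[i] + ou_b[i] * xi[i]

        # synaptic state decay (+ adaptation decay)
        for i in range(n):
            g_adapt[i] *= ad_decay[i]
            a_d[i] *= fa_d
            a_r[i] *= fa_r
            nm_d[i] *= fn_d
            nm_r[i] *= fn_r
            gA_d[i] *= fg_d
            gA_r[i] *= fg_r
            gB_d[i] *= fg_d
            gB_r[i] *= fg_r

        # deliver spikes from previous step
        for k in range(n_spiked):
            j = spiked[k]
            for i in range(n):
                wa = Wa[j, i]
                if wa > 0.0:
                    a_d[i] += wa * na
                    a_r[i] += wa * na
                wn = Wn[j, i]
                if wn > 0.0:
                    nm_d[i] += wn * nn
                    nm_r[i] += wn * nn
                w = WgA[j, i]
                if w > 0.0:
                    gA_d[i] += w * ng
                    gA_r[i] += w * ng
                w = WgB[j, i]
                if w > 0.0:
                    gB_d[i] += w * ng
                    gB_r[i] += w * ng
        n_spiked = 0

        # stimulus events scheduled for this step
        while sp < m_stim and stim_step[sp] == step:
            i = stim_neuron[sp]
            a_d[i] += stim_ga[sp] * na
            a_r[i] += stim_ga[sp] * na
            nm_d[i] += stim_gn[sp] * nn
            nm_r[i] += stim_gn[sp] * nn
            sp += 1

        # currents, dipole, membrane update, spike detection
        dip = 0.0
        for i in range(n):
            v = V[i]
            ga = a_d[i] - a_r[i]
            gn = nm_d[i] - nm_r[i]
            gia = gA_d[i] - gA_r[i]
            gib = gB_d[i] - gB_r[i]
            gou = g_ou[i] + g_alpha if is_pyr[i] else g_ou[i]
            if gou < 0.0:
                gou = 0.0
            mg = 1.0 / (1.0 + mg_b * math.exp(-mg_k * v))
            i_exc = (ga + gn * mg) * (v - e_exc)
            i_inh_a = gia * (v - e_inh)
            i_inh_b = gib * (v - e_inh)
            i_ou = gou * (v - e_exc)
            if is_pyr[i]:
                dip += z_bas * (i_exc + i_inh_b) + z_api * i_inh_a + z_ou * i_ou
            if refrac[i] > 0:
                refrac[i] -= 1
                V[i] = Vres[i]
                continue
            dv = (
                -gL[i] * (v - EL[i])
                - i_exc
                - i_inh_a
                - i_inh_b
                - i_ou
                - g_adapt[i] * (v - e_adapt)
            ) * dt / C[i]
            v += dv
            if not math.isfinite(v):
                return -step - 1  # integration blew up; caller raises
            if v >= Vth[i]:
                V[i] = Vres[i]
                refrac[i] = ref_steps[i]
                g_adapt[i] += ad_b[i]
                spiked[n_spiked] = i
                n_spiked += 1
                if n_spikes < max_spikes:
                    spike_t[n_spikes] = step * dt
                    spike_i[n_spikes] = i
                n_spikes += 1
            else:
                V[i] = v

        dip_acc += dip
        dip_count += 1
        if dip_count == decim:
            if out_i < dipole_out.size:
                dipole_out[out_i] = dip_acc / decim * 1e-3  # pA·μm → nA·μm
                out_i += 1
            dip_acc = 0.0
            dip_count = 0

    return n_spikes


def _build_stim_events(
    circuit: Circuit,
    stimulus: StimulusSpec,
    stim_times_ms: np.ndarray,
    rng: np.random.Generator,
    dt: float,
):
    """Expand a stimulus protocol into per-step synaptic events.

    Target neurons are a fixed random subset per entry (chosen once per
    circuit); per-neuron delays are redrawn uniformly each trial. The NMDA
    component of stimulus synapses onto Pyr neurons is scaled by the
    profile's NMDA multiplier.
    """
    steps, neurons, gas, gns = [], [], [], []
    ratio = circuit.config.stim_nmda_ratio
    for entry in stimulus.entries:
        pop = "VIP" if entry.pop.startswith("VIP") else entry.pop
        cells = circuit.neurons_of(pop)
        n_tgt = min(entry.n_targets, cells.size)
        targets = rng.choice(cells, size=n_tgt, replace=False)
        nmda_scale = circuit.profile.nmda_multiplier if pop == "Pyr" else 1.0
        g = entry.gmax_ns * entry.n_syn * circuit.config.stim_gain
        for t0 in stim_times_ms:
            delays = rng.uniform(entry.delay_ms[0], entry.delay_ms[1], size=n_tgt)
            for i, d in zip(targets, delays):
                steps.append(int(round((t0 + d) / dt)))
                neurons.append(i)
                gas.append(g)
                gns.append(g * ratio * nmda_scale)
    if not steps:
        return (
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            np.empty(0),
            np.empty(0),
        )
    order = np.argsort(np.asarray(steps), kind="stable")
    return (
        np.asarray(steps, dtype=np.int64)[order],
        np.asarray(neurons, dtype=np.int64)[order],
        np.asarray(gas, dtype=float)[order],
        np.asarray(gns, dtype=float)[order],
    )


def simulate(
    circuit: Circuit,
    duration_ms: float,
    stimulus: StimulusSpec | None = None,
    n_trials: int = 0,
    stim_start_ms: float = 3500.0,
    stim_interval_ms: float = 500.0,
    seed: int = 0,
    max_rate_hz: float = 200.0,
) -> tuple[SpikeData, DipoleTrace]:
    """Integrate the network for ``duration_ms`` and return spikes + dipole.

    With a stimulus, ``n_trials`` stimulus onsets are placed every
    ``stim_interval_ms`` starting at ``stim_start_ms``. Fixed-step Euler
    integration at the config's ``dt``; the dipole trace is boxcar-averaged
    down to ``dipole_fs``. Deterministic in ``seed``.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    cfg = circuit.config
    dt = cfg.dt
    n_steps = int(round(duration_ms / dt))
    decim = max(1, int(round(1000.0 / cfg.dipole_fs / dt)))
    n_out = n_steps // decim

    if stimulus is not None and n_trials > 0:
        stim_times = stim_start_ms + stim_interval_ms * np.arange(n_trials)
        if stim_times[-1] + 100.0 > duration_ms:
            raise ValueError("duration too short for the requested stimulus trials")
    else:
        stim_times = np.empty(0)

    rng = np.random.default_rng(seed)
    stim_step, stim_neuron, stim_ga, stim_gn = _build_stim_events(
        circuit, stimulus, stim_times, rng, dt
    ) if stimulus is not None and n_trials > 0 else (
        np.empty(0, dtype=np.int64),
        np.empty(0, dtype=np.int64),
        np.empty(0),
        np.empty(0),
    )

    kin = cfg.kinetics
    fa_d = math.exp(-dt / kin.ampa_decay)
    fa_r = math.exp(-dt / kin.ampa_rise)
    fn_d = math.exp(-dt / kin.nmda_decay)
    fn_r = math.exp(-dt / kin.nmda_rise)
    fg_d = math.exp(-dt / kin.gaba_decay)
    fg_r = math.exp(-dt / kin.gaba_rise)
    na = _dexp_norm(kin.ampa_rise, kin.ampa_decay)
    nn = _dexp_norm(kin.nmda_rise, kin.nmda_decay)
    ng = _dexp_norm(kin.gaba_rise, kin.gaba_decay)

    alpha_w = 2.0 * math.pi * cfg.alpha_freq / 1000.0  # rad/ms
    tau = circuit.ou_tau
    ou_a = np.exp(-dt / tau)
    ou_b = circuit.ou_sd * np.sqrt(1.0 - ou_a**2)
    ref_steps = np.maximum(1, np.round(circuit.refrac_ms / dt)).astype(np.int64)

    max_spikes = int(circuit.n_neurons * duration_ms * 1e-3 * max_rate_hz) + 1000
    spike_t = np.empty(max_spikes)
    spike_i = np.empty(max_spikes, dtype=np.int64)
    dipole_out = np.empty(n_out)

    kernel_seed = int(rng.integers(0, 2**31 - 1))
    n_spikes = _run_network(
        n_steps,
        dt,
        kernel_seed,
        circuit.capacitance,
        circuit.g_leak,
        circuit.e_leak,
        circuit.v_thresh,
        circuit.v_reset,
        ref_steps,
        circuit.ou_mean,
        circuit.ou_sd,
        ou_a,
        ou_b,
        circuit.adapt_b,
        np.exp(-dt / circuit.adapt_tau),
        cfg.e_adapt,
        circuit.W_ampa,
        circuit.W_nmda,
        circuit.W_gabaA,
        circuit.W_gabaB,
        circuit.pop_idx == _PYR,
        fa_d,
        fa_r,
        fn_d,
        fn_r,
        fg_d,
        fg_r,
        na,
        nn,
        ng,
        cfg.e_exc,
        cfg.e_inh,
        kin.mg_conc_factor,
        kin.mg_slope,
        stim_step,
        stim_neuron,
        stim_ga,
        stim_gn,
        alpha_w,
        cfg.alpha_damping,
        cfg.alpha_gain,
        cfg.z_basal,
        cfg.z_apical_sst,
        cfg.z_ou,
        decim,
        dipole_out,
        spike_t,
        spike_i,
    )
    if n_spikes < 0:
        raise RuntimeError(
            f"non-finite membrane state at integration step {-n_spikes - 1}"
        )
    if n_spikes > max_spikes:
        raise RuntimeError(
            f"spike buffer overflow ({n_spikes} spikes > cap {max_spikes}); "
            "raise max_rate_hz"
        )
    spikes = SpikeData(
        times_ms=spike_t[:n_spikes].copy(),
        neuron_ids=spike_i[:n_spikes].copy(),
        pop_idx=circuit.pop_idx.copy(),
        duration_ms=duration_ms,
        stim_times_ms=stim_times,
    )
    return spikes, DipoleTrace(values=dipole_out, fs=cfg.dipole_fs)


def replay_dipole(circuit: Circuit, spikes: SpikeData, weight_scale: float = 1.0) -> DipoleTrace:
    """Open-loop dipole reconstruction from frozen spike trains.

    Re-derives the per-class synaptic conductance time courses implied by
    the given spike trains and converts them to currents at the resting
    driving force of Pyr neurons (membrane voltage held at leak reversal).
    By construction the result is exactly linear in the synaptic weights,
    which is the open-loop counterpart of the dipole's linearity in
    synaptic currents. The OU drive is excluded (it is not spike-mediated).
    """
    from scipy.signal import lfilter

    cfg = circuit.config
    kin = cfg.kinetics
    fs = cfg.dipole_fs
    dt_out = 1000.0 / fs  # ms
    n_out = int(round(spikes.duration_ms / dt_out))
    pyr_cols = circuit.pop_idx == _PYR
    v_rest = cfg.e_leak[_PYR]

    # per-presynaptic-neuron total weight onto Pyr cells, per channel
    w_eff = {
        "ampa": circuit.W_ampa[:, pyr_cols].sum(axis=1),
        "nmda": circuit.W_nmda[:, pyr_cols].sum(axis=1),
        "gabaA": circuit.W_gabaA[:, pyr_cols].sum(axis=1),
        "gabaB": circuit.W_gabaB[:, pyr_cols].sum(axis=1),
    }
    taus = {
        "ampa": (kin.ampa_rise, kin.ampa_decay),
        "nmda": (kin.nmda_rise, kin.nmda_decay),
        "gabaA": (kin.gaba_rise, kin.gaba_decay),
        "gabaB": (kin.gaba_rise, kin.gaba_decay),
    }
    mg = 1.0 / (1.0 + kin.mg_conc_factor * math.exp(-kin.mg_slope * v_rest))
    drive = {
        "ampa": (v_rest - cfg.e_exc) * cfg.z_basal,
        "nmda": (v_rest - cfg.e_exc) * mg * cfg.z_basal,
        "gabaA": (v_rest - cfg.e_inh) * cfg.z_apical_sst,
        "gabaB": (v_rest - cfg.e_inh) * cfg.z_basal,
    }

    bins = np.floor(spikes.times_ms / dt_out).astype(int)
    valid = bins < n_out
    dip = np.zeros(n_out)
    for ch, w in w_eff.items():
        drv = np.zeros(n_out)
        np.add.at(drv, bins[valid], weight_scale * w[spikes.neuron_ids[valid]])
        tr, td = taus[ch]
        norm = _dexp_norm(tr, td)
        ad = math.exp(-dt_out / td)
        ar = math.exp(-dt_out / tr)
        g = norm * (lfilter([1.0], [1.0, -ad], drv) - lfilter([1.0], [1.0, -ar], drv))
        dip += g * drive[ch]
    return DipoleTrace(values=dip * 1e-3, fs=fs)  # pA·μm → nA·μm
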