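"""Forward-Euler simulation of the LIF/AdEx network with synaptic delays.

Model
-----
The network holds 300 excitatory (E) and 75 inhibitory (I) units plus 3
readout ("output") units.  Subthreshold membrane dynamics are

    C dv/dt = -gL (v - EL) + (g_e - g_i) * V_unit + I_ext(t, i)

for LIF units; AdEx units add the exponential spike-initiation term
``gL DeltaT exp((v - VT)/DeltaT)`` and subtract an adaptation current ``w``
with ``tau_w dw/dt = a (v - EL) - w`` and a spike-triggered jump ``w += b``.
Synapses carry no driving force: conductances are converted to currents by
multiplication with one volt.  After a presynaptic spike the conductance
jumps by the (delayed) connection weight and then decays exponentially,
``dg/dt = -g / tau``.

Spiking is threshold-reset: LIF units fire at ``v >= VT``; AdEx units fire at
a cut voltage ``VT + 5 DeltaT`` (the exponential term is clamped there to
avoid overflow).  After a spike the unit sits at ``V_reset`` for the
refractory period.  Input currents are injected into E units only; output
units are always LIF, whatever the hidden-layer model, and their membrane
voltage traces are the network's analog readout.

Integration is plain forward Euler at the stimulus resolution (0.1 ms by
default); spikes occurring in distinct units within one step are all
delivered.  The simulation is fully deterministic given configuration and
stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .connectivity import WeightSet
from .signal_gen import SignalSet

__all__ = [
    "NeuronParams",
    "UnitClassConfig",
    "SimResult",
    "unit_class",
    "UNIT_CLASSES",
    "simulate",
    "fi_curve",
    "firing_rate",
    "rheobase",
    "lif_rate_closed_form",
]

#: Conversion factor from synaptic conductance to current (volts).
V_UNIT = 1.0


@dataclass(frozen=True)
class NeuronParams:
    """Membrane, adaptation and synaptic parameters of one population.

    Units: C pF, gL nS, voltages mV, times ms, a nS, b pA.
    """

    C: float = 125.0
    gL: float = 4.0
    EL: float = -70.0
    VT: float = -50.0
    V_reset: float | None = None  # None -> EL
    t_ref: float = 2.0
    DeltaT: float = 2.0  # AdEx slope factor (mV)
    a: float = 0.0  # subthreshold adaptation (nS)
    b: float = 5000.0  # spike-triggered adaptation (pA)
    tau_w: float = 500.0  # adaptation time constant (ms)
    tau_syn_e: float = 5.0
    tau_syn_i: float = 5.0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.gL < 0:
            raise ValueError("gL must be nonnegative")
        if min(self.tau_syn_e, self.tau_syn_i, self.tau_w) <= 0:
            raise ValueError("time constants must be positive")
        if self.t_ref < 0:
            raise ValueError("t_ref must be nonnegative")

    @property
    def v_reset(self) -> float:
        return self.EL if self.V_reset is None else self.V_reset

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/gL in ms."""
        return self.C / self.gL


@dataclass(frozen=True)
class UnitClassConfig:
    """Named parameter regime: NeuronParams per population plus delays."""

    name: str
    e: NeuronParams
    i: NeuronParams
    out: NeuronParams
    delay_ei_ms: float = 3.0
    delay_out_ms: float = 3.0
    model: str = "lif"

    def __post_init__(self) -> None:
        if self.model not in ("lif", "adex"):
            raise ValueError(f"model must be 'lif' or 'adex', got {self.model!r}")


# AdEx adaptation presets are network-calibrated, not literature values: the
# adapting (E) units carry strong spike-triggered adaptation and the
# fast-spiking-like (I) units a weak, sharper-onset one, chosen so the AdEx
# network at the Comrade start point fires at roughly a quarter of the LIF
# rate (see scripts/calibrate.py).  Every field is overridable.
_I_ADAPT = {"DeltaT": 0.5, "a": 0.0, "b": 1000.0, "tau_w": 200.0}


def _comrade() -> UnitClassConfig:
    # One parameter set for E, I and output units; output tau_m = 31.25 ms.
    p = NeuronParams()
    return UnitClassConfig("Comrade", e=p, i=replace(p, **_I_ADAPT), out=p,
                           delay_ei_ms=0.5)


def _bacon() -> UnitClassConfig:
    # Literature-style values: regular-spiking pyramidal E, fast basket-like I.
    e = NeuronParams(C=90.0, gL=5.0, EL=-72.0, VT=-53.0)
    i = NeuronParams(C=60.0, gL=12.0, EL=-72.0, VT=-52.0, **_I_ADAPT)
    return UnitClassConfig("Bacon", e=e, i=i, out=NeuronParams(),
                           delay_ei_ms=0.5)


def _hifi() -> UnitClassConfig:
    # Comrade with fast, leaky output units: gL 4 -> 40 nS, delay 3 -> 1 ms,
    # so the output tau_m drops from 31.25 ms to 3.125 ms.
    p = NeuronParams()
    return UnitClassConfig("HiFi", e=p, i=replace(p, **_I_ADAPT),
                           out=replace(p, gL=40.0),
                           delay_ei_ms=0.5, delay_out_ms=1.0)


UNIT_CLASSES = {"Comrade": _comrade, "Bacon": _bacon, "HiFi": _hifi}


def unit_class(name: str, model: str = "lif", **overrides: Any) -> UnitClassConfig:
    """Fetch a named unit-class preset, optionally overriding fields.

    Overrides may address top-level fields (``delay_ei_ms=5``) or population
    parameters via ``e=``/``i=``/``out=`` dicts merged into the preset.
    """
    try:
        cfg = UNIT_CLASSES[name]()
    except KeyError:
        raise ValueError(
            f"unknown unit class {name!r}; available: {sorted(UNIT_CLASSES)}"
        ) from None
    pop_over = {}
    for pop in ("e", "i", "out"):
        if pop in overrides:
            pop_over[pop] = replace(getattr(cfg, pop), **overrides.pop(pop))
    return replace(cfg, model=model, **pop_over, **overrides)


@dataclass(frozen=True)
class SimResult:
    """Spike trains per population plus output membrane traces.

    ``spikes[pop]`` is an ``(n_spikes, 2)`` float array of (unit index,
    spike time ms) rows, for ``pop`` in {"e", "i", "out"}.  ``vm_out`` holds
    the output-unit membrane traces in mV.
    """

    spikes: dict[str, np.ndarray]
    vm_out: SignalSet
    n_units: dict[str, int]
    duration_ms: float
    provenance: dict[str, Any] = field(default_factory=dict)
    traces: dict[str, np.ndarray] = field(default_factory=dict)

    def spike_count(self, population: str) -> int:
        return len(self.spikes[population])


class _Population:
    """Mutable Euler state of one population (SI units internally)."""

    def __init__(self, n: int, p: NeuronParams, model: str, dt_s: float):
        self.n = n
        self.model = model
        self.C = p.C * 1e-12
        self.gL = p.gL * 1e-9
        self.EL = p.EL * 1e-3
        self.VT = p.VT * 1e-3
        self.V_reset = p.v_reset * 1e-3
        self.DeltaT = p.DeltaT * 1e-3
        self.a = p.a * 1e-9
        self.b = p.b * 1e-12
        self.tau_w = p.tau_w * 1e-3
        self.ref_steps = int(round(p.t_ref * 1e-3 / dt_s))
        self.dt = dt_s
        self.decay_e = 1.0 - dt_s / (p.tau_syn_e * 1e-3)
        self.decay_i = 1.0 - dt_s / (p.tau_syn_i * 1e-3)
        self.v = np.full(n, self.EL)
        self.ge = np.zeros(n)
        self.gi = np.zeros(n)
        self.w = np.zeros(n)
        self.ref = np.zeros(n, dtype=np.int64)
        # AdEx spike detection happens at a cut voltage above VT; the
        # exponential term is clamped there to keep Euler steps finite.
        self.v_cut = self.VT + 5.0 * self.DeltaT if model == "adex" else self.VT

    def step(self, i_ext: np.ndarray | float) -> np.ndarray:
        """Advance one Euler step; return indices of units spiking this step."""
        active = self.ref == 0
        syn = (self.ge - self.gi) * V_UNIT
        if self.model == "adex":
            exp_term = self.gL * self.DeltaT * np.exp(
                np.minimum((self.v - self.VT) / self.DeltaT, 5.0)
            )
            dv = (-self.gL * (self.v - self.EL) + exp_term - self.w + syn + i_ext) \
                / self.C
            self.w += self.dt * (self.a * (self.v - self.EL) - self.w) / self.tau_w
        else:
            dv = (-self.gL * (self.v - self.EL) + syn + i_ext) / self.C
        self.v = np.where(active, self.v + self.dt * dv, self.V_reset)
        np.maximum(self.ref - 1, 0, out=self.ref)
        spiking = np.flatnonzero(active & (self.v >= self.v_cut))
        if spiking.size:
            self.v[spiking] = self.V_reset
            self.ref[spiking] = self.ref_steps
            if self.model == "adex":
                self.w[spiking] += self.b
        self.ge *= self.decay_e
        self.gi *= self.decay_i
        return spiking


def simulate(
    cfg: UnitClassConfig,
    ws: WeightSet,
    inputs: SignalSet,
    duration_ms: float | None = None,
    dt_ms: float | None = None,
    seed: int = 0,
    record_traces: bool = False,
) -> SimResult:
    """Simulate the full network driven by the given input currents.

    Parameters
    ----------
    cfg : UnitClassConfig
        Membrane parameters and hidden-layer model ("lif" or "adex").
        Output units are integrated as LIF regardless.
    ws : WeightSet
        Physiologically scaled connectivity; its delays are used (they are
        the single shared EE/EI/IE/II delay plus the fixed E->Out delay).
    inputs : SignalSet
        n_in input current channels; injected into E units only, unit ``i``
        receiving ``sum_j ff[i, j] x_j(t)``.
    duration_ms, dt_ms : float, optional
        Default to the input signal's span and sampling interval.
    seed : int
        Recorded in provenance (the integration itself is deterministic).
    record_traces : bool
        Additionally record E/I state traces of unit 0 (diagnostics).
    """
    if not ws.scale_applied:
        raise ValueError("WeightSet must be physiologically scaled before simulation")
    if inputs.n_channels != ws.n_in:
        raise ValueError(
            f"inputs have {inputs.n_channels} channels but ff expects {ws.n_in}"
        )
    dt_ms = inputs.dt if dt_ms is None else dt_ms
    duration_ms = inputs.duration if duration_ms is None else duration_ms
    n_steps = int(round(duration_ms / dt_ms))
    if n_steps > inputs.n_samples:
        raise ValueError("inputs shorter than requested duration")
    dt_s = dt_ms * 1e-3

    d_ei = int(round(ws.delay_ei_ms / dt_ms))
    d_out = int(round(ws.delay_out_ms / dt_ms))
    if d_ei < 1 or d_out < 1:
        raise ValueError("synaptic delays must be at least one time step")

    pop_e = _Population(ws.n_e, cfg.e, cfg.model, dt_s)
    pop_i = _Population(ws.n_i, cfg.i, cfg.model, dt_s)
    pop_o = _Population(ws.n_out, cfg.out, "lif", dt_s)

    # Input currents precomputed for all steps: [n_e x n_steps].
    i_ext = ws.ff @ inputs.values[:, :n_steps]

    # Delay lines: one ring-buffer per (pathway, synapse variable).
    L = max(d_ei, d_out) + 1
    buf_ge_e = np.zeros((L, ws.n_e))  # E->E
    buf_gi_e = np.zeros((L, ws.n_e))  # I->E
    buf_ge_i = np.zeros((L, ws.n_i))  # E->I
    buf_gi_i = np.zeros((L, ws.n_i))  # I->I
    buf_s_o = np.zeros((L, ws.n_out))  # E->Out (signed)

    vm_out = np.empty((ws.n_out, n_steps))
    spikes: dict[str, list[tuple[int, float]]] = {"e": [], "i": [], "out": []}
    traces: dict[str, list[float]] = (
        {"v_e0": [], "ge_e0": [], "gi_e0": [], "w_e0": []} if record_traces else {}
    )

    for t in range(n_steps):
        slot = t % L
        pop_e.ge += buf_ge_e[slot]
        pop_e.gi += buf_gi_e[slot]
        pop_i.ge += buf_ge_i[slot]
        pop_i.gi += buf_gi_i[slot]
        pop_o.ge += buf_s_o[slot]  # signed drive rides the "excitatory" channel
        buf_ge_e[slot] = 0.0
        buf_gi_e[slot] = 0.0
        buf_ge_i[slot] = 0.0
        buf_gi_i[slot] = 0.0
        buf_s_o[slot] = 0.0

        sp_e = pop_e.step(i_ext[:, t])
        sp_i = pop_i.step(0.0)
        sp_o = pop_o.step(0.0)
        vm_out[:, t] = pop_o.v

        if sp_e.size:
            t_ms = t * dt_ms
            spikes["e"].extend((int(k), t_ms) for k in sp_e)
            slot_ei = (t + d_ei) % L
            buf_ge_e[slot_ei] += ws.ee[:, sp_e].sum(axis=1)
            buf_ge_i[slot_ei] += ws.ei[:, sp_e].sum(axis=1)
            buf_s_o[(t + d_out) % L] += ws.e_out[:, sp_e].sum(axis=1)
        if sp_i.size:
            t_ms = t * dt_ms
            spikes["i"].extend((int(k), t_ms) for k in sp_i)
            slot_ei = (t + d_ei) % L
            buf_gi_e[slot_ei] += ws.ie[:, sp_i].sum(axis=1)
            buf_gi_i[slot_ei] += ws.ii[:, sp_i].sum(axis=1)
        if sp_o.size:
            t_ms = t * dt_ms
            spikes["out"].extend((int(k), t_ms) for k in sp_o)

        if record_traces:
            traces["v_e0"].append(pop_e.v[0])
            traces["ge_e0"].append(pop_e.ge[0])
            traces["gi_e0"].append(pop_e.gi[0])
            traces["w_e0"].append(pop_e.w[0])

        if t % 256 == 0 and not np.isfinite(pop_e.v).all():
            raise FloatingPointError(
                f"non-finite membrane state at step {t} (t = {t * dt_ms} ms)"
            )

    if not (np.isfinite(vm_out).all() and np.isfinite(pop_e.v).all()):
        raise FloatingPointError("non-finite state at end of simulation")

    def _arr(rows: list[tuple[int, float]]) -> np.ndarray:
        return np.array(rows, dtype=float).reshape(-1, 2)

    return SimResult(
        spikes={k: _arr(v) for k, v in spikes.items()},
        vm_out=SignalSet(
            vm_out * 1e3,
            dt=dt_ms,
            t0=inputs.t0,
            meta={"kind": "vm_out", "unit": "mV", "seed": int(seed)},
        ),
        n_units={"e": ws.n_e, "i": ws.n_i, "out": ws.n_out},
        duration_ms=n_steps * dt_ms,
        provenance={
            "unit_class": cfg.name,
            "model": cfg.model,
            "seed": int(seed),
            "dt_ms": dt_ms,
            "delay_ei_ms": ws.delay_ei_ms,
            "delay_out_ms": ws.delay_out_ms,
            "weights_meta": dict(ws.meta),
        },
        traces={k: np.asarray(v) for k, v in traces.items()},
    )


def rheobase(params: NeuronParams) -> float:
    """Minimal constant current (A) driving a LIF unit to threshold."""
    return params.gL * 1e-9 * (params.VT - params.EL) * 1e-3


def lif_rate_closed_form(params: NeuronParams, current: float) -> float:
    """Stationary LIF firing rate (Hz) under constant suprathreshold current.

    ``1 / (t_ref + tau_m ln((I/gL + EL - V_reset) / (I/gL + EL - VT)))``;
    returns 0 below rheobase.
    """
    gL = params.gL * 1e-9
    if current <= rheobase(params):
        return 0.0
    v_inf = current / gL + params.EL * 1e-3
    tau = params.tau_m * 1e-3
    t_isi = params.t_ref * 1e-3 + tau * np.log(
        (v_inf - params.v_reset * 1e-3) / (v_inf - params.VT * 1e-3)
    )
    return 1.0 / t_isi


def fi_curve(
    params: NeuronParams,
    model: str = "lif",
    currents: "list[float] | np.ndarray" = (),
    step_duration_ms: float = 1000.0,
    dt_ms: float = 0.1,
) -> list[tuple[float, float]]:
    """f-I curve of one isolated unit: rate (Hz) versus step current (A).

    All current levels are integrated in parallel as independent synapse-free
    units; the rate is the spike count divided by the step duration.
    """
    currents = np.asarray(list(currents), dtype=float)
    if currents.size == 0:
        raise ValueError("currents must be non-empty")
    if np.any(np.diff(currents) < 0):
        raise ValueError("currents must be sorted ascending")
    dt_s = dt_ms * 1e-3
    pop = _Population(currents.size, params, model, dt_s)
    n_steps = int(round(step_duration_ms / dt_ms))
    counts = np.zeros(currents.size, dtype=np.int64)
    for _ in range(n_steps):
        spiking = pop.step(currents)
        counts[spiking] += 1
    rates = counts / (step_duration_ms * 1e-3)
    return list(zip(currents.tolist(), rates.tolist()))


def firing_rate(
    res: SimResult,
    population: str = "e",
    window: tuple[float, float] | None = None,
) -> float:
    """Population mean firing rate (Hz) within a time window (ms).

    Total spikes in the window divided by window length and population size.
    """
    n = res.n_units[population]
    if n == 0:
        raise ValueError(f"population {population!r} is empty")
    t_lo, t_hi = window if window is not None else (0.0, res.duration_ms)
    if not (0.0 <= t_lo < t_hi <= res.duration_ms + 1e-9):
        raise ValueError(f"window {window!r} outside simulated span")
    times = res.spikes[population][:, 1]
    count = int(np.count_nonzero((times >= t_lo) & (times < t_hi)))
    return count / ((t_hi - t_lo) * 1e-3 * n)
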