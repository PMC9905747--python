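"""Parameter-grid searches with repeated independent-noise iterations.

A search varies one membrane parameter (capacitance, leak conductance, leak
equilibrium potential or spike threshold — two-dimensionally, inhibitory x
excitatory) or the shared EE/EI/IE/II synaptic delay (one-dimensionally)
around a unit-class start point.  Every grid point is simulated for
``n_iterations`` iterations with independent noise; within an iteration one
connectivity (built from that iteration's seed) is shared by all grid
points, so differences across the grid reflect physiology only.  Each
(point, iteration) yields the four pairwise metric matrices and firing
rates; aggregation produces mean-matching values, accuracies and exact
binomial p-values Bonferroni-corrected over the grid.

Controls mirror the main experiment: a 6-input/6-output run guards against
ceiling effects (chance 1/6), and permuted-connectivity arms (EI-only and
all-pathways) measure how much of the transfer rests on the learned
structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from . import classify as cls
from . import connectivity as conn
from . import metrics as met
from . import network_sim as net
from . import signal_gen as sig

__all__ = [
    "SearchSpec",
    "SearchResult",
    "TABLE1_RANGES",
    "DEFAULT_NOISE_AMPLITUDE",
    "build_grid",
    "run_search",
    "run_control_6x6",
    "run_permutation_controls",
    "bin_by_firing_rate",
    "passband_scan",
    "simulate_trial",
]

logger = logging.getLogger(__name__)

#: Published search ranges (min, max, step) per parameter and population.
TABLE1_RANGES = {
    "C": {"i": (30.0, 270.0, 10.0), "e": (30.0, 130.0, 10.0)},
    "gL": {"i": (1.0, 28.0, 1.0), "e": (0.5, 15.0, 1.0)},
    "EL": {"i": (-85.0, -35.0, 5.0), "e": (-85.0, -20.0, 5.0)},
    "VT": {"i": (-65.0, -15.0, 3.0), "e": (-67.0, -35.0, 3.0)},
    "delay": {"shared": (0.5, 25.0, 0.25)},
}

#: White-noise standard deviation (current units, before 3 ms smoothing),
#: calibrated once (scripts/calibrate.py) so the Comrade LIF start point
#: fires in the 8-9 Hz band while the AdEx variant stays at 1-3 Hz.
DEFAULT_NOISE_AMPLITUDE = 15.0

_SEARCHABLE = ("C", "gL", "EL", "VT", "delay")
_CONN_MODES = ("structured", "initial", "permuted_ei", "permuted_all", "loaded")


@dataclass(frozen=True)
class SearchSpec:
    """Declarative description of one parameter search."""

    parameter: str = "gL"
    range_i: tuple[float, float, float] | None = None  # (min, max, step)
    range_e: tuple[float, float, float] | None = None
    unit_class: str = "Comrade"
    model: str = "lif"
    n_iterations: int = 10
    connectivity_mode: str = "structured"
    weights_path: str | None = None  # for mode "loaded"
    master_seed: int = 0
    n_channels: int = 3
    duration_ms: float = 2000.0
    dt_ms: float = 0.1
    trim_ms: float = 200.0
    sigma_ms: float = 3.0
    amplitude: float = DEFAULT_NOISE_AMPLITUDE
    max_lag_ms: float = 100.0
    alpha: float = 0.05
    overrides: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.parameter not in _SEARCHABLE:
            raise ValueError(
                f"parameter must be one of {_SEARCHABLE}, got {self.parameter!r}"
            )
        if self.connectivity_mode not in _CONN_MODES:
            raise ValueError(f"unknown connectivity mode {self.connectivity_mode!r}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass(frozen=True)
class SearchResult:
    """Aggregated records (one row per grid point) plus grid metadata."""

    spec: SearchSpec
    records: pd.DataFrame
    grid: list[tuple[float, ...]]
    classif: dict[tuple[float, ...], dict[str, cls.ClassifResult]]

    @property
    def n_points(self) -> int:
        return len(self.grid)


def _inclusive_range(lo: float, hi: float, step: float) -> np.ndarray:
    return np.arange(lo, hi + step / 2.0, step)


def build_grid(spec: SearchSpec) -> list[tuple[float, ...]]:
    """Inclusive arithmetic grid: 2D (inhibitory x excitatory) for membrane
    parameters, 1D for the shared synaptic delay."""
    if spec.parameter == "delay":
        lo, hi, step = spec.range_i or TABLE1_RANGES["delay"]["shared"]
        return [(float(v),) for v in _inclusive_range(lo, hi, step)]
    r_i = spec.range_i or TABLE1_RANGES[spec.parameter]["i"]
    r_e = spec.range_e or TABLE1_RANGES[spec.parameter]["e"]
    vals_i = _inclusive_range(*r_i)
    vals_e = _inclusive_range(*r_e)
    return [(float(vi), float(ve)) for vi in vals_i for ve in vals_e]


def _config_for_point(spec: SearchSpec, point: tuple[float, ...]) -> net.UnitClassConfig:
    """Unit-class config with the searched parameter applied to E/I units."""
    overrides = dict(spec.overrides)
    if spec.parameter != "delay":
        vi, ve = point
        overrides.setdefault("i", {})
        overrides.setdefault("e", {})
        overrides["i"] = {**overrides["i"], spec.parameter: vi}
        overrides["e"] = {**overrides["e"], spec.parameter: ve}
    return net.unit_class(spec.unit_class, model=spec.model, **overrides)


def _weights_for_iteration(spec: SearchSpec, cfg: net.UnitClassConfig,
                           w_seed: int, p_seed: int) -> conn.WeightSet:
    if spec.connectivity_mode == "loaded":
        if spec.weights_path is None:
            raise ValueError("connectivity_mode='loaded' requires weights_path")
        return conn.load_weights(spec.weights_path)
    base_mode = "initial" if spec.connectivity_mode == "initial" else "structured"
    ws = conn.build_default_weights(
        n_in=spec.n_channels,
        seed=w_seed,
        mode=base_mode,
        delay_ei_ms=cfg.delay_ei_ms,
        delay_out_ms=cfg.delay_out_ms,
    )
    if spec.connectivity_mode == "permuted_ei":
        ws = conn.permute_ei(ws, seed=p_seed)
    elif spec.connectivity_mode == "permuted_all":
        ws = conn.permute_all(ws, seed=p_seed)
    return ws


def simulate_trial(
    cfg: net.UnitClassConfig,
    ws: conn.WeightSet,
    noise_seed: int,
    n_channels: int = 3,
    duration_ms: float = 2000.0,
    dt_ms: float = 0.1,
    trim_ms: float = 200.0,
    sigma_ms: float = 3.0,
    amplitude: float = DEFAULT_NOISE_AMPLITUDE,
) -> tuple[sig.SignalSet, sig.SignalSet, net.SimResult]:
    """One 2 s noise-driven simulation, returning the trimmed analysis pair
    (inputs, output traces) plus the raw SimResult."""
    inputs = sig.generate_noise_inputs(
        n_channels, duration_ms, dt_ms, sigma_ms, amplitude, seed=noise_seed
    )
    res = net.simulate(cfg, ws, inputs, seed=noise_seed)
    return (
        sig.trim_edges(inputs, trim_ms),
        sig.trim_edges(res.vm_out, trim_ms),
        res,
    )


def _iteration_seeds(spec: SearchSpec) -> list[dict[str, int]]:
    ss = np.random.SeedSequence(spec.master_seed)
    state = ss.generate_state(3 * spec.n_iterations).astype(np.int64) % (2**31)
    return [
        {"weights": int(state[3 * m]), "noise": int(state[3 * m + 1]),
         "permutation": int(state[3 * m + 2])}
        for m in range(spec.n_iterations)
    ]


def run_search(spec: SearchSpec) -> SearchResult:
    """Run the full grid x iteration campaign and aggregate.

    Failed simulations (numerical blow-up) are recorded per point with a
    logged reason and excluded from the aggregates; the record count always
    equals the grid size.
    """
    grid = build_grid(spec)
    seeds = _iteration_seeds(spec)
    n_points = len(grid)

    rows = []
    classif_by_point: dict[tuple[float, ...], dict[str, cls.ClassifResult]] = {}
    for point in grid:
        cfg = _config_for_point(spec, point)
        matrices: dict[str, list[np.ndarray]] = {m: [] for m in met.METRIC_NAMES}
        fr_e_vals, fr_i_vals = [], []
        n_failed = 0
        for m, sd in enumerate(seeds):
            try:
                ws = _weights_for_iteration(spec, cfg, sd["weights"], sd["permutation"])
                if spec.parameter == "delay":
                    ws = replace(ws, delay_ei_ms=point[0])
                x_trim, y_trim, res = simulate_trial(
                    cfg, ws, sd["noise"],
                    n_channels=spec.n_channels,
                    duration_ms=spec.duration_ms,
                    dt_ms=spec.dt_ms,
                    trim_ms=spec.trim_ms,
                    sigma_ms=spec.sigma_ms,
                    amplitude=spec.amplitude,
                )
            except FloatingPointError as exc:
                logger.warning("point %s iteration %d failed: %s", point, m, exc)
                n_failed += 1
                continue
            window = (spec.trim_ms, spec.duration_ms - spec.trim_ms)
            fr_e_vals.append(net.firing_rate(res, "e", window))
            fr_i_vals.append(net.firing_rate(res, "i", window))
            tau_out = cfg.out.tau_m
            for name in met.METRIC_NAMES:
                matrices[name].append(
                    met.metric_matrix(x_trim, y_trim, name, tau_ms=tau_out,
                                      max_lag_ms=spec.max_lag_ms)
                )

        row: dict[str, Any] = {"status": "ok" if n_failed == 0 else "partial",
                               "n_failed": n_failed,
                               "n_iterations": spec.n_iterations - n_failed}
        if spec.parameter == "delay":
            row["delay_ms"] = point[0]
        else:
            row[f"{spec.parameter}_i"] = point[0]
            row[f"{spec.parameter}_e"] = point[1]
        row["fr_e"] = float(np.mean(fr_e_vals)) if fr_e_vals else np.nan
        row["fr_i"] = float(np.mean(fr_i_vals)) if fr_i_vals else np.nan
        point_classif: dict[str, cls.ClassifResult] = {}
        for name in met.METRIC_NAMES:
            mats = matrices[name]
            if not mats:
                row[name] = np.nan
                row[f"acc_{name}"] = np.nan
                row[f"p_{name}"] = np.nan
                row[f"sig_{name}"] = False
                continue
            with np.errstate(all="ignore"):
                row[name] = float(np.nanmean([met.mean_matching(m_) for m_ in mats]))
            cr = cls.score_iterations(
                mats,
                direction=met.METRIC_DIRECTIONS[name],
                alpha=spec.alpha,
                n_comparisons=n_points,
                seed=seeds[0]["noise"],
            )
            point_classif[name] = cr
            row[f"acc_{name}"] = cr.accuracy
            row[f"p_{name}"] = cr.p_value
            row[f"sig_{name}"] = cr.significant
        row["seed_master"] = spec.master_seed
        rows.append(row)
        classif_by_point[point] = point_classif

    return SearchResult(
        spec=spec, records=pd.DataFrame(rows), grid=grid, classif=classif_by_point
    )


def run_control_6x6(spec: SearchSpec) -> SearchResult:
    """Ceiling-effect control: identical pipeline with 6 inputs/outputs
    (chance accuracy 1/6, n = 60 trials at 10 iterations)."""
    return run_search(replace(spec, n_channels=6))


def run_permutation_controls(spec: SearchSpec) -> dict[str, Any]:
    """Run the same grid under structured, EI-permuted and all-permuted
    connectivity, plus a per-metric median comparison table.

    Each arm derives an independent seed stream from the master seed.
    """
    arms = {}
    for offset, mode in ((0, "structured"), (1, "permuted_ei"), (2, "permuted_all")):
        arm_seed = int(
            np.random.SeedSequence([spec.master_seed, offset]).generate_state(1)[0]
            % (2**31)
        )
        arms[mode] = run_search(
            replace(spec, connectivity_mode=mode, master_seed=arm_seed)
        )
    medians = pd.DataFrame(
        {
            mode: {name: float(res.records[name].median())
                   for name in met.METRIC_NAMES}
            for mode, res in arms.items()
        }
    )
    return {**arms, "medians": medians}


def bin_by_firing_rate(res: SearchResult, n_bins: int = 10,
                       n_boot: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Bin grid points into ``n_bins`` equal-width excitatory-firing-rate
    bins; report per-bin mean accuracy per metric with a bootstrap CI.

    Empty bins are absent from the output, not reported as zero.
    """
    rec = res.records.dropna(subset=["fr_e"])
    if rec.empty:
        raise ValueError("no grid points with a firing rate")
    fr = rec["fr_e"].to_numpy()
    lo, hi = fr.min(), fr.max()
    edges = np.linspace(lo, hi, n_bins + 1) if hi > lo else np.array([lo, lo + 1e-9])
    idx = np.clip(np.digitize(fr, edges) - 1, 0, len(edges) - 2)
    rows = []
    rng_seed = seed
    for b in range(len(edges) - 1):
        mask = idx == b
        if not mask.any():
            continue
        row: dict[str, Any] = {
            "bin": b,
            "fr_lo": float(edges[b]),
            "fr_hi": float(edges[b + 1]),
            "n_points": int(mask.sum()),
            "fr_mean": float(fr[mask].mean()),
        }
        for name in met.METRIC_NAMES:
            acc = rec.loc[mask, f"acc_{name}"].dropna().to_numpy()
            if acc.size == 0:
                row[f"acc_{name}"] = np.nan
                row[f"ci_{name}"] = (np.nan, np.nan)
                continue
            row[f"acc_{name}"] = float(acc.mean())
            row[f"ci_{name}"] = cls.bootstrap_ci(acc, n_boot=n_boot, seed=rng_seed)
        rows.append(row)
    return pd.DataFrame(rows)


def passband_scan(
    cfg: net.UnitClassConfig,
    ws: conn.WeightSet,
    freqs_hz: "list[int] | np.ndarray" = tuple(range(1, 100)),
    amplitude: float = DEFAULT_NOISE_AMPLITUDE,
    duration_ms: float = 2000.0,
    dt_ms: float = 0.1,
    trim_ms: float = 200.0,
) -> pd.DataFrame:
    """Sinusoidal pass-band characterisation.

    For each frequency, drive the network with pure sinusoids of the given
    peak amplitude and report whether any excitatory spikes occur in the
    analysis window, plus the mean excitatory rate.
    """
    rows = []
    for f in freqs_hz:
        stim = sig.generate_sinusoid_inputs(
            ws.n_in, duration_ms, dt_ms, float(f), amplitude
        )
        res = net.simulate(cfg, ws, stim)
        window = (trim_ms, duration_ms - trim_ms)
        fr = net.firing_rate(res, "e", window)
        rows.append({"freq_hz": float(f), "spiking": bool(fr > 0), "fr_e": fr})
    return pd.DataFrame(rows)
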