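"""Input->output information-transfer metrics and their shared preprocessing.

Four scalar metrics compare one input current channel ``x`` with one output
membrane trace ``y``:

* **Coherence** — magnitude-squared coherence ``|Pxy|^2 / (Pxx Pyy)`` from
  Welch spectral estimates, averaged over a 0–100 Hz grid at 3 Hz spacing.
* **Granger causality** — log residual-variance ratio between a univariate
  autoregression of ``y`` and a bivariate one that adds lagged ``x`` terms,
  with the lag order selected by AIC under a 100 ms cap, after downsampling
  by 40 and first-differencing.  Also expressed in bits as
  ``log2(var(v)/var(u))``.
* **Transfer entropy** — plug-in conditional mutual information
  ``H(Y_{t+1}|Y_t) - H(Y_{t+1}|Y_t, X_p)`` on 4-bin quantized sequences,
  with ``x`` first shifted to the best (nonnegative) cross-correlation
  latency and both sequences downsampled and differenced.
* **Reconstruction error** — variance of the difference between the
  min-max-scaled leaky-integrated input (target) and the scaled output
  trace, normalised by target variance.  1 means a silent network; 0 a
  perfect reconstruction; values above 1 indicate worse-than-silent output
  (e.g. from time shifts).

Preprocessing conventions (documented once, applied everywhere): plain
decimation without anti-alias filtering; differencing after decimation
(dropping the first element, so 400 kept samples give 399 transitions);
equal-width quantization bins spanning each sequence's own observed range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats as spst

from .signal_gen import SignalSet

__all__ = [
    "SpectralEstimate",
    "VarFit",
    "TeEstimate",
    "ReResult",
    "best_latency",
    "coherence_spectrum",
    "coherence_mean",
    "downsample_and_difference",
    "granger",
    "transfer_entropy",
    "bin_count_rule",
    "leaky_target",
    "reconstruction_error",
    "reconstruction_error_multi",
    "metric_matrix",
    "mean_matching",
    "METRIC_NAMES",
    "METRIC_DIRECTIONS",
]

METRIC_NAMES = ("coherence", "granger", "te", "re")
#: Winner-selection direction per metric: max for Coh/GC/TE, min for RE.
METRIC_DIRECTIONS = {"coherence": "max", "granger": "max", "te": "max", "re": "min"}

DOWNSAMPLE_FACTOR = 40


# ---------------------------------------------------------------------------
# Latency
# ---------------------------------------------------------------------------

def best_latency(
    x: np.ndarray, y: np.ndarray, dt_ms: float, max_lag_ms: float | None = None
) -> float:
    """Latency (ms) maximising the plain cross-correlation of x with y.

    Restricted to nonnegative lags (input preceding output); ties break
    toward the smallest lag.  The correlation is not normalised and the
    maximum is signed (an inverted copy does *not* map back to its delay).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant signal: cross-correlation undefined, latency 0",
                      stacklevel=2)
        return 0.0
    xc = x - x.mean()
    yc = y - y.mean()
    corr = sps.correlate(yc, xc, mode="full")
    lags = sps.correlation_lags(len(yc), len(xc), mode="full")
    keep = lags >= 0
    if max_lag_ms is not None:
        keep &= lags * dt_ms <= max_lag_ms
    corr, lags = corr[keep], lags[keep]
    return float(lags[np.argmax(corr)] * dt_ms)


# ---------------------------------------------------------------------------
# Coherence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralEstimate:
    """Welch spectra and coherence on the metric's frequency grid."""

    freqs: np.ndarray
    pxx: np.ndarray
    pyy: np.ndarray
    pxy: np.ndarray
    cxy: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.cxy < -1e-9) or np.any(self.cxy > 1 + 1e-9):
            raise ValueError("coherence out of [0, 1]")


def coherence_spectrum(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: tuple[float, float] = (0.0, 100.0),
    step: float = 3.0,
    nperseg: int = 3200,
    noverlap: int | None = None,
) -> SpectralEstimate:
    """Welch coherence evaluated on a fixed frequency grid.

    The default segment length (3200 samples at 10 kHz) keeps the native
    resolution at 3.125 Hz with 50 % overlap, giving nine averaging
    segments on a standard 16,000-sample analysis window.  At least four
    averaging segments are required.  The DC bin is dropped (undefined after
    per-segment detrending); the grid value at 0 Hz takes the lowest resolved
    frequency's coherence via interpolation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if noverlap is None:
        noverlap = nperseg // 2
    n_seg = (len(x) - noverlap) // (nperseg - noverlap)
    if n_seg < 4:
        raise ValueError(
            f"signal too short: {n_seg} Welch segments available, need >= 4"
        )
    f, pxx = sps.welch(x, fs=fs, nperseg=nperseg, noverlap=noverlap)
    _, pyy = sps.welch(y, fs=fs, nperseg=nperseg, noverlap=noverlap)
    _, pxy = sps.csd(x, y, fs=fs, nperseg=nperseg, noverlap=noverlap)
    with np.errstate(invalid="ignore", divide="ignore"):
        cxy = np.abs(pxy) ** 2 / (pxx * pyy)
    # drop the (detrended, hence degenerate) DC bin
    f, pxx, pyy, pxy, cxy = f[1:], pxx[1:], pyy[1:], pxy[1:], cxy[1:]
    cxy = np.clip(np.nan_to_num(cxy), 0.0, 1.0)
    grid = np.arange(band[0], band[1] + 1e-9, step)
    return SpectralEstimate(
        freqs=grid,
        pxx=np.interp(grid, f, pxx),
        pyy=np.interp(grid, f, pyy),
        pxy=np.interp(grid, f, np.abs(pxy)),
        cxy=np.interp(grid, f, cxy),
    )


def coherence_mean(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: tuple[float, float] = (0.0, 100.0),
    step: float = 3.0,
    nperseg: int = 3200,
    noverlap: int | None = None,
) -> float:
    """Mean coherence over the 0–100 Hz grid at 3 Hz spacing (scalar metric)."""
    est = coherence_spectrum(x, y, fs, band=band, step=step,
                             nperseg=nperseg, noverlap=noverlap)
    return float(est.cxy.mean())


# ---------------------------------------------------------------------------
# Shared discretization for Granger / transfer entropy
# ---------------------------------------------------------------------------

def downsample_and_difference(
    values: np.ndarray, factor: int = DOWNSAMPLE_FACTOR
) -> np.ndarray:
    """Keep every ``factor``-th sample (plain decimation, no anti-alias
    filter), then first-difference.

    Output length is ``floor(n / factor) - 1``: 16,000 analysis samples at
    factor 40 give 400 kept observations and 399 usable transitions.
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor!r}")
    kept = np.asarray(values, dtype=float)[::factor]
    n_kept = int(np.floor(len(values) / factor))
    kept = kept[:n_kept]
    return np.diff(kept)


# ---------------------------------------------------------------------------
# Granger causality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarFit:
    """Nested autoregression fit underlying the Granger statistic."""

    order: int
    coef_uni: np.ndarray  # alpha_i of the univariate model
    coef_y: np.ndarray  # alpha_i of the bivariate model
    coef_x: np.ndarray  # beta_i of the bivariate model
    var_v: float
    var_u: float
    f_stat: float  # ln(var_v / var_u)
    p_value: float
    bits: float  # log2(var_v / var_u)
    p_start: int = 1  # first X lag entering the bivariate model
    max_order: int = 0
    n_obs: int = 0

    def __post_init__(self) -> None:
        if self.f_stat < -1e-12:
            raise ValueError("F statistic must be nonnegative (nested LS)")


def _lag_matrix(z: np.ndarray, order: int, start: int) -> np.ndarray:
    """Columns z[t-1] ... z[t-order] for t in [start, n)."""
    return np.column_stack([z[start - k : len(z) - k] for k in range(1, order + 1)])


def granger(
    x: np.ndarray,
    y: np.ndarray,
    fs_down: float,
    max_lag_ms: float = 100.0,
) -> VarFit:
    """Granger causality of x onto y on downsampled, differenced sequences.

    The autoregressive order of the output's own history is selected by AIC
    over 1..max_lag on a common sample (the cap translates ``max_lag_ms`` at
    the downsampled rate, 25 lags for 100 ms at 250 Hz).  The input block
    always spans the full lag cap: an output driven purely by lagged input
    is itself nearly white, so any criterion applied to the tested block
    would either truncate the model below the transfer latency (missing the
    coupling) or select the best-fitting noise lags (inflating the test).
    With the input span fixed a priori the likelihood-ratio null stays
    calibrated.  Restricted and unrestricted models are fit by least squares
    on the same rows, so the restricted residual variance can never fall
    below the unrestricted one.  ``F = ln(var(v)/var(u))``; the p-value is
    the likelihood-ratio test (``n F`` against chi-square with ``max_lag``
    degrees of freedom, the input-block size); the bits value re-bases the
    ratio to log2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(y)
    max_order = max(int(np.floor(max_lag_ms * fs_down / 1000.0)), 1)
    max_order = min(max_order, (n - 8) // 3)
    if max_order < 1 or np.ptp(y) == 0 or np.ptp(x) == 0:
        warnings.warn("degenerate Granger input: constant series", stacklevel=2)
        return VarFit(0, np.empty(0), np.empty(0), np.empty(0),
                      0.0, 0.0, 0.0, 1.0, 0.0, max_order=max_order, n_obs=n)

    # AIC order selection for the output's own history, common sample.
    target_sel = y[max_order:]
    n_sel = len(target_sel)
    best_order, best_aic = 1, np.inf
    for order in range(1, max_order + 1):
        design = _lag_matrix(y, order, max_order)
        beta, *_ = np.linalg.lstsq(design, target_sel, rcond=None)
        rss = float(np.sum((target_sel - design @ beta) ** 2))
        aic = n_sel * np.log(max(rss / n_sel, 1e-300)) + 2 * order
        if aic < best_aic:
            best_aic, best_order = aic, order

    order = best_order
    target = y[max_order:]
    n_eff = len(target)
    design_v = _lag_matrix(y, order, max_order)
    design_u = np.hstack([design_v, _lag_matrix(x, max_order, max_order)])

    coef_v, *_ = np.linalg.lstsq(design_v, target, rcond=None)
    coef_u, *_ = np.linalg.lstsq(design_u, target, rcond=None)
    var_v = float(np.mean((target - design_v @ coef_v) ** 2))
    var_u = float(np.mean((target - design_u @ coef_u) ** 2))
    if var_u <= 0 or var_v <= 0:
        warnings.warn("rank-deficient Granger design; returning F = 0",
                      stacklevel=2)
        return VarFit(order, coef_v, coef_u[:order], coef_u[order:],
                      var_v, var_u, 0.0, 1.0, 0.0,
                      max_order=max_order, n_obs=n_eff)
    ratio = max(var_v / var_u, 1.0)  # guard tiny negative rounding
    f_stat = float(np.log(ratio))
    lr = n_eff * f_stat
    p_value = float(spst.chi2.sf(lr, df=max_order))
    return VarFit(
        order=order,
        coef_uni=coef_v,
        coef_y=coef_u[:order],
        coef_x=coef_u[order:],
        var_v=var_v,
        var_u=var_u,
        f_stat=f_stat,
        p_value=max(p_value, np.finfo(float).tiny),
        bits=float(np.log2(ratio)),
        max_order=max_order,
        n_obs=n_eff,
    )


# ---------------------------------------------------------------------------
# Transfer entropy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TeEstimate:
    """Plug-in transfer-entropy estimate on quantized sequences."""

    counts: np.ndarray  # [n_bins x n_bins x n_bins] over (y_{t+1}, y_t, x_p)
    h_y: float  # H(Y_{t+1} | Y_t), bits
    h_yx: float  # H(Y_{t+1} | Y_t, X_p), bits
    te: float  # bits
    shift_ms: float
    edges_x: np.ndarray
    edges_y: np.ndarray

    def __post_init__(self) -> None:
        n_bins = self.counts.shape[0]
        if not -1e-9 <= self.te <= np.log2(n_bins) + 1e-9:
            raise ValueError("TE out of [0, log2(n_bins)]")


def _quantize(z: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width bins over the sequence's own observed range."""
    lo, hi = float(np.min(z)), float(np.max(z))
    if hi <= lo:
        raise ValueError("cannot quantize a zero-range sequence")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(((z - lo) / (hi - lo) * n_bins).astype(np.int64), 0, n_bins - 1)
    return idx, edges


def _plugin_entropy(counts: np.ndarray) -> float:
    """Plug-in joint entropy in bits, with 0 log 0 = 0."""
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log2(p)))


def transfer_entropy(
    x: np.ndarray,
    y: np.ndarray,
    shift_ms: float = 0.0,
    n_bins: int = 4,
    k: int = 1,
    l: int = 1,
) -> TeEstimate:
    """Plug-in transfer entropy from x to y, in bits.

    ``x`` and ``y`` are expected to be preprocessed and aligned already (the
    input shifted by its best latency so ``x_p`` lines up with ``y_t``, both
    downsampled and differenced; :func:`te_pipeline` does this).  Each
    sequence is quantized into ``n_bins`` equal-width bins over its own
    range; a 3-D count tensor over ``(y_{t+1}, y_t, x_p)`` yields the
    conditional entropies and ``TE = H(Y_{t+1}|Y_t) - H(Y_{t+1}|Y_t, X_p)``.
    Only embedding dimensions ``k = l = 1`` are supported.
    """
    if (k, l) != (1, 1):
        raise NotImplementedError("only k = l = 1 embeddings are supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(y) < 2:
        raise ValueError("sequences too short for one transition")
    xq, edges_x = _quantize(x, n_bins)
    yq, edges_y = _quantize(y, n_bins)
    counts = np.zeros((n_bins, n_bins, n_bins))
    np.add.at(counts, (yq[1:], yq[:-1], xq[:-1]), 1.0)
    h_ynext_y = _plugin_entropy(counts.sum(axis=2)) - _plugin_entropy(
        counts.sum(axis=(0, 2))
    )
    h_ynext_yx = _plugin_entropy(counts) - _plugin_entropy(counts.sum(axis=0))
    return TeEstimate(
        counts=counts,
        h_y=h_ynext_y,
        h_yx=h_ynext_yx,
        te=max(h_ynext_y - h_ynext_yx, 0.0),
        shift_ms=float(shift_ms),
        edges_x=edges_x,
        edges_y=edges_y,
    )


def te_pipeline(
    x: np.ndarray,
    y: np.ndarray,
    dt_ms: float,
    factor: int = DOWNSAMPLE_FACTOR,
    max_lag_ms: float | None = None,
    n_bins: int | None = None,
) -> TeEstimate:
    """Full transfer-entropy preprocessing chain on raw traces.

    Shift ``x`` forward by the best cross-correlation latency (so the
    shifted input sample corresponds to the concurrent output sample),
    decimate and difference both, choose the bin count by the sample-size
    rule if not given, then estimate TE.
    """
    shift_ms = best_latency(x, y, dt_ms, max_lag_ms=max_lag_ms)
    n_shift = int(round(shift_ms / dt_ms))
    if n_shift > 0:
        x, y = x[:-n_shift], y[n_shift:]
    xd = downsample_and_difference(x, factor)
    yd = downsample_and_difference(y, factor)
    if n_bins is None:
        n_bins = bin_count_rule(len(xd) + 1)
    return transfer_entropy(xd, yd, shift_ms=shift_ms, n_bins=n_bins)


def bin_count_rule(N: int, k: int = 1, l: int = 1) -> int:
    """Quantization bin count from the sample size: ``(N/5)^(1/(k+l+1))``.

    The plug-in estimator fills an ``n^(k+l+1)`` count tensor; requiring at
    least ~5 expected observations per cell gives ``n = (N/5)^(1/(k+l+1))``,
    rounded to the nearest integer — 4 bins for the standard 400
    observations at ``k = l = 1``.  Clamped below at 2 with a warning.
    """
    if N < 1:
        raise ValueError(f"N must be positive, got {N!r}")
    n = int(round((N / 5.0) ** (1.0 / (k + l + 1))))
    if n < 2:
        warnings.warn(f"bin-count rule gave {n} for N={N}; clamping to 2",
                      stacklevel=2)
        return 2
    return n


# ---------------------------------------------------------------------------
# Reconstruction error
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReResult:
    """Normalized reconstruction error and its intermediate traces."""

    target: np.ndarray  # leaky-integrated input
    target_scaled: np.ndarray
    output_scaled: np.ndarray
    re: float

    def __post_init__(self) -> None:
        if self.re < 0:
            raise ValueError("RE must be nonnegative")


def leaky_target(x: np.ndarray, tau_ms: float, dt_ms: float) -> np.ndarray:
    """Leaky integration of the input: ``tau dX/dt = x - X``, Euler, X(0)=0.

    ``tau_ms`` matches the output units' membrane time constant (31.25 ms
    for Comrade/Bacon readouts, 3.125 ms for HiFi).
    """
    if tau_ms <= 0 or dt_ms <= 0:
        raise ValueError("tau_ms and dt_ms must be positive")
    alpha = dt_ms / tau_ms
    x = np.asarray(x, dtype=float)
    # X[t] = (1 - alpha) X[t-1] + alpha x[t-1], zero initial state
    return sps.lfilter([0.0, alpha], [1.0, -(1.0 - alpha)], x)


def _minmax_scale(z: np.ndarray) -> np.ndarray:
    """Scale to [-1, 1]; a zero-range trace maps to all zeros."""
    lo, hi = float(np.min(z)), float(np.max(z))
    if hi <= lo:
        return np.zeros_like(z)
    return 2.0 * (z - lo) / (hi - lo) - 1.0


def reconstruction_error(
    x: np.ndarray, vm_out: np.ndarray, tau_ms: float, dt_ms: float
) -> ReResult:
    """Variance-normalized reconstruction error of one output channel.

    The target is the leaky-integrated input; target and output are min-max
    scaled to [-1, 1] and compared as ``Var(target - output) / Var(target)``.
    A constant (silent, resting) output scales to zero and yields exactly 1;
    delays or distortions can push the value above 1.
    """
    x = np.asarray(x, dtype=float)
    vm_out = np.asarray(vm_out, dtype=float)
    if x.shape != vm_out.shape:
        raise ValueError("x and vm_out must have equal length")
    target = leaky_target(x, tau_ms, dt_ms)
    t_s = _minmax_scale(target)
    var_t = float(np.var(t_s))
    if var_t == 0:
        raise ValueError("zero-variance target: cannot normalize")
    o_s = _minmax_scale(vm_out)
    return ReResult(
        target=target,
        target_scaled=t_s,
        output_scaled=o_s,
        re=float(np.var(t_s - o_s) / var_t),
    )


def reconstruction_error_multi(
    inputs: SignalSet, vm_out: SignalSet, tau_ms: float
) -> float:
    """Multi-channel RE: numerator and denominator variances summed over the
    matching channel pairs before the ratio."""
    if inputs.n_channels != vm_out.n_channels:
        raise ValueError("channel count mismatch")
    num = den = 0.0
    for c in range(inputs.n_channels):
        r = reconstruction_error(inputs.values[c], vm_out.values[c], tau_ms,
                                 inputs.dt)
        num += np.var(r.target_scaled - r.output_scaled)
        den += np.var(r.target_scaled)
    return float(num / den)


# ---------------------------------------------------------------------------
# Pairwise metric matrices
# ---------------------------------------------------------------------------

def metric_matrix(
    inputs: SignalSet,
    vm_out: SignalSet,
    metric: str,
    tau_ms: float = 31.25,
    max_lag_ms: float = 100.0,
    factor: int = DOWNSAMPLE_FACTOR,
) -> np.ndarray:
    """Evaluate one metric for every (input, output) pair.

    Returns an ``[n_in x n_out]`` matrix; each pair gets the metric's own
    preprocessing (latency shift for TE, decimation + differencing for
    GC/TE, leaky target for RE).  Granger and TE values are in bits.
    """
    if metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRIC_NAMES}")
    if inputs.dt != vm_out.dt:
        raise ValueError("inputs and outputs must share the sampling interval")
    n = min(inputs.n_samples, vm_out.n_samples)
    out = np.empty((inputs.n_channels, vm_out.n_channels))
    fs = inputs.fs_hz
    fs_down = fs / factor
    for i in range(inputs.n_channels):
        x = inputs.values[i, :n]
        for o in range(vm_out.n_channels):
            y = vm_out.values[o, :n]
            if metric == "coherence":
                # zero-variance (silent) outputs are flagged missing
                out[i, o] = coherence_mean(x, y, fs) if np.ptp(y) > 0 else np.nan
            elif metric == "granger":
                if np.ptp(y) == 0:
                    out[i, o] = np.nan
                    continue
                xd = downsample_and_difference(x, factor)
                yd = downsample_and_difference(y, factor)
                out[i, o] = granger(xd, yd, fs_down, max_lag_ms).bits
            elif metric == "te":
                if np.ptp(y) == 0:
                    out[i, o] = np.nan
                    continue
                out[i, o] = te_pipeline(x, y, inputs.dt, factor,
                                        max_lag_ms=max_lag_ms).te
            else:  # re
                out[i, o] = reconstruction_error(x, y, tau_ms, inputs.dt).re
    return out


def mean_matching(m: np.ndarray) -> float:
    """Mean of the matching (diagonal) input-output pairs."""
    m = np.asarray(m, dtype=float)
    k = min(m.shape)
    return float(np.mean(np.diag(m)[:k]))
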