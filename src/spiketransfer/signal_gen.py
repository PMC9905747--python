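"""Stimulus generation: smoothed Gaussian noise, sinusoids, and window trimming.

All stimuli in this package are generated, not recorded.  The workhorse is
temporally low-pass filtered white noise: independent Gaussian white-noise
channels convolved with a Gaussian kernel (default standard deviation 3 ms),
which is the canonical band-limited analog drive for the network.  Sinusoidal
and constant-step currents serve the pass-band and f-I characterisations.

Conventions
-----------
* A :class:`SignalSet` stores channels as rows of ``values`` with a fixed
  sampling interval ``dt`` in milliseconds and a start time ``t0`` (ms).
* Noise amplitude refers to the white-noise standard deviation *before*
  smoothing.  Gaussian smoothing shrinks the variance by the kernel energy
  factor ``1 / (2 sigma sqrt(pi) / dt)``; this attenuation is deliberate and
  not renormalised.
* Smoothing uses reflective padding so that the (later trimmed) edges carry
  no startup transient.
* One master seed spawns independent per-channel child streams, so channels
  are uncorrelated and any (seed, parameters) pair is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "SignalSet",
    "generate_noise_inputs",
    "generate_sinusoid_inputs",
    "generate_step_inputs",
    "trim_edges",
    "save_signals",
    "load_signals",
]


@dataclass(frozen=True)
class SignalSet:
    """Multichannel analog time series with sampling metadata.

    Attributes
    ----------
    values : ndarray, shape (n_channels, n_samples)
        Channel-major sample matrix.
    dt : float
        Sampling interval in ms.
    t0 : float
        Time of the first sample in ms.
    meta : dict
        Provenance: seed, generator name, smoothing sigma, amplitude scale.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(v)):
            raise ValueError("SignalSet values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Spanned duration in ms (n_samples * dt)."""
        return self.n_samples * self.dt

    @property
    def fs_hz(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self.dt

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms."""
        return self.t0 + self.dt * np.arange(self.n_samples)


def _check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be positive, got {value!r}")


def generate_noise_inputs(
    n_channels: int,
    duration_ms: float,
    dt_ms: float,
    sigma_ms: float = 3.0,
    amplitude: float = 1.0,
    seed: int = 0,
) -> SignalSet:
    """Generate independent Gaussian white-noise channels, temporally smoothed.

    Each channel is i.i.d. Gaussian noise of standard deviation ``amplitude``
    convolved with a Gaussian kernel of standard deviation ``sigma_ms``
    (``sigma_ms = 0`` leaves the noise unfiltered).  The convolution is
    same-length with reflective boundary handling.

    Parameters
    ----------
    n_channels : int
        Number of independent channels (>= 1).
    duration_ms, dt_ms : float
        Signal duration and sampling interval, ms.
    sigma_ms : float
        Standard deviation of the temporal Gaussian kernel, ms.
    amplitude : float
        White-noise standard deviation before smoothing (current units).
    seed : int
        Master seed; each channel draws from an independent child stream.
    """
    _check_positive("duration_ms", duration_ms)
    _check_positive("dt_ms", dt_ms)
    if sigma_ms < 0:
        raise ValueError(f"sigma_ms must be >= 0, got {sigma_ms!r}")
    if n_channels < 1:
        raise ValueError(f"n_channels must be >= 1, got {n_channels!r}")

    n_samples = int(round(duration_ms / dt_ms))
    children = np.random.SeedSequence(seed).spawn(n_channels)
    rows = np.empty((n_channels, n_samples))
    for c, child in enumerate(children):
        white = np.random.default_rng(child).standard_normal(n_samples) * amplitude
        if sigma_ms > 0:
            rows[c] = gaussian_filter1d(white, sigma_ms / dt_ms, mode="reflect")
        else:
            rows[c] = white
    return SignalSet(
        rows,
        dt=dt_ms,
        t0=0.0,
        meta={
            "generator": "smoothed_gaussian_noise",
            "seed": int(seed),
            "sigma_ms": float(sigma_ms),
            "amplitude": float(amplitude),
        },
    )


def generate_sinusoid_inputs(
    n_channels: int,
    duration_ms: float,
    dt_ms: float,
    freq_hz: float,
    amplitude: float = 1.0,
    phase: float = 0.0,
) -> SignalSet:
    """Pure sinusoid per channel: ``amplitude * sin(2 pi f t + phase)``.

    The frequency must lie strictly inside (0, Nyquist).
    """
    _check_positive("duration_ms", duration_ms)
    _check_positive("dt_ms", dt_ms)
    nyquist = 1000.0 / (2.0 * dt_ms)
    if not 0 < freq_hz < nyquist:
        raise ValueError(
            f"freq_hz must lie in (0, {nyquist} Hz); got {freq_hz!r}"
        )
    n_samples = int(round(duration_ms / dt_ms))
    t_s = dt_ms * np.arange(n_samples) / 1000.0
    row = amplitude * np.sin(2.0 * np.pi * freq_hz * t_s + phase)
    return SignalSet(
        np.tile(row, (n_channels, 1)),
        dt=dt_ms,
        meta={
            "generator": "sinusoid",
            "freq_hz": float(freq_hz),
            "amplitude": float(amplitude),
            "phase": float(phase),
        },
    )


def generate_step_inputs(
    n_channels: int, duration_ms: float, dt_ms: float, amplitude: float
) -> SignalSet:
    """Constant (step) current of the given amplitude on every channel."""
    _check_positive("duration_ms", duration_ms)
    _check_positive("dt_ms", dt_ms)
    n_samples = int(round(duration_ms / dt_ms))
    return SignalSet(
        np.full((n_channels, n_samples), float(amplitude)),
        dt=dt_ms,
        meta={"generator": "step", "amplitude": float(amplitude)},
    )


def trim_edges(sig: SignalSet, trim_ms: float) -> SignalSet:
    """Drop ``trim_ms`` from both ends of the signal (response-stability window).

    The standard analysis window omits the first and last 200 ms of a 2 s
    simulation, leaving 1.6 s (16,000 samples at 0.1 ms).
    """
    if trim_ms < 0:
        raise ValueError(f"trim_ms must be >= 0, got {trim_ms!r}")
    if trim_ms == 0:
        return sig
    n_trim = int(round(trim_ms / sig.dt))
    if 2 * n_trim >= sig.n_samples:
        raise ValueError(
            f"trim_ms={trim_ms!r} removes the whole signal "
            f"(duration {sig.duration} ms)"
        )
    return replace(
        sig,
        values=sig.values[:, n_trim : sig.n_samples - n_trim],
        t0=sig.t0 + n_trim * sig.dt,
    )


# ---------------------------------------------------------------------------
# Serialization: one HDF5 dataset per channel plus sampling attributes, and a
# plain-text form for small fixtures.
# ---------------------------------------------------------------------------

def save_signals(sig: SignalSet, path: str | Path) -> None:
    """Write a SignalSet to HDF5 (``channel_<k>`` datasets + attrs) or, when
    the path ends in ``.csv``/``.tsv``, as delimited text with a header line."""
    path = Path(path)
    if path.suffix in {".csv", ".tsv"}:
        sep = "," if path.suffix == ".csv" else "\t"
        header = f"dt_ms={sig.dt} t0_ms={sig.t0}"
        np.savetxt(path, sig.values.T, delimiter=sep, header=header)
        return
    import h5py

    with h5py.File(path, "w") as f:
        for c in range(sig.n_channels):
            f.create_dataset(f"channel_{c}", data=sig.values[c])
        f.attrs["dt"] = sig.dt
        f.attrs["t0"] = sig.t0
        f.attrs["n_channels"] = sig.n_channels
        for key, val in sig.meta.items():
            f.attrs[f"meta_{key}"] = val


def load_signals(path: str | Path) -> SignalSet:
    """Inverse of :func:`save_signals`."""
    path = Path(path)
    if path.suffix in {".csv", ".tsv"}:
        sep = "," if path.suffix == ".csv" else "\t"
        with open(path) as fh:
            header = fh.readline().lstrip("# ").split()
        kv = dict(item.split("=") for item in header)
        values = np.loadtxt(path, delimiter=sep).T
        return SignalSet(values, dt=float(kv["dt_ms"]), t0=float(kv["t0_ms"]))
    import h5py

    with h5py.File(path, "r") as f:
        n = int(f.attrs["n_channels"])
        values = np.stack([f[f"channel_{c}"][:] for c in range(n)])
        meta = {
            k[len("meta_") :]: (v.item() if hasattr(v, "item") else v)
            for k, v in f.attrs.items()
            if k.startswith("meta_")
        }
        return SignalSet(values, dt=float(f.attrs["dt"]), t0=float(f.attrs["t0"]), meta=meta)
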