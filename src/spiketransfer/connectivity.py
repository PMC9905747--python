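"""Construction, scaling, permutation and serialization of the six weight matrices.

The network has six pathways: input->E feedforward (``ff``, signed), the four
recurrent pathways E->E, E->I, I->E, I->I (nonnegative magnitudes; polarity —
EE/EI depolarizing, IE/II hyperpolarizing — is applied by the simulator), and
the E->output decoder (``e_out``, signed).

The trained connectivity of the reference spike-coding network is not
re-learned here.  Instead the default connectivity is an analytic stand-in
built on the structure of the spike-coding optimum, where the decoder is
proportional to the feedforward weights and the recurrent interaction
approximates ``ff @ ff.T`` (rank <= n_in), realised through the inhibitory
population as a low-rank relay.  ``build_initial_ei`` reproduces the sparse
pre-training initial state; ``load_weights`` accepts externally trained
matrices.

All matrices are stored ``[target x source]``.  "Post-synaptic target index"
therefore refers to the row index; a permutation of post-synaptic targets
shuffles, for each source (column), which targets its weights land on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np

__all__ = [
    "WeightSet",
    "build_feedforward",
    "compute_abstract_thresholds",
    "build_decoder",
    "build_initial_ei",
    "build_structured_ei",
    "build_default_weights",
    "scale_to_physiological",
    "permute_ei",
    "permute_all",
    "save_weights",
    "load_weights",
    "PHYS_SCALE",
    "DECODER_SCALE",
]

#: Physiological scaling applied to all pathways except E->Out.
PHYS_SCALE = 1e-7
#: Scaling of the decoder (E->Out) weights.
DECODER_SCALE = 3e-8

EI_PATHWAYS = ("ee", "ei", "ie", "ii")


@dataclass(frozen=True)
class WeightSet:
    """All six connection matrices plus per-pathway delays.

    ``ff``: [n_E x n_in] signed; ``ee``: [n_E x n_E]; ``ei``: [n_I x n_E];
    ``ie``: [n_E x n_I]; ``ii``: [n_I x n_I] (nonnegative magnitudes);
    ``e_out``: [n_out x n_E] signed.

    ``delay_ei_ms`` is the single shared delay for the EE/EI/IE/II pathways
    (varied together during parameter search); ``delay_out_ms`` is the fixed
    E->Out delay.
    """

    ff: np.ndarray
    ee: np.ndarray
    ei: np.ndarray
    ie: np.ndarray
    ii: np.ndarray
    e_out: np.ndarray
    delay_ei_ms: float = 3.0
    delay_out_ms: float = 3.0
    scale_applied: bool = False
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_e, n_in = self.ff.shape
        n_i = self.ei.shape[0]
        n_out = self.e_out.shape[0]
        expected = {
            "ee": (n_e, n_e),
            "ei": (n_i, n_e),
            "ie": (n_e, n_i),
            "ii": (n_i, n_i),
            "e_out": (n_out, n_e),
        }
        for name, shape in expected.items():
            actual = getattr(self, name).shape
            if actual != shape:
                raise ValueError(f"{name} has shape {actual}, expected {shape}")
        for name in EI_PATHWAYS:
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be nonnegative (polarity is per-pathway)")

    @property
    def n_e(self) -> int:
        return self.ff.shape[0]

    @property
    def n_i(self) -> int:
        return self.ei.shape[0]

    @property
    def n_in(self) -> int:
        return self.ff.shape[1]

    @property
    def n_out(self) -> int:
        return self.e_out.shape[0]


def build_feedforward(
    n_e: int = 300, n_in: int = 3, seed: int = 0, normalize: str = "global"
) -> np.ndarray:
    """Random-normal feedforward weights normalised to sum of one.

    ``normalize="global"`` divides by the sum over all entries (the default);
    ``normalize="row"`` normalises each row to unit sum instead.
    """
    if n_e < 1 or n_in < 1:
        raise ValueError("n_e and n_in must be >= 1")
    rng = np.random.default_rng(seed)
    ff = rng.standard_normal((n_e, n_in))
    if normalize == "global":
        ff /= ff.sum()
    elif normalize == "row":
        ff /= ff.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown normalize mode {normalize!r}")
    return ff


def compute_abstract_thresholds(ff: np.ndarray) -> np.ndarray:
    """Abstract-model spiking thresholds: half the L2 norm of each ff row.

    These document the training-stage convention only; the physiological
    simulator takes its threshold from :class:`~.network_sim.NeuronParams`.
    """
    norms = np.linalg.norm(ff, axis=1)
    if np.any(norms == 0):
        warnings.warn("zero feedforward row -> abstract threshold 0", stacklevel=2)
    return norms / 2.0


def build_decoder(ff: np.ndarray, scale: float = DECODER_SCALE) -> np.ndarray:
    """Decoder weights ``e_out = scale * ff.T``.

    In the optimal spike-coding solution the linear readout decoder is
    proportional to the feedforward weights; the scale places the output
    units' membrane excursions in their dynamic voltage range.
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale!r}")
    return scale * ff.T.copy()


def build_initial_ei(
    n_e: int = 300, n_i: int = 75, seed: int = 0
) -> dict[str, np.ndarray]:
    """Sparse pre-training recurrent state.

    E->I: each inhibitory unit receives from 4 distinct random excitatory
    units with weight 0.5; I->E: each inhibitory unit contacts 4 random
    excitatory units with magnitude 0.15; EE and II carry autapses only
    (magnitudes 0.02 and 0.5 on the diagonal).
    """
    if n_i > n_e:
        raise ValueError("n_i must not exceed n_e")
    rng = np.random.default_rng(seed)
    ei = np.zeros((n_i, n_e))
    ie = np.zeros((n_e, n_i))
    for i in range(n_i):
        ei[i, rng.choice(n_e, size=4, replace=False)] = 0.5
        ie[rng.choice(n_e, size=4, replace=False), i] = 0.15
    ee = np.diag(np.full(n_e, 0.02))
    ii = np.diag(np.full(n_i, 0.5))
    return {"ee": ee, "ei": ei, "ie": ie, "ii": ii}


def build_structured_ei(
    ff: np.ndarray,
    n_i: int = 75,
    seed: int = 0,
    c_ei: float = 1.0,
    c_ie: float = 1.0,
    c_ii: float = 1.0,
) -> dict[str, np.ndarray]:
    """Low-rank inhibitory relay approximating the trained recurrent optimum.

    The ideal recurrent interaction of the spike-coding network is
    ``ff @ ff.T`` with rank <= n_in, so an inhibitory population of n_i >>
    n_in units can relay it: draw ``B`` [n_i x n_in] with unit-norm rows and
    set ``ei = c_ei [B ff.T]+``, ``ie = c_ie [ff B.T]+``, ``ii = c_ii
    [B B.T]+`` (rectification enforces pathway nonnegativity).  EE keeps
    autapses only (reset analog).
    """
    rng = np.random.default_rng(seed)
    n_e, n_in = ff.shape
    b = rng.standard_normal((n_i, n_in))
    b /= np.linalg.norm(b, axis=1, keepdims=True)
    ei = c_ei * np.clip(b @ ff.T, 0.0, None)
    ie = c_ie * np.clip(ff @ b.T, 0.0, None)
    ii = c_ii * np.clip(b @ b.T, 0.0, None)
    ee = np.diag(np.full(n_e, 0.02))
    return {"ee": ee, "ei": ei, "ie": ie, "ii": ii}


# Default relay gains, calibrated once (scripts/calibrate.py) together with
# the stimulus amplitude: strong enough that the inhibitory loop cancels the
# common-mode drive (which otherwise drifts and saturates the readout) while
# the Comrade LIF start point keeps firing in the single-digit-Hz band.
DEFAULT_C_EI = 1.0
DEFAULT_C_IE = 0.5
DEFAULT_C_II = 0.2


def build_default_weights(
    n_e: int = 300,
    n_i: int = 75,
    n_in: int = 3,
    seed: int = 0,
    mode: str = "structured",
    decoder_scale: float = DECODER_SCALE,
    c_ei: float = DEFAULT_C_EI,
    c_ie: float = DEFAULT_C_IE,
    c_ii: float = DEFAULT_C_II,
    delay_ei_ms: float = 3.0,
    delay_out_ms: float = 3.0,
    scale: bool = True,
) -> WeightSet:
    """Assemble the full default connectivity and (optionally) scale it.

    ``mode`` selects ``"structured"`` (trained-optimum stand-in) or
    ``"initial"`` (pre-training control).
    """
    ff = build_feedforward(n_e, n_in, seed=seed)
    if mode == "structured":
        rec = build_structured_ei(ff, n_i, seed=seed, c_ei=c_ei, c_ie=c_ie, c_ii=c_ii)
    elif mode == "initial":
        rec = build_initial_ei(n_e, n_i, seed=seed)
    else:
        raise ValueError(f"unknown connectivity mode {mode!r}")
    ws = WeightSet(
        ff=ff,
        e_out=build_decoder(ff, scale=decoder_scale),
        delay_ei_ms=delay_ei_ms,
        delay_out_ms=delay_out_ms,
        meta={"seed": int(seed), "mode": mode},
        **rec,
    )
    return scale_to_physiological(ws) if scale else ws


def scale_to_physiological(ws: WeightSet, factor: float = PHYS_SCALE) -> WeightSet:
    """Scale all pathways except E->Out into the nanosiemens-equivalent range.

    ``e_out`` carries its own decoder scale and is left untouched.  Double
    application is rejected.
    """
    if ws.scale_applied:
        raise ValueError("physiological scale already applied")
    return replace(
        ws,
        ff=ws.ff * factor,
        ee=ws.ee * factor,
        ei=ws.ei * factor,
        ie=ws.ie * factor,
        ii=ws.ii * factor,
        scale_applied=True,
        meta={**ws.meta, "phys_scale": float(factor)},
    )


def _permute_targets(mat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle post-synaptic target (row) assignment, one draw per pathway."""
    perm = rng.permutation(mat.shape[0])
    return mat[perm, :]


def permute_ei(ws: WeightSet, seed: int = 0) -> WeightSet:
    """Randomly permute post-synaptic targets within each recurrent pathway.

    Each of EE, EI, IE, II gets an independent random permutation of its
    target index; the per-pathway weight multiset (indeed each source's
    outgoing weight multiset) is preserved exactly.  ``ff`` and ``e_out``
    are untouched.
    """
    rng = np.random.default_rng(seed)
    return replace(
        ws,
        ee=_permute_targets(ws.ee, rng),
        ei=_permute_targets(ws.ei, rng),
        ie=_permute_targets(ws.ie, rng),
        ii=_permute_targets(ws.ii, rng),
        meta={**ws.meta, "permutation": "ei", "permutation_seed": int(seed)},
    )


def permute_all(ws: WeightSet, seed: int = 0) -> WeightSet:
    """Permute the recurrent pathways plus input->E targets and E->Out sources.

    On top of :func:`permute_ei`, the feedforward rows (which excitatory unit
    receives each input weight) and the decoder columns (which excitatory
    unit feeds each output weight) are shuffled, destroying the learned
    alignment between drive and readout.
    """
    rng = np.random.default_rng(seed)
    ws2 = permute_ei(ws, seed=seed)
    ff_perm = rng.permutation(ws.n_e)
    out_perm = rng.permutation(ws.n_e)
    return replace(
        ws2,
        ff=ws.ff[ff_perm, :],
        e_out=ws.e_out[:, out_perm],
        meta={**ws.meta, "permutation": "all", "permutation_seed": int(seed)},
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_PATHWAYS = ("ff", "ee", "ei", "ie", "ii", "e_out")


def save_weights(ws: WeightSet, path: str | Path) -> None:
    """Write a WeightSet to HDF5: one dataset per pathway plus attributes."""
    import h5py

    with h5py.File(path, "w") as f:
        for name in _PATHWAYS:
            f.create_dataset(name, data=getattr(ws, name))
        f.attrs["delay_ei_ms"] = ws.delay_ei_ms
        f.attrs["delay_out_ms"] = ws.delay_out_ms
        f.attrs["scale_applied"] = ws.scale_applied
        for key, val in ws.meta.items():
            f.attrs[f"meta_{key}"] = val


def load_weights(path: str | Path) -> WeightSet:
    """Load a WeightSet written by :func:`save_weights` (or externally trained
    matrices stored in the same layout)."""
    import h5py

    with h5py.File(path, "r") as f:
        mats = {name: f[name][:] for name in _PATHWAYS}
        meta = {
            k[len("meta_") :]: (v.item() if hasattr(v, "item") else v)
            for k, v in f.attrs.items()
            if k.startswith("meta_")
        }
        return WeightSet(
            delay_ei_ms=float(f.attrs["delay_ei_ms"]),
            delay_out_ms=float(f.attrs["delay_out_ms"]),
            scale_applied=bool(f.attrs["scale_applied"]),
            meta=meta,
            **mats,
        )
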