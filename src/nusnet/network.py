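"""The reconstruction network: encoders, a modified LSTM cell, output head.

The graph maps a sparse FID (a 2 x sp real matrix, one row each for the
real and imaginary samples) and its sampling schedule to a full 2 x np
time-domain FID:

* two input encoders — the flattened sparse data (length 2*sp) and a 0/1
  schedule mask (length 2*np) each pass through a linear layer with tanh
  activation, producing the initial hidden state ``h0`` (from the data)
  and cell state ``c0`` (from the schedule), both of length 2*np;
* a modified LSTM cell, applied N times with shared weights by default:
  four sigmoid linear layers of ``h`` (the forget, input, candidate and
  output gates) combined only by elementwise products and sums,
  ``c' = c*f + i*g`` and ``h' = o*c'``;
* an output head that concatenates ``(hN, cN)`` (length 4*np) and applies
  one linear layer without activation, reshaped to the 2 x np output.

Everything is plain numpy: parameters are explicit arrays, the forward
pass is a pure function of them, and an analytic reverse-mode gradient
(validated against finite differences in the test-suite) drives training.

The exact gate wiring is a named, versioned configuration
(``wiring="lstm-v1"``) so alternative cell graphs can be added without
invalidating saved models.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .schedules import SamplingSchedule

__all__ = [
    "LinearLayerParams",
    "NetworkParams",
    "linear_forward",
    "encode_inputs",
    "cell_forward",
    "head_forward",
    "network_forward",
    "forward_batch",
    "init_params",
    "save_params",
    "load_params",
    "param_count",
]

GATE_NAMES = ("f", "i", "g", "o")
WIRING = "lstm-v1"


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # overflow-free logistic via the tanh identity
    return 0.5 * (1.0 + np.tanh(0.5 * x))


_ACTIVATIONS = {
    "tanh": np.tanh,
    "sigmoid": _sigmoid,
    "none": lambda x: x,
}


@dataclasses.dataclass
class LinearLayerParams:
    """One dense layer: y = a(A x + b)."""

    kernel: np.ndarray  # (out, in)
    bias: np.ndarray  # (out,)
    activation: str

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=np.float64)
        self.bias = np.asarray(self.bias, dtype=np.float64)
        if self.kernel.ndim != 2 or self.bias.ndim != 1:
            raise ValueError("kernel must be 2-D and bias 1-D")
        if self.kernel.shape[0] != self.bias.shape[0]:
            raise ValueError(
                f"kernel rows {self.kernel.shape[0]} != bias length "
                f"{self.bias.shape[0]}"
            )
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


def linear_forward(layer: LinearLayerParams, x: np.ndarray) -> np.ndarray:
    """Apply a dense layer to a vector ``(in,)`` or batch ``(B, in)``."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != layer.kernel.shape[1]:
        raise ValueError(
            f"input length {x.shape[-1]} != layer in-dimension "
            f"{layer.kernel.shape[1]}"
        )
    z = x @ layer.kernel.T + layer.bias
    return _ACTIVATIONS[layer.activation](z)


@dataclasses.dataclass
class NetworkParams:
    """All weights of the reconstruction graph, with shape metadata.

    ``gate_sets`` holds one dict {f, i, g, o} of sigmoid layers when the
    cell weights are shared across the N applications (the default), or
    N dicts when untied.
    """

    sp: int
    n_points: int
    n_cells: int
    encoder_fid: LinearLayerParams  # tanh, 2sp -> 2np
    encoder_sched: LinearLayerParams  # tanh, 2np -> 2np
    gate_sets: list  # list of dicts name -> LinearLayerParams, sigmoid, 2np -> 2np
    head: LinearLayerParams  # none, 4np -> 2np
    wiring: str = WIRING

    def __post_init__(self) -> None:
        d = 2 * self.n_points
        if self.encoder_fid.kernel.shape != (d, 2 * self.sp):
            raise ValueError("encoder_fid shape mismatch")
        if self.encoder_sched.kernel.shape != (d, d):
            raise ValueError("encoder_sched shape mismatch")
        if len(self.gate_sets) not in (1, self.n_cells):
            raise ValueError("gate_sets must have length 1 (tied) or n_cells")
        for gates in self.gate_sets:
            if set(gates) != set(GATE_NAMES):
                raise ValueError(f"gates must be named {GATE_NAMES}")
            for g in gates.values():
                if g.kernel.shape != (d, d):
                    raise ValueError("gate shape mismatch")
        if self.head.kernel.shape != (d, 2 * d):
            raise ValueError("head shape mismatch")

    @property
    def tied(self) -> bool:
        return len(self.gate_sets) == 1

    def gates_at(self, step: int) -> dict:
        return self.gate_sets[0] if self.tied else self.gate_sets[step]

    def layers(self):
        """Yield (name, layer) pairs in a stable order."""
        yield "encoder_fid", self.encoder_fid
        yield "encoder_sched", self.encoder_sched
        for s, gates in enumerate(self.gate_sets):
            for g in GATE_NAMES:
                yield f"gate{s}_{g}", gates[g]
        yield "head", self.head


def schedule_mask_vector(schedule: SamplingSchedule) -> np.ndarray:
    """Length-2np 0/1 vector: ones at the real slot ``i`` and imaginary
    slot ``n_points + i`` of every sampled index ``i``."""
    m = np.zeros(2 * schedule.n_points)
    m[schedule.indices] = 1.0
    m[schedule.n_points + schedule.indices] = 1.0
    return m


def encode_inputs(sparse: np.ndarray, schedule: SamplingSchedule,
                  params: NetworkParams):
    """Encode the two network inputs into the initial (h0, c0) states.

    The 2 x sp sparse matrix is flattened row-major (full real row, then
    full imaginary row) and passed through the tanh data encoder; the
    schedule becomes a 0/1 mask of length 2np through the tanh schedule
    encoder.
    """
    if schedule.n_points != params.n_points:
        raise ValueError(
            f"schedule grid {schedule.n_points} != model n_points "
            f"{params.n_points}"
        )
    sparse = np.asarray(sparse, dtype=np.float64)
    flat = sparse.reshape(*sparse.shape[:-2], 2 * sparse.shape[-1])
    h0 = linear_forward(params.encoder_fid, flat)
    c0 = linear_forward(params.encoder_sched, schedule_mask_vector(schedule))
    return h0, c0


def cell_forward(h: np.ndarray, c: np.ndarray, gates: dict):
    """One application of the modified LSTM cell.

    All four gates are sigmoid layers of ``h`` alone;
    ``c' = c*f + i*g`` and ``h' = o*c'``.
    """
    f = linear_forward(gates["f"], h)
    i = linear_forward(gates["i"], h)
    g = linear_forward(gates["g"], h)
    o = linear_forward(gates["o"], h)
    c_new = c * f + i * g
    h_new = o * c_new
    return h_new, c_new


def head_forward(h: np.ndarray, c: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Concatenate (h, c), apply the activation-free output layer and
    reshape to 2 x np (row 0 real, row 1 imaginary)."""
    hc = np.concatenate([h, c], axis=-1)
    y = linear_forward(params.head, hc)
    return y.reshape(*y.shape[:-1], 2, params.n_points)


def network_forward(sparse: np.ndarray, schedule: SamplingSchedule,
                    params: NetworkParams) -> np.ndarray:
    """Full forward pass: (2, sp) -> (2, np), or batched (B, 2, sp) ->
    (B, 2, np).  Deterministic for fixed parameters."""
    h, c = encode_inputs(sparse, schedule, params)
    if h.ndim == 2 and np.ndim(c) == 1:
        c = np.broadcast_to(c, h.shape)
    for step in range(params.n_cells):
        h, c = cell_forward(h, c, params.gates_at(step))
    return head_forward(h, c, params)


def forward_batch(X: np.ndarray, mask: np.ndarray, params: NetworkParams,
                  with_cache: bool = False):
    """Batched forward on pre-flattened inputs.

    ``X`` is (B, 2sp) flattened sparse data, ``mask`` the length-2np
    schedule mask.  With ``with_cache=True`` also returns the
    intermediates needed by :func:`backward_batch`.  Arithmetic follows
    the dtype of ``X`` (float32 inputs make training markedly faster on
    one CPU; parameters stay float64 masters).
    """
    B = X.shape[0]
    dt = X.dtype if X.dtype in (np.float32, np.float64) else np.float64

    def k(layer):
        return layer.kernel.astype(dt, copy=False)

    def b(layer):
        return layer.bias.astype(dt, copy=False)

    h = np.tanh(X @ k(params.encoder_fid).T + b(params.encoder_fid))
    c0_vec = np.tanh(k(params.encoder_sched) @ mask.astype(dt, copy=False)
                     + b(params.encoder_sched))
    c = np.broadcast_to(c0_vec, h.shape).copy()
    cache = {"X": X, "mask": mask, "h0": h, "c0_vec": c0_vec, "steps": []}
    for step in range(params.n_cells):
        gates = params.gates_at(step)
        f = _sigmoid(h @ k(gates["f"]).T + b(gates["f"]))
        i = _sigmoid(h @ k(gates["i"]).T + b(gates["i"]))
        g = _sigmoid(h @ k(gates["g"]).T + b(gates["g"]))
        o = _sigmoid(h @ k(gates["o"]).T + b(gates["o"]))
        c_new = c * f + i * g
        h_new = o * c_new
        if with_cache:
            cache["steps"].append(
                {"h_in": h, "c_in": c, "f": f, "i": i, "g": g, "o": o,
                 "c_out": c_new}
            )
        h, c = h_new, c_new
    hc = np.concatenate([h, c], axis=-1)
    Y = (hc @ k(params.head).T + b(params.head)).reshape(
        B, 2, params.n_points)
    if with_cache:
        cache["hc"] = hc
        return Y, cache
    return Y


def backward_batch(dY: np.ndarray, cache: dict, params: NetworkParams) -> dict:
    """Reverse-mode gradients of a scalar loss through the whole graph.

    ``dY`` is dLoss/dY, shape (B, 2, np).  Returns a dict mapping the
    layer names of ``NetworkParams.layers()`` to {"kernel": dA, "bias": db}.
    Gate gradients accumulate over the N applications when weights are
    tied.
    """
    B = dY.shape[0]
    d = 2 * params.n_points
    dt = dY.dtype if dY.dtype in (np.float32, np.float64) else np.float64
    grads = {name: {"kernel": np.zeros(layer.kernel.shape, dtype=dt),
                    "bias": np.zeros(layer.bias.shape, dtype=dt)}
             for name, layer in params.layers()}

    dflat = dY.reshape(B, d)
    grads["head"]["kernel"] += dflat.T @ cache["hc"]
    grads["head"]["bias"] += dflat.sum(axis=0)
    dhc = dflat @ params.head.kernel.astype(dt, copy=False)
    dh, dc = dhc[:, :d], dhc[:, d:]
    dh = dh.copy()
    dc = dc.copy()

    for step in range(params.n_cells - 1, -1, -1):
        s = cache["steps"][step]
        gname = f"gate{0 if params.tied else step}"
        gates = params.gates_at(step)
        # h_out = o * c_out ; c_out = c_in*f + i*g
        do = dh * s["c_out"]
        dc_out = dc + dh * s["o"]
        dc = dc_out * s["f"]
        df = dc_out * s["c_in"]
        di = dc_out * s["g"]
        dg = dc_out * s["i"]
        dh_in = np.zeros_like(dh)
        for name, dact, act in (("f", df, s["f"]), ("i", di, s["i"]),
                                ("g", dg, s["g"]), ("o", do, s["o"])):
            dz = dact * act * (1.0 - act)  # sigmoid'
            grads[f"{gname}_{name}"]["kernel"] += dz.T @ s["h_in"]
            grads[f"{gname}_{name}"]["bias"] += dz.sum(axis=0)
            dh_in += dz @ gates[name].kernel.astype(dt, copy=False)
        dh = dh_in

    # data encoder (tanh)
    dz = dh * (1.0 - cache["h0"] ** 2)
    grads["encoder_fid"]["kernel"] += dz.T @ cache["X"]
    grads["encoder_fid"]["bias"] += dz.sum(axis=0)
    # schedule encoder: c0 is shared across the batch, so its gradient is
    # the batch sum of dc
    dz0 = dc.sum(axis=0) * (1.0 - cache["c0_vec"] ** 2)
    grads["encoder_sched"]["kernel"] += np.outer(dz0, cache["mask"])
    grads["encoder_sched"]["bias"] += dz0
    return grads


def _glorot(rng: np.random.Generator, n_out: int, n_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_out, n_in))


def init_params(sp: int, n_points: int, n_cells: int = 3, seed=0,
                tied: bool = True) -> NetworkParams:
    """Glorot-uniform kernels, zero biases, fully seeded."""
    if sp > n_points:
        raise ValueError(f"sp={sp} cannot exceed n_points={n_points}")
    rng = np.random.default_rng(seed)
    d = 2 * n_points
    enc_fid = LinearLayerParams(_glorot(rng, d, 2 * sp), np.zeros(d), "tanh")
    enc_sched = LinearLayerParams(_glorot(rng, d, d), np.zeros(d), "tanh")
    n_sets = 1 if tied else n_cells
    gate_sets = [
        {g: LinearLayerParams(_glorot(rng, d, d), np.zeros(d), "sigmoid")
         for g in GATE_NAMES}
        for _ in range(n_sets)
    ]
    head = LinearLayerParams(_glorot(rng, d, 2 * d), np.zeros(d), "none")
    return NetworkParams(sp=sp, n_points=n_points, n_cells=n_cells,
                         encoder_fid=enc_fid, encoder_sched=enc_sched,
                         gate_sets=gate_sets, head=head)


def param_count(params: NetworkParams) -> int:
    """Total number of trainable scalars — a pure function of
    (sp, np, N, tied)."""
    return sum(layer.kernel.size + layer.bias.size
               for _, layer in params.layers())


def save_params(params: NetworkParams, path,
                schedule: SamplingSchedule | None = None,
                train_seed: int | None = None) -> None:
    """Serialise to a single ``.npz`` container with shape metadata.

    Recording (sp, n_points, N, wiring) — and the training schedule when
    given — lets :func:`load_params` refuse mismatched inference.
    """
    arrays = {}
    for name, layer in params.layers():
        arrays[f"{name}__kernel"] = layer.kernel
        arrays[f"{name}__bias"] = layer.bias
    meta = {
        "sp": params.sp, "n_points": params.n_points,
        "n_cells": params.n_cells, "wiring": params.wiring,
        "tied": params.tied,
        "activations": {name: layer.activation
                        for name, layer in params.layers()},
    }
    if train_seed is not None:
        meta["train_seed"] = train_seed
    if schedule is not None:
        arrays["schedule__indices"] = schedule.indices
        meta["schedule_kind"] = schedule.kind
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_params(path, expect_sp: int | None = None,
                expect_n_points: int | None = None):
    """Load a model container; returns ``(params, schedule_or_None)``.

    Raises if the stored (sp, n_points) disagree with what the caller is
    about to apply the model to.
    """
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"].tobytes()).decode())
        if expect_sp is not None and meta["sp"] != expect_sp:
            raise ValueError(f"model was trained for sp={meta['sp']}, "
                             f"data has sp={expect_sp}")
        if expect_n_points is not None and meta["n_points"] != expect_n_points:
            raise ValueError(
                f"model reconstructs n_points={meta['n_points']}, "
                f"requested {expect_n_points}")
        acts = meta["activations"]

        def layer(name):
            return LinearLayerParams(z[f"{name}__kernel"], z[f"{name}__bias"],
                                     acts[name])

        n_sets = 1 if meta["tied"] else meta["n_cells"]
        gate_sets = [{g: layer(f"gate{s}_{g}") for g in GATE_NAMES}
                     for s in range(n_sets)]
        params = NetworkParams(
            sp=meta["sp"], n_points=meta["n_points"],
            n_cells=meta["n_cells"],
            encoder_fid=layer("encoder_fid"),
            encoder_sched=layer("encoder_sched"),
            gate_sets=gate_sets, head=layer("head"),
            wiring=meta["wiring"],
        )
        schedule = None
        if "schedule__indices" in z:
            schedule = SamplingSchedule(
                indices=z["schedule__indices"],
                n_points=meta["n_points"],
                kind=meta.get("schedule_kind", "custom"),
            )
    return params, schedule
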