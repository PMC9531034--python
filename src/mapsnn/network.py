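"""Feed-forward spiking network: multi-spike neurons + state-free synapses.

Dataflow per layer and timestep, all on the autodiff tape:

1. weighted sum of the previous layer's response currents plus a
   per-neuron constant bias;
2. membrane update ``v[t] = decay * (v[t-dt] - u[t-dt]) + I[t]``;
3. firing gate (Linear or SFA mode) yielding the integer spike count
   ``s[t]`` and consumed potential ``u[t]``;
4. optionally, the trainable delayed 2-exponential response kernel
   applied as a causal convolution over the trailing window, producing
   the output current passed to the next layer.

Classification uses rate decoding: total output spike counts pass
through a softmax, trained with cross-entropy via
backpropagation-through-time.  The floor in the gate is non-
differentiable; training treats its derivative as the constant 1
(straight-through), so gradients flow through the smooth spike
intensity ``n*``.  A ``relaxed=True`` forward replaces the floor by the
identity — the exact function whose derivative the surrogate defines —
which is what finite-difference gradient checks probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .grids import SpikeGrid
from .kernel import PARAM_FLOOR

_FLOOR_EPS = 1e-9


@dataclass
class LayerSpec:
    """Configuration of one fully connected spiking layer.

    ``gate`` selects the firing mode: ``"linear"`` (constant per-spike
    cost, optional cap — ``s_max=1`` gives the binary single-spike
    neuron) or ``"sfa"`` (geometric threshold growth with inhibition
    coefficient ``q``).  ``apply_kernel=False`` passes raw spike counts
    to the next layer (used for the output layer and for plain binary
    baselines); otherwise each neuron filters its own spike train with
    its own trainable kernel.  ``surrogate="rect"`` swaps the unit
    straight-through factor for a rectangular window of width
    ``rect_width`` (mV) around threshold, the convention of binary-spike
    baselines.
    """

    n_in: int
    n_out: int
    gate: str = "sfa"             # "linear" | "sfa"
    v_th: float = 2.0
    q: float = 1.2
    s_max: Optional[int] = None   # linear-mode cap; SFA uses sfa_s_max
    sfa_s_max: int = 64           # numerical guard on q**s
    decay: float = 0.2
    apply_kernel: bool = True
    kernel_size: int = 7
    delay_init: float = 0.8
    ab_init: Tuple[float, float] = (0.5, 1.0)   # uniform range for a, b
    surrogate: str = "unit"       # "unit" | "rect"
    rect_width: float = 1.0
    weight_mask: Optional[np.ndarray] = None   # 0/1 connectivity (n_out x n_in)

    def __post_init__(self) -> None:
        if self.weight_mask is not None:
            self.weight_mask = np.asarray(self.weight_mask, dtype=float)
            if self.weight_mask.shape != (self.n_out, self.n_in):
                raise ValueError("weight_mask must be (n_out x n_in)")
        if self.gate not in ("linear", "sfa"):
            raise ValueError(f"unknown gate {self.gate!r}")
        if self.gate == "sfa" and not self.q > 1:
            raise ValueError("SFA gate requires q > 1")
        if not 0.0 < self.decay < 1.0:
            raise ValueError("decay factor must lie in (0, 1)")
        if self.surrogate not in ("unit", "rect"):
            raise ValueError(f"unknown surrogate {self.surrogate!r}")


class Layer:
    """Runtime layer: parameter tensors initialised from a `LayerSpec`."""

    def __init__(self, spec: LayerSpec, rng: np.random.Generator):
        self.spec = spec
        std = math.sqrt(2.0 / (spec.n_in + spec.n_out))  # Xavier normal
        self.W = Tensor(rng.normal(0.0, std, (spec.n_out, spec.n_in)),
                        requires_grad=True)
        self.bias = Tensor(np.zeros((spec.n_out, 1)), requires_grad=True)
        if spec.apply_kernel:
            lo, hi = spec.ab_init
            self.a = Tensor(rng.uniform(lo, hi, (spec.n_out, 1)), requires_grad=True)
            self.b = Tensor(rng.uniform(lo, hi, (spec.n_out, 1)), requires_grad=True)
            self.delay = Tensor(np.full((spec.n_out, 1), spec.delay_init),
                                requires_grad=True)
        else:
            self.a = self.b = self.delay = None
        if spec.weight_mask is not None:
            self.W.data *= spec.weight_mask

    def parameters(self) -> List[Tensor]:
        ps = [self.W, self.bias]
        if self.spec.apply_kernel:
            ps += [self.a, self.b, self.delay]
        return ps

    # -- kernel sampling (on tape) --------------------------------------

    def taps(self, dt: float) -> Tensor:
        """Sample per-neuron kernel taps from (a, b, delay), on the tape.

        Parameters are softly clamped at ``PARAM_FLOOR`` (zero gradient
        below it); the onset mask ``t >= delay`` is evaluated on forward
        values, so ``delay``'s gradient flows only through the smooth
        shifted argument of the active taps.
        """
        spec = self.spec
        a = (self.a - PARAM_FLOOR).relu() + PARAM_FLOOR
        b = (self.b - PARAM_FLOOR).relu() + PARAM_FLOOR
        if np.any(np.abs(a.data - b.data) < 1e-6):
            b = b + Tensor((np.abs(a.data - b.data) < 1e-6) * 1e-6)
        delay = (self.delay - PARAM_FLOOR).relu() + PARAM_FLOOR
        t = Tensor(np.arange(spec.kernel_size) * dt)      # [K]
        arg = t - delay                                   # [n_out, K]
        mask = Tensor((t.data >= delay.data).astype(float))
        return mask * ((arg * (-1) * a).exp() - (arg * (-1) * b).exp())

    # -- firing gate (on tape) ------------------------------------------

    def apply_gate(self, v: Tensor, relaxed: bool) -> Tuple[Tensor, Tensor]:
        """Return (spike count s, consumed potential u) for membrane v.

        In spiking mode ``s`` carries the floored integer forward value
        with a straight-through gradient; ``relaxed`` replaces the floor
        by the identity (continuous spike intensity).
        """
        spec = self.spec
        if spec.gate == "linear":
            n_star = v * (1.0 / spec.v_th)
        else:
            # intensity log_q(v/v_th (q-1) + 1) for v >= 0; below zero its
            # C1 linear continuation (slope at v=0), so negative membranes
            # still emit s=0 but keep a gradient path instead of dying
            c = (spec.q - 1.0) / spec.v_th
            slope0 = c / math.log(spec.q)
            pos_mask = Tensor((v.data >= 0).astype(float))
            pos = (v.relu() * c + 1.0).log() * (1.0 / math.log(spec.q))
            neg = v * slope0
            n_star = pos_mask * pos + (Tensor(1.0) - pos_mask) * neg
        if relaxed:
            s = n_star
        else:
            hi = spec.s_max if spec.gate == "linear" else spec.sfa_s_max
            floored = np.floor(n_star.data + _FLOOR_EPS)
            floored = np.clip(floored, 0, hi) if hi is not None else np.maximum(floored, 0)
            if spec.surrogate == "rect":
                win = (np.abs(v.data - spec.v_th) <= spec.rect_width / 2.0)
                factor = Tensor(win.astype(float) * spec.v_th)
            else:
                factor = Tensor(np.ones_like(n_star.data))
            # straight-through: forward = floored count, backward = factor
            s = Tensor(floored) + factor * (n_star - Tensor(n_star.data))
        if spec.gate == "linear":
            u = s * spec.v_th
        else:
            u = ((s * math.log(spec.q)).exp() - 1.0) * (spec.v_th / (spec.q - 1.0))
        return s, u


@dataclass
class DecodeResult:
    """Rate decoding of output spikes: counts, class probabilities, loss."""

    Z: np.ndarray
    p: np.ndarray
    loss: Optional[float] = None

    @property
    def predictions(self) -> np.ndarray:
        return np.argmax(self.p, axis=-1)


def decode(output_spikes) -> DecodeResult:
    """Rate decoding: ``Z_i = sum_t S_i[t]``, ``p = softmax(Z)``."""
    if isinstance(output_spikes, SpikeGrid):
        output_spikes = output_spikes.counts
    S = np.asarray(output_spikes, dtype=float)
    Z = S.sum(axis=-1)
    return DecodeResult(Z=Z, p=ad.softmax(Z))


def cross_entropy(p, y_onehot) -> float:
    """Cross-entropy ``-sum_i y_i log p_i`` (mean over a leading batch)."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y_onehot, dtype=float)
    nll = -(y * np.log(p + 1e-300)).sum(axis=-1)
    return float(np.mean(nll))


@dataclass
class ForwardResult:
    """Network forward pass: output spike counts plus rate decoding."""

    output_spikes: np.ndarray      # [batch x L_out x T] integer counts (spiking mode)
    decode: DecodeResult
    loss_node: Optional[Tensor] = None   # tape node, present when targets given


class Network:
    """A stack of spiking layers sharing one simulation step length."""

    def __init__(self, specs: Sequence[LayerSpec], dt: float, seed: int = 0):
        for prev, nxt in zip(specs, specs[1:]):
            if prev.n_out != nxt.n_in:
                raise ValueError(
                    f"layer size mismatch: {prev.n_out} out vs {nxt.n_in} in"
                )
        if not dt > 0:
            raise ValueError("dt must be positive")
        self.dt = dt
        rng = np.random.default_rng(seed)
        self.layers = [Layer(s, rng) for s in specs]

    def parameters(self) -> List[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(
        self,
        x: np.ndarray,
        targets: Optional[np.ndarray] = None,
        relaxed: bool = False,
    ) -> ForwardResult:
        """Run the spatio-temporal dataflow on a batch.

        ``x``: input spike counts ``[batch x channels x T]`` (a single
        sample ``[channels x T]`` is auto-promoted).  With ``targets``
        (integer class labels) the cross-entropy loss node is built so
        ``backward()`` can run BPTT.
        """
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != self.layers[0].spec.n_in:
            raise ValueError(
                f"input has {x.shape[1]} channels, first layer expects "
                f"{self.layers[0].spec.n_in}"
            )
        T = x.shape[2]
        O = Tensor(x)
        for layer in self.layers:
            spec = layer.spec
            W = layer.W
            if spec.weight_mask is not None:
                # structural sparsity: masked entries carry no signal and,
                # through the product rule, receive zero gradient
                W = W * Tensor(spec.weight_mask)
            I_hat = ad.layer_matmul(W, O) + layer.bias
            v = Tensor(np.zeros((x.shape[0], spec.n_out)))
            u = Tensor(np.zeros((x.shape[0], spec.n_out)))
            cols: List[Tensor] = []
            for t in range(T):
                v = (v - u) * spec.decay + ad.getcol(I_hat, t)
                s, u = layer.apply_gate(v, relaxed)
                cols.append(s)
            S = ad.stack_time(cols)
            # Kernel time is measured in timestep units: the initial shape
            # rates (~0.5-1.0) and delay (0.8) describe a response bump a few
            # steps wide regardless of the physical bin width.
            O = ad.causal_conv(S, layer.taps(1.0)) if spec.apply_kernel else S
        out_spikes = S.data
        Z_node = S.sum_last()
        dec = DecodeResult(Z=Z_node.data, p=ad.softmax(Z_node.data))
        loss_node = None
        if targets is not None:
            targets = np.asarray(targets).reshape(-1)
            loss_node = ad.cross_entropy_mean(Z_node, targets)
            y_onehot = np.eye(dec.p.shape[-1])[targets]
            dec.loss = cross_entropy(dec.p, y_onehot)
        return ForwardResult(output_spikes=out_spikes, decode=dec,
                             loss_node=loss_node)


    # -- checkpointing ---------------------------------------------------

    _PARAM_NAMES = ("W", "bias", "a", "b", "delay")

    def save(self, path: str) -> None:
        """Write layer specs and all parameters as a JSON checkpoint."""
        import dataclasses
        import json

        payload = {"dt": self.dt, "layers": []}
        for layer in self.layers:
            spec = dataclasses.asdict(layer.spec)
            if spec["weight_mask"] is not None:
                spec["weight_mask"] = np.asarray(spec["weight_mask"]).tolist()
            params = {name: getattr(layer, name).data.tolist()
                      for name in self._PARAM_NAMES
                      if getattr(layer, name) is not None}
            payload["layers"].append({"spec": spec, "params": params})
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "Network":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        specs = []
        for entry in payload["layers"]:
            spec_kwargs = dict(entry["spec"])
            if spec_kwargs.get("ab_init") is not None:
                spec_kwargs["ab_init"] = tuple(spec_kwargs["ab_init"])
            specs.append(LayerSpec(**spec_kwargs))
        net = cls(specs, dt=payload["dt"])
        for layer, entry in zip(net.layers, payload["layers"]):
            for name, value in entry["params"].items():
                getattr(layer, name).data = np.asarray(value, dtype=float)
        return net


# -- training -------------------------------------------------------------


@dataclass
class TrainConfig:
    epochs: int = 50
    lr: float = 1e-3            # Adam step size
    batch_size: int = 32
    seed: int = 0
    shuffle: bool = True
    target_accuracy: Optional[float] = None   # early record, no early stop


@dataclass
class TrainHistory:
    loss: List[float] = field(default_factory=list)
    accuracy: List[float] = field(default_factory=list)
    epochs_to_target: Optional[int] = None    # 1-based epoch index

    @property
    def final_accuracy(self) -> float:
        return self.accuracy[-1]


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _as_arrays(dataset) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(dataset, tuple):
        X, y = dataset
        return np.asarray(X, dtype=float), np.asarray(y)
    X = np.stack([g.counts for g in dataset]).astype(float)
    y = np.array([g.label for g in dataset])
    if any(v is None for v in y.tolist()):
        raise ValueError("dataset grids must carry labels for training")
    return X, y.astype(int)


def train(net: Network, dataset, cfg: TrainConfig = TrainConfig()) -> TrainHistory:
    """Mini-batch BPTT training with Adam; logs per-epoch loss/accuracy.

    ``dataset`` is either a list of labelled `SpikeGrid`s or an
    ``(X [N x C x T], y [N])`` pair.  Aborts with a diagnostic on NaN
    loss.  Fixed seed gives a bit-identical loss history on the same
    platform (batch order and initialisation are both generator-driven).
    """
    X, y = _as_arrays(dataset)
    n = len(y)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.parameters(), lr=cfg.lr)
    hist = TrainHistory()
    for epoch in range(cfg.epochs):
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            opt.zero_grad()
            res = net.forward(X[idx], targets=y[idx])
            loss_val = float(res.loss_node.data)
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch + 1}"
                )
            res.loss_node.backward()
            opt.step()
            epoch_loss += loss_val * len(idx)
        full = net.forward(X)
        acc = float(np.mean(full.decode.predictions == y))
        hist.loss.append(epoch_loss / n)
        hist.accuracy.append(acc)
        if (cfg.target_accuracy is not None and hist.epochs_to_target is None
                and acc >= cfg.target_accuracy):
            hist.epochs_to_target = epoch + 1
    return hist
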