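"""Canonical network configurations for the synthetic event-stream task.

The four configurations mirror the ablation structure of the model
family: a binary single-spike baseline (``ssp``), the same with
trainable response kernels (``ssp+sfsrm``), the multi-spike SFA neuron
alone (``msp``), and the full model (``msp+sfsrm``).
"""

from __future__ import annotations

from typing import List

from .data import SyntheticTaskSpec
from .network import LayerSpec, Network

CONFIGS = ("ssp", "ssp+sfsrm", "msp", "msp+sfsrm")


def make_layer_specs(
    n_in: int, n_classes: int, hidden: int = 64, config: str = "msp+sfsrm",
    v_th: float = 2.0, q: float = 1.2, decay: float = 0.2,
    kernel_size: int = 7,
) -> List[LayerSpec]:
    """Two-layer specs (hidden + readout) for one ablation configuration.

    ``ssp`` variants use the binary linear gate (cap 1); ``msp``
    variants use the SFA gate.  All gates default to the unit
    straight-through surrogate — the rectangular window conventional in
    binary-spike baselines is available per layer, but with a 2 mV
    threshold its default 1 mV window is unreachable from a silent
    start, leaving no gradient support (see the methods note).
    ``+sfsrm`` attaches the trainable response kernel to the hidden
    layer; the readout layer always emits raw spike counts for rate
    decoding.
    """
    if config not in CONFIGS:
        raise ValueError(f"unknown config {config!r}; expected one of {CONFIGS}")
    binary = config.startswith("ssp")
    with_kernel = config.endswith("+sfsrm")
    gate_kwargs = (
        dict(gate="linear", s_max=1, surrogate="unit")
        if binary else dict(gate="sfa", q=q, surrogate="unit")
    )
    hidden_spec = LayerSpec(n_in=n_in, n_out=hidden, v_th=v_th, decay=decay,
                            apply_kernel=with_kernel, kernel_size=kernel_size,
                            **gate_kwargs)
    out_spec = LayerSpec(n_in=hidden, n_out=n_classes, v_th=v_th, decay=decay,
                         apply_kernel=False, **gate_kwargs)
    return [hidden_spec, out_spec]


def make_dual_channel_specs(
    channels_per_polarity: int = 1156, hidden_per_block: int = 400,
    n_classes: int = 10, config: str = "msp+sfsrm", **kwargs,
) -> List[LayerSpec]:
    """Two-polarity event-camera topology with disjoint hidden blocks.

    The two polarity channels are processed in parallel: each block of
    ``hidden_per_block`` neurons is fully connected to its own polarity's
    channels and to nothing else (a block-diagonal weight mask), and both
    blocks feed the dense readout — the (2 x 1156)-(400+400)-10 layout
    for 34x34 event-camera digits.
    """
    import numpy as np

    n_in = 2 * channels_per_polarity
    n_hidden = 2 * hidden_per_block
    mask = np.zeros((n_hidden, n_in))
    mask[:hidden_per_block, :channels_per_polarity] = 1.0
    mask[hidden_per_block:, channels_per_polarity:] = 1.0
    specs = make_layer_specs(n_in, n_classes, hidden=n_hidden, config=config,
                             **kwargs)
    specs[0].weight_mask = mask
    return specs


def make_network(
    task: SyntheticTaskSpec, hidden: int = 64, config: str = "msp+sfsrm",
    seed: int = 0, **kwargs,
) -> Network:
    """Build the two-layer network matched to a synthetic task spec."""
    specs = make_layer_specs(task.n_channels, task.n_classes, hidden=hidden,
                             config=config, **kwargs)
    return Network(specs, dt=task.dt, seed=seed)
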