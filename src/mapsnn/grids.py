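"""The universal signal container: integer spike counts on a time grid."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class SpikeGrid:
    """Integer spike counts on a [channels x timesteps] grid.

    Each column collects every spike that fell in the half-open-left
    window ``((k)*dt, (k+1)*dt]``.  Counts may exceed 1 per bin —
    multi-spike neurons and stacked sensor events both rely on that —
    while binary (single-spike) signals are the 0/1 special case.
    """

    counts: np.ndarray
    dt: float
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D [channels x timesteps] array")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_channels(self) -> int:
        return self.counts.shape[0]

    @property
    def n_timesteps(self) -> int:
        return self.counts.shape[1]

    @property
    def total_time(self) -> float:
        return self.n_timesteps * self.dt

    def total_spikes(self) -> int:
        return int(self.counts.sum())
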