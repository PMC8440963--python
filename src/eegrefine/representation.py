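"""3D input representation: electrodes mapped to a scalp grid, stacked in time.

Each trial becomes a (grid_height x grid_width x time) volume in which the
cell of every placed electrode carries that electrode's time course and every
unplaced cell is identically zero, preserving the spatial neighbourhood
relations of the 10-20 layout for the convolutional network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EpochSet, N_CLASSES, encode_label
from .montage import Montage, MontageError

__all__ = ["Tensor3DBatch", "build_tensor", "extract_electrodes", "standardize"]


class DegenerateChannelError(ValueError):
    """A placed electrode has zero variance and cannot be z-scored."""


@dataclass
class Tensor3DBatch:
    """Grid-mapped network input: data is trial x height x width x time (uV)."""

    data: np.ndarray
    labels: np.ndarray  # trial x 4 one-hot
    montage: Montage

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be trial x height x width x time")
        n, h, w, _ = self.data.shape
        if (h, w) != (self.montage.grid_height, self.montage.grid_width):
            raise ValueError("grid dims do not match montage")
        if self.labels.shape != (n, N_CLASSES):
            raise ValueError("labels must be trial x 4 one-hot")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def input_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def class_ids(self) -> np.ndarray:
        return np.argmax(self.labels, axis=1)

    def subset(self, indices) -> "Tensor3DBatch":
        return Tensor3DBatch(self.data[indices], self.labels[indices], self.montage)


def build_tensor(eset: EpochSet, montage: Montage | None = None) -> Tensor3DBatch:
    """Map an equal-length EpochSet onto the montage grid.

    data[t, r, c, :] is the signal of the electrode placed at (r, c) for trial
    t; unplaced cells are exactly zero.  Trial order is preserved, so the map
    is invertible on placed cells.
    """
    m = montage or eset.montage
    missing = [e for e in eset.electrodes if e not in m.placement]
    if missing:
        raise MontageError(f"electrodes not in montage placement: {missing}")
    lengths = {e.n_samples for e in eset}
    if len(lengths) != 1:
        raise ValueError(f"epochs have unequal lengths {sorted(lengths)}")
    (T,) = lengths
    n = len(eset)
    data = np.zeros((n, m.grid_height, m.grid_width, T), dtype=np.float64)
    rows = [m.placement[e] for e in eset.electrodes]
    for i, epoch in enumerate(eset):
        for ch, (r, c) in enumerate(rows):
            data[i, r, c, :] = epoch.signal[ch]
    labels = np.stack([encode_label(e.label) for e in eset])
    return Tensor3DBatch(data, labels, m)


def extract_electrodes(batch: Tensor3DBatch, electrodes: list[str]) -> np.ndarray:
    """Read placed cells back out as trial x electrode x time (inverse of build)."""
    cells = [batch.montage.placement[e] for e in electrodes]
    return np.stack([batch.data[:, r, c, :] for (r, c) in cells], axis=1)


def electrode_stats(batch: Tensor3DBatch, electrodes: list[str]):
    """Per-electrode mean/std pooled over trials and time (training-fold use)."""
    sig = extract_electrodes(batch, electrodes)  # n x e x t
    mean = sig.mean(axis=(0, 2))
    std = sig.std(axis=(0, 2))
    return mean, std


def standardize(
    batch: Tensor3DBatch,
    stats: tuple[np.ndarray, np.ndarray] | None,
    electrodes: list[str],
) -> Tensor3DBatch:
    """Per-electrode z-scoring of placed cells; unplaced cells stay zero.

    ``stats`` must come from the training fold only; ``None`` is the identity.
    """
    if stats is None:
        return batch
    mean, std = stats
    bad = np.flatnonzero(std <= 0)
    if bad.size:
        names = [electrodes[i] for i in bad]
        raise DegenerateChannelError(f"zero-variance electrode(s): {names}")
    data = batch.data.copy()
    for ch, e in enumerate(electrodes):
        r, c = batch.montage.placement[e]
        data[:, r, c, :] = (data[:, r, c, :] - mean[ch]) / std[ch]
    return Tensor3DBatch(data, batch.labels.copy(), batch.montage)
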