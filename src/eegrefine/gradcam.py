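"""Signed Grad-CAM saliency on the EEG input axes, and its segmentation into
useful/useless time intervals.

For a chosen branch and target class, each final-conv filter map is weighted
by the global average of the gradient of the pre-softmax class score with
respect to that map; the weighted sum is kept signed (no rectification —
negatively contributing regions are the whole point), linearly upsampled from
conv resolution back to grid-and-time resolution, read out at each placed
electrode and normalised to unit peak magnitude per trial.  Positive runs
above a threshold become "useful" intervals, negative runs below its mirror
become "useless" ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import EpochSet, N_CLASSES
from .network import MultiBranchModel
from .representation import Tensor3DBatch, build_tensor

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledInterval",
    "SaliencyMap",
    "SampleSizeError",
    "gradcam",
    "resize_linear",
    "sample_for_attribution",
    "segment_intervals",
]


class SampleSizeError(ValueError):
    """Requested attribution sample is empty."""


@dataclass
class SaliencyMap:
    """Per-trial signed saliency: electrode x time, max |value| = 1 (or all 0)."""

    values: np.ndarray
    electrodes: list[str]
    trial_id: str
    branch: str
    target_class: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("saliency contains NaN/Inf")
        peak = np.abs(self.values).max()
        if peak > 1.0 + 1e-9:
            raise ValueError("saliency not normalised to unit peak")


@dataclass(frozen=True)
class LabeledInterval:
    """Half-open [start, end) sample interval on one electrode."""

    electrode: str
    start: int
    end: int
    kind: str  # "useful" | "useless"
    trial_id: str
    branch: str


def resize_linear(arr: np.ndarray, new_shape: tuple[int, ...]) -> np.ndarray:
    """Separable linear interpolation to new_shape, endpoints aligned."""
    out = arr.astype(np.float64)
    for axis, m in enumerate(new_shape):
        n = out.shape[axis]
        if n == m:
            continue
        if n == 1:
            out = np.repeat(out, m, axis=axis)
            continue
        pos = np.linspace(0.0, n - 1, m)
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, n - 1)
        frac = pos - lo
        sl_lo = np.take(out, lo, axis=axis)
        sl_hi = np.take(out, hi, axis=axis)
        shape = [1] * out.ndim
        shape[axis] = m
        frac = frac.reshape(shape)
        out = sl_lo * (1 - frac) + sl_hi * frac
    return out


def gradcam(
    model: MultiBranchModel,
    trial: np.ndarray,
    electrodes: list[str],
    montage,
    branch: str,
    target_class: int,
    trial_id: str = "",
) -> SaliencyMap:
    """Signed Grad-CAM for one trial (grid x time array) on one branch."""
    if trial.ndim != 3:
        raise ValueError("trial must be a single (h, w, t) volume")
    a3, grad, _ = model.conv_tap(trial[None], branch, target_class)
    # per-filter weight: global average of the score gradient over h, w, t
    alpha = grad[0].mean(axis=(0, 1, 2))  # (filters,)
    cam = np.einsum("xyzf,f->xyz", a3[0], alpha)  # signed, conv resolution
    h, w, t = trial.shape
    cam_full = resize_linear(cam, (h, w, t))
    values = np.stack([cam_full[r, c, :] for (r, c) in (montage.placement[e] for e in electrodes)])
    peak = np.abs(values).max()
    if peak == 0.0:
        logger.warning("degenerate saliency (all-zero gradient map) for trial %s", trial_id)
    else:
        values = values / peak
    return SaliencyMap(values, list(electrodes), trial_id, branch, target_class)


def _runs(mask: np.ndarray):
    """Yield (start, end) of maximal True runs (half-open)."""
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return zip(starts, ends)


DEFAULT_THRESHOLD = 0.35
DEFAULT_MIN_RUN = 64  # 256 ms at 250 Hz: integer-Hz peaks need ~1/4 s of data


def segment_intervals(
    smap: SaliencyMap,
    threshold: float = DEFAULT_THRESHOLD,
    min_run: int = DEFAULT_MIN_RUN,
) -> list[LabeledInterval]:
    """Maximal runs with value > +threshold (useful) / < -threshold (useless);
    runs shorter than min_run samples are discarded."""
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must be in [0, 1)")
    intervals: list[LabeledInterval] = []
    for ch, elec in enumerate(smap.electrodes):
        v = smap.values[ch]
        for kind, mask in (("useful", v > threshold), ("useless", v < -threshold)):
            for start, end in _runs(mask):
                if end - start >= min_run:
                    intervals.append(
                        LabeledInterval(
                            electrode=elec,
                            start=int(start),
                            end=int(end),
                            kind=kind,
                            trial_id=smap.trial_id,
                            branch=smap.branch,
                        )
                    )
    return intervals


def sample_for_attribution(eset: EpochSet, fraction: float, seed: int) -> EpochSet:
    """Class-stratified uniform subsample of round(fraction * N) trials.

    Deterministic given seed; a tenth of the data is the conventional default.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    n = len(eset)
    target = int(round(fraction * n))
    if target < 1:
        raise SampleSizeError(f"round({fraction} * {n}) = 0 trials")
    labels = eset.labels
    rng = np.random.default_rng(seed)
    # proportional allocation, largest remainder, ties to lower class id
    by_class = {c: np.flatnonzero(labels == c) for c in range(N_CLASSES)}
    quotas = {c: fraction * len(idx) for c, idx in by_class.items()}
    take = {c: int(np.floor(q)) for c, q in quotas.items()}
    short = target - sum(take.values())
    remainders = sorted(
        ((quotas[c] - take[c], -c) for c in by_class), reverse=True
    )
    for _, neg_c in remainders[:max(short, 0)]:
        take[-neg_c] += 1
    chosen: list[int] = []
    for c in range(N_CLASSES):
        idx = by_class[c]
        k = min(take[c], len(idx))
        if k:
            chosen.extend(rng.choice(idx, size=k, replace=False).tolist())
    order = rng.permutation(len(chosen))
    chosen = [chosen[i] for i in order]
    return eset.subset(chosen)


def attribute_set(
    model: MultiBranchModel,
    eset: EpochSet,
    threshold: float = DEFAULT_THRESHOLD,
    min_run: int = DEFAULT_MIN_RUN,
    target: str = "true",
) -> list[LabeledInterval]:
    """Grad-CAM + segmentation over all trials and all three branches, pooled.

    target "true" attributes each trial's own class (contribution to the
    correct answer); "predicted" uses the fused prediction instead.
    """
    batch: Tensor3DBatch = build_tensor(eset)
    if target == "predicted":
        classes = model.predict(batch.data)
    else:
        classes = batch.class_ids
    intervals: list[LabeledInterval] = []
    for i, epoch in enumerate(eset):
        for bspec in model.params.branches:
            smap = gradcam(
                model,
                batch.data[i],
                eset.electrodes,
                eset.montage,
                bspec.name,
                int(classes[i]),
                trial_id=epoch.trial_id,
            )
            intervals.extend(segment_intervals(smap, threshold, min_run))
    return intervals
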