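"""Epoched-EEG data model, recording ingestion, cropping and serialization.

An :class:`Epoch` is one cue-aligned trial (electrode x sample matrix in
microvolts plus metadata); an :class:`EpochSet` is an ordered, homogeneous
collection of them and is the exchange object every pipeline stage consumes
and produces.  Recordings arrive as EDF or GDF files (read through MNE);
internally a set round-trips losslessly through a ``signals.npy`` array plus a
JSON sidecar, so intermediate artifacts stay inspectable from any language.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .montage import Montage, default_montage

logger = logging.getLogger(__name__)

__all__ = [
    "Epoch",
    "EpochSet",
    "FormatError",
    "IntegrityError",
    "MontageMismatchError",
    "N_CLASSES",
    "crop_post_cue",
    "encode_label",
    "load_epochset",
    "read_recording",
    "save_epochset",
]

N_CLASSES = 4

#: annotation descriptions recognised as motor-imagery cues -> class id.
#: 769..772 are the standard event codes (left hand, right hand, feet, tongue);
#: the named variants are written by the synthetic EDF emitter.
CUE_EVENT_MAP: dict[str, int] = {
    "769": 0, "770": 1, "771": 2, "772": 3,
    "cue_left": 0, "cue_right": 1, "cue_feet": 2, "cue_tongue": 3,
}


class FormatError(ValueError):
    """Recording lacks required structure (event table, header fields)."""


class MontageMismatchError(ValueError):
    """Channel set does not match the expected montage."""


class IntegrityError(ValueError):
    """Sidecar metadata and array payload disagree."""


@dataclass
class Epoch:
    """One cue-aligned labeled trial.

    signal is electrode x sample in microvolts; ``cue_index`` is the sample of
    cue onset within ``signal``; ``label`` is a class id in {0,1,2,3} = left
    hand, right hand, feet, tongue.
    """

    signal: np.ndarray
    fs: float
    cue_index: int
    label: int
    subject_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (electrodes x samples)")
        if not np.isfinite(self.signal).all():
            raise ValueError("signal contains NaN/Inf")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not (0 <= self.label < N_CLASSES):
            raise ValueError(f"label {self.label} outside 0..{N_CLASSES - 1}")
        if not (0 <= self.cue_index <= self.signal.shape[1]):
            raise ValueError("cue_index outside signal")

    @property
    def n_electrodes(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class EpochSet:
    """Ordered collection of homogeneous epochs sharing fs and channel order."""

    epochs: list[Epoch]
    electrodes: list[str]
    montage: Montage
    provenance: str = "raw"

    def __post_init__(self) -> None:
        for e in self.epochs:
            if e.n_electrodes != len(self.electrodes):
                raise MontageMismatchError(
                    f"epoch {e.trial_id!r} has {e.n_electrodes} channels, "
                    f"expected {len(self.electrodes)}"
                )
            if self.epochs and e.fs != self.epochs[0].fs:
                raise ValueError("epochs disagree on sampling rate")

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def __getitem__(self, i):
        return self.epochs[i]

    @property
    def fs(self) -> float:
        if not self.epochs:
            raise ValueError("empty EpochSet has no sampling rate")
        return self.epochs[0].fs

    @property
    def labels(self) -> np.ndarray:
        return np.array([e.label for e in self.epochs], dtype=np.int64)

    def subset(self, indices, provenance: str | None = None) -> "EpochSet":
        return EpochSet(
            epochs=[self.epochs[i] for i in indices],
            electrodes=list(self.electrodes),
            montage=self.montage,
            provenance=provenance if provenance is not None else self.provenance,
        )

    def with_signals(self, signals: np.ndarray, provenance: str) -> "EpochSet":
        """Same metadata, new per-trial signal matrices (trial x elec x sample)."""
        if signals.shape[0] != len(self.epochs):
            raise ValueError("trial count mismatch")
        new = [replace(e, signal=signals[i]) for i, e in enumerate(self.epochs)]
        return EpochSet(new, list(self.electrodes), self.montage, provenance)


def encode_label(class_id: int) -> np.ndarray:
    """Class id -> length-4 one-hot vector."""
    if not (isinstance(class_id, (int, np.integer)) and 0 <= class_id < N_CLASSES):
        raise ValueError(f"class id {class_id!r} outside 0..{N_CLASSES - 1}")
    v = np.zeros(N_CLASSES, dtype=np.float64)
    v[class_id] = 1.0
    return v


def crop_post_cue(epoch: Epoch, duration: float) -> Epoch:
    """Crop the half-open window [cue, cue + floor(duration*fs)) after cue onset.

    At 250 Hz a 1.25 s crop is exactly 312 samples.  The result's cue_index is
    0, so cropping is idempotent.
    """
    n = int(np.floor(duration * epoch.fs))
    if n < 1:
        raise ValueError("crop window shorter than one sample")
    stop = epoch.cue_index + n
    if stop > epoch.n_samples:
        raise IndexError(
            f"crop [{epoch.cue_index}, {stop}) exceeds {epoch.n_samples} samples"
        )
    return replace(epoch, signal=epoch.signal[:, epoch.cue_index:stop], cue_index=0)


def crop_set(eset: EpochSet, duration: float) -> EpochSet:
    return EpochSet(
        [crop_post_cue(e, duration) for e in eset],
        list(eset.electrodes),
        eset.montage,
        eset.provenance,
    )


# ---------------------------------------------------------------------------
# recording ingestion
# ---------------------------------------------------------------------------

def read_recording(
    path: str,
    format: str | None = None,
    *,
    montage: Montage | None = None,
    window_seconds: float = 2.0,
    subject_id: str | None = None,
) -> EpochSet:
    """Read an EDF/GDF recording into cue-aligned epochs.

    One epoch is cut per recognised cue event, covering ``window_seconds``
    after cue onset (cue_index 0).  Channels whose name marks them as
    non-EEG (EOG) are dropped; exactly 22 EEG channels must remain.
    """
    import mne

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).lower()
    if fmt == "gdf":
        raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    elif fmt == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise FormatError(f"unsupported recording format {fmt!r}")

    drop = [ch for ch in raw.ch_names if "EOG" in ch.upper()]
    if drop:
        logger.info("dropping %d non-EEG channel(s): %s", len(drop), ", ".join(drop))
        raw.drop_channels(drop)

    m = montage or default_montage()
    if len(raw.ch_names) != len(m):
        raise MontageMismatchError(
            f"{len(raw.ch_names)} EEG channels after EOG removal, expected {len(m)}"
        )

    fs = float(raw.info["sfreq"])
    data_uv = raw.get_data() * 1e6  # MNE returns volts
    ann = raw.annotations
    if ann is None or len(ann) == 0:
        logger.warning("%s: no event annotations found; empty EpochSet", path)
        return EpochSet([], list(raw.ch_names), m, provenance="raw")

    sid = subject_id or os.path.splitext(os.path.basename(path))[0]
    win = int(np.floor(window_seconds * fs))
    epochs: list[Epoch] = []
    n_cues = 0
    for onset, desc in zip(ann.onset, ann.description):
        label = CUE_EVENT_MAP.get(str(desc).strip())
        if label is None:
            continue
        n_cues += 1
        start = int(round(onset * fs))
        if start + win > data_uv.shape[1]:
            logger.warning("cue at %.3f s too close to end of recording; skipped", onset)
            continue
        epochs.append(
            Epoch(
                signal=data_uv[:, start:start + win],
                fs=fs,
                cue_index=0,
                label=label,
                subject_id=sid,
                trial_id=f"{sid}-t{len(epochs):04d}",
            )
        )
    if n_cues == 0:
        logger.warning("%s: annotations present but no cue events; empty EpochSet", path)
    return EpochSet(epochs, list(raw.ch_names), m, provenance="raw")


# ---------------------------------------------------------------------------
# internal exchange format: signals.npy + meta.json
# ---------------------------------------------------------------------------

def save_epochset(eset: EpochSet, directory: str) -> None:
    """Write ``signals.npy`` (trial x electrode x sample) + ``meta.json``.

    Requires equal-length epochs (always true after cropping); the round trip
    is bit-exact.
    """
    lengths = {e.n_samples for e in eset}
    if len(lengths) > 1:
        raise ValueError(f"epochs have unequal lengths {sorted(lengths)}; crop first")
    os.makedirs(directory, exist_ok=True)
    arr = np.stack([e.signal for e in eset]) if len(eset) else np.zeros((0, len(eset.electrodes), 0))
    np.save(os.path.join(directory, "signals.npy"), arr)
    meta = {
        "fs": eset.epochs[0].fs if eset.epochs else None,
        "montage": eset.montage.name,
        "electrodes": eset.electrodes,
        "n_trials": len(eset),
        "n_channels": len(eset.electrodes),
        "n_samples": int(arr.shape[2]) if arr.ndim == 3 else 0,
        "labels": [int(e.label) for e in eset],
        "cue_indices": [int(e.cue_index) for e in eset],
        "subject_ids": [e.subject_id for e in eset],
        "trial_ids": [e.trial_id for e in eset],
        "provenance": eset.provenance,
    }
    with open(os.path.join(directory, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_epochset(directory: str, montage: Montage | None = None) -> EpochSet:
    arr = np.load(os.path.join(directory, "signals.npy"))
    with open(os.path.join(directory, "meta.json")) as fh:
        meta = json.load(fh)
    if arr.ndim != 3:
        raise IntegrityError("signals.npy is not a 3-D trial x channel x sample array")
    if arr.shape[0] != meta["n_trials"] or arr.shape[1] != meta["n_channels"]:
        raise IntegrityError(
            f"sidecar declares {meta['n_trials']}x{meta['n_channels']} trials/channels, "
            f"array is {arr.shape[0]}x{arr.shape[1]}"
        )
    if len(meta["electrodes"]) != meta["n_channels"]:
        raise IntegrityError("electrode list length disagrees with n_channels")
    m = montage or default_montage()
    if m.name != meta["montage"]:
        logger.warning("montage name %r in sidecar, using %r", meta["montage"], m.name)
    epochs = [
        Epoch(
            signal=arr[i],
            fs=float(meta["fs"]),
            cue_index=int(meta["cue_indices"][i]),
            label=int(meta["labels"][i]),
            subject_id=meta["subject_ids"][i],
            trial_id=meta["trial_ids"][i],
        )
        for i in range(arr.shape[0])
    ]
    return EpochSet(epochs, list(meta["electrodes"]), m, provenance=meta["provenance"])
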