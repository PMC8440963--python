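"""Synthetic cue-aligned motor-imagery EEG with known ground truth.

Each trial is the sum of three ingredients:

* a 1/f^a background (spectrally shaped white noise, independent per
  electrode) emulating the broadband EEG spectrum;
* a class-specific oscillatory burst — a Hann-windowed sinusoid of 300-500 ms
  at the class's characteristic frequency, full amplitude on its designated
  focal electrodes and volume-conducted at reduced gain to the rest of the
  scalp — standing in for cue-locked ERD/ERS-style band-power modulation over
  sensorimotor cortex (10 Hz over C3/C4 for the hand classes, 22 Hz over Cz
  for feet, 7 Hz over Fz for tongue, by default).  Like real event-related
  responses the burst follows the cue at a stereotyped latency;
* class-irrelevant narrowband interference (50 and 35 Hz by default, all
  electrodes) whose timing and amplitude distributions are identical across
  classes — the planted "bad" frequencies the pipeline is supposed to
  discover.  Interference arrives in transient episodes by default, timed the
  way cue-evoked artifacts are in practice (reflexive blinks and muscle
  tension right after the visual cue, before the imagery response develops);
  a continuous-tone mode is available.

The generator is deterministic per seed and can also emit an EDF+ file with
cue annotations so the recording reader can be exercised end to end.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field

import numpy as np

from .io import Epoch, EpochSet
from .montage import Montage, default_montage

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "ground_truth", "simulate", "write_edf"]

_DEFAULT_CLASS_BANDS = {
    0: (10.0, 10.0, ("C3",)),     # left hand: mu over contralateral motor cortex
    1: (10.0, 10.0, ("C4",)),     # right hand
    2: (22.0, 10.0, ("Cz",)),     # feet: beta over midline
    3: (7.0, 10.0, ("Fz",)),      # tongue: theta-ish frontal
}
_DEFAULT_INTERFERENCE = [(50.0, 6.0, "all"), (35.0, 6.0, "all")]


@dataclass
class SimConfig:
    n_trials_per_class: int = 40
    fs: float = 250.0
    duration: float = 1.25
    montage: Montage | None = None
    #: class id -> (center Hz, amplitude uV, electrode subset)
    class_bands: dict = field(default_factory=lambda: dict(_DEFAULT_CLASS_BANDS))
    #: list of (Hz, amplitude uV, electrode subset | "all")
    interference: list = field(default_factory=lambda: list(_DEFAULT_INTERFERENCE))
    #: "burst" plants each interference entry as one transient episode per
    #: trial at a class-independent random time; "continuous" keeps it on for
    #: the whole epoch
    interference_mode: str = "burst"
    noise_exponent: float = 1.0
    noise_scale: float = 1.0  # uV (std of the background)
    #: volume-conduction factor: fraction of the burst amplitude that reaches
    #: every electrode outside the designated focal subset
    spatial_spread: float = 0.6
    burst_ms: tuple[float, float] = (300.0, 500.0)
    #: event-related responses are cue-locked: burst onset latency is drawn
    #: uniformly from this window (seconds after the cue)
    burst_onset_s: tuple[float, float] = (0.45, 0.6)
    #: artifact episodes are cue-evoked too (blink/startle right after the
    #: cue): onset window (s) and duration range (ms)
    interference_onset_s: tuple[float, float] = (0.0, 0.08)
    interference_ms: tuple[float, float] = (300.0, 450.0)
    amplitude_jitter: float = 0.2  # +-20% uniform, identical across classes
    seed: int = 0
    subject_id: str = "sim"

    def __post_init__(self) -> None:
        if self.montage is None:
            self.montage = default_montage()
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        nyq = self.fs / 2
        for f, _, _ in self.interference:
            if f >= nyq:
                raise ValueError(f"interference at {f} Hz >= Nyquist {nyq}")
        for f, _, _ in self.class_bands.values():
            if f >= nyq:
                raise ValueError(f"class band at {f} Hz >= Nyquist {nyq}")


def ground_truth(cfg: SimConfig) -> tuple[set[int], set[int]]:
    """(class-informative band centers, planted nuisance frequencies), in Hz."""
    informative = {int(round(f)) for f, _, _ in cfg.class_bands.values()}
    nuisance = {int(round(f)) for f, _, _ in cfg.interference}
    overlap = informative & nuisance
    if overlap:
        logger.warning("frequencies planted as both informative and nuisance: %s",
                       sorted(overlap))
    return informative, nuisance


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int, exponent: float,
                scale: float) -> np.ndarray:
    """1/f^exponent (power) noise via spectral shaping, std = scale per channel."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shape[0] = 0.0
    shaped = np.fft.irfft(spec * shape, n=n, axis=1)
    std = shaped.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return scale * shaped / std


def simulate(cfg: SimConfig) -> EpochSet:
    """Generate a balanced, labelled, cue-aligned EpochSet (cue_index 0)."""
    rng = np.random.default_rng(cfg.seed)
    m = cfg.montage
    electrodes = m.electrodes
    ch_index = {e: i for i, e in enumerate(electrodes)}
    n_ch = len(electrodes)
    n = int(np.floor(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    epochs: list[Epoch] = []
    order = rng.permutation(
        np.repeat(np.arange(len(cfg.class_bands)), cfg.n_trials_per_class)
    )
    for trial, label in enumerate(order):
        sig = _pink_noise(rng, n_ch, n, cfg.noise_exponent, cfg.noise_scale)
        # class-specific burst(s)
        f0, amp, subset = cfg.class_bands[int(label)]
        lo_ms, hi_ms = cfg.burst_ms
        burst_len = int(rng.uniform(lo_ms, hi_ms) / 1000.0 * cfg.fs)
        start = int(rng.uniform(*cfg.burst_onset_s) * cfg.fs)
        start = min(start, max(n - burst_len, 0))
        burst_len = min(burst_len, n - start)
        phase = rng.uniform(0, 2 * np.pi)
        env = np.hanning(burst_len)
        tone = amp * np.sin(2 * np.pi * f0 * t[start:start + burst_len] + phase) * env
        focal = {ch_index[e] for e in subset}
        for ch in range(n_ch):
            gain = 1.0 if ch in focal else cfg.spatial_spread
            sig[ch, start:start + burst_len] += gain * tone
        # class-irrelevant interference, same distribution for every class
        for f_i, a_i, sub in cfg.interference:
            chans = range(n_ch) if sub == "all" else [ch_index[e] for e in sub]
            a = a_i * (1.0 + cfg.amplitude_jitter * rng.uniform(-1, 1))
            ph = rng.uniform(0, 2 * np.pi)
            if cfg.interference_mode == "burst":
                ilen = int(rng.uniform(*cfg.interference_ms) / 1000.0 * cfg.fs)
                istart = int(rng.uniform(*cfg.interference_onset_s) * cfg.fs)
                istart = min(istart, max(n - ilen, 0))
                ilen = min(ilen, n - istart)
                wave = np.zeros(n)
                wave[istart:istart + ilen] = (
                    a * np.sin(2 * np.pi * f_i * t[istart:istart + ilen] + ph)
                    * np.hanning(ilen)
                )
            else:
                wave = a * np.sin(2 * np.pi * f_i * t + ph)
            for ch in chans:
                sig[ch, :] += wave
        epochs.append(
            Epoch(
                signal=sig,
                fs=cfg.fs,
                cue_index=0,
                label=int(label),
                subject_id=cfg.subject_id,
                trial_id=f"{cfg.subject_id}-t{trial:04d}",
            )
        )
    return EpochSet(epochs, electrodes, m, provenance=f"synthetic(seed={cfg.seed})")


# ---------------------------------------------------------------------------
# EDF+ emission (for exercising the recording reader)
# ---------------------------------------------------------------------------

_CUE_DESCRIPTIONS = {0: "769", 1: "770", 2: "771", 3: "772"}


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field {text!r} longer than {width}")
    return b + b" " * (width - len(b))


def write_edf(
    eset: EpochSet,
    path: str,
    *,
    trial_seconds: float = 3.0,
    n_eog: int = 0,
    physical_range: float = 800.0,
) -> None:
    """Write an EpochSet as an EDF+ recording with cue annotations.

    Trials are laid out back to back in slots of ``trial_seconds``; each slot
    starts with the trial's cue annotation (the standard numeric cue codes).
    Optional all-zero EOG channels exercise non-EEG channel dropping.  EDF's
    16-bit quantisation makes this path approximate by design; the lossless
    interchange format is the array + sidecar pair.
    """
    if not len(eset):
        raise ValueError("cannot write an empty EpochSet")
    fs = eset.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs_i = int(round(fs))
    slot = int(round(trial_seconds * fs_i))
    if any(e.n_samples > slot for e in eset):
        raise ValueError("trial_seconds too short for the epochs")
    n_trials = len(eset)
    total = n_trials * slot
    n_records = int(np.ceil(total / fs_i))  # 1-second records
    n_eeg = len(eset.electrodes)
    ns = n_eeg + n_eog + 1  # + annotations channel

    data = np.zeros((n_eeg, n_records * fs_i))
    onsets = []
    for i, e in enumerate(eset):
        start = i * slot
        data[:, start:start + e.n_samples] = e.signal
        onsets.append((start / fs_i, _CUE_DESCRIPTIONS[e.label]))

    pr = physical_range
    peak = np.abs(data).max()
    if peak > pr:
        raise ValueError(f"signal peak {peak:.1f} uV exceeds physical range {pr}")
    digital = np.clip(np.round(data / pr * 32767), -32768, 32767).astype("<i2")

    ann_bytes = 120  # per record; 60 two-byte "samples"
    header_bytes = 256 * (ns + 1)
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))
        fh.write(_pad("Startdate 01-JAN-2021 X X X", 80))
        fh.write(_pad("01.01.21", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("EDF+C", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(ns), 4))

        labels = [f"EEG {e}" for e in eset.electrodes]
        labels += [f"EOG EOG-{i}" for i in range(n_eog)]
        labels += ["EDF Annotations"]
        for lab in labels:
            fh.write(_pad(lab, 16))
        for i in range(ns):
            fh.write(_pad("AgAgCl electrode" if i < n_eeg + n_eog else "", 80))
        for i in range(ns):
            fh.write(_pad("uV" if i < n_eeg + n_eog else "", 8))
        for i in range(ns):
            fh.write(_pad(str(-pr) if i < n_eeg + n_eog else "-1", 8))
        for i in range(ns):
            fh.write(_pad(str(pr) if i < n_eeg + n_eog else "1", 8))
        for _ in range(ns):
            fh.write(_pad("-32768", 8))
        for _ in range(ns):
            fh.write(_pad("32767", 8))
        for _ in range(ns):
            fh.write(_pad("", 80))
        for i in range(ns):
            fh.write(_pad(str(fs_i if i < n_eeg + n_eog else ann_bytes // 2), 8))
        for _ in range(ns):
            fh.write(_pad("", 32))

        for rec in range(n_records):
            sl = slice(rec * fs_i, (rec + 1) * fs_i)
            fh.write(digital[:, sl].tobytes(order="C"))
            for _ in range(n_eog):
                fh.write(struct.pack(f"<{fs_i}h", *([0] * fs_i)))
            tal = f"+{rec}\x14\x14\x00".encode("ascii")
            for onset, desc in onsets:
                if rec <= onset < rec + 1:
                    tal += f"+{onset:.6f}\x150\x14{desc}\x14\x00".encode("ascii")
            if len(tal) > ann_bytes:
                raise ValueError("annotation record overflow")
            fh.write(tal + b"\x00" * (ann_bytes - len(tal)))
    logger.info("wrote EDF+ %s (%d records, %d channels)", path, n_records, ns)


def save_ground_truth(cfg: SimConfig, path: str) -> None:
    informative, nuisance = ground_truth(cfg)
    with open(path, "w") as fh:
        json.dump(
            {"informative_freqs": sorted(informative),
             "nuisance_freqs": sorted(nuisance),
             "seed": cfg.seed},
            fh, indent=2,
        )
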