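"""Zero-phase notch filtering of epochs at the selected frequencies.

Each selected frequency gets a second-order IIR notch (quality factor q,
default 30, i.e. about 1.7 Hz of -3 dB bandwidth at 50 Hz) applied forward and
backward so the net phase response is zero.  Filtering acts on the cropped
per-trial signal; edge transients are controlled by reflect-padding before the
bidirectional pass.  Frequencies closer together than a minimum gap are merged
first so overlapping notches do not cascade.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .freqselect import FilterSet
from .io import EpochSet

logger = logging.getLogger(__name__)

__all__ = ["FrequencyError", "NotchSpec", "apply_notches", "merge_close", "notch_report"]

PAD_SAMPLES = 64


class FrequencyError(ValueError):
    """Notch frequency at or above Nyquist."""


@dataclass(frozen=True)
class NotchSpec:
    f0: float
    q: float
    fs: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f0 < self.fs / 2):
            raise FrequencyError(f"f0={self.f0} outside (0, {self.fs / 2})")
        if self.q <= 0:
            raise ValueError("quality factor must be positive")

    def coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        return sps.iirnotch(self.f0, self.q, fs=self.fs)


def merge_close(fset: FilterSet, min_gap: float = 1.0) -> FilterSet:
    """Collapse frequencies closer than min_gap to the higher-count member.

    Ties go to the lower frequency.  A gap of 0 is the identity.
    """
    if min_gap < 0:
        raise ValueError("min_gap must be >= 0")
    if min_gap == 0 or len(fset) <= 1:
        return fset
    counts = fset.bad_counts
    freqs = sorted(fset.frequencies)
    # greedy clustering of ascending freqs: neighbours < min_gap apart join
    clusters: list[list[int]] = []
    for f in freqs:
        if clusters and f - clusters[-1][-1] < min_gap:
            clusters[-1].append(f)
        else:
            clusters.append([f])
    kept = [
        min(cluster, key=lambda f: (-counts.get(f, 0), f))
        for cluster in clusters
    ]
    prov = dict(fset.provenance)
    prov["merged_from"] = freqs
    prov["min_gap"] = min_gap
    return FilterSet(sorted(kept), prov)


def _filter_array(x: np.ndarray, specs: list[NotchSpec], family: str, order: int) -> np.ndarray:
    """Apply all notches, zero-phase, along the last axis."""
    y = x
    n = x.shape[-1]
    padlen = min(PAD_SAMPLES, n - 1)
    for spec in specs:
        if family == "iir-notch":
            b, a = spec.coefficients()
        elif family == "fir-band-stop":
            width = spec.f0 / spec.q
            lo = max(spec.f0 - width / 2, 0.1)
            hi = min(spec.f0 + width / 2, spec.fs / 2 - 0.1)
            b = sps.firwin(order | 1, [lo, hi], fs=spec.fs)  # odd taps, band-stop
            a = np.array([1.0])
        else:
            raise ValueError(f"unknown filter family {family!r}")
        y = sps.filtfilt(b, a, y, axis=-1, padtype="even", padlen=padlen)
    return y


def apply_notches(
    eset: EpochSet,
    fset: FilterSet,
    q: float = 30.0,
    *,
    family: str = "iir-notch",
    fir_order: int = 255,
    stage: int = 2,
) -> EpochSet:
    """Notch every selected frequency out of every epoch, zero-phase.

    Output length equals input length; an empty filter set returns
    bit-identical signals (provenance still advanced to the new stage).
    """
    provenance = f"filtered(stage{stage})"
    if len(fset) == 0:
        return eset.with_signals(
            np.stack([e.signal for e in eset]) if len(eset) else np.zeros((0, 0, 0)),
            provenance,
        )
    fs = eset.fs
    specs = [NotchSpec(float(f0), q, fs) for f0 in fset]  # validates vs Nyquist
    signals = np.stack([e.signal for e in eset])
    filtered = _filter_array(signals, specs, family, fir_order)
    return eset.with_signals(filtered, provenance)


def notch_report(
    fset: FilterSet, fs: float, q: float = 30.0, *, family: str = "iir-notch",
    fir_order: int = 255, probe_seconds: float = 4.0,
) -> dict:
    """Measure achieved attenuation on unit probe tones at each notch frequency."""
    t = np.arange(int(probe_seconds * fs)) / fs
    report = {"fs": fs, "q": q, "family": family, "notches": []}
    for f0 in fset:
        probe = np.sin(2 * np.pi * f0 * t)
        out = _filter_array(probe[None, :], [NotchSpec(float(f0), q, fs)], family, fir_order)[0]
        mid = slice(len(t) // 4, 3 * len(t) // 4)  # steady-state portion
        rms_in = np.sqrt(np.mean(probe[mid] ** 2))
        rms_out = np.sqrt(np.mean(out[mid] ** 2))
        atten_db = -20.0 * np.log10(max(rms_out / rms_in, 1e-300))
        report["notches"].append(
            {"f0": int(f0), "attenuation_db": float(atten_db)}
        )
    return report


def save_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
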