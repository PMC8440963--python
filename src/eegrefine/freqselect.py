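"""Peak-frequency tallies of useful/useless intervals and the
top-k-bad minus top-m-good selection rule.

Every labeled interval is reduced to the integer-Hz frequency of the highest
magnitude-spectrum peak inside the search band.  Peaks of useless intervals
accumulate into the "bad" tally, peaks of useful intervals into the "good"
one.  Because the 1/f background makes low frequencies dominate both tallies,
the filtering set is the set difference: the top k_bad bad frequencies that do
not rank among the top m_good good frequencies (defaults 20 and 100).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .gradcam import LabeledInterval
from .io import EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSet",
    "FrequencyTally",
    "NoPeakError",
    "SelectionConfig",
    "TooShortError",
    "peak_frequency",
    "select_filter_frequencies",
    "tally",
]


class TooShortError(ValueError):
    """Interval shorter than the minimum analysable length."""


class NoPeakError(ValueError):
    """Segment carries no in-band spectral energy."""


@dataclass(frozen=True)
class SelectionConfig:
    k_bad: int = 20
    m_good: int = 100
    sample_fraction: float = 0.1
    band: tuple[float, float] = (0.5, 100.0)
    window: str | None = None  # None = plain magnitude spectrum; "hann" optional
    n_fft: int = 512

    def __post_init__(self) -> None:
        if self.k_bad < 1 or self.m_good < 1:
            raise ValueError("k_bad and m_good must be positive")
        if not (0.0 < self.sample_fraction <= 1.0):
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.band[0] <= 0 or self.band[0] >= self.band[1]:
            raise ValueError("band must satisfy 0 < lo < hi")


@dataclass
class FrequencyTally:
    kind: str  # "good" | "bad"
    counts: dict[int, int] = field(default_factory=dict)
    band: tuple[float, float] = (0.5, 100.0)
    skipped: dict[str, int] = field(default_factory=dict)

    def add(self, freq: int) -> None:
        self.counts[freq] = self.counts.get(freq, 0) + 1

    def top(self, k: int) -> list[int]:
        """Top-k bins by descending count, ties broken toward lower Hz."""
        ranked = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return [f for f, _ in ranked[:k]]

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind, "band": list(self.band),
             "counts": {str(k): v for k, v in sorted(self.counts.items())},
             "skipped": self.skipped},
            indent=2,
        )


@dataclass
class FilterSet:
    """Ascending integer frequencies to notch, with full provenance."""

    frequencies: list[int]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frequencies)

    def __iter__(self):
        return iter(self.frequencies)

    @property
    def bad_counts(self) -> dict[int, int]:
        return {int(k): v for k, v in self.provenance.get("bad_counts", {}).items()}

    def to_json(self) -> str:
        return json.dumps(
            {"frequencies": self.frequencies, "provenance": self.provenance}, indent=2
        )

    @classmethod
    def from_json(cls, text: str) -> "FilterSet":
        d = json.loads(text)
        return cls(frequencies=[int(f) for f in d["frequencies"]],
                   provenance=d.get("provenance", {}))


def peak_frequency(
    segment: np.ndarray,
    fs: float,
    band: tuple[float, float] = (0.5, 100.0),
    *,
    n_fft: int = 512,
    window: str | None = None,
) -> int:
    """Integer-Hz frequency of the in-band magnitude-spectrum maximum.

    The mean-removed segment is zero-padded to ``n_fft`` samples before the
    transform, giving sub-Hz native resolution at 250 Hz; the argmax frequency
    is rounded to the nearest integer Hz, with ties resolved toward the lower
    frequency.
    """
    seg = np.asarray(segment, dtype=np.float64)
    if seg.ndim != 1:
        raise ValueError("segment must be 1-D")
    if seg.size < 8:
        raise TooShortError(f"segment of {seg.size} samples (< 8)")
    if not (0.0 < band[0] < band[1] < fs / 2 + 1e-9):
        raise ValueError(f"band {band} outside (0, fs/2)")
    scale = np.abs(seg).max()
    if scale == 0.0:
        raise NoPeakError("all-zero segment")
    x = seg - seg.mean()
    if np.abs(x).max() < 1e-9 * scale:
        raise NoPeakError("segment is constant (DC only, excluded by band)")
    if window == "hann":
        x = x * np.hanning(x.size)
    nfft = max(n_fft, x.size)
    amp = np.abs(np.fft.rfft(x, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise NoPeakError("no FFT bins inside band")
    idx = np.flatnonzero(in_band)
    best = idx[np.argmax(amp[idx])]  # argmax returns first (= lowest) on ties
    return int(round(freqs[best]))


def tally(
    intervals: list[LabeledInterval],
    eset: EpochSet,
    cfg: SelectionConfig = SelectionConfig(),
) -> tuple[FrequencyTally, FrequencyTally]:
    """Pool peak frequencies of all intervals into (good, bad) tallies.

    Intervals across branches and electrodes feed two pooled tallies; too-short
    or spectrally empty intervals are skipped and counted.
    """
    by_trial = {e.trial_id: e for e in eset}
    ch_index = {name: i for i, name in enumerate(eset.electrodes)}
    good = FrequencyTally("good", band=cfg.band)
    bad = FrequencyTally("bad", band=cfg.band)
    skipped = {"too_short": 0, "no_peak": 0, "unknown_trial": 0}
    for iv in intervals:
        epoch = by_trial.get(iv.trial_id)
        if epoch is None:
            skipped["unknown_trial"] += 1
            continue
        seg = epoch.signal[ch_index[iv.electrode], iv.start:iv.end]
        try:
            f = peak_frequency(seg, epoch.fs, cfg.band, n_fft=cfg.n_fft, window=cfg.window)
        except TooShortError:
            skipped["too_short"] += 1
            continue
        except NoPeakError:
            skipped["no_peak"] += 1
            continue
        (good if iv.kind == "useful" else bad).add(f)
    if any(skipped.values()):
        logger.info("tally skipped intervals: %s", skipped)
    good.skipped = dict(skipped)
    bad.skipped = dict(skipped)
    return good, bad


def select_filter_frequencies(
    bad: FrequencyTally,
    good: FrequencyTally,
    cfg: SelectionConfig = SelectionConfig(),
    *,
    seed: int | None = None,
) -> FilterSet:
    """Top k_bad bad bins minus top m_good good bins, ascending.

    Both rankings are by descending count with ties toward lower Hz; the
    result can never exceed k_bad frequencies.
    """
    if not bad.counts:
        logger.warning("empty bad tally; empty filter set")
        return FilterSet([], {"seed": seed, "config": _cfg_dict(cfg),
                              "bad_counts": {}, "good_counts": {}})
    b = bad.top(cfg.k_bad)
    g = set(good.top(cfg.m_good))
    selected = sorted(f for f in b if f not in g)
    provenance = {
        "seed": seed,
        "config": _cfg_dict(cfg),
        "bad_counts": {str(f): bad.counts[f] for f in sorted(bad.counts)},
        "good_counts": {str(f): good.counts[f] for f in sorted(good.counts)},
        "top_bad": b,
        "top_good": sorted(g),
    }
    return FilterSet(selected, provenance)


def _cfg_dict(cfg: SelectionConfig) -> dict:
    return {
        "k_bad": cfg.k_bad,
        "m_good": cfg.m_good,
        "sample_fraction": cfg.sample_fraction,
        "band": list(cfg.band),
        "window": cfg.window,
        "n_fft": cfg.n_fft,
    }
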