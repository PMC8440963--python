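"""Scalp montage: electrode-name -> 2D grid cell mapping.

The 22-electrode 10-20 layout used by four-class motor-imagery recordings is
shipped as package data and laid out anatomically on a 6x7 grid (rows run
frontal to posterior, columns left to right).  Alternative layouts are a JSON
file away; nothing in the pipeline hard-codes grid dimensions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

__all__ = ["Montage", "MontageError", "default_montage"]


class MontageError(ValueError):
    """Electrode/grid bookkeeping violation."""


@dataclass(frozen=True)
class Montage:
    name: str
    grid_height: int
    grid_width: int
    placement: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for elec, (r, c) in self.placement.items():
            if not (0 <= r < self.grid_height and 0 <= c < self.grid_width):
                raise MontageError(
                    f"electrode {elec!r} placed at ({r},{c}) outside "
                    f"{self.grid_height}x{self.grid_width} grid"
                )
            if (r, c) in seen:
                raise MontageError(f"grid cell ({r},{c}) assigned twice")
            seen.add((r, c))

    @property
    def electrodes(self) -> list[str]:
        return list(self.placement)

    def __len__(self) -> int:
        return len(self.placement)

    def to_json(self, path: str) -> None:
        payload = {
            "name": self.name,
            "grid_height": self.grid_height,
            "grid_width": self.grid_width,
            "placement": {k: list(v) for k, v in self.placement.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "Montage":
        with open(path) as fh:
            payload = json.load(fh)
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: dict) -> "Montage":
        return cls(
            name=payload["name"],
            grid_height=int(payload["grid_height"]),
            grid_width=int(payload["grid_width"]),
            placement={k: (int(r), int(c)) for k, (r, c) in payload["placement"].items()},
        )


def default_montage() -> Montage:
    """The 22-electrode 10-20 montage on a 6x7 grid."""
    text = resources.files("eegrefine.data").joinpath("montage_10_20_22.json").read_text()
    return Montage._from_payload(json.loads(text))
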