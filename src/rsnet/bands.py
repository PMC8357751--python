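"""Frequency-band definitions.

Bands are half-open intervals [low, high) so that shared edges
(8 Hz between theta and alpha-1, 10.5 Hz between alpha-1 and alpha-2)
are counted exactly once when binning spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator


@dataclass(frozen=True)
class Band:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"band {self.name}: need 0 < low < high")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)


class BandSet:
    """Ordered collection of non-overlapping frequency bands."""

    def __init__(self, bands: Iterable[Band]):
        self.bands = list(bands)
        if not self.bands:
            raise ValueError("BandSet needs at least one band")
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError("band names must be unique")
        ordered = sorted(self.bands, key=lambda b: b.low)
        for a, b in zip(ordered, ordered[1:]):
            if b.low < a.high:
                raise ValueError(f"bands {a.name} and {b.name} overlap")

    def __iter__(self) -> Iterator[Band]:
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)

    def __getitem__(self, name: str) -> Band:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    @classmethod
    def default(cls) -> "BandSet":
        """Theta 4-8, alpha-1 8-10.5, alpha-2 10.5-13 Hz."""
        return cls(
            [
                Band("theta", 4.0, 8.0),
                Band("alpha1", 8.0, 10.5),
                Band("alpha2", 10.5, 13.0),
            ]
        )
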