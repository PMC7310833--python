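"""Temperature with exact Celsius/Kelvin round-tripping."""

from __future__ import annotations

from dataclasses import dataclass

KELVIN_OFFSET = 273.15


@dataclass(frozen=True, order=True)
class Temperature:
    """A temperature stored in degrees Celsius.

    ``kelvin`` is derived as ``celsius + 273.15`` so the Celsius↔Kelvin
    round trip is exact.  Absolute zero is the hard lower bound.
    """

    celsius: float

    def __post_init__(self) -> None:
        if self.kelvin <= 0:
            raise ValueError(
                f"temperature {self.celsius} degC is at or below absolute zero"
            )

    @property
    def kelvin(self) -> float:
        return self.celsius + KELVIN_OFFSET

    @classmethod
    def from_kelvin(cls, kelvin: float) -> "Temperature":
        return cls(kelvin - KELVIN_OFFSET)
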