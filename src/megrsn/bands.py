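"""Frequency-band definitions for the six-band analysis.

The canonical decomposition of the 0.5-48 Hz spectrum used throughout
the package: delta, theta, lower/upper alpha, beta and lower gamma.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FrequencyBand:
    """A closed frequency interval in Hz with a canonical name."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 <= low < high, got [{self.low}, {self.high}]"
            )

    @property
    def width(self) -> float:
        return self.high - self.low

    def contains(self, freq: float) -> bool:
        return self.low <= freq <= self.high


#: The six analysis bands (Hz).
DEFAULT_BANDS: dict[str, FrequencyBand] = {
    b.name: b
    for b in (
        FrequencyBand("delta", 0.5, 4.0),
        FrequencyBand("theta", 4.0, 8.0),
        FrequencyBand("lower_alpha", 8.0, 10.0),
        FrequencyBand("upper_alpha", 10.0, 13.0),
        FrequencyBand("beta", 13.0, 30.0),
        FrequencyBand("lower_gamma", 30.0, 48.0),
    )
}

#: The broad band covering all six analysis bands.
BROADBAND = FrequencyBand("broadband", 0.5, 48.0)


def get_band(name: str) -> FrequencyBand:
    """Look up one of the six default bands by name."""
    try:
        return DEFAULT_BANDS[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; expected one of {sorted(DEFAULT_BANDS)}"
        ) from None
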