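"""Activity labels and the per-activity frequency-band scheme.

The mango pulp weevil (*Sternochetus frigidus*) produces band-limited
sounds whose spectral location depends on what the animal is doing:
mating calls sit in a narrow low band, pupal movement and adult walking
occupy progressively higher bands. ``BandScheme`` captures that mapping
and is shared by the synthetic-scene generator, the dominant-band
characterization and the rule-based baseline classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class Activity(str, Enum):
    """The four behavioural classes distinguished acoustically."""

    MATING = "mating"
    PUPA_MOVING = "pupa_moving"
    ADULT_WALKING = "adult_walking"
    RESTING = "resting"


#: Classes that emit a band-limited signal; ``resting`` is background noise.
BAND_ACTIVITIES = (Activity.MATING, Activity.PUPA_MOVING, Activity.ADULT_WALKING)


@dataclass(frozen=True)
class BandScheme:
    """Per-activity frequency bands in Hz, ``{activity: (low, high)}``.

    Defaults are the measured bands: mating 800-950 Hz, pupal movement
    1-4 kHz, adult walking 4-5 kHz.
    """

    bands: dict = field(
        default_factory=lambda: {
            Activity.MATING: (800.0, 950.0),
            Activity.PUPA_MOVING: (1000.0, 4000.0),
            Activity.ADULT_WALKING: (4000.0, 5000.0),
        }
    )

    def __post_init__(self) -> None:
        for activity, (low, high) in self.bands.items():
            if not 0.0 < low < high:
                raise ValueError(f"invalid band for {activity}: ({low}, {high})")

    def validate_for_sample_rate(self, sample_rate: float) -> None:
        """Raise if any band edge reaches the Nyquist frequency."""
        nyquist = sample_rate / 2.0
        for activity, (_, high) in self.bands.items():
            if high >= nyquist:
                raise ValueError(
                    f"band for {activity} reaches {high} Hz, at or above the "
                    f"Nyquist frequency {nyquist} Hz"
                )

    def __getitem__(self, activity: Activity) -> tuple[float, float]:
        return self.bands[Activity(activity)]

    def items(self):
        return self.bands.items()


DEFAULT_BANDS = BandScheme()
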