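"""The in-memory fluorescence record.

Every analysis in this package starts from a :class:`FluorescenceTrace`:
time-stamped fluorescence with the actinic light level and a boolean flag
marking samples taken while a saturating (super) pulse was active.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

PROTOCOL_IDS = ("LC", "KC", "OJIP", "YIELD")


@dataclass
class FluorescenceTrace:
    """Time-resolved fluorescence with light annotations.

    Attributes
    ----------
    time_s : strictly increasing sample times, seconds from trace start.
    fluorescence : fluorescence signal, arbitrary units, strictly positive.
    actinic_ppfd : actinic light at each sample, µmol photons m⁻² s⁻¹.
    pulse_flag : True where a saturating pulse was active.
    protocol_id : one of ``LC``, ``KC``, ``OJIP``, ``YIELD``.
    meta : free-form sidecar metadata (plant_id, cytotype, ...).
    """

    time_s: np.ndarray
    fluorescence: np.ndarray
    actinic_ppfd: np.ndarray
    pulse_flag: np.ndarray
    protocol_id: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.actinic_ppfd = np.asarray(self.actinic_ppfd, dtype=float)
        self.pulse_flag = np.asarray(self.pulse_flag, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n = len(self.time_s)
        if n == 0:
            raise ValidationError("trace is empty")
        for name in ("fluorescence", "actinic_ppfd", "pulse_flag"):
            if len(getattr(self, name)) != n:
                raise ValidationError(
                    f"column {name!r} has {len(getattr(self, name))} samples, "
                    f"time_s has {n}"
                )
        if self.protocol_id not in PROTOCOL_IDS:
            raise ValidationError(
                f"unknown protocol_id {self.protocol_id!r}; expected one of {PROTOCOL_IDS}"
            )
        bad = np.nonzero(np.diff(self.time_s) <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"time_s must be strictly increasing; first violation at sample {bad[0] + 1}"
            )
        bad = np.nonzero(~(self.fluorescence > 0))[0]
        if bad.size:
            raise ValidationError(
                f"fluorescence must be > 0; first violation at sample {bad[0]}"
            )
        if np.any(self.actinic_ppfd < 0):
            raise ValidationError("actinic_ppfd must be >= 0")

    def __len__(self) -> int:
        return len(self.time_s)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FluorescenceTrace):
            return NotImplemented
        return (
            self.protocol_id == other.protocol_id
            and np.array_equal(self.time_s, other.time_s)
            and np.array_equal(self.fluorescence, other.fluorescence)
            and np.array_equal(self.actinic_ppfd, other.actinic_ppfd)
            and np.array_equal(self.pulse_flag, other.pulse_flag)
        )
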