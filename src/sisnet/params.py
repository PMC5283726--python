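"""Epidemic rate parameters shared by simulation and closure models."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class EpidemicParams:
    """SIS rates: ``tau`` is the transmission rate per S–I link, ``gamma``
    the recovery rate per infectious node (both per unit time).

    A susceptible with j infectious neighbours becomes infectious at rate
    ``tau * j``; an infectious node recovers (back to susceptible) at rate
    ``gamma``.
    """

    tau: float
    gamma: float = 1.0

    def __post_init__(self):
        if self.tau < 0 or self.gamma < 0:
            raise ValueError("rates must be non-negative")
        if self.tau == 0 and self.gamma == 0:
            raise ValueError("tau and gamma cannot both be zero")
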