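"""Closed-form kinetics of a basic multicellular unit (BMU).

A BMU tunnels through cortical bone: osteoclasts at the cutting cone advance
longitudinally at ~40 um/day, while osteoblasts behind them refill the tunnel
radially at ~1.0-1.5 um/day, from the cement line (~100 um radius) down to the
finished Haversian canal (~10 um radius).  Radial infilling is modelled at a
constant apposition rate; real osteons show substantial resting periods, so
the computed duration is a lower-bound estimate.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BmuKinetics:
    """Default BMU rates and radii (um, um/day)."""

    advance_rate_um_per_d: float = 40.0
    appo_rate_min_um_per_d: float = 1.0
    appo_rate_max_um_per_d: float = 1.5
    r_cement_um: float = 100.0
    r_final_um: float = 10.0

    def __post_init__(self) -> None:
        if self.advance_rate_um_per_d <= 0 or self.appo_rate_min_um_per_d <= 0:
            raise ValueError("rates must be positive")
        if not self.r_cement_um > self.r_final_um >= 0:
            raise ValueError("need r_cement > r_final >= 0")

    def infill_bounds_days(self) -> tuple[float, float]:
        """(shortest, longest) infill duration over the apposition-rate range."""
        return (
            infill_duration(self.r_cement_um, self.r_final_um, self.appo_rate_max_um_per_d),
            infill_duration(self.r_cement_um, self.r_final_um, self.appo_rate_min_um_per_d),
        )


def infill_duration(r_start_um: float, r_end_um: float,
                    appo_rate_um_per_d: float) -> float:
    """Days to infill radially from r_start to r_end at a constant rate."""
    if r_start_um < r_end_um:
        raise ValueError("r_start must be >= r_end")
    if appo_rate_um_per_d <= 0:
        raise ValueError("apposition rate must be positive")
    return (r_start_um - r_end_um) / appo_rate_um_per_d


def cutting_advance(days: float, advance_rate_um_per_d: float = 40.0) -> float:
    """Longitudinal distance (um) advanced by the cutting cone in ``days``."""
    if days < 0:
        raise ValueError("days must be non-negative")
    if advance_rate_um_per_d <= 0:
        raise ValueError("advance rate must be positive")
    return days * advance_rate_um_per_d
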