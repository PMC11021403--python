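"""Intertemporal-choice item construction.

Items emulate the geometry of a 27-trial monetary choice questionnaire:
three reward-magnitude bands (defined by the larger-later amount) with
hyperbolic indifference points log-spaced over a configurable range, each
item presented in two time frames ("delay" = day counts, "date" = calendar
dates obtained by adding the delay to an anchor date).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: larger-later amount range (USD) per magnitude band
BAND_AMOUNTS: dict[str, tuple[float, float]] = {
    "small": (25.0, 35.0),
    "medium": (50.0, 60.0),
    "large": (75.0, 85.0),
}

FRAMES = ("delay", "date")

DEFAULT_K_RANGE = (0.0016, 0.25)
DEFAULT_ANCHOR = _dt.date(2022, 11, 11)


@dataclass(frozen=True)
class ChoiceItem:
    """One binary choice between a smaller-immediate and a larger-later reward."""

    item_id: str
    ss_amount: float
    ss_delay_days: int
    ll_amount: float
    ll_delay_days: int
    magnitude_band: str
    frame: str
    render_date_anchor: _dt.date = field(default=DEFAULT_ANCHOR)

    def __post_init__(self) -> None:
        if self.ll_amount <= self.ss_amount:
            raise ValueError(f"{self.item_id}: ll_amount must exceed ss_amount")
        if self.ll_delay_days <= self.ss_delay_days:
            raise ValueError(f"{self.item_id}: ll_delay_days must exceed ss_delay_days")
        if self.magnitude_band not in BAND_AMOUNTS:
            raise ValueError(f"unknown magnitude band {self.magnitude_band!r}")
        if self.frame not in FRAMES:
            raise ValueError(f"unknown frame {self.frame!r}")

    @property
    def ll_date(self) -> _dt.date:
        """Calendar date of the larger-later reward (date frame rendering)."""
        return self.render_date_anchor + _dt.timedelta(days=int(self.ll_delay_days))

    def render(self) -> str:
        if self.frame == "delay":
            return (
                f"Would you prefer ${self.ss_amount:.0f} in {self.ss_delay_days} days, "
                f"or ${self.ll_amount:.0f} in {self.ll_delay_days} days?"
            )
        anchor = self.render_date_anchor + _dt.timedelta(days=int(self.ss_delay_days))
        return (
            f"Would you prefer ${self.ss_amount:.0f} on {anchor:%B %d, %Y}, "
            f"or ${self.ll_amount:.0f} on {self.ll_date:%B %d, %Y}?"
        )


def item_indifference_k(item: ChoiceItem) -> float:
    """Hyperbolic discount rate at which both options have equal value.

    With an immediate smaller option, ``A_ss = A_ll / (1 + k D)`` solves to
    ``k* = (A_ll / A_ss - 1) / D``.
    """
    if item.ll_delay_days <= 0:
        raise ValueError("larger-later delay must be positive")
    return (item.ll_amount / item.ss_amount - 1.0) / item.ll_delay_days


def generate_item_set(
    n_items: int = 27,
    bands: Sequence[str] = ("small", "medium", "large"),
    k_range: tuple[float, float] = DEFAULT_K_RANGE,
    seed: int | None = None,
    anchor_date: _dt.date = DEFAULT_ANCHOR,
) -> list[ChoiceItem]:
    """Build ``n_items`` unique choices, each emitted in both frames.

    Within each band the hyperbolic indifference points are exactly
    log-spaced over ``k_range``; delays are spread so that ``k* D`` (and
    hence the smaller-sooner / larger-later amount ratio) varies across
    items, as in the canonical instrument.

    Returns ``2 * n_items`` :class:`ChoiceItem` objects (delay + date frame).
    """
    bands = list(bands)
    for b in bands:
        if b not in BAND_AMOUNTS:
            raise ValueError(f"unknown magnitude band {b!r}")
    if n_items <= 0 or n_items % len(bands):
        raise ValueError("n_items must be a positive multiple of the number of bands")
    lo, hi = float(k_range[0]), float(k_range[1])
    if lo <= 0 or hi <= 0 or hi < lo:
        raise ValueError("k_range must be a positive, ordered interval")

    rng = np.random.default_rng(seed)
    per_band = n_items // len(bands)
    items: list[ChoiceItem] = []
    for band in bands:
        amt_lo, amt_hi = BAND_AMOUNTS[band]
        ks = np.geomspace(lo, hi, per_band) if per_band > 1 else np.array([lo])
        # kD targets (SS/LL ratio between ~0.26 and ~0.74) cycled across
        # neighboring k* so that an agent near indifference sees items at
        # short, medium and long delays -- the delay diversity of the
        # emulated instrument, which identifies discount-curve shape
        kd = np.array([(0.35, 1.0, 2.8)[j % 3] for j in range(per_band)])
        lls = rng.permutation(
            np.linspace(amt_lo, amt_hi, per_band) if per_band > 1 else np.array([amt_lo])
        )
        for j, (k_star, target_kd, ll) in enumerate(zip(ks, kd, lls)):
            delay = max(2, int(round(target_kd / k_star)))
            ss = ll / (1.0 + k_star * delay)  # exact indifference by construction
            for frame in FRAMES:
                items.append(
                    ChoiceItem(
                        item_id=f"{band}_{j + 1:02d}",
                        ss_amount=float(ss),
                        ss_delay_days=0,
                        ll_amount=float(ll),
                        ll_delay_days=delay,
                        magnitude_band=band,
                        frame=frame,
                        render_date_anchor=anchor_date,
                    )
                )
    return items
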