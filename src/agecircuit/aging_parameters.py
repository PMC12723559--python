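"""Data-driven aging-mechanism parameterization.

Three cellular/synaptic aging mechanisms are modeled as linear-in-age
changes, each summarized by a small set of scalars applied to a cortical
microcircuit model:

* **Interneuron loss** — per-year fractional loss of SST, VIP and PV
  interneurons (1.21, 0.88 and 0.52 %/year), applied as survival fractions
  scaling interneuron counts.
* **NMDA loss** — 2.5 %/year decline in pyramidal-neuron NMDA conductance.
* **Spine loss** — 1 %/year loss of dendritic spines, translated into
  (a) a reduced Pyr→Pyr connection probability and (b) a small reduction in
  dendritic leak conductance and membrane capacitance derived from
  thin-spine surface-area arithmetic.

All derivations are for an age offset in years relative to a middle-aged
(~50 y) reference circuit; the default study comparison is +20 years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field

__all__ = [
    "LossRates",
    "SpineGeometry",
    "AgingProfile",
    "CONDITION_LABELS",
    "interneuron_loss",
    "nmda_multiplier",
    "spine_connection_multiplier",
    "thin_fraction_middle_age",
    "thin_spine_surface_area",
    "passive_reduction",
    "make_profile",
]

#: The five experimental conditions: reference, all mechanisms combined,
#: and each mechanism in isolation.
CONDITION_LABELS = ("middle_age", "older", "inhib_loss", "nmda_loss", "spine_loss")


@dataclass(frozen=True)
class LossRates:
    """Per-year fractional loss rates for each aging mechanism."""

    sst_per_year: float = 0.0121
    vip_per_year: float = 0.0088
    pv_per_year: float = 0.0052
    nmda_per_year: float = 0.025
    spine_per_year: float = 0.01

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class SpineGeometry:
    """Thin-spine geometry and membrane surface areas (pyramidal neuron).

    Thin spines are modeled as truncated cones with a half base-to-tip
    diameter ratio (base diameter = ratio x tip diameter) plus a flat
    end-cap disc at the tip.
    """

    n_spines_total: int = 8169
    thin_fraction_old: float = 0.25
    thin_length: float = 1.2  # μm
    tip_diameter: float = 0.35  # μm
    base_to_tip_ratio: float = 0.5
    total_spine_area: float = 11954.0  # μm²
    total_dendrite_area: float = 20410.0  # μm²

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0 and not (name == "n_spines_total" and value == 0):
                raise ValueError(f"{name} must be positive, got {value}")


@dataclass(frozen=True)
class AgingProfile:
    """Multipliers parameterizing one experimental condition.

    All fields are fractions in [0, 1]; 1.0 means "unchanged from the
    middle-aged reference". ``passive_multiplier`` scales both the dendritic
    leak conductance G_pas and membrane capacitance c_m of Pyr neurons.
    """

    label: str
    years: float = 20.0
    sst_survival: float = 1.0
    vip_survival: float = 1.0
    pv_survival: float = 1.0
    nmda_multiplier: float = 1.0
    pyr_pyr_connection_multiplier: float = 1.0
    passive_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in CONDITION_LABELS:
            raise ValueError(
                f"unknown condition label {self.label!r}; expected one of {CONDITION_LABELS}"
            )
        for name in (
            "sst_survival",
            "vip_survival",
            "pv_survival",
            "nmda_multiplier",
            "pyr_pyr_connection_multiplier",
            "passive_multiplier",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")

    def to_dict(self) -> dict:
        return asdict(self)


def _check_years(years: float) -> None:
    if years < 0:
        raise ValueError(f"years must be non-negative, got {years}")


def interneuron_loss(rates: LossRates, years: float) -> dict:
    """Fractional loss of each interneuron type after ``years`` of aging.

    Losses accumulate linearly and are clamped at total loss (1.0).
    Returns a dict with per-type ``*_loss`` and ``*_survival`` entries.
    """
    _check_years(years)
    out = {}
    for key, rate in (
        ("sst", rates.sst_per_year),
        ("vip", rates.vip_per_year),
        ("pv", rates.pv_per_year),
    ):
        loss = min(1.0, rate * years)
        out[f"{key}_loss"] = loss
        out[f"{key}_survival"] = 1.0 - loss
    return out


def nmda_multiplier(rates: LossRates, years: float) -> float:
    """Surviving fraction of Pyr-neuron NMDA conductance after ``years``."""
    _check_years(years)
    return max(0.0, 1.0 - rates.nmda_per_year * years)


def spine_connection_multiplier(rates: LossRates, years: float) -> float:
    """Surviving fraction of Pyr→Pyr connection probability after ``years``."""
    _check_years(years)
    return max(0.0, 1.0 - rates.spine_per_year * years)


def thin_fraction_middle_age(thin_fraction_old: float, spine_loss_20y: float) -> float:
    """Back-project the old-age thin-spine fraction to middle age.

    Spine loss with age is dominated by thin spines: if thin spines make up
    ``thin_fraction_old`` of spines after a fractional loss ``spine_loss_20y``
    of all spines, they made up ``thin_fraction_old / (1 - spine_loss_20y)``
    of the original complement.
    """
    if spine_loss_20y >= 1.0:
        raise ValueError("spine loss fraction must be < 1")
    return thin_fraction_old / (1.0 - spine_loss_20y)


def thin_spine_surface_area(geom: SpineGeometry, thin_fraction_mid: float) -> float:
    """Total membrane surface area (μm²) contributed by thin spines.

    Per-spine area is the lateral surface of a truncated cone (tip radius =
    tip_diameter / 2, base radius = base_to_tip_ratio x tip radius, slant
    height from the spine length) plus the end-cap disc at the tip.
    """
    r_tip = geom.tip_diameter / 2.0
    r_base = geom.base_to_tip_ratio * r_tip
    slant = math.hypot(geom.thin_length, r_base - r_tip)
    lateral = math.pi * (r_tip + r_base) * slant
    cap = math.pi * r_tip**2
    per_spine = lateral + cap
    return per_spine * geom.n_spines_total * thin_fraction_mid


def passive_reduction(
    geom: SpineGeometry, thin_area: float, spine_loss_20y: float
) -> dict:
    """Reduction in dendritic passive parameters due to thin-spine loss.

    The thin-spine membrane is ``thin_area`` out of the total (spine +
    dendrite) membrane; losing ``spine_loss_20y`` of spines — all thin —
    removes that fraction of the thin-spine membrane, reducing effective
    G_pas and c_m proportionally.

    Returns ``area_fraction``, ``reduction`` and ``passive_multiplier``.
    """
    total_area = geom.total_spine_area + geom.total_dendrite_area
    area_fraction = thin_area / total_area
    reduction = area_fraction * spine_loss_20y
    return {
        "area_fraction": area_fraction,
        "reduction": reduction,
        "passive_multiplier": 1.0 - reduction,
    }


def spine_loss_chain(
    rates: LossRates | None = None, geom: SpineGeometry | None = None, years: float = 20.0
) -> dict:
    """Run the full spine-loss derivation and return all intermediates.

    Chains: connection multiplier → middle-age thin-spine fraction →
    thin-spine surface area → passive reduction.
    """
    rates = rates or LossRates()
    geom = geom or SpineGeometry()
    _check_years(years)
    spine_loss = 1.0 - spine_connection_multiplier(rates, years)
    # far beyond the studied range the back-projection leaves its physical
    # domain; clamp the thin-spine fraction and the passive multiplier
    if spine_loss >= 1.0:
        thin_mid = 1.0
    else:
        thin_mid = min(1.0, thin_fraction_middle_age(geom.thin_fraction_old, spine_loss))
    thin_area = thin_spine_surface_area(geom, thin_mid)
    passive = passive_reduction(geom, thin_area, spine_loss)
    passive["passive_multiplier"] = min(1.0, max(0.0, passive["passive_multiplier"]))
    return {
        "spine_loss": spine_loss,
        "connection_multiplier": 1.0 - spine_loss,
        "thin_fraction_middle_age": thin_mid,
        "thin_spine_area": thin_area,
        **passive,
    }


def make_profile(
    label: str,
    years: float = 20.0,
    rates: LossRates | None = None,
    geom: SpineGeometry | None = None,
) -> AgingProfile:
    """Compose an :class:`AgingProfile` for one experimental condition.

    ``middle_age`` is the identity; ``older`` activates all three
    mechanisms at ``years``; the single-mechanism labels (``inhib_loss``,
    ``nmda_loss``, ``spine_loss``) activate only their own multipliers.
    """
    if label not in CONDITION_LABELS:
        raise ValueError(
            f"unknown condition label {label!r}; expected one of {CONDITION_LABELS}"
        )
    rates = rates or LossRates()
    geom = geom or SpineGeometry()
    kwargs: dict = {"label": label, "years": years}
    if label in ("older", "inhib_loss"):
        surv = interneuron_loss(rates, years)
        kwargs.update(
            sst_survival=surv["sst_survival"],
            vip_survival=surv["vip_survival"],
            pv_survival=surv["pv_survival"],
        )
    if label in ("older", "nmda_loss"):
        kwargs["nmda_multiplier"] = nmda_multiplier(rates, years)
    if label in ("older", "spine_loss"):
        chain = spine_loss_chain(rates, geom, years)
        kwargs["pyr_pyr_connection_multiplier"] = chain["connection_multiplier"]
        kwargs["passive_multiplier"] = chain["passive_multiplier"]
    return AgingProfile(**kwargs)
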