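"""Isotope bookkeeping for ¹⁵N tracer data.

Converts between atom% ¹⁵N and atom% excess (abundance above natural
background), reverses the dilution introduced by unlabelled carrier N in
diffusion-trap samples, and converts KCl-extract concentrations to
per-gram-dry-soil units.

All enrichment arithmetic works on atom% excess; the natural-abundance
background of atmospheric N₂ (0.3663 atom%) is the default reference and can
be overridden per dataset when measured backgrounds are available.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

#: Natural ¹⁵N abundance of atmospheric N₂, atom%.
N15_NATURAL_ABUNDANCE = 0.3663


@dataclass(frozen=True)
class IsotopeMeasurement:
    """A single ¹⁵N abundance measurement referenced to a background.

    Attributes
    ----------
    atom_pct : float
        Measured ¹⁵N abundance, atom%.
    background_atom_pct : float
        Natural-abundance reference, atom%.
    """

    atom_pct: float
    background_atom_pct: float = N15_NATURAL_ABUNDANCE

    def __post_init__(self) -> None:
        for name, v in (("atom_pct", self.atom_pct),
                        ("background_atom_pct", self.background_atom_pct)):
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{name}={v} outside [0, 100] atom%")

    @property
    def excess(self) -> float:
        """Atom% excess ¹⁵N (may be negative for unlabelled material)."""
        return self.atom_pct - self.background_atom_pct

    @property
    def below_background(self) -> bool:
        """True when the measurement falls below the reference background."""
        return self.excess < 0.0


@dataclass(frozen=True)
class CarrierSpec:
    """Unlabelled carrier N added to a diffusion sample before analysis.

    Attributes
    ----------
    carrier_n : float
        µg carrier N added to the sample.
    sample_n : float
        µg N of the original sample aliquot.
    carrier_atom_pct : float or None
        Carrier ¹⁵N abundance; ``None`` means exactly at background
        (zero excess), which is the standard assumption for an
        unlabelled NH₄NO₃ carrier.
    """

    carrier_n: float
    sample_n: float
    carrier_atom_pct: float | None = None

    def __post_init__(self) -> None:
        if self.carrier_n < 0:
            raise ValidationError(f"carrier_n={self.carrier_n} must be >= 0")
        if self.sample_n <= 0:
            raise ValidationError(f"sample_n={self.sample_n} must be > 0")

    def carrier_excess(self, background: float = N15_NATURAL_ABUNDANCE) -> float:
        if self.carrier_atom_pct is None:
            return 0.0
        return self.carrier_atom_pct - background


def to_excess(atom_pct: float, background: float = N15_NATURAL_ABUNDANCE) -> float:
    """Convert atom% ¹⁵N to atom% excess above ``background``.

    The result may be ≤ 0 for unlabelled material; values are never
    clamped (truncation would bias pool-dilution estimates downstream).
    Use :class:`IsotopeMeasurement` when a below-background flag is needed.
    """
    if not 0.0 <= atom_pct <= 100.0:
        raise ValidationError(f"atom_pct={atom_pct} outside [0, 100]")
    if not 0.0 <= background <= 100.0:
        raise ValidationError(f"background={background} outside [0, 100]")
    return atom_pct - background


def mix_with_carrier(sample_excess: float, carrier: CarrierSpec,
                     background: float = N15_NATURAL_ABUNDANCE) -> float:
    """Forward two-pool mixing: excess measured after carrier addition.

    Mass-balance of ¹⁵N excess over the combined (sample + carrier) pool.
    This is the inverse of :func:`carrier_correct` and is used by the
    simulator to emulate the diffusion-trap measurement chain.
    """
    total = carrier.sample_n + carrier.carrier_n
    return (sample_excess * carrier.sample_n
            + carrier.carrier_excess(background) * carrier.carrier_n) / total


def carrier_correct(measured_excess: float, carrier: CarrierSpec,
                    background: float = N15_NATURAL_ABUNDANCE) -> float:
    """Undo carrier dilution: recover the original sample's atom% excess.

    With a carrier at exactly background abundance (zero excess) this is

        excess = measured × (sample_n + carrier_n) / sample_n

    and more generally the carrier's own excess contribution is subtracted
    before rescaling. Linear in ``measured_excess``; exact round trip with
    :func:`mix_with_carrier`.
    """
    total = carrier.sample_n + carrier.carrier_n
    contribution = carrier.carrier_excess(background) * carrier.carrier_n
    return (measured_excess * total - contribution) / carrier.sample_n


def extract_to_soil_concentration(extract_conc_mg_l: float,
                                  extract_volume_l: float,
                                  fresh_soil_mass_g: float,
                                  gravimetric_moisture: float) -> float:
    """Convert a KCl-extract N concentration to µg N per g dry soil.

    Parameters
    ----------
    extract_conc_mg_l : float
        Measured N concentration of the filtered extract, mg N l⁻¹.
    extract_volume_l : float
        Volume of extractant added, l.
    fresh_soil_mass_g : float
        Mass of moist soil shaken, g.
    gravimetric_moisture : float
        Water mass fraction of the fresh soil (water / fresh mass), in
        [0, 1). Soil water adds to the solution volume and is accounted
        for in the mass balance.
    """
    if extract_volume_l <= 0 or fresh_soil_mass_g <= 0:
        raise ValidationError("extract volume and soil mass must be > 0")
    if not 0.0 <= gravimetric_moisture < 1.0:
        raise ValidationError(
            f"gravimetric_moisture={gravimetric_moisture} outside [0, 1)")
    dry_mass_g = fresh_soil_mass_g * (1.0 - gravimetric_moisture)
    water_volume_l = fresh_soil_mass_g * gravimetric_moisture / 1000.0
    n_ug = extract_conc_mg_l * 1000.0 * (extract_volume_l + water_volume_l)
    return n_ug / dry_mass_g
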