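"""Physical constants in the unit system used throughout (kcal, nm, s, K, mol).

Two presets are provided.  ``precise`` carries CODATA 2018 values converted
into this unit system and is the default everywhere.  ``printed`` carries the
rounded three-significant-figure values commonly quoted alongside the thermal
activation formula (h = 1.58e-37 kcal s, c = 3.00e17 nm/s,
R = 1.99e-3 kcal/(K mol)); with these the predicted rate constant shifts by
roughly 10-15%, so the preset is exposed for comparison but not used by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError

_KCAL_PER_JOULE = 1.0 / 4184.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants for the barrier-energy calculation.

    Parameters
    ----------
    h : float
        Planck constant, kcal s.
    c : float
        Speed of light, nm s^-1.
    R : float
        Gas constant, kcal K^-1 mol^-1.
    N_A : float
        Avogadro number, mol^-1.
    """

    h: float
    c: float
    R: float
    N_A: float

    def __post_init__(self) -> None:
        for name in ("h", "c", "R", "N_A"):
            if not getattr(self, name) > 0:
                raise DomainError(f"physical constant {name} must be > 0")


#: CODATA 2018 values expressed in kcal / nm / s / K / mol.
PRECISE = PhysicalConstants(
    h=6.62607015e-34 * _KCAL_PER_JOULE,
    c=2.99792458e17,
    R=8.314462618 * _KCAL_PER_JOULE,
    N_A=6.02214076e23,
)

#: Rounded constants as printed alongside the rate formula.
PRINTED = PhysicalConstants(
    h=1.58e-37,
    c=3.00e17,
    R=1.99e-3,
    N_A=6.022e23,
)

_PRESETS = {"precise": PRECISE, "printed": PRINTED}


def get_constants(preset: str | PhysicalConstants = "precise") -> PhysicalConstants:
    """Resolve a preset name ('precise' or 'printed') or pass through a constants object."""
    if isinstance(preset, PhysicalConstants):
        return preset
    try:
        return _PRESETS[preset]
    except KeyError:
        raise DomainError(
            f"unknown constants preset {preset!r}; expected 'precise' or 'printed'"
        ) from None
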