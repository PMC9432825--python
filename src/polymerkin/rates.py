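"""Kinetic rate constants for stepwise actin polymerization schemes.

Units are fixed throughout the package: concentrations in µM, time in s,
association rate constants in µM⁻¹ s⁻¹, dissociation and transition rate
constants in s⁻¹.  Conversions (copy numbers, kDa) happen only at I/O and
observable boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "RateSet",
    "INTERPRETATIONS",
    "atp_hydrolysis_rates",
    "cation_exchange_rates",
    "equal_step_rates",
]

INTERPRETATIONS = frozenset(
    {
        "sept_mccammon",
        "sept_mccammon_adjusted",
        "atp_hydrolysis",
        "cation_exchange",
        "custom",
    }
)

#: Filament-end elongation rate constants for Mg-ATP-actin (Pollard 1986):
#: barbed end 11.6 µM⁻¹s⁻¹ on / 1.4 s⁻¹ off, pointed end 1.3 / 0.8.
BARBED_ON = 11.6
BARBED_OFF = 1.4
POINTED_ON = 1.3
POINTED_OFF = 0.8

#: End-summed elongation rates for Ca-ATP-actin (Cooper et al. 1983):
#: 9.5 + 1.1 = 10.6 µM⁻¹s⁻¹ on, 4.2 + 0.8 = 5.0 s⁻¹ off.
CA_ACTIN_ON = 9.5 + 1.1
CA_ACTIN_OFF = 4.2 + 0.8

#: ATP hydrolysis rate of filament-incorporated subunits (s⁻¹), standard
#: literature value; used as the default state-transition rate constant.
DEFAULT_K_HYDR = 0.3

#: Dimer dissociation rate constant (s⁻¹).  Not available from independent
#: measurements; adjusted manually so that the two-state model shows the
#: burst-then-ratchet phenomenology (substantial steady-state oligomer pool,
#: filament growth driven by the slow state transition).  See docs/methods.md.
DEFAULT_KM1 = 1.0e6

#: Ca²⁺→Mg²⁺ monomer activation rate (s⁻¹); placeholder order of magnitude.
DEFAULT_K_CATION = 0.05


class RateValidationError(ValueError):
    """A rate set violates a structural or sign constraint."""


@dataclass(frozen=True)
class RateSet:
    """All rate constants of one polymerization scheme.

    ``k1..k4`` are association rate constants (µM⁻¹ s⁻¹), ``km1..km4``
    dissociation rate constants (s⁻¹) and ``k_trans`` the irreversible
    transition rate constant (s⁻¹; 0 for the single-state scheme).

    In the two-state scheme the unprimed pathway uses ``k1/km1`` (dimer),
    ``k2/km2`` (trimer) and ``k3/km3`` (all larger species), while the
    primed pathway uses ``k4/km4``.  The ``interpretation`` label records
    the biological reading of the constants (e.g. for ``atp_hydrolysis``
    the transition is ATP hydrolysis at the pointed-end terminal subunit
    and ``k4/km4`` are the barbed-end elongation rates).
    """

    k1: float
    k2: float
    k3: float
    k4: float
    km1: float
    km2: float
    km3: float
    km4: float
    k_trans: float = 0.0
    interpretation: str = "custom"
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4", "km1", "km2", "km3", "km4", "k_trans"):
            v = getattr(self, name)
            if not (v >= 0.0):  # catches NaN too
                raise RateValidationError(f"rate constant {name}={v!r} must be >= 0")
        if self.interpretation not in INTERPRETATIONS:
            raise RateValidationError(
                f"unknown interpretation {self.interpretation!r}; "
                f"expected one of {sorted(INTERPRETATIONS)}"
            )
        if self.interpretation == "atp_hydrolysis":
            if not (self.k1 == self.k2 == self.k3):
                raise RateValidationError(
                    "atp_hydrolysis interpretation requires k1 == k2 == k3 "
                    "(end-summed elongation rate)"
                )
            if self.km2 != self.km3:
                raise RateValidationError(
                    "atp_hydrolysis interpretation requires km2 == km3 "
                    "(end-summed shortening rate)"
                )

    # -- biological interpretation map -------------------------------------
    @property
    def k_hydr(self) -> float:
        """Transition rate under the ATP-hydrolysis reading."""
        return self.k_trans

    @property
    def k_b(self) -> float:
        """Barbed-end association rate under the ATP-hydrolysis reading."""
        return self.k4

    @property
    def km_b(self) -> float:
        return self.km4

    @property
    def k_p(self) -> float:
        """Pointed-end association rate (end-summed minus barbed)."""
        return self.k3 - self.k4

    @property
    def km_p(self) -> float:
        return self.km3 - self.km4

    def with_(self, **kwargs) -> "RateSet":
        """Return a copy with selected constants replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {
            name: getattr(self, name)
            for name in ("k1", "k2", "k3", "k4", "km1", "km2", "km3", "km4", "k_trans")
        }
        d["interpretation"] = self.interpretation
        d["provenance"] = dict(self.provenance)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RateSet":
        return cls(**d)


def atp_hydrolysis_rates(
    k_hydr: float = DEFAULT_K_HYDR,
    km1: float = DEFAULT_KM1,
    k_b: float = BARBED_ON,
    km_b: float = BARBED_OFF,
    k_p: float = POINTED_ON,
    km_p: float = POINTED_OFF,
) -> RateSet:
    """ATP-hydrolysis interpretation of the two-state scheme.

    Before hydrolysis, oligomers exchange subunits at both ends
    (k1=k2=k3=k_b+k_p, km2=km3=km_b+km_p).  After hydrolysis of the
    pointed-end terminal subunit the pointed end is stabilized and growth
    proceeds from the barbed end only (k4=k_b, km4=km_b).
    """
    return RateSet(
        k1=k_b + k_p,
        k2=k_b + k_p,
        k3=k_b + k_p,
        k4=k_b,
        km1=km1,
        km2=km_b + km_p,
        km3=km_b + km_p,
        km4=km_b,
        k_trans=k_hydr,
        interpretation="atp_hydrolysis",
        provenance={
            "k1": "k_b + k_p, Mg-ATP-actin filament-end rates (Pollard 1986)",
            "km2": "km_b + km_p, Mg-ATP-actin filament-end rates (Pollard 1986)",
            "k4": "barbed-end rate k_b (Pollard 1986); pointed end stabilized after hydrolysis",
            "km4": "barbed-end rate km_b (Pollard 1986)",
            "k_trans": "filament ATP hydrolysis rate k_hydr (literature)",
            "km1": "manually adjusted - unverified",
        },
    )


def cation_exchange_rates(
    k_trans: float = DEFAULT_K_CATION,
    km1: float = DEFAULT_KM1,
) -> RateSet:
    """Cation-exchange interpretation: Ca-actin rates before the Ca²⁺→Mg²⁺
    exchange, Mg-actin rates after."""
    return RateSet(
        k1=CA_ACTIN_ON,
        k2=CA_ACTIN_ON,
        k3=CA_ACTIN_ON,
        k4=BARBED_ON + POINTED_ON,
        km1=km1,
        km2=CA_ACTIN_OFF,
        km3=CA_ACTIN_OFF,
        km4=BARBED_OFF + POINTED_OFF,
        k_trans=k_trans,
        interpretation="cation_exchange",
        provenance={
            "k1": "end-summed Ca-ATP-actin elongation rate (Cooper et al. 1983)",
            "km2": "end-summed Ca-ATP-actin shortening rate (Cooper et al. 1983)",
            "k4": "end-summed Mg-ATP-actin elongation rate (Pollard 1986)",
            "km4": "end-summed Mg-ATP-actin shortening rate (Pollard 1986)",
            "k_trans": "Ca->Mg monomer activation rate, placeholder - unverified",
            "km1": "manually adjusted - unverified",
        },
    )


def equal_step_rates(k: float, km: float) -> RateSet:
    """Single-state scheme with identical stepwise rates (simple isodesmic
    equilibrium; yields an approximately geometric oligomer distribution)."""
    return RateSet(
        k1=k, k2=k, k3=k, k4=k, km1=km, km2=km, km3=km, km4=km,
        k_trans=0.0, interpretation="custom",
        provenance={"all": "equal stepwise rates"},
    )
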