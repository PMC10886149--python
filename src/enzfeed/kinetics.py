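"""Two-fraction Michaelis-Menten kinetics of enzymatic glucose release.

Glucoamylase cleaves glucose monomers from maltodextrin. Under
cultivation-friendly conditions (30 degC, pH 7) the substrate behaves as two
pools: a susceptible fraction ``SS`` that is hydrolyzed quickly and a
resistant fraction ``SR`` that is hydrolyzed roughly 60-fold slower. The
state is expressed in the measurable variables: free glucose ``P`` [g/L],
total dextrin ``S = SS + SR`` [g/L], the susceptible proportion
``WS = SS/S`` (dimensionless), enzyme activity ``E`` [U/L] and liquid
volume ``V`` [L]. Hydrolysis of polymerized anhydroglucose gains one water
per bond, so 1 g of dextrin yields up to ``nu = 1.111`` g of free glucose.

Units are fixed package-wide: g/L, U/L, L, h. The enzyme unit U is the
supplier-defined activity unit; all rates scale linearly in U/L.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, asdict

__all__ = [
    "ReleaseParameters",
    "ReleaseState",
    "ModelVariant",
    "release_rates",
    "variant_rate",
    "release_rhs",
    "max_release",
    "ZERO_SUBSTRATE_EPS",
]

#: Below this total dextrin concentration [g/L] the susceptible-fraction
#: derivative dWS/dt (a quotient in S) is defined as 0.
ZERO_SUBSTRATE_EPS = 1e-12


class ModelVariant(str, enum.Enum):
    """Model family: simple (one-pool) vs two-substrate Michaelis-Menten,
    optionally with product inhibition (PI) and/or substrate inhibition (SI).
    """

    SIMPLE_MM = "simple_mm"
    SIMPLE_MM_PI = "simple_mm_with_product_inhibition"
    SIMPLE_MM_SI = "simple_mm_with_substrate_inhibition"
    SIMPLE_MM_PI_SI = "simple_mm_with_product_and_substrate_inhibition"
    TWO_SUBSTRATE = "mm_two_substrates"
    TWO_SUBSTRATE_PI = "mm_two_substrates_with_product_inhibition"
    TWO_SUBSTRATE_PI_SI = "mm_two_substrates_with_product_and_substrate_inhibition"

    @property
    def two_substrate(self) -> bool:
        return self in (
            ModelVariant.TWO_SUBSTRATE,
            ModelVariant.TWO_SUBSTRATE_PI,
            ModelVariant.TWO_SUBSTRATE_PI_SI,
        )

    @property
    def product_inhibition(self) -> bool:
        return self in (
            ModelVariant.SIMPLE_MM_PI,
            ModelVariant.SIMPLE_MM_PI_SI,
            ModelVariant.TWO_SUBSTRATE_PI,
            ModelVariant.TWO_SUBSTRATE_PI_SI,
        )

    @property
    def substrate_inhibition(self) -> bool:
        return self in (
            ModelVariant.SIMPLE_MM_SI,
            ModelVariant.SIMPLE_MM_PI_SI,
            ModelVariant.TWO_SUBSTRATE_PI_SI,
        )

    @classmethod
    def from_tag(cls, tag: str) -> "ModelVariant":
        tag = tag.strip().lower()
        for member in cls:
            if member.value == tag or member.name.lower() == tag:
                return member
        raise ValueError(f"unknown model variant tag: {tag!r}")


@dataclass
class ReleaseParameters:
    """Kinetic constants of the glucose-release model.

    Parameters
    ----------
    k_s : float
        Catalytic constant of the susceptible fraction [g/(U h)].
    k_r : float
        Catalytic constant of the resistant fraction [g/(U h)].
    K : float
        Michaelis constant [g/L]; a single value shared by both pools
        (the data cannot discriminate different affinities).
    ws0 : float
        Susceptible proportion of fresh dextrin [g/g], in [0, 1].
    nu : float
        Anhydroglucose-to-glucose conversion factor (mass gain on
        hydrolysis), dimensionless.
    r_evap : float
        Evaporation rate [L/h]; removes water only.
    k_single : float or None
        Catalytic constant of the single-pool (simple MM) variants.
    Ki_P : float or None
        Product-inhibition constant [g/L]; competitive, rescales K.
    Ki_S : float or None
        Substrate-inhibition constant [g/L]; adds S^2/Ki_S to the
        rate denominator.
    """

    k_s: float = 0.134
    k_r: float = 0.00212
    K: float = 0.001
    ws0: float = 0.464
    nu: float = 1.111
    r_evap: float = 3.0e-5
    k_single: float | None = None
    Ki_P: float | None = None
    Ki_S: float | None = None

    def __post_init__(self) -> None:
        if self.k_s <= 0:
            raise ValueError(f"k_s must be > 0, got {self.k_s}")
        if self.k_r < 0:
            raise ValueError(f"k_r must be >= 0, got {self.k_r}")
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if not 0.0 <= self.ws0 <= 1.0:
            raise ValueError(f"ws0 must lie in [0, 1], got {self.ws0}")
        if self.nu < 1.0:
            raise ValueError(f"nu must be >= 1, got {self.nu}")
        if self.r_evap < 0:
            raise ValueError(f"r_evap must be >= 0, got {self.r_evap}")
        for name in ("k_single", "Ki_P", "Ki_S"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0 when set, got {v}")

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "ReleaseParameters":
        return cls(**d)

    def replace(self, **kwargs) -> "ReleaseParameters":
        d = asdict(self)
        d.update(kwargs)
        return ReleaseParameters(**d)


@dataclass
class ReleaseState:
    """Concentrations and volume of one well-mixed vessel.

    P : free glucose [g/L]; S : total dextrin [g/L]; WS : susceptible
    proportion SS/S in [0, 1]; E : enzyme activity [U/L]; V : volume [L].
    """

    P: float
    S: float
    WS: float
    E: float
    V: float

    def __post_init__(self) -> None:
        if self.P < 0 or self.S < 0 or self.E < 0:
            raise ValueError(
                f"concentrations must be >= 0 (P={self.P}, S={self.S}, E={self.E})"
            )
        if not 0.0 <= self.WS <= 1.0:
            raise ValueError(f"WS must lie in [0, 1], got {self.WS}")
        if self.V <= 0:
            raise ValueError(f"V must be > 0, got {self.V}")

    @property
    def SS(self) -> float:
        """Susceptible dextrin [g/L]."""
        return self.WS * self.S

    @property
    def SR(self) -> float:
        """Resistant dextrin [g/L]."""
        return (1.0 - self.WS) * self.S

    def as_vector(self) -> list[float]:
        return [self.P, self.S, self.WS, self.E, self.V]

    @classmethod
    def from_vector(cls, y) -> "ReleaseState":
        P, S, WS, E, V = (float(v) for v in y)
        return cls(P=max(P, 0.0), S=max(S, 0.0), WS=min(max(WS, 0.0), 1.0), E=max(E, 0.0), V=V)


def _denominator(S: float, P: float, params: ReleaseParameters, variant: ModelVariant) -> float:
    """Michaelis-Menten denominator, with the variant's inhibition terms."""
    K = params.K
    if variant.product_inhibition:
        if params.Ki_P is None:
            raise ValueError(f"variant {variant.value} requires Ki_P")
        K = K * (1.0 + P / params.Ki_P)
    denom = S + K
    if variant.substrate_inhibition:
        if params.Ki_S is None:
            raise ValueError(f"variant {variant.value} requires Ki_S")
        denom += S * S / params.Ki_S
    return denom


def release_rates(
    state: ReleaseState,
    params: ReleaseParameters,
    variant: ModelVariant = ModelVariant.TWO_SUBSTRATE,
) -> tuple[float, float]:
    """Hydrolysis rates (rS, rR) [g/(L h)] of the two dextrin pools.

    rS = k_s * E * SS / (S + K),  rR = k_r * E * SR / (S + K);
    inhibition variants modify the shared denominator. For the single-pool
    variants the whole substrate reacts with ``k_single`` and rR = 0.
    """
    denom = _denominator(state.S, state.P, params, variant)
    if variant.two_substrate:
        rS = params.k_s * state.E * state.SS / denom
        rR = params.k_r * state.E * state.SR / denom
        return rS, rR
    if params.k_single is None:
        raise ValueError(f"variant {variant.value} requires k_single")
    return params.k_single * state.E * state.S / denom, 0.0


def variant_rate(
    state: ReleaseState,
    params: ReleaseParameters,
    variant: ModelVariant,
) -> float:
    """Total pre-conversion release rate [g/(L h)] for a model variant."""
    rS, rR = release_rates(state, params, variant)
    return rS + rR


def max_release(D: float, params: ReleaseParameters | None = None) -> float:
    """Glucose-equivalent yield [g/L] of complete hydrolysis of ``D`` g/L dextrin.

    Each anhydroglucose unit gains one water on cleavage, so the obtainable
    free glucose is ``nu * D`` (nu = 1.111 for glucose polymers).
    """
    if D < 0:
        raise ValueError(f"dextrin concentration must be >= 0, got {D}")
    nu = params.nu if params is not None else 1.111
    return nu * D


def release_rhs(
    state: ReleaseState,
    params: ReleaseParameters,
    variant: ModelVariant = ModelVariant.TWO_SUBSTRATE,
) -> tuple[float, float, float, float, float]:
    """Time derivatives (dP, dS, dWS, dE, dV) of the release ODE system.

    Between liquid-handling events the balances are

        dP/dt  =  nu*(rS + rR) - (dV/dt)/V * P
        dS/dt  = -(rS + rR)    - (dV/dt)/V * S
        dWS/dt = (-rS + WS*(rS + rR)) / S        (quotient rule; 0 at S ~ 0)
        dE/dt  = -(dV/dt)/V * E
        dV/dt  = -r_evap

    Evaporation removes water only, so the dilution terms with
    dV/dt < 0 *concentrate* all species. Single-pool variants have
    dWS/dt = 0.
    """
    rS, rR = release_rates(state, params, variant)
    dV = -params.r_evap
    dil = dV / state.V
    dP = params.nu * (rS + rR) - dil * state.P
    dS = -(rS + rR) - dil * state.S
    if variant.two_substrate and state.S > ZERO_SUBSTRATE_EPS:
        dWS = (-rS + state.WS * (rS + rR)) / state.S
    else:
        dWS = 0.0
    dE = -dil * state.E
    return dP, dS, dWS, dE, dV


def rhs_vector(t, y, params: ReleaseParameters, variant: ModelVariant):
    """Array-valued right-hand side for scipy integrators.

    y = [P, S, WS, E, V]. Negative round-off values are treated as 0 inside
    the rate laws; WS is clamped to [0, 1].
    """
    P = y[0] if y[0] > 0.0 else 0.0
    S = y[1] if y[1] > 0.0 else 0.0
    WS = min(max(y[2], 0.0), 1.0)
    E = y[3] if y[3] > 0.0 else 0.0
    V = y[4]

    denom = _denominator(S, P, params, variant)
    if variant.two_substrate:
        rS = params.k_s * E * WS * S / denom
        rR = params.k_r * E * (1.0 - WS) * S / denom
    else:
        if params.k_single is None:
            raise ValueError(f"variant {variant.value} requires k_single")
        rS = params.k_single * E * S / denom
        rR = 0.0

    dV = -params.r_evap
    dil = dV / V
    dP = params.nu * (rS + rR) - dil * P
    dS = -(rS + rR) - dil * S
    if variant.two_substrate and S > ZERO_SUBSTRATE_EPS:
        dWS = (-rS + WS * (rS + rR)) / S
    else:
        dWS = 0.0
    dE = -dil * E
    return [dP, dS, dWS, dE, dV]
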