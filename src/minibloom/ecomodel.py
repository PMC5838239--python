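"""0-D trait-based C-S-R phytoplankton community simulator.

The model represents four phytoplankton strategists competing for light and
dissolved nutrients in a closed, zero-dimensional water parcel over a spring
bloom time scale:

* ``SS`` — stress-tolerant picocyanobacteria (*Synechococcus*-like): small,
  high-light adapted, best nutrient affinity, slow growth.
* ``C1`` — colonist nanoflagellates/cryptophytes: fast-growing, non-silicified.
* ``C2`` — colonist nano-diatom (*Minidiscus*-like): fast-growing, silicified.
* ``R``  — ruderal bloom diatoms (*Chaetoceros*-like): largest, fastest
  growing, silicified, light-stress tolerant, and the only group whose
  mortality is modulated by the top-down control experiments.

Each strategist carries separate C, N, P, Si and Chl state variables so that
internal stoichiometry is free to vary (non-Redfieldian behaviour).  Growth
follows a Liebig-minimum Droop quota law, light saturation follows the
Geider formulation through the Chl:C ratio, and nutrient uptake is
Michaelis–Menten with a linear quota-headroom down-regulation.  Strategists
are mixotrophic: dissolved organic N and P can be taken up alongside the
inorganic pools.  A heterotrophic bacteria compartment recycles dissolved
organic matter back to inorganic nutrients, and detrital biogenic silica
redissolves at a first-order rate.  Grazers and viruses are implicit: each
strategist simply loses biomass at a specific mortality rate, and the
mortality of the R strategist is the experimental control knob (10 % d⁻¹
versus 25 % d⁻¹).

The system is integrated by forward Euler at a 300 s time step with a
proportional flux limiter that keeps every pool non-negative.  N, P and Si
budgets are closed by construction; C enters by photosynthesis and leaves by
bacterial respiration only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

__all__ = [
    "STRATEGIST_ORDER",
    "NUTRIENT_CONDITIONS",
    "MORTALITY_CONDITIONS",
    "StrategistTraits",
    "TraitsTable",
    "ForcingConfig",
    "BacteriaParams",
    "ExperimentSpec",
    "CommunityState",
    "SimulationResult",
    "default_traits",
    "initial_community_state",
    "light_field",
    "mm_limitation",
    "quota_status",
    "gross_photosynthesis",
    "chl_synthesis",
    "uptake_fluxes",
    "exudation_fluxes",
    "mortality_fluxes",
    "bacterial_recycling",
    "step",
    "run",
    "dominance",
]

#: Fixed strategist ordering, also the dominance tie-break order.
STRATEGIST_ORDER = ("SS", "C1", "C2", "R")

#: Initial dissolved inorganic nutrients (NO3, PO4, SiOH4) in µmol L⁻¹ for the
#: two convection scenarios: deep winter convection (HCNC) versus a weakly
#: convective winter (LCNC).
NUTRIENT_CONDITIONS = {
    "HCNC": (8.40, 0.39, 7.72),
    "LCNC": (2.66, 0.09, 2.10),
}

#: Mortality rate (d⁻¹) applied to the R strategist under high versus low
#: top-down control.
MORTALITY_CONDITIONS = {"HCC": 0.25, "LCC": 0.10}

#: Carbon gram mass used for Chl:C (g:g) conversions, g (mol C)⁻¹.
GRAMS_C_PER_MOL = 12.0

#: First-order relaxation rate (d⁻¹) venting quota overshoot back to DOM.
QUOTA_RELAX_RATE = 1.0

#: Pools more negative than this after a limited Euler step indicate a bug or
#: an unstable configuration rather than round-off.
_NEGATIVE_TOL = -1e-6


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrategistTraits:
    """Physiological trait set of one strategist.

    Units: rates in d⁻¹; half-saturation constants in µmol L⁻¹; quotas in
    mol X (mol C)⁻¹; ``alpha_chl`` in g C (g Chl)⁻¹ (W m⁻²)⁻¹ d⁻¹;
    ``theta_max`` in g Chl (g C)⁻¹.
    """

    name: str
    strategy: str
    uses_silicon: bool
    mu_max: float
    alpha_chl: float
    theta_max: float
    K_NO3: float
    K_PO4: float
    K_DOM: float
    Qmin_N: float
    Qmax_N: float
    Qmin_P: float
    Qmax_P: float
    m: float
    exud_frac: float
    K_Si: float = 0.0
    Qmin_Si: float = 0.0
    Qmax_Si: float = 0.0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIST_ORDER:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.mu_max <= 0:
            raise ValueError("mu_max must be positive")
        if self.m < 0:
            raise ValueError("mortality must be non-negative")
        if not 0 <= self.exud_frac < 1:
            raise ValueError("exud_frac must lie in [0, 1)")
        for k_name in ("alpha_chl", "theta_max", "K_NO3", "K_PO4", "K_DOM"):
            if getattr(self, k_name) <= 0:
                raise ValueError(f"{k_name} must be positive")
        for el in ("N", "P") + (("Si",) if self.uses_silicon else ()):
            qmin = getattr(self, f"Qmin_{el}")
            qmax = getattr(self, f"Qmax_{el}")
            if not 0 < qmin < qmax:
                raise ValueError(f"need 0 < Qmin_{el} < Qmax_{el}")
        if self.uses_silicon and self.K_Si <= 0:
            raise ValueError("silicified strategists need K_Si > 0")


class TraitsTable:
    """Ordered collection of strategist traits with vectorised views."""

    def __init__(self, traits: Iterable[StrategistTraits]):
        self.traits = tuple(traits)
        if not self.traits:
            raise ValueError("empty traits table")
        self.names = tuple(t.name for t in self.traits)
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate strategist names")

        def arr(attr: str) -> np.ndarray:
            return np.array([getattr(t, attr) for t in self.traits], dtype=float)

        self.mu_max = arr("mu_max")
        self.alpha_chl = arr("alpha_chl")
        self.theta_max = arr("theta_max")
        self.K_NO3 = arr("K_NO3")
        self.K_PO4 = arr("K_PO4")
        self.K_Si = arr("K_Si")
        self.K_DOM = arr("K_DOM")
        self.Qmin_N = arr("Qmin_N")
        self.Qmax_N = arr("Qmax_N")
        self.Qmin_P = arr("Qmin_P")
        self.Qmax_P = arr("Qmax_P")
        self.Qmin_Si = arr("Qmin_Si")
        self.Qmax_Si = arr("Qmax_Si")
        self.m = arr("m")
        self.exud_frac = arr("exud_frac")
        self.uses_silicon = np.array([t.uses_silicon for t in self.traits])
        self.is_r = np.array([t.strategy == "R" for t in self.traits])

    def __len__(self) -> int:
        return len(self.traits)

    def __iter__(self):
        return iter(self.traits)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def with_overrides(self, overrides: dict) -> "TraitsTable":
        """Return a copy with per-strategist field overrides, e.g.
        ``{"C2": {"mu_max": 1.4}}``."""
        new = []
        for t in self.traits:
            if t.name in overrides:
                new.append(replace(t, **overrides[t.name]))
            else:
                new.append(t)
        return TraitsTable(new)


def default_traits() -> TraitsTable:
    """Default strategist trait table.

    Values follow standard allometric orderings: nutrient half-saturation
    constants increase and photosynthetic efficiency decreases with cell
    size (SS < C1 ≈ C2 < R), maximum quotas decrease with cell volume, and
    the homogeneous nano-diatom group (C2) carries a higher baseline
    mortality than the heterogeneous nanoflagellate mix (C1), which is
    buffered against any single pathogen or grazer.  The R strategist grows
    fastest but is the most nutrient- and light-inefficient, and its
    mortality is overridden by the experiment.
    """
    return TraitsTable(
        [
            StrategistTraits(
                name="SS", strategy="SS", uses_silicon=False,
                mu_max=0.9, alpha_chl=6.0, theta_max=0.020,
                K_NO3=0.3, K_PO4=0.03, K_DOM=1.0,
                Qmin_N=0.07, Qmax_N=0.20, Qmin_P=0.004, Qmax_P=0.013,
                m=0.08, exud_frac=0.05,
            ),
            StrategistTraits(
                name="C1", strategy="C1", uses_silicon=False,
                mu_max=1.2, alpha_chl=5.0, theta_max=0.030,
                K_NO3=0.7, K_PO4=0.04, K_DOM=1.0,
                Qmin_N=0.06, Qmax_N=0.17, Qmin_P=0.0035, Qmax_P=0.011,
                m=0.10, exud_frac=0.05,
            ),
            StrategistTraits(
                name="C2", strategy="C2", uses_silicon=True,
                mu_max=1.6, alpha_chl=4.0, theta_max=0.040,
                K_NO3=1.0, K_PO4=0.045, K_DOM=1.0, K_Si=1.0,
                Qmin_N=0.05, Qmax_N=0.15, Qmin_P=0.003, Qmax_P=0.009,
                Qmin_Si=0.05, Qmax_Si=0.15,
                m=0.12, exud_frac=0.05,
            ),
            StrategistTraits(
                name="R", strategy="R", uses_silicon=True,
                mu_max=1.7, alpha_chl=3.0, theta_max=0.060,
                K_NO3=1.5, K_PO4=0.05, K_DOM=1.0, K_Si=1.5,
                Qmin_N=0.04, Qmax_N=0.12, Qmin_P=0.0025, Qmax_P=0.007,
                Qmin_Si=0.04, Qmax_Si=0.12,
                m=0.10, exud_frac=0.05,
            ),
        ]
    )


@dataclass(frozen=True)
class ForcingConfig:
    """Physical forcing: square-wave day/night irradiance and integration grid.

    ``irradiance_day`` in W m⁻², ``photoperiod_h`` in hours per 24 h cycle,
    ``dt`` in seconds, ``duration`` in days.
    """

    irradiance_day: float = 300.0
    photoperiod_h: float = 12.0
    dt: float = 300.0
    duration: float = 40.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if not 0 <= self.photoperiod_h <= 24:
            raise ValueError("photoperiod_h must lie in [0, 24]")
        if self.irradiance_day < 0:
            raise ValueError("irradiance must be non-negative")

    @property
    def dt_days(self) -> float:
        return self.dt / 86400.0

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt_days)) if self.duration else 0


@dataclass(frozen=True)
class BacteriaParams:
    """Heterotrophic bacteria and abiotic recycling parameters.

    Uptake rates are per unit bacterial C biomass (d⁻¹ for C;
    mol X (mol C)⁻¹ d⁻¹ for N and P); ``growth_efficiency`` is the fraction
    of each uptake incorporated into bacterial biomass, the remainder being
    respired (C) or remineralised to NO3/PO4 (N, P).  ``bsi_dissolution`` is
    the first-order redissolution rate of detrital biogenic silica, d⁻¹.
    """

    vmax_doc: float = 4.0
    vmax_don: float = 0.3
    vmax_dop: float = 0.03
    k_doc: float = 2.0
    k_don: float = 0.3
    k_dop: float = 0.02
    growth_efficiency: float = 0.3
    mortality: float = 0.1
    bsi_dissolution: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.growth_efficiency <= 1:
            raise ValueError("growth_efficiency must lie in (0, 1]")
        for k_name in ("k_doc", "k_don", "k_dop"):
            if getattr(self, k_name) <= 0:
                raise ValueError(f"{k_name} must be positive")


@dataclass(frozen=True)
class ExperimentSpec:
    """One factorial mortality × nutrient experiment.

    ``nutrient_condition`` selects the initial dissolved nutrient field
    (HCNC after deep convection, LCNC after a mild winter);
    ``control_condition`` selects the implicit top-down mortality applied to
    the R strategist (HCC 25 % d⁻¹, LCC 10 % d⁻¹).  ``seed`` is unused by
    the deterministic core and reserved for stochastic extensions.
    """

    nutrient_condition: str = "HCNC"
    control_condition: str = "LCC"
    initial_biomass_c: float = 0.05
    r_mortality_override: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nutrient_condition not in NUTRIENT_CONDITIONS:
            raise ValueError(f"unknown nutrient condition {self.nutrient_condition!r}")
        if self.control_condition not in MORTALITY_CONDITIONS:
            raise ValueError(f"unknown control condition {self.control_condition!r}")
        if self.initial_biomass_c < 0:
            raise ValueError("initial biomass must be non-negative")
        if self.r_mortality_override is not None and self.r_mortality_override < 0:
            raise ValueError("r_mortality_override must be non-negative")

    @property
    def initial_nutrients(self) -> tuple[float, float, float]:
        """(NO3, PO4, SiOH4) in µmol L⁻¹."""
        return NUTRIENT_CONDITIONS[self.nutrient_condition]

    @property
    def r_mortality(self) -> float:
        """Mortality rate applied to the R strategist, d⁻¹.

        Derived from the control condition; ``r_mortality_override`` lets
        sensitivity sweeps place the rate anywhere between (or beyond) the
        two factorial levels.
        """
        if self.r_mortality_override is not None:
            return self.r_mortality_override
        return MORTALITY_CONDITIONS[self.control_condition]

    @property
    def label(self) -> str:
        return f"{self.nutrient_condition.lower()}_x_{self.control_condition.lower()}"


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------


@dataclass
class CommunityState:
    """Full model state at one instant.

    Per-strategist arrays are ordered like the traits table.  Units:
    µmol L⁻¹ for all element pools, µg Chl L⁻¹ for ``Chl``, days for
    ``time``.
    """

    C: np.ndarray
    N: np.ndarray
    P: np.ndarray
    Si: np.ndarray
    Chl: np.ndarray
    BC: float
    BN: float
    BP: float
    NO3: float
    PO4: float
    SiOH4: float
    DOC: float
    DON: float
    DOP: float
    dBSi: float
    time: float = 0.0

    def copy(self) -> "CommunityState":
        return CommunityState(
            C=self.C.copy(), N=self.N.copy(), P=self.P.copy(),
            Si=self.Si.copy(), Chl=self.Chl.copy(),
            BC=self.BC, BN=self.BN, BP=self.BP,
            NO3=self.NO3, PO4=self.PO4, SiOH4=self.SiOH4,
            DOC=self.DOC, DON=self.DON, DOP=self.DOP,
            dBSi=self.dBSi, time=self.time,
        )

    # budget diagnostics (closed by construction for N, P, Si)
    def total_N(self) -> float:
        return float(self.N.sum() + self.BN + self.NO3 + self.DON)

    def total_P(self) -> float:
        return float(self.P.sum() + self.BP + self.PO4 + self.DOP)

    def total_Si(self) -> float:
        return float(self.Si.sum() + self.SiOH4 + self.dBSi)

    def total_C(self) -> float:
        return float(self.C.sum() + self.BC + self.DOC)

    def validate(self) -> None:
        pools = np.concatenate(
            [self.C, self.N, self.P, self.Si, self.Chl,
             [self.BC, self.BN, self.BP, self.NO3, self.PO4, self.SiOH4,
              self.DOC, self.DON, self.DOP, self.dBSi]]
        )
        if not np.all(np.isfinite(pools)):
            raise FloatingPointError("non-finite state (unstable step; reduce dt)")
        if pools.min() < _NEGATIVE_TOL:
            raise ValueError("negative pool in state")


def initial_community_state(
    experiment: ExperimentSpec,
    traits: TraitsTable,
    *,
    bacteria_c: float = 0.05,
    dom: tuple[float, float, float] = (1.0, 0.15, 0.01),
) -> CommunityState:
    """Build the default initial state for one experiment.

    Each strategist is seeded at a small equal C biomass with quotas at the
    midpoint of their admissible range and Chl:C at half ``theta_max``;
    bacteria start at the same small biomass with a Redfield-like
    stoichiometry; DOM pools start at modest background concentrations.
    """
    c0 = np.full(len(traits), experiment.initial_biomass_c, dtype=float)
    qn0 = 0.5 * (traits.Qmin_N + traits.Qmax_N)
    qp0 = 0.5 * (traits.Qmin_P + traits.Qmax_P)
    qsi0 = np.where(traits.uses_silicon, 0.5 * (traits.Qmin_Si + traits.Qmax_Si), 0.0)
    theta0 = 0.5 * traits.theta_max
    no3, po4, sioh4 = experiment.initial_nutrients
    return CommunityState(
        C=c0,
        N=qn0 * c0,
        P=qp0 * c0,
        Si=qsi0 * c0,
        Chl=theta0 * c0 * GRAMS_C_PER_MOL,
        BC=bacteria_c, BN=0.2 * bacteria_c, BP=0.02 * bacteria_c,
        NO3=no3, PO4=po4, SiOH4=sioh4,
        DOC=dom[0], DON=dom[1], DOP=dom[2],
        dBSi=0.0, time=0.0,
    )


# ---------------------------------------------------------------------------
# elemental process kernels
# ---------------------------------------------------------------------------


def light_field(t: float, forcing: ForcingConfig) -> float:
    """Square-wave irradiance (W m⁻²) at time ``t`` (days since run start).

    Light is on during the first ``photoperiod_h`` hours of every 24 h
    cycle and off otherwise.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    hour = (t % 1.0) * 24.0
    return forcing.irradiance_day if hour < forcing.photoperiod_h else 0.0


def mm_limitation(S, K):
    """Michaelis–Menten saturation S/(K+S), dimensionless in [0, 1]."""
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("half-saturation constant must be positive")
    S = np.asarray(S, dtype=float)
    out = S / (K + S)
    return float(out) if out.ndim == 0 else out


def quota_status(X_s, C_s, traits: StrategistTraits, element: str):
    """Quota diagnostics for one strategist and element.

    Returns ``(Q, droop, headroom)`` where ``Q = X_s / C_s`` is the cell
    quota, ``droop = max(0, 1 - Qmin/Q)`` is the raw Droop growth
    limitation and ``headroom = clip((Qmax - Q)/(Qmax - Qmin), 0, 1)`` is
    the linear uptake down-regulation.
    """
    if C_s <= 0:
        raise ValueError("empty carbon pool: quota undefined")
    qmin = getattr(traits, f"Qmin_{element}")
    qmax = getattr(traits, f"Qmax_{element}")
    q = X_s / C_s
    droop = max(0.0, 1.0 - qmin / q) if q > 0 else 0.0
    headroom = min(1.0, max(0.0, (qmax - q) / (qmax - qmin)))
    return q, droop, headroom


def _normalized_droop(Q, qmin, qmax):
    """Droop limitation normalised so growth reaches mu_max at Q = Qmax."""
    q = np.maximum(np.asarray(Q, dtype=float), 1e-300)
    raw = np.maximum(0.0, 1.0 - qmin / q)
    return np.minimum(1.0, raw / (1.0 - qmin / qmax))


def gross_photosynthesis(traits: StrategistTraits, C_s: float, Chl_s: float,
                         E: float, growth_cap: float) -> float:
    """Gross C fixation of one strategist, µmol C L⁻¹ d⁻¹.

    Geider-form light saturation: the C-specific rate is
    ``growth_cap * (1 - exp(-alpha_chl * theta * E / growth_cap))`` with
    ``theta`` the Chl:C ratio (g:g), so that photosynthesis rises linearly
    with irradiance at low light (slope ``alpha_chl * theta``) and
    saturates at the nutrient-set ``growth_cap``.
    """
    if growth_cap <= 0 or E <= 0 or C_s <= 0:
        return 0.0
    theta = Chl_s / (GRAMS_C_PER_MOL * C_s)
    x = traits.alpha_chl * theta * E
    pc = growth_cap * -math.expm1(-x / growth_cap)
    return pc * C_s


def chl_synthesis(traits: StrategistTraits, pc_specific: float, E: float,
                  theta: float, C_s: float = 1.0) -> float:
    """Chlorophyll production, µg Chl L⁻¹ d⁻¹ (Geider regulation).

    ``rho_chl = theta_max * P^C / (alpha_chl * theta * E)`` is the Chl
    allocated per unit C fixed (``pc_specific`` = C-specific photosynthesis
    P^C, d⁻¹): at low light the full ``theta_max`` is allocated, at
    saturating light allocation is down-regulated, so the ratio never drives
    theta above ``theta_max``.  When ``theta * E = 0`` the allocation
    defaults to ``theta_max``.
    """
    if pc_specific < 0:
        raise ValueError("photosynthesis rate must be non-negative")
    x = traits.alpha_chl * theta * E
    rho = traits.theta_max * pc_specific / x if x > 0 else traits.theta_max
    return rho * pc_specific * GRAMS_C_PER_MOL * C_s


def _chl_synthesis_specific(theta_max, alpha_chl, pc_specific, theta, E):
    """Vectorised Geider Chl synthesis from the C-specific rate (d⁻¹).

    Returns synthesis per unit C biomass in g Chl (mol C)⁻¹ d⁻¹ so that
    multiplying by C (µmol L⁻¹) gives µg Chl L⁻¹ d⁻¹.
    """
    x = alpha_chl * theta * E
    rho = np.where(x > 0, theta_max * pc_specific / np.where(x > 0, x, 1.0), theta_max)
    return rho * pc_specific * GRAMS_C_PER_MOL


def uptake_fluxes(traits: StrategistTraits, state: CommunityState, s: int):
    """Nutrient uptake of strategist ``s``: (V_NO3, V_PO4, V_Si, V_DON, V_DOP).

    Each flux (µmol L⁻¹ d⁻¹) is ``Vmax * MM(S, K) * headroom * C`` with the
    sufficiency closure ``Vmax_X = mu_max * Qmax_X``; dissolved organic N
    and P are taken up through the common mixotrophy half-saturation
    ``K_DOM``.  Silicate uptake is zero for non-silicified strategists.
    """
    c = state.C[s]
    if c <= 0:
        return (0.0, 0.0, 0.0, 0.0, 0.0)
    _, _, head_n = quota_status(state.N[s], c, traits, "N")
    _, _, head_p = quota_status(state.P[s], c, traits, "P")
    vmax_n = traits.mu_max * traits.Qmax_N
    vmax_p = traits.mu_max * traits.Qmax_P
    v_no3 = vmax_n * mm_limitation(state.NO3, traits.K_NO3) * head_n * c
    v_don = vmax_n * mm_limitation(state.DON, traits.K_DOM) * head_n * c
    v_po4 = vmax_p * mm_limitation(state.PO4, traits.K_PO4) * head_p * c
    v_dop = vmax_p * mm_limitation(state.DOP, traits.K_DOM) * head_p * c
    v_si = 0.0
    if traits.uses_silicon:
        _, _, head_si = quota_status(state.Si[s], c, traits, "Si")
        v_si = (traits.mu_max * traits.Qmax_Si
                * mm_limitation(state.SiOH4, traits.K_Si) * head_si * c)
    return (v_no3, v_po4, v_si, v_don, v_dop)


def exudation_fluxes(traits: StrategistTraits, state: CommunityState, s: int,
                     gross_C: float):
    """DOM release of strategist ``s``: (to_DOC, to_DON, to_DOP) µmol L⁻¹ d⁻¹.

    A fixed fraction of gross C fixation is exuded as DOC; any element whose
    quota exceeds its maximum is vented to the matching DOM pool at a
    relaxation rate restoring the bound within about one day.
    """
    if gross_C < 0:
        raise ValueError("gross_C must be non-negative")
    to_doc = traits.exud_frac * gross_C
    c = state.C[s]
    to_don = QUOTA_RELAX_RATE * max(0.0, state.N[s] - traits.Qmax_N * c)
    to_dop = QUOTA_RELAX_RATE * max(0.0, state.P[s] - traits.Qmax_P * c)
    return (to_doc, to_don, to_dop)


def mortality_fluxes(traits: StrategistTraits, state: CommunityState, s: int,
                     experiment: ExperimentSpec):
    """Per-pool mortality losses of strategist ``s``, µmol L⁻¹ d⁻¹ (Chl in µg).

    Implicit grazing/lysis: every pool is lost at the specific mortality
    rate; for the R strategist the rate is the experiment's control knob.
    C, N, P go to DOC/DON/DOP, Si to detrital biogenic silica.
    """
    rate = experiment.r_mortality if traits.strategy == "R" else traits.m
    return {
        "C": rate * state.C[s],
        "N": rate * state.N[s],
        "P": rate * state.P[s],
        "Si": rate * state.Si[s],
        "Chl": rate * state.Chl[s],
    }


def bacterial_recycling(state: CommunityState, params: BacteriaParams = BacteriaParams()):
    """Bacterial DOM uptake/remineralisation and BSi dissolution fluxes.

    Returns a dict with DOC/DON/DOP uptake (µmol L⁻¹ d⁻¹), the respective
    incorporation into bacterial biomass, respiration (C) and
    remineralisation to NO3/PO4 (N, P), bacterial mortality back to DOM,
    and first-order dissolution of detrital biogenic silica to silicate.
    """
    eps = params.growth_efficiency
    u_doc = params.vmax_doc * mm_limitation(state.DOC, params.k_doc) * state.BC
    u_don = params.vmax_don * mm_limitation(state.DON, params.k_don) * state.BC
    u_dop = params.vmax_dop * mm_limitation(state.DOP, params.k_dop) * state.BC
    return {
        "uptake_DOC": u_doc, "uptake_DON": u_don, "uptake_DOP": u_dop,
        "to_BC": eps * u_doc, "respired": (1 - eps) * u_doc,
        "to_BN": eps * u_don, "to_NO3": (1 - eps) * u_don,
        "to_BP": eps * u_dop, "to_PO4": (1 - eps) * u_dop,
        "mort_BC": params.mortality * state.BC,
        "mort_BN": params.mortality * state.BN,
        "mort_BP": params.mortality * state.BP,
        "bsi_dissolution": params.bsi_dissolution * state.dBSi,
    }


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------


def _limiter(pool, sink, dt):
    """Proportional flux-limiter factor for one source pool."""
    out = sink * dt
    return np.where(out > pool, np.where(out > 0, pool / np.where(out > 0, out, 1.0), 1.0), 1.0)


def _limiter_scalar(pool: float, sink: float, dt: float) -> float:
    out = sink * dt
    return pool / out if out > pool and out > 0 else 1.0


def step(
    state: CommunityState,
    traits: TraitsTable,
    experiment: ExperimentSpec,
    forcing: ForcingConfig,
    bacteria: BacteriaParams = BacteriaParams(),
) -> CommunityState:
    """Advance the community one forward-Euler step of ``forcing.dt``.

    All fluxes leaving a given pool are scaled by a common factor whenever
    they would overdraw it within the step, which guarantees non-negativity
    while preserving the N, P and Si budgets exactly (every scaled sink is
    added to its destination with the same factor).
    """
    dt = forcing.dt_days
    tr = traits
    E = light_field(state.time, forcing)

    C, N, P, Si, Chl = state.C, state.N, state.P, state.Si, state.Chl
    active = C > 0
    Cs = np.where(active, C, 1.0)

    # quota diagnostics
    QN, QP, QSi = N / Cs, P / Cs, Si / Cs
    droop_n = _normalized_droop(QN, tr.Qmin_N, tr.Qmax_N)
    droop_p = _normalized_droop(QP, tr.Qmin_P, tr.Qmax_P)
    droop_si = np.where(
        tr.uses_silicon,
        _normalized_droop(QSi, np.where(tr.uses_silicon, tr.Qmin_Si, 1e-12),
                          np.where(tr.uses_silicon, tr.Qmax_Si, 1.0)),
        1.0,
    )
    head_n = np.clip((tr.Qmax_N - QN) / (tr.Qmax_N - tr.Qmin_N), 0.0, 1.0)
    head_p = np.clip((tr.Qmax_P - QP) / (tr.Qmax_P - tr.Qmin_P), 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        head_si = np.where(
            tr.uses_silicon,
            np.clip((tr.Qmax_Si - QSi)
                    / np.where(tr.uses_silicon, tr.Qmax_Si - tr.Qmin_Si, 1.0),
                    0.0, 1.0),
            0.0,
        )

    cap = tr.mu_max * np.minimum(np.minimum(droop_n, droop_p), droop_si)
    cap = np.where(active, cap, 0.0)

    # light-saturated photosynthesis and photoacclimation
    theta = Chl / (GRAMS_C_PER_MOL * Cs)
    x = tr.alpha_chl * theta * E
    safe_cap = np.where(cap > 0, cap, 1.0)
    pc = np.where((cap > 0) & (x > 0), safe_cap * -np.expm1(-x / safe_cap), 0.0)
    pp = pc * C
    synth_specific = _chl_synthesis_specific(tr.theta_max, tr.alpha_chl, pc, theta, E)
    synth = np.where(theta < tr.theta_max, synth_specific * C, 0.0)

    # uptake (sufficiency closure Vmax = mu_max * Qmax)
    vmax_n, vmax_p = tr.mu_max * tr.Qmax_N, tr.mu_max * tr.Qmax_P
    v_no3 = vmax_n * (state.NO3 / (tr.K_NO3 + state.NO3)) * head_n * C
    v_don = vmax_n * (state.DON / (tr.K_DOM + state.DON)) * head_n * C
    v_po4 = vmax_p * (state.PO4 / (tr.K_PO4 + state.PO4)) * head_p * C
    v_dop = vmax_p * (state.DOP / (tr.K_DOM + state.DOP)) * head_p * C
    safe_ksi = np.where(tr.uses_silicon, tr.K_Si, 1.0)
    v_si = np.where(
        tr.uses_silicon,
        tr.mu_max * tr.Qmax_Si * (state.SiOH4 / (safe_ksi + state.SiOH4)) * head_si * C,
        0.0,
    )

    # exudation and quota-overshoot venting
    exud = tr.exud_frac * pp
    vent_n = QUOTA_RELAX_RATE * np.maximum(0.0, N - tr.Qmax_N * C)
    vent_p = QUOTA_RELAX_RATE * np.maximum(0.0, P - tr.Qmax_P * C)
    vent_si = QUOTA_RELAX_RATE * np.maximum(0.0, Si - tr.Qmax_Si * C) * tr.uses_silicon

    # mortality (R strategist rate set by the experiment)
    m_eff = np.where(tr.is_r, experiment.r_mortality, tr.m)
    mort_c, mort_n, mort_p = m_eff * C, m_eff * N, m_eff * P
    mort_si, mort_chl = m_eff * Si, m_eff * Chl

    # bacteria and abiotic recycling
    bp = bacteria
    eps = bp.growth_efficiency
    u_doc = bp.vmax_doc * (state.DOC / (bp.k_doc + state.DOC)) * state.BC
    u_don = bp.vmax_don * (state.DON / (bp.k_don + state.DON)) * state.BC
    u_dop = bp.vmax_dop * (state.DOP / (bp.k_dop + state.DOP)) * state.BC
    mort_bc = bp.mortality * state.BC
    mort_bn = bp.mortality * state.BN
    mort_bp_ = bp.mortality * state.BP
    diss = bp.bsi_dissolution * state.dBSi

    # per-source-pool limiter factors
    lam_no3 = _limiter_scalar(state.NO3, float(v_no3.sum()), dt)
    lam_po4 = _limiter_scalar(state.PO4, float(v_po4.sum()), dt)
    lam_sioh4 = _limiter_scalar(state.SiOH4, float(v_si.sum()), dt)
    lam_doc = _limiter_scalar(state.DOC, u_doc, dt)
    lam_don = _limiter_scalar(state.DON, float(v_don.sum()) + u_don, dt)
    lam_dop = _limiter_scalar(state.DOP, float(v_dop.sum()) + u_dop, dt)
    lam_dbsi = _limiter_scalar(state.dBSi, diss, dt)
    lam_bc = _limiter_scalar(state.BC, mort_bc, dt)
    lam_bn = _limiter_scalar(state.BN, mort_bn, dt)
    lam_bp = _limiter_scalar(state.BP, mort_bp_, dt)
    lam_c = _limiter(C, exud + mort_c, dt)
    lam_n = _limiter(N, mort_n + vent_n, dt)
    lam_p = _limiter(P, mort_p + vent_p, dt)
    lam_si = _limiter(Si, mort_si + vent_si, dt)
    lam_chl = _limiter(Chl, mort_chl, dt)

    # assemble the limited Euler update
    new = state.copy()
    new.C = C + dt * (pp - lam_c * (exud + mort_c))
    new.N = N + dt * (lam_no3 * v_no3 + lam_don * v_don - lam_n * (mort_n + vent_n))
    new.P = P + dt * (lam_po4 * v_po4 + lam_dop * v_dop - lam_p * (mort_p + vent_p))
    new.Si = Si + dt * (lam_sioh4 * v_si - lam_si * (mort_si + vent_si))
    new.Chl = Chl + dt * (synth - lam_chl * mort_chl)

    new.NO3 = state.NO3 + dt * (-lam_no3 * float(v_no3.sum()) + (1 - eps) * lam_don * u_don)
    new.PO4 = state.PO4 + dt * (-lam_po4 * float(v_po4.sum()) + (1 - eps) * lam_dop * u_dop)
    new.SiOH4 = state.SiOH4 + dt * (-lam_sioh4 * float(v_si.sum()) + lam_dbsi * diss)

    new.DOC = state.DOC + dt * (
        float((lam_c * (exud + mort_c)).sum()) + lam_bc * mort_bc - lam_doc * u_doc
    )
    new.DON = state.DON + dt * (
        float((lam_n * (mort_n + vent_n)).sum()) + lam_bn * mort_bn
        - lam_don * (float(v_don.sum()) + u_don)
    )
    new.DOP = state.DOP + dt * (
        float((lam_p * (mort_p + vent_p)).sum()) + lam_bp * mort_bp_
        - lam_dop * (float(v_dop.sum()) + u_dop)
    )
    new.dBSi = state.dBSi + dt * (
        float((lam_si * (mort_si + vent_si)).sum()) - lam_dbsi * diss
    )
    new.BC = state.BC + dt * (eps * lam_doc * u_doc - lam_bc * mort_bc)
    new.BN = state.BN + dt * (eps * lam_don * u_don - lam_bn * mort_bn)
    new.BP = state.BP + dt * (eps * lam_dop * u_dop - lam_bp * mort_bp_)

    # round-off can leave pools a few ulp below zero after an exact limit hit
    new.C = np.maximum(new.C, 0.0)
    new.N = np.maximum(new.N, 0.0)
    new.P = np.maximum(new.P, 0.0)
    new.Si = np.maximum(new.Si, 0.0)
    new.Chl = np.maximum(new.Chl, 0.0)
    for attr in ("BC", "BN", "BP", "NO3", "PO4", "SiOH4", "DOC", "DON", "DOP", "dBSi"):
        v = getattr(new, attr)
        if v < 0:
            if v < _NEGATIVE_TOL:
                raise FloatingPointError(f"{attr} went negative ({v}); reduce dt")
            setattr(new, attr, 0.0)

    new.time = state.time + dt
    if not np.isfinite(new.C).all():
        raise FloatingPointError("non-finite state after step; reduce dt")
    return new


# ---------------------------------------------------------------------------
# simulation driver and diagnostics
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Trajectory and diagnostics of one experiment run."""

    experiment: ExperimentSpec
    strategists: tuple
    time: np.ndarray                  # (n_out,) days
    states: list                      # CommunityState at each output time
    biomass_C: np.ndarray             # (n_out, n_strategists) µmol C L⁻¹
    budget_N: np.ndarray
    budget_P: np.ndarray
    budget_Si: np.ndarray

    def budget_drift(self) -> dict:
        """Maximum relative drift of each conserved budget over the run."""
        out = {}
        for name, series in (("N", self.budget_N), ("P", self.budget_P),
                             ("Si", self.budget_Si)):
            ref = series[0]
            out[name] = float(np.abs(series - ref).max() / ref) if ref > 0 else 0.0
        return out

    def final_dominant(self) -> str:
        return dominance(self)[-1][0][0]


def run(
    experiment: ExperimentSpec,
    traits: TraitsTable | None = None,
    forcing: ForcingConfig | None = None,
    output_stride: int = 144,
    bacteria: BacteriaParams = BacteriaParams(),
    initial_state: CommunityState | None = None,
) -> SimulationResult:
    """Integrate one experiment and collect the trajectory.

    ``output_stride`` is the number of Euler steps between stored outputs
    (144 steps of 300 s = twice daily).  The initial state is always stored;
    with ``duration = 0`` the trajectory holds just the initial state.
    """
    traits = traits if traits is not None else default_traits()
    forcing = forcing if forcing is not None else ForcingConfig()
    if output_stride < 1:
        raise ValueError("output_stride must be >= 1")
    state = (initial_state.copy() if initial_state is not None
             else initial_community_state(experiment, traits))

    times, states = [state.time], [state.copy()]
    n_steps = forcing.n_steps
    for i in range(1, n_steps + 1):
        state = step(state, traits, experiment, forcing, bacteria)
        if i % output_stride == 0 or i == n_steps:
            times.append(state.time)
            states.append(state.copy())

    biomass = np.array([s.C for s in states])
    return SimulationResult(
        experiment=experiment,
        strategists=traits.names,
        time=np.array(times),
        states=states,
        biomass_C=biomass,
        budget_N=np.array([s.total_N() for s in states]),
        budget_P=np.array([s.total_P() for s in states]),
        budget_Si=np.array([s.total_Si() for s in states]),
    )


def dominance(result: SimulationResult) -> list:
    """Strategists ranked by C biomass at each output time.

    Returns, per output time, a list of ``(name, biomass)`` pairs sorted by
    descending biomass; ties are broken by the fixed strategist order
    SS < C1 < C2 < R.
    """
    if len(result.time) == 0:
        raise ValueError("empty simulation result")
    ranked = []
    for row in result.biomass_C:
        order = sorted(range(len(row)), key=lambda i: (-row[i], i))
        ranked.append([(result.strategists[i], float(row[i])) for i in order])
    return ranked
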