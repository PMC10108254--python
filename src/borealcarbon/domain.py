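"""Core record types of the carbon-budget pipeline.

The pipeline itself works on pandas DataFrames (one per field table); these
dataclasses define the validated per-record view and the budget identities
that every emitted row must satisfy:

    NEP   = NPP - RH
    NPP   = NPP_t + NPP_u
    NPP_t = ANPP_t + BNPP_t_cr + BNPP_t_fr
    NPP_u = ANPP_u + BNPP_u
    RH    = RH_s + RH_dw

All fluxes are in g C m-2 yr-1.  NPP and RH components are non-negative;
NEP may take either sign (positive = net ecosystem C uptake).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields


TREE_STATUSES = ("live", "dead_standing", "dead_downed", "removed")
DEADWOOD_POSITIONS = ("standing", "downed")
UNDERSTORY_MONTHS = ("june", "august")


@dataclass
class DriverVector:
    """Stand-level abiotic and biotic covariates used in the driver analysis."""

    slope: float = 0.0          # degrees
    ns_aspect: float = 0.0      # cos(aspect), [-1, 1]
    ew_aspect: float = 0.0      # sin(aspect), [-1, 1]
    b_t: float = 0.0            # total tree biomass, Mg ha-1
    lai_max: float | None = None  # peak-season leaf area index, m2 m-2
    o_depth: float = 0.0        # organic-layer depth, cm
    cn_ratio: float = 0.0
    bd: float = 0.0             # bulk density, g cm-3
    swc: float = 0.0            # soil volumetric water content, %
    ts: float = 0.0             # mean soil temperature at 10 cm, degC
    soc: float = 0.0            # soil organic carbon, Mg C ha-1
    ba: float = 0.0             # basal area, m2 ha-1


@dataclass
class StandRecord:
    stand_id: str
    age: int
    age_class: str
    species_group: str          # 'pine' | 'spruce'
    soil_type: str              # 'till' | 'sediment'
    plot_radius: float = 10.0
    drivers: DriverVector = field(default_factory=DriverVector)

    def __post_init__(self):
        if self.age < 0:
            raise ValueError(f"stand {self.stand_id}: age must be >= 0")
        if self.plot_radius <= 0:
            raise ValueError(f"stand {self.stand_id}: plot_radius must be > 0")


@dataclass
class TreeObservation:
    stand_id: str
    tree_id: str
    year: int
    dbh: float                  # cm
    species: str
    status: str = "live"
    decay_class: int | None = None

    def __post_init__(self):
        if self.status not in TREE_STATUSES:
            raise ValueError(f"unknown tree status '{self.status}'")
        if self.status.startswith("dead") and self.decay_class is None:
            raise ValueError(
                f"tree {self.tree_id}: dead trees require a decay class")
        if self.status == "live" and self.decay_class is not None:
            raise ValueError(
                f"tree {self.tree_id}: live trees must not carry a decay class")


@dataclass
class ChamberMeasurement:
    """One chamber deployment: a closed-chamber CO2 concentration series."""

    stand_id: str
    timestamp: str
    seconds: list[float]        # since chamber closure
    ppm: list[float]
    ts_c: float                 # soil temperature at 10 cm
    swc_pct: float
    ta_bc_c: float              # below-canopy air temperature
    pressure_kpa: float = 101.325
    base_side_m: float = 0.45
    height_m: float = 0.20

    def __post_init__(self):
        if len(self.seconds) != len(self.ppm):
            raise ValueError("seconds and ppm must have equal length")
        if len(self.seconds) < 5:
            raise ValueError("chamber series needs at least 5 points")
        if any(b >= a for a, b in zip(self.seconds[1:], self.seconds[:-1])):
            raise ValueError("chamber series times must be strictly increasing")

    @property
    def volume_area_ratio_m(self) -> float:
        return self.height_m


# Ordered budget columns as written to budgets.csv.
BUDGET_COMPONENTS = (
    "anpp_t", "l", "bnpp_t_cr", "bnpp_t_fr", "npp_t",
    "anpp_u", "bnpp_u", "npp_u", "bnpp_fr", "npp",
    "rh_s", "rh_dw", "rh", "nep",
)


@dataclass
class CarbonBudget:
    """Per-stand, per-year carbon budget (all fluxes g C m-2 yr-1)."""

    stand_id: str
    year: int
    anpp_t: float
    l: float                    # litterfall, already included in anpp_t
    bnpp_t_cr: float
    bnpp_t_fr: float
    npp_t: float
    anpp_u: float
    bnpp_u: float
    npp_u: float
    bnpp_fr: float
    npp: float
    rh_s: float
    rh_dw: float
    rh: float
    nep: float

    def check_identities(self, rtol: float = 1e-9) -> None:
        """Raise ValueError if any budget identity is violated."""
        checks = {
            "npp_t = anpp_t + bnpp_t_cr + bnpp_t_fr":
                (self.npp_t, self.anpp_t + self.bnpp_t_cr + self.bnpp_t_fr),
            "npp_u = anpp_u + bnpp_u": (self.npp_u, self.anpp_u + self.bnpp_u),
            "bnpp_fr = bnpp_u + bnpp_t_fr":
                (self.bnpp_fr, self.bnpp_u + self.bnpp_t_fr),
            "npp = npp_t + npp_u": (self.npp, self.npp_t + self.npp_u),
            "rh = rh_s + rh_dw": (self.rh, self.rh_s + self.rh_dw),
            "nep = npp - rh": (self.nep, self.npp - self.rh),
        }
        for name, (got, want) in checks.items():
            if not math.isclose(got, want, rel_tol=rtol, abs_tol=1e-9):
                raise ValueError(
                    f"stand {self.stand_id} year {self.year}: identity "
                    f"'{name}' violated ({got!r} vs {want!r})")
        for comp in BUDGET_COMPONENTS:
            if comp == "nep":
                continue
            if getattr(self, comp) < 0:
                raise ValueError(
                    f"stand {self.stand_id} year {self.year}: component "
                    f"{comp} is negative")

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


@dataclass
class RotationSummary:
    """Rotation-forestry carbon calculus on a fitted NEP(age) curve."""

    optimum_age: float          # years
    ccp: float                  # carbon compensation point, years
    cumulative_at_optimum: float  # t C ha-1
    lcsr: float                 # t C ha-1 per rotation
    harvest_rate: float         # % yr-1
    no_interior_optimum: bool = False
    ccp_not_reached: bool = False
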