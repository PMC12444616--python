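"""Energy demand and Monte Carlo carbon-footprint assessment.

The functional unit is 1 L of bioreactor volume.  The inventory covers the
leaching stage (electricity, FeSO4 medium, water, acid/base, micronutrients),
the metal-recovery stage (NaOH for Fe precipitation, Zn for Cu cementation at
a 1.1:1 Zn/Cu molar ratio, oxalic acid for Zn precipitation at a 1.3:1 OA/Zn
molar ratio, recovery energy) and avoided-burden credits for the recovered Cu
and Zn displacing primary production.

Net footprint = leaching + recovery - credit (kg CO2-equiv).  A Monte Carlo
layer propagates (i) the spread of PCB loading and of the Cu/Zn content of
the feedstock and (ii) a 10% relative uncertainty on every characterization
factor.

Characterization factors are a required user input for any absolute claim:
the table shipped by :mod:`cubioleach.synthetic` is an explicitly labelled
synthetic placeholder, so only the structure of the results (shares, signs,
monotonicity), never their absolute values, is meaningful with it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "AW_ZN",
    "MW_OXALIC_ACID",
    "Inventory",
    "CFTable",
    "MCResult",
    "stirred_energy",
    "pump_energy",
    "reagent_demand",
    "build_inventory",
    "carbon_footprint",
    "monte_carlo",
    "TABLE1_RANGES",
    "TABLE2_GRID",
]

AW_ZN = 65.38
MW_OXALIC_ACID = 90.03
AW_CU = 63.546

#: Zn/Cu molar ratio for cementation and OA/Zn molar ratio for precipitation.
ZN_PER_CU_MOL = 1.1
OA_PER_ZN_MOL = 1.3

#: Fixed inventory entries per functional unit (1 L bioreactor).
_FIXED_LEACHING = {
    "electricity_kwh": 0.132,
    "feso4_g": 2.5,
    "water_kg": 0.17,
    "h2so4_kg": 0.015,
    "naoh_leaching_kg": 0.01,
    "micronutrients_g": 0.4,
}
_FIXED_RECOVERY = {
    "naoh_recovery_kg": 0.035,
    "recovery_energy_kwh": 4.7e-4,
}

#: Sampling envelopes of the variable inventory items (per functional unit).
TABLE1_RANGES = {
    "pcb_g_l": (50.0, 200.0),
    "zn_conc_g_l": (4.0, 45.0),
    "oa_conc_g_l": (7.0, 78.0),
    "cu_credit_g": (3.5, 40.0),
    "zn_credit_g": (0.5, 6.5),
}

#: (mean, sd) grid for the share-repartition analysis:
#: PCB loading in % w/v crossed with Cu content in % w/w.
TABLE2_GRID = {
    "pcb_pct_wv": [(5.0, 2.0), (10.0, 2.0), (15.0, 2.0)],
    "cu_pct_ww": [(10.0, 5.0), (20.0, 5.0), (50.0, 5.0)],
}

#: (mean, sd) of the Zn content of the feedstock, % w/w.
ZN_PCT_WW = (2.0, 0.5)


def stirred_energy(volume_l: float, power_density_w_m3: float,
                   duration_days: float) -> float:
    """Electricity for mechanical stirring, kWh: power density x volume x time."""
    if volume_l < 0 or power_density_w_m3 < 0 or duration_days < 0:
        raise ValueError("volume, power density and duration must be >= 0")
    watts = power_density_w_m3 * volume_l / 1000.0
    return watts * duration_days * 24.0 / 1000.0


def pump_energy(power_w: float, duration_days: float) -> float:
    """Electricity for a peristaltic pump, kWh: power x time."""
    if power_w < 0 or duration_days < 0:
        raise ValueError("power and duration must be >= 0")
    return power_w * duration_days * 24.0 / 1000.0


def reagent_demand(cu_leached_mol: float, zn_in_solution_mol: float) -> dict:
    """Recovery-stage reagent masses for given leached Cu and dissolved Zn.

    Cementation consumes Zn at 1.1 mol per mol Cu; that Zn re-enters solution,
    so the oxalic-acid demand covers PCB-derived plus cementation Zn at
    1.3 mol OA per mol Zn.  NaOH for Fe precipitation is a fixed entry.
    """
    if cu_leached_mol < 0 or zn_in_solution_mol < 0:
        raise ValueError("mole amounts must be >= 0")
    zn_cement_mol = ZN_PER_CU_MOL * cu_leached_mol
    zn_total_mol = zn_in_solution_mol + zn_cement_mol
    return {
        "zn_cement_g": zn_cement_mol * AW_ZN,
        "oa_g": OA_PER_ZN_MOL * zn_total_mol * MW_OXALIC_ACID,
        "naoh_kg": _FIXED_RECOVERY["naoh_recovery_kg"],
    }


@dataclass(frozen=True)
class Inventory:
    """Life-cycle inventory per functional unit: item -> quantity, by stage.

    ``credit`` holds recovered masses (g) that earn avoided-burden credits.
    """

    leaching: dict
    recovery: dict
    credit: dict

    def items(self):
        for stage_name, stage in (
            ("leaching", self.leaching),
            ("recovery", self.recovery),
            ("credit", self.credit),
        ):
            for item, qty in stage.items():
                yield stage_name, item, qty


def build_inventory(pcb_g_l: float, cu_mass_fraction: float,
                    zn_mass_fraction: float) -> Inventory:
    """Inventory per 1 L of bioreactor for a given PCB loading and composition.

    Assumes the process end point: leached Cu and Zn fully recovered (the
    reference process reports >95% leaching and recovery efficiencies).
    """
    if pcb_g_l < 0:
        raise ValueError("PCB loading must be >= 0")
    cu_g = pcb_g_l * cu_mass_fraction
    zn_g = pcb_g_l * zn_mass_fraction
    demand = reagent_demand(cu_g / AW_CU, zn_g / AW_ZN)
    recovery = dict(_FIXED_RECOVERY)
    recovery["zn_cement_g"] = demand["zn_cement_g"]
    recovery["oa_g"] = demand["oa_g"]
    return Inventory(
        leaching=dict(_FIXED_LEACHING),
        recovery=recovery,
        credit={"cu_primary_g": cu_g, "zn_primary_g": zn_g},
    )


@dataclass(frozen=True)
class CFTable:
    """Characterization factors (kg CO2-equiv per item unit) with uncertainty.

    Burden and credit factors are all stored positive; credits enter the
    aggregation with a negative sign.  ``placeholder`` marks tables whose
    values are synthetic stand-ins rather than a licensed LCA database.
    """

    factors: dict
    rel_uncertainty: dict = field(default_factory=dict)
    placeholder: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        for item, f in self.factors.items():
            if f <= 0:
                raise ValueError(f"factor for {item!r} must be > 0")
        for item, u in self.rel_uncertainty.items():
            if u < 0:
                raise ValueError(f"uncertainty for {item!r} must be >= 0")

    def uncertainty(self, item: str) -> float:
        return self.rel_uncertainty.get(item, 0.10)

    def factor(self, item: str) -> float:
        try:
            return self.factors[item]
        except KeyError:
            raise KeyError(
                f"no characterization factor for inventory item {item!r}"
            ) from None

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "item": list(self.factors),
                "cf_kg_co2e_per_unit": [self.factors[i] for i in self.factors],
                "rel_uncertainty": [self.uncertainty(i) for i in self.factors],
                "provenance": [
                    "SYNTHETIC-PLACEHOLDER" if self.placeholder else "user"
                ] * len(self.factors),
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CFTable":
        df = pd.read_csv(path)
        required = {"item", "cf_kg_co2e_per_unit"}
        if not required.issubset(df.columns):
            raise ValueError(f"CF table must have columns {sorted(required)}")
        factors = dict(zip(df["item"], df["cf_kg_co2e_per_unit"].astype(float)))
        unc = (
            dict(zip(df["item"], df["rel_uncertainty"].astype(float)))
            if "rel_uncertainty" in df.columns
            else {}
        )
        placeholder = bool(
            "provenance" in df.columns
            and (df["provenance"] == "SYNTHETIC-PLACEHOLDER").any()
        )
        return cls(factors=factors, rel_uncertainty=unc, placeholder=placeholder)


def carbon_footprint(inv: Inventory, cf: CFTable) -> dict:
    """Aggregate the footprint: components and net, in kg CO2-equiv.

    net = leaching + recovery - credit.  Raises a KeyError naming the item if
    an inventory entry has no characterization factor.
    """
    leaching = sum(qty * cf.factor(item) for item, qty in inv.leaching.items())
    recovery = sum(qty * cf.factor(item) for item, qty in inv.recovery.items())
    credit = sum(qty * cf.factor(item) for item, qty in inv.credit.items())
    return {
        "leaching": leaching,
        "recovery": recovery,
        "credit": credit,
        "net": leaching + recovery - credit,
    }


@dataclass
class MCResult:
    """Monte Carlo output: the full draw table and the share repartition.

    ``draws`` has one row per draw with sampled inputs, the three footprint
    components, the net value and the absolute-value shares (%).  ``shares``
    gives mean and SD of each share per (PCB loading x Cu content) grid cell,
    mirroring the repartition-table layout.
    """

    draws: pd.DataFrame
    shares: pd.DataFrame
    n_draws: int
    seed: int

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write(f"Monte Carlo carbon footprint ({self.n_draws} draws, "
                  f"seed {self.seed})\n")
        buf.write(f"net footprint: mean {self.draws['net'].mean():+.3f} "
                  f"kg CO2e / FU, {100 * (self.draws['net'] < 0).mean():.1f}% "
                  "of draws net-negative\n\n")
        buf.write("share repartition (%) by PCB loading and Cu content:\n")
        buf.write(self.shares.to_string(float_format=lambda x: f"{x:6.1f}"))
        return buf.getvalue()


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int, low: float = 0.0) -> np.ndarray:
    """Normal draws resampled until all exceed ``low`` (rejection sampling)."""
    out = rng.normal(mean, sd, size)
    bad = out <= low
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= low
    return out


def monte_carlo(
    cf: CFTable,
    n_draws: int = 8000,
    seed: int = 0,
    design: str = "grid",
    cf_uncertainty: Optional[float] = None,
) -> MCResult:
    """Propagate feedstock and factor uncertainty through the footprint.

    design="grid" splits the draws evenly over the 3x3 (PCB loading x Cu
    content) grid, sampling each cell's mean +/- SD as a truncated normal;
    design="uniform" samples the PCB loading uniformly over its envelope with
    the same compositional grid collapsed to uniform spreads.  Every factor
    is perturbed per draw by an independent multiplicative normal (sigma =
    its relative uncertainty, default 10%), truncated at zero.

    Fixed seed => bit-identical draw table.
    """
    if n_draws <= 0:
        raise ValueError("n_draws must be > 0")
    if design not in ("grid", "uniform"):
        raise ValueError("design must be 'grid' or 'uniform'")
    rng = np.random.default_rng(seed)

    cells = [
        (pcb, cu)
        for pcb in TABLE2_GRID["pcb_pct_wv"]
        for cu in TABLE2_GRID["cu_pct_ww"]
    ]
    per_cell = n_draws // len(cells)
    counts = [per_cell + (1 if i < n_draws % len(cells) else 0)
              for i in range(len(cells))]

    rows = []
    for ((pcb_mean, pcb_sd), (cu_mean, cu_sd)), count in zip(cells, counts):
        if count == 0:
            continue
        if design == "grid":
            pcb_pct = _truncated_normal(rng, pcb_mean, pcb_sd, count)
            cu_pct = _truncated_normal(rng, cu_mean, cu_sd, count)
        else:
            lo, hi = TABLE1_RANGES["pcb_g_l"]
            pcb_pct = rng.uniform(lo / 10.0, hi / 10.0, count)
            cu_pct = rng.uniform(cu_mean - cu_sd, cu_mean + cu_sd, count)
        zn_pct = _truncated_normal(rng, ZN_PCT_WW[0], ZN_PCT_WW[1], count)
        rows.append(
            pd.DataFrame(
                {
                    "cell_pcb_pct": pcb_mean,
                    "cell_cu_pct": cu_mean,
                    "pcb_pct_wv": pcb_pct,
                    "cu_pct_ww": cu_pct,
                    "zn_pct_ww": zn_pct,
                }
            )
        )
    draws = pd.concat(rows, ignore_index=True)

    # per-draw multiplicative factor perturbation, truncated at zero
    n = len(draws)
    items = list(cf.factors)
    perturbed = {}
    for item in items:
        u = cf.uncertainty(item) if cf_uncertainty is None else cf_uncertainty
        if u == 0:
            perturbed[item] = np.full(n, cf.factors[item])
        else:
            mult = _truncated_normal(rng, 1.0, u, n)
            perturbed[item] = cf.factors[item] * mult

    pcb_g_l = draws["pcb_pct_wv"].to_numpy() * 10.0  # % w/v -> g/L
    cu_g = pcb_g_l * draws["cu_pct_ww"].to_numpy() / 100.0
    zn_g = pcb_g_l * draws["zn_pct_ww"].to_numpy() / 100.0
    zn_cement_g = ZN_PER_CU_MOL * cu_g / AW_CU * AW_ZN
    oa_g = OA_PER_ZN_MOL * (zn_g / AW_ZN + zn_cement_g / AW_ZN) * MW_OXALIC_ACID

    leaching = sum(
        qty * perturbed[item] for item, qty in _FIXED_LEACHING.items()
    )
    recovery = (
        sum(qty * perturbed[item] for item, qty in _FIXED_RECOVERY.items())
        + zn_cement_g * perturbed["zn_cement_g"]
        + oa_g * perturbed["oa_g"]
    )
    credit = cu_g * perturbed["cu_primary_g"] + zn_g * perturbed["zn_primary_g"]
    net = leaching + recovery - credit

    total_abs = np.abs(leaching) + np.abs(recovery) + np.abs(credit)
    draws["pcb_g_l"] = pcb_g_l
    draws["cu_leached_g"] = cu_g
    draws["zn_leached_g"] = zn_g
    draws["leaching"] = leaching
    draws["recovery"] = recovery
    draws["credit"] = credit
    draws["net"] = net
    draws["share_leaching"] = 100.0 * np.abs(leaching) / total_abs
    draws["share_recovery"] = 100.0 * np.abs(recovery) / total_abs
    draws["share_credit"] = 100.0 * np.abs(credit) / total_abs

    shares = (
        draws.groupby(["cell_cu_pct", "cell_pcb_pct"])[
            ["share_leaching", "share_recovery", "share_credit"]
        ]
        .agg(["mean", "std"])
        .round(6)
    )
    return MCResult(draws=draws, shares=shares, n_draws=n, seed=seed)
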