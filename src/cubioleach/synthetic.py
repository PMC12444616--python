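"""Synthetic fixtures: noisy outflow series, placeholder CF tables, schedules.

The generators stand in for the wet experiments and the licensed LCA
database, so every pipeline stage is exercisable offline:

* :func:`generate_outflow_series` runs the forward column model and adds
  multiplicative Gaussian noise emulating assay scatter (AAS for Cu,
  colorimetric thiocyanate for iron), with an optional detection floor.
* :func:`generate_cf_table` emits characterization factors that are
  order-of-magnitude literature stand-ins, explicitly labelled
  SYNTHETIC-PLACEHOLDER — structure, not absolute values.
* :func:`generate_scenario_fixture` writes the two reference operating
  schedules in the declarative config format.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bioreactor import ProcessSchedule
from .column import InflowProgram, simulate_column
from .core import ChemKinetics, ColumnGeometry
from .lca import CFTable

__all__ = [
    "NoiseModel",
    "generate_outflow_series",
    "generate_cf_table",
    "generate_scenario_fixture",
    "default_sampling_times",
]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian measurement noise with a detection floor.

    ``relative_sd`` defaults to 5%, a plausible assay scatter (the true
    magnitude is instrument-dependent and undocumented); ``floor`` emulates
    a reporting detection limit: values below the floor are reported at the
    floor.
    """

    relative_sd: float = 0.05
    seed: int = 0
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be >= 0")
        if self.floor < 0:
            raise ValueError("floor must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        noisy = values * (1.0 + self.relative_sd * rng.standard_normal(values.shape))
        return np.maximum(noisy, self.floor)


def default_sampling_times(duration_min: float) -> np.ndarray:
    """Assay cadence: every 5 min for the first 2 h, hourly afterwards."""
    early = np.arange(0.0, min(duration_min, 120.0) + 1e-9, 5.0)
    if duration_min <= 120.0:
        return early
    late = np.arange(180.0, duration_min + 1e-9, 60.0)
    return np.concatenate([early, late])


def generate_outflow_series(
    geom: ColumnGeometry,
    kin: ChemKinetics,
    inflow: InflowProgram,
    q_ml_min: float,
    duration_min: float,
    sampling_times: Optional[Sequence[float]] = None,
    noise: Optional[NoiseModel] = None,
    dt_min: float = 0.1,
    path=None,
) -> pd.DataFrame:
    """Forward-model outflow sampled at assay times with measurement noise.

    Returns the standard outflow table (time_min + mol/L columns, plus g/L
    convenience columns) and optionally writes it as CSV.
    """
    if noise is None:
        noise = NoiseModel()
    if sampling_times is None:
        sampling_times = default_sampling_times(duration_min)
    sampling_times = np.asarray(sampling_times, dtype=float)
    if sampling_times.max() > duration_min + 1e-9:
        raise ValueError("sampling time beyond the simulated duration")

    run = simulate_column(geom, kin, inflow, q_ml_min, duration_min, dt_min=dt_min)
    t = run.times_min
    clean = np.vstack(
        [
            np.interp(sampling_times, t, run.cu2_out),
            np.interp(sampling_times, t, run.fe3_out),
            np.interp(sampling_times, t, run.fe2_out),
        ]
    )
    rng = np.random.default_rng(noise.seed)
    noisy = noise.apply(clean, rng)
    from .core import AW_CU, AW_FE

    df = pd.DataFrame(
        {
            "time_min": sampling_times,
            "cu_out_mol_L": noisy[0],
            "fe3_out_mol_L": noisy[1],
            "fe2_out_mol_L": noisy[2],
            "cu_out_g_L": noisy[0] * AW_CU,
            "fe3_out_g_L": noisy[1] * AW_FE,
            "fe2_out_g_L": noisy[2] * AW_FE,
        }
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df


#: Order-of-magnitude global-warming characterization factors
#: (kg CO2-equiv per item unit).  SYNTHETIC PLACEHOLDERS: chosen from public
#: round-number literature ballparks only so that the pipeline runs end to
#: end; they are NOT the licensed database values used for any published
#: absolute footprint, and absolute results computed from them carry no
#: meaning beyond structure and sign.
_PLACEHOLDER_FACTORS = {
    "electricity_kwh": 0.45,
    "feso4_g": 4.0e-4,
    "water_kg": 3.0e-4,
    "h2so4_kg": 0.13,
    "naoh_leaching_kg": 1.3,
    "micronutrients_g": 2.0e-3,
    "naoh_recovery_kg": 1.3,
    "recovery_energy_kwh": 0.45,
    "zn_cement_g": 3.5e-3,
    "oa_g": 1.2e-3,
    "cu_primary_g": 4.2e-3,
    "zn_primary_g": 3.5e-3,
}


def generate_cf_table(seed: int = 0, path=None) -> CFTable:
    """The placeholder characterization-factor table (10% relative uncertainty).

    Deterministic: the same seed (indeed any seed) yields the same table; the
    seed argument is accepted for generator-interface uniformity.
    """
    table = CFTable(
        factors=dict(_PLACEHOLDER_FACTORS),
        rel_uncertainty={item: 0.10 for item in _PLACEHOLDER_FACTORS},
        placeholder=True,
        note="SYNTHETIC-PLACEHOLDER order-of-magnitude factors; supply a "
        "licensed table for absolute results",
    )
    if path is not None:
        table.to_csv(path)
    return table


def generate_scenario_fixture(name: str, path=None) -> ProcessSchedule:
    """The named reference operating schedule ('sim1' or 'sim2')."""
    builders = {
        "sim1": ProcessSchedule.simulation_1,
        "sim2": ProcessSchedule.simulation_2,
    }
    try:
        schedule = builders[name]()
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; options: {sorted(builders)}"
        ) from None
    if path is not None:
        from .config import write_schedule

        write_schedule(schedule, path)
    return schedule
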