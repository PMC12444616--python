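"""Coupled column-bioreactor bioleaching model with the scenario engine.

A 3.6 L stirred tank holds the iron-oxidizing culture; its solution is pumped
through the packed PCB column and returns to the tank.  In the column, Fe3+
attacks solid Cu (producing Cu2+ and Fe2+); in the tank, bacteria re-oxidize
Fe2+ to Fe3+ while Fe3+ and Cu2+ inhibit growth quadratically:

    dN/dt   = mu N - mu_d (Fe3+)^2 N - mu_tox (Cu2+)^2 N
    mu      = mu_max Fe2+ / (K_S + Fe2+)
    Fe2+ oxidation rate = (mu / Y_NS) N      [g/(L min)]

The tank is advanced with the discrete stirred-tank balance implied by the
residual volume V_rim = V_biorea - Q dt: over one step each solute is diluted
by V_rim/V and receives Q dt C_out from the column, then the reaction
increments are applied.  Column and tank use each other's *pre-step* states
(a simultaneous update), which makes the loop mass balance exact for the
discrete scheme.

Process schedules are ordered event lists; an event fires once, at a clock
time or when a state trigger is met, and the next event then becomes active.
Actions: start_recirculation, set_flow, replace_medium, stop.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    AW_CU,
    AW_FE,
    BioKinetics,
    BioreactorState,
    ChemKinetics,
    ColumnGeometry,
    LoopConfig,
    pore_volume,
)

__all__ = [
    "ScheduleEvent",
    "ProcessSchedule",
    "CoupledRunResult",
    "monod_mu",
    "bacteria_rhs",
    "bioreactor_step",
    "metabolic_rate",
    "replace_medium",
    "run_coupled",
    "default_initial_bioreactor",
]

logger = logging.getLogger(__name__)

_ACTIONS = ("start_recirculation", "set_flow", "replace_medium", "stop")
_TRIGGERS = ("metabolic_rate_ge", "cu_biorea_ge", "fe2_eq_fe3", "fe2_fraction_le")

#: Default fresh-medium ferrous iron strength (g/L), the growth-medium loading.
DEFAULT_MEDIUM_FE2_G_L = 9.4


def monod_mu(fe2_g: float, bio: BioKinetics) -> float:
    """Monod specific growth rate (1/min) on Fe2+; bounded by mu_max."""
    if fe2_g < 0:
        raise ValueError(f"substrate concentration must be >= 0, got {fe2_g}")
    return bio.mu_max_per_min * fe2_g / (bio.k_s_g_l + fe2_g)


def bacteria_rhs(state: BioreactorState, bio: BioKinetics) -> float:
    """dN/dt (cells/(L min)): Monod growth minus quadratic Fe3+/Cu2+ toxicity."""
    mu = monod_mu(state.fe2_g, bio)
    return (
        mu
        - bio.mu_d_l2_g2_min * state.fe3_g**2
        - bio.mu_tox_l2_g2_min * state.cu2_g**2
    ) * state.n_bacteria


def metabolic_rate(state: BioreactorState, bio: BioKinetics) -> float:
    """Fe2+ oxidation rate by the culture, (mu / Y_NS) N, in g/(L min)."""
    return monod_mu(state.fe2_g, bio) / bio.yield_cells_per_g * state.n_bacteria


def replace_medium(
    state: BioreactorState,
    fraction: float,
    fresh_fe2_g_l: float = DEFAULT_MEDIUM_FE2_G_L,
) -> BioreactorState:
    """Remove ``fraction`` of the leaching solution and top up with fresh medium.

    Every solute and the suspended cells are retained with factor
    (1 - fraction); the fresh medium carries Fe2+ only.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"replacement fraction must be in (0, 1), got {fraction}")
    keep = 1.0 - fraction
    return BioreactorState(
        n_bacteria=state.n_bacteria * keep,
        fe2_g=state.fe2_g * keep + fresh_fe2_g_l * fraction,
        fe3_g=state.fe3_g * keep,
        cu2_g=state.cu2_g * keep,
    )


def bioreactor_step(
    state: BioreactorState,
    column_out_mol: tuple[float, float, float],
    cfg: LoopConfig,
    bio: BioKinetics,
) -> BioreactorState:
    """One discrete tank update over dt: dilution to V_rim + inflow, then reaction.

    ``column_out_mol`` is the column outflow (cu2, fe3, fe2) in mol/L, converted
    to g/L on entry.  Fe2+ oxidation is capped at the available Fe2+ so the
    explicit step cannot drive it negative.
    """
    v = cfg.v_bioreactor_l
    v_rim = cfg.v_rim_l
    if v_rim <= 0:
        raise ValueError("V_rim must be positive (Q*dt < V_biorea)")
    qdt = cfg.q_ml_min / 1000.0 * cfg.dt_min
    cu_out, fe3_out, fe2_out = column_out_mol

    cu = (state.cu2_g * v_rim + qdt * cu_out * bio.aw_cu) / v
    fe3 = (state.fe3_g * v_rim + qdt * fe3_out * bio.aw_fe) / v
    fe2 = (state.fe2_g * v_rim + qdt * fe2_out * bio.aw_fe) / v

    diluted = BioreactorState(
        n_bacteria=state.n_bacteria, fe2_g=fe2, fe3_g=fe3, cu2_g=cu
    )
    ox = min(metabolic_rate(diluted, bio) * cfg.dt_min, fe2)
    dn = bacteria_rhs(diluted, bio) * cfg.dt_min
    return BioreactorState(
        n_bacteria=max(state.n_bacteria + dn, 0.0),
        fe2_g=fe2 - ox,
        fe3_g=fe3 + ox,
        cu2_g=cu,
    )


@dataclass(frozen=True)
class ScheduleEvent:
    """One schedule step: a timing (at_h / after_h / when) and an action.

    ``at_h`` is absolute hours from run start; ``after_h`` is hours after the
    anchor event fired — by default the previous event, or the most recent
    fired event whose action equals ``after_event``; ``when`` is a state
    trigger, one of
    ``{"metabolic_rate_ge": x}``, ``{"cu_biorea_ge": x}``,
    ``{"fe2_eq_fe3": true}`` (concentration crossing) or
    ``{"fe2_fraction_le": x}``.  Exactly one timing must be given.
    Events fire once, in list order.
    """

    action: str
    at_h: Optional[float] = None
    after_h: Optional[float] = None
    when: Optional[dict] = None
    after_event: Optional[str] = None
    q_ml_min: Optional[float] = None
    fraction: Optional[float] = None
    fresh_fe2_g_l: float = DEFAULT_MEDIUM_FE2_G_L

    def __post_init__(self) -> None:
        if self.action not in _ACTIONS:
            raise ValueError(f"unknown action {self.action!r}; options: {_ACTIONS}")
        timings = sum(x is not None for x in (self.at_h, self.after_h, self.when))
        if timings != 1:
            raise ValueError("exactly one of at_h / after_h / when must be set")
        if self.when is not None:
            unknown = set(self.when) - set(_TRIGGERS)
            if unknown:
                raise ValueError(f"unknown trigger(s) {unknown}; options: {_TRIGGERS}")
            if len(self.when) != 1:
                raise ValueError("a trigger event takes exactly one trigger")
        if self.action in ("start_recirculation", "set_flow") and self.q_ml_min is None:
            raise ValueError(f"{self.action} requires q_ml_min")
        if self.action == "replace_medium":
            if self.fraction is None or not (0.0 < self.fraction < 1.0):
                raise ValueError("replace_medium requires fraction in (0, 1)")


@dataclass(frozen=True)
class ProcessSchedule:
    """Ordered operating plan for a coupled run."""

    events: tuple[ScheduleEvent, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("schedule needs at least one event")

    @classmethod
    def simulation_1(cls) -> "ProcessSchedule":
        """Clock-driven baseline: 48 h growth; recirculation at 5 mL/min;
        80% medium replacement after 48 h of leaching; stop after a further
        96 h (8 days total)."""
        return cls(
            name="sim1",
            events=(
                ScheduleEvent("start_recirculation", at_h=48.0, q_ml_min=5.0),
                ScheduleEvent("replace_medium", at_h=96.0, fraction=0.8),
                ScheduleEvent("stop", at_h=192.0),
            ),
        )

    @classmethod
    def simulation_2(cls) -> "ProcessSchedule":
        """Trigger-driven plan: recirculation starts at the metabolic-rate peak
        (threshold 0.005 g/(L min)) at half flow (2.5 mL/min); flow halved again
        15 h later (clock form of the Cu ~ 1 g/L cue); 65% replacement 33 h
        after that; flow doubled at the Fe2+ = Fe3+ crossing; stop 96 h after
        the replacement."""
        return cls(
            name="sim2",
            events=(
                ScheduleEvent(
                    "start_recirculation",
                    when={"metabolic_rate_ge": 0.005},
                    q_ml_min=2.5,
                ),
                ScheduleEvent("set_flow", after_h=15.0, q_ml_min=1.25),
                ScheduleEvent("replace_medium", after_h=33.0, fraction=0.65),
                ScheduleEvent("set_flow", when={"fe2_eq_fe3": True}, q_ml_min=2.5),
                ScheduleEvent("stop", after_h=96.0, after_event="replace_medium"),
            ),
        )


@dataclass
class CoupledRunResult:
    """Full trajectories of a coupled run plus events and per-phase metrics."""

    times_min: np.ndarray
    n_bacteria: np.ndarray
    fe2_g: np.ndarray
    fe3_g: np.ndarray
    cu_g: np.ndarray
    col_cu2: np.ndarray
    col_fe3: np.ndarray
    col_fe2: np.ndarray
    col_solid: np.ndarray
    q_series: np.ndarray
    removed_fe_mol: np.ndarray
    removed_cu_mol: np.ndarray
    added_fe_mol: np.ndarray
    events: list
    geometry: ColumnGeometry
    config: LoopConfig
    schedule_name: str = "custom"

    @property
    def v_free_l(self) -> float:
        return pore_volume(self.geometry)

    @property
    def efficiency(self) -> np.ndarray:
        """Cu leaching efficiency from solid depletion (fraction, non-decreasing)."""
        extracted = (self.col_solid[0] - self.col_solid) * self.v_free_l
        return extracted / (self.geometry.initial_cu_g / AW_CU)

    @property
    def total_fe_mol(self) -> np.ndarray:
        """Fe inventory: column solution + tank + removed - added (mol)."""
        col = (self.col_fe2 + self.col_fe3) * self.v_free_l
        tank = (self.fe2_g + self.fe3_g) * self.config.v_bioreactor_l / AW_FE
        return col + tank + self.removed_fe_mol - self.added_fe_mol

    @property
    def total_cu_mol(self) -> np.ndarray:
        """Cu inventory: solid + column solution + tank + removed (mol)."""
        col = (self.col_cu2 + self.col_solid) * self.v_free_l
        tank = self.cu_g * self.config.v_bioreactor_l / AW_CU
        return col + tank + self.removed_cu_mol

    def time_to_efficiency(self, target: float) -> float:
        """First time (hours) the leaching efficiency reaches ``target``; NaN if never."""
        eff = self.efficiency
        idx = np.argmax(eff >= target)
        if eff[idx] < target:
            return float("nan")
        return float(self.times_min[idx] / 60.0)

    @property
    def phase_metrics(self) -> list[dict]:
        """Per-phase Cu extraction rate, end efficiency and duration.

        Phases are delimited by fired events (plus run start and end).
        """
        bounds = sorted({0.0, float(self.times_min[-1])}
                        | {e["time_min"] for e in self.events})
        t = self.times_min
        extracted_g = (self.col_solid[0] - self.col_solid) * self.v_free_l * AW_CU
        out = []
        for t0, t1 in zip(bounds[:-1], bounds[1:]):
            if t1 <= t0:
                continue
            e0 = float(np.interp(t0, t, extracted_g))
            e1 = float(np.interp(t1, t, extracted_g))
            hours = (t1 - t0) / 60.0
            out.append(
                {
                    "t_start_h": t0 / 60.0,
                    "t_end_h": t1 / 60.0,
                    "duration_h": hours,
                    "cu_extracted_g": e1 - e0,
                    "cu_rate_g_h": (e1 - e0) / hours,
                    "efficiency_end": float(np.interp(t1, t, self.efficiency)),
                }
            )
        return out

    def to_frame(self, every: int = 1) -> pd.DataFrame:
        s = slice(None, None, every)
        return pd.DataFrame(
            {
                "time_min": self.times_min[s],
                "n_cells_per_L": self.n_bacteria[s],
                "fe2_g_L": self.fe2_g[s],
                "fe3_g_L": self.fe3_g[s],
                "cu_g_L": self.cu_g[s],
                "q_ml_min": self.q_series[s],
                "efficiency": self.efficiency[s],
            }
        )

    def plot(self, ax=None):
        """Quick-look tank trajectory (g/L and efficiency vs hours)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t_h = self.times_min / 60.0
        ax.plot(t_h, self.fe2_g, label="Fe2+ (g/L)")
        ax.plot(t_h, self.fe3_g, label="Fe3+ (g/L)")
        ax.plot(t_h, self.cu_g, label="Cu2+ (g/L)")
        ax2 = ax.twinx()
        ax2.plot(t_h, self.efficiency, "k--", label="efficiency")
        ax2.set_ylabel("Cu leaching efficiency")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("tank concentration (g/L)")
        ax.legend(loc="upper left")
        return ax


def default_initial_bioreactor(
    n_bacteria: float = 1.8e9, fe2_g: float = DEFAULT_MEDIUM_FE2_G_L
) -> BioreactorState:
    """Growth-phase start: fresh ferrous medium plus the inoculum.

    The inoculum density is a calibrated default (the experimental value is
    unpublished); it sets the absolute scale of the metabolic-rate curve.
    """
    return BioreactorState(n_bacteria=n_bacteria, fe2_g=fe2_g)


def _check_trigger(
    trigger: dict,
    state: BioreactorState,
    bio: BioKinetics,
    context: dict,
) -> bool:
    (name, value), = trigger.items()
    if name == "metabolic_rate_ge":
        rate = metabolic_rate(state, bio)
        prev = context.get("prev_rate")
        context["prev_rate"] = rate
        # fire at the threshold crossing or at the discrete peak, whichever
        # comes first
        if rate >= value:
            return True
        return prev is not None and prev > 0 and rate < prev
    if name == "cu_biorea_ge":
        return state.cu2_g >= value
    if name == "fe2_eq_fe3":
        diff = state.fe2_g - state.fe3_g
        sign0 = context.get("sign0")
        if sign0 is None:
            context["sign0"] = math.copysign(1.0, diff) if diff != 0 else 0.0
            return diff == 0.0
        return diff == 0.0 or math.copysign(1.0, diff) != sign0
    if name == "fe2_fraction_le":
        total = state.fe2_g + state.fe3_g
        return total > 0 and state.fe2_g / total <= value
    raise ValueError(f"unknown trigger {name!r}")


def run_coupled(
    schedule: ProcessSchedule,
    geom: ColumnGeometry,
    kin: ChemKinetics,
    bio: BioKinetics,
    cfg: LoopConfig,
    initial: Optional[BioreactorState] = None,
    max_duration_h: float = 400.0,
) -> CoupledRunResult:
    """Run the coupled column-bioreactor loop under a process schedule.

    Before the ``start_recirculation`` event the column is decoupled and the
    tank evolves as a pure growth culture.  Once recirculating, every dt the
    column receives the tank's composition (g/L -> mol/L) and the tank
    receives the column outflow, both evaluated on pre-step states so the
    loop conserves mass exactly.  Triggers are evaluated every step in
    schedule order with single-fire semantics.  If the schedule is not
    exhausted by ``max_duration_h`` the run stops there with a warning.
    """
    if initial is None:
        initial = default_initial_bioreactor()
    dt = cfg.dt_min
    v_b = cfg.v_bioreactor_l
    v_col = pore_volume(geom)
    k = kin.k_l_per_mol_min
    m = kin.m
    mu_max, k_s = bio.mu_max_per_min, bio.k_s_g_l
    y_ns = bio.yield_cells_per_g
    mu_d, mu_tox = bio.mu_d_l2_g2_min, bio.mu_tox_l2_g2_min
    aw_fe, aw_cu = bio.aw_fe, bio.aw_cu

    n_steps = int(round(max_duration_h * 60.0 / dt))
    times = np.empty(n_steps + 1)
    rec = {
        name: np.empty(n_steps + 1)
        for name in (
            "n", "fe2", "fe3", "cu", "ccu2", "cfe3", "cfe2", "csolid",
            "q", "rfe", "rcu", "afe",
        )
    }

    # state
    n_b, fe2_b, fe3_b, cu_b = (
        initial.n_bacteria, initial.fe2_g, initial.fe3_g, initial.cu2_g,
    )
    c_cu, c_fe3, c_fe2 = 0.0, 0.0, 0.0
    c_solid = geom.initial_cu_solid_mol_l
    q = 0.0
    recirculating = False
    removed_fe = removed_cu = added_fe = 0.0

    events_log: list[dict] = []
    pending = list(schedule.events)
    next_idx = 0
    last_fire_min = 0.0
    trig_context: dict = {}
    stop = False

    def record(i: int, t: float) -> None:
        times[i] = t
        rec["n"][i] = n_b
        rec["fe2"][i] = fe2_b
        rec["fe3"][i] = fe3_b
        rec["cu"][i] = cu_b
        rec["ccu2"][i] = c_cu
        rec["cfe3"][i] = c_fe3
        rec["cfe2"][i] = c_fe2
        rec["csolid"][i] = c_solid
        rec["q"][i] = q
        rec["rfe"][i] = removed_fe
        rec["rcu"][i] = removed_cu
        rec["afe"][i] = added_fe

    record(0, 0.0)
    i = 0
    t = 0.0
    while i < n_steps and not stop:
        # --- event engine: fire due events (in order) on the current state ---
        while next_idx < len(pending):
            ev = pending[next_idx]
            state = BioreactorState(
                n_bacteria=n_b, fe2_g=fe2_b, fe3_g=fe3_b, cu2_g=cu_b
            )
            due = False
            if ev.at_h is not None:
                due = t >= ev.at_h * 60.0 - 1e-9
            elif ev.after_h is not None:
                anchor = last_fire_min
                if ev.after_event is not None:
                    fired = [e for e in events_log if e["action"] == ev.after_event]
                    if not fired:
                        raise ValueError(
                            f"after_event {ev.after_event!r} has not fired "
                            "before this event became active"
                        )
                    anchor = fired[-1]["time_min"]
                due = t >= anchor + ev.after_h * 60.0 - 1e-9
            else:
                due = _check_trigger(ev.when, state, bio, trig_context)
            if not due:
                break
            # apply
            if ev.action == "start_recirculation":
                recirculating = True
                q = ev.q_ml_min
            elif ev.action == "set_flow":
                q = ev.q_ml_min
            elif ev.action == "replace_medium":
                removed_fe += ev.fraction * (fe2_b + fe3_b) * v_b / aw_fe
                removed_cu += ev.fraction * cu_b * v_b / aw_cu
                added_fe += ev.fraction * ev.fresh_fe2_g_l * v_b / aw_fe
                new = replace_medium(state, ev.fraction, ev.fresh_fe2_g_l)
                n_b, fe2_b, fe3_b, cu_b = (
                    new.n_bacteria, new.fe2_g, new.fe3_g, new.cu2_g,
                )
            elif ev.action == "stop":
                stop = True
            events_log.append(
                {"time_min": t, "action": ev.action, "event": ev}
            )
            last_fire_min = t
            trig_context = {}
            next_idx += 1
            if stop:
                break
        if stop:
            break

        # --- dynamics over one dt, simultaneous (pre-step) exchange ---
        q_l = q / 1000.0
        qdt = q_l * dt
        if recirculating and q > 0.0:
            # column step, fed by the tank's pre-step composition
            a = q_l / v_col
            cu_in = cu_b / aw_cu
            fe3_in = fe3_b / aw_fe
            fe2_in = fe2_b / aw_fe
            r = k * max(c_solid - c_cu, 0.0) * c_fe3
            new_c_cu = c_cu + dt * (a * (cu_in - c_cu) + r)
            new_c_fe3 = c_fe3 + dt * (a * (fe3_in - c_fe3) - m * r)
            new_c_fe2 = c_fe2 + dt * (a * (fe2_in - c_fe2) + m * r)
            new_c_solid = max(c_solid - dt * r, 0.0)
            if new_c_fe3 < 0.0:
                new_c_fe3 = 0.0
            # tank step, fed by the column's pre-step outflow
            v_rim = v_b - qdt
            cu_b_new = (cu_b * v_rim + qdt * c_cu * aw_cu) / v_b
            fe3_b_new = (fe3_b * v_rim + qdt * c_fe3 * aw_fe) / v_b
            fe2_b_new = (fe2_b * v_rim + qdt * c_fe2 * aw_fe) / v_b
            c_cu, c_fe3, c_fe2, c_solid = (
                new_c_cu, new_c_fe3, new_c_fe2, new_c_solid,
            )
        else:
            cu_b_new, fe3_b_new, fe2_b_new = cu_b, fe3_b, fe2_b

        # tank reaction (post-dilution state)
        mu = mu_max * fe2_b_new / (k_s + fe2_b_new) if fe2_b_new > 0 else 0.0
        ox = min(mu / y_ns * n_b * dt, fe2_b_new)
        dn = (mu - mu_d * fe3_b_new**2 - mu_tox * cu_b_new**2) * n_b * dt
        n_b = max(n_b + dn, 0.0)
        fe2_b = fe2_b_new - ox
        fe3_b = fe3_b_new + ox
        cu_b = cu_b_new

        i += 1
        t = i * dt
        record(i, t)

    if not stop:
        logger.warning(
            "schedule not exhausted at max duration %.1f h; %d event(s) pending",
            max_duration_h,
            len(pending) - next_idx,
        )

    last = i + 1
    return CoupledRunResult(
        times_min=times[:last],
        n_bacteria=rec["n"][:last],
        fe2_g=rec["fe2"][:last],
        fe3_g=rec["fe3"][:last],
        cu_g=rec["cu"][:last],
        col_cu2=rec["ccu2"][:last],
        col_fe3=rec["cfe3"][:last],
        col_fe2=rec["cfe2"][:last],
        col_solid=rec["csolid"][:last],
        q_series=rec["q"][:last],
        removed_fe_mol=rec["rfe"][:last],
        removed_cu_mol=rec["rcu"][:last],
        added_fe_mol=rec["afe"][:last],
        events=events_log,
        geometry=geom,
        config=cfg,
        schedule_name=schedule.name,
    )
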