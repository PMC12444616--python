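"""Config file parsing and report writing.

Configs are flat YAML key-value files with explicit unit suffixes in the keys
(``height_cm``, ``q_ml_min``, ...).  Unknown keys are rejected with the list
of valid options; missing required keys are named.  Schedules are YAML event
lists with ``at_h:`` / ``after_h:`` / ``when:`` timing keys.

Every report written by the package embeds the config hash and the seed for
auditability.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .bioreactor import ProcessSchedule, ScheduleEvent
from .core import BioKinetics, ChemKinetics, ColumnGeometry, LoopConfig

__all__ = [
    "PipelineConfig",
    "parse_geometry",
    "parse_chem_kinetics",
    "parse_bio_kinetics",
    "parse_loop_config",
    "parse_config",
    "write_config",
    "read_schedule",
    "write_schedule",
    "config_hash",
]

_GEOMETRY_KEYS = {
    "height_cm": "height_cm",
    "inner_diameter_cm": "inner_diameter_cm",
    "porosity": "porosity",
    "pcb_mass_g": "pcb_mass_g",
    "cu_mass_fraction": "cu_mass_fraction",
}
_CHEM_KEYS = {"k_l_per_mol_min": "k_l_per_mol_min", "m_fe3_per_cu": "m"}
_BIO_KEYS = {
    "mu_max_per_min": "mu_max_per_min",
    "k_s_g_per_l": "k_s_g_l",
    "yield_cells_per_g": "yield_cells_per_g",
    "mu_d_l2_per_g2_min": "mu_d_l2_g2_min",
    "mu_tox_l2_per_g2_min": "mu_tox_l2_g2_min",
}
_LOOP_KEYS = {
    "q_ml_min": "q_ml_min",
    "v_bioreactor_l": "v_bioreactor_l",
    "dt_min": "dt_min",
    "inflow_mode": "inflow_mode",
}


def _load_yaml(path) -> dict:
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return data


def _build(section: dict, keymap: dict, cls, where: str):
    unknown = set(section) - set(keymap)
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in {where}; valid keys "
            f"(note the unit suffixes): {sorted(keymap)}"
        )
    return cls(**{keymap[k]: v for k, v in section.items()})


def parse_geometry(data: dict) -> ColumnGeometry:
    return _build(data, _GEOMETRY_KEYS, ColumnGeometry, "geometry")


def parse_chem_kinetics(data: dict) -> ChemKinetics:
    return _build(data, _CHEM_KEYS, ChemKinetics, "chem_kinetics")


def parse_bio_kinetics(data: dict) -> BioKinetics:
    return _build(data, _BIO_KEYS, BioKinetics, "bio_kinetics")


def parse_loop_config(data: dict) -> LoopConfig:
    return _build(data, _LOOP_KEYS, LoopConfig, "loop")


@dataclass
class PipelineConfig:
    """Inputs for the end-to-end pipeline run."""

    geometry: ColumnGeometry = field(default_factory=ColumnGeometry)
    chem: ChemKinetics = field(default_factory=ChemKinetics)
    bio: BioKinetics = field(default_factory=BioKinetics)
    loop: LoopConfig = field(default_factory=LoopConfig)
    seed: int = 0
    out_dir: str = "pipeline_out"
    mc_draws: int = 8000
    cf_table_path: Optional[str] = None


_SECTIONS = {
    "geometry": (_GEOMETRY_KEYS, parse_geometry),
    "chem_kinetics": (_CHEM_KEYS, parse_chem_kinetics),
    "bio_kinetics": (_BIO_KEYS, parse_bio_kinetics),
    "loop": (_LOOP_KEYS, parse_loop_config),
}
_SCALARS = {"seed", "out_dir", "mc_draws", "cf_table_path"}


def parse_config(path) -> PipelineConfig:
    """Read and validate a pipeline config file."""
    data = _load_yaml(path)
    unknown = set(data) - set(_SECTIONS) - _SCALARS
    if unknown:
        raise ValueError(
            f"unknown top-level key(s) {sorted(unknown)}; valid: "
            f"{sorted(set(_SECTIONS) | _SCALARS)}"
        )
    kwargs = {}
    for name, (_, parser) in _SECTIONS.items():
        if name in data:
            key = {"chem_kinetics": "chem", "bio_kinetics": "bio"}.get(name, name)
            kwargs[key] = parser(data[name] or {})
    for name in _SCALARS & set(data):
        kwargs[name] = data[name]
    return PipelineConfig(**kwargs)


def _as_sections(cfg: PipelineConfig) -> dict:
    def invert(obj, keymap):
        d = asdict(obj)
        return {k: d[v] for k, v in keymap.items() if v in d}

    return {
        "geometry": invert(cfg.geometry, _GEOMETRY_KEYS),
        "chem_kinetics": invert(cfg.chem, _CHEM_KEYS),
        "bio_kinetics": invert(cfg.bio, _BIO_KEYS),
        "loop": invert(cfg.loop, _LOOP_KEYS),
        "seed": cfg.seed,
        "out_dir": cfg.out_dir,
        "mc_draws": cfg.mc_draws,
        "cf_table_path": cfg.cf_table_path,
    }


def write_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_as_sections(cfg), fh, sort_keys=True)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of the scientific config, for output headers.

    The output directory is excluded: it changes where results land, not
    what they are.
    """
    sections = _as_sections(cfg)
    sections.pop("out_dir")
    canonical = yaml.safe_dump(sections, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


_EVENT_KEYS = {
    "action", "at_h", "after_h", "when", "after_event", "q_ml_min", "fraction",
    "fresh_fe2_g_l",
}


def read_schedule(path) -> ProcessSchedule:
    data = _load_yaml(path)
    unknown = set(data) - {"name", "events"}
    if unknown:
        raise ValueError(f"unknown schedule key(s) {sorted(unknown)}")
    if "events" not in data:
        raise ValueError("schedule file must have an 'events' list")
    events = []
    for i, entry in enumerate(data["events"]):
        bad = set(entry) - _EVENT_KEYS
        if bad:
            raise ValueError(
                f"unknown key(s) {sorted(bad)} in event {i}; valid: "
                f"{sorted(_EVENT_KEYS)}"
            )
        events.append(ScheduleEvent(**entry))
    return ProcessSchedule(events=tuple(events), name=data.get("name", "custom"))


def write_schedule(schedule: ProcessSchedule, path) -> None:
    events = []
    for ev in schedule.events:
        d = {k: v for k, v in asdict(ev).items() if v is not None}
        if ev.action != "replace_medium":
            d.pop("fresh_fe2_g_l", None)
        events.append(d)
    with open(path, "w") as fh:
        yaml.safe_dump({"name": schedule.name, "events": events}, fh, sort_keys=False)
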