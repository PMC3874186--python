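"""Structured scenario configuration (YAML) and provenance records.

A configuration file has nested sections ``locus``, ``damage``, ``kinetics``,
``dynamics``, ``chromatin``, ``assays`` and ``scenario``; every key is
optional and falls back to the package defaults, so an empty file (or no
file) describes the standard wild-type UV scenario.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import dataclass

import yaml

from . import __version__
from .chromatin import ChromatinParams
from .damage import DamageRateProfile, RepairKinetics
from .dynamics import SimulationParams
from .locus import ConfigurationError, Interval, RDNAUnit, build_locus

DEFAULT_TIMEPOINTS_H = [-0.25, 0.0, 0.5, 1.0, 2.0, 4.0]


@dataclass
class Scenario:
    """Everything needed to run one strain's UV time course."""

    locus: RDNAUnit
    profile: DamageRateProfile
    params: SimulationParams
    kinetics: RepairKinetics
    chrom_params: ChromatinParams
    timepoints_h: list
    open_fraction: float
    strain: str
    chip_background: float
    raw: dict


def load_config(path=None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError("top level of the config must be a mapping")
    return cfg


def _pick(d: dict, keys) -> dict:
    return {k: d[k] for k in keys if k in d}


def build_scenario(cfg: dict | None = None, strain: str | None = None) -> Scenario:
    """Assemble all model objects from a configuration dict.

    ``strain`` ('WT' or 'rad14d') overrides the scenario section; rad14d
    only switches NER off, every other parameter is shared.
    """
    cfg = dict(cfg or {})
    locus = build_locus(cfg.get("locus"))

    dmg = dict(cfg.get("damage", {}))
    if "uniform_rate_per_kb" in dmg:
        profile = DamageRateProfile.uniform(
            dmg["uniform_rate_per_kb"], locus.gene_length
        )
    elif "segments" in dmg:
        segs = tuple(
            (Interval(float(s["start"]), float(s["end"])), float(s["rate_per_kb"]))
            for s in dmg["segments"]
        )
        profile = DamageRateProfile(segments=segs)
    else:
        profile = DamageRateProfile.default_piecewise(locus)

    dyn_keys = ("elongation_rate", "steady_spacing", "footprint",
                "initiation_rate", "release_mode", "k_release",
                "k_collision", "post_uv_initiation_factor", "dt")
    params = SimulationParams(**_pick(cfg.get("dynamics", {}), dyn_keys))

    kin_cfg = dict(cfg.get("kinetics", {}))
    scen = dict(cfg.get("scenario", {}))
    strain = strain or scen.get("strain", "WT")
    if strain not in ("WT", "rad14d"):
        raise ConfigurationError(f"unknown strain {strain!r}; use WT or rad14d")
    if strain == "rad14d":
        kin_cfg["ner_active"] = False
    kin_keys = ("k_tcr", "k_ggr", "ner_active", "tcr_rule",
                "pp64_repair_multiplier")
    kinetics = RepairKinetics(**_pick(kin_cfg, kin_keys))

    chrom_keys = ("deposition_delay", "deposition_bin", "open_threshold",
                  "closed_threshold")
    chrom = ChromatinParams(**_pick(cfg.get("chromatin", {}), chrom_keys))

    return Scenario(
        locus=locus,
        profile=profile,
        params=params,
        kinetics=kinetics,
        chrom_params=chrom,
        timepoints_h=list(scen.get("timepoints_h", DEFAULT_TIMEPOINTS_H)),
        open_fraction=float(scen.get("open_fraction", 0.5)),
        strain=strain,
        chip_background=float(cfg.get("assays", {}).get("chip_background", 0.05)),
        raw=cfg,
    )


def write_provenance(out_dir, cfg: dict, seed) -> pathlib.Path:
    """Record config hash, seed and package version next to the outputs."""
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    record = {
        "package": "ribotraffic",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
    }
    import datetime

    record["written_at"] = datetime.datetime.now().isoformat(timespec="seconds")
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2) + "\n")
    return path
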