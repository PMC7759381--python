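"""Config-driven end-to-end runs: generate -> preprocess -> analyze ->
report, with stage-dependency checking and reproducible summaries.

A run config is a plain mapping (YAML on disk)::

    seed: 1                # mandatory for stochastic runs
    scenario: burst        # one of SCENARIOS
    stages: [generate, prep, transport, report]
    outdir: runs/demo      # optional; CSV/JSON products written here

Identical config + seed gives identical numerical output; the summary JSON
is written with sorted keys so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import scenarios
from .core import trajectories_to_frame

SCENARIOS = ("cloud", "burst", "burst_depletion", "enrichment_2x",
             "enrichment_6x", "beads_intact", "beads_fragmented",
             "oscillation", "comoving", "separation_field")

STAGES = ("generate", "prep", "piv", "transport", "cloud", "track",
          "separation", "report")

STAGE_DEPS = {
    "generate": set(),
    "prep": {"generate"},
    "piv": {"generate"},
    "transport": {"prep"},
    "cloud": {"generate"},
    "track": {"generate"},
    "separation": {"generate"},
    "report": set(),
}

_ALLOWED_KEYS = {"seed", "scenario", "stages", "outdir"}


class StageDependencyError(RuntimeError):
    pass


def validate_config(config: dict) -> dict:
    unknown = set(config) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in config:
        raise ValueError("seed is mandatory")
    scenario = config.get("scenario", "burst")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    stages = list(config.get("stages", ["generate"]))
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
        missing = STAGE_DEPS[s] - set(stages)
        if missing:
            raise StageDependencyError(
                f"stage {s!r} requires {sorted(missing)} earlier in the run")
    out = dict(config)
    out["scenario"] = scenario
    out["stages"] = [s for s in STAGES if s in stages]  # dependency order
    return out


def _config_hash(config: dict) -> str:
    # outdir is bookkeeping, not science: identical seed + scenario + stages
    # must give byte-identical summaries wherever they are written
    core = {k: v for k, v in config.items() if k != "outdir"}
    return hashlib.sha256(
        json.dumps(core, sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(config: dict) -> dict:
    """Execute the requested stages; returns the machine-readable summary."""
    from . import __version__

    cfg = validate_config(config)
    seed = int(cfg["seed"])
    scen = cfg["scenario"]
    outdir = Path(cfg["outdir"]) if cfg.get("outdir") else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"scenario": scen, "seed": seed,
                     "config_hash": _config_hash(cfg),
                     "version": __version__}
    products: dict = {}

    for stage in cfg["stages"]:
        if stage == "generate":
            if scen == "cloud":
                products["stack"], products["gt"] = \
                    scenarios.make_cloud_scene(seed)
            elif scen == "burst":
                products["stack"], products["gt"] = \
                    scenarios.make_burst_scene(seed)
            elif scen == "burst_depletion":
                products["stack"], products["gt"] = \
                    scenarios.make_burst_scene(seed, depletion=True)
            elif scen in ("enrichment_2x", "enrichment_6x"):
                fold = 2.0 if scen.endswith("2x") else 6.0
                products["stack"], products["gt"] = \
                    scenarios.make_enrichment_scene(seed, fold)
            elif scen in ("beads_intact", "beads_fragmented"):
                speed = (scenarios.BEAD_SPEED_INTACT if scen.endswith("intact")
                         else scenarios.BEAD_SPEED_FRAGMENTED)
                products["stack"], products["gt"] = \
                    scenarios.make_bead_regime(seed, speed)
            elif scen == "oscillation":
                products["stack"], products["gt"] = \
                    scenarios.make_oscillation(seed)
            elif scen == "comoving":
                products["stack"], products["gt"] = \
                    scenarios.make_comoving(seed)
            elif scen == "separation_field":
                products["trajs"], products["labels"] = \
                    scenarios.make_separation_field(seed)
        elif stage == "prep":
            products["prepped"] = scenarios.preprocess_transport(
                products["stack"], products["gt"])
        elif stage == "piv":
            res = scenarios.measure_band_speed(products["stack"],
                                               products["gt"]) \
                if scen.startswith("burst") else \
                scenarios.measure_network_speed(products["stack"],
                                                products["gt"])
            key = ("inward_band_speed_um_s" if scen.startswith("burst")
                   else "network_speed_um_s")
            summary[key] = res[key]
        elif stage == "transport":
            res = scenarios.measure_flux_peak(products["stack"],
                                              products["gt"])
            summary["peak_flux_pct_per_min"] = res["peak_flux_pct_per_min"]
            summary["r_peak_um"] = res["r_peak_um"]
            if outdir:
                np.savetxt(outdir / "flux_map.csv", res["map"].flux,
                           delimiter=",")
        elif stage == "cloud":
            res = scenarios.measure_viscosity(products["stack"],
                                              products["gt"])
            summary["viscosity_ratio"] = res["viscosity_ratio"]
            summary["D_um2_s"] = res["D"]
            if outdir:
                res["fits"].to_csv(outdir / "cloud_fits.csv", index=False)
        elif stage == "track":
            if scen in ("beads_intact", "beads_fragmented"):
                res = scenarios.measure_bead_speed(products["stack"],
                                                   products["gt"])
                summary["mean_inward_bead_speed_um_s"] = \
                    res["mean_inward_speed_um_s"]
            elif scen == "oscillation":
                res = scenarios.measure_oscillation_speed(products["stack"],
                                                          products["gt"])
                summary["mtoc_speed_um_s"] = res["mean_speed_um_s"]
        elif stage == "separation":
            res = scenarios.measure_separation_fit(products["trajs"],
                                                   products["labels"])
            if res["fit"]:
                summary["separation_slope"] = res["fit"]["slope"]
                summary["separation_intercept"] = res["fit"]["intercept"]
            if outdir:
                res["table"].to_csv(outdir / "separation.csv", index=False)
        elif stage == "report":
            pass
    if outdir:
        if "stack" in products:
            products["stack"].save_tiff(outdir / f"{scen}.tif")
        if "trajs" in products:
            trajectories_to_frame(products["trajs"]).to_csv(
                outdir / "trajectories.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, sort_keys=True, indent=1)
            fh.write("\n")
    return summary
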