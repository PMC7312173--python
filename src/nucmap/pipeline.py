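"""End-to-end run orchestration from a single YAML config.

Stages run in a fixed order (simulate/load -> segment -> correct ->
features -> normalize -> classify -> damage); every stage writes its
outputs into the run directory before the next starts and records a
completion marker keyed by the config hash, so an interrupted run resumes
from the first incomplete stage and a finished run is a no-op.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correction, damage as dmg, features as feat, io, segmentation
from .synthetic import ArtifactSpec, generate_slide
from .types import SlideImage

log = logging.getLogger("nucmap.pipeline")

STAGES = ("acquire", "segment", "correct", "features", "normalize",
          "classify", "damage")

DEFAULTS: dict = {
    "seed": 0,
    "pixel_size": 1.0,
    "fast_axis": "rows",
    "cohort": "treated",           # treated | flow_control | untreated_control
    "incubation_h": None,
    "segment": {"sigma": 1.0, "min_area_um2": 30.0, "adaptive_window": 1024,
                "method": "seeded_watershed", "area_factor": 1.6,
                "solidity_threshold": 0.9},
    "qc": {"tile": 512, "density_threshold": 0.0, "focus_threshold": 0.0},
    "correct": {"block": 64, "n_windows": 12, "lowess_frac": 0.3,
                "block_um": 1000.0, "percentile_band": [2.0, 4.0],
                "normalize_dapi": True, "flatten_gh2ax": True},
    "features": {"families": ["shape", "intensity"]},
    "classify": {"enabled": False, "mog_min_records": 2000},
    "damage": {"enabled": False, "statistic": "mean_damage", "phase": "all",
               "bin_mm": 0.25, "diameter_mm": 18.0, "dr_threshold": 75.0,
               "calibration_percentile": 99.9, "scale": None,
               "treatment_center_um": None, "control_damage_csv": None},
}


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, n_records: int, cause: Exception):
        super().__init__(f"stage '{stage}' failed after {n_records} records: {cause}")
        self.stage = stage
        self.cause = cause


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(source) -> dict:
    """Merge a YAML file or dict over the recorded defaults and validate."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    else:
        raw = dict(source)
    cfg = _merge(DEFAULTS, raw)
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ConfigError("config needs either a 'simulate' or an 'inputs' section")
    if cfg["cohort"] not in ("treated", "flow_control", "untreated_control"):
        raise ConfigError(f"unknown cohort {cfg['cohort']!r}")
    if cfg["damage"]["enabled"]:
        center = cfg["damage"]["treatment_center_um"]
        if center is None:
            center = (cfg.get("simulate") or {}).get("artifacts", {}).get(
                "treatment_center_um")
        if center is None:
            raise ConfigError(
                "damage map requested but no treatment_center_um given "
                "(damage.treatment_center_um or simulate.artifacts)")
        cfg["damage"]["treatment_center_um"] = list(center)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


class _Run:
    def __init__(self, cfg: dict, out_dir: Path):
        self.cfg = cfg
        self.dir = out_dir
        self.hash = config_hash(cfg)
        self.state_path = out_dir / "state.json"
        self.state = (json.loads(self.state_path.read_text())
                      if self.state_path.exists() else {})

    def done(self, stage: str) -> bool:
        return self.state.get(stage) == self.hash

    def mark(self, stage: str) -> None:
        self.state[stage] = self.hash
        self.state_path.write_text(json.dumps(self.state, indent=2))


def run_pipeline(config, out_dir) -> Path:
    """Execute the full pipeline; returns the run directory.

    ``config`` is a YAML path or dict (see :data:`DEFAULTS` for every
    recorded default).  Reruns with an unchanged config skip completed
    stages; any stage failure aborts with the stage name and the record
    count reached so far.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_snapshot.yaml").write_text(
        yaml.safe_dump({**cfg, "config_hash": config_hash(cfg)}, sort_keys=True))
    run = _Run(cfg, out)
    n_records = 0

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        for stage in STAGES:
            if run.done(stage):
                log.info("stage %s: up to date, skipping", stage)
                continue
            try:
                n_records = _run_stage(stage, cfg, out, n_records)
            except Exception as e:  # noqa: BLE001 - annotate and re-raise
                raise StageError(stage, n_records, e) from e
            run.mark(stage)
            log.info("stage %s: done (%d records)", stage, n_records)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _load_channels(cfg, out) -> tuple[SlideImage, SlideImage | None]:
    ps = cfg["pixel_size"]
    fa = cfg["fast_axis"]
    if (out / "dapi.tif").exists():
        dapi = io.read_slide(out / "dapi.tif", "dapi", ps, fa)
        gh = (io.read_slide(out / "gh2ax.tif", "gh2ax", ps, fa)
              if (out / "gh2ax.tif").exists() else None)
        return dapi, gh
    paths = cfg["inputs"]
    dapi = io.read_slide(paths["dapi"], "dapi", ps, fa)
    gh = io.read_slide(paths["gh2ax"], "gh2ax", ps, fa) if paths.get("gh2ax") else None
    return dapi, gh


def _run_stage(stage: str, cfg: dict, out: Path, n_records: int) -> int:
    ps = cfg["pixel_size"]
    fa = cfg["fast_axis"]

    if stage == "acquire":
        if "simulate" in cfg:
            sim = dict(cfg["simulate"])
            art = ArtifactSpec(**sim.pop("artifacts", {}))
            shape = tuple(sim.pop("shape", (2048, 2048)))
            dapi, gh, truth = generate_slide(
                artifacts=art, seed=cfg["seed"], shape=shape, pixel_size=ps,
                fast_axis=fa, **sim)
            io.write_slide(out / "dapi.tif", dapi, dtype=np.float32)
            io.write_slide(out / "gh2ax.tif", gh, dtype=np.float32)
            io.write_labels(out / "truth_labels.tif", truth.labels)
            io.write_table(out / "truth.csv", truth.table)
            (out / "artifacts.yaml").write_text(art.to_yaml())
        else:
            for ch in ("dapi", "gh2ax"):
                p = cfg["inputs"].get(ch)
                if p and not Path(p).exists():
                    raise FileNotFoundError(p)
        return n_records

    dapi, gh = _load_channels(cfg, out)

    if stage == "segment":
        sc = cfg["segment"]
        labels = segmentation.segment_nuclei(
            dapi, sigma=sc["sigma"], min_area_um2=sc["min_area_um2"],
            adaptive_window=sc["adaptive_window"])
        labels = segmentation.partition_overlaps(
            labels, dapi, method=sc["method"], area_factor=sc["area_factor"],
            solidity_threshold=sc["solidity_threshold"])
        io.write_labels(out / "labels.tif", labels)
        return int(labels.max())

    labels = io.read_labels(out / "labels.tif")

    if stage == "correct":
        from scipy import ndimage as ndi
        fg = ndi.binary_dilation(labels > 0, iterations=3)
        model = {}
        for name, img in (("dapi", dapi), ("gh2ax", gh)):
            if img is None:
                continue
            surf = correction.estimate_background_surface(
                img, ~fg, block=cfg["correct"]["block"])
            flat = correction.subtract_background(img, surf)
            flat, factors = correction.remove_stripes(flat, ~fg, surf)
            io.write_slide(out / f"{name}_corrected.tif", flat, dtype=np.float32)
            model[name] = {"background_mean": float(surf.mean()),
                           "stripe_factors_minmax": [float(factors.min()),
                                                     float(factors.max())]}
        (out / "correction_model.yaml").write_text(yaml.safe_dump(model))
        return int(labels.max())

    dapi_c = io.read_slide(out / "dapi_corrected.tif", "dapi", ps, fa)
    gh_c = (io.read_slide(out / "gh2ax_corrected.tif", "gh2ax", ps, fa)
            if (out / "gh2ax_corrected.tif").exists() else None)

    if stage == "features":
        qc = io.qc_mask(dapi_c, labels=labels, tile=cfg["qc"]["tile"],
                        density_threshold=cfg["qc"]["density_threshold"],
                        focus_threshold=cfg["qc"]["focus_threshold"])
        fam = tuple(cfg["features"]["families"])
        table = feat.extract_features(labels, dapi_c, gh_c, families=fam, qc=qc)
        table["i_dapi"] = table["dapi_integrated"]
        if gh_c is not None:
            table["i_gh2ax"] = table["gh2ax_integrated"]
        slow = "centroid_row" if fa == "rows" else "centroid_col"
        table["slow_um"] = table[slow] * ps
        io.write_table(out / "nuclei.csv", table)
        np.save(out / "qc_reasons.npy", qc.reasons)
        return len(table)

    table = io.read_table(out / "nuclei.csv")

    if stage == "normalize":
        cc = cfg["correct"]
        if cc["normalize_dapi"]:
            table, curve = correction.normalize_dapi_foreground(
                table, n_windows=cc["n_windows"], lowess_frac=cc["lowess_frac"])
            if cc["flatten_gh2ax"] and "i_gh2ax" in table:
                table, _ = correction.flatten_gh2ax_foreground(
                    table, block_um=cc["block_um"],
                    percentile_band=tuple(cc["percentile_band"]))
        io.write_table(out / "nuclei.csv", table)
        return len(table)

    if stage == "classify":
        if not cfg["classify"]["enabled"]:
            return len(table)
        from . import cellcycle
        nn_path = cfg["classify"].get("nn_model")
        if nn_path:
            model = cellcycle.MitosisClassifierModel.load(nn_path)
            nn_class, _ = cellcycle.classify_mitosis(model, table)
        else:
            nn_class = np.ones(len(table), dtype=int)
        table["nn_class"] = nn_class
        inter = table[table["nn_class"] == 1]
        mog = cellcycle.fit_interphase_mog(
            inter, seed=cfg["seed"],
            min_records=cfg["classify"]["mog_min_records"])
        mog.save(out / "mog_model.json")
        phases = np.where(table["nn_class"] == 1, "", "M").astype(object)
        ph, _ = cellcycle.classify_interphase(mog, inter)
        phases[table["nn_class"].to_numpy() == 1] = ph
        table["phase"] = phases
        io.write_table(out / "nuclei.csv", table)
        return len(table)

    if stage == "damage":
        if not cfg["damage"]["enabled"]:
            return len(table)
        dc = cfg["damage"]
        gh_col = "i_gh2ax_corr" if "i_gh2ax_corr" in table else "i_gh2ax"
        da_col = "i_dapi_corr" if "i_dapi_corr" in table else "i_dapi"
        ratios = table[gh_col].to_numpy(float) / np.maximum(
            table[da_col].to_numpy(float), 1e-12)
        scale = dc["scale"] or dmg.calibrate_damage_scale(
            ratios, dc["calibration_percentile"])
        table["damage"] = dmg.damage_value(table[gh_col], table[da_col], scale)
        if dc["control_damage_csv"]:
            ctrl = pd.read_csv(dc["control_damage_csv"])["damage"].to_numpy()
            table["damage"] = dmg.subtract_control_baseline(table["damage"], ctrl)
        io.write_table(out / "nuclei.csv", table)
        if "phase" not in table:
            table["phase"] = "all"
        m = dmg.build_damage_map(
            table, tuple(dc["treatment_center_um"]),
            diameter_mm=dc["diameter_mm"], bin_mm=dc["bin_mm"],
            statistic=dc["statistic"], phase_filter=dc["phase"],
            dr_threshold=dc["dr_threshold"])
        m.metadata["damage_scale"] = float(scale)
        m.to_csv(out / f"map_{dc['statistic']}_{dc['phase']}.csv")
        m.to_png(out / f"map_{dc['statistic']}_{dc['phase']}.png")
        (out / "damage_meta.json").write_text(json.dumps(
            {"scale": float(scale), "dr_threshold": dc["dr_threshold"]}, indent=2))
        return len(table)

    raise ValueError(f"unknown stage {stage}")
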