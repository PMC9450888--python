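"""End-to-end orchestration: simulate -> segment -> register -> detect/
classify -> average -> report, with a reproducibility manifest.

A run is driven by a single YAML/JSON config with per-stage sections; every
source of randomness flows from the config seed, so re-running an identical
config reproduces identical outputs (verified by the checksums recorded in
the manifest).  Stage boundaries log the counts that make silent failures
visible (spots detected, clusters formed, structures per class).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage.filters import threshold_otsu

from . import averaging as avg_mod
from . import segmentation as seg_mod
from . import simulate as sim_mod
from . import spots as spot_mod
from .image import VoxelGrid, write_volume
from .registration import register_control_points, split_control_points
from .units import ExmError, to_pre_expansion, PhysicalLength

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "load_config", "run_pipeline", "make_report"]


class ConfigError(ExmError):
    """The run configuration is missing or misusing keys."""


_REQUIRED_TOP_KEYS = ("seed", "simulate", "detect")
_REQUIRED_DETECT_KEYS = ("quality_threshold",)

#: Stage defaults; every key can be overridden from the config file.
_DETECT_DEFAULTS = {
    "expected_radius_nm": [520.0, 180.0, 180.0],
    "link_radius_nm": 1500.0,
    "search_radius_nm": spot_mod.DEFAULT_SEARCH_RADIUS_NM,
}
_AVERAGE_DEFAULTS = {
    "max_tilt_deg": 20.0,
    "band_width_nm": 100.0,
    "crop_edge_um": 5.0,
    "target_class": 5,
}
_REGISTER_DEFAULTS = {"n_control_points": 21, "train_fraction": 0.8}


def load_config(path) -> dict:
    """Load and validate a pipeline config (YAML or JSON)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    missing = [k for k in _REQUIRED_TOP_KEYS if k not in cfg]
    missing += [
        f"detect.{k}"
        for k in _REQUIRED_DETECT_KEYS
        if k not in cfg.get("detect", {})
    ]
    sim = cfg.get("simulate", {})
    known_sim = {f.name for f in dataclasses.fields(sim_mod.SimulationConfig)}
    unknown = [f"simulate.{k}" for k in sim if k not in known_sim]
    if missing or unknown:
        parts = []
        if missing:
            parts.append(f"missing keys: {missing}")
        if unknown:
            parts.append(f"unknown keys: {unknown}")
        raise ConfigError("invalid config: " + "; ".join(parts))
    taxonomy = sim.get("taxonomy", "two_channel")
    channels = sim.get("partner_channels")
    if channels is not None:
        want = 1 if taxonomy == "two_channel" else 2
        if len(channels) != want:
            raise ConfigError(
                f"invalid config: simulate.partner_channels needs {want} "
                f"channel role(s) for taxonomy {taxonomy!r}, got {list(channels)}"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _sim_config(cfg: dict) -> sim_mod.SimulationConfig:
    sim = dict(cfg.get("simulate", {}))
    sim.setdefault("seed", cfg["seed"])
    if "partner_channels" in sim:
        sim["partner_channels"] = tuple(sim["partner_channels"])
    for key in ("nucleus_semiaxes_pre_nm", "voxel_size_pre_nm", "voxel_size_post_nm",
                "psf_sigma_pre_nm", "psf_sigma_post_nm"):
        if key in sim:
            sim[key] = tuple(sim[key])
    if "n_structures_per_class" in sim:
        sim["n_structures_per_class"] = {
            int(k): int(v) for k, v in sim["n_structures_per_class"].items()
        }
    if "class_geometry" in sim:
        geo = dict(sim["class_geometry"])
        for key in ("tilt_range_deg", "site_spread_nm", "partner_distance_nm",
                    "satellite_count_range", "site_count_range", "partner_count_range"):
            if key in geo:
                geo[key] = tuple(geo[key])
        sim["class_geometry"] = sim_mod.ClassGeometry(**geo)
    return sim_mod.SimulationConfig(**sim)


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute all stages in dependency order; return (and write) the
    run manifest.  Any stage failure raises with the stage name."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    outputs: dict[str, str] = {}
    summary: dict = {}

    def _save_df(df: pd.DataFrame, name: str) -> Path:
        path = out / name
        df.to_csv(path, index=False, float_format="%.6g")
        outputs[name] = ""
        return path

    # ---- stage: simulate -------------------------------------------------
    stage = "simulate"
    try:
        sim_cfg = _sim_config(config)
        pre, post, truth = sim_mod.generate_nucleus_scene(sim_cfg)
        write_volume(out / "pre.tif", pre)
        write_volume(out / "post.tif", post)
        outputs["pre.tif"] = outputs["post.tif"] = ""
        _save_df(truth.spots, "truth_spots.csv")
        _save_df(truth.structures, "truth_structures.csv")
        summary["simulate"] = {
            "n_structures": int(len(truth.structures)),
            "n_spots": int(len(truth.spots)),
            "expansion_factor_true": sim_cfg.expansion_factor,
        }
        logger.info("simulate: %d structures, %d spots", len(truth.structures), len(truth.spots))
    except Exception as exc:
        raise ExmError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: segment + expansion factor -------------------------------
    stage = "segment"
    try:
        dna_pre = pre.channel(sim_cfg.dna_channel)
        dna_post = post.channel(sim_cfg.dna_channel)
        mask3d_pre = seg_mod.segment_nuclei_3d(dna_pre)
        mask3d_post = seg_mod.segment_nuclei_3d(dna_post)
        factor_vol = seg_mod.expansion_factor_from_masks(mask3d_pre, mask3d_post, "volume")

        mid_pre = VoxelGrid(dna_pre.data[dna_pre.data.shape[0] // 2], dna_pre.voxel_size[-2:])
        mid_post = VoxelGrid(dna_post.data[dna_post.data.shape[0] // 2], dna_post.voxel_size[-2:])
        a, b = sorted(sim_cfg.nucleus_semiaxes_pre_nm)[-2:]
        area_um2 = np.pi * a * b / 1e6
        bounds_pre = (0.25 * area_um2, 4.0 * area_um2)
        bounds_post = tuple(v * sim_cfg.expansion_factor**2 for v in bounds_pre)

        def _area_mask(img2d: VoxelGrid, bounds) -> seg_mod.NucleusMask:
            data = np.asarray(img2d.data, dtype=float)
            thr = float(threshold_otsu(data))
            return seg_mod.segment_nuclei_2d(
                img2d, thr, bounds[0], bounds[1], rolling_ball_radius_px=0
            )

        mask2d_pre = _area_mask(mid_pre, bounds_pre)
        mask2d_post = _area_mask(mid_post, bounds_post)
        factor_area = seg_mod.expansion_factor_from_masks(mask2d_pre, mask2d_post, "area")
        seg_summary = {
            "n_nuclei_3d": mask3d_post.n_nuclei,
            "area_ratio": factor_area.raw_ratio,
            "volume_ratio": factor_vol.raw_ratio,
            "linear_factor_area": factor_area.linear_factor,
            "linear_factor_volume": factor_vol.linear_factor,
        }
        with open(out / "expansion_factor.json", "w") as fh:
            json.dump(seg_summary, fh, indent=2, sort_keys=True)
        outputs["expansion_factor.json"] = ""
        summary["segment"] = seg_summary
    except Exception as exc:
        raise ExmError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: register -------------------------------------------------
    stage = "register"
    try:
        reg_cfg = {**_REGISTER_DEFAULTS, **config.get("register", {})}
        cps = truth.control_point_set()
        n_pts = min(int(reg_cfg["n_control_points"]), len(cps))
        rng = np.random.default_rng(seed + 10)
        pick = np.sort(rng.choice(len(cps), size=n_pts, replace=False))
        cps = type(cps)(cps.pre[pick], cps.post[pick], cps.ids[pick])
        report = register_control_points(
            cps, float(reg_cfg["train_fraction"]), seed=seed + 11
        )
        with open(out / "registration.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        outputs["registration.json"] = ""
        summary["register"] = {
            "mse_train_nm": report.mse_train_nm,
            "mse_validation_nm": report.mse_validation_nm,
            "scale": report.transform.scale,
        }
    except Exception as exc:
        raise ExmError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: detect + classify ----------------------------------------
    stage = "classify"
    try:
        det = {**_DETECT_DEFAULTS, **config["detect"]}
        radius = det["expected_radius_nm"]
        qthr = float(det["quality_threshold"])
        rules_file = config.get("classify", {}).get("rules_file")
        if rules_file:
            rules = spot_mod.ClassRuleSet.from_yaml(rules_file)
        elif sim_cfg.taxonomy == "three_channel":
            rules = spot_mod.three_channel_rules(
                sim_cfg.site_channel, *sim_cfg.partner_channels
            )
        else:
            rules = spot_mod.two_channel_rules(
                sim_cfg.site_channel, sim_cfg.partner_channels[0]
            )

        detections = {}
        for ch in (sim_cfg.site_channel, *sim_cfg.partner_channels):
            detections[ch] = spot_mod.detect_spots(post.channel(ch), radius, qthr)
            logger.info("detect: %d spots in channel %s", len(detections[ch]), ch)
        site_df = detections[sim_cfg.site_channel]
        site_pos = site_df[["z", "y", "x"]].to_numpy()
        labels, cores = spot_mod.cluster_site_spots(site_pos, float(det["link_radius_nm"]))
        structures = spot_mod.assemble_structures(
            site_pos, labels, cores,
            {ch: detections[ch][["z", "y", "x"]].to_numpy() for ch in sim_cfg.partner_channels},
            float(det["search_radius_nm"]),
            site_channel=sim_cfg.site_channel,
        )
        for s in structures:
            spot_mod.classify_structure(s, rules)
            if s.class_label == 5 and sim_cfg.taxonomy == "two_channel":
                spot_mod.subclassify_by_distance(s, channel=rules.encapsulation_channel)

        all_spots = pd.concat(
            [d.assign(channel=ch) for ch, d in detections.items()], ignore_index=True
        )[["channel", "z", "y", "x", "quality"]]
        _save_df(all_spots, "spots.csv")
        struct_rows = [
            {
                "structure_id": s.structure_id,
                "core_z": s.core_position[0],
                "core_y": s.core_position[1],
                "core_x": s.core_position[2],
                "n_site": s.site_count,
                **{f"n_{ch}": s.partner_count(ch) for ch in sim_cfg.partner_channels},
                "class": s.class_label,
                "distance_subclass": s.distance_subclass or "",
            }
            for s in structures
        ]
        _save_df(pd.DataFrame(struct_rows), "structures.csv")
        freq = spot_mod.class_frequency_table(structures)
        _save_df(freq, "class_frequencies.csv")
        summary["classify"] = {
            "n_spots": {ch: int(len(d)) for ch, d in detections.items()},
            "n_structures": len(structures),
            "class_counts": {int(r["class"]): int(r["count"]) for _, r in freq.iterrows()},
        }
        logger.info("classify: %d structures, classes %s", len(structures),
                    summary["classify"]["class_counts"])
    except Exception as exc:
        raise ExmError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: average --------------------------------------------------
    stage = "average"
    try:
        acfg = {**_AVERAGE_DEFAULTS, **config.get("average", {})}
        target = [s for s in structures if s.class_label == int(acfg["target_class"])]
        in_plane = avg_mod.select_in_plane(
            target, float(acfg["max_tilt_deg"]), float(acfg["band_width_nm"]),
            channel=rules.encapsulation_channel,
        )
        avg_summary: dict = {"n_candidates": len(target), "n_in_plane": len(in_plane)}
        if in_plane:
            edge_nm = float(acfg["crop_edge_um"]) * 1000.0
            crops = [
                spot_mod.crop_structure(post, s.core_position, edge_nm) for s in in_plane
            ]
            average = avg_mod.average_structures(crops, [s.structure_id for s in in_plane])
            write_volume(out / "average_structure.tif", average.mean)
            outputs["average_structure.tif"] = ""
            profile = avg_mod.radial_profile(average, float(acfg["band_width_nm"]))
            prof_df = pd.DataFrame(
                {"radius_nm": profile.radii_nm, "n_pixels": profile.n_pixels}
                | {f"mean_{ch}": v for ch, v in profile.values.items()}
            )
            _save_df(prof_df, "radial_profile.csv")
            partner = rules.encapsulation_channel
            pk = avg_mod.peak_to_peak(profile, partner)
            meas = {
                "peak_to_peak_nm": pk.peak_to_peak.value,
                "peak_flag": pk.flag,
            }
            try:
                sg = avg_mod.span_and_gap(profile, sim_cfg.site_channel, partner)
                meas |= {k: v.value for k, v in sg.items()}
            except avg_mod.UndefinedSpanError:
                meas["span_gap_error"] = "flat profile"
            factor = sim_cfg.expansion_factor
            meas["peak_to_peak_pre_nm"] = to_pre_expansion(
                pk.peak_to_peak, factor
            ).value
            with open(out / "profile_measurements.json", "w") as fh:
                json.dump(meas, fh, indent=2, sort_keys=True)
            outputs["profile_measurements.json"] = ""
            avg_summary |= meas
        summary["average"] = avg_summary
    except Exception as exc:
        raise ExmError(f"stage {stage!r} failed: {exc}") from exc

    # ---- manifest --------------------------------------------------------
    for name in outputs:
        outputs[name] = _sha256(out / name)
    manifest = {
        "config": config,
        "seed": seed,
        "outputs": outputs,
        "summary": summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def make_report(manifest: dict | str | Path, out_path: str | Path | None = None) -> str:
    """Deterministic human-readable summary of a completed run."""
    if not isinstance(manifest, dict):
        with open(manifest) as fh:
            manifest = json.load(fh)
    summary = manifest.get("summary")
    if not summary or "classify" not in summary:
        raise ExmError("manifest does not reference a completed run")
    lines = ["# exmfoci run report", ""]
    seg = summary.get("segment", {})
    if seg:
        lines += [
            "## Expansion",
            f"area ratio post/pre:   {seg['area_ratio']:.3f} "
            f"(linear factor {seg['linear_factor_area']:.3f})",
            f"volume ratio post/pre: {seg['volume_ratio']:.3f} "
            f"(linear factor {seg['linear_factor_volume']:.3f})",
            "",
        ]
    reg = summary.get("register", {})
    if reg:
        lines += [
            "## Registration",
            f"similarity scale: {reg['scale']:.4f}",
            f"MSE train:      {reg['mse_train_nm']:.2f} nm",
            f"MSE validation: {reg['mse_validation_nm']:.2f} nm",
            "",
        ]
    cls = summary["classify"]
    lines += ["## Structure classes"]
    total = 0
    for label in sorted(cls["class_counts"]):
        n = cls["class_counts"][label]
        total += n
        lines.append(f"class {label}: {n}")
    lines += [f"total structures: {total}", ""]
    avg = summary.get("average", {})
    if avg:
        lines += ["## Average class-5 structure"]
        lines.append(f"candidates: {avg.get('n_candidates', 0)}, in-plane: {avg.get('n_in_plane', 0)}")
        if "peak_to_peak_nm" in avg:
            lines.append(
                f"53BP1 peak-to-peak: {avg['peak_to_peak_nm']:.0f} nm post-expansion "
                f"({avg['peak_to_peak_pre_nm']:.0f} nm pre-expansion equivalent)"
            )
            if avg.get("peak_flag"):
                lines.append(f"flag: {avg['peak_flag']}")
        lines.append("")
    text = "\n".join(lines)
    if out_path is not None:
        Path(out_path).write_text(text)
    return text
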