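"""Shipped experiment presets and the orchestration layer.

Each preset runs one of the package's experiments end-to-end with its
standard configuration, writes its tables and trained networks under an
output directory, and records a manifest (JSON) with the exact configuration,
seed, config hash, output files and headline summary metrics, so that every
unprinted modeling choice is auditable per run. Presets are byte-reproducible
given the same root seed and package version.

Available presets
-----------------
holism_sweep
    Variance-ratio x classifier-count sweep on the sphere; reports the
    per-dimension classifier spread for every cell.
race_exposure
    Two-population exposure experiment (1000 vs 100 exemplars, 50 neurons)
    plus the balanced control; reports classifier counts per group.
race_discrimination
    Trains the exposure map, then measures 360-degree radial discrimination
    profiles around both group means.
hierarchy_faces
    Two-layer image hierarchy on a synthetic 43 + 7 face population;
    reports unique-code counts, cluster labels and the holistic
    manipulation-overlap table.
cortical_h_sweep
    9 x 9 cortical sheet at lateral gains h = 0, 0.3, 1; reports the
    neighbor-agreement index per gain.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Callable

import pandas as pd

from .cortical import default_category_specs, run_cortical_experiment
from .discrimination import compare_groups, discrimination_profile
from .engine import PoolParams, TrainSchedule
from .hierarchy import (
    HierarchyConfig,
    cluster_outputs,
    holistic_test,
    layer2_response,
    train_hierarchy,
    unique_code_count,
)
from .io import save_classifier_map, save_hierarchy
from .sphere import (
    classifier_density_by_group,
    classifier_spread,
    run_face_space_experiment,
    run_holism_condition,
)
from .synth import PopulationSpec, sample_face_population

__all__ = ["PRESETS", "run_preset", "UnknownPresetError"]


class UnknownPresetError(ValueError):
    """Requested preset name is not registered."""


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, default=float))


def _classifier_csv(cmap, path: Path) -> None:
    df = pd.DataFrame(cmap.classifier_azel, columns=["azimuth", "elevation"])
    df[["w1", "w2", "w3"]] = cmap.weights
    df.to_csv(path, index=False)


def _preset_holism_sweep(seed: int, out: Path, cfg: dict) -> dict:
    ratios = cfg.get("ratios", [0.25, 0.5, 1.0])
    counts = cfg.get("classifier_counts", [4, 16])
    n_exemplars = cfg.get("n_exemplars", 500)
    epochs = cfg.get("epochs", 2000)
    rows = []
    outputs = []
    for ratio in ratios:
        for n in counts:
            cmap = run_holism_condition(
                ratio, n, seed, n_exemplars=n_exemplars, epochs=epochs
            )
            sd_minor, sd_major = classifier_spread(cmap)
            rows.append(
                {"ratio": ratio, "n_classifiers": n,
                 "spread_minor": sd_minor, "spread_major": sd_major}
            )
            fname = out / f"classifiers_ratio{ratio}_N{n}.csv"
            _classifier_csv(cmap, fname)
            outputs.append(fname.name)
    table = pd.DataFrame(rows)
    table.to_csv(out / "spread_summary.csv", index=False)
    outputs.append("spread_summary.csv")
    return {"outputs": outputs, "summary": {"n_conditions": len(rows)}}


def _exposure_specs(cfg: dict) -> list[PopulationSpec]:
    return [
        PopulationSpec(
            center_azel=tuple(cfg.get("own_center", (30.0, 40.0))),
            sd_azel=(cfg.get("group_sd", 6.0),) * 2,
            count=cfg.get("n_own", 1000), label="own",
        ),
        PopulationSpec(
            center_azel=tuple(cfg.get("other_center", (62.0, 50.0))),
            sd_azel=(cfg.get("group_sd", 6.0),) * 2,
            count=cfg.get("n_other", 100), label="other",
        ),
    ]


def _exposure_map(seed: int, cfg: dict):
    specs = _exposure_specs(cfg)
    n = cfg.get("n_classifiers", 50)
    params = PoolParams(N=n, r=cfg.get("r", 0.001), alpha=cfg.get("alpha", float(n)))
    return run_face_space_experiment(
        specs, params, TrainSchedule(epochs=cfg.get("epochs", 200)), seed
    )


def _preset_race_exposure(seed: int, out: Path, cfg: dict) -> dict:
    cmap = _exposure_map(seed, cfg)
    counts = classifier_density_by_group(cmap)
    balanced_cfg = dict(cfg, n_other=cfg.get("n_own", 1000))
    balanced = _exposure_map(seed, balanced_cfg)
    counts_balanced = classifier_density_by_group(balanced)
    _classifier_csv(cmap, out / "classifiers_unbalanced.csv")
    _classifier_csv(balanced, out / "classifiers_balanced.csv")
    cmap.points.to_csv(out / "points_unbalanced.csv")
    save_classifier_map(cmap, out / "map_unbalanced.h5")
    summary = {
        "unbalanced_counts": counts,
        "balanced_counts": counts_balanced,
    }
    _write_json(out / "density.json", summary)
    return {
        "outputs": [
            "classifiers_unbalanced.csv", "classifiers_balanced.csv",
            "points_unbalanced.csv", "map_unbalanced.h5", "density.json",
        ],
        "summary": summary,
    }


def _preset_race_discrimination(seed: int, out: Path, cfg: dict) -> dict:
    cmap = _exposure_map(seed, cfg)
    p_own = discrimination_profile(cmap, "own")
    p_other = discrimination_profile(cmap, "other")
    pd.concat([p_own.to_frame(), p_other.to_frame()]).to_csv(
        out / "profiles.csv", index=False
    )
    comparison = compare_groups(p_own, p_other)
    comparison.pop("per_angle_difference")
    _write_json(out / "comparison.json", comparison)
    return {
        "outputs": ["profiles.csv", "comparison.json"],
        "summary": comparison,
    }


def _preset_hierarchy_faces(seed: int, out: Path, cfg: dict) -> dict:
    images = sample_face_population(
        cfg.get("n_own", 43), cfg.get("n_other", 7), seed
    )
    hcfg = HierarchyConfig(
        N2=cfg.get("n_outputs", 10), seed=seed,
        layer1_epochs=cfg.get("layer1_epochs", 100),
        layer2_epochs=cfg.get("layer2_epochs", 300),
    )
    net = train_hierarchy(images, hcfg)
    save_hierarchy(net, out / "network.h5")
    codes = [layer2_response(net, im) for im in images]
    n_unique, fractions = unique_code_count(codes)
    labels, _ = cluster_outputs(codes, k=cfg.get("n_clusters", 6))
    pd.DataFrame(
        {
            "face_id": [c.stimulus_id for c in codes],
            "population": [c.population for c in codes],
            "cluster": labels,
            "unique": [
                sum(c.ranked_order == d.ranked_order for d in codes) == 1
                for c in codes
            ],
        }
    ).to_csv(out / "codes.csv", index=False)
    overlaps = holistic_test(net, images, seed=seed)
    overlaps.to_csv(out / "holistic_overlap.csv", index=False)
    summary = {
        "n_unique_codes": n_unique,
        "unique_fraction_by_population": fractions,
    }
    _write_json(out / "unique_codes.json", summary)
    return {
        "outputs": ["network.h5", "codes.csv", "holistic_overlap.csv",
                    "unique_codes.json"],
        "summary": summary,
    }


def _preset_cortical_h_sweep(seed: int, out: Path, cfg: dict) -> dict:
    gains = cfg.get("gains", [0.0, 0.3, 1.0])
    specs = default_category_specs(tuple(cfg.get("counts", (50, 40, 20, 50, 100))))
    epochs = cfg.get("epochs", 1000)
    agreement = {}
    outputs = []
    for h in gains:
        result = run_cortical_experiment(specs, h=h, seed=seed, epochs=epochs)
        coords = result.topology.coordinates()
        df = pd.DataFrame(coords, columns=["row", "col"])
        df["label"] = result.preferred
        df[["w1", "w2", "w3"]] = result.weights
        fname = out / f"neurons_h{h}.csv"
        df.to_csv(fname, index=False)
        outputs.append(fname.name)
        agreement[str(h)] = result.agreement_index
    _write_json(out / "agreement.json", agreement)
    outputs.append("agreement.json")
    return {"outputs": outputs, "summary": {"agreement_index": agreement}}


PRESETS: dict[str, Callable[[int, Path, dict], dict]] = {
    "holism_sweep": _preset_holism_sweep,
    "race_exposure": _preset_race_exposure,
    "race_discrimination": _preset_race_discrimination,
    "hierarchy_faces": _preset_hierarchy_faces,
    "cortical_h_sweep": _preset_cortical_h_sweep,
}


def run_preset(
    name: str, root_seed: int, out_dir, overrides: dict | None = None
) -> dict:
    """Run a named preset end-to-end and write its manifest.

    Returns the manifest dict (also written to ``manifest.json`` in
    ``out_dir``): preset name, seed, full configuration and its hash, the
    files written, and the preset's summary metrics.
    """
    if name not in PRESETS:
        raise UnknownPresetError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dict(overrides or {})
    result = PRESETS[name](int(root_seed), out, cfg)
    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = {
        "preset": name,
        "seed": int(root_seed),
        "config": cfg,
        "config_hash": config_hash,
        "outputs": result["outputs"],
        "summary": result["summary"],
    }
    _write_json(out / "manifest.json", manifest)
    return manifest
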