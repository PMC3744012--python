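"""HDF5 serialization of trained networks and maps."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .engine import PoolParams, TrainSchedule
from .hierarchy import FrontEndConfig, HierarchyConfig, TrainedHierarchy
from .sphere import ClassifierMap
from .synth import FacePointSet, PopulationSpec

__all__ = [
    "save_classifier_map",
    "load_classifier_map",
    "save_hierarchy",
    "load_hierarchy",
]


def _specs_to_json(specs) -> str:
    return json.dumps(
        [
            {
                "center_azel": list(s.center_azel),
                "sd_azel": list(s.sd_azel),
                "count": s.count,
                "label": s.label,
            }
            for s in specs
        ]
    )


def _specs_from_json(text: str) -> tuple[PopulationSpec, ...]:
    return tuple(
        PopulationSpec(
            center_azel=tuple(d["center_azel"]),
            sd_azel=tuple(d["sd_azel"]),
            count=d["count"],
            label=d["label"],
        )
        for d in json.loads(text)
    )


def save_classifier_map(cmap: ClassifierMap, path) -> None:
    with h5py.File(Path(path), "w") as f:
        f.create_dataset("weights", data=cmap.weights)
        f.create_dataset("classifier_azel", data=cmap.classifier_azel)
        f.create_dataset("points", data=cmap.points.points)
        f.create_dataset("points_azel", data=cmap.points.azel)
        f.create_dataset(
            "point_labels",
            data=np.array([str(x) for x in cmap.points.labels], dtype="S64"),
        )
        f.attrs["specs"] = _specs_to_json(cmap.specs)
        f.attrs["seed"] = cmap.seed
        f.attrs["epochs"] = cmap.schedule.epochs
        for name in ("N", "r", "alpha", "kappa", "avg_count"):
            f.attrs[name] = getattr(cmap.params, name)


def load_classifier_map(path) -> ClassifierMap:
    with h5py.File(Path(path), "r") as f:
        params = PoolParams(
            N=int(f.attrs["N"]), r=float(f.attrs["r"]),
            alpha=float(f.attrs["alpha"]), kappa=float(f.attrs["kappa"]),
            avg_count=int(f.attrs["avg_count"]),
        )
        points = FacePointSet(
            points=f["points"][:],
            labels=np.array([s.decode() for s in f["point_labels"][:]], dtype=object),
            azel=f["points_azel"][:],
        )
        return ClassifierMap(
            weights=f["weights"][:],
            classifier_azel=f["classifier_azel"][:],
            params=params,
            schedule=TrainSchedule(epochs=int(f.attrs["epochs"])),
            specs=_specs_from_json(f.attrs["specs"]),
            seed=int(f.attrs["seed"]),
            points=points,
        )


def save_hierarchy(net: TrainedHierarchy, path) -> None:
    cfg = net.config
    with h5py.File(Path(path), "w") as f:
        f.create_dataset("layer1_weights", data=net.layer1_weights)
        f.create_dataset("layer2_weights", data=net.layer2_weights)
        for name in ("N1", "N2", "r", "kappa", "layer1_epochs", "layer2_epochs", "seed"):
            f.attrs[name] = getattr(cfg, name)
        f.attrs["log_sigma"] = cfg.front_end.log_sigma
        f.attrs["smooth_sigma"] = cfg.front_end.smooth_sigma


def load_hierarchy(path) -> TrainedHierarchy:
    with h5py.File(Path(path), "r") as f:
        cfg = HierarchyConfig(
            N1=int(f.attrs["N1"]), N2=int(f.attrs["N2"]),
            r=float(f.attrs["r"]), kappa=float(f.attrs["kappa"]),
            layer1_epochs=int(f.attrs["layer1_epochs"]),
            layer2_epochs=int(f.attrs["layer2_epochs"]),
            seed=int(f.attrs["seed"]),
            front_end=FrontEndConfig(
                log_sigma=float(f.attrs["log_sigma"]),
                smooth_sigma=float(f.attrs["smooth_sigma"]),
            ),
        )
        return TrainedHierarchy(
            layer1_weights=f["layer1_weights"][:],
            layer2_weights=f["layer2_weights"][:],
            config=cfg,
        )
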