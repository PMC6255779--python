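"""Experiment configuration: YAML round-trip and the shipped default scene.

Keys carry explicit units (``*_mm``, ``*_hu``) to prevent unit bugs. All
randomness flows from one ``root_seed`` through named substreams
(``phantom.vessels``, ``segmentation.perturb``, ``noise.<profile>``), so a
config fully determines a run.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .imaging import AcquisitionProfile, PSFModel, gaussian_psf_from_cutoff, preset_profile
from .phantom import GridSpec, NoduleSpec, PhantomScene, VesselParams

__all__ = [
    "ExperimentConfig",
    "default_config",
    "load_config",
    "save_config",
    "substream_seed",
]


def _plain(obj):
    """Recursively convert numpy scalars/sequences to plain Python types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


def substream_seed(root_seed: int, name: str) -> int:
    """Deterministic per-purpose seed derived from the root seed."""
    return (int(root_seed) ^ zlib.crc32(name.encode())) & 0x7FFFFFFF


@dataclass
class SegmentationConfig:
    repeats: int = 3
    perturb_mm: float | None = None  # None -> one voxel of the image segmented


@dataclass
class RegistrationConfig:
    angles_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    search: bool = False
    target_mm: float = 0.14


@dataclass
class WireConfig:
    profile: str  # which acquisition profile images this wire
    wire_diameter_mm: float


@dataclass
class ExperimentConfig:
    scene: PhantomScene
    profiles: list[AcquisitionProfile]
    nodule_names: list[str]
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    wires: list[WireConfig] = field(default_factory=list)
    root_seed: int = 0
    save_volumes: bool = True

    def to_dict(self) -> dict:
        return _plain({
            "root_seed": self.root_seed,
            "save_volumes": self.save_volumes,
            "phantom": {
                "grid": {
                    "shape": list(self.scene.grid.shape),
                    "spacing_mm": list(self.scene.grid.spacing_mm),
                    "origin_mm": list(self.scene.grid.origin_mm),
                },
                "lung_background_hu": self.scene.lung_background_hu,
                "structure_hu": self.scene.structure_hu,
                "vessel_seed": self.scene.vessel_seed,
                "vessel_params": asdict(self.scene.vessel_params),
                "vessel_root_mm": (
                    list(self.scene.vessel_root_mm)
                    if self.scene.vessel_root_mm is not None
                    else None
                ),
                "vessel_direction": list(self.scene.vessel_direction),
                "nodules": [
                    {"name": name, **asdict(spec)}
                    for name, spec in zip(self.nodule_names, self.scene.nodules)
                ],
            },
            "profiles": [
                {
                    "name": p.name,
                    "psf": {"sigma_mm": p.psf.sigma_mm, "sigma_z_mm": p.psf.sigma_z_mm},
                    "recon_spacing_mm": list(p.recon_spacing_mm),
                    "noise_sigma_hu": p.noise_sigma_hu,
                }
                for p in self.profiles
            ],
            "segmentation": asdict(self.segmentation),
            "registration": {
                "angles_deg": list(self.registration.angles_deg),
                "search": self.registration.search,
                "target_mm": self.registration.target_mm,
            },
            "mtf": {
                "wires": [
                    {"profile": w.profile, "wire_diameter_mm": w.wire_diameter_mm}
                    for w in self.wires
                ]
            },
        })

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        ph = d["phantom"]
        nodules, names = [], []
        for nd in ph["nodules"]:
            nd = dict(nd)
            names.append(nd.pop("name"))
            nd["center_mm"] = tuple(nd["center_mm"])
            nodules.append(NoduleSpec(**nd))
        scene = PhantomScene(
            grid=GridSpec(
                shape=tuple(ph["grid"]["shape"]),
                spacing_mm=tuple(ph["grid"]["spacing_mm"]),
                origin_mm=tuple(ph["grid"].get("origin_mm", (0.0, 0.0, 0.0))),
            ),
            nodules=nodules,
            lung_background_hu=ph["lung_background_hu"],
            structure_hu=ph["structure_hu"],
            vessel_seed=ph["vessel_seed"],
            vessel_params=VesselParams(
                **{
                    **ph["vessel_params"],
                    "branch_angle_deg": tuple(ph["vessel_params"]["branch_angle_deg"]),
                }
            ),
            vessel_root_mm=(
                tuple(ph["vessel_root_mm"]) if ph.get("vessel_root_mm") else None
            ),
            vessel_direction=tuple(ph.get("vessel_direction", (1.0, 0.3, 0.1))),
        )
        root_seed = d.get("root_seed", 0)
        profiles = []
        for p in d["profiles"]:
            profiles.append(
                AcquisitionProfile(
                    name=p["name"],
                    psf=PSFModel(
                        sigma_mm=p["psf"]["sigma_mm"], sigma_z_mm=p["psf"]["sigma_z_mm"]
                    ),
                    recon_spacing_mm=tuple(p["recon_spacing_mm"]),
                    noise_sigma_hu=p.get("noise_sigma_hu", 0.0),
                    noise_seed=substream_seed(root_seed, f"noise.{p['name']}"),
                )
            )
        reg = d.get("registration", {})
        return cls(
            scene=scene,
            profiles=profiles,
            nodule_names=names,
            segmentation=SegmentationConfig(**d.get("segmentation", {})),
            registration=RegistrationConfig(
                angles_deg=tuple(reg.get("angles_deg", (0.0, 0.0, 0.0))),
                search=reg.get("search", False),
                target_mm=reg.get("target_mm", 0.14),
            ),
            wires=[WireConfig(**w) for w in d.get("mtf", {}).get("wires", [])],
            root_seed=root_seed,
            save_volumes=d.get("save_volumes", True),
        )


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        return ExperimentConfig.from_dict(yaml.safe_load(fh))


def save_config(config: ExperimentConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def default_config(root_seed: int = 0, noise_sigma_hu: float = 0.0) -> ExperimentConfig:
    """The shipped six-nodule, three-profile experiment.

    Six nodules (3/6/9 mm, one sphere and one spiked sphere each) on a 3 x 2
    layout with 16 mm pitch inside a 48 x 32 x 18 mm lung block sampled at
    0.08 mm isotropically — fine enough that all three reconstruction grids
    subsample it. A seeded vessel tree adds connected tubular clutter.
    """
    spacing = 0.08
    shape = (600, 400, 225)  # 48 x 32 x 18 mm
    z = 9.0
    nodules, names = [], []
    for x, diameter in zip((8.0, 24.0, 40.0), (3.0, 6.0, 9.0)):
        for y, kind in zip((8.0, 24.0), ("sphere", "spiked_sphere")):
            spec = NoduleSpec(
                kind=kind,
                diameter_mm=diameter,
                center_mm=(x, y, z),
                spike_seed=substream_seed(root_seed, f"spikes.{diameter}mm"),
            )
            nodules.append(spec)
            names.append(f"{int(diameter)}mm_{'sphere' if kind == 'sphere' else 'spiked'}")

    scene = PhantomScene(
        grid=GridSpec(shape=shape, spacing_mm=(spacing,) * 3),
        nodules=nodules,
        vessel_seed=substream_seed(root_seed, "phantom.vessels"),
        vessel_root_mm=(0.0, 16.0, 9.0),
    )
    profiles = [
        preset_profile(name, noise_sigma_hu, substream_seed(root_seed, f"noise.{name}"))
        for name in ("ct", "hrct", "spcct")
    ]
    wires = [
        WireConfig(profile="ct", wire_diameter_mm=0.2),
        WireConfig(profile="hrct", wire_diameter_mm=0.2),
        WireConfig(profile="spcct", wire_diameter_mm=0.1),
    ]
    return ExperimentConfig(
        scene=scene,
        profiles=profiles,
        nodule_names=names,
        wires=wires,
        root_seed=root_seed,
    )
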