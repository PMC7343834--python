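"""End-to-end orchestration: phantom/volume -> segmentation -> morphometry -> stats.

A single :class:`PipelineConfig` (YAML-loadable) drives all stages.  The
global seed fans out to per-stage seeds by hashing the stage name, so each
stage is independently reproducible; identical config + seed produce
byte-identical CSV/JSON outputs.  Every run writes a manifest listing all
outputs with SHA-256 checksums, the seed, package versions and stage
timings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _pkg_version
from ._exceptions import CereplaqError, ConfigurationError
from . import morphometry, phantom, purkinje, segmentation, stats
from .volume_io import (
    LabelMap,
    read_seed_rois,
    read_volume,
    write_label_map,
    write_seed_rois,
    write_volume,
)

log = logging.getLogger(__name__)


def derive_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: stable hash of the stage name mixed with the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class PipelineConfig:
    """Everything one run needs.  Exactly one input source must be set."""

    # input: either a phantom spec, or a volume (+ seeds) on disk
    phantom_spec: phantom.PhantomSpec | None = None
    volume_path: str | None = None
    seeds_path: str | None = None
    voxel_size_um: float | None = None       # override for files without metadata

    min_volume_um3: float = segmentation.DEFAULT_MIN_VOLUME_UM3
    connectivity: int = 26
    max_gray: float | None = None

    purkinje_scales_um: tuple[float, ...] = purkinje.DEFAULT_SCALES_UM
    purkinje_threshold: float = purkinje.DEFAULT_BLOBNESS_THRESHOLD
    purkinje_diameter_um: tuple[float, float] = purkinje.DEFAULT_DIAMETER_RANGE_UM

    orient_hist_bin_deg: float = stats.ORIENT_HIST_BIN_DEG
    mip_thickness_um: float = 25.0

    out_dir: str = "cereplaq_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        has_phantom = self.phantom_spec is not None
        has_file = self.volume_path is not None
        if has_phantom == has_file:
            raise ConfigurationError(
                "exactly one input source required: phantom_spec or volume_path"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        spec = None
        if "phantom" in raw:
            spec = _phantom_spec_from_dict(raw.pop("phantom") or {})
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name == "phantom_spec":
                continue
            if f.name in raw:
                v = raw.pop(f.name)
                if f.name in ("purkinje_scales_um", "purkinje_diameter_um") and v is not None:
                    v = tuple(v)
                kwargs[f.name] = v
        if raw:
            raise ConfigurationError(f"unknown config keys: {sorted(raw)}")
        return cls(phantom_spec=spec, **kwargs)


def _phantom_spec_from_dict(d: dict) -> phantom.PhantomSpec:
    d = dict(d)
    kwargs: dict = {}
    if "grid_shape" in d:
        kwargs["grid_shape"] = tuple(d.pop("grid_shape"))
    for name, cls_ in (("layer_model", phantom.LayerModel),
                       ("plaque_model", phantom.PlaqueModel),
                       ("purkinje_model", phantom.PurkinjeModel),
                       ("vessel_model", phantom.VesselModel)):
        if name in d:
            sub = dict(d.pop(name))
            for k in ("aspect_ratio_range", "diameter_range_um", "radius_range_um"):
                if k in sub:
                    sub[k] = tuple(sub[k])
            kwargs[name] = cls_(**sub)
    if "region_map" in d:
        kwargs["region_map"] = [
            phantom.RegionSpec(
                name=r["name"], ml_range=tuple(r["ml_range"]),
                preferred_axis=tuple(r["preferred_axis"]),
                spread_deg=float(r.get("spread_deg", 30.0)),
                spread2_deg=(float(r["spread2_deg"])
                             if r.get("spread2_deg") is not None else None),
            )
            for r in d.pop("region_map")
        ]
    kwargs.update(d)
    return phantom.PhantomSpec(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(type(o))
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; return the manifest (also written to the output dir).

    Any stage error aborts with the stage name; outputs of completed stages
    are preserved on disk.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    outputs: list[Path] = []
    manifest: dict = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "versions": {"cereplaq": _pkg_version, "numpy": np.__version__},
        "stages": timings,
        "counts": {},
    }
    stage = "input"
    try:
        t0 = time.perf_counter()
        gt = None
        if config.phantom_spec is not None:
            spec = dataclasses.replace(
                config.phantom_spec, seed=derive_seed(config.seed, "phantom")
            )
            volume, gt = phantom.generate_phantom(spec)
            write_volume(volume, out / "volume.h5", format="hdf5")
            gt.records_frame().to_csv(out / "ground_truth.csv", index=False)
            seeds = phantom.ground_truth_seeds(gt)
            write_seed_rois(seeds, out / "seeds.csv")
            outputs += [out / "volume.h5", out / "ground_truth.csv", out / "seeds.csv"]
        else:
            volume = read_volume(config.volume_path, voxel_size_um=config.voxel_size_um)
            seeds = (read_seed_rois(config.seeds_path, volume.shape)
                     if config.seeds_path else [])
        timings[stage] = time.perf_counter() - t0

        stage = "segment"
        t0 = time.perf_counter()
        if seeds:
            voi = segmentation.build_voi_mask(seeds, volume)
            thr = segmentation.find_bimodal_threshold(volume, voi)
            plaque_labels = segmentation.extract_plaques(
                volume, voi, thr.threshold,
                min_volume_um3=config.min_volume_um3,
                connectivity=config.connectivity,
                max_gray=config.max_gray,
            )
            (out / "threshold.json").write_text(json.dumps(thr.to_dict(), indent=2))
            outputs.append(out / "threshold.json")
        else:
            log.warning("no seeds: skipping plaque segmentation")
            voi = None
            plaque_labels = LabelMap(
                np.zeros(volume.shape, dtype=np.int32), volume.voxel_size_um
            )
        write_label_map(plaque_labels, out / "plaque_labels.tif")
        outputs.append(out / "plaque_labels.tif")
        timings[stage] = time.perf_counter() - t0

        stage = "purkinje"
        t0 = time.perf_counter()
        blob = purkinje.hessian_blobness(volume, config.purkinje_scales_um)
        purkinje_labels = purkinje.detect_purkinje(
            blob, volume, threshold=config.purkinje_threshold,
            diameter_range_um=config.purkinje_diameter_um,
        )
        write_label_map(purkinje_labels, out / "purkinje_labels.tif")
        outputs.append(out / "purkinje_labels.tif")
        timings[stage] = time.perf_counter() - t0

        stage = "measure"
        t0 = time.perf_counter()
        regions = _label_regions(plaque_labels, voi, seeds)
        plaque_records = morphometry.measure_all(
            plaque_labels, volume, object_class="plaque", regions=regions
        )
        purkinje_records = morphometry.measure_all(
            purkinje_labels, volume, object_class="purkinje"
        )
        records = plaque_records + purkinje_records
        morphometry.write_records(records, out / "morphometry.csv")
        outputs.append(out / "morphometry.csv")
        manifest["counts"] = {
            "plaques": len(plaque_records),
            "purkinje": len(purkinje_records),
        }
        timings[stage] = time.perf_counter() - t0

        stage = "stats"
        t0 = time.perf_counter()
        report = _stats_report(plaque_records, purkinje_records, config)
        (out / "stats.json").write_text(json.dumps(report, indent=2))
        outputs.append(out / "stats.json")
        timings[stage] = time.perf_counter() - t0

        stage = "mip"
        t0 = time.perf_counter()
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        for plane in ("coronal", "sagittal", "transverse"):
            img = phantom.render_mip(volume, plane, config.mip_thickness_um, 0.0)
            p = out / f"mip_{plane}.png"
            plt.imsave(p, img, cmap="gray")
            outputs.append(p)
        timings[stage] = time.perf_counter() - t0
    except CereplaqError as exc:
        raise CereplaqError(f"stage '{stage}' failed: {exc}") from exc

    manifest["files"] = {p.name: _sha256(p) for p in outputs}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _label_regions(plaque_labels: LabelMap, voi, seeds) -> dict[int, str]:
    """Region tag per label: the region of the seed claiming its centroid."""
    regions: dict[int, str] = {}
    if voi is None or voi.provenance is None:
        return regions
    lab = plaque_labels.labels
    for oid in plaque_labels.ids():
        idx = np.nonzero(lab == oid)
        ci = tuple(int(round(a.mean())) for a in idx)
        si = int(voi.provenance[ci])
        if 0 <= si < len(seeds):
            regions[int(oid)] = seeds[si].region_tag
        elif idx[0].size:  # centroid outside any cylinder: majority vote
            provs = voi.provenance[idx]
            provs = provs[provs >= 0]
            if provs.size:
                regions[int(oid)] = seeds[int(np.bincount(provs).argmax())].region_tag
    return regions


def _stats_report(plaque_records, purkinje_records, config: PipelineConfig) -> dict:
    report: dict = {"warnings": [], "notes": {
        "surface_estimator": ("coarea gradient integral of the Gaussian-smoothed "
                              "mask indicator, sigma = clip(inradius/8, 0.5, 1.2) voxels"),
        "group_test": "two-sided Mann-Whitney U (exact enumeration when both n <= 8)",
    }}
    p_sph = [r.sphericity for r in plaque_records]
    k_sph = [r.sphericity for r in purkinje_records]
    if p_sph:
        s = stats.summarize(p_sph)
        report["plaque_sphericity"] = s.to_dict()
        report["plaque_volume"] = stats.summarize(
            [r.volume_um3 for r in plaque_records]).to_dict()
        if len(plaque_records) >= 10:
            report["lognormal_check"] = stats.lognormal_check(
                [r.volume_um3 for r in plaque_records]).to_dict()
        elongated = stats.select_elongated(plaque_records, s)
        report["n_elongated"] = len(elongated)
        osumm = stats.orientation_summary(
            elongated, hist_bin_deg=config.orient_hist_bin_deg)
        report["orientation"] = {k: v.to_dict() for k, v in osumm.items()}
    else:
        report["warnings"].append("no plaque records; plaque statistics skipped")
    if k_sph:
        report["purkinje_sphericity"] = stats.summarize(k_sph).to_dict()
    else:
        report["warnings"].append("no purkinje records")
    if len(p_sph) >= 3 and len(k_sph) >= 3:
        u, p = stats.compare_groups(p_sph, k_sph)
        report["sphericity_group_test"] = {"U": u, "p_value": p}
    return report


def verify_manifest(out_dir: str | Path) -> bool:
    """Re-hash every file listed in a run manifest; True iff all match."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    return all(
        _sha256(out / name) == digest for name, digest in manifest["files"].items()
    )
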