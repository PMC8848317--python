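"""Batch pipeline: configuration and unsupervised end-to-end runs.

The pipeline runs read → [median] → [z-drop] → resample → [Gaussian] →
binarize → [close] → [islands] → skeletonize → graph build/reduce/clean/
smooth → assemble → measure → export.  Optional steps are switched by the
config; with every optional step off the image passes through conditioning
untouched, so the tool works on raw as well as pre-processed input.  Each
stage is logged with its parameters and timing, and a run is deterministic
given the config and input.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import graphnet, io_formats, preprocess, segmentation, skeletonize
from .morphometry import Network, network_summary

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "dump_config"]

log = logging.getLogger("nettrace3d")


@dataclass
class PipelineConfig:
    """Every switch and parameter of the reconstruction pipeline.

    Keys mirror the config-file layout: the file is a YAML mapping of dotted
    keys (``preprocess.median.enabled: true``); unknown keys are rejected.
    """

    input_path: str = ""
    output_dir: str = "."
    channel: int | None = None
    voxel_size: tuple[float, float, float] | None = None   # override, μm
    seed: int = 0

    median_enabled: bool = False
    median_size: int = 3
    zdrop_enabled: bool = False
    resample_target_edge: float | None = None
    gaussian_enabled: bool = False
    gaussian_sigma: float = 2.0

    threshold_method: str = "otsu"
    threshold_percentage: float = 50.0
    close_iterations: int = 0
    min_island_um3: float = 0.0

    algorithm: str = "thinning"
    teasar_scale: float = 1.5
    teasar_const: float = 3.0
    min_edge_voxels: int = 6
    points_per_voxel: float = 0.1
    min_points: int = 5
    spline_smoothing: float = 0.5


_KEY_MAP = {
    "input.path": "input_path",
    "output.dir": "output_dir",
    "input.channel": "channel",
    "input.voxel_size": "voxel_size",
    "seed": "seed",
    "preprocess.median.enabled": "median_enabled",
    "preprocess.median.size": "median_size",
    "preprocess.zdrop.enabled": "zdrop_enabled",
    "preprocess.resample.target_edge": "resample_target_edge",
    "preprocess.gaussian.enabled": "gaussian_enabled",
    "preprocess.gaussian.sigma": "gaussian_sigma",
    "segmentation.method": "threshold_method",
    "segmentation.percentage": "threshold_percentage",
    "segmentation.close_iterations": "close_iterations",
    "segmentation.min_island_um3": "min_island_um3",
    "reconstruct.algorithm": "algorithm",
    "reconstruct.teasar.scale": "teasar_scale",
    "reconstruct.teasar.const": "teasar_const",
    "reconstruct.min_edge_voxels": "min_edge_voxels",
    "reconstruct.points_per_voxel": "points_per_voxel",
    "reconstruct.min_points": "min_points",
    "reconstruct.spline_smoothing": "spline_smoothing",
}
_FIELD_MAP = {v: k for k, v in _KEY_MAP.items()}


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config of dotted keys; unknown keys raise ValueError."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    kwargs = {}
    for key, value in raw.items():
        if key not in _KEY_MAP:
            raise ValueError(f"unknown config key {key!r}")
        if key == "input.voxel_size" and value is not None:
            value = tuple(float(v) for v in value)
        kwargs[_KEY_MAP[key]] = value
    return PipelineConfig(**kwargs)


def dump_config(config: PipelineConfig, path: str | Path) -> Path:
    """Write the config as a YAML mapping of dotted keys (round-trips)."""
    out = {}
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if isinstance(value, tuple):
            value = list(value)
        out[_FIELD_MAP[f.name]] = value
    path = Path(path)
    path.write_text(yaml.safe_dump(out, sort_keys=True))
    return path


class _Stage:
    """Context manager logging a pipeline stage with parameters and timing."""

    def __init__(self, name: str, **params):
        self.name = name
        self.params = params

    def __enter__(self):
        pretty = ", ".join(f"{k}={v}" for k, v in self.params.items())
        log.info("stage %-12s start %s", self.name, pretty)
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            log.info("stage %-12s done in %.2f s", self.name, dt)
        else:
            log.error("stage %-12s FAILED after %.2f s: %s", self.name, dt,
                      exc)
        return False


def run_pipeline(config: PipelineConfig,
                 stack: io_formats.ImageStack | None = None,
                 export: bool = True) -> tuple[Network, dict]:
    """Run the full reconstruction pipeline and return (network, summary).

    ``stack`` short-circuits the read stage for in-memory input; otherwise
    ``config.input_path`` is loaded.  With ``export`` the network (swc,
    mv3d, csv) and the summary (json) are written into ``config.output_dir``.
    """
    if stack is None:
        with _Stage("read", path=config.input_path):
            stack = io_formats.read_stack(
                config.input_path, voxel_size_override=config.voxel_size,
                channel=config.channel)

    if config.median_enabled:
        with _Stage("median", size=config.median_size):
            stack = preprocess.median_filter(stack, config.median_size)
    if config.zdrop_enabled:
        with _Stage("zdrop"):
            fit = preprocess.fit_attenuation(stack)
            log.info("attenuation fit: a=%.4g b=%.5g 1/um", fit.a, fit.b)
            stack = preprocess.correct_attenuation(stack, fit)
    with _Stage("resample", target=config.resample_target_edge):
        stack = preprocess.resample_isotropic(stack,
                                              config.resample_target_edge)
    if config.gaussian_enabled:
        with _Stage("gaussian", sigma=config.gaussian_sigma):
            stack = preprocess.gaussian_smooth(stack, config.gaussian_sigma)

    with _Stage("binarize", method=config.threshold_method):
        threshold = segmentation.compute_threshold(
            stack, config.threshold_method,
            config.threshold_percentage
            if config.threshold_method == "percentage" else None)
        log.info("threshold: %.4g", threshold)
        binary = segmentation.binarize(stack, threshold)
    if config.close_iterations:
        with _Stage("close", iterations=config.close_iterations):
            binary = segmentation.morphological_close(
                binary, config.close_iterations)
    if config.min_island_um3:
        with _Stage("islands", min_um3=config.min_island_um3):
            binary = segmentation.remove_islands(binary,
                                                 config.min_island_um3)

    with _Stage("skeletonize", algorithm=config.algorithm):
        if config.algorithm == "thinning":
            skeleton = skeletonize.thin(binary)
        elif config.algorithm == "teasar":
            skeleton = skeletonize.teasar_skeletonize(
                binary, config.teasar_scale, config.teasar_const)
        else:
            raise ValueError(f"unknown algorithm {config.algorithm!r}")

    with _Stage("graph"):
        graph = graphnet.build_voxel_graph(skeleton)
        reduced = graphnet.reduce_graph(graph)
        cleaned = graphnet.clean_graph(reduced, config.min_edge_voxels)
        segments = graphnet.smooth_paths(
            cleaned, config.points_per_voxel, config.min_points,
            config.spline_smoothing)
        network = graphnet.assemble_network(
            segments, voxel_size=binary.voxel_size[0],
            metadata={
                "source": stack.source or config.input_path,
                "algorithm": config.algorithm,
                "config": {k: getattr(config, v)
                           for k, v in _KEY_MAP.items()},
            })

    with _Stage("measure"):
        summary = network_summary(network)

    if export:
        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with _Stage("export", dir=str(out_dir)):
            if network.segments:
                try:
                    io_formats.write_network(network,
                                             out_dir / "network.swc")
                except ValueError as exc:
                    # looped networks are legitimate but SWC is a forest
                    log.warning("skipping SWC export: %s", exc)
                io_formats.write_network(network, out_dir / "network.mv3d")
            io_formats.export_summary(network, out_dir / "summary.json")
            io_formats.export_summary(network, out_dir / "segments.csv",
                                      format="csv")
    return network, summary
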