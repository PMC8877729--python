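"""End-to-end orchestration with a single validated configuration.

Stage order is fixed: deconvolve → background subtraction → static
thresholding → nuclear segmentation → constrained cell growth → surrogate
cells → anucleate rescue → cytoplasm derivation → per-cell measurement →
positivity calling → glial screen → normalization/quintiles.  A run manifest
echoes the exact resolved configuration so any output is reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import RoiSpec
from .imaging import (
    MultiChannelStack,
    read_stack,
    write_cell_table,
    write_label_volume,
    extract_roi,
)
from .preprocessing import (
    BackgroundParams,
    ChannelThresholds,
    DeconvolutionParams,
    binarize,
    deconvolve,
    subtract_background,
)
from .quantify import (
    ScreeningParams,
    assign_volume_quintiles,
    classify_positivity,
    measure_cells,
    normalize_pcjun,
    screen_glia,
)
from .segmentation import (
    SegmentationParams,
    derive_cytoplasm,
    grow_cell_masks,
    nuclei_without_signal,
    segment_anucleate_cells,
    segment_nuclei,
    surrogate_cell_masks,
)

__all__ = ["RunConfig", "PipelineResult", "process_stack", "run_pipeline"]


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run.

    ``thresholds`` is mandatory — static per-channel thresholds are an
    experiment-wide setting, never inferred silently.  All other stage
    blocks carry their documented defaults.
    """

    thresholds: ChannelThresholds
    stack_path: str | None = None
    channel_map: dict[str, int] | None = None
    voxel_size_um: tuple[float, float, float] | None = None
    roi: RoiSpec | None = None
    deconvolution: DeconvolutionParams = field(default_factory=DeconvolutionParams)
    background: BackgroundParams = field(default_factory=BackgroundParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    screening: ScreeningParams = field(default_factory=ScreeningParams)
    animal_id: str = "A1"
    group: str = "SH"
    section: str = "s1"
    normalize_pcjun_to_threshold: bool = True
    assign_quintiles: bool = False
    seed: int = 0
    output_dir: str = "somaquant_out"
    save_intermediates: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "thresholds" not in raw:
            raise ValueError("config must define per-channel 'thresholds'")
        kwargs: dict = {"thresholds": ChannelThresholds(**raw["thresholds"])}
        inp = raw.get("input", {})
        kwargs["stack_path"] = inp.get("stack")
        kwargs["channel_map"] = inp.get("channel_map")
        if inp.get("voxel_size_um") is not None:
            kwargs["voxel_size_um"] = tuple(inp["voxel_size_um"])
        if raw.get("roi", {}).get("enabled", False):
            roi = {k: v for k, v in raw["roi"].items() if k != "enabled"}
            kwargs["roi"] = RoiSpec(**roi)
        for key, cls_ in (
            ("deconvolution", DeconvolutionParams),
            ("background", BackgroundParams),
            ("segmentation", SegmentationParams),
            ("screening", ScreeningParams),
        ):
            if key in raw:
                kwargs[key] = cls_(**raw[key])
        ident = raw.get("identity", {})
        for key in ("animal_id", "group", "section"):
            if key in ident:
                kwargs[key] = ident[key]
        for key in (
            "normalize_pcjun_to_threshold",
            "assign_quintiles",
            "seed",
            "output_dir",
            "save_intermediates",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = {
            "thresholds": self.thresholds.as_dict(),
            "input": {
                "stack": self.stack_path,
                "channel_map": self.channel_map,
                "voxel_size_um": list(self.voxel_size_um) if self.voxel_size_um else None,
            },
            "roi": (
                {"enabled": True, **dataclasses.asdict(self.roi)}
                if self.roi is not None
                else {"enabled": False}
            ),
            "deconvolution": dataclasses.asdict(self.deconvolution),
            "background": dataclasses.asdict(self.background),
            "segmentation": dataclasses.asdict(self.segmentation),
            "screening": dataclasses.asdict(self.screening),
            "identity": {
                "animal_id": self.animal_id,
                "group": self.group,
                "section": self.section,
            },
            "normalize_pcjun_to_threshold": self.normalize_pcjun_to_threshold,
            "assign_quintiles": self.assign_quintiles,
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "save_intermediates": self.save_intermediates,
        }
        return d


@dataclass
class PipelineResult:
    """Everything a run produces, in memory."""

    all_cells: pd.DataFrame
    retained: pd.DataFrame
    excluded: pd.DataFrame
    screening_report: dict
    nuclei: np.ndarray
    cells: np.ndarray
    cytoplasm: np.ndarray
    log: list[str] = field(default_factory=list)


def process_stack(stack: MultiChannelStack, config: RunConfig) -> PipelineResult:
    """Run all analysis stages on an in-memory stack."""
    log: list[str] = []
    if config.roi is not None:
        stack = extract_roi(stack, config.roi)
        log.append(f"roi: cropped to {stack.grid.shape}")

    stack = deconvolve(stack, config.deconvolution)
    log.append(
        "deconvolution: "
        + ("applied" if config.deconvolution.enabled else "skipped")
    )

    masks: dict[str, np.ndarray] = {}
    retained: dict[str, np.ndarray] = {}
    for name, arr in stack.channels.items():
        flattened = subtract_background(arr, config.background)
        mask, kept = binarize(flattened, config.thresholds[name])
        masks[name], retained[name] = mask, kept
        log.append(
            f"channel {name}: threshold {config.thresholds[name]:g}, "
            f"{int(mask.sum())} positive voxels"
        )

    seg = config.segmentation
    nuclei = segment_nuclei(masks["draq5"], seg)
    log.append(f"nuclei: {int(nuclei.max())} objects")

    cell_signal = masks["neurotrace"] | masks["neun"]
    cells = grow_cell_masks(nuclei, cell_signal, seg)

    surrogate_ids = nuclei_without_signal(nuclei, cells, cell_signal)
    if len(surrogate_ids):
        surrogates = surrogate_cell_masks(nuclei, surrogate_ids, cells, seg)
        cells = np.where(surrogates > 0, surrogates, cells)
    log.append(f"surrogate cells: {len(surrogate_ids)}")

    anucleate = segment_anucleate_cells(masks["neurotrace"], cells, seg)
    n_anucleate = int(len(np.unique(anucleate))) - 1
    cells = np.where(anucleate > 0, anucleate, cells)
    log.append(f"anucleate rescue: {n_anucleate} cells")

    cytoplasm = derive_cytoplasm(cells, nuclei)

    table = measure_cells(
        cells,
        nuclei,
        cytoplasm,
        {m: retained[m] for m in ("neurotrace", "neun", "pcjun")},
        stack.grid,
        animal_id=config.animal_id,
        group=config.group,
        section=config.section,
    )
    table = classify_positivity(table, config.thresholds)
    log.append(f"measured {len(table)} cells")

    kept, dropped, report = screen_glia(table, config.screening)
    log.append(
        f"screen: kept {report['n_retained']} / {report['n_input']} "
        f"(volume cut {report['volume_threshold_um3']:.2f} um^3)"
    )
    if config.normalize_pcjun_to_threshold:
        kept = normalize_pcjun(kept, config.thresholds)
    if config.assign_quintiles:
        kept = assign_volume_quintiles(kept)
    return PipelineResult(
        all_cells=table,
        retained=kept,
        excluded=dropped,
        screening_report=report,
        nuclei=nuclei,
        cells=cells,
        cytoplasm=cytoplasm,
        log=log,
    )


def run_pipeline(
    config: RunConfig, stack: MultiChannelStack | None = None
) -> PipelineResult:
    """File-level pipeline run: read, process, persist, manifest.

    Validation happens before any computation; rerunning with the same
    configuration and inputs reproduces all tables.
    """
    if stack is None:
        if config.stack_path is None:
            raise ValueError("config.stack_path is required when no stack is passed")
        stack = read_stack(
            config.stack_path,
            channel_map=config.channel_map,
            voxel_size_um=config.voxel_size_um,
        )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = process_stack(stack, config)
    write_cell_table(result.all_cells, out / "cells_all.csv")
    write_cell_table(result.retained, out / "cells_retained.csv")
    write_cell_table(result.excluded, out / "cells_excluded.csv")
    with open(out / "screening_report.yaml", "w") as fh:
        yaml.safe_dump(result.screening_report, fh, sort_keys=False)
    if config.save_intermediates:
        write_label_volume(result.nuclei, out / "nuclei_labels.tif", stack.grid)
        write_label_volume(result.cells, out / "cell_labels.tif", stack.grid)
        write_label_volume(result.cytoplasm, out / "cytoplasm_labels.tif", stack.grid)
    manifest = {
        "software": {"name": "somaquant", "version": __version__},
        "config": config.to_dict(),
        "log": result.log,
    }
    with open(out / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return result
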