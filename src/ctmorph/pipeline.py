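"""End-to-end orchestration: phantom/volume -> segmentation -> summary.

Presets bundle the per-tissue analysis settings (VOI edge length, debris
filter, porosity) for the three fruit tissue types; group statistics are
independent two-sample t tests across replicate VOIs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from scipy import stats

from .core import VolumeImage
from .morphometry import (
    AnalysisSummary,
    CellRecord,
    VOISpec,
    extract_voi,
    measure_labels,
    percent_increase,
    sem,
    summarize_voi,
)
from .phantom import PRESET_POROSITY, PhantomSpec, generate_tissue
from .segmentation import (
    FilterSpec,
    SegmentationParams,
    SegmentationResult,
    segment_cells,
)
from . import volume_io

log = logging.getLogger(__name__)

#: Per-tissue presets: VOI edge (µm), debris filter, porosity preset.
PRESETS: dict[str, dict[str, Any]] = {
    "apple": {
        "voi_edge_um": 2400.0,
        "filter": FilterSpec(d_min=40.0, d_max=200.0, sphericity_min=0.75),
        "porosity": PRESET_POROSITY["apple"],
    },
    "pear": {
        "voi_edge_um": 2400.0,
        # no lower diameter filter: stone-cell neighbourhoods would be lost
        "filter": FilterSpec(d_min=None, d_max=200.0, sphericity_min=0.75),
        "porosity": PRESET_POROSITY["pear"],
    },
    "tomato": {
        "voi_edge_um": 2000.0,
        "filter": FilterSpec(d_min=100.0, d_max=None, sphericity_min=0.75),
        "porosity": PRESET_POROSITY["tomato"],
    },
}

#: Alternative debris minima (µm) stated elsewhere in the source workflow;
#: selectable via RunConfig but never applied silently.
ALT_DEBRIS_MIN_UM = {"apple": 40.0, "tomato": 80.0}


@dataclass
class RunConfig:
    """Fully resolved parameters of one analysis run."""

    mode: str = "enhanced"  # control | enhanced
    preset: str = "custom"  # apple | pear | tomato | custom
    input_path: str | None = None
    phantom: PhantomSpec | None = None
    voi: VOISpec | None = None  # None = analyze the full volume
    filters: FilterSpec = field(default_factory=FilterSpec)
    params: SegmentationParams = field(default_factory=SegmentationParams)
    recover_before_filter: bool = False
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("control", "enhanced"):
            raise ValueError("mode must be 'control' or 'enhanced'")
        if self.preset not in ("apple", "pear", "tomato", "custom"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.preset != "custom":
            # explicit fields win; the preset fills whatever was left default
            if self.filters == FilterSpec():
                self.filters = PRESETS[self.preset]["filter"]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def config_from_yaml(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML mapping (nested sections by field name)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict[str, Any] = {}
    for key in ("mode", "preset", "input_path", "seed", "output_dir",
                "recover_before_filter"):
        if key in raw:
            kwargs[key] = raw[key]
    if "phantom" in raw:
        ph = dict(raw["phantom"])
        if "shape" in ph:
            ph["shape"] = tuple(ph["shape"])
        kwargs["phantom"] = PhantomSpec(**ph)
    if "voi" in raw:
        kwargs["voi"] = VOISpec(
            origin=tuple(raw["voi"]["origin"]),
            edge_lengths=tuple(raw["voi"]["edge_lengths"]),
        )
    if "filters" in raw:
        kwargs["filters"] = FilterSpec(**raw["filters"])
    if "params" in raw:
        kwargs["params"] = SegmentationParams(**raw["params"])
    return RunConfig(**kwargs)


@dataclass
class RunResult:
    summary: AnalysisSummary
    segmentation: SegmentationResult
    volume: VolumeImage
    config: RunConfig


def _load_input(config: RunConfig) -> VolumeImage:
    if (config.input_path is None) == (config.phantom is None):
        raise ValueError("exactly one of input_path or phantom must be set")
    if config.input_path is not None:
        vol = volume_io.read_volume(config.input_path)
        if vol.bit_depth > 8:
            vol = volume_io.rescale_to_8bit(vol)
        return vol
    spec = config.phantom
    if config.preset != "custom" and spec.target_porosity != PRESETS[config.preset][
        "porosity"
    ]:
        log.info(
            "phantom porosity %.2f overrides preset %.2f",
            spec.target_porosity,
            PRESETS[config.preset]["porosity"],
        )
    spec = dataclasses.replace(spec, contrast_mode=(config.mode == "enhanced"))
    return generate_tissue(spec).greyscale


def run_analysis(config: RunConfig) -> RunResult:
    """Execute the full stage chain for one VOI and summarize it.

    Any stage failure aborts with the stage named in the exception. When
    ``output_dir`` is set, the label volume, cell table, summary and the
    resolved config are written there.
    """
    stage = "load_input"
    try:
        volume = _load_input(config)
        if config.voi is not None:
            stage = "extract_voi"
            volume = extract_voi(volume, config.voi)
        stage = "segment"
        seg = segment_cells(
            volume,
            mode=config.mode,
            filter_spec=config.filters,
            params=config.params,
            recover_before_filter=config.recover_before_filter,
        )
        stage = "summarize"
        voi_volume = volume.data.size * volume.voxel_volume
        structure_records = [
            CellRecord(
                label_id=s.structure_id,
                volume=s.volume,
                equivalent_diameter=(6 * s.volume / math.pi) ** (1 / 3),
                surface_area=float("nan"),
                sphericity=float("nan"),
                anisotropy=s.anisotropy,
                centroid=(0.0, 0.0, 0.0),
                structure_class=s.structure_class,
            )
            for s in seg.structures
        ]
        summary = summarize_voi(
            seg.borderkilled_cells, seg.cells, structure_records, voi_volume
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline aborted at stage '{stage}': {exc}") from exc

    result = RunResult(summary=summary, segmentation=seg, volume=volume, config=config)
    if config.output_dir is not None:
        _write_artifacts(result)
    return result


def _write_artifacts(result: RunResult) -> None:
    out = Path(result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    volume_io.write_volume(
        VolumeImage(
            result.segmentation.labels.astype(np.uint16),
            voxel_size=result.volume.voxel_size,
            bit_depth=16,
        ),
        out / "labels.tif",
    )
    volume_io.write_cell_table(result.segmentation.cells, out / "cells.csv")
    (out / "summary.json").write_text(
        json.dumps(dataclasses.asdict(result.summary), indent=2)
    )
    (out / "stage_log.json").write_text(
        json.dumps(result.segmentation.stage_log, indent=2, default=str)
    )
    (out / "config.json").write_text(
        json.dumps(result.config.to_dict(), indent=2, default=str)
    )


def run_replicates(
    base_config: RunConfig, seeds: list[int]
) -> list[AnalysisSummary]:
    """Run one phantom analysis per seed (replicate VOIs)."""
    if base_config.phantom is None:
        raise ValueError("replicate runs require a phantom spec")
    summaries = []
    for s in seeds:
        cfg = dataclasses.replace(
            base_config,
            phantom=dataclasses.replace(base_config.phantom, random_seed=s),
            seed=s,
            output_dir=(
                str(Path(base_config.output_dir) / f"seed_{s}")
                if base_config.output_dir
                else None
            ),
        )
        summaries.append(run_analysis(cfg).summary)
    return summaries


SUMMARY_FIELDS = (
    "borderkilled_cell_volume_pct",
    "filtered_cell_volume_pct",
    "structures_volume_pct",
    "cell_count",
    "mean_equivalent_diameter",
    "mean_anisotropy",
)


def aggregate_summaries(summaries: list[AnalysisSummary]) -> dict:
    """Group mean and SEM per summary field across replicate VOIs."""
    out: dict[str, dict[str, float | None]] = {}
    for f in SUMMARY_FIELDS:
        vals = [float(getattr(s, f)) for s in summaries]
        out[f] = {"mean": float(np.mean(vals)), "sem": sem(vals), "n": len(vals)}
    return out


def table2_report(
    control: list[AnalysisSummary], enhanced: list[AnalysisSummary]
) -> dict:
    """Control-vs-enhanced report with the summary-table column structure.

    Percent increases are computed on the group means of the filtered
    cell volume fraction and cell count.
    """
    ctrl = aggregate_summaries(control)
    enh = aggregate_summaries(enhanced)
    report = {"control": ctrl, "enhanced": enh, "pct_increase": {}}
    for f in ("filtered_cell_volume_pct", "cell_count"):
        c, e = ctrl[f]["mean"], enh[f]["mean"]
        report["pct_increase"][f] = percent_increase(c, e) if c > 0 else None
    return report


@dataclass
class GroupComparison:
    """Two-sample t test on one summary field across two groups."""

    field: str
    control_mean: float
    enhanced_mean: float
    control_sem: float | None
    enhanced_sem: float | None
    t_statistic: float
    p_value: float
    significant: bool  # p < 0.05
    pct_increase: float | None


def compare_groups(
    control: list[AnalysisSummary],
    enhanced: list[AnalysisSummary],
    field_name: str,
    welch: bool = False,
) -> GroupComparison:
    """Independent t test (pooled variance by default, Welch by flag)."""
    if len(control) < 2 or len(enhanced) < 2:
        raise ValueError("need at least 2 replicates per group")
    a = np.array([float(getattr(s, field_name)) for s in control])
    b = np.array([float(getattr(s, field_name)) for s in enhanced])
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate: identical-variance-free groups
        if a.mean() == b.mean():
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = math.inf if b.mean() > a.mean() else -math.inf, 0.0
    else:
        t_stat, p = stats.ttest_ind(b, a, equal_var=not welch)
        t_stat, p = float(t_stat), float(p)
    return GroupComparison(
        field=field_name,
        control_mean=float(a.mean()),
        enhanced_mean=float(b.mean()),
        control_sem=sem(a),
        enhanced_sem=sem(b),
        t_statistic=t_stat,
        p_value=p,
        significant=bool(p < 0.05),
        pct_increase=percent_increase(a.mean(), b.mean()) if a.mean() > 0 else None,
    )


__all__ = [
    "PRESETS",
    "ALT_DEBRIS_MIN_UM",
    "RunConfig",
    "RunResult",
    "GroupComparison",
    "config_from_yaml",
    "run_analysis",
    "run_replicates",
    "aggregate_summaries",
    "table2_report",
    "compare_groups",
    "SUMMARY_FIELDS",
]
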