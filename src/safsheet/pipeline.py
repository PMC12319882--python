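"""End-to-end analysis pipeline and its parameter bundle.

Stages run in the standard narrative order: (optional) SNR + smoothing of
the retinotopic maps, V1/V2 overlap resolution, V1-V2 streamline selection,
length filter, deep-white-matter exclusion, intracortical filter, geometry
metrics, sheet model, retinotopy projection, topographic clustering, group
summaries.  Every stage logs its input/output streamline counts and the
bookkeeping conserves streamlines (input = kept + removed at every stage).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CorticalLabel,
    SurfaceMesh,
    Tractogram,
    ValidationError,
    VertexScalarMap,
    write_report,
)
from .projection_topography import (
    ProjectionParams,
    TopographicClustering,
    band_labels,
    cluster_by_band,
    project_retinotopy,
    topographic_order_index,
)
from .retinotopy import (
    FMRITimeSeries,
    ReliabilityParams,
    compute_snr,
    reliable_mask,
    resolve_label_overlap,
    smooth_vertex_map,
)
from .sheet_analysis import SheetModel
from .streamline_metrics import (
    SelectionParams,
    compute_geometry,
    deep_wm_exclusion,
    intracortical_filter,
    length_filter,
    select_connecting,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisParams", "PipelineResult", "run_pipeline"]


@dataclass
class AnalysisParams:
    """Union of all stage parameters with in vivo / post mortem presets."""

    reliability: ReliabilityParams = field(default_factory=ReliabilityParams)
    selection: SelectionParams = field(default_factory=SelectionParams)
    projection: ProjectionParams = field(default_factory=ProjectionParams)
    surface_degree: int = 2
    sheet_ratio: float = 3.0
    sheet_comparable: float = 3.0
    n_ecc_bands: int = 6
    n_polar_bands: int = 15
    label_tolerance: float = 1.0
    preset: str = "invivo"

    @classmethod
    def from_preset(cls, name: str) -> "AnalysisParams":
        return cls(selection=SelectionParams.preset(name), preset=name)

    def echo(self) -> None:
        logger.info("analysis parameters: %s", self)


@dataclass
class PipelineResult:
    """Everything the pipeline produced, plus stage bookkeeping."""

    stage_log: pd.DataFrame
    geometry: pd.DataFrame
    sheet: SheetModel | None
    projection: np.recarray | None
    clusterings: dict[str, TopographicClustering]
    summary: dict
    selected: Tractogram

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(self.stage_log, out / "stage_log.tsv")
        if len(self.geometry):
            write_report(self.geometry, out / "streamline_geometry.tsv")
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, default=float)
        if self.sheet is not None:
            with open(out / "sheet_model.json", "w") as fh:
                json.dump(self.sheet.to_dict(), fh, indent=2)


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) == 0:
        return float("nan"), float("nan")
    return float(np.mean(values)), float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


def run_pipeline(
    tractogram: Tractogram,
    white: SurfaceMesh,
    pial: SurfaceMesh,
    eccentricity: VertexScalarMap,
    polar_angle: VertexScalarMap,
    v1: CorticalLabel,
    v2: CorticalLabel,
    params: AnalysisParams | None = None,
    timeseries: FMRITimeSeries | None = None,
    v1_probability: dict | np.ndarray | None = None,
) -> PipelineResult:
    """Run the full SAF analysis on one subject's inputs.

    When ``timeseries`` is given, the maps are first masked by the SNR
    reliability threshold and smoothed on the mesh; when the labels are
    voxel-based and overlap, ``v1_probability`` resolves the overlap.
    """
    params = params or AnalysisParams()
    params.echo()
    stages: list[dict] = []

    def log_stage(name: str, n_in: int, n_kept: int) -> None:
        stages.append(
            {"stage": name, "n_in": n_in, "n_kept": n_kept, "n_removed": n_in - n_kept}
        )
        logger.info("%s: %d -> %d streamlines", name, n_in, n_kept)

    # --- map conditioning -------------------------------------------------
    if timeseries is not None:
        snr = compute_snr(timeseries)
        mask = reliable_mask(snr, params.reliability)
        eccentricity = smooth_vertex_map(eccentricity, white, mask, params.reliability)
        polar_angle = smooth_vertex_map(polar_angle, white, mask, params.reliability)

    if (
        v1.voxels is not None
        and v2.voxels is not None
        and (v1.voxel_set() & v2.voxel_set())
    ):
        if v1_probability is None:
            raise ValidationError("overlapping voxel labels need a V1 probability map")
        v1, v2 = resolve_label_overlap(v1, v2, v1_probability)

    # --- streamline selection --------------------------------------------
    t = tractogram
    t, keep = select_connecting(t, v1, v2, mesh=white, tolerance=params.label_tolerance)
    log_stage("v1_v2_selection", len(keep), len(t))

    n_in = len(t)
    t, keep = length_filter(t, params.selection)
    log_stage("length_filter", n_in, len(t))

    n_in = len(t)
    t, keep = deep_wm_exclusion(t, white, params=params.selection)
    log_stage("deep_wm_exclusion", n_in, len(t))

    n_in = len(t)
    t, keep, icf = intracortical_filter(t, white, pial, params.selection)
    icf = icf[keep]
    log_stage("intracortical_filter", n_in, len(t))

    summary: dict = {
        "n_input": len(tractogram),
        "n_selected": len(t),
        "stage_counts": None,  # filled at the end
        "parameters": {
            "preset": params.preset,
            "min_length_mm": params.selection.min_length,
            "max_length_mm": params.selection.max_length,
            "intracortical_max_fraction": params.selection.intracortical_max_fraction,
            "deep_exclusion_depth_mm": params.selection.deep_exclusion_depth,
            "snr_threshold": params.reliability.snr_threshold,
            "smoothing_iterations": params.reliability.smoothing_iterations,
            "n_ecc_bands": params.n_ecc_bands,
            "n_polar_bands": params.n_polar_bands,
        },
    }

    if len(t) == 0:
        logger.warning("zero streamlines survived selection: empty result")
        summary.update(
            {
                "length_mm": (float("nan"), float("nan")),
                "bending_angle_deg": (float("nan"), float("nan")),
            }
        )
        summary["stage_counts"] = stages
        return PipelineResult(
            stage_log=pd.DataFrame(stages),
            geometry=pd.DataFrame(),
            sheet=None,
            projection=None,
            clusterings={},
            summary=summary,
            selected=t,
        )

    # --- geometry metrics -------------------------------------------------
    geoms = compute_geometry(t, params.selection)
    geometry = pd.DataFrame(
        {
            "index": [g.index for g in geoms],
            "length_mm": [g.length for g in geoms],
            "bending_angle_deg": [g.bending_angle for g in geoms],
            "apex_x": [g.apex_position[0] for g in geoms],
            "apex_y": [g.apex_position[1] for g in geoms],
            "apex_z": [g.apex_position[2] for g in geoms],
            "intracortical_fraction": icf,
            "degenerate": [g.degenerate for g in geoms],
        }
    )
    summary["length_mm"] = _mean_sd(geometry["length_mm"].to_numpy())
    summary["bending_angle_deg"] = _mean_sd(geometry["bending_angle_deg"].to_numpy())

    # --- sheet model --------------------------------------------------------
    sheet = None
    if len(t) >= 2:
        sheet = SheetModel.fit(
            t,
            degree=params.surface_degree,
            ratio=params.sheet_ratio,
            comparable=params.sheet_comparable,
        )
        summary["sheet_sizes_mm2"] = sheet.sizes.tolist()
        summary["sheet_classification"] = sheet.classification
        summary["sheet_residual_sd_mm"] = sheet.residual_sd

    # --- retinotopy projection ---------------------------------------------
    assignments, rec = project_retinotopy(
        t, white, eccentricity, polar_angle, v1, v2, params.projection,
        intracortical_fractions=icf,
    )
    log_stage("projection", len(t), int(rec.projected.sum()))
    summary["n_projected"] = int(rec.projected.sum())

    clusterings: dict[str, TopographicClustering] = {}
    proj = rec.projected
    if proj.sum() >= 3 and sheet is not None and v1.vertex_indices is not None:
        ends = np.full((len(t), 3), np.nan)
        v2_ends = np.full((len(t), 3), np.nan)
        for i in np.flatnonzero(proj):
            s = t.streamlines[i]
            ends[i] = s[0] if rec.v1_end[i] == 0 else s[-1]
            v2_ends[i] = s[-1] if rec.v1_end[i] == 0 else s[0]

        ecc_bands = band_labels(
            white, v1.vertex_indices, sheet.frame[0], params.n_ecc_bands, "eccentricity"
        )
        pol_bands = band_labels(
            white, v1.vertex_indices, sheet.frame[1], params.n_polar_bands, "polar_angle"
        )
        clusterings["eccentricity"] = cluster_by_band(
            t, ecc_bands, white, ends, direction="eccentricity"
        )
        clusterings["polar_angle"] = cluster_by_band(
            t, pol_bands, white, ends, direction="polar_angle"
        )

        # order: carried V1-end value vs the V2-end position along the axis
        pos_ecc = v2_ends @ sheet.frame[0]
        pos_pol = v2_ends @ sheet.frame[1]
        oi_ecc = topographic_order_index(rec.ecc_v1[proj], pos_ecc[proj])
        oi_pol = topographic_order_index(
            rec.pol_v1[proj], pos_pol[proj], circular=True
        )
        clusterings["eccentricity"].order_index = oi_ecc
        clusterings["polar_angle"].order_index = oi_pol
        summary["order_index_eccentricity"] = oi_ecc
        summary["order_index_polar_angle"] = oi_pol
        summary["cluster_occupancy_eccentricity"] = (
            clusterings["eccentricity"].occupancy().tolist()
        )
        summary["cluster_occupancy_polar_angle"] = (
            clusterings["polar_angle"].occupancy().tolist()
        )
        geometry["ecc_v1"] = rec.ecc_v1
        geometry["pol_v1"] = rec.pol_v1
        geometry["ecc_v2"] = rec.ecc_v2
        geometry["pol_v2"] = rec.pol_v2
        geometry["cluster_ecc"] = clusterings["eccentricity"].cluster_id
        geometry["cluster_pol"] = clusterings["polar_angle"].cluster_id

    summary["stage_counts"] = stages
    return PipelineResult(
        stage_log=pd.DataFrame(stages),
        geometry=geometry,
        sheet=sheet,
        projection=rec,
        clusterings=clusterings,
        summary=summary,
        selected=t,
    )
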