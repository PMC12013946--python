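"""End-to-end per-nucleus quantification.

Stage order per nucleus: rolling-ball background subtraction of both
channels -> nucleus and territory segmentation -> 3D volume fraction ->
mid-slice selection -> ellipse fit + ellipticity QC -> three-zone radial
fractions -> line-scan enrichment -> nuclear/background intensity ratio.

Background subtraction feeds segmentation and the zone assay only; the
line-scan enrichment E and the intensity ratio I are read from raw
intensities, matching how those two metrics are defined (the background
divides out of I and E is a within-nucleus contrast).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .background import subtract_background
from .linescan import enrichment_ratio, line_scan, mean_intensity_ratio
from .segmentation import segment_nucleus, segment_signal, select_mid_slice, volume_fraction
from .stacks import QuantResult, VoxelStack
from .zones import check_ellipticity, fit_ellipse, make_zones, zone_fractions

logger = logging.getLogger(__name__)


@dataclass
class QuantConfig:
    """Tunable knobs of the quantification pipeline."""

    rolling_ball_radius: float = 50.0
    threshold_method: str = "otsu"
    min_ellipse_overlap: float = 0.90
    smooth_profile: bool = True
    intensity_weighted_zones: bool = False


def quantify_nucleus(
    dapi: VoxelStack,
    signal: VoxelStack,
    nucleus_id: str = "nucleus",
    config: QuantConfig | None = None,
) -> QuantResult:
    """Run the full quantification on one two-channel nucleus stack.

    Nuclei failing the ellipticity QC keep their volumetric and intensity
    metrics but have zone fractions omitted (``None``), mirroring the
    exclusion of non-elliptical nuclei from the radial assay.
    """
    cfg = config or QuantConfig()
    if dapi.shape != signal.shape:
        raise ValueError("channels must be congruent")

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ValueError as err:
            raise ValueError(f"[{name}] {err}") from err

    dapi_sub = _stage("background", subtract_background, dapi, cfg.rolling_ball_radius)
    sig_sub = _stage("background", subtract_background, signal, cfg.rolling_ball_radius)

    nucleus = _stage("segment_nucleus", segment_nucleus, dapi_sub, cfg.threshold_method)
    terr = _stage("segment_signal", segment_signal, sig_sub, nucleus, cfg.threshold_method)
    v = _stage("volume_fraction", volume_fraction, terr, nucleus)

    z = _stage("select_mid_slice", select_mid_slice, sig_sub, nucleus)
    nuc_slice = nucleus.plane(z)
    terr_slice = terr.plane(z)

    ellipse = _stage("fit_ellipse", fit_ellipse, nuc_slice)
    qc_pass, qc_score = check_ellipticity(nuc_slice, ellipse, cfg.min_ellipse_overlap)

    zones_p = None
    if qc_pass:
        zones = _stage("make_zones", make_zones, ellipse, nuc_slice.shape)
        try:
            zones_p = zone_fractions(
                terr_slice,
                zones,
                intensities=sig_sub.plane(z) if cfg.intensity_weighted_zones else None,
            )
        except ValueError:
            logger.info("%s: no signal in zones at slice %d", nucleus_id, z)
            zones_p = None
    else:
        logger.info("%s: ellipticity QC failed (score %.3f); zone metrics excluded", nucleus_id, qc_score)

    profile = _stage("line_scan", line_scan, signal.plane(z), nuc_slice, terr_slice)
    e = _stage("enrichment_ratio", enrichment_ratio, profile, cfg.smooth_profile)
    i = _stage("mean_intensity_ratio", mean_intensity_ratio, signal, nucleus)

    return QuantResult(
        nucleus_id=nucleus_id,
        volume_fraction=v,
        zone_fractions=zones_p,
        enrichment_ratio=e,
        intensity_ratio=i,
        slice_used=z,
        qc_pass=qc_pass,
        qc_score=qc_score,
    )


def results_to_frame(results: list[QuantResult]) -> pd.DataFrame:
    """Tidy per-nucleus results table (one row per nucleus)."""
    rows = []
    for r in results:
        p = r.zone_fractions or (None, None, None)
        rows.append(
            {
                "nucleus_id": r.nucleus_id,
                "v": r.volume_fraction,
                "p_central": p[0],
                "p_mid": p[1],
                "p_periph": p[2],
                "E": r.enrichment_ratio,
                "I": r.intensity_ratio,
                "slice_used": r.slice_used,
                "qc_pass": r.qc_pass,
            }
        )
    return pd.DataFrame(rows)
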