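"""Per-image feature extraction: mask + optic disc -> F1..F5 and auxiliaries.

Composes the stages in method order: skeletonize, prune spurs, split into
segments, fit splines, measure tortuosity/curvature, sample calibers, and
compute vessel density, all inside the configured zones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.morphology import dilation, disk

from .caliber_density import (
    SegmentCaliber,
    mask_distance_transform,
    segment_diameter,
    vessel_density,
    zone_max_diameter,
)
from .core_io import BinaryMask, OpticDiscSpec, RunConfig, logger, make_5dd_zone
from .skeleton import extract_segments, junction_pixels, prune_spurs, skeletonize_mask
from .tortuosity import (
    arc_over_chord,
    assign_zone,
    curvature_profile,
    downsample_path,
    fit_spline,
    refine_centerline,
    tortuosity,
    tortuosity_features,
)

FEATURE_COLUMNS = ["F1", "F2", "F3", "F4", "F5"]
AUX_COLUMNS = [
    "aux_arc_over_chord_mean",
    "aux_T_mean",
    "aux_T_median",
    "aux_diameter_mean",
    "aux_segment_count",
]


def extract_image_features(
    mask: BinaryMask,
    disc: OpticDiscSpec,
    config: RunConfig | None = None,
    seed: int = 0,
    image_id: str = "",
) -> tuple[dict, pd.DataFrame]:
    """All image-level features plus the per-segment audit table.

    F2 and F4 are NaN (and the image flagged for exclusion downstream) when
    no segment lies in the 5DD zone.
    """
    cfg = config or RunConfig()
    skel = prune_spurs(skeletonize_mask(mask), int(cfg["skeleton.min_branch_len"]))
    paths = extract_segments(skel, int(cfg["skeleton.min_segment_len"]))
    if not paths:
        raise ValueError(f"{image_id or 'image'}: no usable vessel segment")
    zone = make_5dd_zone(disc, mask.shape)
    edt = mask_distance_transform(mask)

    junctions = junction_pixels(skel)
    exclude = np.zeros(mask.shape, dtype=bool)
    if len(junctions):
        exclude[junctions[:, 0], junctions[:, 1]] = True
        exclude = dilation(exclude, footprint=disk(int(cfg["skeleton.min_branch_len"])))

    seg_tortuosities, profiles, calibers, seg_rows = [], [], [], []
    n_samples = int(cfg["curvature.n_samples"])
    distance_field = gaussian_filter(edt, 1.5) if bool(cfg["spline.refine_subpixel"]) else None
    for sid, path in enumerate(paths):
        points = downsample_path(path, float(cfg["spline.spacing_px"]))
        if distance_field is not None:
            points = refine_centerline(points, distance_field)
        spline = fit_spline(points, smoothing=float(cfg["spline.smoothing"]))
        in_zone = assign_zone(path, zone, float(cfg["zone.membership_threshold"]))
        st = tortuosity(
            spline,
            segment_id=sid,
            n_samples=n_samples,
            in_5dd=in_zone,
            savgol_window_px=float(cfg["curvature.savgol_window_px"]),
            savgol_order=int(cfg["curvature.savgol_order"]),
        )
        profile = curvature_profile(spline, n_samples=n_samples)
        cal = segment_diameter(
            path,
            mask,
            fraction=float(cfg["caliber.fraction"]),
            seed=(seed + 7919 * sid) % (2**31),
            edt=edt,
            exclude=exclude,
            halfwidth_convention=bool(cfg["caliber.halfwidth_convention"]),
            segment_id=sid,
            in_5dd=in_zone,
        )
        seg_tortuosities.append(st)
        profiles.append(profile)
        calibers.append(cal)
        seg_rows.append(
            {
                "image_id": image_id,
                "segment_id": sid,
                "n_pixels": len(path),
                "L_c": st.L_c,
                "T": st.T,
                "mean_diameter": cal.mean_diameter,
                "in_5dd": in_zone,
                "arc_over_chord": arc_over_chord(spline),
            }
        )

    f1, f2, f3 = tortuosity_features(seg_tortuosities, profiles)
    f4 = zone_max_diameter(calibers)
    dens = vessel_density(mask, int(cfg["density.dilation_radius_px"]))
    seg_df = pd.DataFrame(seg_rows)
    valid_diam = [c.mean_diameter for c in calibers if np.isfinite(c.mean_diameter)]
    features = {
        "image_id": image_id,
        "F1": f1,
        "F2": np.nan if f2 is None else f2,
        "F3": f3,
        "F4": np.nan if f4 is None else f4,
        "F5": dens.density,
        "aux_arc_over_chord_mean": float(seg_df["arc_over_chord"].mean()),
        "aux_T_mean": float(seg_df["T"].mean()),
        "aux_T_median": float(seg_df["T"].median()),
        "aux_diameter_mean": float(np.mean(valid_diam)) if valid_diam else np.nan,
        "aux_segment_count": float(len(paths)),
        "vessel_px": dens.vessel_px,
        "vascularized_px": dens.vascularized_px,
    }
    return features, seg_df


def cohort_features(
    masks: dict[str, BinaryMask],
    discs: dict[str, OpticDiscSpec],
    config: RunConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature rows for every image; per-image failures are logged, not fatal."""
    rows, seg_tables = [], []
    for i, image_id in enumerate(sorted(masks)):
        try:
            feats, segs = extract_image_features(
                masks[image_id],
                discs[image_id],
                config=config,
                seed=(seed + 104729 * i) % (2**31),
                image_id=image_id,
            )
        except (ValueError, KeyError) as exc:
            logger.warning("feature extraction failed for %s: %s", image_id, exc)
            rows.append({"image_id": image_id})
            continue
        rows.append(feats)
        seg_tables.append(segs)
    features = pd.DataFrame(rows).set_index("image_id")
    segments = (
        pd.concat(seg_tables, ignore_index=True) if seg_tables else pd.DataFrame()
    )
    return features, segments


def classifiable_rows(features: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Drop images with missing required features, logging each exclusion."""
    cols = columns or FEATURE_COLUMNS
    bad = features.index[features[cols].isna().any(axis=1)]
    for image_id in bad:
        missing = [c for c in cols if pd.isna(features.loc[image_id, c])]
        logger.warning("excluding %s from classification (missing %s)", image_id, missing)
    return features.drop(index=bad)
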