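"""Image front-end: nucleus segmentation, puncta detection, raft mapping.

Converts two-channel fields (nuclei + mitochondria) into the same per-cell
feature schema the synthetic generator emits, and calibrates the affine
map from stage/pixel coordinates to raft grid indices using fiduciary
marks. This is a deliberately parameter-light stand-in for commercial
tracing software: Otsu thresholding plus connected components for nuclei,
a difference-of-Gaussians band-pass with a median+MAD threshold for
mitochondrial puncta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature, filters, measure

from .raftgrid import encode_raft_id

# Puncta farther than this from the nucleus boundary are discarded.
PUNCTA_MAX_DIST_UM = 20.0


@dataclass(frozen=True)
class NucleusObject:
    label: int
    centroid: tuple[float, float]  # (x, y) pixels
    area: float
    perimeter: float
    form_factor: float  # 4*pi*A / P^2
    mean_intensity: float
    total_intensity: float


def segment_nuclei(image: np.ndarray, min_area_px: int = 25) -> list[NucleusObject]:
    """Segment nuclei from a single-channel field.

    Automatic bimodal (Otsu) threshold, hole filling, small-object
    removal, connected components. A blank image yields an empty list.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if img.max() <= img.min():
        return []
    thresh = filters.threshold_otsu(img)
    mask = ndimage.binary_fill_holes(img > thresh)
    if not mask.any():
        return []
    labels = measure.label(mask)
    out = []
    for rp in measure.regionprops(labels, intensity_image=img):
        if rp.area < min_area_px:
            continue
        perim = max(rp.perimeter, 1e-9)
        ff = min(4.0 * np.pi * rp.area / perim**2, 1.0)
        cy, cx = rp.centroid
        out.append(
            NucleusObject(
                label=rp.label,
                centroid=(cx, cy),
                area=float(rp.area),
                perimeter=float(perim),
                form_factor=float(ff),
                mean_intensity=float(rp.intensity_mean),
                total_intensity=float(rp.intensity_mean * rp.area),
            )
        )
    return out


def detect_mito_puncta(
    image: np.ndarray,
    nuclei: list[NucleusObject],
    pixel_size_um: float,
    punctum_sigma_px: float = 1.5,
    threshold_k: float = 5.0,
) -> pd.DataFrame:
    """Detect mitochondrial puncta and aggregate them per nucleus.

    Puncta are local maxima of a difference-of-Gaussians band-pass
    (scales sigma and 3*sigma) above median + k*MAD of the filtered
    image. Each punctum is assigned to the nearest nucleus if it lies
    within 20 um of that nucleus's boundary (approximated as centroid
    distance minus equivalent-disc radius), else discarded.

    Returns one row per nucleus: n_puncta, puncta_total_intensity,
    puncta_mean_intensity, radial_mean_um, radial_sd_um,
    frac_perinuclear (within 5 um of the boundary).
    """
    cols = [
        "nucleus_label",
        "n_puncta",
        "puncta_total_intensity",
        "puncta_mean_intensity",
        "radial_mean_um",
        "radial_sd_um",
        "frac_perinuclear",
    ]
    if not nuclei:
        return pd.DataFrame(columns=cols)
    img = np.asarray(image, dtype=float)
    bp = filters.gaussian(img, punctum_sigma_px) - filters.gaussian(img, 3.0 * punctum_sigma_px)
    med = np.median(bp)
    mad = np.median(np.abs(bp - med)) + 1e-12
    thr = med + threshold_k * mad
    peaks = feature.peak_local_max(bp, min_distance=2, threshold_abs=thr, exclude_border=False)

    centroids = np.array([n.centroid for n in nuclei])  # (x, y)
    radii_px = np.array([np.sqrt(n.area / np.pi) for n in nuclei])
    per_nuc: dict[int, list[tuple[float, float]]] = {i: [] for i in range(len(nuclei))}
    for py, px in peaks:
        d = np.hypot(centroids[:, 0] - px, centroids[:, 1] - py)
        i = int(np.argmin(d))
        boundary_dist_um = max(d[i] - radii_px[i], 0.0) * pixel_size_um
        if boundary_dist_um <= PUNCTA_MAX_DIST_UM:
            per_nuc[i].append((boundary_dist_um, float(img[py, px])))

    rows = []
    for i, nuc in enumerate(nuclei):
        pts = per_nuc[i]
        dists = np.array([p[0] for p in pts])
        intens = np.array([p[1] for p in pts])
        rows.append(
            {
                "nucleus_label": nuc.label,
                "n_puncta": len(pts),
                "puncta_total_intensity": float(intens.sum()) if len(pts) else 0.0,
                "puncta_mean_intensity": float(intens.mean()) if len(pts) else 0.0,
                "radial_mean_um": float(dists.mean()) if len(pts) else np.nan,
                "radial_sd_um": float(dists.std()) if len(pts) else np.nan,
                "frac_perinuclear": float((dists <= 5.0).mean()) if len(pts) else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class RaftMap:
    """Affine stage/pixel -> raft-grid-index calibration.

    ``matrix`` is 2x2 and ``offset`` length-2 so that
    ``grid = matrix @ xy + offset`` in continuous grid units; integer
    indices are the floor of the continuous coordinates.
    """

    matrix: np.ndarray
    offset: np.ndarray
    fiduciary_rafts: frozenset[str] = frozenset()

    def to_grid(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(xy, float) @ self.matrix.T + self.offset

    def raft_id(self, x: float, y: float) -> str:
        gx, gy = self.to_grid(np.array([x, y]))
        row, col = int(np.floor(gy)), int(np.floor(gx))
        if row < 0 or col < 0:
            raise ValueError(f"point ({x}, {y}) maps outside the raft grid")
        return encode_raft_id(row, col)


def fit_raft_map(
    fiduciary_xy: np.ndarray,
    fiduciary_grid: np.ndarray,
    fiduciary_rafts: frozenset[str] = frozenset(),
) -> RaftMap:
    """Least-squares affine fit from fiduciary detections.

    ``fiduciary_xy`` are detected (x, y) positions, ``fiduciary_grid``
    the known continuous grid coordinates of the same marks. Requires at
    least 3 non-collinear points.
    """
    xy = np.asarray(fiduciary_xy, float)
    grid = np.asarray(fiduciary_grid, float)
    if len(xy) < 3:
        raise ValueError("calibration failure: need >= 3 fiduciary points")
    A = np.hstack([xy, np.ones((len(xy), 1))])
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError("calibration failure: fiduciary points are collinear")
    coef, *_ = np.linalg.lstsq(A, grid, rcond=None)
    matrix = coef[:2].T
    offset = coef[2]
    if abs(np.linalg.det(matrix)) < 1e-12:
        raise ValueError("calibration failure: degenerate transform")
    return RaftMap(matrix=matrix, offset=offset, fiduciary_rafts=fiduciary_rafts)


def map_rafts(
    detections: pd.DataFrame,
    field_positions: pd.DataFrame,
    raft_map: RaftMap,
    field_size_px: tuple[int, int],
    overlap_fraction: float = 0.12,
    dedup_radius_px: float = 5.0,
) -> pd.DataFrame:
    """Assign raft IDs to detections and de-duplicate field overlaps.

    ``detections`` has columns (field, x, y) in field-local pixels;
    ``field_positions`` maps field -> (stage_x, stage_y) of the field
    origin in the same units. Fields overlap by ``overlap_fraction`` of
    their area; a cell seen in two adjacent fields appears as two
    detections at nearly identical stage coordinates, resolved by
    nearest-centroid matching within ``dedup_radius_px``.
    """
    fp = field_positions.set_index("field")
    df = detections.copy()
    df["stage_x"] = df["x"] + fp.loc[df["field"], "stage_x"].to_numpy(float)
    df["stage_y"] = df["y"] + fp.loc[df["field"], "stage_y"].to_numpy(float)
    df = df.sort_values(["field"], kind="stable").reset_index(drop=True)

    keep = np.ones(len(df), bool)
    pts = df[["stage_x", "stage_y"]].to_numpy()
    for i in range(len(df)):
        if not keep[i]:
            continue
        d = np.hypot(pts[i + 1 :, 0] - pts[i, 0], pts[i + 1 :, 1] - pts[i, 1])
        dup = np.nonzero(d < dedup_radius_px)[0] + i + 1
        # only cross-field duplicates are merged
        same_field = df["field"].to_numpy()[dup] == df["field"].iat[i]
        keep[dup[~same_field]] = False
    df = df[keep].reset_index(drop=True)
    df["raft_id"] = [raft_map.raft_id(x, y) for x, y in df[["stage_x", "stage_y"]].to_numpy()]
    df["fiduciary"] = df["raft_id"].isin(raft_map.fiduciary_rafts)
    return df


def features_from_field(
    nuc_img: np.ndarray, mito_img: np.ndarray, pixel_size_um: float, field: int = 1
) -> pd.DataFrame:
    """Per-cell feature rows for one field, schema-compatible with the
    synthetic table's morphology columns plus puncta features."""
    nuclei = segment_nuclei(nuc_img)
    puncta = detect_mito_puncta(mito_img, nuclei, pixel_size_um)
    rows = []
    for nuc, (_, prow) in zip(nuclei, puncta.iterrows()):
        rows.append(
            {
                "field": field,
                "x": nuc.centroid[0],
                "y": nuc.centroid[1],
                "nuc_area": nuc.area * pixel_size_um**2,
                "nuc_form_factor": nuc.form_factor,
                "nuc_intensity": nuc.mean_intensity,
                "cell_intensity": nuc.total_intensity,
                **{k: prow[k] for k in puncta.columns if k != "nucleus_label"},
            }
        )
    return pd.DataFrame(rows)
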