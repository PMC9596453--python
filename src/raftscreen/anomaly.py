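"""Anomaly-detection ensemble for screen mode.

Detectors are fit on control cells only (e.g. the -Dox, no-Cas9
population) and deployed to every cell. Each detector owns a random
feature subset with per-feature robust center (median) and scale
(sigma-consistent MAD) estimated on controls; its raw score for a cell
is the Euclidean norm of the robustly standardized subset features. A
cell's anomaly score is the number of detectors placing it in the top
5% (and 10%) of all scored cells — percentiles are taken over the
scored population, not over controls, and ties at a threshold fall
below it (strict inequality).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

MIN_CELLS_FOR_PERCENTILES = 20


@dataclass(frozen=True)
class Detector:
    features: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray

    def raw_scores(self, X: pd.DataFrame) -> np.ndarray:
        Z = (X[list(self.features)].to_numpy(float) - self.center) / self.scale
        return np.linalg.norm(Z, axis=1)


@dataclass(frozen=True)
class AnomalyEnsemble:
    detectors: tuple[Detector, ...]
    seed: int

    @property
    def n_detectors(self) -> int:
        return len(self.detectors)

    def save(self, path) -> None:
        """Persist detector parameters so scoring is reproducible."""
        payload = {
            "version": 1,
            "seed": self.seed,
            "detectors": [
                {
                    "features": list(d.features),
                    "center": d.center.tolist(),
                    "scale": d.scale.tolist(),
                }
                for d in self.detectors
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "AnomalyEnsemble":
        payload = json.loads(Path(path).read_text())
        dets = tuple(
            Detector(
                features=tuple(d["features"]),
                center=np.asarray(d["center"], float),
                scale=np.asarray(d["scale"], float),
            )
            for d in payload["detectors"]
        )
        return cls(detectors=dets, seed=payload["seed"])


def fit_anomaly_ensemble(
    controls: pd.DataFrame,
    feature_cols: list[str],
    n_detectors: int = 25,
    subset_size: int = 8,
    seed: int = 0,
) -> AnomalyEnsemble:
    """Fit the detector ensemble on control cells.

    Each detector draws ``subset_size`` features without replacement and
    stores their control median and MAD (zero MADs fall back to 1 so a
    constant control feature cannot blow up scores).
    """
    if subset_size < 2:
        raise ValueError("subset_size must be >= 2")
    if subset_size > len(feature_cols):
        raise ValueError("subset_size exceeds available features")
    rng = np.random.default_rng(seed)
    dets = []
    for _ in range(n_detectors):
        idx = rng.choice(len(feature_cols), size=subset_size, replace=False)
        feats = tuple(feature_cols[i] for i in sorted(idx))
        block = controls[list(feats)].to_numpy(float)
        center = np.median(block, axis=0)
        scale = stats.median_abs_deviation(block, axis=0, scale="normal")
        scale[scale <= 0] = 1.0
        dets.append(Detector(features=feats, center=center, scale=scale))
    return AnomalyEnsemble(detectors=tuple(dets), seed=seed)


def anomaly_scores(
    ensemble: AnomalyEnsemble, cells: pd.DataFrame, id_col: str = "cell_id"
) -> pd.DataFrame:
    """Count, per cell, the detectors placing it in the top 5% / 10%.

    Thresholds are each detector's 95th / 90th percentile of raw scores
    over ALL scored cells. Returns columns (cell_id, n_top5, n_top10,
    n_detectors).
    """
    if len(cells) < MIN_CELLS_FOR_PERCENTILES:
        raise ValueError(
            f"need >= {MIN_CELLS_FOR_PERCENTILES} cells for stable percentile thresholds"
        )
    n = len(cells)
    n_top5 = np.zeros(n, int)
    n_top10 = np.zeros(n, int)
    for det in ensemble.detectors:
        raw = det.raw_scores(cells)
        t5 = np.percentile(raw, 95.0)
        t10 = np.percentile(raw, 90.0)
        n_top5 += raw > t5
        n_top10 += raw > t10
    out = pd.DataFrame(
        {
            id_col: cells[id_col].to_numpy() if id_col in cells else np.arange(n),
            "n_top5": n_top5,
            "n_top10": n_top10,
            "n_detectors": ensemble.n_detectors,
        }
    )
    assert (out["n_top5"] <= out["n_top10"]).all()
    return out
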