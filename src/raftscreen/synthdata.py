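"""Synthetic screening experiments: feature tables, images, amplicon reads.

Everything downstream of the microscope is driven by three inputs — a
per-cell feature table, a plate layout, and (after picking) per-well
paired FASTQ files. This module generates all three with known ground
truth so the full pipeline is testable end to end.

The feature model is deliberately simple but captures the failure modes
that matter for model selection on real screens:

* informative features carry a standardized mean shift (``effect_size``)
  in pathogenic cells under block-correlated Gaussian noise, giving the
  "largely overlapping distributions" regime;
* every plate adds a per-feature additive batch offset, so models trained
  and tested on the same wells overfit measurably;
* a configurable number of "leaky" features encode well position almost
  exactly, providing a guaranteed positive control for leak detection;
* a fraction of records are debris with out-of-gate nuclear morphology;
* cells occupy rafts under truncated-Poisson occupancy, so the
  crowded-raft QC gate and multi-cell raft picking are exercised.

One master seed determines every output byte; stage-specific child
streams are spawned at fixed indices from a ``SeedSequence``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import LocusPanel, revcomp
from .raftgrid import encode_raft_id

# Fixed spawn indices for per-stage random streams.
_STREAM_LAYOUT = 0
_STREAM_FEATURES = 1
_STREAM_RAFTS = 2
_STREAM_DEBRIS = 3
_STREAM_READS = 4
_STREAM_IMAGES = 5


@dataclass(frozen=True)
class GenotypeSpec:
    name: str
    cls: str  # "WT" | "benign" | "pathogenic"

    def __post_init__(self) -> None:
        if self.cls not in ("WT", "benign", "pathogenic"):
            raise ValueError(f"unknown genotype class {self.cls!r}")


def default_genotypes() -> tuple[GenotypeSpec, ...]:
    """WT plus the four pathogenic MFN2 variants used in the mixing assay."""
    return (
        GenotypeSpec("WT", "WT"),
        GenotypeSpec("L76P", "pathogenic"),
        GenotypeSpec("R94Q", "pathogenic"),
        GenotypeSpec("P251A", "pathogenic"),
        GenotypeSpec("R280H", "pathogenic"),
    )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated microraft screening experiment.

    Defaults mirror the mixing-experiment design: two plates, three
    labeled wells per class spread across plates, and two unlabeled
    admixture wells at 50:50 and 90:10 WT:pathogenic.
    """

    n_plates: int = 2
    wells_per_plate: int = 4
    cells_per_well: int = 300
    genotypes: tuple[GenotypeSpec, ...] = field(default_factory=default_genotypes)
    effect_size: float = 1.0
    n_features: int = 170
    n_informative: int = 12
    feature_correlation: float = 0.3
    corr_block_size: int = 5
    batch_sd: float = 0.5
    leaky_feature_count: int = 2
    raft_grid: tuple[int, int] = (30, 30)
    mean_cells_per_raft: float = 1.8
    max_cells_per_raft: int = 10
    fiduciary_fraction: float = 0.02
    debris_fraction: float = 0.05
    mix_positive_fractions: tuple[float, ...] = (0.5, 0.1)
    labeled_wells_per_class: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative exceeds n_features")
        for name in ("n_plates", "wells_per_plate", "cells_per_well", "n_features"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.feature_correlation < 1:
            raise ValueError("feature_correlation must be in [0, 1)")
        if self.effect_size < 0 or self.batch_sd < 0:
            raise ValueError("effect_size and batch_sd must be nonnegative")
        if not 0 <= self.debris_fraction <= 1 or not 0 <= self.fiduciary_fraction <= 1:
            raise ValueError("fractions must be in [0, 1]")
        if self.mean_cells_per_raft <= 0:
            raise ValueError("mean_cells_per_raft must be positive")
        n_labeled = 2 * self.labeled_wells_per_class
        if n_labeled + len(self.mix_positive_fractions) > self.n_plates * self.wells_per_plate:
            raise ValueError("not enough wells for the requested layout")

    @property
    def pathogenic_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genotypes if g.cls == "pathogenic")

    @property
    def class_map(self) -> dict[str, str]:
        return {g.name: g.cls for g in self.genotypes}

    def feature_names(self) -> list[str]:
        return [f"F{i + 1:03d}" for i in range(self.n_features)]

    def leaky_feature_names(self) -> list[str]:
        names = self.feature_names()
        return names[self.n_features - self.leaky_feature_count :] if self.leaky_feature_count else []

    def informative_feature_names(self) -> list[str]:
        return self.feature_names()[: self.n_informative]


@dataclass
class GroundTruth:
    """Per-cell truth plus raft composition for a simulated experiment."""

    cells: pd.DataFrame  # cell_id, genotype, genotype_class, raft_id, is_debris
    grna: pd.DataFrame | None = None  # cell_id, grna_id (screen mode)

    def genotype_of(self, cell_id: str) -> str:
        return self._index().loc[cell_id, "genotype"]

    def raft_members(self, raft_id: str) -> list[str]:
        return list(self.cells.loc[self.cells["raft_id"] == raft_id, "cell_id"])

    def raft_genotypes(self) -> pd.Series:
        """raft_id -> tuple of member genotypes (debris excluded)."""
        live = self.cells[~self.cells["is_debris"]]
        return live.groupby("raft_id")["genotype"].agg(tuple)

    def _index(self) -> pd.DataFrame:
        return self.cells.set_index("cell_id")


def build_layout(config: SimConfig) -> pd.DataFrame:
    """Assign a role to every well.

    Labeled wells are interleaved across plates so that the well-wise
    split can always place its two training wells on distinct plates.
    Returns columns plate, well, well_index, role, positive_fraction.
    """
    order = [
        (p, w)
        for w in range(config.wells_per_plate)
        for p in range(config.n_plates)
    ]
    roles: list[tuple[str, float]] = []
    roles += [("labeled_wt", 0.0)] * config.labeled_wells_per_class
    roles += [("labeled_mut", 1.0)] * config.labeled_wells_per_class
    mixes = list(config.mix_positive_fractions)
    i = 0
    while len(roles) < len(order):
        if mixes:
            roles.append(("unlabeled_mix", mixes[i % len(mixes)]))
            i += 1
        else:
            roles.append(("unused", 0.0))
    rows = []
    for (p, w), (role, frac) in zip(order, roles):
        rows.append(
            {
                "plate": f"P{p + 1}",
                "well": f"W{w + 1:02d}",
                "well_index": w,
                "role": role,
                "positive_fraction": frac,
            }
        )
    return pd.DataFrame(rows).sort_values(["plate", "well"], ignore_index=True)


def _block_correlated_noise(rng: np.random.Generator, n: int, p: int, rho: float, block: int) -> np.ndarray:
    """MVN noise with pairwise correlation ``rho`` inside feature blocks."""
    eps = rng.standard_normal((n, p))
    if rho <= 0:
        return eps
    n_blocks = -(-p // block)
    shared = rng.standard_normal((n, n_blocks))
    shared_full = np.repeat(shared, block, axis=1)[:, :p]
    return np.sqrt(rho) * shared_full + np.sqrt(1.0 - rho) * eps


def _assign_rafts(
    rng: np.random.Generator, n_cells: int, config: SimConfig
) -> tuple[list[str], set[str]]:
    """Pack cells onto rafts with truncated-Poisson occupancy.

    Occupancies are drawn from Poisson(mean) conditioned on 1..max; the
    final raft takes the remainder. Returns the per-cell raft id list and
    the set of fiduciary raft ids in this well's grid.
    """
    rows, cols = config.raft_grid
    n_rafts_total = rows * cols
    raft_ids = [encode_raft_id(r, c) for r in range(rows) for c in range(cols)]
    n_fid = int(round(config.fiduciary_fraction * n_rafts_total))
    fid_idx = rng.choice(n_rafts_total, size=n_fid, replace=False) if n_fid else []
    fiduciary = {raft_ids[i] for i in fid_idx}

    perm = rng.permutation(n_rafts_total)
    assignment: list[str] = []
    ri = 0
    while len(assignment) < n_cells:
        if ri >= n_rafts_total:
            raise ValueError("raft grid too small for the requested cell count")
        k = 0
        while not 1 <= k <= config.max_cells_per_raft:
            k = rng.poisson(config.mean_cells_per_raft)
        k = min(k, n_cells - len(assignment))
        assignment.extend([raft_ids[perm[ri]]] * k)
        ri += 1
    return assignment, fiduciary


def simulate_plate(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the imaged-and-traced cell table for one experiment.

    Returns ``(cells, layout, truth)``. The cell table carries identifier
    columns (cell_id, plate, well, well_index, field, raft_id, x, y),
    QC morphology columns (nuc_area, nuc_form_factor, nuc_intensity,
    cell_intensity, dist_raft_edge, fiduciary) and feature columns
    F001..Fnnn. The truth table records each cell's genotype, class,
    raft and debris status.
    """
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(6)
    rng_layout = np.random.default_rng(streams[_STREAM_LAYOUT])
    rng_feat = np.random.default_rng(streams[_STREAM_FEATURES])
    rng_raft = np.random.default_rng(streams[_STREAM_RAFTS])
    rng_debris = np.random.default_rng(streams[_STREAM_DEBRIS])

    layout = build_layout(config)
    pathogenic = list(config.pathogenic_names)
    if not pathogenic:
        raise ValueError("config.genotypes must include at least one pathogenic genotype")

    records = []
    genotypes: list[str] = []
    for row in layout.itertuples(index=False):
        if row.role == "unused":
            continue
        n = config.cells_per_well
        if row.role == "labeled_wt":
            geno = ["WT"] * n
        elif row.role == "labeled_mut":
            geno = list(rng_layout.choice(pathogenic, size=n))
        else:
            is_mut = rng_layout.random(n) < row.positive_fraction
            mut_draw = rng_layout.choice(pathogenic, size=n)
            geno = [m if hit else "WT" for hit, m in zip(is_mut, mut_draw)]
        raft_of, fiduciary = _assign_rafts(rng_raft, n, config)
        rows_px, cols_px = config.raft_grid
        for j in range(n):
            # raft_id is globally unique (plate:well:code); raft_code is the
            # four-character on-plate coordinate.
            records.append(
                {
                    "plate": row.plate,
                    "well": row.well,
                    "well_index": row.well_index,
                    "field": 1,
                    "raft_id": f"{row.plate}:{row.well}:{raft_of[j]}",
                    "raft_code": raft_of[j],
                    "fiduciary": raft_of[j] in fiduciary,
                    "x": float(rng_raft.uniform(0, cols_px * 100.0)),
                    "y": float(rng_raft.uniform(0, rows_px * 100.0)),
                }
            )
        genotypes.extend(geno)

    cells = pd.DataFrame(records)
    n_total = len(cells)
    cells.insert(0, "cell_id", [f"c{i:06d}" for i in range(n_total)])
    genotypes = np.asarray(genotypes, dtype=object)
    is_pathogenic = np.array([config.class_map[g] == "pathogenic" for g in genotypes])

    # Feature matrix: correlated noise + effect shift + plate batch offsets.
    X = _block_correlated_noise(
        rng_feat, n_total, config.n_features, config.feature_correlation, config.corr_block_size
    )
    X[is_pathogenic, : config.n_informative] += config.effect_size
    plate_codes = pd.Categorical(cells["plate"]).codes
    batch = rng_feat.normal(0.0, config.batch_sd, size=(config.n_plates, config.n_features))
    X += batch[plate_codes]
    # Leaky features: near-exact copies of well position.
    if config.leaky_feature_count:
        leak = cells["well_index"].to_numpy(float)[:, None] + rng_feat.normal(
            0.0, 0.01, size=(n_total, config.leaky_feature_count)
        )
        X[:, config.n_features - config.leaky_feature_count :] = leak
    feat_df = pd.DataFrame(X, columns=config.feature_names())

    # Morphology / QC columns for live nuclei.
    cells["nuc_area"] = rng_debris.normal(170.0, 25.0, n_total).clip(40.0)
    cells["nuc_form_factor"] = rng_debris.normal(0.88, 0.04, n_total).clip(0.2, 1.0)
    cells["nuc_intensity"] = rng_debris.lognormal(5.0, 0.25, n_total)
    cells["cell_intensity"] = rng_debris.lognormal(6.0, 0.3, n_total)
    cells["dist_raft_edge"] = rng_debris.uniform(0.0, 50.0, n_total)

    # Debris records: small dim nuclei, out of every intensity/area gate.
    is_debris = rng_debris.random(n_total) < config.debris_fraction
    n_debris = int(is_debris.sum())
    if n_debris:
        cells.loc[is_debris, "nuc_area"] = rng_debris.uniform(5.0, 35.0, n_debris)
        cells.loc[is_debris, "nuc_form_factor"] = rng_debris.uniform(0.2, 0.6, n_debris)
        cells.loc[is_debris, "nuc_intensity"] = rng_debris.uniform(1.0, 25.0, n_debris)
        cells.loc[is_debris, "cell_intensity"] = rng_debris.uniform(1.0, 40.0, n_debris)

    cells = pd.concat([cells, feat_df], axis=1)
    truth_cells = pd.DataFrame(
        {
            "cell_id": cells["cell_id"],
            "genotype": genotypes,
            "genotype_class": [config.class_map[g] for g in genotypes],
            "plate": cells["plate"],
            "well": cells["well"],
            "raft_id": cells["raft_id"],
            "is_debris": is_debris,
        }
    )
    return cells, layout, GroundTruth(cells=truth_cells)


# ---------------------------------------------------------------------------
# Image simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageSimConfig:
    """Rendering parameters for two-channel synthetic fields.

    ``aggregation_um`` is the mean radial distance of mitochondrial
    puncta from the nucleus centroid; pathogenic cells aggregate
    perinuclearly (small value), wild-type cells disperse (large value).
    """

    field_shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.65
    raft_pitch_um: float = 100.0
    wall_width_px: int = 2
    n_nuclei: int = 12
    nucleus_radius_um: float = 6.0
    puncta_per_cell: int = 10
    aggregation_um: float = 10.0
    aggregation_sd_um: float = 2.0
    noise_sd: float = 20.0
    background: float = 200.0
    nucleus_peak: float = 12000.0
    punctum_peak: float = 8000.0
    punctum_sigma_px: float = 1.2
    fiduciary_rafts: tuple[tuple[int, int], ...] = ((0, 0),)
    seed: int = 0


def simulate_images(config: ImageSimConfig) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Render one two-channel field.

    Returns ``(nuclei_img, mito_img, nuclei_truth, puncta_truth)``; images
    are uint16 arrays. Nuclei are smooth Gaussian blobs; puncta are narrow
    Gaussian spots placed at radii ~ N(aggregation_um, aggregation_sd_um)
    around their nucleus. Raft walls and fiduciary squares are drawn in
    both channels.
    """
    h, w = config.field_shape
    pitch_px = config.raft_pitch_um / config.pixel_size_um
    if h < pitch_px or w < pitch_px:
        raise ValueError("field smaller than one raft")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[_STREAM_IMAGES])

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    nuc = np.zeros((h, w))
    mito = np.zeros((h, w))
    nuc_rows, punc_rows = [], []
    r_nuc_px = config.nucleus_radius_um / config.pixel_size_um

    margin = r_nuc_px + config.aggregation_um / config.pixel_size_um + 8
    for i in range(config.n_nuclei):
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        # Flat-top disc softened by a narrow Gaussian edge: smooth blob.
        nuc += config.nucleus_peak * np.exp(-np.maximum(np.sqrt(d2) - r_nuc_px, 0.0) ** 2 / (2 * 2.0**2)) * (
            np.sqrt(d2) < r_nuc_px * 2.5
        )
        n_p = config.puncta_per_cell
        radii = rng.normal(config.aggregation_um, config.aggregation_sd_um, n_p).clip(0.5)
        radii_px = radii / config.pixel_size_um
        theta = rng.uniform(0, 2 * np.pi, n_p)
        px = cx + radii_px * np.cos(theta)
        py = cy + radii_px * np.sin(theta)
        for j in range(n_p):
            d2p = (xx - px[j]) ** 2 + (yy - py[j]) ** 2
            mito += config.punctum_peak * np.exp(-d2p / (2 * config.punctum_sigma_px**2))
            punc_rows.append({"nucleus": i, "x": px[j], "y": py[j], "radius_um": radii[j]})
        nuc_rows.append({"nucleus": i, "x": cx, "y": cy, "n_puncta": n_p})

    # Raft walls on the grid pitch, and fiduciary marks (filled squares).
    wall = np.zeros((h, w), bool)
    for gy in np.arange(0, h, pitch_px):
        wall[int(gy) : int(gy) + config.wall_width_px, :] = True
    for gx in np.arange(0, w, pitch_px):
        wall[:, int(gx) : int(gx) + config.wall_width_px] = True
    fid = np.zeros((h, w), bool)
    for fr, fc in config.fiduciary_rafts:
        y0, x0 = int(fr * pitch_px), int(fc * pitch_px)
        s = max(3, int(pitch_px // 8))
        if 0 <= y0 < h and 0 <= x0 < w:
            fid[y0 + 2 : y0 + 2 + s, x0 + 2 : x0 + 2 + s] = True

    def finish(img: np.ndarray) -> np.ndarray:
        out = img + config.background
        out[wall] += 1500.0
        out[fid] += 3000.0
        if config.noise_sd > 0:
            out = out + rng.normal(0.0, config.noise_sd, img.shape)
        return np.clip(out, 0, 65535).astype(np.uint16)

    return finish(nuc), finish(mito), pd.DataFrame(nuc_rows), pd.DataFrame(punc_rows)


def write_field_tiffs(nuc: np.ndarray, mito: np.ndarray, outdir, field: int = 1) -> list[Path]:
    """Write one field as two 16-bit TIFFs (one per channel)."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, img in (("ch1_nuclei", nuc), ("ch2_mito", mito)):
        p = outdir / f"field{field:03d}_{name}.tiff"
        tifffile.imwrite(p, img)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Amplicon read simulation
# ---------------------------------------------------------------------------

def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    if hits.size == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_amplicon_reads(
    pick_list: pd.DataFrame,
    truth: GroundTruth,
    panel: LocusPanel,
    reads_per_cell: int = 30,
    error_rate: float = 0.001,
    capture_rate: float = 0.8,
    mutant_allele_fraction=(8.0, 2.0),
    read_length: int = 150,
    seed: int = 0,
) -> dict[tuple[str, str], tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]]:
    """Simulate paired amplicon reads for every picked raft.

    ``pick_list`` needs columns raft_id, dest_plate, dest_well. For each
    captured raft, every live member cell contributes ``reads_per_cell``
    read pairs per panel locus. A cell whose genotype matches a locus's
    mutant name emits the mutant fragment with a per-cell probability
    drawn from ``mutant_allele_fraction`` (Beta(a, b) parameters, or a
    constant float); every other locus emits the WT fragment. A fraction
    ``1 - capture_rate`` of rafts is lost and emits nothing.

    Returns ``{(dest_plate, dest_well): (r1_records, r2_records)}`` where
    each record is ``(read_id, sequence, quality)``.
    """
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(6)[_STREAM_READS])
    raft_geno = truth.cells[~truth.cells["is_debris"]].groupby("raft_id")["genotype"].agg(list)
    mutant_names = set(panel.mutant_names)

    out: dict[tuple[str, str], tuple[list, list]] = {}
    for row in pick_list.itertuples(index=False):
        if row.raft_id not in raft_geno.index:
            raise KeyError(f"unknown raft id {row.raft_id!r}")
        key = (str(row.dest_plate), str(row.dest_well))
        r1s: list[tuple[str, str, str]] = []
        r2s: list[tuple[str, str, str]] = []
        out[key] = (r1s, r2s)
        if rng.random() >= capture_rate:
            continue  # raft lost: zero reads
        for ci, geno in enumerate(raft_geno.loc[row.raft_id]):
            if callable(mutant_allele_fraction):
                p_mut = float(mutant_allele_fraction(rng))
            elif isinstance(mutant_allele_fraction, (int, float)):
                p_mut = float(mutant_allele_fraction)
            else:
                a, b = mutant_allele_fraction
                p_mut = float(rng.beta(a, b))
            for loc in panel:
                is_mut_locus = geno in mutant_names and loc.mutant_name == geno
                for k in range(reads_per_cell):
                    allele = "mut" if (is_mut_locus and rng.random() < p_mut) else "wt"
                    amp = panel.forward_tag + loc.amplicon(allele) + revcomp(panel.reverse_tag)
                    r1 = _apply_errors(rng, amp[:read_length], error_rate)
                    r2 = _apply_errors(rng, revcomp(amp[-read_length:]), error_rate)
                    rid = f"{row.raft_id}:{ci}:{loc.name}:{k}"
                    q = "I" * len(r1)
                    r1s.append((rid, r1, q))
                    r2s.append((rid, r2, "I" * len(r2)))
    return out


def write_fastq_pairs(reads, outdir) -> list[Path]:
    """Write simulated reads as gzipped FASTQ pairs named
    ``<plate>_<well>_R1/R2.fastq.gz``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (plate, well), (r1s, r2s) in sorted(reads.items()):
        for tag, recs in (("R1", r1s), ("R2", r2s)):
            p = outdir / f"{plate}_{well}_{tag}.fastq.gz"
            # mtime=0 keeps the gzip stream byte-identical across reruns
            with open(p, "wb") as raw, gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as fh:
                for rid, seq, qual in recs:
                    fh.write(f"@{rid}\n{seq}\n+\n{qual}\n".encode())
            paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Screen mode helpers (gRNA assignment and gRNA-bearing reads)
# ---------------------------------------------------------------------------

def simulate_grna_library(n_grnas: int, seed: int = 0) -> pd.DataFrame:
    """Random 20 nt spacer library; columns grna_id, spacer."""
    rng = np.random.default_rng(seed)
    spacers = set()
    while len(spacers) < n_grnas:
        spacers.add("".join(rng.choice(list("ACGT"), size=20)))
    spacers = sorted(spacers)
    rng.shuffle(spacers)
    return pd.DataFrame(
        {"grna_id": [f"g{i + 1:04d}" for i in range(n_grnas)], "spacer": spacers[:n_grnas]}
    )


def assign_grnas(truth: GroundTruth, library: pd.DataFrame, seed: int = 0) -> GroundTruth:
    """Assign each cell one gRNA uniformly at random (screen mode)."""
    rng = np.random.default_rng(seed)
    ids = library["grna_id"].to_numpy()
    grna = pd.DataFrame(
        {
            "cell_id": truth.cells["cell_id"],
            "grna_id": rng.choice(ids, size=len(truth.cells)),
        }
    )
    return GroundTruth(cells=truth.cells, grna=grna)
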