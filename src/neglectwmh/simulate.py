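"""Synthetic stroke cohorts with lesion maps, WMH maps, ratings and behavior.

The generator emulates the data structure of an acute right-hemisphere stroke
cohort on a desk-scale 2 mm voxel grid:

* an ellipsoidal brain mask with two box-shaped lateral ventricles;
* one connected right-hemisphere stroke lesion per patient, its volume drawn
  from a lognormal calibrated to a clinical scale (mean ~27.5 cm³, SD ~33 cm³);
* roughly bilateral white-matter hyperintensities (WMH) composed of
  periventricular rims (thickness driven by a latent PV severity) and deep
  punctate foci (count driven by a latent DS severity), masked by the lesion
  (mean total volume ~8 cm³);
* age moderately correlated with the latent WMH burden;
* visual ratings (CHS 0-9; Fazekas PV/DS 0-3) as monotone binnings of the
  simulated burden plus integer rater noise;
* behavioral scores: a latent neglect severity
  ``b = beta_lesion * (lesion overlap with a critical right-hemisphere region)
  + beta_wmh * standardized right-hemisphere WMH volume + noise``, observed as
  letter/bells CoC scores with independent per-test noise (or, optionally, via
  simulated cancellation sheets).

All randomness flows through :class:`~neglectwmh.streams.RandomStream`
substreams, so cohorts are bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .behavior import CancellationSheet, center_of_cancellation, mean_coc, prepare_target
from .streams import FLAIR, RATING, SIM, RandomStream
from .volumes import Volume, write_volume, read_volume


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Volume scales are calibrated to the clinical anchors (lesion mean 27.5 cm³,
    WMH mean 8.0 cm³); ``beta_*`` control how strongly lesion topography and
    right-hemisphere WMH burden drive neglect severity, with defaults chosen so
    that fusing the WMH map into the lesion map gains roughly 0.05 R² over the
    lesion-only model.
    """

    n_patients: int = 103
    grid: tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    #: (mu, sigma) of ln(lesion volume in cm³); (2.87, 0.94) gives mean ~27.5, SD ~33
    lesion_volume_lognormal: tuple[float, float] = (2.87, 0.94)
    max_lesion_cm3: float = 80.0
    beta_lesion: float = 0.9
    beta_wmh: float = 0.10
    noise_sd: float = 0.10
    coc_noise_sd: float = 0.05
    age_wmh_corr: float = 0.65
    #: SD of the per-hemisphere deviation from the shared PV/DS latents;
    #: makes WMH only roughly bilateral, so the two hemisphere maps carry
    #: partly independent information
    hemi_asym_sd: float = 0.7
    rater_noise_sd: float = 0.7
    critical_region: Optional[np.ndarray] = None  # bool grid; default box if None
    sheet_mode: bool = False
    n_sheet_targets: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        nx, ny, nz = self.grid
        if nx % 2 != 0:
            raise SimulationError("grid nx must be even (midsagittal plane between voxels)")
        if self.n_patients < 1:
            raise SimulationError("n_patients must be >= 1")
        for name in ("noise_sd",):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be > 0")
        for name in ("beta_lesion", "beta_wmh", "rater_noise_sd", "coc_noise_sd", "hemi_asym_sd"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if not 0 <= self.age_wmh_corr < 1:
            raise SimulationError("age_wmh_corr must lie in [0, 1)")
        if self.critical_region is not None:
            cr = np.asarray(self.critical_region, dtype=bool)
            if cr.shape != tuple(self.grid):
                raise SimulationError("critical_region grid mismatch")
            if cr[: nx // 2].any():
                raise SimulationError("critical_region must lie in the right hemisphere")
            self.critical_region = cr

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0


@dataclass
class CohortTable:
    """A simulated (or loaded) cohort: per-patient maps plus a tabular record.

    ``table`` columns include observed variables (age, ratings, letter/bells
    CoC, volumes) and latent ground truth (``latent_b``, ``overlap_fraction``,
    ``pv_latent``, ``ds_latent``) retained for recovery tests.
    """

    table: pd.DataFrame
    lesions: np.ndarray        # (n, nx, ny, nz) bool
    wmhs: np.ndarray           # (n, nx, ny, nz) bool, lesion-masked
    voxel_size_mm: tuple[float, float, float]
    critical_region: np.ndarray
    config: Optional[SimulationConfig] = None

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.lesions.shape[1:]

    def lesion_volume(self, i: int) -> Volume:
        return Volume(self.lesions[i].astype(np.uint8), self.voxel_size_mm)

    def wmh_volume(self, i: int) -> Volume:
        return Volume(self.wmhs[i].astype(np.uint8), self.voxel_size_mm)

    def lesion_matrix(self) -> np.ndarray:
        """(n, n_voxels) flattened binary lesion matrix."""
        return self.lesions.reshape(self.n, -1).astype(np.uint8)

    def wmh_matrix(self, side: str = "bilateral", perm: Optional[np.ndarray] = None) -> np.ndarray:
        """(n, n_voxels) flattened WMH matrix, optionally one hemisphere and/or
        re-paired by a permutation of patients."""
        maps = self.wmhs
        if perm is not None:
            maps = maps[np.asarray(perm, dtype=int)]
        nx = self.grid[0]
        if side == "bilateral":
            data = maps
        elif side == "left":
            data = maps.copy()
            data[:, nx // 2 :, :, :] = False
        elif side == "right":
            data = maps.copy()
            data[:, : nx // 2, :, :] = False
        else:
            raise ValueError(f"unknown side {side!r}")
        return data.reshape(self.n, -1).astype(np.uint8)

    def mean_coc(self) -> np.ndarray:
        return np.array(
            [mean_coc(l, b) for l, b in zip(self.table["letter_coc"], self.table["bells_coc"])]
        )

    def targets(self) -> np.ndarray:
        """Square-root-transformed, negativity-clamped mean CoC — the variable
        the regression predicts."""
        return prepare_target(self.mean_coc())

    def validate(self) -> None:
        """Check the structural invariants of a cohort."""
        nx = self.grid[0]
        if self.lesions[:, : nx // 2].any():
            raise SimulationError("lesion voxels found in the left hemisphere")
        if (self.lesions & self.wmhs).any():
            raise SimulationError("WMH overlaps lesion (maps must be lesion-masked)")
        t = self.table
        for col, lo, hi in [("chs", 0, 9), ("pv_wmh", 0, 3), ("ds_wmh", 0, 3)]:
            if (t[col] < lo).any() or (t[col] > hi).any():
                raise SimulationError(f"rating {col} out of range")
        if not (t["fazekas_total"] == t["pv_wmh"] + t["ds_wmh"]).all():
            raise SimulationError("fazekas_total != pv + ds")
        for col in ("letter_coc", "bells_coc"):
            vals = t[col].dropna()
            if (vals.abs() > 1).any():
                raise SimulationError(f"{col} outside [-1, 1]")


# ---------------------------------------------------------------------------
# anatomy helpers

def brain_mask(grid: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal stand-in brain mask for a desk-scale grid."""
    nx, ny, nz = grid
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ax, ay, az = 0.45 * nx, 0.45 * ny, 0.42 * nz
    x, y, z = np.ogrid[:nx, :ny, :nz]
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def ventricle_boxes(grid: tuple[int, int, int]) -> list[tuple[slice, slice, slice]]:
    """Two paramedian boxes (left, right) anchoring the periventricular rims."""
    nx, ny, nz = grid
    xw = max(2, round(0.075 * nx))              # box width in x
    gap = max(1, round(0.05 * nx))              # distance from midline
    y0, y1 = round(0.40 * ny), round(0.60 * ny)
    z0, z1 = round(0.42 * nz), round(0.57 * nz)
    mid = nx // 2
    left = (slice(mid - gap - xw, mid - gap), slice(y0, y1), slice(z0, z1))
    right = (slice(mid + gap, mid + gap + xw), slice(y0, y1), slice(z0, z1))
    return [left, right]


def default_critical_region(grid: tuple[int, int, int]) -> np.ndarray:
    """Box in the right temporo-parietal region whose damage drives neglect."""
    nx, ny, nz = grid
    region = np.zeros(grid, dtype=bool)
    region[
        round(0.62 * nx) : round(0.88 * nx),
        round(0.28 * ny) : round(0.55 * ny),
        round(0.35 * nz) : round(0.65 * nz),
    ] = True
    return region & brain_mask(grid)


def _expand_box(box: tuple[slice, slice, slice], t: int, grid: tuple[int, int, int]):
    return tuple(
        slice(max(0, s.start - t), min(n, s.stop + t)) for s, n in zip(box, grid)
    )


_BALL_OFFSETS = {
    1: np.array([(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                 if dx * dx + dy * dy + dz * dz <= 1]),
    2: np.array([(dx, dy, dz) for dx in (-2, -1, 0, 1, 2) for dy in (-2, -1, 0, 1, 2)
                 for dz in (-2, -1, 0, 1, 2) if dx * dx + dy * dy + dz * dz <= 4]),
}


def _grow_lesion(
    rng: np.random.Generator,
    target_voxels: int,
    grid: tuple[int, int, int],
    brain: np.ndarray,
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    centers_pool: np.ndarray,
) -> np.ndarray:
    """One connected right-hemisphere lesion: a random ellipsoid clipped to the
    brain and hemisphere, radius-rescaled toward the target voxel count."""
    nx = grid[0]
    center = centers_pool[rng.integers(len(centers_pool))]
    ratios = np.exp(rng.normal(0.0, 0.25, size=3))
    ratios /= ratios.prod() ** (1 / 3)
    radius = (3 * target_voxels / (4 * np.pi)) ** (1 / 3)
    x, y, z = coords
    right = np.zeros(grid, dtype=bool)
    right[nx // 2 :] = True
    allowed = brain & right
    semi = radius * ratios
    lesion = np.zeros(grid, dtype=bool)
    for _ in range(4):
        d = (
            ((x - center[0]) / semi[0]) ** 2
            + ((y - center[1]) / semi[1]) ** 2
            + ((z - center[2]) / semi[2]) ** 2
        )
        lesion = (d <= 1.0) & allowed
        count = int(lesion.sum())
        if count >= 0.85 * target_voxels or count == 0:
            if count == 0:
                semi = semi * 1.5
                continue
            break
        semi = semi * min(1.6, (target_voxels / count) ** (1 / 3))
    if not lesion.any():  # fall back to a single voxel at the centre
        lesion[tuple(center)] = True
    return lesion


def _pv_thickness(pv_latent: float) -> int:
    """Monotone map from latent PV severity to rim thickness 0..3 voxels."""
    return int(np.clip(round(1.2 + 0.9 * pv_latent), 0, 3))


def _ds_count(ds_latent: float) -> int:
    """Monotone map from latent DS severity to the number of deep foci."""
    return max(0, int(round(7 + 5 * ds_latent)))


def _make_wmh(
    rng: np.random.Generator,
    pv_latent_lr: tuple[float, float],
    ds_latent_lr: tuple[float, float],
    grid: tuple[int, int, int],
    brain: np.ndarray,
    ventricles: list[tuple[slice, slice, slice]],
    ventricle_mask: np.ndarray,
) -> np.ndarray:
    """Roughly bilateral WMH: one periventricular rim and one set of deep foci
    per hemisphere, each driven by that hemisphere's latent severity."""
    nx = grid[0]
    wmh = np.zeros(grid, dtype=bool)
    for box, pv_lat in zip(ventricles, pv_latent_lr):  # ventricles = [left, right]
        t = _pv_thickness(pv_lat)
        if t > 0:
            wmh[_expand_box(box, t, grid)] = True
    wmh &= ~ventricle_mask
    hemi_masks = (slice(0, nx // 2), slice(nx // 2, nx))
    for hemi, ds_lat in zip(hemi_masks, ds_latent_lr):
        n_foci = _ds_count(ds_lat) // 2  # per-hemisphere share
        if n_foci <= 0:
            continue
        allowed = np.zeros(grid, dtype=bool)
        allowed[hemi] = True
        candidates = np.argwhere(brain & ~ventricle_mask & allowed)
        picks = candidates[rng.integers(len(candidates), size=n_foci)]
        radii = rng.integers(1, 3, size=n_foci)  # ball radius 1 or 2
        for (cx, cy, cz), r in zip(picks, radii):
            pts = _BALL_OFFSETS[int(r)] + (cx, cy, cz)
            valid = (
                (pts >= 0).all(axis=1)
                & (pts[:, 0] < grid[0]) & (pts[:, 1] < grid[1]) & (pts[:, 2] < grid[2])
            )
            pts = pts[valid]
            wmh[pts[:, 0], pts[:, 1], pts[:, 2]] = True
    wmh &= brain
    return wmh


# ---------------------------------------------------------------------------
# main generators

def simulate_cohort(config: SimulationConfig) -> CohortTable:
    """Generate a cohort; deterministic given ``config.seed``."""
    stream = RandomStream(config.seed)
    n = config.n_patients
    grid = tuple(config.grid)
    brain = brain_mask(grid)
    ventricles = ventricle_boxes(grid)
    ventricle_mask = np.zeros(grid, dtype=bool)
    for box in ventricles:
        ventricle_mask[box] = True
    coords = np.ogrid[: grid[0], : grid[1], : grid[2]]
    critical = (
        config.critical_region
        if config.critical_region is not None
        else default_critical_region(grid)
    )

    # latent variables (one substream so downstream draws are stable)
    rng_lat = stream.substream(SIM, 0)
    z_wmh = rng_lat.normal(size=n)
    age_eps = rng_lat.normal(size=n)
    rho = config.age_wmh_corr
    age = 58.2 + 13.7 * (rho * z_wmh + np.sqrt(1 - rho**2) * age_eps)
    age = np.clip(age, 26.0, 90.0)
    # loadings give a weak PV-DS association and, with age_wmh_corr=0.65, an
    # age-to-WMH-volume Spearman correlation in the moderate 0.4-0.5 range
    pv_latent = 0.85 * z_wmh + np.sqrt(1 - 0.85**2) * rng_lat.normal(size=n)
    ds_latent = 0.55 * z_wmh + np.sqrt(1 - 0.55**2) * rng_lat.normal(size=n)
    # per-hemisphere deviations: WMH are only roughly bilateral
    pv_asym = config.hemi_asym_sd * rng_lat.normal(size=(n, 2))
    ds_asym = config.hemi_asym_sd * rng_lat.normal(size=(n, 2))

    # per-patient geometry
    mu, sigma = config.lesion_volume_lognormal
    nx = grid[0]
    right_brain = brain.copy()
    right_brain[: nx // 2] = False
    # candidate lesion centres: right-hemisphere brain voxels away from the edge
    inner = np.argwhere(right_brain)
    lesions = np.zeros((n,) + grid, dtype=bool)
    wmhs = np.zeros((n,) + grid, dtype=bool)
    for i in range(n):
        rng_i = stream.substream(SIM, 1, i)
        vol_cm3 = float(np.clip(np.exp(rng_i.normal(mu, sigma)), 0.1, config.max_lesion_cm3))
        target_voxels = max(1, int(round(vol_cm3 / config.voxel_volume_cm3)))
        lesions[i] = _grow_lesion(rng_i, target_voxels, grid, brain, coords, inner)
        wmh = _make_wmh(
            rng_i,
            (pv_latent[i] + pv_asym[i, 0], pv_latent[i] + pv_asym[i, 1]),
            (ds_latent[i] + ds_asym[i, 0], ds_latent[i] + ds_asym[i, 1]),
            grid,
            brain,
            ventricles,
            ventricle_mask,
        )
        wmhs[i] = wmh & ~lesions[i]

    voxvol = config.voxel_volume_cm3
    lesion_vol = lesions.reshape(n, -1).sum(axis=1) * voxvol
    wmh_vol = wmhs.reshape(n, -1).sum(axis=1) * voxvol
    right_wmh_vol = wmhs[:, nx // 2 :].reshape(n, -1).sum(axis=1) * voxvol

    # behavior
    rng_b = stream.substream(SIM, 2)
    overlap = (lesions & critical).reshape(n, -1).sum(axis=1) / max(1, critical.sum())
    sd = right_wmh_vol.std()
    z_rwmh = (right_wmh_vol - right_wmh_vol.mean()) / sd if sd > 0 else np.zeros(n)
    latent_b = (
        config.beta_lesion * overlap
        + config.beta_wmh * z_rwmh
        + config.noise_sd * rng_b.normal(size=n)
    )
    if config.sheet_mode:
        letter = np.array(
            [_simulate_sheet_coc(latent_b[i], config, stream.substream(SIM, 3, i, 0)) for i in range(n)]
        )
        bells = np.array(
            [_simulate_sheet_coc(latent_b[i], config, stream.substream(SIM, 3, i, 1)) for i in range(n)]
        )
    else:
        letter = np.clip(latent_b + config.coc_noise_sd * rng_b.normal(size=n), -1, 1)
        bells = np.clip(latent_b + config.coc_noise_sd * rng_b.normal(size=n), -1, 1)

    ratings = simulate_ratings(
        wmh_vol, pv_latent, ds_latent, stream.substream(RATING, 0), config.rater_noise_sd
    )

    table = pd.DataFrame(
        {
            "id": [f"P{i:03d}" for i in range(n)],
            "age": age,
            "letter_coc": letter,
            "bells_coc": bells,
            "chs": ratings["chs"],
            "pv_wmh": ratings["pv_wmh"],
            "ds_wmh": ratings["ds_wmh"],
            "fazekas_total": ratings["fazekas_total"],
            "lesion_volume_cm3": lesion_vol,
            "wmh_volume_cm3": wmh_vol,
            "right_wmh_volume_cm3": right_wmh_vol,
            "overlap_fraction": overlap,
            "latent_b": latent_b,
            "pv_latent": pv_latent,
            "ds_latent": ds_latent,
        }
    )
    cohort = CohortTable(
        table=table,
        lesions=lesions,
        wmhs=wmhs,
        voxel_size_mm=tuple(config.voxel_size_mm),
        critical_region=critical,
        config=config,
    )
    cohort.validate()
    return cohort


def _simulate_sheet_coc(
    severity: float, config: SimulationConfig, rng: np.random.Generator
) -> float:
    """Observe a latent severity through a simulated symmetric cancellation
    sheet: targets on a uniform grid, miss probability rising toward the left
    with severity."""
    m = config.n_sheet_targets
    x = np.linspace(-0.95, 0.95, m)
    # logistic miss profile: severe patients miss left-sided targets
    p_miss = 1.0 / (1.0 + np.exp((x + 1.0 - 2.2 * max(0.0, severity)) / 0.12))
    hit = rng.random(m) >= p_miss
    if not hit.any():
        return 1.0
    return center_of_cancellation(CancellationSheet(x, hit))


def simulate_ratings(
    wmh_volumes: np.ndarray,
    pv_latent: np.ndarray,
    ds_latent: np.ndarray,
    rng: np.random.Generator,
    rater_noise_sd: float = 0.7,
) -> pd.DataFrame:
    """Visual WMH ratings for one rater.

    CHS 0-9 is a monotone quantile (decile-rank) binning of the total WMH
    volume; PV and DS ratings 0-3 are monotone binnings of their latents; each
    gets independent rounded-Gaussian rater noise and is clipped to range.
    The total Fazekas score is recomputed as PV + DS.
    """
    wmh_volumes = np.asarray(wmh_volumes, dtype=float)
    n = wmh_volumes.size
    order = np.argsort(np.argsort(wmh_volumes, kind="stable"), kind="stable")
    chs0 = np.floor((order + 0.5) / n * 10).astype(int)
    if np.all(wmh_volumes == 0):
        chs0 = np.zeros(n, dtype=int)
    pv0 = np.array([_pv_thickness(v) for v in np.asarray(pv_latent, dtype=float)])
    ds0 = np.digitize([_ds_count(v) for v in np.asarray(ds_latent, dtype=float)], [2, 7, 12])
    if rater_noise_sd > 0:
        chs = np.clip(chs0 + np.round(rng.normal(0, rater_noise_sd, n)).astype(int), 0, 9)
        pv = np.clip(pv0 + np.round(rng.normal(0, rater_noise_sd, n)).astype(int), 0, 3)
        ds = np.clip(ds0 + np.round(rng.normal(0, rater_noise_sd, n)).astype(int), 0, 3)
    else:
        chs, pv, ds = chs0, pv0, ds0
    return pd.DataFrame(
        {"chs": chs, "pv_wmh": pv, "ds_wmh": ds, "fazekas_total": pv + ds}
    )


def simulate_flair(lesion: Volume, wmh: Volume, rng: np.random.Generator) -> Volume:
    """Synthetic FLAIR-like intensity volume: background N(100, 5²), damaged
    voxels (lesion or WMH) N(160, 5²) — 6 sigma of separation, so threshold 130
    recovers the planted union up to cluster-size filtering."""
    lesion.check_same_grid(wmh)
    lesion.require_binary("lesion map")
    wmh.require_binary("wmh map")
    data = rng.normal(100.0, 5.0, size=lesion.shape)
    fg = (lesion.data.astype(bool)) | (wmh.data.astype(bool))
    data[fg] = rng.normal(160.0, 5.0, size=int(fg.sum()))
    return Volume(data, lesion.voxel_size_mm)


# ---------------------------------------------------------------------------
# cohort I/O (directory of NIfTI maps + CSV table)

def write_cohort(cohort: CohortTable, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i in range(cohort.n):
        pid = cohort.table["id"].iloc[i]
        write_volume(cohort.lesion_volume(i), outdir / f"{pid}_lesion.nii.gz")
        write_volume(cohort.wmh_volume(i), outdir / f"{pid}_wmh.nii.gz")
    write_volume(
        Volume(cohort.critical_region.astype(np.uint8), cohort.voxel_size_mm),
        outdir / "critical_region.nii.gz",
    )
    cohort.table.to_csv(outdir / "cohort.csv", index=False)
    return outdir


def read_cohort(indir: str | Path) -> CohortTable:
    indir = Path(indir)
    table = pd.read_csv(indir / "cohort.csv")
    lesions, wmhs = [], []
    voxel_size = None
    for pid in table["id"]:
        les = read_volume(indir / f"{pid}_lesion.nii.gz")
        wmh = read_volume(indir / f"{pid}_wmh.nii.gz")
        voxel_size = les.voxel_size_mm
        lesions.append(les.data.astype(bool))
        wmhs.append(wmh.data.astype(bool))
    critical = read_volume(indir / "critical_region.nii.gz").data.astype(bool)
    return CohortTable(
        table=table,
        lesions=np.stack(lesions),
        wmhs=np.stack(wmhs),
        voxel_size_mm=voxel_size,
        critical_region=critical,
    )
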