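"""Synthetic cohort generator: toy atlas, spherical lesions, covariates and
survival outcomes with the statistical structure the downstream analysis
assumes.

The generator emulates a brain-metastasis cohort on a small template grid: a
brain-like ellipsoidal foreground is partitioned into left/right region pairs
plus midline regions (the default configuration yields 18 regions — 8 lateral
pairs and 2 midline structures); per-patient lesion counts follow the observed
1 / 2 / >=3 split of about 49.4 / 17.0 / 33.6 percent; lesions are spheres of
varying radius placed with per-region weights; and survival times come from an
exponential proportional-hazards model in which infratentorial involvement
(computed from the patient's own rasterized lesions) and lesion-number group
shift the log-hazard.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import lesion_metrics
from .volumes_io import GridSpec, LesionMask, Region, RegionAtlas

# Default covariate frequencies mirror a large published BM cohort:
# 60.5% male; primaries dominated by lung cancer (86.1%) with adenocarcinoma
# the most common subtype; Ki-67 medians near 35% (primary) and 45% (BM).
DEFAULT_LESION_COUNT_PROBS = (0.494, 0.170, 0.336)
DEFAULT_SEX_MALE_PROB = 0.605
DEFAULT_PRIMARY_PROBS = {
    "lung": 0.861,
    "breast": 0.042,
    "colorectal": 0.025,
    "head-and-neck": 0.013,
    "kidney": 0.011,
    "melanoma": 0.006,
    "other": 0.042,
}
DEFAULT_LUNG_SUBTYPE_PROBS = {
    "adenocarcinoma": 0.664,
    "squamous": 0.112,
    "small-cell": 0.178,
    "other": 0.046,
}
DEFAULT_TREATMENT_PROBS = {
    "surgery": 0.363,
    "WBRT": 0.483,
    "SRS": 0.025,
    "surgery+WBRT": 0.092,
    "surgery+SRS": 0.037,
}
#: Generating infratentorial hazard ratio used for parameter-recovery tests.
DEFAULT_INFRATENTORIAL_HR = 1.473
#: Hazard ratios for lesion-number groups 2 and >=3 relative to 1.
DEFAULT_NUMBER_GROUP_HRS = (1.036, 1.751)
#: Baseline exponential hazard per month; ln(2)/10.84 puts the baseline
#: median overall survival near 10.84 months.
DEFAULT_BASELINE_HAZARD = float(np.log(2.0) / 10.84)


@dataclass(frozen=True)
class PatientRecord:
    """Synthetic patient covariates and survival outcome."""

    patient_id: str
    age: float
    sex: str
    primary_class: str
    lung_subtype: str | None
    ki67_primary: float
    ki67_bm: float
    treatment: str
    os_time: float
    event: bool
    n_lesions: int
    infratentorial_involvement: bool

    def __post_init__(self) -> None:
        if self.os_time < 0:
            raise ValueError("os_time must be >= 0")
        for k in (self.ki67_primary, self.ki67_bm):
            if not 0 <= k <= 100:
                raise ValueError("Ki-67 must lie in [0, 100]")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort.

    ``lesion_count_probs`` gives P(1), P(2), P(>=3); within the >=3 bin the
    count is 3 plus a geometric tail with success probability
    ``extra_lesion_geom_p``.  ``region_weights`` maps region_id to a placement
    weight (None = proportional to region volume).  The survival model is an
    exponential baseline with log-linear effects for infratentorial
    involvement and lesion-number group, and independent uniform censoring on
    [0, censoring_max].
    """

    n_patients: int = 100
    lesion_count_probs: tuple[float, float, float] = DEFAULT_LESION_COUNT_PROBS
    extra_lesion_geom_p: float = 0.5
    region_weights: dict[int, float] | None = None
    radius_range: tuple[float, float] = (1.0, 3.0)
    age_mean: float = 59.8
    age_sd: float = 12.0
    sex_male_prob: float = DEFAULT_SEX_MALE_PROB
    primary_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PRIMARY_PROBS)
    )
    lung_subtype_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LUNG_SUBTYPE_PROBS)
    )
    ki67_primary_median: float = 35.0
    ki67_bm_median: float = 45.0
    ki67_sd: float = 15.0
    treatment_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_PROBS)
    )
    baseline_hazard: float = DEFAULT_BASELINE_HAZARD
    infratentorial_hr: float = DEFAULT_INFRATENTORIAL_HR
    number_group_hrs: tuple[float, float] = DEFAULT_NUMBER_GROUP_HRS
    censoring_max: float = 72.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        p = np.asarray(self.lesion_count_probs, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("lesion_count_probs must be 3 nonnegative values summing to 1")
        if not 0 < self.extra_lesion_geom_p <= 1:
            raise ValueError("extra_lesion_geom_p must lie in (0, 1]")
        if self.radius_range[0] < 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("radius_range must be 0 <= lo <= hi")
        if self.region_weights is not None:
            w = np.asarray(list(self.region_weights.values()), dtype=float)
            if np.any(w < 0) or not np.any(w > 0):
                raise ValueError("region weights must be >= 0 with at least one positive")


# ---------------------------------------------------------------------------
# Toy atlas
# ---------------------------------------------------------------------------


def _band_edges(zmin: int, zmax: int, n_bands: int, z_cut: float | None) -> np.ndarray:
    """Equal-width z-band edges over [zmin, zmax+1); the interior edge nearest
    an infratentorial cut is snapped to it so bands never straddle the cut."""
    edges = np.linspace(zmin, zmax + 1, n_bands + 1)
    if z_cut is not None and n_bands >= 2 and edges[0] < z_cut < edges[-1]:
        interior = edges[1:-1]
        i = int(np.argmin(np.abs(interior - z_cut)))
        edges[i + 1] = z_cut
    return edges


def build_toy_atlas(
    shape: tuple[int, int, int] = (24, 28, 24),
    n_lateral_pairs: int = 8,
    n_midline: int = 2,
    infratentorial_fraction: float = 0.25,
    *,
    voxel_volume: float = 0.08,
) -> RegionAtlas:
    """Partition an ellipsoidal brain-like foreground into atlas regions.

    The foreground is split into ``n_lateral_pairs`` left/right region pairs
    (z-bands, mirrored about the x midplane) plus ``n_midline`` midline
    regions occupying a central x-strip in the lower z-bands, standing in for
    the cerebellar vermis and brainstem.  Regions whose z-extent lies below
    ``infratentorial_fraction`` of the foreground z-range are flagged
    infratentorial.
    """
    if n_lateral_pairs < 1:
        raise ValueError("need at least one lateral pair")
    if n_midline < 0:
        raise ValueError("n_midline must be >= 0")
    if not 0 <= infratentorial_fraction < 1:
        raise ValueError("infratentorial_fraction must lie in [0, 1)")
    grid = GridSpec(shape=shape, voxel_volume=voxel_volume)
    nx, ny, nz = grid.shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    # ellipsoidal foreground with semi-axes at 90% of the half-extent
    fg = (
        ((ii - cx) / (0.9 * nx / 2)) ** 2
        + ((jj - cy) / (0.9 * ny / 2)) ** 2
        + ((kk - cz) / (0.9 * nz / 2)) ** 2
    ) <= 1.0
    if not fg.any():
        raise ValueError(f"shape {shape} too small to host a foreground")
    zs = np.unique(kk[fg])
    zmin, zmax = int(zs.min()), int(zs.max())
    z_cut = (
        zmin + infratentorial_fraction * (zmax + 1 - zmin)
        if infratentorial_fraction > 0
        else None
    )

    # midline strip: central x-slab, only below the cut (or lowest band if no cut)
    midline_halfwidth = max(1.0, nx / 12.0)
    midline_strip = np.zeros_like(fg)
    if n_midline > 0:
        strip_top = z_cut if z_cut is not None else zmin + (zmax + 1 - zmin) / max(
            n_lateral_pairs, 2
        )
        midline_strip = fg & (np.abs(ii - cx) <= midline_halfwidth) & (kk < strip_top)
        if int(midline_strip.sum()) < n_midline:
            raise ValueError("infeasible partition: midline strip too small")

    lateral = fg & ~midline_strip
    labels = np.zeros(grid.shape, dtype=np.int32)
    regions: list[Region] = []
    next_id = 1

    edges = _band_edges(zmin, zmax, n_lateral_pairs, z_cut)
    for b in range(n_lateral_pairs):
        band = lateral & (kk >= edges[b]) & (kk < edges[b + 1])
        infra = z_cut is not None and edges[b + 1] <= z_cut + 1e-9
        comp = "infratentorial" if infra else "supratentorial"
        for side, sel in (("left", ii < cx), ("right", ii > cx)):
            vox = band & sel
            if not vox.any():
                raise ValueError(
                    f"infeasible partition: empty {side} region in band {b}"
                )
            labels[vox] = next_id
            regions.append(
                Region(
                    region_id=next_id,
                    name=f"{side}_band{b}",
                    laterality=side,
                    compartment=comp,
                )
            )
            next_id += 1
        # odd-x center plane voxels in a lateral-only atlas join the right side
        leftover = band & (ii == cx)
        if leftover.any():
            labels[leftover] = next_id - 1

    if n_midline > 0:
        mz = kk[midline_strip]
        m_edges = np.quantile(mz, np.linspace(0, 1, n_midline + 1))
        m_edges[-1] += 1
        for b in range(n_midline):
            vox = midline_strip & (kk >= m_edges[b]) & (kk < m_edges[b + 1])
            if not vox.any():
                raise ValueError("infeasible partition: empty midline region")
            labels[vox] = next_id
            regions.append(
                Region(
                    region_id=next_id,
                    name=f"midline_band{b}",
                    laterality="midline",
                    compartment="infratentorial" if z_cut is not None else "supratentorial",
                )
            )
            next_id += 1

    return RegionAtlas(grid=grid, labels=labels, regions=tuple(regions))


# ---------------------------------------------------------------------------
# Sphere rasterization and cohort simulation
# ---------------------------------------------------------------------------


def rasterize_sphere(
    center: Sequence[float], radius: float, grid: GridSpec
) -> LesionMask:
    """Binary mask of voxels whose centers lie within ``radius`` of ``center``.

    Radius 0 yields exactly the center voxel.  Spheres extending past the grid
    boundary are clipped.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    center = np.asarray(center, dtype=float)
    if np.any(center < 0) or np.any(center > np.asarray(grid.shape) - 1):
        raise ValueError(f"center {tuple(center)} outside grid {grid.shape}")
    data = np.zeros(grid.shape, dtype=np.uint8)
    lo = np.maximum(np.floor(center - radius).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius).astype(int) + 1, grid.shape)
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]),
        np.arange(lo[1], hi[1]),
        np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    d2 = (ii - center[0]) ** 2 + (jj - center[1]) ** 2 + (kk - center[2]) ** 2
    data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = d2 <= radius**2 + 1e-9
    if not data.any():  # radius 0 between voxel centers still marks the center voxel
        data[tuple(np.round(center).astype(int))] = 1
    return LesionMask(grid=grid, data=data)


def sample_lesion_counts(
    rng: np.random.Generator,
    n: int,
    probs: tuple[float, float, float] = DEFAULT_LESION_COUNT_PROBS,
    geom_p: float = 0.5,
) -> np.ndarray:
    """Draw per-patient lesion counts: categorical over {1, 2, >=3} with a
    shifted geometric tail inside the >=3 bin."""
    bins = rng.choice(3, size=n, p=np.asarray(probs, dtype=float))
    counts = bins + 1
    tail = bins == 2
    counts[tail] = 3 + rng.geometric(geom_p, size=int(tail.sum())) - 1
    return counts


def _region_placement_weights(
    spec: CohortSpec, atlas: RegionAtlas
) -> tuple[list[int], np.ndarray]:
    ids = [r.region_id for r in atlas.regions]
    if spec.region_weights is None:
        w = np.array([atlas.region(rid).volume for rid in ids], dtype=float)
    else:
        w = np.array([spec.region_weights.get(rid, 0.0) for rid in ids], dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("region weights must be >= 0 with positive total")
    return ids, w / w.sum()


def simulate_cohort(
    spec: CohortSpec, atlas: RegionAtlas
) -> tuple[list[PatientRecord], list[LesionMask]]:
    """Simulate a full synthetic cohort on the atlas grid.

    Reproducible under a fixed ``spec.seed``.  Each patient receives >= 1
    spherical lesion; sphere centers are drawn from region-weighted placement
    (uniform over the region's voxels) and rasterized within the atlas
    foreground, overlapping spheres merging by union.  The survival time is
    exponential with log-hazard shifted by the patient's infratentorial
    involvement — determined from the patient's own rasterized lesions via
    connected-component labeling and centroid region assignment — and
    lesion-number group, with independent uniform censoring.
    """
    rng = np.random.default_rng(spec.seed)
    ids, probs = _region_placement_weights(spec, atlas)
    region_voxels = {rid: np.argwhere(atlas.labels == rid) for rid in ids}
    fg = atlas.foreground
    counts = sample_lesion_counts(
        rng, spec.n_patients, spec.lesion_count_probs, spec.extra_lesion_geom_p
    )

    records: list[PatientRecord] = []
    masks: list[LesionMask] = []
    for i in range(spec.n_patients):
        pid = f"P{i:05d}"
        data = np.zeros(atlas.grid.shape, dtype=np.uint8)
        for _ in range(int(counts[i])):
            rid = ids[rng.choice(len(ids), p=probs)]
            vox = region_voxels[rid]
            center = vox[rng.integers(len(vox))]
            radius = rng.uniform(*spec.radius_range)
            sphere = rasterize_sphere(center, radius, atlas.grid)
            data |= sphere.data & fg
        mask = LesionMask(grid=atlas.grid, data=data, patient_id=pid)

        labeled = lesion_metrics.label_components(mask)
        lrecords = lesion_metrics.lesion_records(labeled, atlas, patient_id=pid)
        infra = any(r.compartment == "infratentorial" for r in lrecords)

        age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 16, 89))
        sex = "male" if rng.random() < spec.sex_male_prob else "female"
        primary = rng.choice(
            list(spec.primary_probs), p=_normalized(spec.primary_probs)
        )
        subtype = (
            str(rng.choice(list(spec.lung_subtype_probs), p=_normalized(spec.lung_subtype_probs)))
            if primary == "lung"
            else None
        )
        ki67p = float(np.clip(rng.normal(spec.ki67_primary_median, spec.ki67_sd), 0, 100))
        ki67b = float(np.clip(rng.normal(spec.ki67_bm_median, spec.ki67_sd), 0, 100))
        treatment = str(
            rng.choice(list(spec.treatment_probs), p=_normalized(spec.treatment_probs))
        )

        group = lesion_metrics.number_group(int(counts[i]))
        log_hr = 0.0
        if infra:
            log_hr += np.log(spec.infratentorial_hr)
        if group == "2":
            log_hr += np.log(spec.number_group_hrs[0])
        elif group == ">=3":
            log_hr += np.log(spec.number_group_hrs[1])
        hazard = spec.baseline_hazard * np.exp(log_hr)
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.uniform(0, spec.censoring_max)
        os_time = float(min(t_event, t_cens))
        event = bool(t_event <= t_cens)

        records.append(
            PatientRecord(
                patient_id=pid,
                age=age,
                sex=sex,
                primary_class=str(primary),
                lung_subtype=subtype,
                ki67_primary=ki67p,
                ki67_bm=ki67b,
                treatment=treatment,
                os_time=os_time,
                event=event,
                n_lesions=int(counts[i]),
                infratentorial_involvement=infra,
            )
        )
        masks.append(mask)
    return records, masks


def _normalized(probs: dict[str, float]) -> np.ndarray:
    w = np.asarray(list(probs.values()), dtype=float)
    return w / w.sum()


def records_to_frame(records: Sequence[PatientRecord]):
    """Covariate table (one row per patient) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "age": r.age,
                "sex": r.sex,
                "primary_class": r.primary_class,
                "lung_subtype": r.lung_subtype if r.lung_subtype is not None else "",
                "ki67_primary": r.ki67_primary,
                "ki67_bm": r.ki67_bm,
                "treatment": r.treatment,
                "os_time": r.os_time,
                "event": int(r.event),
                "n_lesions": r.n_lesions,
                "infratentorial_involvement": int(r.infratentorial_involvement),
            }
            for r in records
        ]
    )


def weighted_spec(
    spec: CohortSpec, atlas: RegionAtlas, *, infratentorial_factor: float
) -> CohortSpec:
    """Copy of ``spec`` with infratentorial region weights scaled by a factor.

    Used to plant a differential-involvement effect between two groups: group
    A simulated with factor k places lesions in infratentorial regions k-fold
    more often (per unit weight) than group B with factor 1.
    """
    base = {
        r.region_id: (
            spec.region_weights.get(r.region_id, 0.0)
            if spec.region_weights is not None
            else r.volume
        )
        for r in atlas.regions
    }
    weights = {
        rid: w * (infratentorial_factor if atlas.region(rid).compartment == "infratentorial" else 1.0)
        for rid, w in base.items()
    }
    return replace(spec, region_weights=weights)
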