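"""Lesion-level metrics: connected-component labeling, centroids, volumes,
region assignment, per-patient summaries and nonparametric group comparisons.

Adjacent lesion masks are differentiated by 3-D connected-component labeling.
The default connectivity is 26 (faces, edges and corners of the voxel cube),
matching the MATLAB ``bwlabeln`` default; 6 and 18 are selectable.  Each
component's centroid (unweighted mean of member voxel indices) determines the
brain region the lesion is assigned to, winner-takes-all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .volumes_io import GridSpec, LesionMask, RegionAtlas

CONNECTIVITY_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}

DEFAULT_CONNECTIVITY = 26

NUMBER_GROUPS = ("1", "2", ">=3")


@dataclass(frozen=True)
class LabeledLesions:
    """Connected lesion components: 0 = background, 1..K = components."""

    grid: GridSpec
    labels: np.ndarray
    connectivity: int
    patient_id: str = ""

    @property
    def n_lesions(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class LesionRecord:
    """One connected lesion: size, volume, centroid and assigned region."""

    patient_id: str
    lesion_id: int
    voxel_count: int
    volume: float
    centroid: tuple[float, float, float]
    region_id: int
    laterality: str
    compartment: str


def label_components(
    mask: LesionMask, connectivity: int = DEFAULT_CONNECTIVITY
) -> LabeledLesions:
    """Label maximal connected foreground sets under the chosen connectivity."""
    if connectivity not in CONNECTIVITY_STRUCTURES:
        raise ValueError(
            f"connectivity must be one of {sorted(CONNECTIVITY_STRUCTURES)}, "
            f"got {connectivity}"
        )
    labels, _ = ndimage.label(mask.data, structure=CONNECTIVITY_STRUCTURES[connectivity])
    return LabeledLesions(
        grid=mask.grid,
        labels=labels.astype(np.int32),
        connectivity=connectivity,
        patient_id=mask.patient_id,
    )


def lesion_centroid(labeled: LabeledLesions, lesion_id: int) -> tuple[float, float, float]:
    """Unweighted mean of member voxel indices."""
    if lesion_id < 1 or lesion_id > labeled.n_lesions:
        raise KeyError(f"unknown lesion_id {lesion_id} (have 1..{labeled.n_lesions})")
    coords = np.argwhere(labeled.labels == lesion_id)
    return tuple(coords.mean(axis=0))


def _nearest_voxel_index(centroid: Sequence[float], shape: tuple[int, ...]) -> tuple[int, ...]:
    # round to nearest voxel; .5 ties break toward the lower index
    idx = tuple(int(np.ceil(c - 0.5)) for c in centroid)
    return tuple(min(max(i, 0), s - 1) for i, s in zip(idx, shape))


def assign_region(
    centroid: Sequence[float], atlas: RegionAtlas
) -> tuple[int, str, str]:
    """Assign a centroid to the atlas region at its nearest voxel.

    If the nearest voxel is background, the nearest labeled voxel (Euclidean
    distance from the centroid) wins; exact distance ties break toward the
    lowest region_id.
    """
    centroid = np.asarray(centroid, dtype=float)
    if np.any(centroid < -0.5) or np.any(centroid > np.array(atlas.grid.shape) - 0.5):
        raise ValueError(f"centroid {tuple(centroid)} outside grid {atlas.grid.shape}")
    idx = _nearest_voxel_index(centroid, atlas.grid.shape)
    rid = int(atlas.labels[idx])
    if rid == 0:
        fg = np.argwhere(atlas.labels > 0)
        if len(fg) == 0:
            raise ValueError("atlas has no labeled voxels")
        tree = cKDTree(fg)
        dist, _ = tree.query(centroid, k=1)
        candidates = tree.query_ball_point(centroid, r=dist + 1e-9)
        cand_ids = [int(atlas.labels[tuple(fg[i])]) for i in candidates]
        rid = min(cand_ids)
    region = atlas.region(rid)
    return rid, region.laterality, region.compartment


def lesion_records(
    labeled: LabeledLesions, atlas: RegionAtlas, *, patient_id: str | None = None
) -> list[LesionRecord]:
    """Build one record per labeled lesion (size, volume, centroid, region)."""
    pid = patient_id if patient_id is not None else labeled.patient_id
    records: list[LesionRecord] = []
    counts = np.bincount(labeled.labels.ravel(), minlength=labeled.n_lesions + 1)
    for lesion_id in range(1, labeled.n_lesions + 1):
        centroid = lesion_centroid(labeled, lesion_id)
        rid, lat, comp = assign_region(centroid, atlas)
        voxel_count = int(counts[lesion_id])
        records.append(
            LesionRecord(
                patient_id=pid,
                lesion_id=lesion_id,
                voxel_count=voxel_count,
                volume=voxel_count * labeled.grid.voxel_volume,
                centroid=centroid,
                region_id=rid,
                laterality=lat,
                compartment=comp,
            )
        )
    return records


def number_group(n: int) -> str:
    """Bin a lesion count into the 1 / 2 / >=3 groups."""
    if n < 1:
        raise ValueError("lesion number must be >= 1")
    return "1" if n == 1 else "2" if n == 2 else ">=3"


def summarize_patient(records: Sequence[LesionRecord]) -> dict:
    """Per-patient lesion summary.

    Returns lesion number and number group, total volume (TV), mean volume of
    the single lesion (VSL = TV / number), per-region counts/TV/VSL, and
    whether any lesion sits in an infratentorial region.
    """
    if not records:
        raise ValueError("empty lesion record list")
    pids = {r.patient_id for r in records}
    if len(pids) != 1:
        raise ValueError(f"records span multiple patients: {sorted(pids)}")
    n = len(records)
    tv = float(sum(r.volume for r in records))
    per_region: dict[int, dict] = {}
    for r in records:
        reg = per_region.setdefault(r.region_id, {"count": 0, "tv": 0.0})
        reg["count"] += 1
        reg["tv"] += r.volume
    for reg in per_region.values():
        reg["vsl"] = reg["tv"] / reg["count"]
    return {
        "patient_id": records[0].patient_id,
        "n_lesions": n,
        "number_group": number_group(n),
        "tv": tv,
        "vsl": tv / n,
        "per_region": per_region,
        "infratentorial_involvement": any(
            r.compartment == "infratentorial" for r in records
        ),
    }


def records_to_table(records: Iterable[LesionRecord]) -> pd.DataFrame:
    """Tidy lesion table (one row per lesion) for CSV export."""
    rows = [
        {
            "patient_id": r.patient_id,
            "lesion_id": r.lesion_id,
            "voxel_count": r.voxel_count,
            "volume_mm3": r.volume,
            "cx": r.centroid[0],
            "cy": r.centroid[1],
            "cz": r.centroid[2],
            "region_id": r.region_id,
            "laterality": r.laterality,
            "compartment": r.compartment,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "lesion_id",
            "voxel_count",
            "volume_mm3",
            "cx",
            "cy",
            "cz",
            "region_id",
            "laterality",
            "compartment",
        ],
    )


def summaries_to_table(summaries: Iterable[Mapping]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": s["patient_id"],
            "n_lesions": s["n_lesions"],
            "number_group": s["number_group"],
            "tv": s["tv"],
            "vsl": s["vsl"],
            "infratentorial_involvement": bool(s["infratentorial_involvement"]),
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Nonparametric group comparisons (Mann-Whitney / Kruskal-Wallis + Dunn)
# ---------------------------------------------------------------------------


def _dunn_posthoc(
    values_by_group: Mapping[str, Sequence[float]], adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's rank-based pairwise z-tests after Kruskal-Wallis.

    Uses pooled mid-ranks with the standard tie correction; p-values are
    adjusted across all pairs (Bonferroni by default).
    """
    groups = list(values_by_group)
    pooled = np.concatenate([np.asarray(values_by_group[g], float) for g in groups])
    sizes = {g: len(values_by_group[g]) for g in groups}
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    # mean rank per group
    mean_rank = {}
    start = 0
    for g in groups:
        mean_rank[g] = ranks[start : start + sizes[g]].mean()
        start += sizes[g]
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    rows = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            se = np.sqrt(
                (n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1)))
                * (1.0 / sizes[g1] + 1.0 / sizes[g2])
            )
            z = (mean_rank[g1] - mean_rank[g2]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_1": g1, "group_2": g2, "z": z, "p_raw": p})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = multipletests(table["p_raw"], method=adjust)[1].clip(0, 1)
    return table


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    test: str = "auto",
    *,
    posthoc: bool = True,
    adjust: str = "bonferroni",
) -> dict:
    """Compare distributions across groups.

    ``test`` is ``"mann-whitney"`` (two groups), ``"kruskal-wallis"`` (any
    number), or ``"auto"`` which picks Mann-Whitney for exactly two groups.
    With three or more groups Dunn's pairwise post hoc comparisons are
    appended unless ``posthoc=False``.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, v in groups.items():
        if len(v) < 1:
            raise ValueError(f"group {g!r} is empty")
    if test == "auto":
        test = "mann-whitney" if len(groups) == 2 else "kruskal-wallis"
    if test == "mann-whitney":
        if len(groups) != 2:
            raise ValueError("mann-whitney requires exactly two groups")
        (x, y) = groups.values()
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        out = {"test": "mann-whitney", "statistic": float(res.statistic), "p": float(res.pvalue)}
    elif test == "kruskal-wallis":
        res = stats.kruskal(*groups.values())
        out = {"test": "kruskal-wallis", "statistic": float(res.statistic), "p": float(res.pvalue)}
        if posthoc and len(groups) >= 3:
            out["posthoc"] = _dunn_posthoc(values_by_group, adjust=adjust)
    else:
        raise ValueError(f"unknown test {test!r}")
    return out
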