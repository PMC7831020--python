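"""Voxel-wise mapping statistics: tumor-frequency heatmaps, per-voxel
two-sided Fisher exact-test maps (analysis of differential involvement,
ADIFFI), significant-cluster extraction, and region-wise relative metastatic
risk (RMR).

ADIFFI compares lesion presence between two patient phenotypes voxel by
voxel.  At each voxel the 2x2 contingency table is

    a = patients of phenotype A with a lesion at the voxel
    b = patients of phenotype B with a lesion at the voxel
    c = nA - a (tumor-free A patients), d = nB - b (tumor-free B patients)

and the two-sided exact p-value sums hypergeometric point probabilities

    P(table) = (a+b)! (c+d)! (a+c)! (b+d)! / (a! b! c! d! n!)

over all tables with the observed margins whose probability does not exceed
the observed table's.  Counting is patient-level: a patient contributes at
most one to a voxel regardless of lesion multiplicity.

The relative metastatic risk of region x normalizes the patient-level
metastasis rate by region volume and by the across-region average:

    RMR_x = (N_x / N_p / V_x) / (sum_i (N_i / N_p / V_i) / N_R)

so the arithmetic mean of RMR over regions is exactly 1; RMR > 1 marks a
susceptible region.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .lesion_metrics import CONNECTIVITY_STRUCTURES, DEFAULT_CONNECTIVITY, LesionRecord
from .volumes_io import GridSpec, LesionMask, RegionAtlas, validate_cohort_grids

DIRECTION_NONE = 0
DIRECTION_A = 1
DIRECTION_B = -1

#: Relative tolerance when comparing point probabilities to the observed
#: table's; keeps tied tables in the tail despite floating rounding.
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class FrequencyMap:
    """Voxel-wise count of patients with a lesion at each voxel."""

    grid: GridSpec
    counts: np.ndarray
    n_patients: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != self.grid.shape:
            raise ValueError("counts shape does not match grid")
        if counts.min() < 0 or counts.max() > self.n_patients:
            raise ValueError("counts must lie in [0, n_patients]")
        object.__setattr__(self, "counts", counts.astype(np.int32))


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table of lesion presence by phenotype with fixed margins."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError("cell counts must be nonnegative integers")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class PValueMap:
    """Per-voxel two-sided exact p with the direction of the higher-rate group."""

    grid: GridSpec
    p: np.ndarray
    direction: np.ndarray  # {+1: A higher, -1: B higher, 0: none}
    n_a: int
    n_b: int


def frequency_map(masks: Sequence[LesionMask]) -> FrequencyMap:
    """Overlap binary masks into a voxel-wise patient count."""
    if not masks:
        raise ValueError("empty mask list")
    grid = validate_cohort_grids(masks)
    counts = np.zeros(grid.shape, dtype=np.int32)
    for m in masks:
        counts += m.data
    return FrequencyMap(grid=grid, counts=counts, n_patients=len(masks))


@lru_cache(maxsize=4096)
def _two_sided_p_vector(n_a: int, n_b: int, k: int) -> tuple[float, ...]:
    """Two-sided exact p for every achievable ``a`` at fixed margins.

    Margins: column totals (n_a, n_b) and row totals (k, n-k) where k = a+b.
    Returns p indexed by a - max(0, k - n_b).
    """
    n = n_a + n_b
    a_lo = max(0, k - n_b)
    a_hi = min(k, n_a)
    support = np.arange(a_lo, a_hi + 1)
    pmf = hypergeom.pmf(support, n, k, n_a)
    ps = []
    for p_obs in pmf:
        ps.append(float(min(1.0, pmf[pmf <= p_obs * (1 + _TIE_RTOL)].sum())))
    return tuple(ps)


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Sums the point probabilities of all tables with the observed margins
    whose probability is <= the observed table's (ties included).  Degenerate
    margins (an empty row or column) give p = 1.
    """
    n_a = table.a + table.c
    n_b = table.b + table.d
    k = table.a + table.b
    if n_a == 0 or n_b == 0 or k == 0 or k == table.n:
        return 1.0
    ps = _two_sided_p_vector(n_a, n_b, k)
    return ps[table.a - max(0, k - n_b)]


def adiffi_map(
    masks_a: Sequence[LesionMask], masks_b: Sequence[LesionMask]
) -> PValueMap:
    """Per-voxel two-sided Fisher exact test between two phenotype groups.

    Voxels untouched in both groups get p = 1 and direction none.  The
    direction marks which group has the higher lesion proportion at the
    voxel.
    """
    if not masks_a or not masks_b:
        raise ValueError("both groups must be nonempty")
    grid = validate_cohort_grids(list(masks_a) + list(masks_b))
    n_a, n_b = len(masks_a), len(masks_b)
    count_a = frequency_map(masks_a).counts
    count_b = frequency_map(masks_b).counts

    p = np.ones(grid.shape, dtype=float)
    direction = np.zeros(grid.shape, dtype=np.int8)

    # evaluate the exact test once per distinct (a, b) pair
    pair = count_a.astype(np.int64) * (n_b + 1) + count_b
    unique_pairs, inverse = np.unique(pair, return_inverse=True)
    p_flat = np.empty(len(unique_pairs))
    d_flat = np.empty(len(unique_pairs), dtype=np.int8)
    for i, code in enumerate(unique_pairs):
        a, b = int(code // (n_b + 1)), int(code % (n_b + 1))
        p_flat[i] = fisher_exact_two_sided(
            ContingencyTable(a=a, b=b, c=n_a - a, d=n_b - b)
        )
        rate_a, rate_b = a / n_a, b / n_b
        d_flat[i] = (
            DIRECTION_A if rate_a > rate_b else DIRECTION_B if rate_b > rate_a else DIRECTION_NONE
        )
    p[:] = p_flat[inverse].reshape(grid.shape)
    direction[:] = d_flat[inverse].reshape(grid.shape)
    return PValueMap(grid=grid, p=p, direction=direction, n_a=n_a, n_b=n_b)


def fdr_adjust(pmap: PValueMap, foreground: np.ndarray | None = None) -> PValueMap:
    """Optional Benjamini-Hochberg adjustment across tested voxels.

    Degenerate voxels (p = 1, direction none) are skipped.  Off by default in
    the pipeline, matching per-voxel thresholding at alpha.
    """
    tested = pmap.direction != DIRECTION_NONE
    if foreground is not None:
        tested &= foreground
    q = pmap.p.copy()
    if tested.any():
        q[tested] = multipletests(pmap.p[tested], method="fdr_bh")[1]
    return PValueMap(
        grid=pmap.grid, p=q, direction=pmap.direction, n_a=pmap.n_a, n_b=pmap.n_b
    )


def extract_clusters(
    pmap: PValueMap,
    alpha: float = 0.05,
    min_size: int = 1,
    atlas: RegionAtlas | None = None,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> pd.DataFrame:
    """Connected components of significant voxels, per direction.

    Voxels with p < alpha are grouped by the same connectivity rule as lesion
    labeling, separately for each direction; clusters below ``min_size``
    voxels are dropped.  With an atlas, per-compartment voxel fractions and
    the dominant region are reported.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    structure = CONNECTIVITY_STRUCTURES[connectivity]
    rows = []
    cluster_id = 0
    for direction, dname in ((DIRECTION_A, "A"), (DIRECTION_B, "B")):
        sig = (pmap.p < alpha) & (pmap.direction == direction)
        labels, k = ndimage.label(sig, structure=structure)
        for comp in range(1, k + 1):
            vox = labels == comp
            size = int(vox.sum())
            if size < min_size:
                continue
            cluster_id += 1
            masked_p = np.where(vox, pmap.p, np.inf)
            peak = np.unravel_index(int(np.argmin(masked_p)), pmap.p.shape)
            row = {
                "cluster_id": cluster_id,
                "direction": dname,
                "size": size,
                "peak_i": peak[0],
                "peak_j": peak[1],
                "peak_k": peak[2],
                "peak_p": float(pmap.p[peak]),
            }
            if atlas is not None:
                infra = atlas.compartment_mask("infratentorial")
                row["infratentorial_fraction"] = float((vox & infra).sum() / size)
                row["supratentorial_fraction"] = float(
                    (vox & atlas.compartment_mask("supratentorial")).sum() / size
                )
                in_cluster = atlas.labels[vox]
                in_cluster = in_cluster[in_cluster > 0]
                row["dominant_region"] = (
                    int(np.bincount(in_cluster).argmax()) if len(in_cluster) else 0
                )
            rows.append(row)
    cols = [
        "cluster_id", "direction", "size", "peak_i", "peak_j", "peak_k", "peak_p",
    ]
    if atlas is not None:
        cols += ["infratentorial_fraction", "supratentorial_fraction", "dominant_region"]
    frame = pd.DataFrame(rows, columns=cols)
    return frame.sort_values(["direction", "size"], ascending=[True, False]).reset_index(
        drop=True
    )


def relative_metastatic_risk(
    records_by_patient: Mapping[str, Sequence[LesionRecord]],
    atlas: RegionAtlas,
    n_patients: int,
) -> pd.DataFrame:
    """Region-wise relative metastatic risk.

    ``N_x`` counts patients (not lesions) with at least one centroid-assigned
    lesion in region x.  The per-volume risk N_x / N_p / V_x is normalized by
    its across-region mean, so mean(RMR) = 1.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    region_ids = [r.region_id for r in atlas.regions]
    volumes = {r.region_id: r.volume for r in atlas.regions}
    if any(v <= 0 for v in volumes.values()):
        raise ValueError("every region must have positive volume")
    n_x = dict.fromkeys(region_ids, 0)
    for records in records_by_patient.values():
        for rid in {r.region_id for r in records}:
            if rid not in n_x:
                raise ValueError(f"record region {rid} not in atlas")
            n_x[rid] += 1
    risk = {rid: n_x[rid] / n_patients / volumes[rid] for rid in region_ids}
    mean_risk = sum(risk.values()) / len(region_ids)
    if mean_risk == 0:
        raise ValueError("no patient has any lesion; RMR undefined")
    table = pd.DataFrame(
        {
            "region_id": region_ids,
            "n_patients_with_bm": [n_x[rid] for rid in region_ids],
            "volume_mm3": [volumes[rid] for rid in region_ids],
            "per_volume_risk": [risk[rid] for rid in region_ids],
            "rmr": [risk[rid] / mean_risk for rid in region_ids],
        }
    )
    table.attrs["n_patients"] = n_patients
    table.attrs["n_regions"] = len(region_ids)
    return table
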