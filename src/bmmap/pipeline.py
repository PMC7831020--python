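"""End-to-end orchestration: simulate (or load) a cohort, compute lesion
metrics, frequency and ADIFFI maps, relative metastatic risk, and survival
tables from one config, with a reproducible run manifest.

All randomness flows from the single config seed through
``numpy.random.SeedSequence.spawn``, so a rerun with the same config produces
byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .lesion_metrics import (
    DEFAULT_CONNECTIVITY,
    label_components,
    lesion_records,
    records_to_table,
    summaries_to_table,
    summarize_patient,
)
from .mapping_stats import (
    DIRECTION_NONE,
    adiffi_map,
    extract_clusters,
    fdr_adjust,
    frequency_map,
    relative_metastatic_risk,
)
from .survival_stage import DEFAULT_FACTORS, build_strata, cox_regression, km_by_stratum
from .synthetic_cohort import CohortSpec, build_toy_atlas, records_to_frame, simulate_cohort
from .volumes_io import write_atlas, write_map

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    n_patients: int = 60
    seed: int = 0
    atlas_shape: tuple[int, int, int] = (24, 28, 24)
    n_lateral_pairs: int = 8
    n_midline: int = 2
    infratentorial_fraction: float = 0.25
    voxel_volume: float = 0.08
    connectivity: int = DEFAULT_CONNECTIVITY
    alpha: float = 0.05
    min_cluster_size: int = 1
    fdr: bool = False
    adiffi_factor: str = "sex"  # covariate splitting the two ADIFFI phenotypes
    medians: dict[str, float] = field(default_factory=dict)
    output_dir: str = "bmmap_run"
    cohort: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        self.atlas_shape = tuple(int(s) for s in self.atlas_shape)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "stages": [],
        "outputs": {},
    }

    def stage(name: str):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("atlas")
        atlas = build_toy_atlas(
            shape=config.atlas_shape,
            n_lateral_pairs=config.n_lateral_pairs,
            n_midline=config.n_midline,
            infratentorial_fraction=config.infratentorial_fraction,
            voxel_volume=config.voxel_volume,
        )
        write_atlas(atlas, out / "atlas.nii.gz", out / "atlas_regions.tsv")

        stage("simulate")
        seeds = np.random.SeedSequence(config.seed).spawn(1)
        spec = CohortSpec(
            n_patients=config.n_patients,
            seed=int(seeds[0].generate_state(1)[0] % (2**31)),
            **config.cohort,
        )
        patients, masks = simulate_cohort(spec, atlas)
        covariates = records_to_frame(patients)
        _write_csv(covariates, out / "covariates.csv")

        stage("metrics")
        all_records = []
        summaries = []
        for mask in masks:
            labeled = label_components(mask, config.connectivity)
            recs = lesion_records(labeled, atlas)
            all_records.extend(recs)
            summaries.append(summarize_patient(recs))
        _write_csv(records_to_table(all_records), out / "lesions.csv")
        summary_table = summaries_to_table(summaries)
        _write_csv(summary_table, out / "patient_summaries.csv")

        stage("freqmap")
        fmap = frequency_map(masks)
        write_map(fmap.counts, atlas.grid, out / "frequency_map.nii.gz")

        stage("adiffi")
        values = covariates[config.adiffi_factor]
        levels = sorted(values.unique())
        if len(levels) != 2:
            raise ValueError(
                f"ADIFFI factor {config.adiffi_factor!r} must have 2 levels, has {len(levels)}"
            )
        group_a = [m for m, v in zip(masks, values) if v == levels[0]]
        group_b = [m for m, v in zip(masks, values) if v == levels[1]]
        pmap = adiffi_map(group_a, group_b)
        if config.fdr:
            pmap = fdr_adjust(pmap, atlas.foreground)
        write_map(pmap.p, atlas.grid, out / "adiffi_p.nii.gz")
        write_map(pmap.direction.astype(np.int8), atlas.grid, out / "adiffi_direction.nii.gz")
        clusters = extract_clusters(
            pmap,
            alpha=config.alpha,
            min_size=config.min_cluster_size,
            atlas=atlas,
            connectivity=config.connectivity,
        )
        _write_csv(clusters, out / "adiffi_clusters.csv")
        manifest["adiffi"] = {
            "factor": config.adiffi_factor,
            "phenotype_a": str(levels[0]),
            "phenotype_b": str(levels[1]),
            "n_a": pmap.n_a,
            "n_b": pmap.n_b,
            "n_significant_voxels": int(
                ((pmap.p < config.alpha) & (pmap.direction != DIRECTION_NONE)).sum()
            ),
        }

        stage("rmr")
        by_patient: dict[str, list] = {}
        for rec in all_records:
            by_patient.setdefault(rec.patient_id, []).append(rec)
        rmr = relative_metastatic_risk(by_patient, atlas, n_patients=len(patients))
        _write_csv(rmr, out / "rmr.csv")

        stage("survival")
        strata = build_strata(covariates, summary_table, medians=config.medians)
        factors = [f for f in DEFAULT_FACTORS if f in strata.frame.columns]
        uni = cox_regression(strata, factors, mode="univariate")
        multi = cox_regression(strata, factors, mode="multivariate")
        _write_csv(pd.concat([uni, multi], ignore_index=True), out / "cox.csv")
        km_rows = []
        for factor in factors:
            res = km_by_stratum(strata, factor)
            for level, est in res["estimates"].items():
                km_rows.append(
                    {
                        "factor": factor,
                        "level": level,
                        "n": int((strata.frame[factor].astype(str) == level).sum()),
                        "median_os": est["median"] if est["median_defined"] else np.nan,
                        "logrank_p": res["logrank"]["p"] if res["logrank"] else np.nan,
                    }
                )
        _write_csv(pd.DataFrame(km_rows), out / "km_medians.csv")
        manifest["medians"] = strata.medians

        stage("summary")
        demo = demographic_summary(covariates, summary_table)
        _write_csv(demo, out / "demographics.csv")
    except Exception as err:
        current = manifest["stages"][-1] if manifest["stages"] else "init"
        raise RuntimeError(f"pipeline stage {current!r} failed: {err}") from err

    for p in sorted(out.iterdir()):
        if p.suffix in (".csv", ".tsv") or p.name.endswith(".nii.gz"):
            manifest["outputs"][p.name] = _hash_file(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


# ---------------------------------------------------------------------------
# Demographic summary
# ---------------------------------------------------------------------------


def percentage(count: int, denominator: int) -> float:
    """Percentage with one-decimal half-up rounding (display convention)."""
    if denominator == 0:
        return 0.0
    return float(np.floor(1000.0 * count / denominator + 0.5) / 10.0)


def demographic_summary(
    covariates: pd.DataFrame, summaries: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Cohort summary table: counts and percentages by category.

    Denominators: the full cohort for sex, primaries and lesion-number
    groups; lung-cancer patients for lung subtypes; treated patients for
    treatment categories.
    """
    if len(covariates) == 0:
        raise ValueError("empty cohort")
    n = len(covariates)
    rows: list[dict] = []

    def add(parameter: str, category: str, count: int, denom: int) -> None:
        rows.append(
            {
                "parameter": parameter,
                "category": category,
                "count": int(count),
                "percent": percentage(count, denom),
            }
        )

    for sex in ("male", "female"):
        add("sex", sex, (covariates["sex"] == sex).sum(), n)
    for primary, cnt in covariates["primary_class"].value_counts().items():
        add("primary", str(primary), cnt, n)
    if "lung_subtype" in covariates.columns:
        lung = covariates[covariates["primary_class"] == "lung"]
        if len(lung):
            for sub, cnt in lung["lung_subtype"].value_counts().items():
                if str(sub):
                    add("lung_subtype", str(sub), cnt, len(lung))
    counts_col = None
    if summaries is not None and "number_group" in summaries.columns:
        counts_col = summaries["number_group"]
    elif "n_lesions" in covariates.columns:
        from .lesion_metrics import number_group

        counts_col = covariates["n_lesions"].map(number_group)
    if counts_col is not None:
        for grp in ("1", "2", ">=3"):
            add("bm_number", grp, (counts_col == grp).sum(), len(counts_col))
    if "treatment" in covariates.columns:
        treated = covariates[covariates["treatment"].astype(str) != ""]
        for trt, cnt in treated["treatment"].value_counts().items():
            add("treatment", str(trt), cnt, len(treated))
    return pd.DataFrame(rows, columns=["parameter", "category", "count", "percent"])
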