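"""End-to-end runs: configuration, QC filters, logging, cohort assembly.

A run simulates (or loads) per-subject DWI and stain data, fits the
ADC_aqp maps, applies the ROI-area QC rule (a lesion must cover at least
100 mm² on its largest axial plane), extracts histogram features, scores
the IHC both ways, assembles the cohort table and runs the statistical
battery. Every stage logs its seed and the exact thresholds applied;
reruns with the same config are bit-identical for deterministic stages.

Clinical exclusion criteria beyond ROI area (prior treatment, DWI-surgery
interval, histology type, stain quality) are consumed as metadata, not
computed here.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import adc, features, ihc, stats, synthetic

__all__ = ["RunConfig", "qc_roi_area", "run_end_to_end", "MIN_ROI_AREA_MM2"]

log = logging.getLogger("adcaqp")

#: smallest acceptable lesion ROI area on the largest axial plane (mm²)
MIN_ROI_AREA_MM2 = 100.0


@dataclass
class RunConfig:
    """Every switch of a run, serializable to one JSON file."""

    out_dir: str = "run_out"
    seed: int = 0
    # simulation block
    n_subjects: int = 8
    grid_shape: list = field(default_factory=lambda: [32, 32, 10])
    voxel_size_mm: list = field(default_factory=lambda: [1.0, 1.0, 5.0])
    lesion_radius_mm: list = field(default_factory=lambda: [10.0])
    adc_spread: float = 0.05
    adc_texture_mm: float = 3.0
    s0_level: float = 1000.0
    noise_sigma: float = 10.0
    b_values: list = field(default_factory=lambda: list(synthetic.DEFAULT_B_VALUES))
    stain_image_px: int = 560
    stain_mpp: float = 1.0
    stain_n_cells: int = 600
    # module switches (documented defaults)
    kurtosis_convention: str = "excess"
    weighted_fit: bool = False
    stain_matrix: list = None
    tile_um: float = 100.0
    tile_min_coverage: float = 0.5
    background_percentile: float = 5.0
    t_test_variant: str = "student"
    alpha: float = 0.05
    family_alpha: float = 0.05
    min_roi_area_mm2: float = MIN_ROI_AREA_MM2

    def to_json(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=1, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def qc_roi_area(mask, voxel_size_mm, min_area_mm2: float = MIN_ROI_AREA_MM2):
    """Largest-axial-plane ROI area rule.

    The area on each axial slice (last axis) is the voxel count times the
    in-plane voxel area; a lesion passes iff its largest slice covers at
    least ``min_area_mm2``. Returns ``(largest_axial_area_mm2, pass_flag)``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    in_plane = float(voxel_size_mm[0]) * float(voxel_size_mm[1])
    per_slice = mask.reshape(-1, mask.shape[-1]).sum(axis=0) * in_plane
    largest = float(per_slice.max())
    return largest, largest >= min_area_mm2


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str):
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def _subject_groups(n: int):
    """Deterministic differentiation labels, moderate-heavy like the cohort."""
    cycle = ["good", "moderate", "moderate", "poor"]
    return [cycle[i % len(cycle)] for i in range(n)]


_GROUP_ADC_MEAN = {"good": 0.346, "moderate": 0.388, "poor": 0.442}
_GROUP_INTENSITY = {"good": 1, "moderate": 2, "poor": 3}


def run_end_to_end(config: RunConfig) -> Path:
    """Simulate, fit, QC, extract, score and analyze; returns the report dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    cfg_hash = config.config_hash()
    try:
        config.to_json(out / "run_config.json")
        log.info("run start: seed=%d n_subjects=%d config_hash=%s",
                 config.seed, config.n_subjects, cfg_hash)
        groups = _subject_groups(config.n_subjects)
        radii = list(config.lesion_radius_mm)
        rows, exclusions = [], []
        ss = np.random.SeedSequence([int(config.seed), 4])
        obs_rng = np.random.default_rng(ss)
        for i in range(config.n_subjects):
            sid = f"sub-{i + 1:03d}"
            sdir = out / "subjects" / sid
            group = groups[i]
            radius = radii[i % len(radii)]
            sub_seed = int(config.seed) * 10_000 + i
            try:
                row = _process_subject(i, sid, sdir, group, radius, sub_seed,
                                       config, obs_rng, exclusions)
            except ValueError as err:
                raise RuntimeError(f"stage failure for subject {sid}: {err}") from err
            if row is not None:
                rows.append(row)
        excl = pd.DataFrame(exclusions, columns=["subject_id", "reason", "value"])
        _write_csv(excl, out / "exclusions.csv", cfg_hash)
        if not rows:
            raise RuntimeError("no subject passed QC; cohort is empty")
        cohort = pd.DataFrame(rows)
        _write_csv(cohort, out / "cohort.csv", cfg_hash)
        log.info("cohort assembled: %d subjects, %d excluded", len(cohort), len(excl))

        # inter-observer reliability of the manual score
        icc_res = stats.icc_two_observers(
            cohort[["manual_score_obs1", "manual_score_obs2"]].to_numpy())
        icc_df = pd.DataFrame([{"parameter": "manual_score", "icc": icc_res.icc,
                                "model": icc_res.model_label,
                                "reliability": icc_res.reliability_label}])
        _write_csv(icc_df, out / "icc.csv", cfg_hash)

        if len(cohort) >= 6 and cohort["differentiation"].value_counts().min() >= 2:
            report = stats.analyze_cohort(cohort, family_alpha=config.family_alpha,
                                          alpha=config.alpha,
                                          t_variant=config.t_test_variant)
            _write_csv(report["correlations"], out / "correlations.csv", cfg_hash)
            _write_csv(report["differentiation_anova"],
                       out / "differentiation_anova.csv", cfg_hash)
            _write_csv(report["stage_tests"], out / "stage_tests.csv", cfg_hash)
            (out / "thresholds.json").write_text(
                json.dumps(report["thresholds"], indent=1))
            log.info("statistics written; thresholds: %s", report["thresholds"])
        else:
            log.warning("cohort too small for the group statistics; skipped")
        log.info("run complete")
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _process_subject(idx, sid, sdir, group, radius, sub_seed, config, obs_rng,
                     exclusions):
    spec = synthetic.PhantomSpec(
        grid_shape=tuple(config.grid_shape),
        voxel_size_mm=tuple(config.voxel_size_mm),
        lesion_radius_mm=radius,
        adc_mean=_GROUP_ADC_MEAN[group],
        adc_spread=config.adc_spread,
        adc_texture_mm=config.adc_texture_mm,
        s0_level=config.s0_level,
        noise_sigma=config.noise_sigma,
        seed=sub_seed,
    )
    truth, mask = synthetic.generate_adc_phantom(spec)
    series = synthetic.generate_dwi_series(truth, mask, spec, config.b_values)
    adc.save_dwi_series(series, sdir / "dwi")
    adc.save_mask(mask, spec.voxel_size_mm, sdir / "mask.nii.gz")

    # reload from disk so the file interfaces are exercised on every run
    series = adc.load_dwi_series(sdir / "dwi")
    mask, _vs = adc.load_mask(sdir / "mask.nii.gz")
    area, ok = qc_roi_area(mask, spec.voxel_size_mm, config.min_roi_area_mm2)
    if not ok:
        log.info("%s excluded: largest axial ROI area %.1f mm² < %.0f mm²",
                 sid, area, config.min_roi_area_mm2)
        exclusions.append({"subject_id": sid,
                           "reason": "roi_area_below_minimum", "value": area})
        return None
    amap = adc.fit_adcaqp_map(series, mask, weighted=config.weighted_fit)
    adc.save_adc_map(amap, sdir / "adcaqp.nii.gz")
    vals = features.extract_masked_values(amap, mask)
    adc_feats = features.compute_histogram_features(
        vals, kurtosis_convention=config.kurtosis_convention)

    # stain phantom linked to the tumor's ADC level so the cohort carries a
    # recoverable imaging-pathology association
    adc_mean = adc_feats.mean
    dab_level = float(np.clip(0.9 * adc_mean + obs_rng.normal(0.0, 0.02), 0.05, 1.2))
    positive_fraction = float(np.clip(0.5 + 3.0 * (adc_mean - 0.39)
                                      + obs_rng.normal(0.0, 0.05), 0.05, 1.0))
    sspec = synthetic.StainPhantomSpec(
        image_shape_px=(config.stain_image_px, config.stain_image_px),
        microns_per_pixel=config.stain_mpp,
        positive_fraction=positive_fraction,
        dab_od_level=dab_level,
        n_cells=config.stain_n_cells,
        seed=sub_seed,
    )
    rgb, roi, truth_rec = synthetic.generate_stain_image(sspec, config.stain_matrix)
    synthetic.save_stain_phantom(rgb, roi, truth_rec, sdir / "ihc")
    dab = ihc.dab_od_image(rgb, config.stain_matrix)
    dab = ihc.background_correct(dab, roi, config.background_percentile)
    grid = ihc.tile_roi(roi, config.stain_mpp, config.tile_um,
                        config.tile_min_coverage)
    ihc_feats = ihc.tile_histogram_features(
        dab, grid, roi, kurtosis_convention=config.kurtosis_convention)

    # two simulated observers grade intensity/positivity with small disagreement
    pct = positive_fraction * 100.0
    base_intensity = _GROUP_INTENSITY[group]
    totals = []
    for _ in range(2):
        intensity = int(np.clip(base_intensity + obs_rng.integers(-1, 2), 0, 3))
        seen_pct = float(np.clip(pct + obs_rng.normal(0.0, 5.0), 0.0, 100.0))
        totals.append(ihc.manual_score(intensity, seen_pct).total)
    row = {"subject_id": sid, "differentiation": group}
    for name, val in adc_feats.to_dict().items():
        row[f"adc_{name}" if name != "n_voxels" else "n_voxels"] = val
    for name, val in ihc_feats.to_dict().items():
        if name != "n_voxels":
            row[f"ihc_{name}"] = val
    row["n_tiles"] = ihc_feats.n
    row["manual_score_obs1"] = totals[0]
    row["manual_score_obs2"] = totals[1]
    row["manual_score"] = ihc.average_observers(totals)
    # deterministic, balanced stage labels so both levels are populated even
    # in small demo cohorts (no planted stage effect)
    row["t_stage"] = "T1-2" if idx % 3 == 0 else "T3-4"
    row["n_status"] = "N-" if idx % 2 == 0 else "N+"
    row["roi_area_mm2"] = qc_roi_area(mask, spec.voxel_size_mm,
                                      config.min_roi_area_mm2)[0]
    log.info("%s: group=%s adc_mean=%.3f dab_level=%.3f tiles=%d",
             sid, group, adc_mean, dab_level, ihc_feats.n)
    return row
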