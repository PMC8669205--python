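"""End-to-end orchestration: generate -> map -> screen -> extract -> test.

Runs the full serial-study analysis on a synthetic cohort (or a study
directory saved earlier): computes R2* maps from the multi-echo GRE
series, R2 maps from the spin-echo series, builds SWI volumes, screens
each visit's DWI trace for acute cortical microinfarcts (or takes the
study's truth masks, the analogue of manual rater segmentations), builds
the control ROIs, extracts realigned baseline-normalized
lesion-minus-control series, and runs the stage-wise repeated-measures
inference per parameter.  Everything is deterministic given the config
and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .longitudinal import (ACCEPT_RANGE_DEFAULT, AlignedSeries, LesionExcluded,
                           LesionRecord, extract_series, realign_and_normalize)
from .phantom import Study, build_phantom, default_cohort_spec
from .relaxometry import r2_loglinear, r2star_trapz
from .screen import ScreenParams, detect_acmi
from .stats import STAGES, StageMatrix, paired_t, rm_anova_oneway
from .swi import PhaseMaskParams, build_swi

log = logging.getLogger("qmi")

#: The six parameters analysed longitudinally (the DWI trace panel uses
#: the b=1000 shell; screening uses the higher-contrast b=3000 shell).
ANALYSIS_PARAMETERS = ("dwi_b1000", "md", "fa", "r1", "r2", "r2star")
SCREEN_PARAMETER = "dwi_b3000"

#: Post-hoc stage contrasts, in reporting order.
CONTRASTS = (("pre-lesional", "lesional"),
             ("lesional", "post-lesional"),
             ("pre-lesional", "post-lesional"))


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    n_lesions: int = 15
    study_dir: Optional[str] = None        # load instead of generating
    lesion_source: str = "detect"          # "detect" | "truth"
    parameters: Tuple[str, ...] = ANALYSIS_PARAMETERS
    noise_sd: Optional[float] = None       # phantom overrides (None = default)
    param_noise_frac: Optional[float] = None
    accept_range: Tuple[float, float] = ACCEPT_RANGE_DEFAULT
    min_lesion_voxels: int = 3
    screen: ScreenParams = field(default_factory=ScreenParams)
    swi: PhaseMaskParams = field(default_factory=PhaseMaskParams)
    make_plots: bool = True

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "screen" in d and isinstance(d["screen"], Mapping):
            d["screen"] = ScreenParams(**d["screen"])
        if "swi" in d and isinstance(d["swi"], Mapping):
            d["swi"] = PhaseMaskParams(**d["swi"])
        if "parameters" in d:
            d["parameters"] = tuple(d["parameters"])
        if "accept_range" in d:
            d["accept_range"] = tuple(d["accept_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Everything a run produces, with writers for the results bundle."""

    config: PipelineConfig
    aligned: List[AlignedSeries]
    stage_matrices: Dict[str, StageMatrix]
    stage_rows: pd.DataFrame
    tests: pd.DataFrame
    report: Dict
    maps_by_visit: Optional[List[Dict[str, np.ndarray]]] = None
    study: Optional[Study] = None

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.aligned_table().to_csv(out / "aligned_series.csv", index=False,
                                    float_format="%.10g")
        self.stage_rows.to_csv(out / "stage_values.csv", index=False,
                               float_format="%.10g")
        self.tests.to_csv(out / "tests.csv", index=False, float_format="%.10g")
        (out / "report.json").write_text(
            json.dumps(self.report, indent=2, sort_keys=True))
        if self.config.make_plots:
            self.plot(out / "figures")

    def aligned_table(self) -> pd.DataFrame:
        rows = []
        for s in self.aligned:
            for p, vals in s.values.items():
                for i, off in enumerate(s.offsets):
                    rows.append({"lesion_id": s.lesion_id, "parameter": p,
                                 "offset": int(off), "value": vals[i],
                                 "stage": s.stage_labels[i],
                                 "n_accepted": int(s.accepted_voxel_counts[i])})
        return pd.DataFrame(rows)

    def plot(self, fig_dir) -> None:
        """Per-parameter time courses: transparent per-lesion lines with a
        group mean +/- SD band, indexed by visit offset from onset."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig_dir = Path(fig_dir)
        fig_dir.mkdir(parents=True, exist_ok=True)
        table = self.aligned_table()
        if table.empty:
            return
        for p, sub in table.groupby("parameter"):
            fig, ax = plt.subplots(figsize=(5, 3.5))
            for _, les in sub.groupby("lesion_id"):
                ax.plot(les["offset"], les["value"], color="C0", alpha=0.25)
            g = sub.groupby("offset")["value"]
            mean, sd = g.mean(), g.std()
            ax.plot(mean.index, mean.values, color="C0", lw=2)
            ax.fill_between(mean.index, mean - sd, mean + sd,
                            color="C0", alpha=0.2)
            ax.axvline(0, color="k", lw=0.5, ls="--")
            ax.set_xlabel("visit offset from onset (months)")
            ax.set_ylabel(f"normalized lesion - control ({p})")
            fig.tight_layout()
            fig.savefig(fig_dir / f"{p}.png", dpi=110)
            plt.close(fig)


def compute_visit_maps(study: Study,
                       swi_params: Optional[PhaseMaskParams] = None,
                       ) -> List[Dict[str, np.ndarray]]:
    """Derive the per-visit analysis maps: the emitted quantitative maps
    plus R2* (trapezoidal closed form), R2 (log-linear spin-echo fit) and
    the SWI volume."""
    out = []
    for visit in study.visits:
        maps = {p: q.values for p, q in visit.maps.items()}
        maps["r2star"] = r2star_trapz(visit.gre).values
        maps["r2"] = r2_loglinear(visit.spin_echo).values
        maps["swi"] = build_swi(visit.gre, swi_params)
        out.append(maps)
    return out


def screen_study(maps_by_visit: Sequence[Mapping[str, np.ndarray]],
                 cortex_mask: np.ndarray,
                 voxel_size_mm: Sequence[float],
                 params: Optional[ScreenParams] = None,
                 ) -> List[Tuple[np.ndarray, int]]:
    """Screen every visit's DWI trace and merge detections across visits.

    Accepted candidates that overlap a previously found lesion are taken
    to be the same lesion; each lesion keeps the mask and visit of its
    first appearance (the onset visit).  Returns (mask, onset) pairs.
    """
    found: List[Tuple[np.ndarray, int]] = []
    for v, maps in enumerate(maps_by_visit):
        cands = detect_acmi(maps[SCREEN_PARAMETER], maps["md"], cortex_mask,
                            params, voxel_size_mm)
        for c in cands:
            if not c.accepted:
                continue
            if any(np.any(c.mask & m) for m, _ in found):
                continue
            found.append((c.mask, v))
    return found


def run_pipeline(config: PipelineConfig,
                 out_dir=None,
                 study: Optional[Study] = None) -> PipelineResult:
    """Run the full analysis and (optionally) write the results bundle.

    ``study`` short-circuits generation/loading with an in-memory study.
    """
    log.info("pipeline start: seed=%d config=%s", config.seed, config.digest())
    if study is not None:
        pass
    elif config.study_dir:
        from .io import load_study
        study = load_study(config.study_dir)
    else:
        overrides = {}
        if config.noise_sd is not None:
            overrides["noise_sd"] = config.noise_sd
        if config.param_noise_frac is not None:
            overrides["param_noise_frac"] = config.param_noise_frac
        spec = default_cohort_spec(n_lesions=config.n_lesions,
                                   seed=config.seed, **overrides)
        study, _ = build_phantom(spec)

    maps_by_visit = compute_visit_maps(study, config.swi)

    if config.lesion_source == "truth":
        lesions = [(study.lesion_masks[i], study.onset_visits[i])
                   for i in sorted(study.lesion_masks)]
    elif config.lesion_source == "detect":
        lesions = screen_study(maps_by_visit, study.cortex_mask,
                               study.voxel_size_mm, config.screen)
    else:
        raise ValueError("lesion_source must be 'detect' or 'truth'")

    aligned: List[AlignedSeries] = []
    exclusions: Dict[int, str] = {}
    for lid, (mask, onset) in enumerate(lesions):
        try:
            record = LesionRecord(lesion_mask=mask, onset_visit=onset,
                                  lesion_id=lid)
            diffs = extract_series(maps_by_visit, record, config.parameters,
                                   config.accept_range,
                                   config.min_lesion_voxels)
            aligned.append(realign_and_normalize(diffs, onset, lesion_id=lid))
        except LesionExcluded as exc:
            exclusions[lid] = exc.reason
            log.info("lesion %d excluded: %s", lid, exc.reason)

    stage_rows_list = []
    stage_matrices: Dict[str, StageMatrix] = {}
    for p in config.parameters:
        rows, ids = [], []
        for s in aligned:
            sv = s.stage_values(p)
            if all(st in sv for st in STAGES):
                rows.append([sv[st] for st in STAGES])
                ids.append(s.lesion_id)
        for lid, r in zip(ids, rows):
            stage_rows_list.append({"lesion_id": lid, "parameter": p,
                                    STAGES[0]: r[0], STAGES[1]: r[1],
                                    STAGES[2]: r[2]})
        if len(rows) >= 2:
            stage_matrices[p] = StageMatrix(np.asarray(rows), parameter=p)
    stage_rows = pd.DataFrame(stage_rows_list)

    test_rows = []
    stats_skipped = []
    for p in config.parameters:
        if p not in stage_matrices:
            stats_skipped.append(p)
            continue
        m = stage_matrices[p]
        res = rm_anova_oneway(m)
        test_rows.append({"parameter": p, "test": "rm_anova",
                          "statistic": res.statistic,
                          "df1": res.df[0], "df2": res.df[1],
                          "p": res.p_two_tailed, "direction": 0})
        cols = {st: m.data[:, i] for i, st in enumerate(STAGES)}
        for a, b in CONTRASTS:
            t = paired_t(cols[b], cols[a])
            test_rows.append({"parameter": p, "test": f"{a}_vs_{b}",
                              "statistic": t.statistic, "df1": t.df,
                              "df2": np.nan, "p": t.p_two_tailed,
                              "direction": t.effect_direction})
    tests = pd.DataFrame(test_rows)

    report = {
        "qmi_version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "lesion_source": config.lesion_source,
        "n_lesions_found": len(lesions),
        "n_lesions_analyzable": len(aligned),
        "exclusions": {str(k): v for k, v in exclusions.items()},
        "statistics_skipped_parameters": stats_skipped,
        "accepted_voxel_counts": {
            str(s.lesion_id): [int(c) for c in s.accepted_voxel_counts]
            for s in aligned},
        "n_anova": int((tests["test"] == "rm_anova").sum()) if len(tests) else 0,
        "n_posthoc": int((tests["test"] != "rm_anova").sum()) if len(tests) else 0,
    }
    if len(aligned) < 2:
        report["statistics_skipped"] = "fewer than 2 analyzable lesions"

    result = PipelineResult(config=config, aligned=aligned,
                            stage_matrices=stage_matrices,
                            stage_rows=stage_rows, tests=tests, report=report,
                            maps_by_visit=maps_by_visit, study=study)
    if out_dir is not None:
        result.save(out_dir)
    log.info("pipeline done: %d analyzable lesions, %d tests",
             len(aligned), len(tests))
    return result
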