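"""End-to-end orchestration: design -> data -> filters -> models -> report.

One :class:`RunConfig` fully determines a run directory: the design CSV, the
cleaned blocks, one validated consensus OPLS-DA model per indicator column, a
summary CSV (one row per indicator: prediction accuracy, majority baseline,
empirical p-value), combined S-plot tables, the metabolite loading matrix and
its Ward/Euclidean heat map. All randomness flows from explicit seeds and no
output embeds timestamps, so identical configs give identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biomarkers import cluster_heatmap, loading_matrix, splot
from .design import (
    build_design,
    check_orthogonality,
    indicator_matrix,
    tobacco_screen_factors,
    write_design,
)
from .opls import ConsensusOPLSDA
from .preprocess import ParetoScaler, qc_cv, remove_background_features
from .simulate import MultiBlockDataset, simulate_dataset, tobacco_screen_config
from .validation import FoldKernelCache, permutation_test

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("mbopls")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Exactly one of ``data_dir`` (load a written :class:`MultiBlockDataset`)
    or ``simulate`` (draw one; ``True`` for the default screen config or a
    dict of :func:`tobacco_screen_config` overrides) must be supplied.
    ``reduced`` shrinks simulated blocks to 200/180/180 features and is the
    recommended costing for routine verification runs.
    """

    outdir: str
    seed: int = 0
    runs: int = 96
    data_dir: str | None = None
    simulate: bool | dict = False
    reduced: bool = True
    detection_threshold: float = 30.0
    qc_cv_threshold: float = 40.0
    max_n_orthogonal: int = 2
    n_perm: int = 99
    p_cutoff: float = 0.05
    indicators: list[str] | None = None  # default: all

    def __post_init__(self) -> None:
        if bool(self.data_dir) == bool(self.simulate):
            raise ValueError(
                "exactly one of data_dir or simulate must be supplied"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    log.info("stage=%s", name)
    return time.perf_counter()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the run directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.resolved(), indent=1))

    t0 = _stage("design")
    if config.data_dir:
        dataset = MultiBlockDataset.read(config.data_dir)
        if dataset.design is None:
            raise ValueError(f"stage=design: no design found in {config.data_dir}")
        design = dataset.design
    else:
        design = build_design(tobacco_screen_factors(), config.runs, config.seed)
    if not check_orthogonality(design)["pass"]:
        raise ValueError("stage=design: balance checks failed")
    write_design(design, out / "design.csv")

    _stage("data")
    if not config.data_dir:
        n_feat = (200, 180, 180) if config.reduced else (1500, 1366, 1368)
        sim_cfg = tobacco_screen_config(config.seed, n_features=n_feat)
        if isinstance(config.simulate, dict):
            sim_cfg = dataclasses.replace(sim_cfg, **config.simulate)
        dataset = simulate_dataset(design, sim_cfg)
        dataset.write(out / "data")

    t1 = _stage("preprocess")
    blanks = dataset.samples_with_role("blank")
    additives = dataset.samples_with_role("additive")
    qcs = dataset.samples_with_role("qc")
    exp_ids = dataset.samples_with_role("experiment")
    blocks, filter_reports = {}, {}
    for name, table in dataset.blocks.items():
        filtered, rep = remove_background_features(
            table, blanks, additives, config.detection_threshold
        )
        if len(qcs) >= 2:
            rep.qc_cv_percent = qc_cv(filtered, qcs, config.qc_cv_threshold)[
                "cv_percent"
            ]
        blocks[name] = filtered.loc[exp_ids]
        filter_reports[name] = rep
        filtered.loc[exp_ids].to_csv(out / f"{name}.clean.csv")
    (out / "filter_report.json").write_text(json.dumps(
        {
            name: {
                "features_in": r.features_in,
                "removed_blank": r.removed_blank,
                "removed_additive": r.removed_additive,
                "features_out": r.features_out,
                "median_qc_cv_percent": (
                    None if r.qc_cv_percent is None
                    else float(np.nanmedian(r.qc_cv_percent))
                ),
            }
            for name, r in filter_reports.items()
        }, indent=1,
    ))

    t2 = _stage("models")
    indicators = indicator_matrix(design)
    names = config.indicators or list(indicators.columns)
    unknown = set(names) - set(indicators.columns)
    if unknown:
        raise ValueError(f"stage=models: unknown indicator(s) {sorted(unknown)}")
    raw_blocks = [blocks[b].to_numpy(dtype=float) for b in blocks]
    cache = FoldKernelCache(raw_blocks, scale=True)
    scaled_full = {
        name: ParetoScaler().fit_transform(df) for name, df in blocks.items()
    }
    feature_ann = {
        name: dataset.features[name] for name in blocks
    } if dataset.features else None

    summary_rows, splots, p_values = [], {}, {}
    for name in names:
        y = indicators[name].to_numpy()
        report = permutation_test(
            raw_blocks, y, n_perm=config.n_perm, seed=config.seed,
            max_n_orthogonal=config.max_n_orthogonal, cache=cache,
        )
        model = ConsensusOPLSDA(n_orthogonal=report.chosen_n_orthogonal).fit(
            [scaled_full[b].to_numpy() for b in blocks], y
        )
        tab = splot(model, scaled_full, features=feature_ann)
        tab.to_csv(out / f"splot_{name.replace('/', '_')}.csv", index=False)
        splots[name] = tab
        p_values[name] = report.p_value
        summary_rows.append({
            "indicator": name,
            "pa_percent": round(report.pa_percent, 1),
            "majority_baseline_percent": round(
                report.majority_baseline_percent, 1),
            "p_value": report.p_value,
            "dq2": round(report.dq2_by_size[report.chosen_n_orthogonal], 4),
            "n_orthogonal": report.chosen_n_orthogonal,
            "n_perm": config.n_perm,
        })
        log.info("model=%s pa=%.1f p=%.4g", name, report.pa_percent,
                 report.p_value)
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "summary.csv", index=False)

    _stage("interpretation")
    if dataset.metabolite_map and any(
        p < config.p_cutoff for p in p_values.values()
    ):
        lm = loading_matrix(
            splots, p_values, dataset.metabolite_map, p_cutoff=config.p_cutoff
        )
        filled = lm.values.fillna(0.0)
        filled.to_csv(out / "loading_matrix.csv")
        if len(filled) >= 2:
            cluster_heatmap(filled, out_png=str(out / "heatmap.png"))
    log.info("done stages_sec=%.1f/%.1f/%.1f", t1 - t0, t2 - t1,
             time.perf_counter() - t2)
    return out
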