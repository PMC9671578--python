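"""End-to-end orchestration: synthesize → preprocess → decode → RP → ESA → report.

A single JSON-serializable config drives the full analysis and every output
carries the code version, a config hash and the seeds, so a re-run with the
same config reproduces all numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decoding import (
    classification_score,
    coding_pair_cumulative,
    features_from_dataset,
    pairwise_scores,
    score_table,
    taste_pairs,
)
from .elastic import esa_classification_scores
from .rate_phase import dataset_rp_codes, separation_scores
from .spike_io import read_trials, write_trials
from .stats import dagostino_k2, one_sample_t, paired_t, ratio_summary
from .synthetic import TasteCodeSpec, generate_population, population_configs

log = logging.getLogger(__name__)

_CODE_SPECS = {
    "uniform": TasteCodeSpec.uniform,
    "rate": TasteCodeSpec.rate_code,
    "phase": TasteCodeSpec.phase_code,
}


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips through JSON."""

    source: str | None = None          # event-table CSV; None → synthesize
    n_neurons: int = 30
    n_trials_per_taste: int = 15
    code_spec: str = "rate"            # uniform | rate | phase
    seed: int = 0
    smoothing_window: float = 250.0
    svm_repeats: int = 20
    train_frac: float = 0.67
    esa_modes: list = field(default_factory=lambda: ["whole_window"])
    esa_n_grid: int = 200
    esa_seg_grid: int = 50
    esa_karcher_iters: int = 4
    esa_random_repeats: int = 20
    run_pairwise: bool = False
    out_dir: str = "lickshape_run"

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_or_generate(config: PipelineConfig):
    if config.source:
        return read_trials(config.source), False
    spec = _CODE_SPECS[config.code_spec]()
    configs = population_configs(
        config.n_neurons, spec, seed=config.seed,
        n_trials_per_taste=config.n_trials_per_taste,
    )
    return generate_population(configs), True


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        filename=out / "run.log", level=logging.INFO, force=True,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    meta = {
        "version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "svm_seed": config.seed,
        "feature_standardization": "per-column z-score fit on the training split",
    }
    log.info("pipeline start: %s", meta)

    datasets, generated = _load_or_generate(config)
    if generated:
        write_trials(datasets, out / "dataset.csv")
    config.to_json(out / "config.json")
    (out / "manifest.json").write_text(json.dumps(meta, indent=2))

    # --- stage: SVM decoding ------------------------------------------------
    log.info("stage: svm decoding (%d neurons)", len(datasets))
    all5, skipped = [], []
    for ds in datasets:
        feats = features_from_dataset(
            ds, "smoothed", window=config.smoothing_window, epoch="post"
        )
        try:
            all5.append(
                classification_score(
                    feats, n_repeats=config.svm_repeats,
                    train_frac=config.train_frac, seed=config.seed,
                )
            )
        except ValueError as exc:
            skipped.append({"neuron_id": ds.neuron_id, "reason": str(exc)})
            log.warning("neuron %s skipped: %s", ds.neuron_id, exc)
    table5 = score_table(all5)
    table5.to_csv(out / "scores_all5.csv", index=False)

    if config.run_pairwise:
        pw = []
        for ds in datasets:
            pw.extend(
                pairwise_scores(
                    ds, "smoothed", window=config.smoothing_window,
                    n_repeats=config.svm_repeats, seed=config.seed,
                )
            )
        table_pw = score_table(pw)
        table_pw.to_csv(out / "scores_pairs.csv", index=False)
        coding_pair_cumulative(table_pw).to_csv(
            out / "coding_pair_cumulative.csv", index=False
        )

    # --- stage: RP codes and separation scores ------------------------------
    log.info("stage: rate-phase codes")
    rp_rows, sep_rows, exclusion_tally = [], [], {}
    for ds in datasets:
        codes, exclusions = dataset_rp_codes(ds)
        for tid, reason in exclusions:
            exclusion_tally[reason] = exclusion_tally.get(reason, 0) + 1
            rp_rows.append(
                {"neuron_id": ds.neuron_id, "trial_id": tid, "tastant": "",
                 "R": np.nan, "P": np.nan, "excluded": True, "reason": reason}
            )
        for taste, lst in codes.items():
            for k, c in enumerate(lst):
                rp_rows.append(
                    {"neuron_id": ds.neuron_id, "trial_id": f"{taste}-{k}",
                     "tastant": taste, "R": c.R, "P": c.P,
                     "excluded": False, "reason": ""}
                )
        for a, b in taste_pairs():
            if len(codes.get(a, [])) < 2 or len(codes.get(b, [])) < 2:
                continue
            res = separation_scores(codes[a], codes[b])
            sep_rows.append(
                {"neuron_id": ds.neuron_id, "taste_pair": f"{a}|{b}",
                 "rate_score": res.rate_score, "phase_score": res.phase_score,
                 "combination_score": res.combination_score}
            )
    pd.DataFrame(rp_rows).to_csv(out / "rp.csv", index=False)
    pd.DataFrame(sep_rows).to_csv(out / "sep.csv", index=False)

    # --- stage: elastic shape analysis ---------------------------------------
    esa_rows = []
    for mode in config.esa_modes:
        log.info("stage: esa mode=%s", mode)
        for ds in datasets:
            sc = esa_classification_scores(
                ds, mode, window=config.smoothing_window,
                n_grid=config.esa_n_grid, seg_grid=config.esa_seg_grid,
                karcher_iters=config.esa_karcher_iters,
                svm_repeats=config.svm_repeats, train_frac=config.train_frac,
                n_random_repeats=config.esa_random_repeats, seed=config.seed,
            )
            esa_rows.append(
                {"neuron_id": ds.neuron_id, "mode": mode,
                 "original": sc["original"].score,
                 "aligned": sc["aligned"].score,
                 "warp": sc["warp"].score}
            )
    esa_df = pd.DataFrame(esa_rows)
    if not esa_df.empty:
        esa_df.to_csv(out / "esa_scores.csv", index=False)

    # --- stage: statistical report -------------------------------------------
    log.info("stage: report")
    report: dict = {"meta": meta, "exclusions": exclusion_tally,
                    "skipped_neurons": skipped}
    scores = table5["score"].to_numpy()
    if scores.size >= 20:
        nt = dagostino_k2(scores)
        report["normality_all5"] = {"K2": nt.statistic, "p": nt.p_value}
    if scores.size >= 2 and np.ptp(scores) > 0:
        tt = one_sample_t(scores, 0.2, alternative="greater")
        report["t_vs_chance_all5"] = {"t": tt.statistic, "p": tt.p_value,
                                      "df": tt.df}
    for mode in config.esa_modes:
        sub = esa_df[esa_df["mode"] == mode]
        if sub.empty:
            continue
        ra = ratio_summary(sub["original"], sub["aligned"])
        rw = ratio_summary(sub["original"], sub["warp"])
        report[f"ratios_{mode}"] = {
            "aligned_over_original_mean": ra.mean_ratio,
            "warp_over_original_mean": rw.mean_ratio,
        }
    if {"interlick", "random_intervals"} <= set(config.esa_modes):
        il = esa_df[esa_df["mode"] == "interlick"].set_index("neuron_id")
        rnd = esa_df[esa_df["mode"] == "random_intervals"].set_index("neuron_id")
        common = il.index.intersection(rnd.index)
        cmp = {}
        for col in ("aligned", "warp"):
            r_il = (il.loc[common, col] / il.loc[common, "original"]).to_numpy()
            r_rd = (rnd.loc[common, col] / rnd.loc[common, "original"]).to_numpy()
            t = paired_t(r_il, r_rd)
            cmp[f"{col}_over_original"] = {"t": t.statistic, "p": t.p_value,
                                           "df": t.df, "n": int(common.size)}
        report["interlick_vs_random"] = cmp
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    log.info("pipeline done")
    return out
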