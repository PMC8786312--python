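"""End-to-end orchestration: stimuli -> simulated choices -> statistics -> report.

`run_pipeline` wires the stages together under a single seed: generate one
stimulus set per control condition, measure magnitudes and spectral total
power, simulate (or ingest) a choice table, run the training and test
analyses (GLMM backward selection, exact binomial summaries), the
congruency-level analysis, and the accuracy/spatial-frequency correlation.
All outputs are plain CSV/JSON plus a run log recording the effective
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .choicestats import (
    backward_select,
    congruency_analysis,
    exact_binomial,
    inv_logit,
    validate_choice_table,
)
from .magnitudes import compute_magnitudes, congruency_level
from .spectra import (
    SpectrumOptions,
    accuracy_spectrum_correlation,
    image_total_power,
    total_power_index,
)
from .stimgen import CONDITIONS, GenerationConfig, generate_pair, render_image
from .synthdata import simulate_study

logger = logging.getLogger("numfish")

__all__ = ["PipelineConfig", "run_pipeline", "stimulus_power_indices"]


@dataclass
class PipelineConfig:
    """Effective configuration of one pipeline run (echoed to the run log)."""

    seed: int = 0
    design: str = "exp1"
    comparison: tuple[int, int] = (3, 6)
    n_pairs_per_condition: int = 4
    stimulus: GenerationConfig = field(default_factory=GenerationConfig)
    spectra_px_side: int = 512
    dc_included: bool = False
    use_power_not_amplitude: bool = False
    selection_criterion: str = "BIC"  # consistent under the null; AIC available
    out_dir: str = "numfish_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        # output location does not change what is computed
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def stimulus_power_indices(
    comparison: tuple[int, int],
    n_pairs: int,
    seed: int,
    config: GenerationConfig | None = None,
    options: SpectrumOptions | None = None,
    px_side: int = 512,
) -> pd.DataFrame:
    """Per-condition total-power indices on freshly generated stimulus pairs.

    Renders each pair at ``px_side`` pixels across the field (outline off so
    only the dots contribute) and returns one row per pair with the two
    total powers and their normalised index.
    """
    config = config or GenerationConfig()
    options = options or SpectrumOptions()
    px_per_mm = px_side / (2 * config.field_radius)
    rows = []
    for ci, condition in enumerate(CONDITIONS):
        for j in range(n_pairs):
            pair_seed = seed + 1000 * ci + j
            pair = generate_pair(*comparison, condition, config, pair_seed)
            img_s = render_image(pair.array_small, px_per_mm, draw_outline=False)
            img_l = render_image(pair.array_large, px_per_mm, draw_outline=False)
            tp_s = image_total_power(img_s, options)
            tp_l = image_total_power(img_l, options)
            idx = total_power_index(tp_l, tp_s)
            rows.append(
                {
                    "condition": condition.label(),
                    "pair": j,
                    "tp_small": tp_s,
                    "tp_large": tp_l,
                    "power_index": idx.index,
                }
            )
    return pd.DataFrame(rows)


def _proportion_report(table: pd.DataFrame) -> dict:
    sub = table[table["responded"].astype(int) == 1]
    k = int(sub["chose_target"].sum())
    n = int(len(sub))
    s = exact_binomial(k, n)
    return {
        "k": s.k,
        "n": s.n,
        "p_hat": s.p_hat,
        "ci_low": s.ci_low,
        "ci_high": s.ci_high,
        "p_value": s.p_value,
        "cohens_g": s.cohens_g,
        "g_band": s.g_band,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write the report bundle to disk.

    Returns the in-memory report dict.  Each stage failure aborts with the
    stage name in the raised error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
    }
    logger.info("pipeline start: seed=%s hash=%s", config.seed, config.config_hash())

    stage = "stimuli"
    try:
        options = SpectrumOptions(
            dc_included=config.dc_included,
            use_power_not_amplitude=config.use_power_not_amplitude,
        )
        power_df = stimulus_power_indices(
            config.comparison,
            config.n_pairs_per_condition,
            config.seed,
            config.stimulus,
            options,
            config.spectra_px_side,
        )
        power_df.to_csv(out / "power_indices.csv", index=False)
        per_condition_index = (
            power_df.groupby("condition", sort=True)["power_index"].mean()
        )

        stage = "simulation"
        table = simulate_study(config.design, seed=config.seed)
        validate_choice_table(table)
        table.to_csv(out / "choice_table.csv", index=False)

        stage = "training-analysis"
        train = _last_two_training_sessions(table)
        train_fit, train_trace = backward_select(
            train,
            ["geometry_control", "spatial_control",
             ("geometry_control", "spatial_control")],
            criterion=config.selection_criterion,
        )
        report["training"] = {
            "selected_terms": [list(t) for t in train_trace[-1]["terms"]],
            "intercept_log_odds": float(train_fit.fixed_effects[0]),
            "intercept_natural": inv_logit(float(train_fit.fixed_effects[0])),
            "random_intercept_variance": train_fit.random_intercept_variance,
            "binomial": _proportion_report(train),
        }

        stage = "test-analysis"
        tests = table[table["phase"] == "test"]
        test_fit, test_trace = backward_select(
            tests,
            ["geometry_control", "spatial_control", "comparison"],
            criterion=config.selection_criterion,
        )
        report["test"] = {
            "selected_terms": [list(t) for t in test_trace[-1]["terms"]],
            "intercept_log_odds": float(test_fit.fixed_effects[0]),
            "intercept_natural": inv_logit(float(test_fit.fixed_effects[0])),
            "random_intercept_variance": test_fit.random_intercept_variance,
            "binomial": _proportion_report(tests),
        }

        stage = "congruency-analysis"
        cong = congruency_analysis(tests)
        cong["contrasts"].to_csv(out / "congruency_contrasts.csv", index=False)
        cong["level_estimates"].to_csv(out / "congruency_levels.csv", index=False)
        report["congruency"] = {
            "max_adjusted_p": float(cong["contrasts"]["p_adjusted"].max()),
            "min_adjusted_p": float(cong["contrasts"]["p_adjusted"].min()),
        }

        stage = "spectral-correlation"
        acc = (
            tests[tests["responded"].astype(int) == 1]
            .assign(
                condition=lambda d: d["geometry_control"].map(
                    {"radius_fixed": "radius-fixed", "area_eq": "area",
                     "perim_eq": "perimeter"}
                )
                + "-"
                + d["spatial_control"].map({"ch_eq": "ch", "id_eq": "id"})
            )
            .groupby("condition")["chose_target"]
            .mean()
        )
        common = sorted(set(acc.index) & set(per_condition_index.index))
        r, df, p = accuracy_spectrum_correlation(
            acc.loc[common].to_numpy(), per_condition_index.loc[common].to_numpy()
        )
        report["spectral_correlation"] = {"r": r, "df": df, "p": p}
        report["power_index_by_condition"] = per_condition_index.to_dict()
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    with open(out / "run_log.txt", "w") as fh:
        fh.write(json.dumps(
            {"config": config.to_dict(), "hash": config.config_hash(),
             "version": __version__},
            indent=2, default=str,
        ))
    logger.info("pipeline done: %s", out / "report.json")
    return report


def _last_two_training_sessions(table: pd.DataFrame) -> pd.DataFrame:
    """Per fish, the trials of the last two training sessions (over criterion)."""
    train = table[table["phase"] == "training"]
    keep = []
    for fish, sub in train.groupby("fish_id"):
        sessions = sorted(sub["session"].unique())[-2:]
        keep.append(sub[sub["session"].isin(sessions)])
    return pd.concat(keep, ignore_index=True)
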