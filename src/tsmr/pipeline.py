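"""End-to-end orchestration: selection -> clumping -> harmonization -> MR.

`analyze_pair` runs one exposure-outcome analysis on in-memory summary
statistics and is the unit everything else wraps: `run_mr` adds file I/O,
config echo and logging; `run_bidirectional` swaps the trait roles to test
the reverse direction with identical thresholds.

Each analysis emits one results row per method. With a single surviving
instrument the Wald ratio is the main test; with two or more, IVW is, with
the fixed-effect point estimate and the multiplicative random-effects SE
both reported. Egger, the medians, Cochran's Q and the pleiotropy RSS test
join when enough instruments survive (3, 3, 2 and 4 respectively).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import estimators as est
from .harmonize import harmonize, instruments_to_frame, retained_instruments
from .instruments import ClumpingConfig, LDMatrix, clump, filter_by_pvalue, instrument_report
from .summary_io import ColumnMap, SummaryStats, read_summary_stats

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ("ivw", "egger", "weighted_median", "simple_median")

RESULT_COLUMNS = [
    "exposure", "outcome", "ancestry", "direction", "method", "status", "reason",
    "n_snp", "beta", "se", "ci_low", "ci_high", "or", "or_low", "or_high", "pvalue",
    "egger_intercept", "egger_intercept_se", "egger_intercept_p",
    "Q", "Q_df", "Q_p", "presso_rss", "presso_global_p", "presso_n_outliers",
    "min_f", "mean_f", "n_input", "n_selected", "n_clumped", "n_harmonized",
]


@dataclass
class AnalysisConfig:
    """Everything one pipeline run needs; echoed verbatim into the output dir."""

    exposure_path: str
    outcome_path: str
    seed: int
    exposure_colmap: Optional[str] = None  # YAML paths; None = canonical columns
    outcome_colmap: Optional[str] = None
    exposure_trait: str = "exposure"
    outcome_trait: str = "outcome"
    exposure_type: str = "quantitative"
    outcome_type: str = "binary"
    ancestry: str = "unspecified"
    clumping: ClumpingConfig = field(default_factory=ClumpingConfig)
    ld_path: Optional[str] = None
    palindromic_band: float = 0.40
    methods: Sequence[str] = DEFAULT_METHODS
    n_boot: int = 1000
    n_sim: int = 1000
    out_dir: Optional[str] = None
    reverse: bool = False


@dataclass
class MRAnalysis:
    """One direction's full output: results rows plus the instrument table."""

    results: pd.DataFrame
    harmonized: pd.DataFrame
    attrition: dict


def _base_row(exposure: SummaryStats, outcome: SummaryStats, direction: str) -> dict:
    return {c: np.nan for c in RESULT_COLUMNS} | {
        "exposure": exposure.trait_name,
        "outcome": outcome.trait_name,
        "ancestry": exposure.ancestry,
        "direction": direction,
        "status": "ok",
        "reason": "",
    }


def _result_row(base: dict, res: est.MRResult) -> dict:
    return base | {
        "method": res.method,
        "n_snp": res.n_snp,
        "beta": res.beta,
        "se": res.se,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "or": res.or_,
        "or_low": res.or_low,
        "or_high": res.or_high,
        "pvalue": res.pvalue,
        "egger_intercept": res.intercept,
        "egger_intercept_se": res.intercept_se,
        "egger_intercept_p": res.intercept_p,
    }


def analyze_pair(
    exposure: SummaryStats,
    outcome: SummaryStats,
    *,
    seed: int,
    clumping: Optional[ClumpingConfig] = None,
    ld: Optional[LDMatrix] = None,
    palindromic_band: float = 0.40,
    methods: Sequence[str] = DEFAULT_METHODS,
    n_boot: int = 1000,
    n_sim: int = 1000,
    direction: str = "forward",
) -> MRAnalysis:
    """Run one exposure -> outcome MR analysis on in-memory summary stats.

    Never raises on an empty instrument set: a failed analysis is a results
    row with ``status='failed'`` and the reason, so multi-trait batches keep
    going.
    """
    clumping = clumping or ClumpingConfig()
    base = _base_row(exposure, outcome, direction)
    attrition = {"n_input": len(exposure)}

    selected = filter_by_pvalue(exposure, clumping.p_threshold)
    attrition["n_selected"] = len(selected)
    if len(selected) == 0:
        logger.warning("%s -> %s: zero instruments after p-value filtering",
                       exposure.trait_name, outcome.trait_name)
        row = base | {"status": "failed", "reason": "zero instruments after p-value filtering"}
        return MRAnalysis(pd.DataFrame([row], columns=RESULT_COLUMNS),
                          instruments_to_frame([]), attrition)

    clumped = clump(selected, clumping, ld)
    attrition["n_clumped"] = len(clumped)
    logger.info("%s -> %s: %d/%d instruments survive clumping",
                exposure.trait_name, outcome.trait_name, len(clumped), len(selected))

    instruments, h_report = harmonize(clumped, outcome, palindromic_band)
    kept = retained_instruments(instruments)
    attrition["n_harmonized"] = len(kept)
    attrition["harmonization_actions"] = dict(h_report.actions)
    harmonized_df = instruments_to_frame(instruments)
    if len(kept) == 0:
        row = base | {"status": "failed", "reason": "zero instruments after harmonization"}
        return MRAnalysis(pd.DataFrame([row], columns=RESULT_COLUMNS), harmonized_df, attrition)

    f_rep = instrument_report(clumped)
    counts = {
        "n_input": attrition["n_input"],
        "n_selected": attrition["n_selected"],
        "n_clumped": attrition["n_clumped"],
        "n_harmonized": attrition["n_harmonized"],
        "min_f": f_rep.min_f,
        "mean_f": f_rep.mean_f,
    }
    base |= counts

    het = presso = None
    k = len(kept)
    if k >= 2:
        beta_ivw = est.ivw(kept, model="fixed").beta
        het = est.cochran_q(kept, beta_ivw)
        base |= {"Q": het.Q, "Q_df": het.df, "Q_p": het.pvalue}
    if k >= 4:
        presso = est.presso_global(kept, n_sim=n_sim, seed=seed)
        base |= {
            "presso_rss": presso.rss_observed,
            "presso_global_p": presso.global_p,
            "presso_n_outliers": int(presso.outlier_flags.sum()),
        }

    rows: list[dict] = []
    if k == 1:
        rows.append(_result_row(base, est.wald_ratio(kept[0])))
    else:
        if "ivw" in methods:
            rows.append(_result_row(base, est.ivw(kept, model="fixed")))
            rows.append(_result_row(base, est.ivw(kept, model="multiplicative_random_effects")))
        if "egger" in methods and k >= 3:
            rows.append(_result_row(base, est.mr_egger(kept)))
        if "weighted_median" in methods and k >= 3:
            rows.append(_result_row(
                base, est.median_estimator(kept, "inverse_variance", n_boot, seed=seed)))
        if "simple_median" in methods and k >= 3:
            rows.append(_result_row(
                base, est.median_estimator(kept, "simple", n_boot, seed=seed)))
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return MRAnalysis(results, harmonized_df, attrition)


def _load(path: str, colmap_path: Optional[str], trait: str, ttype: str, ancestry: str) -> SummaryStats:
    cmap = ColumnMap.from_yaml(colmap_path) if colmap_path else ColumnMap()
    stats, report = read_summary_stats(
        path, cmap, trait_name=trait, trait_type=ttype, ancestry=ancestry
    )
    if report.n_rejected:
        logger.warning("%s: %d rows rejected on ingest", path, report.n_rejected)
    return stats


def run_mr(config: AnalysisConfig) -> pd.DataFrame:
    """File-level forward analysis; writes outputs when ``out_dir`` is set."""
    exposure = _load(config.exposure_path, config.exposure_colmap,
                     config.exposure_trait, config.exposure_type, config.ancestry)
    outcome = _load(config.outcome_path, config.outcome_colmap,
                    config.outcome_trait, config.outcome_type, config.ancestry)
    ld = LDMatrix.read(config.ld_path) if config.ld_path else None
    analysis = analyze_pair(
        exposure, outcome, seed=config.seed, clumping=config.clumping, ld=ld,
        palindromic_band=config.palindromic_band, methods=config.methods,
        n_boot=config.n_boot, n_sim=config.n_sim, direction="forward",
    )
    _write_outputs(config, analysis.results, analysis.harmonized)
    return analysis.results


def run_bidirectional(config: AnalysisConfig) -> pd.DataFrame:
    """Forward and reverse analysis with identical thresholds in both directions.

    The reverse run needs the outcome file to be full summary statistics
    (not just an instrument list) so its own instruments can be selected.
    """
    exposure = _load(config.exposure_path, config.exposure_colmap,
                     config.exposure_trait, config.exposure_type, config.ancestry)
    outcome = _load(config.outcome_path, config.outcome_colmap,
                    config.outcome_trait, config.outcome_type, config.ancestry)
    ld = LDMatrix.read(config.ld_path) if config.ld_path else None
    common = dict(
        seed=config.seed, clumping=config.clumping, ld=ld,
        palindromic_band=config.palindromic_band, methods=config.methods,
        n_boot=config.n_boot, n_sim=config.n_sim,
    )
    fwd = analyze_pair(exposure, outcome, direction="forward", **common)
    rev = analyze_pair(outcome, exposure, direction="reverse", **common)
    results = pd.concat([fwd.results, rev.results], ignore_index=True)
    harmonized = pd.concat(
        [fwd.harmonized.assign(direction="forward"),
         rev.harmonized.assign(direction="reverse")],
        ignore_index=True,
    )
    _write_outputs(config, results, harmonized)
    return results


def _write_outputs(config: AnalysisConfig, results: pd.DataFrame, harmonized: pd.DataFrame) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.to_csv(out / "results.tsv", sep="\t", index=False, float_format="%.10g")
    harmonized.to_csv(out / "harmonized_instruments.tsv", sep="\t", index=False,
                      float_format="%.10g")
    echo = {k: (v if not isinstance(v, (ClumpingConfig,)) else vars(v) | {})
            for k, v in vars(config).items()}
    echo["clumping"] = {
        "p_threshold": config.clumping.p_threshold,
        "window_kb": config.clumping.window_kb,
        "r2_threshold": config.clumping.r2_threshold,
    }
    echo["methods"] = list(config.methods)
    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(echo, fh)
    format_forest_table(results).to_csv(out / "forest_table.tsv", sep="\t", index=False)


def format_forest_table(results: pd.DataFrame) -> pd.DataFrame:
    """Forest-plot-style summary: one line per analysis row, OR (95% CI) text.

    Rows are ordered by ancestry, then exposure trait, then direction and
    method — stable across runs.
    """
    if results.empty:
        raise ValueError("no results to format")
    ok = results[results["status"] == "ok"].copy()
    ok = ok.sort_values(
        ["ancestry", "exposure", "direction", "method"], kind="stable"
    ).reset_index(drop=True)
    ok["or_ci"] = [
        f"{o:.2f} ({lo:.3f}, {hi:.3f})"
        for o, lo, hi in zip(ok["or"], ok["or_low"], ok["or_high"])
    ]
    ok["p_str"] = [f"{p:.3g}" for p in ok["pvalue"]]
    return ok[
        ["ancestry", "exposure", "outcome", "direction", "method", "n_snp", "or_ci", "p_str"]
    ]


def forest_plot(results: pd.DataFrame, path: str | Path) -> None:
    """Optional graphical forest plot of the OR estimates (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = results[results["status"] == "ok"].copy()
    if ok.empty:
        raise ValueError("no successful analyses to plot")
    labels = [
        f"{r.exposure} → {r.outcome} [{r.method}]" for r in ok.itertuples()
    ]
    y = np.arange(len(ok))[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(ok) + 1.5))
    ax.errorbar(
        ok["or"], y,
        xerr=[ok["or"] - ok["or_low"], ok["or_high"] - ok["or"]],
        fmt="s", color="black", ecolor="gray", capsize=3,
    )
    ax.axvline(1.0, color="firebrick", linestyle="--", linewidth=1)
    ax.set_yticks(y)
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel("Odds ratio (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


__all__ = [
    "AnalysisConfig",
    "DEFAULT_METHODS",
    "MRAnalysis",
    "RESULT_COLUMNS",
    "analyze_pair",
    "forest_plot",
    "format_forest_table",
    "run_bidirectional",
    "run_mr",
]
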