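"""End-to-end orchestration: simulate/ingest -> inclusion -> descriptives ->
group models -> criterion correlations -> permutation -> thresholding ->
summary table.

The summary table mirrors the headline layout of a two-arm scale
comparison: one row per outcome, with the direction of the mean, variance
and zero-inflation differences and whether each 90% HDI excludes zero
("no difference" otherwise, matching the qualitative inference rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .core import InclusionConfig, StudyDataset, apply_inclusion, detect_careless
from .descriptives import compute_stat_table
from .models import ModelSpec, PosteriorDraws, emm_summary, fit_group_model, hdi
from .resampling import permutation_test_from_dataset
from .simulate import SyntheticConfig, generate_study
from .thresholding import ThresholdMap, threshold_counterfactual
from . import models as _models

logger = logging.getLogger("emascale")

#: response family per analyzed outcome
DEFAULT_FAMILIES: dict[str, ModelSpec] = {
    "wp_mean": ModelSpec("zoib", zero_inflation=True),
    "wp_sd": ModelSpec("zoib", zero_inflation=True),
    "rmssd": ModelSpec("zoib", zero_inflation=True),
    "wp_skew": ModelSpec("gaussian"),
    "ar1": ModelSpec("gaussian"),
    "init_elev": ModelSpec("gaussian"),
    "mean_abs_corr": ModelSpec("zoib", zero_inflation=False),
    "missing_prop": ModelSpec(
        "zoib", zero_inflation=True, one_inflation=True, valence_effects=False, random_effects=()
    ),
    "duration": ModelSpec("lognormal", valence_effects=False, random_effects=("participant",)),
}

_STAGE_SEEDS = {
    "simulate": 0,
    "modes": 11,
    "models": 23,
    "criterion": 37,
    "permutation": 41,
    "thresholding": 53,
}


@dataclass
class PipelineConfig:
    """One run of the full comparison.

    Either ``synthetic`` (a generator config) or ``study`` (a loaded
    dataset) provides the data.  ``outcomes`` selects which statistics get
    a group model; ``backend`` applies to all of them.
    """

    synthetic: SyntheticConfig | None = None
    study: StudyDataset | None = None
    inclusion: InclusionConfig = field(default_factory=InclusionConfig)
    outcomes: tuple[str, ...] = ("wp_mean", "wp_sd", "wp_skew", "rmssd", "ar1", "init_elev", "mean_abs_corr", "missing_prop")
    families: dict | None = None
    backend: str = "mcmc"
    seed: int = 0
    n_perm: int = 500
    alpha: float = 0.10
    boot_B: int = 2000
    mcmc_chains: int = 3
    mcmc_warmup: int = 1000
    mcmc_draws: int = 1000
    include_modes: bool = True
    run_thresholding: bool = True
    threshold_B: int = 500
    threshold_map: ThresholdMap = field(default_factory=ThresholdMap)
    outdir: str | None = None


def _fit_kwargs(cfg: PipelineConfig, stage_seed: int) -> dict:
    return dict(
        backend=cfg.backend,
        seed=stage_seed,
        chains=cfg.mcmc_chains,
        warmup=cfg.mcmc_warmup,
        draws=cfg.mcmc_draws,
        B=cfg.boot_B,
    )


def multimodality_comparison(stat_table: pd.DataFrame, n_draws: int = 4000, seed: int = 0, mass: float = 0.90) -> pd.DataFrame:
    """Beta-binomial comparison of per-group bimodality proportions.

    Each (participant, item) distribution counts as multimodal when its
    density-based mode count exceeds 1; group proportions get independent
    Beta(1 + k, 1 + n - k) posteriors and the difference is summarized by
    median and 90% HDI.
    """
    df = stat_table.dropna(subset=["n_modes"])
    rng = np.random.default_rng(seed)
    draws = {}
    rows = []
    for g, sub in df.groupby("group"):
        k = int((sub["n_modes"] > 1).sum())
        n = len(sub)
        draws[g] = rng.beta(1 + k, 1 + n - k, size=n_draws)
        rows.append({"component": g, "proportion": k / n if n else np.nan, "n_cells": n})
    out = pd.DataFrame(rows).set_index("component")
    for g in draws:
        lo, hi = hdi(draws[g], mass)
        out.loc[g, ["median", "hdi_low", "hdi_high"]] = [float(np.median(draws[g])), lo, hi]
    if set(draws) == {"likert", "vas"}:
        d = draws["vas"] - draws["likert"]
        lo, hi = hdi(d, mass)
        out.loc["difference"] = {
            "proportion": np.nan,
            "n_cells": np.nan,
            "median": float(np.median(d)),
            "hdi_low": lo,
            "hdi_high": hi,
        }
    return out


def _direction(emm: pd.DataFrame, larger_is: str = "vas") -> str:
    lo, hi = emm.loc["difference", "hdi_low"], emm.loc["difference", "hdi_high"]
    med = emm.loc["difference", "median"]
    if lo <= 0 <= hi:
        return "no difference"
    side = "VAS" if med > 0 else "Likert"
    return f"{side} larger"


def build_summary_table(emms: dict) -> pd.DataFrame:
    """Direction labels per outcome for mean / variance / zero-inflation."""
    rows = []
    for outcome, parts in emms.items():
        row = {"outcome": outcome}
        for quantity in ("mean", "variance", "pi0"):
            label = {"mean": "mean", "variance": "variance", "pi0": "zero_inflation"}[quantity]
            if quantity in parts:
                emm = parts[quantity].table
                row[label] = _direction(emm)
                row[f"{label}_diff_median"] = emm.loc["difference", "median"]
            else:
                row[label] = "n/a"
                row[f"{label}_diff_median"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("outcome")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every configured stage; partial results survive failures.

    Returns a dict with keys dataset, careless, stat_table, emms,
    summary_table, multimodality, criterion, permutation, thresholding and
    ``failures`` (stage name -> error message).
    """
    results: dict = {"failures": {}}
    seeds = {k: cfg.seed + off for k, off in _STAGE_SEEDS.items()}

    # -- data ----------------------------------------------------------------
    if cfg.study is not None:
        dataset = cfg.study
    else:
        syn = cfg.synthetic or SyntheticConfig()
        dataset = generate_study(syn, seed=seeds["simulate"] if syn.seed == 0 else None)
    results["careless"] = detect_careless(dataset)
    dataset = apply_inclusion(dataset, cfg.inclusion)
    results["dataset"] = dataset

    # -- descriptives --------------------------------------------------------
    stat_table = compute_stat_table(dataset, include_modes=cfg.include_modes, mode_seed=seeds["modes"])
    results["stat_table"] = stat_table

    # -- group models --------------------------------------------------------
    families = dict(DEFAULT_FAMILIES)
    if cfg.families:
        families.update(cfg.families)
    emms: dict = {}
    fits: dict = {}
    for outcome in cfg.outcomes:
        try:
            spec = families[outcome]
            tab = stat_table
            if outcome == "missing_prop":
                tab = stat_table.groupby("participant_id", as_index=False).first()
            elif outcome == "duration":
                tab = (
                    dataset.records.groupby(["participant_id", "group", "beep"], as_index=False)["duration_s"]
                    .first()
                    .rename(columns={"duration_s": "duration"})
                    .dropna(subset=["duration"])
                )
            post = fit_group_model(tab, outcome, spec, **_fit_kwargs(cfg, seeds["models"]))
            fits[outcome] = post
            parts = {"mean": emm_summary(post, outcome, "mean"), "variance": emm_summary(post, outcome, "variance")}
            if spec.zero_inflation:
                parts["pi0"] = emm_summary(post, outcome, "pi0")
            emms[outcome] = parts
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            logger.exception("group model failed for %s", outcome)
            results["failures"][f"group_model:{outcome}"] = str(exc)
    results["fits"] = fits
    results["emms"] = emms
    results["summary_table"] = build_summary_table(emms)

    # -- multimodality -------------------------------------------------------
    if cfg.include_modes:
        try:
            results["multimodality"] = multimodality_comparison(stat_table, seed=seeds["modes"])
        except Exception as exc:  # noqa: BLE001
            results["failures"]["multimodality"] = str(exc)

    # -- criterion correlations ----------------------------------------------
    if len(dataset.criteria):
        try:
            item_means = stat_table.pivot(index="participant_id", columns="item", values="wp_mean")
            crit_res = {}
            for crit in dataset.criteria.columns:
                crit_res[crit] = _models.criterion_correlations(
                    item_means,
                    dataset.criteria[crit],
                    dataset.group_of(),
                    B=cfg.boot_B,
                    seed=seeds["criterion"],
                )
            results["criterion"] = crit_res
        except Exception as exc:  # noqa: BLE001
            results["failures"]["criterion"] = str(exc)
    else:
        logger.info("no criterion scores; criterion stage skipped")

    # -- permutation test ----------------------------------------------------
    try:
        results["permutation"] = permutation_test_from_dataset(
            dataset, n_perm=cfg.n_perm, alpha=cfg.alpha, seed=seeds["permutation"]
        )
    except Exception as exc:  # noqa: BLE001
        results["failures"]["permutation"] = str(exc)

    # -- thresholding counterfactual ------------------------------------------
    if cfg.run_thresholding:
        try:
            results["thresholding"] = threshold_counterfactual(
                dataset, tmap=cfg.threshold_map, B=cfg.threshold_B, seed=seeds["thresholding"]
            )
        except Exception as exc:  # noqa: BLE001
            results["failures"]["thresholding"] = str(exc)

    if cfg.outdir:
        _write_outputs(results, cfg.outdir)
    return results


def _write_outputs(results: dict, outdir: str) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    results["stat_table"].to_csv(os.path.join(outdir, "stats.csv"), index=False)
    for outcome, parts in results.get("emms", {}).items():
        for quantity, emm in parts.items():
            emm.table.to_csv(os.path.join(outdir, f"emm_{outcome}_{quantity}.csv"))
    if "summary_table" in results:
        results["summary_table"].to_csv(os.path.join(outdir, "summary_table.csv"))
    if "permutation" in results:
        results["permutation"].table.to_csv(os.path.join(outdir, "perm.csv"), index=False)
    if "thresholding" in results:
        results["thresholding"].table.to_csv(os.path.join(outdir, "thr.csv"), index=False)
    if "multimodality" in results:
        results["multimodality"].to_csv(os.path.join(outdir, "multimodality.csv"))
    for crit, res in results.get("criterion", {}).items():
        res.avg_abs.to_csv(os.path.join(outdir, f"criterion_{crit}_avg_abs.csv"))
        res.per_item.to_csv(os.path.join(outdir, f"criterion_{crit}_per_item.csv"))
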