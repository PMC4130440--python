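"""End-to-end orchestration and small descriptive computations.

The full analysis mirrors the study workflow: date the tree, summarize it,
partition trait variance among vs within species, compute treewise signal
(overall and per growth form), build the divergence-time correlogram and
compare decay shapes, fit and rank the trait-evolution models, test node-level
divergence widths, and summarize families.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import signal as sig
from .divergence import classify_divergences, dw_permutation_test
from .models import ModelFit, RegimePainting, compare_models, fit_model, percent_null_deviance
from .phylo import Phylogeny, bladj_date, divergence_time_matrix, subset_tips, tree_stats, write_newick
from .traits import TraitTable

__all__ = ["variance_partition", "family_summaries", "run_full_analysis", "AnalysisReport"]


def variance_partition(traits: TraitTable) -> tuple[float, float]:
    """(V_among, V_within) on raw-scale values.

    V_among is the variance of species means; V_within is the mean of the
    per-species variances (single-record species contribute 0 and are
    counted).
    """
    grouped = traits.data.groupby("species")["value"]
    means = grouped.mean()
    if len(means) < 2:
        raise ValueError("variance partition needs at least 2 species")
    v_among = float(means.var(ddof=1))
    v_within = float(grouped.var(ddof=1).fillna(0.0).mean())
    return v_among, v_within


def family_summaries(
    traits: TraitTable,
    taxonomy: Mapping[str, str],
    min_species: int = 11,
) -> tuple[pd.DataFrame, dict]:
    """Per-family trait summaries plus two OLS r² values.

    Families with fewer than ``min_species`` sampled species are dropped (the
    default keeps families with more than 10 species).  Returns a table with
    species count, mean raw trait, woody proportion and per-class means, and a
    dict with r² of family mean vs woody proportion and of herbaceous vs woody
    family means (``None`` with a flag when a regression is degenerate).
    """
    means = traits.raw_means
    forms = traits.growth_form_of()
    fam = pd.Series({sp: taxonomy.get(sp) for sp in means.index}).dropna()
    if fam.empty:
        raise ValueError("taxonomy does not cover any sampled species")
    df = pd.DataFrame(
        {
            "mean_value": means.reindex(fam.index),
            "family": fam,
            "woody": forms.reindex(fam.index).isin({"shrub", "tree", "woody"}),
        }
    )
    rows = []
    for family, sub in df.groupby("family"):
        if len(sub) < min_species:
            continue
        herb = sub.loc[~sub["woody"], "mean_value"]
        woody = sub.loc[sub["woody"], "mean_value"]
        rows.append(
            {
                "family": family,
                "n_species": len(sub),
                "mean_value": sub["mean_value"].mean(),
                "woody_prop": sub["woody"].mean(),
                "herb_mean": herb.mean() if len(herb) else np.nan,
                "woody_mean": woody.mean() if len(woody) else np.nan,
            }
        )
    if not rows:
        raise ValueError(f"no family has >= {min_species} sampled species")
    table = pd.DataFrame(rows).sort_values("family").reset_index(drop=True)

    def _r2(x: pd.Series, y: pd.Series):
        mask = x.notna() & y.notna()
        if mask.sum() < 3 or np.var(x[mask]) == 0:
            return None, "degenerate"
        res = sps.linregress(x[mask], y[mask])
        return float(res.rvalue**2), "ok"

    r2_woody, flag_woody = _r2(table["woody_prop"], table["mean_value"])
    r2_hw, flag_hw = _r2(table["woody_mean"], table["herb_mean"])
    stats = {
        "r2_mean_vs_woody_prop": r2_woody,
        "r2_mean_vs_woody_prop_flag": flag_woody,
        "r2_herb_vs_woody_mean": r2_hw,
        "r2_herb_vs_woody_mean_flag": flag_hw,
        "n_families": len(table),
    }
    return table, stats


@dataclass
class AnalysisReport:
    """Everything the full analysis produced; sections are None when skipped."""

    tree_stats: dict
    variance_partition: dict
    signal: dict
    correlogram: pd.DataFrame | None
    decay: dict | None
    model_ranking: pd.DataFrame | None
    model_fits: dict
    divergences: pd.DataFrame | None
    family_summaries: pd.DataFrame | None
    family_stats: dict | None
    seed: int | None
    skipped: dict = field(default_factory=dict)


def _signal_block(tree: Phylogeny, traits, n_perm: int, seed: int | None) -> dict:
    d = divergence_time_matrix(tree)
    k = sig.blomberg_k(tree, traits, n_perm=n_perm, seed=seed)
    lam = sig.pagel_lambda(tree, traits)
    moran = sig.moran_i(d, traits, n_perm=n_perm, seed=seed)
    return {
        "n": k.n,
        "K": k.estimate,
        "K_p": k.p_value,
        "lambda": lam.estimate,
        "lambda_p_vs_0": lam.details.get("p_vs_0"),
        "moran_I": moran.estimate,
        "moran_I_p": moran.p_value,
        "moran_null": moran.null_expectation,
    }


def run_full_analysis(
    tree: Phylogeny,
    traits: TraitTable,
    ages: Mapping[str, float] | None = None,
    models: Sequence[str] = ("PI", "BM", "OU1"),
    paintings: Mapping[str, RegimePainting] | None = None,
    taxonomy: Mapping[str, str] | None = None,
    groups: Sequence[str] = ("herbaceous", "woody"),
    n_perm: int = 999,
    dw_perm: int = 1000,
    fdr: float = 0.05,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> AnalysisReport:
    """Run every analysis stage and (optionally) write a report directory.

    Stages: date (when ``ages`` given) → tree stats → variance partition →
    signal overall and per growth-form group → correlogram + decay fits →
    model fits and BIC ranking → divergence classification → family
    summaries.  A stage failure aborts with the stage named; sections whose
    inputs are absent are marked skipped.  Fully reproducible given ``seed``.
    """
    skipped: dict[str, str] = {}
    stage = "dating"
    try:
        if ages is not None:
            tree = bladj_date(tree, ages)
        if not tree.is_dated:
            tree = tree.copy()
            tree.date_from_branch_lengths()

        stage = "tree_stats"
        ts = asdict(tree_stats(tree))

        stage = "restrict_to_tree"
        tips = set(tree.tip_labels)
        traits_on_tree = traits.subset(tips & set(traits.species))
        species = set(traits_on_tree.species)
        if species != tips:
            tree = subset_tips(tree, sorted(species))

        stage = "variance_partition"
        v_among, v_within = variance_partition(traits_on_tree)
        vp = {"v_among": v_among, "v_within": v_within}

        stage = "signal"
        signal_out = {"all": _signal_block(tree, traits_on_tree, n_perm, seed)}
        for group in groups:
            try:
                members = [
                    s for s in traits_on_tree.species_in_class(group) if s in tips
                ]
            except ValueError:
                skipped[f"signal:{group}"] = "no growth_form column"
                continue
            if len(members) < 4:
                skipped[f"signal:{group}"] = f"only {len(members)} species"
                continue
            sub_tree = subset_tips(tree, members)
            sub_traits = traits_on_tree.subset(members)
            signal_out[group] = _signal_block(sub_tree, sub_traits, n_perm, seed)

        stage = "correlogram"
        n_pairs = tree.n_tips * (tree.n_tips - 1) // 2
        corr = sig.correlogram(
            tree,
            traits_on_tree,
            target_min_pairs=max(10, min(100, n_pairs // 20)),
            n_perm=min(n_perm, 199),
            seed=seed,
        )
        if len(corr.bins) >= 4:
            decay = sig.fit_decay(corr)
            decay_out = {
                "preferred": decay.preferred,
                "statistic": decay.statistic,
                "linear_params": decay.linear_params,
                "exponential_params": decay.exponential_params,
                "exponential_converged": decay.exponential_converged,
            }
        else:
            decay_out = None
            skipped["decay"] = f"only {len(corr.bins)} divergence-time classes"

        stage = "model_fits"
        fits: list[ModelFit] = []
        fit_info: dict[str, dict] = {}
        for name in models:
            painting = (paintings or {}).get(name)
            fit = fit_model(tree, traits_on_tree, name, painting=painting)
            fits.append(fit)
            fit_info[fit.model_name] = {
                "loglik": fit.loglik,
                "bic": fit.bic,
                "sigma": fit.sigma,
                "alpha": fit.alpha,
                "half_life": fit.half_life,
                "thetas": fit.thetas,
                "root_state": fit.root_state,
                "pct_null_deviance": percent_null_deviance(fit, traits_on_tree),
                "converged": fit.converged,
            }
        ranking = compare_models(fits) if len(fits) >= 2 else None

        stage = "divergences"
        dw = dw_permutation_test(tree, traits_on_tree, n_perm=dw_perm, seed=seed)
        dw = classify_divergences(dw, fdr=fdr)

        stage = "family_summaries"
        fam_table = fam_stats = None
        if taxonomy is not None:
            fam_table, fam_stats = family_summaries(traits_on_tree, taxonomy)
        else:
            skipped["family_summaries"] = "no taxonomy provided"
    except Exception as exc:
        raise RuntimeError(f"analysis failed at stage {stage!r}: {exc}") from exc

    report = AnalysisReport(
        tree_stats=ts,
        variance_partition=vp,
        signal=signal_out,
        correlogram=corr.bins,
        decay=decay_out,
        model_ranking=ranking,
        model_fits=fit_info,
        divergences=dw,
        family_summaries=fam_table,
        family_stats=fam_stats,
        seed=seed,
        skipped=skipped,
    )
    if out_dir is not None:
        _write_report(report, tree, Path(out_dir))
    return report


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def _write_report(report: AnalysisReport, tree: Phylogeny, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    summary = {
        "seed": report.seed,
        "tree_stats": report.tree_stats,
        "variance_partition": report.variance_partition,
        "signal": report.signal,
        "decay": report.decay,
        "model_fits": report.model_fits,
        "family_stats": report.family_stats,
        "skipped": report.skipped,
    }
    (out / "report.json").write_text(json.dumps(_jsonify(summary), indent=2, sort_keys=True) + "\n")
    (out / "dated_tree.nwk").write_text(write_newick(tree) + "\n")
    if report.correlogram is not None:
        report.correlogram.to_csv(out / "correlogram.csv", index=False)
    if report.model_ranking is not None:
        report.model_ranking.to_csv(out / "model_ranking.csv", index=False)
    if report.divergences is not None:
        report.divergences.to_csv(out / "divergences.csv", index=False)
    if report.family_summaries is not None:
        report.family_summaries.to_csv(out / "family_summaries.csv", index=False)
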