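"""Per-species analysis orchestration and panel-level reporting.

``analyze_species`` runs the full inference chain for one genotype
panel against a prebuilt reference table: repeat-unit conversion, HWE
quality report, resampled diversity (10 individuals) and ABC
observables (40 individuals), ABC model choice, parameter estimation
under the preferred model only, goodness of fit, posterior predictive
simulation, and the heterozygosity-excess test under a set of mutation
models.  ``panel_report`` collates species reports into one table with
cross-species summaries.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import abc as abc_engine
from . import het_excess as hx
from .coalsim import BOTTLENECK
from .genotype_io import GenotypeDataset, hwe_tests, subset, to_repeat_units
from .sumstats import resampled_stats

log = logging.getLogger("msatbot")


@dataclass
class AnalysisConfig:
    """Knobs of the per-species pipeline."""

    tolerance: float = abc_engine.DEFAULT_TOLERANCE
    min_accepted: int = 500
    n_resamples: int = 1000
    n_ind_diversity: int = 10
    n_heq_sims: int = 10_000
    mutation_models: tuple = hx.DEFAULT_MODELS
    hwe_n_mc: int = 10_000
    hwe_alpha: float = 0.05
    #: drop HWE-flagged loci before inference (sensitivity rerun)
    filter_hwe: bool = False
    #: restrict to these individuals (externally supplied largest cluster)
    cluster_individuals: tuple | None = None
    n_ppc_draws: int = 1000
    n_gof_null: int = 1000
    unbiased_he: bool = True


@dataclass
class SpeciesReport:
    """Study-style per-species result record (JSON-serialisable)."""

    species_id: str
    n_individuals: int
    n_loci: int
    diversity: dict
    prop_het_exc: dict
    p_bot: float
    model_probs: dict
    preferred_model: str
    param_estimates: dict
    gof_p: float
    ppc: dict
    hwe_flagged: list
    provenance: dict

    def to_json(self, path=None):
        payload = json.dumps(asdict(self), indent=1, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _effective_tolerance(tolerance, n_rows, min_accepted):
    n_acc = int(np.ceil(tolerance * n_rows))
    if n_acc < min_accepted:
        eff = min(1.0, min_accepted / n_rows)
        log.info("tolerance %.2g keeps %d rows; rescaled to %.2g to keep "
                 ">= %d", tolerance, n_acc, eff, min_accepted)
        return eff
    return tolerance


def analyze_species(
    ds: GenotypeDataset,
    table: abc_engine.ReferenceTable,
    config: AnalysisConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SpeciesReport:
    """Run the end-to-end inference chain for one species.

    Parameters are estimated for the preferred model only; the report
    never carries estimates from the rejected model.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(rng)
    stage = "start"
    try:
        stage = "cluster_subset"
        if config.cluster_individuals is not None:
            ds = subset(ds, keep_individuals=config.cluster_individuals)

        stage = "to_repeat_units"
        ds = to_repeat_units(ds)

        stage = "hwe_tests"
        hwe = hwe_tests(ds, n_mc=config.hwe_n_mc, alpha=config.hwe_alpha,
                        rng=rng)
        if config.filter_hwe and hwe.flagged_loci:
            keep = [l.id for l in ds.loci if l.id not in hwe.flagged_loci]
            ds = subset(ds, keep_loci=keep)

        stage = "resampled_diversity"
        div = resampled_stats(ds, config.n_ind_diversity, config.n_resamples,
                              rng, kind="diversity",
                              unbiased=config.unbiased_he)

        stage = "abc_observables"
        obs = resampled_stats(ds, table.n_ind, config.n_resamples, rng,
                              kind="sumstats", unbiased=config.unbiased_he)

        tol = _effective_tolerance(config.tolerance, table.n_rows,
                                   config.min_accepted)

        stage = "model_posterior"
        choice = abc_engine.model_posterior(obs, table, tolerance=tol)
        preferred = choice.preferred_model

        stage = "param_posterior"
        post = abc_engine.param_posterior(obs, table, preferred,
                                          tolerance=tol)
        estimates = abc_engine.point_estimates(post).to_dict(orient="index")

        stage = "goodness_of_fit"
        gof = abc_engine.goodness_of_fit(obs, table, preferred,
                                         n_null=config.n_gof_null,
                                         tolerance=tol, rng=rng)

        stage = "posterior_predictive"
        ppc_stats = abc_engine.posterior_predictive(
            post, preferred, n_draws=config.n_ppc_draws, n_ind=table.n_ind,
            n_loci=table.n_loci, rng=rng, unbiased=config.unbiased_he,
        )
        obs_ser = obs.as_series()
        ppc = {
            s: {
                "observed": float(obs_ser[s]),
                "pred_q025": float(ppc_stats[s].quantile(0.025)),
                "pred_q975": float(ppc_stats[s].quantile(0.975)),
                "within_95": bool(
                    ppc_stats[s].quantile(0.025) <= obs_ser[s]
                    <= ppc_stats[s].quantile(0.975)
                ),
            }
            for s in ppc_stats.columns
        }

        stage = "het_excess"
        prop = {}
        for model in config.mutation_models:
            res = hx.prop_het_excess(ds, model, n_sims=config.n_heq_sims,
                                     rng=rng, unbiased=config.unbiased_he)
            prop[model.label] = res.prop_het_exc
    except Exception as exc:
        raise RuntimeError(
            f"{ds.species_id}: pipeline failed at stage {stage!r}: {exc}"
        ) from exc

    return SpeciesReport(
        species_id=ds.species_id,
        n_individuals=ds.n_individuals,
        n_loci=ds.n_loci,
        diversity=div.table.to_dict(orient="index"),
        prop_het_exc=prop,
        p_bot=choice.p_bot,
        model_probs=choice.probs,
        preferred_model=preferred,
        param_estimates=estimates,
        gof_p=gof.p_value,
        ppc=ppc,
        hwe_flagged=hwe.flagged_loci,
        provenance={
            "tolerance": tol,
            "table_rows": table.n_rows,
            "table_seed": table.seed,
            "prior_hash": table.priors.spec_hash(),
            "n_resamples": config.n_resamples,
            "n_heq_sims": config.n_heq_sims,
        },
    )


def panel_report(reports: list[SpeciesReport]):
    """Collate species reports: one row per species plus cross-species
    summaries (Pearson correlations among diversity measures, count of
    species with p_bot > 0.5)."""
    if len(reports) < 2:
        raise ValueError("panel_report needs >= 2 species reports")
    rows = []
    for r in reports:
        row = {
            "species_id": r.species_id,
            "n_individuals": r.n_individuals,
            "n_loci": r.n_loci,
            "ho_10": r.diversity["ho"]["mean"],
            "ar_10": r.diversity["ar"]["mean"],
            "he_10": r.diversity["he"]["mean"],
            "lfa_10": r.diversity["lfa"]["mean"],
            "p_bot": r.p_bot,
            "preferred_model": r.preferred_model,
            "gof_p": r.gof_p,
            "n_hwe_flagged": len(r.hwe_flagged),
        }
        for label, v in r.prop_het_exc.items():
            row[f"prop_het_exc_{label}"] = v
        if r.preferred_model == BOTTLENECK:
            row["ne_bot_mode"] = r.param_estimates["ne_bot"]["mode"]
            row["ne_bot_ci_low"] = r.param_estimates["ne_bot"]["ci_low"]
            row["ne_bot_ci_high"] = r.param_estimates["ne_bot"]["ci_high"]
        row["mu_mode"] = r.param_estimates["mu"]["mode"]
        row["gsm_par_mode"] = r.param_estimates["gsm_par"]["mode"]
        rows.append(row)
    tab = pd.DataFrame(rows)

    def _corr(a, b):
        x, y = tab[a], tab[b]
        if x.nunique() < 2 or y.nunique() < 2:
            warnings.warn(f"correlation {a}~{b} undefined (constant input)")
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])

    summary = {
        "n_species": len(tab),
        "n_p_bot_gt_0.5": int((tab["p_bot"] > 0.5).sum()),
        "r_ho_ar": _corr("ho_10", "ar_10"),
        "r_ho_he": _corr("ho_10", "he_10"),
        "r_ar_he": _corr("ar_10", "he_10"),
    }
    return tab, summary
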