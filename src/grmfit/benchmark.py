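"""Desk-scale synthetic benchmarks: parameter recovery and mechanism identification.

Two standard exercises run the full pipeline on generator output with known
truth:

* :func:`recovery_benchmark` — 20 zero-noise genes from the simple model,
  fitted with the simple model on replicate 1; reports how often the mRNA
  degradation rate k_deg is recovered within a factor of two.
* :func:`identification_benchmark` — a mixed cohort (5 genes per model,
  zero noise) run through fitting, concordance and classification; reports
  the fraction of genes whose best-fit call matches the generating model,
  plus the good-fit threshold bookkeeping.

Both use the desk configuration: 20 importance-screened starts per stage
with a capped local search — the protocol structure is unchanged, only the
budget is reduced relative to the 100-start default.
"""

from __future__ import annotations


import numpy as np

from .fitting import TwoStepFit
from .io import PipelineConfig
from .pipeline import MechanismStudy, gene_fold_change
from .selection import UNEXPLAINED
from .synthetic import cohort_genes, make_gene_table, study_timecourses
from .timecourse import prepare_inputs

__all__ = ["desk_config", "recovery_benchmark", "identification_benchmark"]


def desk_config(seed: int, **overrides) -> PipelineConfig:
    """The reduced-budget configuration used by the synthetic benchmarks."""
    base = dict(seed=seed, n_starts=20, screen_factor=15, maxfev=250,
                maxfev_stage2=120)
    base.update(overrides)
    return PipelineConfig(**base)


def recovery_benchmark(seed: int = 0, n_genes: int = 20) -> dict:
    """k_deg recovery on zero-noise simple-model genes (replicate 1).

    Returns the per-gene true/estimated rates and the fraction recovered
    within a factor of two (the ``recovered_fraction`` key).
    """
    cfg = desk_config(seed)
    tcs = study_timecourses(seed=seed)
    inputs = prepare_inputs(tcs)[1]
    genes = cohort_genes(models=["simple"], n_per_model=n_genes, seed=seed)
    table, truth = make_gene_table(genes, inputs)
    fit_cfg = cfg.fit_config()
    rows = []
    ss = np.random.SeedSequence(seed, spawn_key=(901,))
    for child, gene in zip(ss.spawn(len(genes)), genes):
        data_fc = gene_fold_change(table.loc[gene.gene_id].to_numpy(), 13)
        res = TwoStepFit(
            data_fc, inputs, "simple", gene.gene_id, 1, fit_cfg
        ).fit(seed=int(child.generate_state(1)[0] % (2 ** 31)))
        best = min(res.records, key=lambda r: r.nrmsd_total)
        true_kdeg = gene.true_params.free["k_deg"]
        est = best.params.free["k_deg"]
        rows.append({
            "gene_id": gene.gene_id,
            "true_k_deg": true_kdeg,
            "est_k_deg": est,
            "ratio": max(est, true_kdeg) / min(est, true_kdeg),
            "nrmsd_total": best.nrmsd_total,
        })
    recovered = sum(r["ratio"] <= 2.0 for r in rows)
    return {
        "genes": rows,
        "n": len(rows),
        "recovered": recovered,
        "recovered_fraction": recovered / len(rows),
    }


def identification_benchmark(seed: int = 0, n_per_model: int = 5) -> dict:
    """Best-fit mechanism identification on a mixed zero-noise cohort."""
    cfg = desk_config(seed, n_per_model=n_per_model)
    study = MechanismStudy.from_synthetic(cfg)
    results = study.fit()
    table = results.decision_table()
    truth = study.truth

    n = len(table)
    correct = sum(
        table.loc[g, "best_fit"] == truth[g]["model"] for g in table.index
    )
    good_gene_si_max = []
    threshold_ok = True
    for d in results.decisions:
        for model, flag in d.good_fit.items():
            if not flag:
                continue
            pair = d.pairs[model]
            for rec in (pair.rep1, pair.rep2):
                threshold_ok &= rec.nrmsd_ctrl < cfg.nrmsd_ctrl_threshold
                threshold_ok &= rec.nrmsd_si < cfg.nrmsd_si_threshold
        if d.best_fit != UNEXPLAINED:
            pair = d.pairs[d.best_fit]
            good_gene_si_max.append(max(pair.rep1.nrmsd_si, pair.rep2.nrmsd_si))
    return {
        "study": study,
        "results": results,
        "decision_table": table,
        "n": n,
        "correct": int(correct),
        "identified_fraction": correct / n,
        "n_good_fit_genes": len(good_gene_si_max),
        "max_si_nrmsd_good_fit": float(max(good_gene_si_max)) if good_gene_si_max else float("nan"),
        "thresholds_respected": bool(threshold_ok),
    }
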