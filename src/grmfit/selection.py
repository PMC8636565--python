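"""Good-fit classification and best-fit model selection per gene.

A (gene, model) concordant pair is a *good fit* when

* control nRMSD < 0.5 in both replicates,
* siIκBα nRMSD < 0.39 in both replicates (strict inequalities), and
* the fitted simulation reproduces the stronger induction in control:
  MFI_ctrl > MFI_si or AUC_ctrl > AUC_si.

Among a gene's good-fit models, the *best fit* is the one with the smallest
total nRMSD (the sum of the four components: ctrl/siIκBα × replicate 1/2).
A gene with no good-fit model is reported as "unexplained", with its simple-
model fit attached for reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .concordance import ConcordantPair

__all__ = ["Thresholds", "GeneDecision", "classify_good_fit", "pick_best_model"]

UNEXPLAINED = "unexplained"


@dataclass(frozen=True)
class Thresholds:
    """Good-fit thresholds; the siIκBα cutoff mirrors the tighter spread of
    knockdown expression in the underlying data analysis."""

    nrmsd_ctrl: float = 0.5
    nrmsd_si: float = 0.39
    #: which replicate's fitted simulation supplies MFI/AUC for the
    #: induction-relation test ("rep1" or "both")
    induction_from: str = "rep1"


def classify_good_fit(
    pair: ConcordantPair, thresholds: Thresholds = Thresholds()
) -> tuple[bool, list[str]]:
    """Good-fit flag and the list of failed conditions (empty when good)."""
    reasons: list[str] = []
    for rec, rep in ((pair.rep1, 1), (pair.rep2, 2)):
        if not rec.nrmsd_ctrl < thresholds.nrmsd_ctrl:
            reasons.append(f"ctrl rep{rep} nRMSD {rec.nrmsd_ctrl:.3f} >= {thresholds.nrmsd_ctrl}")
        if not rec.nrmsd_si < thresholds.nrmsd_si:
            reasons.append(f"siIkBa rep{rep} nRMSD {rec.nrmsd_si:.3f} >= {thresholds.nrmsd_si}")
    records = (pair.rep1,) if thresholds.induction_from == "rep1" else (pair.rep1, pair.rep2)
    for rec in records:
        if not (rec.mfi_ctrl > rec.mfi_si or rec.auc_ctrl > rec.auc_si):
            reasons.append(
                f"induction relation rep{rec.replicate}: "
                f"MFI {rec.mfi_ctrl:.3g} <= {rec.mfi_si:.3g} and AUC {rec.auc_ctrl:.3g} <= {rec.auc_si:.3g}"
            )
    return len(reasons) == 0, reasons


@dataclass(frozen=True)
class GeneDecision:
    """Per-gene outcome: good-fit flags, total nRMSDs and the best-fit call."""

    gene_id: str
    good_fit: dict[str, bool]
    reasons: dict[str, list[str]]
    total_nrmsd: dict[str, float]
    best_fit: str
    pairs: dict[str, ConcordantPair] = field(repr=False, default_factory=dict)


def pick_best_model(
    pairs: dict[str, ConcordantPair],
    thresholds: Thresholds = Thresholds(),
    require_models: tuple[str, ...] | None = None,
) -> GeneDecision:
    """Classify every model's concordant pair and pick the best-fit model.

    ``pairs`` maps model name to that model's concordant pair for one gene.
    The best fit is the good-fit model with the smallest total nRMSD; with no
    good-fit model the gene is "unexplained".
    """
    if not pairs:
        raise ValueError("no model evaluations supplied")
    if require_models is not None:
        missing = set(require_models) - set(pairs)
        if missing:
            raise ValueError(f"missing model evaluations: {sorted(missing)}")
    gene_id = next(iter(pairs.values())).gene_id
    good: dict[str, bool] = {}
    reasons: dict[str, list[str]] = {}
    totals: dict[str, float] = {}
    for model, pair in pairs.items():
        flag, why = classify_good_fit(pair, thresholds)
        good[model] = flag
        reasons[model] = why
        totals[model] = pair.rep1.nrmsd_total + pair.rep2.nrmsd_total
    good_models = [m for m, ok in good.items() if ok]
    if good_models:
        best = min(good_models, key=lambda m: (totals[m], m))
    else:
        best = UNEXPLAINED
    return GeneDecision(
        gene_id=gene_id,
        good_fit=good,
        reasons=reasons,
        total_nrmsd=totals,
        best_fit=best,
        pairs=dict(pairs),
    )
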