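"""Missing-modality evaluation, selective prediction, site-held-out protocol.

Missing modalities are simulated at inference time: the standardized features
of the masked modality are zeroed and the modality is excluded from attention
readout via the batch's modality mask, without touching model parameters.
Selective prediction abstains whenever the maximum predicted probability falls
below a threshold chosen on the validation split for a pre-specified target
coverage, before any test data is seen.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphs import HeteroGraph, MODALITIES
from .model import CrossOmicsNet, ModelConfig, PatientBatch
from .evaluation import MetricReport, metric_report
from .training import (TrainRun, predict_probs, split_inner_validation,
                       substream, train_model, _standardized_fold_batches)

logger = logging.getLogger(__name__)

_MODALITY_INDEX = {t: i for i, t in enumerate(MODALITIES)}

#: the standard inference-time scenarios: none missing, each single modality
#: missing, and the severe-loss setting where only mRNA remains
STANDARD_SCENARIOS = {
    "full": frozenset(),
    "no_mrna": frozenset({"g"}),
    "no_cpg": frozenset({"c"}),
    "no_mirna": frozenset({"m"}),
    "mrna_only": frozenset({"c", "m"}),
}


@dataclass(frozen=True)
class MissingnessScenario:
    name: str
    masked: frozenset

    def __post_init__(self):
        if set(self.masked) >= set(MODALITIES):
            raise ValueError("at least one modality must remain")


def apply_missingness(batch: PatientBatch, masked) -> PatientBatch:
    """Zero the masked modalities and update the modality mask; idempotent."""
    masked = set(masked)
    mask = batch.modality_mask.copy()
    x = {t: batch.x[t].copy() for t in MODALITIES}
    for t in masked:
        mask[:, _MODALITY_INDEX[t]] = False
        x[t][:] = 0.0
    return PatientBatch(x=x, modality_mask=mask, labels=batch.labels,
                        sample_ids=batch.sample_ids)


# ------------------------------------------------------- selective prediction
def choose_threshold(validation_probs: np.ndarray, target_coverage: float) -> float:
    """Largest threshold whose validation coverage is still >= the target.

    Confidence is the max class probability; accepting means conf >= τ.  The
    conservative rule takes τ as the ⌈target·n⌉-th largest confidence, so
    realized validation coverage is at least the target.
    """
    conf = np.sort(np.asarray(validation_probs).max(axis=1))[::-1]
    n = len(conf)
    need = min(n, max(1, math.ceil(target_coverage * n)))
    return float(conf[need - 1])


def coverage_risk_curve(test_probs: np.ndarray, labels,
                        thresholds) -> pd.DataFrame:
    """(coverage, risk) per threshold; risk undefined (NaN) at zero coverage."""
    probs = np.asarray(test_probs)
    labels = np.asarray(labels)
    conf = probs.max(axis=1)
    correct = probs.argmax(axis=1) == labels
    rows = []
    for tau in thresholds:
        accepted = conf >= tau
        coverage = float(accepted.mean())
        risk = float(1.0 - correct[accepted].mean()) if accepted.any() else np.nan
        rows.append({"threshold": float(tau), "coverage": coverage, "risk": risk})
    return pd.DataFrame(rows)


@dataclass
class SelectiveOperatingPoint:
    target_coverage: float
    threshold: float
    test_coverage: float
    test_risk: float


def selective_operating_points(val_probs: np.ndarray, test_probs: np.ndarray,
                               test_labels,
                               targets=(0.90, 0.80, 0.70)
                               ) -> list[SelectiveOperatingPoint]:
    """Thresholds fixed on validation, then applied unchanged to the test fold."""
    points = []
    for target in targets:
        tau = choose_threshold(val_probs, target)
        curve = coverage_risk_curve(test_probs, test_labels, [tau]).iloc[0]
        points.append(SelectiveOperatingPoint(
            target_coverage=target, threshold=tau,
            test_coverage=float(curve["coverage"]),
            test_risk=float(curve["risk"])))
    return points


# -------------------------------------------------------- scenario evaluation
def evaluate_scenarios(model: CrossOmicsNet, test_batch: PatientBatch,
                       scenarios: dict[str, frozenset] | None = None
                       ) -> dict[str, MetricReport]:
    """MetricReport per missingness scenario, parameters untouched."""
    scenarios = scenarios or STANDARD_SCENARIOS
    out = {}
    for name, masked in scenarios.items():
        batch = apply_missingness(test_batch, masked)
        probs = predict_probs(model, batch)
        out[name] = metric_report(batch.labels, probs,
                                  num_classes=model.config.num_classes)
    return out


# ------------------------------------------------------------- site held-out
def site_heldout_evaluate(graph: HeteroGraph, raw: dict[str, np.ndarray],
                          labels, site_labels, config: ModelConfig,
                          run_template: TrainRun | None = None,
                          seed: int = 0) -> dict:
    """One full training per held-out site; fold-safe preprocessing inside the
    training side only.  Sites with fewer samples than classes are skipped.

    Returns per-site reports plus mean and worst-site summaries.
    """
    labels = np.asarray(labels)
    site_labels = np.asarray(site_labels)
    run_template = run_template or TrainRun()
    sample_ids = [f"S{i:04d}" for i in range(len(labels))]
    reports: dict = {}
    for site in sorted(set(site_labels.tolist())):
        test_ix = np.flatnonzero(site_labels == site)
        train_ix = np.flatnonzero(site_labels != site)
        if len(test_ix) < config.num_classes:
            logger.warning("site %r has %d samples (< %d classes); skipped",
                           site, len(test_ix), config.num_classes)
            continue
        site_seed = int(substream(seed, f"site{site}").integers(2 ** 31))
        train_batch, test_batch, _ = _standardized_fold_batches(
            raw, labels, sample_ids, train_ix, test_ix)
        fit_loc, val_loc = split_inner_validation(
            np.arange(len(train_ix)), train_batch.labels,
            frac=run_template.inner_val_frac, seed=site_seed)
        cfg = ModelConfig(**{**config.to_dict(), "seed": site_seed})
        model = CrossOmicsNet(graph, cfg, rng=substream(site_seed, "init"))
        run = TrainRun(**{**run_template.__dict__, "seed": site_seed,
                          "history": []})
        result = train_model(model, train_batch.subset(fit_loc),
                             train_batch.subset(val_loc), run)
        probs = predict_probs(model, test_batch, set(result["always_masked"]))
        reports[site] = metric_report(test_batch.labels, probs,
                                      num_classes=config.num_classes)
    if not reports:
        raise ValueError("no site had enough samples for held-out evaluation")
    summary = {}
    for metric in ("accuracy", "balanced_accuracy", "macro_f1"):
        vals = [getattr(rep, metric) for rep in reports.values()]
        summary[f"mean_{metric}"] = float(np.mean(vals))
        summary[f"worst_{metric}"] = float(np.min(vals))
    return {"per_site": reports, "summary": summary}
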