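"""End-to-end pipeline orchestration and report rendering.

Produces the standard outputs of a screening evaluation: an inter-rater
kappa matrix, per-rater 11-metric panels with bootstrap CIs and pairwise
p-values against a comparator, a threshold-wise confusion table for the
ordinal rater, a ROC summary, and triage counts — everything both as
pandas frames and as one machine-readable JSON bundle.

``reproduce_tables`` re-derives a published study's whole-dataset results
from the packaged classification counts: the printed counts are expanded
into item-level fixtures and pushed through the same metric, ROC and
bootstrap code paths as fresh data.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field as dc_field
from importlib.resources import files
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from ._util import round_half_up
from .bootstrap import BootstrapConfig, bootstrap_ci, bootstrap_compare
from .consensus import DecisionMatrix, adjudicate, consensus
from .metrics import (
    METRIC_NAMES,
    ConfusionCounts,
    MetricReport,
    confusion,
    evaluate,
    kappa,
)
from .rater_harness import triage
from .roc_threshold import RatingVector, binarize, youden
from .synthetic_data import (
    SimulationSpec,
    default_study_spec,
    fixture_from_counts,
    ratings_fixture_from_cumulative,
    simulate_study,
)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "reproduce_tables",
    "load_published_counts",
    "metric_table",
]

logger = logging.getLogger(__name__)

#: Table row labels in report order, keyed by metric name.
METRIC_LABELS = {
    "sensitivity": "Sensitivity",
    "specificity": "Specificity",
    "ppv": "Precision (PPV)",
    "npv": "Negative Predictive Value",
    "plr": "Positive Likelihood Ratio",
    "nlr": "Negative Likelihood Ratio",
    "balanced_accuracy": "Balanced Accuracy",
    "jaccard": "Jaccard Index",
    "fnr": "False Negative Rate",
    "proportion_missed": "Proportion Missed",
    "workload_saving": "Workload Saving",
}


def load_published_counts() -> dict:
    """The packaged published classification counts (raters x confusion cells)."""
    text = files("screeneval.data").joinpath("published_counts.json").read_text("utf-8")
    return json.loads(text)


def metric_table(reports: dict[str, MetricReport], ndigits: int = 2) -> pd.DataFrame:
    """Metric panel(s) as a printable frame: one labelled row per metric."""
    cols = {}
    for name, rep in reports.items():
        col = {}
        for m in METRIC_NAMES:
            v = round_half_up(rep.value(m), ndigits)
            cell = "inf" if math.isinf(v) else f"{v:.{ndigits}f}"
            if m in rep.cis:
                lo, hi = rep.cis[m]
                lo = round_half_up(lo, ndigits)
                hi_s = "inf" if math.isinf(hi) else f"{round_half_up(hi, ndigits):.{ndigits}f}"
                cell += f" [{lo:.{ndigits}f},{hi_s}]"
            col[METRIC_LABELS[m]] = cell
        cols[name] = col
    return pd.DataFrame(cols).reindex([METRIC_LABELS[m] for m in METRIC_NAMES])


@dataclass
class RunConfig:
    """Configuration for an end-to-end run.

    With ``decisions_csv``/``ratings_csv`` unset the pipeline simulates a
    study from ``simulation`` (defaulting to the packaged study shape).
    ``gold`` selects the gold standard: ``simulated_truth`` (simulation
    only), ``expert_adjudicated`` (the two ``expert_raters`` with
    disagreements broken by majority vote over all raters), or one of the
    consensus rules applied to ``expert_raters``.
    """

    decisions_csv: str | None = None
    ratings_csv: str | None = None
    gold: str = "simulated_truth"
    expert_raters: tuple[str, ...] = ("expert1", "expert2")
    consensus_raters: tuple[str, ...] = ("gp1", "gp2", "gp3")
    comparator: str = "ai"
    low: int = 2
    high: int = 5
    ai_threshold: int | None = None  # None -> Youden-optimal
    bootstrap: BootstrapConfig = dc_field(default_factory=BootstrapConfig)
    simulation: SimulationSpec | None = None
    seed: int = 0
    out_dir: str | None = None


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if math.isnan(f):
            return None
        if math.isinf(f):
            return "inf" if f > 0 else "-inf"
        return f
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    return obj


def _panel_with_inference(
    items: pd.DataFrame,
    rater: str,
    comparator: str | None,
    bconfig: BootstrapConfig,
) -> tuple[MetricReport, dict[str, float | None]]:
    """Metric panel with bootstrap CIs and, optionally, p-values vs a comparator."""
    rep = evaluate(confusion(items[rater].to_numpy(), items["gold"].to_numpy()))
    p_values: dict[str, float | None] = {}
    for m in METRIC_NAMES:
        try:
            res = bootstrap_ci(items, m, rater, bconfig)
            rep.cis[m] = (res.ci_low, res.ci_high)
        except ValueError:
            rep.cis[m] = (math.nan, math.nan)
        if comparator is not None and comparator != rater:
            try:
                cmp_res = bootstrap_compare(items, m, rater, comparator, bconfig)
                p_values[m] = cmp_res.p_value
            except ValueError:
                p_values[m] = None
    return rep, p_values


def run_pipeline(config: RunConfig) -> dict:
    """Run the full evaluation and return the report bundle as a dict.

    The bundle holds the kappa matrix, per-rater metric panels (with CIs and
    p-values against the comparator), the ordinal rater's threshold-wise
    confusion table, the ROC summary, triage counts, and a run log with the
    seed and package version.  Deterministic for a fixed config and seed.
    """
    if config.decisions_csv is not None:
        long = pd.read_csv(config.decisions_csv)
        matrix = DecisionMatrix.from_long(long)
        ratings = None
        if config.ratings_csv is not None:
            rdf = pd.read_csv(config.ratings_csv).set_index("id")
            vals = rdf.reindex(matrix.item_ids)["rating"].to_numpy(float)
            ratings = RatingVector(matrix.item_ids, vals)
    else:
        spec = config.simulation or default_study_spec(config.seed)
        matrix, ratings = simulate_study(spec)

    # --- gold standard -------------------------------------------------
    if config.gold == "simulated_truth":
        if matrix.gold is None:
            raise ValueError("gold='simulated_truth' requires a simulated study")
        gold = matrix.gold
        n_disagreements = None
    elif config.gold == "expert_adjudicated":
        a, b = (matrix.column(r) for r in config.expert_raters[:2])
        tie = consensus(matrix, "voting")
        gold, n_disagreements = adjudicate(a, b, tie)
    elif config.gold in ("sensitive", "specific", "voting"):
        sub = DecisionMatrix(
            matrix.item_ids,
            list(config.expert_raters),
            np.column_stack([matrix.column(r) for r in config.expert_raters]),
        )
        vec = consensus(sub, config.gold)
        if np.isnan(vec).any():
            raise ValueError("gold consensus is undefined on masked items")
        gold = vec.astype(np.int64)
        n_disagreements = None
    else:
        raise ValueError(f"unknown gold definition {config.gold!r}")

    # --- assemble the paired item table --------------------------------
    items = matrix.to_frame().drop(columns=["gold"], errors="ignore")
    items.insert(0, "gold", gold)

    roc = None
    if ratings is not None:
        roc = youden(ratings, gold)
        ai_threshold = config.ai_threshold or roc.optimal_threshold
        items[config.comparator] = binarize(ratings, ai_threshold)
        items[f"{config.comparator}_rating"] = ratings.values
    elif config.comparator not in items.columns:
        raise ValueError(f"comparator {config.comparator!r} not among raters")

    binary_raters = list(matrix.rater_names)
    if ratings is not None:
        binary_raters.append(config.comparator)

    # --- consensus panels over the designated GP-like raters ------------
    consensus_cols = {}
    rule_sub = DecisionMatrix(
        matrix.item_ids,
        list(config.consensus_raters),
        np.column_stack([matrix.column(r) for r in config.consensus_raters]),
    )
    for rule in ("sensitive", "specific", "voting"):
        vec = consensus(rule_sub, rule)
        name = f"{rule}_consensus"
        items[name] = vec.astype(np.int64)
        consensus_cols[name] = rule

    # --- kappa matrix ----------------------------------------------------
    kappa_matrix: dict[str, dict[str, float]] = {}
    for i, ra in enumerate(binary_raters):
        for rb in binary_raters[i + 1 :]:
            kappa_matrix.setdefault(ra, {})[rb] = kappa(
                items[ra].to_numpy(), items[rb].to_numpy()
            ).kappa

    # --- metric panels with inference ------------------------------------
    panel_raters = binary_raters + list(consensus_cols)
    panels: dict[str, MetricReport] = {}
    p_values: dict[str, dict[str, float | None]] = {}
    for rater in panel_raters:
        rep, pv = _panel_with_inference(items, rater, config.comparator, config.bootstrap)
        panels[rater] = rep
        if pv:
            p_values[rater] = pv

    # --- threshold-wise confusion table + triage -------------------------
    threshold_table = {}
    triage_counts = None
    if ratings is not None and roc is not None:
        for t, (tp, fp, tn, fn) in roc._counts.items():
            threshold_table[t] = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
        labels = triage(ratings, config.low, config.high)
        triage_counts = {
            lab: sum(1 for x in labels if x.label == lab)
            for lab in ("auto_exclude", "human_review", "auto_include")
        }

    bundle = {
        "run": {
            "seed": config.seed,
            "version": __version__,
            "n_items": len(items),
            "gold": config.gold,
            "n_gold_positive": int(items["gold"].sum()),
            "n_adjudicated_disagreements": n_disagreements,
            "bootstrap_reps": config.bootstrap.n_reps,
        },
        "kappa_matrix": kappa_matrix,
        "panels": {
            name: {"values": rep.to_dict(), "cis": rep.cis, "counts": rep.counts.as_tuple()}
            for name, rep in panels.items()
        },
        "p_values_vs_comparator": p_values,
        "roc": None
        if roc is None
        else {
            "auc": roc.auc,
            "optimal_threshold": roc.optimal_threshold,
            "optimal_j": roc.optimal_j,
            "youden_j_by_threshold": roc.youden_j_by_threshold,
            "points": roc.points,
        },
        "threshold_confusion": threshold_table,
        "triage_counts": triage_counts,
    }
    bundle = _jsonify(bundle)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(bundle, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        metric_table(panels).to_csv(out / "metric_panels.csv")
        items.to_csv(out / "items.csv", index=True, index_label="id")
        logger.info("report bundle written to %s", out)
    return bundle


def reproduce_tables(bootstrap_reps: int = 1000, seed: int = 0) -> dict:
    """Re-derive the published whole-dataset results from packaged counts.

    Expands the printed confusion/cumulative counts into item-level fixtures
    and recomputes: the ordinal rater's tie-aware AUC and Youden-optimal
    threshold, its metric panel at that threshold (with bootstrap CIs), the
    human raters' and consensuses' panels, and the workload saving at each
    threshold.  All numbers are recomputed; nothing is echoed from print.
    """
    pub = load_published_counts()
    cum = {int(t): (v["tp"], v["fp"]) for t, v in pub["ai_cumulative"].items()}
    ratings, gold = ratings_fixture_from_cumulative(
        cum, pub["n_positive"], pub["n_negative"]
    )
    roc = youden(ratings, gold)
    t_star = roc.optimal_threshold

    bconfig = BootstrapConfig(n_reps=bootstrap_reps, seed=seed)
    panels: dict[str, MetricReport] = {}

    ai_items = pd.DataFrame({"gold": gold, pub["ai_rater"]: binarize(ratings, t_star)})
    rep, _ = _panel_with_inference(ai_items, pub["ai_rater"], None, bconfig)
    panels[pub["ai_rater"]] = rep

    for name, cells in pub["raters"].items():
        c = ConfusionCounts(tp=cells["tp"], fp=cells["fp"], tn=cells["tn"], fn=cells["fn"])
        fx = fixture_from_counts(c)
        fx_items = pd.DataFrame({"gold": fx["gold"], name: fx["pred"]})
        rep, _ = _panel_with_inference(fx_items, name, None, bconfig)
        panels[name] = rep

    workload_by_threshold = {
        t: tn / pub["n_items"]
        for t, (tp, fp, tn, fn) in roc._counts.items()
    }
    return {
        "auc": roc.auc,
        "auc_2dp": round_half_up(roc.auc, 2),
        "optimal_threshold": t_star,
        "youden_j_by_threshold": _jsonify(roc.youden_j_by_threshold),
        "panels": {
            name: {
                "values": _jsonify(rep.to_dict()),
                "rounded": _jsonify(rep.rounded(2)),
                "cis": _jsonify(rep.cis),
                "counts": rep.counts.as_tuple(),
            }
            for name, rep in panels.items()
        },
        "workload_saving_by_threshold": _jsonify(workload_by_threshold),
        "threshold_confusion": _jsonify(
            {t: dict(zip(("tp", "fp", "tn", "fn"), v)) for t, v in roc._counts.items()}
        ),
    }
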