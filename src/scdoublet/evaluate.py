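"""Benchmark metrics and orthogonal-validation scores for doublet calls.

Doublet is the positive class throughout: precision, recall and F1 are
computed over all droplets, and recall additionally within each true
doublet type (selflet / nested / neotypic).  The neotypic confidence score
(NCS) counts, for one droplet, how many *validation loci* — loci with
discordant wt/hom states between two known populations — show an observed
VAF inside the heterozygous window, which a singlet cannot produce except
through amplification noise.

The module also hosts the simulate -> estimate -> call -> score pipeline
used for benchmarking over parameter grids, and median aggregation of the
resulting per-run metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .estimation import EstimationConfig, estimate_parameters
from .model import DropletCall, ErrorModel, classify, omega_matrix
from .simulate import (
    NESTED,
    NEOTYPIC,
    SELFLET,
    SimConfig,
    SimTruth,
    panel_locus_priors,
    simulate_dataset,
)

__all__ = [
    "MetricReport",
    "score_calls",
    "ncs_score",
    "aggregate_medians",
    "run_experiment",
    "run_grid",
    "copy_neutral_grid",
    "cna_grid",
    "DOUBLET_TYPES",
]

DOUBLET_TYPES = (SELFLET, NESTED, NEOTYPIC)


@dataclass(frozen=True)
class MetricReport:
    """Precision/recall/F1 of doublet calls plus per-type recall.

    ``precision`` is reported as 0 (not NaN) when nothing was called a
    doublet, so that medians over many runs stay defined; per-type recall
    is NaN for types absent from the truth.
    """

    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int
    per_type_recall: Dict[str, float]

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> Dict[str, float]:
        out = {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
        }
        for t in DOUBLET_TYPES:
            out[f"recall_{t}"] = self.per_type_recall.get(t, float("nan"))
        return out


def score_calls(truth: SimTruth, calls: Sequence[DropletCall]) -> MetricReport:
    """Score calls against simulated ground truth (doublet = positive)."""
    call_by_id = {c.droplet_id: c for c in calls}
    missing = [d for d in truth.droplet_ids if d not in call_by_id]
    if missing:
        raise KeyError(f"no call for droplet {missing[0]!r}")
    pred = np.array(
        [bool(call_by_id[d].z) for d in truth.droplet_ids], dtype=bool
    )
    true = truth.is_doublet.astype(bool)
    tp = int((pred & true).sum())
    fp = int((pred & ~true).sum())
    fn = int((~pred & true).sum())
    tn = int((~pred & ~true).sum())
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    per_type: Dict[str, float] = {}
    for t in DOUBLET_TYPES:
        mask = true & (truth.doublet_type == t)
        per_type[t] = float(pred[mask].mean()) if mask.any() else float("nan")
    return MetricReport(
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        per_type_recall=per_type,
    )


def ncs_score(
    alt_row: np.ndarray,
    total_row: np.ndarray,
    validation_loci: Sequence[int],
    *,
    low: float = 0.15,
    high: float = 0.85,
    closed: bool = True,
) -> int:
    """Neotypic confidence score of one droplet.

    Counts validation loci with coverage whose observed VAF falls in
    ``[low, high]`` (closed interval by default).
    """
    alt_row = np.asarray(alt_row, dtype=float)
    total_row = np.asarray(total_row, dtype=float)
    idx = np.asarray(validation_loci, dtype=int)
    a, c = alt_row[idx], total_row[idx]
    covered = c > 0
    vaf = np.zeros_like(a)
    vaf[covered] = a[covered] / c[covered]
    if closed:
        inside = (vaf >= low) & (vaf <= high)
    else:
        inside = (vaf > low) & (vaf < high)
    return int((inside & covered).sum())


def aggregate_medians(
    reports: pd.DataFrame, group_keys: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Median metrics of per-run reports, optionally grouped by config keys.

    ``reports`` must have one row per run with metric columns (precision,
    recall, f1, ...); without ``group_keys`` a single pooled-median row is
    returned.  Output ordering is deterministic (sorted group keys).
    """
    if len(reports) == 0:
        raise ValueError("need at least one report")
    metric_cols = [
        c
        for c in reports.columns
        if c not in (group_keys or []) and pd.api.types.is_numeric_dtype(reports[c])
    ]
    if not group_keys:
        return reports[metric_cols].median().to_frame().T
    out = (
        reports.groupby(list(group_keys), sort=True)[metric_cols]
        .median()
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# benchmark pipeline
# ---------------------------------------------------------------------------


def run_experiment(
    sim_cfg: SimConfig,
    est_cfg: Optional[EstimationConfig] = None,
    *,
    use_estimated_parameters: bool = True,
) -> Dict[str, float]:
    """One simulate -> estimate -> call -> score run; returns a flat row.

    With ``use_estimated_parameters`` (default) the genotype priors,
    copy-error rates, precision and doublet prior are all estimated from
    the simulated counts; only the ADO rate is taken as known, as it would
    be from an external assay calibration.  Otherwise the generative
    (oracle) parameters are used directly.
    """
    counts, truth, panel = simulate_dataset(sim_cfg)
    est_cfg = est_cfg or EstimationConfig()
    if use_estimated_parameters:
        priors, err = estimate_parameters(counts, beta=sim_cfg.beta, cfg=est_cfg)
        delta = err.delta
    else:
        priors = panel_locus_priors(panel)
        err = ErrorModel(
            beta=sim_cfg.beta,
            alpha_fp=sim_cfg.alpha_fp,
            alpha_fn=sim_cfg.alpha_fn,
            s=sim_cfg.s,
            delta=sim_cfg.delta,
        )
        delta = sim_cfg.delta
    result = omega_matrix(counts, priors, err)
    calls = classify(result, delta)
    report = score_calls(truth, calls)
    row: Dict[str, float] = {
        "m": sim_cfg.m,
        "beta": sim_cfg.beta,
        "coverage": sim_cfg.coverage,
        "delta_true": sim_cfg.delta,
        "gamma": sim_cfg.gamma,
        "loss_prob": sim_cfg.loss_prob,
        "seed": sim_cfg.seed,
        "delta_used": delta,
    }
    row.update(report.to_dict())
    return row


def run_grid(
    configs: Iterable[SimConfig],
    est_cfg: Optional[EstimationConfig] = None,
    *,
    use_estimated_parameters: bool = True,
) -> pd.DataFrame:
    """Run the benchmark pipeline over many configurations."""
    rows = [
        run_experiment(
            cfg, est_cfg, use_estimated_parameters=use_estimated_parameters
        )
        for cfg in configs
    ]
    return pd.DataFrame(rows)


def copy_neutral_grid(
    *,
    coverage: float = 50.0,
    delta: float = 0.2,
    ms: Sequence[int] = (10, 50, 100),
    betas: Sequence[float] = (0.0, 0.05, 0.25),
    seeds: Sequence[int] = (1, 2, 3, 4, 5),
    s: float = 15.0,
) -> List[SimConfig]:
    """The benchmark grid without CNAs: m x beta x seed configurations."""
    return [
        SimConfig(m=m, beta=beta, coverage=coverage, delta=delta, s=s, seed=seed)
        for m in ms
        for beta in betas
        for seed in seeds
    ]


def cna_grid(
    *,
    coverage: float = 50.0,
    delta: float = 0.2,
    ms: Sequence[int] = (10, 50, 100),
    betas: Sequence[float] = (0.0, 0.05, 0.25),
    gammas: Sequence[float] = (0.0, 0.1, 0.5),
    loss_probs: Sequence[float] = (0.1, 0.5),
    seeds: Sequence[int] = (1, 2, 3, 4, 5),
    s: float = 15.0,
) -> List[SimConfig]:
    """Benchmark grid with CNAs; ``gamma = 0`` runs once (loss rate moot)."""
    combos: List[Tuple[float, float]] = []
    for g in gammas:
        if g == 0.0:
            combos.append((0.0, loss_probs[0]))
        else:
            combos.extend((g, l) for l in loss_probs)
    return [
        SimConfig(
            m=m,
            beta=beta,
            coverage=coverage,
            delta=delta,
            s=s,
            gamma=g,
            loss_prob=l,
            seed=seed,
        )
        for m in ms
        for beta in betas
        for (g, l) in combos
        for seed in seeds
    ]
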