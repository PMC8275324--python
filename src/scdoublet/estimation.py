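"""Data-driven estimation of model parameters from read counts.

The classifier needs per-locus genotype priors ``mu``, the beta-binomial
precision ``s``, copy-error rates ``alpha_fp``/``alpha_fn`` and the doublet
prior ``delta``.  All of these can be estimated from the observed count
matrices alone:

1. every droplet-locus with adequate depth is crudely genotyped from its
   observed VAF (wt below ``vaf_low``, hom above ``vaf_high``, het in
   between);
2. ``mu`` is the Laplace-smoothed per-locus frequency of those states;
3. ``alpha_fp`` / ``alpha_fn`` are the pooled variant-read fractions of the
   wt / hom classes, where any variant (reference) read must come from a
   copy error;
4. ``s`` is a method-of-moments fit on the het class, matching the
   empirical variance of variant counts to the beta-binomial variance
   ``c p (1-p) (1 + (c-1)/(s+1))``;
5. ``delta`` maximises the posterior objective of the closed-form
   classifier over a grid.

Doublet contamination is ignored during steps 1-4 (doublets are a small
minority and the estimates are robust to them); the whole procedure is
deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .model import (
    ErrorModel,
    LikelihoodResult,
    LocusPriors,
    ReadCounts,
    amplification_prob,
    omega_matrix,
)

__all__ = [
    "WT",
    "HET",
    "HOM",
    "MISSING",
    "EstimationConfig",
    "assign_crude_genotypes",
    "estimate_locus_priors",
    "estimate_overdispersion",
    "estimate_delta",
    "estimate_parameters",
]

logger = logging.getLogger(__name__)

#: genotype-state codes used in crude assignment matrices
WT, HET, HOM, MISSING = 0, 1, 2, -1

#: floor applied to deconvolved genotype probabilities
MU_FLOOR = 1e-6


def _default_delta_grid() -> np.ndarray:
    return np.round(np.arange(1, 51) * 0.01, 2)


@dataclass(frozen=True)
class EstimationConfig:
    """Tuning knobs of the estimation procedure.

    ``vaf_low``/``vaf_high`` delimit the heterozygous VAF window used for
    crude genotyping; ``min_depth`` is the minimum total depth for a
    droplet-locus to enter estimation; ``delta_grid`` lists candidate
    doublet priors; ``pseudocount`` is the Laplace smoothing added per
    genotype state and locus.
    """

    vaf_low: float = 0.15
    vaf_high: float = 0.85
    min_depth: int = 10
    delta_grid: np.ndarray = field(default_factory=_default_delta_grid)
    pseudocount: float = 1.0
    s_default: float = 15.0
    s_min: float = 1.0
    s_max: float = 1e6
    alpha_floor: float = 1e-6
    alpha_ceil: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 < self.vaf_low < self.vaf_high < 1.0:
            raise ValueError("require 0 < vaf_low < vaf_high < 1")
        grid = np.asarray(self.delta_grid, dtype=float)
        object.__setattr__(self, "delta_grid", grid)
        if grid.size == 0:
            raise ValueError("delta_grid must be non-empty")
        if (grid <= 0.0).any() or (grid >= 1.0).any():
            raise ValueError("delta_grid values must lie in (0, 1)")
        if (np.diff(grid) <= 0).any():
            raise ValueError("delta_grid must be strictly increasing")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")


def assign_crude_genotypes(counts: ReadCounts, cfg: EstimationConfig) -> np.ndarray:
    """Threshold observed VAFs into a droplet-by-locus state matrix.

    Returns an ``int8`` matrix over {WT, HET, HOM, MISSING}: wt below
    ``vaf_low``, hom above ``vaf_high``, het in between; entries with
    ``total < min_depth`` (including zero coverage) are MISSING.
    """
    total = counts.total
    alt = counts.alt
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
    states = np.full(total.shape, HET, dtype=np.int8)
    states[vaf < cfg.vaf_low] = WT
    states[vaf > cfg.vaf_high] = HOM
    states[(total < cfg.min_depth) | (total == 0)] = MISSING
    return states


def estimate_locus_priors(
    states: np.ndarray,
    cfg: EstimationConfig,
    locus_ids: Sequence,
    beta: float = 0.0,
) -> LocusPriors:
    """Smoothed per-locus genotype frequencies from a crude state matrix.

    With a non-zero ADO rate ``beta`` the crude states are a biased view of
    the genotypes: a heterozygous droplet-locus loses one of its two allele
    copies (conditional on reads being produced) with probability
    ``a = beta / (1 + beta)`` per allele, after which it reads as wt or hom.
    Leaving that phantom wt/hom mass in ``mu`` would let the classifier
    count dropout twice — once in the priors and once in the dropout
    transition — so the observed state frequencies ``q`` are deconvolved
    through the known confusion ``q_het = (1 - 2a) mu_het``,
    ``q_wt = mu_wt + a mu_het``, ``q_hom = mu_hom + a mu_het`` (negative
    solutions are floored and the triple renormalised).

    Loci where every droplet is MISSING fall back to the uniform triple.
    """
    if not 0.0 <= beta < 1.0:
        raise ValueError("beta must be in [0, 1)")
    m = states.shape[1]
    counts = np.empty((m, 3), dtype=float)
    for k, state in enumerate((WT, HET, HOM)):
        counts[:, k] = (states == state).sum(axis=0)
    counts += cfg.pseudocount
    if cfg.pseudocount == 0:
        empty = counts.sum(axis=1) == 0
        counts[empty] = 1.0
    q = counts / counts.sum(axis=1, keepdims=True)
    if beta > 0.0:
        a = beta / (1.0 + beta)
        mu_het = q[:, 1] / (1.0 - 2.0 * a)
        mu_wt = np.maximum(q[:, 0] - a * mu_het, MU_FLOOR)
        mu_hom = np.maximum(q[:, 2] - a * mu_het, MU_FLOOR)
        q = np.stack([mu_wt, mu_het, mu_hom], axis=1)
        q /= q.sum(axis=1, keepdims=True)
    return LocusPriors(locus_ids=np.asarray(locus_ids), mu=q)


def estimate_overdispersion(
    counts: ReadCounts, states: np.ndarray, cfg: EstimationConfig
) -> Tuple[float, float, float]:
    """Estimate ``(alpha_fp, alpha_fn, s)`` from crudely genotyped entries.

    ``alpha_fp`` is the pooled variant-read fraction over wt entries and
    ``alpha_fn`` the pooled reference-read fraction over hom entries.  The
    precision ``s`` solves the beta-binomial variance identity on het
    entries; with no het entries it falls back to ``cfg.s_default``.
    """

    def _pooled_rate(mask: np.ndarray, numer: np.ndarray) -> float:
        tot = counts.total[mask].sum()
        if tot == 0:
            return cfg.alpha_floor
        rate = numer[mask].sum() / tot
        return float(min(max(rate, cfg.alpha_floor), cfg.alpha_ceil))

    alpha_fp = _pooled_rate(states == WT, counts.alt)
    alpha_fn = _pooled_rate(states == HOM, counts.total - counts.alt)

    het = states == HET
    if not het.any():
        logger.warning(
            "no heterozygous entries for precision fitting; "
            "falling back to s=%.3g", cfg.s_default,
        )
        return alpha_fp, alpha_fn, float(cfg.s_default)

    v = counts.alt[het].astype(float)
    c = counts.total[het].astype(float)
    p = amplification_prob(0.5, alpha_fp, alpha_fn)
    base = c * p * (1.0 - p)
    # sum of squared residuals vs sum of binomial variances; the excess is
    # rho * sum(c p (1-p) (c-1)) with rho = 1 / (s + 1)
    excess = ((v - c * p) ** 2 - base).sum()
    scale = (base * (c - 1.0)).sum()
    if scale <= 0.0 or excess <= 0.0:
        s = cfg.s_max
    else:
        rho = excess / scale
        s = 1.0 / rho - 1.0
    s = float(min(max(s, cfg.s_min), cfg.s_max))
    return alpha_fp, alpha_fn, s


def estimate_delta(
    counts: ReadCounts,
    priors: LocusPriors,
    err: ErrorModel,
    grid: Optional[Sequence[float]] = None,
    *,
    result: Optional[LikelihoodResult] = None,
) -> float:
    """Doublet prior maximising the marginal likelihood over a grid.

    The droplet states are latent, so the likelihood of ``delta`` sums
    over both states per droplet:
    ``sum_i log((1 - delta) + delta * exp(sum_j Omega_ij))`` (the singlet
    likelihood factors out and does not depend on ``delta``).  Maximising
    over the latent assignment instead of summing is known to overestimate
    mixture weights when the two hypotheses overlap, which is exactly the
    high-dropout regime.  Ties break toward the smaller candidate.
    """
    if grid is None:
        grid = _default_delta_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("delta grid must be non-empty")
    if result is None:
        result = omega_matrix(counts, priors, err)
    rows = result.row_omega()
    best_delta, best_obj = None, -np.inf
    for delta in grid:
        obj = np.logaddexp(
            math.log(1.0 - delta), math.log(delta) + rows
        ).sum()
        if obj > best_obj:
            best_delta, best_obj = float(delta), obj
    return best_delta


def estimate_parameters(
    counts: ReadCounts,
    beta: float,
    cfg: Optional[EstimationConfig] = None,
    *,
    delta: Optional[float] = None,
    n_refinements: int = 1,
) -> Tuple[LocusPriors, ErrorModel]:
    """Full estimation pipeline: priors, overdispersion, then delta.

    The ADO rate ``beta`` is an assay property that the count matrices do
    not identify well on their own, so it is taken as input (typically an
    externally calibrated platform value).  If ``delta`` is given it is
    used as-is; otherwise it is grid-estimated by marginal likelihood.

    Doublets contaminate the estimation sample — most visibly they inflate
    the apparent heterozygous overdispersion and blur the genotype priors
    at exactly the loci that discriminate doublets — so after a first pass
    the droplets called doublets are set aside and priors, copy-error
    rates, precision and ``delta`` are re-estimated from the putative
    singlets (``n_refinements`` extra passes; the default single pass is
    enough, further passes change almost nothing).
    """
    from .model import classify  # deferred import: model is the heavy half

    cfg = cfg or EstimationConfig()
    current = counts
    for iteration in range(n_refinements + 1):
        states = assign_crude_genotypes(current, cfg)
        priors = estimate_locus_priors(states, cfg, counts.locus_ids, beta=beta)
        alpha_fp, alpha_fn, s = estimate_overdispersion(current, states, cfg)
        err = ErrorModel(beta=beta, alpha_fp=alpha_fp, alpha_fn=alpha_fn, s=s)
        result = omega_matrix(counts, priors, err)
        if delta is None:
            delta_used = estimate_delta(
                counts, priors, err, cfg.delta_grid, result=result
            )
        else:
            delta_used = delta
        if iteration == n_refinements:
            break
        calls = classify(result, delta_used)
        keep = np.fromiter((not c.z for c in calls), dtype=bool, count=len(calls))
        if keep.sum() < max(10, 0.2 * counts.n):  # degenerate first pass
            logger.warning(
                "refinement skipped: only %d droplets called singlet", keep.sum()
            )
            break
        current = ReadCounts(
            droplet_ids=counts.droplet_ids[keep],
            locus_ids=counts.locus_ids,
            total=counts.total[keep],
            alt=counts.alt[keep],
        )
    if delta is None:
        logger.info("grid-estimated doublet prior delta=%.3g", delta_used)
    err = ErrorModel(
        beta=beta, alpha_fp=alpha_fp, alpha_fn=alpha_fn, s=s, delta=delta_used
    )
    return priors, err
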