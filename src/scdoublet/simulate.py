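"""Truth-labelled simulator of scDNA-seq droplet read counts.

Emulates a tumour sequencing run end to end: a random clonal tree over a
handful of genotypes, SNVs placed on tree edges (infinite sites), optional
copy-number aberrations (losses, possibly causing LOH, or gains), Poisson
cell capture into droplets (each droplet a doublet with probability
``delta``), per-copy allelic dropout, and beta-binomial read generation
with copy errors and allelic imbalance.

Every droplet carries ground-truth labels — its constituent clone(s),
doublet status and doublet taxonomy (selflet / nested / neotypic) — which
the evaluation module scores calls against.  A single seeded generator is
threaded through panel, droplet and read simulation so a fixed seed fixes
every output bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .estimation import HET, HOM, WT
from .model import ErrorModel, LocusPriors, ReadCounts, amplification_prob

__all__ = [
    "SimConfig",
    "ClonePanel",
    "SimTruth",
    "simulate_clone_panel",
    "simulate_droplets",
    "simulate_reads",
    "simulate_dataset",
    "simulate_from_model",
    "classify_doublet_type",
    "genotypes_from_copies",
    "panel_locus_priors",
    "beta_binomial_reads",
    "SELFLET",
    "NESTED",
    "NEOTYPIC",
    "NOT_DOUBLET",
]

SELFLET = "selflet"
NESTED = "nested"
NEOTYPIC = "neotypic"
NOT_DOUBLET = "n/a"


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters of one simulated experiment.

    Defaults mirror the benchmark study conditions: 10 clonal genotypes,
    500 droplets, doublet probability 0.2, mean coverage 50x, ADO rate
    0.05 and beta-binomial precision 15.  Copy-error rates default to the
    per-base sequencing/amplification substitution scale (1e-3); the much
    larger values fitted on real targeted panels conflate residual
    alignment artefacts with copy errors and would dominate the VAF signal
    at wild-type loci.  ``gamma`` is
    the per-locus probability of a copy-number aberration and
    ``loss_prob`` the chance that an aberration is a loss rather than a
    gain.
    """

    n_clones: int = 10
    m: int = 100
    n_droplets: int = 500
    delta: float = 0.2
    coverage: float = 50.0
    beta: float = 0.05
    s: float = 15.0
    alpha_fp: float = 0.001
    alpha_fn: float = 0.001
    gamma: float = 0.0
    loss_prob: float = 0.5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("need at least one clone")
        if self.m < 1 or self.n_droplets < 1:
            raise ValueError("m and n_droplets must be positive")
        for name in ("delta", "beta", "gamma", "loss_prob"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.coverage <= 0 or self.s <= 0:
            raise ValueError("coverage and s must be positive")
        if not 0.0 <= self.alpha_fp < 1.0 or not 0.0 <= self.alpha_fn < 1.0:
            raise ValueError("copy-error rates must be in [0, 1)")


@dataclass(frozen=True)
class ClonePanel:
    """Clonal genotypes with per-locus allele copy numbers.

    ``ref_copies`` and ``var_copies`` are ``(n_clones, m)`` integer
    matrices; without CNAs every locus is diploid (2 reference copies at
    wt, 1+1 at het).  ``snv_clone`` records the tree edge (child clone)
    each SNV was placed on, and ``parents`` the tree topology
    (``parents[0] = -1`` for the root).
    """

    parents: np.ndarray
    ref_copies: np.ndarray
    var_copies: np.ndarray
    frequencies: np.ndarray
    snv_clone: np.ndarray
    locus_ids: np.ndarray

    def __post_init__(self) -> None:
        if not np.isclose(self.frequencies.sum(), 1.0):
            raise ValueError("clone frequencies must sum to 1")
        if (self.ref_copies < 0).any() or (self.var_copies < 0).any():
            raise ValueError("copy numbers must be non-negative")

    @property
    def n_clones(self) -> int:
        return len(self.parents)

    @property
    def genotypes(self) -> np.ndarray:
        return genotypes_from_copies(self.ref_copies, self.var_copies)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in range(self.n_clones):
            rows.append(
                {
                    "clone": k,
                    "parent": int(self.parents[k]),
                    "frequency": float(self.frequencies[k]),
                    **{
                        f"{locus}": f"{self.ref_copies[k, j]}|{self.var_copies[k, j]}"
                        for j, locus in enumerate(self.locus_ids)
                    },
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth labels of simulated droplets."""

    droplet_ids: np.ndarray
    clone1: np.ndarray
    clone2: np.ndarray  # -1 for singlets
    is_doublet: np.ndarray
    doublet_type: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "droplet_id": self.droplet_ids,
                "clone1": self.clone1,
                "clone2": self.clone2,
                "is_doublet": self.is_doublet.astype(int),
                "doublet_type": self.doublet_type,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SimTruth":
        return cls(
            droplet_ids=df["droplet_id"].to_numpy(),
            clone1=df["clone1"].to_numpy(dtype=int),
            clone2=df["clone2"].to_numpy(dtype=int),
            is_doublet=df["is_doublet"].to_numpy(dtype=bool),
            doublet_type=df["doublet_type"].to_numpy(dtype=object),
        )


def genotypes_from_copies(ref_copies: np.ndarray, var_copies: np.ndarray) -> np.ndarray:
    """SNV genotype codes implied by allele copy numbers.

    wt when no variant copy survives (including full deletion), hom when
    variant copies exist without reference copies, het otherwise.
    """
    geno = np.full(ref_copies.shape, WT, dtype=np.int8)
    geno[(var_copies > 0) & (ref_copies > 0)] = HET
    geno[(var_copies > 0) & (ref_copies == 0)] = HOM
    return geno


def _subtree_members(parents: np.ndarray, root: int) -> np.ndarray:
    """Indices of the clade rooted at ``root`` (inclusive)."""
    n = len(parents)
    children: List[List[int]] = [[] for _ in range(n)]
    for k in range(1, n):
        children[parents[k]].append(k)
    out, stack = [], [root]
    while stack:
        k = stack.pop()
        out.append(k)
        stack.extend(children[k])
    return np.asarray(sorted(out))


def simulate_clone_panel(cfg: SimConfig, rng: np.random.Generator) -> ClonePanel:
    """Random clonal tree with SNVs on edges and optional CNAs.

    The tree grows by random attachment (clone ``k`` picks a uniform parent
    among clones ``0..k-1``).  Each SNV is a heterozygous single-copy gain
    on a uniformly random edge, shared by the whole clade below it
    (infinite sites for SNVs).  With probability ``gamma`` a locus also
    receives a CNA on a random edge: with probability ``loss_prob`` one
    copy of a randomly chosen allele is lost throughout the clade
    (possibly causing LOH), otherwise that allele gains a copy.  Clone
    frequencies are Dirichlet(1).
    """
    K, m = cfg.n_clones, cfg.m
    parents = np.full(K, -1, dtype=int)
    for k in range(1, K):
        parents[k] = rng.integers(0, k)
    ref = np.full((K, m), 2, dtype=int)
    var = np.zeros((K, m), dtype=int)
    snv_clone = np.full(m, -1, dtype=int)
    if K > 1:
        snv_clone = rng.integers(1, K, size=m)
        for j in range(m):
            clade = _subtree_members(parents, snv_clone[j])
            ref[clade, j] -= 1
            var[clade, j] += 1
        cna_mask = rng.random(m) < cfg.gamma
        for j in np.nonzero(cna_mask)[0]:
            e = int(rng.integers(1, K))
            clade = _subtree_members(parents, e)
            total = ref[e, j] + var[e, j]
            if total == 0:
                continue
            affect_var = rng.random() < var[e, j] / total
            arr = var if affect_var else ref
            step = -1 if rng.random() < cfg.loss_prob else 1
            hit = clade[arr[clade, j] > 0]
            arr[hit, j] += step
    frequencies = rng.dirichlet(np.ones(K))
    locus_ids = np.array([f"L{j:03d}" for j in range(m)], dtype=object)
    return ClonePanel(
        parents=parents,
        ref_copies=ref,
        var_copies=var,
        frequencies=frequencies,
        snv_clone=snv_clone,
        locus_ids=locus_ids,
    )


def classify_doublet_type(g1: np.ndarray, g2: np.ndarray) -> str:
    """Doublet taxonomy from the two constituent genotype vectors.

    Selflet when the genotypes are identical; nested when the mutated-locus
    set (genotype != wt) of one cell is a proper subset of the other's;
    neotypic otherwise (a genotype combination absent from the sample).
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors must have equal length")
    if np.array_equal(g1, g2):
        return SELFLET
    a = g1 != WT
    b = g2 != WT
    if np.array_equal(a, b):
        return NEOTYPIC  # same mutated loci but different zygosity
    if not (a & ~b).any() or not (b & ~a).any():
        return NESTED
    return NEOTYPIC


def simulate_droplets(
    panel: ClonePanel, cfg: SimConfig, rng: np.random.Generator
) -> Tuple[SimTruth, np.ndarray, np.ndarray]:
    """Assemble droplets: doublet coin flips, clone draws, combined copies.

    Returns the truth labels plus the per-droplet reference and variant
    copy-number matrices (sums over the constituent cells for doublets).
    """
    n = cfg.n_droplets
    K = panel.n_clones
    is_doublet = rng.random(n) < cfg.delta
    clone1 = rng.choice(K, size=n, p=panel.frequencies)
    clone2 = np.where(
        is_doublet, rng.choice(K, size=n, p=panel.frequencies), -1
    )
    ref = panel.ref_copies[clone1].copy()
    var = panel.var_copies[clone1].copy()
    geno = panel.genotypes
    dtype_labels = np.full(n, NOT_DOUBLET, dtype=object)
    for i in np.nonzero(is_doublet)[0]:
        ref[i] += panel.ref_copies[clone2[i]]
        var[i] += panel.var_copies[clone2[i]]
        dtype_labels[i] = classify_doublet_type(geno[clone1[i]], geno[clone2[i]])
    truth = SimTruth(
        droplet_ids=np.array([f"d{i:04d}" for i in range(n)], dtype=object),
        clone1=clone1,
        clone2=clone2,
        is_doublet=is_doublet,
        doublet_type=dtype_labels,
    )
    return truth, ref, var


def beta_binomial_reads(
    c: np.ndarray, p: np.ndarray, s: float, rng: np.random.Generator
) -> np.ndarray:
    """Variant read counts ``v ~ BetaBinomial(c, p, s)`` element-wise.

    Draws the per-entry amplification success ``pi ~ Beta(p s, (1-p) s)``
    and then ``v ~ Binomial(c, pi)``; degenerate means 0 and 1 short-cut to
    constant draws.
    """
    c = np.asarray(c)
    p = np.broadcast_to(np.asarray(p, dtype=float), c.shape)
    interior = (p > 0.0) & (p < 1.0)
    pi = np.where(p >= 1.0, 1.0, 0.0)
    if interior.any():
        a = np.clip(p[interior] * s, 1e-12, None)
        b = np.clip((1.0 - p[interior]) * s, 1e-12, None)
        draw = rng.beta(a, b)
        pi = pi.copy()
        pi[interior] = draw
    return rng.binomial(c, pi)


def simulate_reads(
    ref_copies: np.ndarray,
    var_copies: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> ReadCounts:
    """Generate read counts from per-droplet allele copy numbers.

    Each allele copy survives dropout independently with probability
    ``1 - beta``.  Total depth scales with the surviving DNA content:
    ``c ~ Poisson(coverage * k / 2)`` for ``k`` retained copies, so an
    intact diploid singlet averages ``coverage`` and an intact doublet
    twice that; a fully dropped-out locus yields no reads.  Variant reads
    then follow the copy-error + beta-binomial read model.
    """
    kept_var = rng.binomial(var_copies, 1.0 - cfg.beta)
    kept_ref = rng.binomial(ref_copies, 1.0 - cfg.beta)
    k = kept_var + kept_ref
    total = rng.poisson(cfg.coverage * k / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(k > 0, kept_var / np.maximum(k, 1), 0.0)
    p = amplification_prob(y, cfg.alpha_fp, cfg.alpha_fn)
    alt = beta_binomial_reads(total, p, cfg.s, rng)
    alt[k == 0] = 0
    n, m = total.shape
    return ReadCounts(
        droplet_ids=np.array([f"d{i:04d}" for i in range(n)], dtype=object),
        locus_ids=np.array([f"L{j:03d}" for j in range(m)], dtype=object),
        total=total,
        alt=alt,
    )


def simulate_dataset(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[ReadCounts, SimTruth, ClonePanel]:
    """End-to-end simulation: clone panel -> droplets -> read counts."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    panel = simulate_clone_panel(cfg, rng)
    truth, ref, var = simulate_droplets(panel, cfg, rng)
    counts = simulate_reads(ref, var, cfg, rng)
    return counts, truth, panel


def panel_locus_priors(panel: ClonePanel) -> LocusPriors:
    """Frequency-weighted genotype priors implied by a clone panel.

    The "oracle" priors a clairvoyant caller would use: for each locus the
    clone frequencies are summed within each genotype state.
    """
    geno = panel.genotypes
    m = geno.shape[1]
    mu = np.zeros((m, 3))
    for k, state in enumerate((WT, HET, HOM)):
        mu[:, k] = (panel.frequencies[:, None] * (geno == state)).sum(axis=0)
    mu /= mu.sum(axis=1, keepdims=True)
    return LocusPriors(locus_ids=panel.locus_ids, mu=mu)


def simulate_from_model(
    n: int,
    m: int,
    priors: LocusPriors,
    err: ErrorModel,
    coverage: float,
    delta: float,
    rng: np.random.Generator,
) -> Tuple[ReadCounts, np.ndarray]:
    """Sample read counts directly from the inference model's own chain.

    Unlike :func:`simulate_dataset` there is no clonal structure: each
    droplet-locus genotype is drawn i.i.d. from ``priors`` (two independent
    draws for doublets), exactly matching the classifier's generative
    assumptions.  Useful for parameter-recovery and calibration checks.
    Returns the counts and the boolean doublet indicator.
    """
    if err.delta is not None and err.delta != delta:
        raise ValueError("delta argument conflicts with err.delta")
    is_doublet = rng.random(n) < delta
    mu = priors.mu  # (m, 3)
    var = np.zeros((n, m), dtype=int)
    cum = np.cumsum(mu, axis=1)  # per-locus genotype CDF
    for draw in range(2):
        active = is_doublet if draw == 1 else np.ones(n, dtype=bool)
        u = rng.random((n, m))
        geno_copies = (u[:, :] >= cum[None, :, 0]).astype(int) + (
            u[:, :] >= cum[None, :, 1]
        ).astype(int)  # 0, 1 or 2 variant copies per cell
        var[active] += geno_copies[active]
    cells = 1 + is_doublet.astype(int)
    ref = 2 * cells[:, None] - var
    cfg = SimConfig(
        n_clones=1,
        m=m,
        n_droplets=n,
        delta=delta,
        coverage=coverage,
        beta=err.beta,
        s=err.s,
        alpha_fp=err.alpha_fp,
        alpha_fn=err.alpha_fn,
    )
    counts = simulate_reads(ref, var, cfg, rng)
    counts = ReadCounts(
        droplet_ids=counts.droplet_ids,
        locus_ids=np.asarray(priors.locus_ids),
        total=counts.total,
        alt=counts.alt,
    )
    return counts, is_doublet
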