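"""Probabilistic model for doublet detection in scDNA-seq read counts.

A droplet captured in a single-cell DNA sequencing experiment holds either
one cell (a *singlet*) or two (a *doublet*).  Each cell is assumed diploid
at every mutation locus, so the true variant allele frequency (VAF) of a
singlet at a locus lies on ``{0, 1/2, 1}`` and that of a doublet on
``{0, 1/4, 1/2, 3/4, 1}``.  Three error processes then distort what is
observed:

* **allelic dropout (ADO)** — each allele copy independently fails to
  amplify with probability ``beta``, shifting the VAF onto a wider support
  (e.g. ``1/3`` and ``2/3`` become reachable for doublets);
* **copy errors** — a polymerase copies a reference template as variant
  with probability ``alpha_fp`` and vice versa with ``alpha_fn``;
* **allelic imbalance** — uneven amplification modelled by a beta-binomial
  read-count distribution with precision ``s`` (small ``s`` = heavy
  overdispersion).

Marginalising the latent pre- and post-dropout VAFs gives the likelihood
of the observed (variant, total) read counts of a droplet-locus under both
the singlet and the doublet hypothesis.  The per-entry log-likelihood
ratios form a matrix ``Omega``; because droplets are independent, summing
each row and adding the log odds of the doublet prior ``delta`` yields the
exact maximum a posteriori call in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from scipy.stats import betabinom, poisson

__all__ = [
    "SIGMA_SINGLET",
    "SIGMA_DOUBLET",
    "THETA_SINGLET",
    "THETA_DOUBLET",
    "ReadCounts",
    "LocusPriors",
    "ErrorModel",
    "LikelihoodResult",
    "DropletCall",
    "doublet_prior_from_rate",
    "singlet_vaf_prior",
    "doublet_vaf_prior",
    "ado_transition",
    "amplification_prob",
    "beta_binomial_loglik",
    "droplet_locus_loglik",
    "omega_matrix",
    "classify",
    "posterior_doublet_prob",
    "log_posterior_objective",
]

#: pre-dropout VAF support of a singlet (wt, het, hom genotype)
SIGMA_SINGLET: tuple = (0.0, 0.5, 1.0)
#: pre-dropout VAF support of a doublet (sum of two diploid genotypes)
SIGMA_DOUBLET: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
#: post-dropout VAF support of a singlet
THETA_SINGLET: tuple = (0.0, 0.5, 1.0)
#: post-dropout VAF support of a doublet
THETA_DOUBLET: tuple = (0.0, 0.25, 1.0 / 3.0, 0.5, 2.0 / 3.0, 0.75, 1.0)

# copy-error rates are floored and the beta-binomial mean clamped so that a
# single stray read at a wt/hom locus can never contribute -inf
ALPHA_FLOOR = 1e-6
P_EPS = 1e-9


def _clamp_p(p: float) -> float:
    return min(max(p, P_EPS), 1.0 - P_EPS)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadCounts:
    """Paired droplet-by-locus matrices of variant and total read counts.

    The two matrices share row (droplet) and column (locus) labels; cells
    are non-negative integers with ``alt <= total`` everywhere.
    """

    droplet_ids: np.ndarray
    locus_ids: np.ndarray
    total: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        droplet_ids = np.asarray(self.droplet_ids)
        locus_ids = np.asarray(self.locus_ids)
        total = np.asarray(self.total, dtype=np.int64)
        alt = np.asarray(self.alt, dtype=np.int64)
        object.__setattr__(self, "droplet_ids", droplet_ids)
        object.__setattr__(self, "locus_ids", locus_ids)
        object.__setattr__(self, "total", total)
        object.__setattr__(self, "alt", alt)
        if total.shape != alt.shape:
            raise ValueError(
                f"alt shape {alt.shape} != total shape {total.shape}"
            )
        if total.shape != (len(droplet_ids), len(locus_ids)):
            raise ValueError("matrix shape does not match label counts")
        if len(set(map(str, droplet_ids))) != len(droplet_ids):
            raise ValueError("duplicate droplet identifiers")
        if len(set(map(str, locus_ids))) != len(locus_ids):
            raise ValueError("duplicate locus identifiers")
        if (total < 0).any() or (alt < 0).any():
            raise ValueError("read counts must be non-negative")
        bad = alt > total
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "alt > total at droplet "
                f"{droplet_ids[i]!r}, locus {locus_ids[j]!r}"
            )

    @property
    def n(self) -> int:
        return len(self.droplet_ids)

    @property
    def m(self) -> int:
        return len(self.locus_ids)

    @classmethod
    def from_frames(cls, alt: pd.DataFrame, total: pd.DataFrame) -> "ReadCounts":
        """Build from two labelled DataFrames, aligning rows/columns by label.

        Raises ``ValueError`` if the label sets differ.
        """
        if set(alt.index) != set(total.index):
            raise ValueError("droplet label sets of alt and total differ")
        if set(alt.columns) != set(total.columns):
            raise ValueError("locus label sets of alt and total differ")
        total = total.loc[alt.index, alt.columns]
        return cls(
            droplet_ids=alt.index.to_numpy(),
            locus_ids=alt.columns.to_numpy(),
            total=total.to_numpy(),
            alt=alt.to_numpy(),
        )

    def to_frames(self) -> tuple:
        alt = pd.DataFrame(self.alt, index=self.droplet_ids, columns=self.locus_ids)
        total = pd.DataFrame(self.total, index=self.droplet_ids, columns=self.locus_ids)
        return alt, total


@dataclass(frozen=True)
class LocusPriors:
    """Per-locus genotype probabilities ``(mu_wt, mu_het, mu_hom)``.

    ``mu`` is an ``m x 3`` matrix whose rows sum to one; column order is
    wild-type, heterozygous, homozygous-variant.
    """

    locus_ids: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        locus_ids = np.asarray(self.locus_ids)
        mu = np.asarray(self.mu, dtype=float)
        object.__setattr__(self, "locus_ids", locus_ids)
        object.__setattr__(self, "mu", mu)
        if mu.ndim != 2 or mu.shape != (len(locus_ids), 3):
            raise ValueError("mu must be an (m, 3) matrix matching locus_ids")
        if (mu < 0).any():
            raise ValueError("genotype probabilities must be non-negative")
        if not np.allclose(mu.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("genotype probabilities must sum to 1 per locus")

    @classmethod
    def global_triple(
        cls, triple: Sequence[float], locus_ids: Sequence
    ) -> "LocusPriors":
        """Broadcast one ``(mu_wt, mu_het, mu_hom)`` triple to every locus."""
        locus_ids = np.asarray(locus_ids)
        mu = np.tile(np.asarray(triple, dtype=float), (len(locus_ids), 1))
        return cls(locus_ids=locus_ids, mu=mu)

    def _index_of(self, locus) -> int:
        idx = np.nonzero(self.locus_ids == locus)[0]
        if len(idx) == 0:
            raise KeyError(f"unknown locus {locus!r}")
        return int(idx[0])

    def for_locus(self, locus) -> tuple:
        """``(mu_wt, mu_het, mu_hom)`` of one locus; KeyError if unknown."""
        i = self._index_of(locus)
        return tuple(self.mu[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.mu, index=self.locus_ids, columns=["mu_wt", "mu_het", "mu_hom"]
        )


@dataclass(frozen=True)
class ErrorModel:
    """Global nuisance parameters of the read-count model.

    Parameters
    ----------
    beta:
        Allelic dropout rate per allele copy, in ``[0, 1)``.
    alpha_fp, alpha_fn:
        Amplification copy-error rates (reference copied as variant and
        variant copied as reference), each in ``[0, 1)`` with
        ``alpha_fp + alpha_fn < 1``.
    s:
        Beta-binomial precision (> 0); low values mean strong allelic
        imbalance.
    delta:
        Prior probability that a droplet is a doublet, in ``(0, 1)``.
        May be left unset (``None``) while it is being estimated.
    """

    beta: float
    alpha_fp: float
    alpha_fn: float
    s: float
    delta: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta < 1.0:
            raise ValueError("beta must be in [0, 1)")
        if not 0.0 <= self.alpha_fp < 1.0:
            raise ValueError("alpha_fp must be in [0, 1)")
        if not 0.0 <= self.alpha_fn < 1.0:
            raise ValueError("alpha_fn must be in [0, 1)")
        if self.alpha_fp + self.alpha_fn >= 1.0:
            raise ValueError("alpha_fp + alpha_fn must be < 1")
        if not self.s > 0.0:
            raise ValueError("precision s must be positive")
        if self.delta is not None and not 0.0 < self.delta < 1.0:
            raise ValueError("delta must be in (0, 1)")


@dataclass(frozen=True)
class LikelihoodResult:
    """Per droplet-locus log-likelihoods under both droplet states.

    ``omega = log_lik_doublet - log_lik_singlet`` element-wise; entries with
    zero total coverage are treated as missing and contribute 0.
    """

    droplet_ids: np.ndarray
    locus_ids: np.ndarray
    log_lik_singlet: np.ndarray
    log_lik_doublet: np.ndarray

    @property
    def omega(self) -> np.ndarray:
        return self.log_lik_doublet - self.log_lik_singlet

    def row_omega(self) -> np.ndarray:
        """Per-droplet sums over loci of the log-likelihood ratios."""
        return self.omega.sum(axis=1)

    def scores(self, delta: float) -> np.ndarray:
        """Per-droplet decision scores at doublet prior ``delta``."""
        if not 0.0 < delta < 1.0:
            raise ValueError("delta must be in (0, 1)")
        return self.row_omega() + math.log(delta / (1.0 - delta))


@dataclass(frozen=True)
class DropletCall:
    """Doublet call for one droplet.

    ``score`` is the sum of log-likelihood ratios plus log-odds of the
    doublet prior; ``z = 1`` iff ``score > 0``; ``posterior`` is the
    logistic transform of the score.
    """

    droplet_id: object
    z: int
    score: float
    posterior: float

    @property
    def label(self) -> str:
        return "doublet" if self.z else "singlet"


# ---------------------------------------------------------------------------
# priors and latent-variable transitions
# ---------------------------------------------------------------------------


def doublet_prior_from_rate(lam: float) -> float:
    """Doublet prior delta implied by Poisson cell capture at rate ``lam``.

    Droplets capture ``k ~ Poisson(lam)`` cells; only non-empty droplets
    are sequenced and multiplets beyond two cells are neglected, so
    ``delta = Pois(2; lam) / (Pois(1; lam) + Pois(2; lam))``.
    """
    if not lam > 0:
        raise ValueError("capture rate must be positive")
    p1 = poisson.pmf(1, lam)
    p2 = poisson.pmf(2, lam)
    return float(p2 / (p1 + p2))


def singlet_vaf_prior(priors: LocusPriors, locus) -> Dict[float, float]:
    """Categorical prior over the singlet VAF support at one locus."""
    mu_wt, mu_het, mu_hom = priors.for_locus(locus)
    return {0.0: float(mu_wt), 0.5: float(mu_het), 1.0: float(mu_hom)}


def doublet_vaf_prior(priors: LocusPriors, locus) -> Dict[float, float]:
    """Categorical prior over the doublet VAF support at one locus.

    A doublet holds two cells with independent genotypes, so the doublet
    VAF ``f`` aggregates all ordered singlet pairs ``(g, h)`` with
    ``(g + h) / 2 = f``; e.g. ``f = 1/2`` arises from (het, het),
    (hom, wt) and (wt, hom).
    """
    single = singlet_vaf_prior(priors, locus)
    out = {f: 0.0 for f in SIGMA_DOUBLET}
    for g, pg in single.items():
        for h, ph in single.items():
            out[(g + h) / 2.0] += pg * ph
    return out


def _snap(value: float, grid: Sequence[float]) -> float:
    for g in grid:
        if abs(value - g) < 1e-9:
            return g
    raise AssertionError(f"VAF {value} not on support {grid}")


def ado_transition(x: float, z: int, beta: float) -> Dict[float, float]:
    """Distribution of the post-dropout VAF ``y`` given pre-dropout VAF ``x``.

    A droplet in state ``z`` carries ``2z + 2`` allele copies, of which
    ``x * (2z + 2)`` are variant.  Each copy is retained independently with
    probability ``1 - beta``; conditioning on at least one retained copy
    (otherwise no reads are produced), ``y`` is the variant fraction of the
    retained copies.
    """
    if z not in (0, 1):
        raise ValueError("z must be 0 or 1")
    if not 0.0 <= beta < 1.0:
        raise ValueError("beta must be in [0, 1)")
    sigma = SIGMA_DOUBLET if z else SIGMA_SINGLET
    theta = THETA_DOUBLET if z else THETA_SINGLET
    if not any(abs(x - v) < 1e-12 for v in sigma):
        raise ValueError(f"x={x} is not a legal pre-dropout VAF for z={z}")
    n_copies = 2 * z + 2
    n_var = int(round(x * n_copies))
    n_ref = n_copies - n_var
    if beta == 0.0:
        return {_snap(x, theta): 1.0}
    out: Dict[float, float] = {}
    keep = 1.0 - beta
    norm = 1.0 - beta**n_copies
    for kv in range(n_var + 1):
        for kr in range(n_ref + 1):
            if kv + kr == 0:
                continue
            prob = (
                math.comb(n_var, kv) * keep**kv * beta ** (n_var - kv)
                * math.comb(n_ref, kr) * keep**kr * beta ** (n_ref - kr)
            ) / norm
            y = _snap(kv / (kv + kr), theta)
            out[y] = out.get(y, 0.0) + prob
    return out


def amplification_prob(y: float, alpha_fp: float, alpha_fn: float) -> float:
    """Probability a produced copy carries the variant allele.

    Copy errors convert a reference template to variant with rate
    ``alpha_fp`` and a variant template to reference with rate
    ``alpha_fn``: ``p = alpha_fp + (1 - alpha_fp - alpha_fn) * y``.
    """
    return alpha_fp + (1.0 - alpha_fp - alpha_fn) * y


def beta_binomial_loglik(v: int, c: int, p: float, s: float) -> float:
    """Log pmf of ``v`` variant among ``c`` reads, beta-binomial(mean p, precision s).

    Uses the mean-precision parameterisation with shapes ``(p*s, (1-p)*s)``,
    evaluated through log-gamma functions so large counts do not overflow.
    """
    if not (0 <= v <= c):
        raise ValueError("require 0 <= v <= c")
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    if not s > 0.0:
        raise ValueError("precision s must be positive")
    return float(betabinom.logpmf(v, c, p * s, (1.0 - p) * s))


# ---------------------------------------------------------------------------
# marginal likelihoods and the closed-form classifier
# ---------------------------------------------------------------------------


def droplet_locus_loglik(
    v: int, c: int, z: int, priors: LocusPriors, locus, err: ErrorModel
) -> float:
    """Marginal log P(c, v | z) at one droplet-locus.

    Sums over the pre-dropout VAF ``x`` and post-dropout VAF ``y`` in log
    space.  Entries with no coverage carry no signal (the uninformative
    prior on total depth cancels in the likelihood ratio) and return 0.
    """
    if c == 0:
        return 0.0
    vaf_prior = doublet_vaf_prior(priors, locus) if z else singlet_vaf_prior(priors, locus)
    afp = max(err.alpha_fp, ALPHA_FLOOR)
    afn = max(err.alpha_fn, ALPHA_FLOOR)
    terms: List[float] = []
    for x, wx in vaf_prior.items():
        if wx <= 0.0:
            continue
        for y, wy in ado_transition(x, z, err.beta).items():
            if wy <= 0.0:
                continue
            p = _clamp_p(amplification_prob(y, afp, afn))
            terms.append(
                math.log(wx) + math.log(wy) + beta_binomial_loglik(v, c, p, err.s)
            )
    return float(logsumexp(terms))


def _doublet_vaf_prior_matrix(mu: np.ndarray) -> np.ndarray:
    """(5, m) doublet VAF prior over SIGMA_DOUBLET for every locus."""
    w, h, o = mu[:, 0], mu[:, 1], mu[:, 2]
    return np.stack([w * w, 2 * w * h, h * h + 2 * w * o, 2 * h * o, o * o])


def _marginal_loglik_matrix(
    counts: ReadCounts, priors: LocusPriors, err: ErrorModel, z: int
) -> np.ndarray:
    """Vectorised n x m matrix of log P(c, v | z)."""
    sigma = SIGMA_DOUBLET if z else SIGMA_SINGLET
    theta = THETA_DOUBLET if z else THETA_SINGLET
    if z:
        px = _doublet_vaf_prior_matrix(priors.mu)  # (5, m)
    else:
        px = priors.mu.T  # (3, m)
    # transition kernel P(y | x, z): (len(sigma), len(theta))
    trans = np.zeros((len(sigma), len(theta)))
    for a, x in enumerate(sigma):
        for y, wy in ado_transition(x, z, err.beta).items():
            b = theta.index(_snap(y, theta))
            trans[a, b] = wy
    weights = trans.T @ px  # (len(theta), m): P(y | z) per locus
    with np.errstate(divide="ignore"):
        logw = np.log(weights)
    afp = max(err.alpha_fp, ALPHA_FLOOR)
    afn = max(err.alpha_fn, ALPHA_FLOOR)
    parts = np.full((len(theta), counts.n, counts.m), -np.inf)
    for b, y in enumerate(theta):
        if not np.isfinite(logw[b]).any():
            continue
        p = _clamp_p(amplification_prob(y, afp, afn))
        ll = betabinom.logpmf(counts.alt, counts.total, p * err.s, (1.0 - p) * err.s)
        parts[b] = ll + logw[b][None, :]
    out = logsumexp(parts, axis=0)
    out[counts.total == 0] = 0.0
    return out


def omega_matrix(
    counts: ReadCounts, priors: LocusPriors, err: ErrorModel
) -> LikelihoodResult:
    """Log-likelihood ratio matrix of doublet vs singlet per droplet-locus."""
    if counts.m != len(priors.locus_ids) or not np.array_equal(
        np.asarray(counts.locus_ids, dtype=object),
        np.asarray(priors.locus_ids, dtype=object),
    ):
        raise ValueError("locus labels of counts and priors do not match")
    ll0 = _marginal_loglik_matrix(counts, priors, err, z=0)
    ll1 = _marginal_loglik_matrix(counts, priors, err, z=1)
    return LikelihoodResult(
        droplet_ids=counts.droplet_ids,
        locus_ids=counts.locus_ids,
        log_lik_singlet=ll0,
        log_lik_doublet=ll1,
    )


def posterior_doublet_prob(score) -> float:
    """Two-state posterior doublet probability from a decision score.

    ``logistic(score)``; numerically saturates cleanly for huge |score|.
    """
    return expit(score)


def classify(result: LikelihoodResult, delta: float) -> List[DropletCall]:
    """Closed-form maximum a posteriori doublet calls.

    A droplet is called a doublet iff the sum of its log-likelihood ratios
    plus ``log(delta / (1 - delta))`` is strictly positive; a score of
    exactly zero resolves to singlet.  Because droplets are independent the
    per-droplet rule maximises the joint posterior exactly.
    """
    scores = result.scores(delta)
    z = scores > 0.0
    post = posterior_doublet_prob(scores)
    return [
        DropletCall(droplet_id=d, z=int(zi), score=float(sc), posterior=float(pp))
        for d, zi, sc, pp in zip(result.droplet_ids, z, scores, post)
    ]


def log_posterior_objective(
    result: LikelihoodResult, z: Sequence[int], delta: float
) -> float:
    """Unnormalised log posterior of an assignment ``z`` (up to a constant).

    Used to verify that :func:`classify` attains the maximum over all
    ``2^n`` assignments.
    """
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must be in (0, 1)")
    z = np.asarray(z, dtype=bool)
    row0 = result.log_lik_singlet.sum(axis=1)
    row1 = result.log_lik_doublet.sum(axis=1)
    rows = np.where(z, row1, row0)
    prior = np.where(z, math.log(delta), math.log(1.0 - delta))
    return float(rows.sum() + prior.sum())
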