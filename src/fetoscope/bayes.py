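"""Per-locus Bayesian posterior over maternal x fetal genotype combinations.

At each biallelic locus the plasma is modelled as a two-genome mixture: a
fraction ``C`` (the fetal fraction, as a proportion) of reads come from the
fetal genotype F1F2 and ``1 - C`` from the maternal genotype M1M2. Under a
candidate combination the probability of drawing allele ``j`` from plasma
is

    P_j = B_jF / 2 * C + B_jM / 2 * (1 - C)

where ``B_jF`` and ``B_jM`` count allele ``j`` in the fetal and maternal
genotype respectively. The posterior over the enumerated combinations is
prior (Mendelian transmission from the called parental genotypes, with a
small genotyping-error mass ``eps``) times the likelihood of the observed
allele counts, normalised. The fetal call is the fetal genotype of the
maximum-posterior combination; its confidence is the summed posterior of
all combinations sharing that fetal genotype.

The fixed combination set has n = 10 entries: fetal pairs are ordered
(F1 = maternally transmitted, F2 = paternally transmitted), giving 8
Mendelian-consistent pairs, plus the two maternal-error pairs (AA, BB) and
(BB, AA) that receive prior mass only through ``eps``.

Two likelihoods are available. ``multinomial`` (default) scores the counts
under the per-read allele distribution, ``sum_j A_j log P'_j`` — the
product-form likelihood that actually discriminates genotypes. ``literal``
is the linear weighted mean ``sum_j P'_j A_j / sum_j A_j``; it is kept for
reference but, being a linear (improper) score, its argmax always favours
the combination concentrated on the plasma-majority allele and should not
be used for calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .core_model import FetalCall, Genotype, LocusRecord, PlasmaCounts

#: the enumerated maternal x fetal combination set; fetal pairs ordered
#: (maternal transmission, paternal transmission). The final two entries
#: are the Mendelian-inconsistent maternal-error pairs.
COMBOS: tuple[tuple[Genotype, Genotype], ...] = (
    ((0, 0), (0, 0)),
    ((0, 0), (0, 1)),
    ((0, 1), (0, 0)),
    ((0, 1), (0, 1)),
    ((0, 1), (1, 0)),
    ((0, 1), (1, 1)),
    ((1, 1), (1, 0)),
    ((1, 1), (1, 1)),
    ((0, 0), (1, 1)),
    ((1, 1), (0, 0)),
)

N_COMBOS = len(COMBOS)  # the model's n = 10

_GENOTYPES: tuple[Genotype, ...] = ((0, 0), (0, 1), (1, 1))


@dataclass(slots=True)
class PosteriorVector:
    """Prior, likelihood and posterior over the 10 combinations."""

    combos: tuple[tuple[Genotype, Genotype], ...]
    prior: np.ndarray
    likelihood: np.ndarray  # Pfinal: per-combo likelihood normalised to sum 1
    posterior: np.ndarray
    argmax: int

    @property
    def map_combo(self) -> tuple[Genotype, Genotype]:
        return self.combos[self.argmax]


def enumerate_combos() -> tuple[tuple[Genotype, Genotype], ...]:
    """The fixed, ordered 10-entry combination set (see module docstring)."""
    return COMBOS


def _gt_prior(called: Genotype, eps: float) -> dict[Genotype, float]:
    """Genotype-level error model: the called genotype keeps 1-eps mass."""
    called = tuple(sorted(called))  # type: ignore[assignment]
    return {g: (1.0 - eps) if g == called else eps / 2.0 for g in _GENOTYPES}


def _transmit_prob(allele: int, gt: Genotype, eps: float) -> float:
    """P(transmitted allele | parental genotype), with flip probability eps."""
    return sum(
        0.5 * ((1.0 - eps) if a == allele else eps) for a in gt
    )


def combo_prior(
    maternal_gt_called: Genotype, paternal_gt_called: Genotype, eps: float = 1e-3
) -> np.ndarray:
    """Prior over the 10 combinations from called parental genotypes.

    P(Ai) = P(maternal genotype | call; eps)
            x P(F1 | maternal genotype; transmission flip eps)
            x P(F2 | paternal call; genotype-level eps),
    renormalised over the enumerated set. With eps = 0 this is exact
    Mendelian transmission from the called genotypes.
    """
    if not (0.0 <= eps <= 0.1):
        raise ValueError("eps must lie in [0, 0.1]")
    m_prior = _gt_prior(maternal_gt_called, eps)
    p_prior = _gt_prior(paternal_gt_called, eps)
    # marginal paternal-transmission distribution
    f2_prob = {
        a: sum(p_prior[g] * (g.count(a) / 2.0) for g in _GENOTYPES) for a in (0, 1)
    }
    prior = np.array(
        [
            m_prior[m] * _transmit_prob(f[0], m, eps) * f2_prob[f[1]]
            for m, f in COMBOS
        ]
    )
    total = prior.sum()
    if total <= 0:
        raise ValueError("degenerate prior")
    return prior / total


def allele_probs(
    combo: tuple[Genotype, Genotype],
    C: float,
    err: float = 1e-3,
    smoothing: bool = True,
) -> np.ndarray:
    """Plasma allele distribution (ref, alt) under one combination.

    P_j = B_jF/2 * C + B_jM/2 * (1 - C), optionally passed through a
    symmetric read-error channel in which a read is recorded as each wrong
    allele with probability err/k (k = number of alternative alleles; 1 in
    the biallelic ref/alt bookkeeping used here).
    """
    if not (0.0 < C < 1.0):
        raise ValueError("fetal fraction C must lie in (0, 1)")
    if not (0.0 <= err < 0.05):
        raise ValueError("err must lie in [0, 0.05)")
    m, f = combo
    p = np.array(
        [f.count(j) / 2.0 * C + m.count(j) / 2.0 * (1.0 - C) for j in (0, 1)]
    )
    if smoothing and err > 0:
        p = p * (1.0 - err) + (1.0 - p) * err
    return p


def combo_likelihood(
    counts: PlasmaCounts, probs: np.ndarray, mode: str = "multinomial"
) -> float:
    """Score the observed counts under a combination's allele distribution.

    ``multinomial`` returns the log-likelihood sum_j A_j log P_j;
    ``literal`` returns the linear score sum_j P_j A_j / sum_j A_j.
    """
    if counts.depth == 0:
        raise ValueError("zero-depth locus cannot be scored")
    a = np.array([counts.ref_count, counts.alt_count], dtype=float)
    if mode == "literal":
        return float(np.dot(probs, a) / a.sum())
    if mode == "multinomial":
        with np.errstate(divide="ignore"):
            logp = np.log(probs)
        ll = float(np.dot(a, np.where(a > 0, logp, 0.0)))
        return ll
    raise ValueError(f"unknown likelihood mode {mode!r}")


@lru_cache(maxsize=256)
def _prob_matrix(C: float, err: float, smoothing: bool) -> tuple[np.ndarray, np.ndarray]:
    """Per-combo (10 x 2) allele-probability and log-probability matrices."""
    p = np.vstack([allele_probs(c, C, err, smoothing) for c in COMBOS])
    with np.errstate(divide="ignore"):
        logp = np.log(p)
    p.setflags(write=False)
    logp.setflags(write=False)
    return p, logp


@lru_cache(maxsize=64)
def _prior_cached(m_gt: Genotype, p_gt: Genotype, eps: float) -> np.ndarray:
    prior = combo_prior(m_gt, p_gt, eps)
    prior.setflags(write=False)
    return prior


def _mendel_consistent(
    combo: tuple[Genotype, Genotype], m_called: Genotype, p_called: Genotype
) -> bool:
    m, f = combo
    return (
        tuple(sorted(m)) == tuple(sorted(m_called))
        and f[0] in m_called
        and f[1] in p_called
    )


def posterior_call(
    locus: LocusRecord,
    counts: PlasmaCounts,
    C: float,
    eps: float = 1e-3,
    err: float = 1e-3,
    mode: str = "multinomial",
    smoothing: bool = True,
) -> tuple[FetalCall, PosteriorVector]:
    """Bayesian fetal-genotype call at one locus.

    posterior_i is proportional to prior_i x likelihood_i, normalised over
    the 10 combinations. The call is the fetal genotype of the argmax
    combination; its confidence is the summed posterior of combinations
    sharing that (unordered) fetal genotype. Ties prefer the combination
    consistent with the called parental genotypes, then the fetal genotype
    with fewer alt alleles. Zero-depth loci are returned unclassified with
    the prior as posterior.
    """
    prior = _prior_cached(locus.maternal_gt, locus.paternal_gt, eps)
    if counts.depth == 0:
        vec = PosteriorVector(
            combos=COMBOS,
            prior=prior,
            likelihood=np.full(N_COMBOS, 1.0 / N_COMBOS),
            posterior=prior.copy(),
            argmax=int(np.argmax(prior)),
        )
        return FetalCall(locus=locus, genotype=None, method="unclassified"), vec

    pmat, logpmat = _prob_matrix(C, err, smoothing)
    a = (float(counts.ref_count), float(counts.alt_count))
    if mode == "multinomial":
        scores = np.zeros(N_COMBOS)
        for j in (0, 1):
            if a[j] > 0:
                scores = scores + a[j] * logpmat[:, j]
        lik = np.exp(scores - scores.max())
    elif mode == "literal":
        lik = (pmat[:, 0] * a[0] + pmat[:, 1] * a[1]) / counts.depth
    else:
        raise ValueError(f"unknown likelihood mode {mode!r}")
    lik_sum = lik.sum()
    pfinal = lik / lik_sum if lik_sum > 0 else np.full(N_COMBOS, 1.0 / N_COMBOS)
    post = prior * pfinal
    post_sum = post.sum()
    if post_sum <= 0:  # all surviving mass annihilated; fall back to prior
        post = prior.copy()
        post_sum = post.sum()
    post = post / post_sum

    def _tie_key(i: int) -> tuple:
        f_alt = COMBOS[i][1].count(1)
        consistent = _mendel_consistent(COMBOS[i], locus.maternal_gt, locus.paternal_gt)
        return (post[i], consistent, -f_alt, -i)

    best = max(range(N_COMBOS), key=_tie_key)
    fetal_gt: Genotype = tuple(sorted(COMBOS[best][1]))  # type: ignore[assignment]
    confidence = float(
        sum(post[i] for i in range(N_COMBOS) if tuple(sorted(COMBOS[i][1])) == fetal_gt)
    )
    vec = PosteriorVector(
        combos=COMBOS, prior=prior, likelihood=pfinal, posterior=post, argmax=best
    )
    call = FetalCall(
        locus=locus,
        genotype=fetal_gt,
        method="bayes",
        confidence=confidence,
        maternal_allele=COMBOS[best][1][0],
        paternal_allele=COMBOS[best][1][1],
    )
    return call, vec
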