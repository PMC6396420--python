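"""Bayesian fetal genotyping from per-fragment evidence.

For each biallelic site the fetal genotype posterior is

    P(G | data) ∝ P(G) · Π_j P(r_j | G, G_M, f_j)

with a Mendelian trio prior P(G) and a per-read mixture likelihood

    P(r_j | G, G_M, f_j) = P(r_j | fetal, G) · f_j + P(r_j | maternal, G_M) · (1 − f_j),

where f_j is the fetal fraction assigned to read j — the per-template-length
value when the read is properly paired with tlen ≤ 500, else the total
fraction.  The allele emission for a genotype is 1−ε / 0.5 / ε for a matching
homozygote / heterozygote / mismatching homozygote; ε = 0 reproduces the
idealized 0 / 0.5 / 1 emissions under which, e.g.,
P(r=A | G=aa, G_M=Aa, f) = 0·f + 0.5·(1−f).

All products are accumulated in natural-log space with a max-shift
normalization; genotypes with zero Mendelian prior keep posterior zero (de novo
events are not modeled).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .fetal_fraction import FetalFractionProfile
from .sites import CALLING_CATEGORIES, GENOTYPES, Category, VariantSite, parse_genotype
from .store import ALT, EvidenceStore, FragmentObservation

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 1e-3

LENGTH_DEPENDENT = "LENGTH_DEPENDENT"
FIXED = "FIXED"


@dataclass(frozen=True)
class GenotypePrior:
    """Prior over fetal genotypes (0/0, 0/1, 1/1)."""

    p00: float
    p01: float
    p11: float

    def __post_init__(self):
        probs = self.as_array()
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"prior must be a probability vector, got {probs}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p00, self.p01, self.p11], dtype=float)


@dataclass(frozen=True)
class EmissionModel:
    """Per-observation allele error probability ε ∈ [0, 0.5)."""

    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self):
        if not (0.0 <= self.epsilon < 0.5):
            raise ValueError(f"epsilon must be in [0, 0.5), got {self.epsilon}")

    def p_alt(self, genotype: int) -> float:
        """P(observed allele = ALT | source genotype)."""
        return (self.epsilon, 0.5, 1.0 - self.epsilon)[genotype]


@dataclass
class PosteriorResult:
    """Genotype posteriors and bookkeeping for one site."""

    site_id: str
    posteriors: tuple[float, float, float]
    log_likelihoods: tuple[float, float, float]
    called: int
    n_obs: int
    ff_mode: str
    tie: bool = False
    prior: tuple[float, float, float] = field(default=(np.nan, np.nan, np.nan))

    @property
    def max_posterior(self) -> float:
        return self.posteriors[self.called]


def mendelian_prior(g_mother, g_father) -> GenotypePrior:
    """Trio prior: one allele transmitted from each parent, no de novo events."""
    gm, gf = parse_genotype(g_mother), parse_genotype(g_father)
    pm, pf = gm / 2.0, gf / 2.0  # P(transmitting the alt allele)
    return GenotypePrior(
        p00=(1 - pm) * (1 - pf),
        p01=pm * (1 - pf) + (1 - pm) * pf,
        p11=pm * pf,
    )


def emission_prob(allele: str, genotype, epsilon: float = DEFAULT_EPSILON) -> float:
    """P(a read shows `allele` | it originates from `genotype`)."""
    p_alt = EmissionModel(epsilon).p_alt(parse_genotype(genotype))
    return p_alt if allele == ALT else 1.0 - p_alt


def read_log_likelihood(
    obs: FragmentObservation,
    g_fetus,
    g_mother,
    profile: FetalFractionProfile,
    emission: EmissionModel = EmissionModel(),
) -> float:
    """log P(r | G, G_M, f_r): fetal/maternal mixture at the read's fraction."""
    f_r = profile.lookup(obs)
    p = emission_prob(obs.allele, g_fetus, emission.epsilon) * f_r + emission_prob(
        obs.allele, g_mother, emission.epsilon
    ) * (1.0 - f_r)
    return math.log(p) if p > 0 else -math.inf


def _site_log_likelihoods(
    site: VariantSite,
    observations: list[FragmentObservation],
    profile: FetalFractionProfile,
    emission: EmissionModel,
    fixed_ff: bool = False,
) -> np.ndarray:
    """Vectorized Σ_j log P(r_j | G, ...) for G in (0/0, 0/1, 1/1)."""
    if not observations:
        return np.zeros(3)
    is_alt = np.fromiter((o.allele == ALT for o in observations), dtype=bool, count=len(observations))
    if fixed_ff:
        f = np.full(len(observations), profile.total_ff)
    else:
        tl = np.fromiter((o.tlen for o in observations), dtype=np.int64, count=len(observations))
        pp = np.fromiter((o.properly_paired for o in observations), dtype=bool, count=len(observations))
        f = profile.lookup_array(tl, pp)
    e_mat_alt = emission.p_alt(site.g_mother)
    p_mat = np.where(is_alt, e_mat_alt, 1.0 - e_mat_alt)
    out = np.empty(3)
    with np.errstate(divide="ignore"):
        for g in GENOTYPES:
            e_fet_alt = emission.p_alt(g)
            p_fet = np.where(is_alt, e_fet_alt, 1.0 - e_fet_alt)
            out[g] = np.sum(np.log(p_fet * f + p_mat * (1.0 - f)))
    return out


def call_genotype(posteriors) -> tuple[int, bool]:
    """Argmax genotype; exact ties resolve to the earlier of (0/0, 0/1, 1/1)."""
    q = np.asarray(posteriors, dtype=float)
    best = int(np.argmax(q))  # argmax already prefers the earliest maximum
    tie = bool(np.sum(q == q[best]) > 1)
    return best, tie


def site_posteriors(
    site: VariantSite,
    observations: list[FragmentObservation],
    profile: FetalFractionProfile,
    emission: EmissionModel = EmissionModel(),
    prior: GenotypePrior | None = None,
    fixed_ff: bool = False,
) -> PosteriorResult:
    """Posterior over the three fetal genotypes at one site.

    With zero observations the posterior equals the Mendelian prior exactly;
    genotypes with zero prior are never resurrected by data.
    """
    if prior is None:
        prior = mendelian_prior(site.g_mother, site.g_father)
    p = prior.as_array()
    if not np.any(p > 0):
        raise ValueError("all genotype priors are zero")
    ll = _site_log_likelihoods(site, observations, profile, emission, fixed_ff=fixed_ff)
    mode = FIXED if fixed_ff else LENGTH_DEPENDENT
    if len(observations) == 0:
        q = p.copy()
    else:
        logpost = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)) + ll, -np.inf)
        shifted = logpost - np.max(logpost)
        w = np.exp(shifted)
        q = w / w.sum()
    called, tie = call_genotype(q)
    return PosteriorResult(
        site_id=site.site_id,
        posteriors=tuple(float(x) for x in q),
        log_likelihoods=tuple(float(x) for x in ll),
        called=called,
        n_obs=len(observations),
        ff_mode=mode,
        tie=tie,
        prior=tuple(float(x) for x in p),
    )


def genotype_all(
    store: EvidenceStore,
    sites: list[VariantSite],
    profile: FetalFractionProfile,
    emission: EmissionModel = EmissionModel(),
    mode: str = LENGTH_DEPENDENT,
    include_informative: bool = True,
) -> list[PosteriorResult]:
    """Genotype every non-uninformative site, streaming in site order.

    FIXED mode substitutes the total fetal fraction for every observation.
    Uninformative sites (parents identical homozygotes) are skipped and
    counted; fetal-informative sites are genotyped too unless excluded.
    """
    if mode not in (LENGTH_DEPENDENT, FIXED):
        raise ValueError(f"unknown ff mode: {mode}")
    fixed_ff = mode == FIXED
    results = []
    n_uninformative = 0
    wanted = set(CALLING_CATEGORIES) | ({Category.FETAL_INFORMATIVE} if include_informative else set())
    for site in sites:
        if site.category is Category.UNINFORMATIVE:
            n_uninformative += 1
            continue
        if site.category not in wanted:
            continue
        results.append(
            site_posteriors(
                site, store.observations(site.site_id), profile, emission, fixed_ff=fixed_ff
            )
        )
    if n_uninformative:
        logger.info("skipped %d uninformative sites", n_uninformative)
    return results
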