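"""Synthetic cfDNA trios and in-silico fetal-fraction / depth reduction.

Two jobs live here.  First, a generator of fully synthetic family trios —
parental genotypes per inheritance category, a Mendelian fetal genotype, and a
per-site pool of cfDNA fragments that are fetal with probability f*, with
template lengths drawn from fetal/maternal length laws peaking at 140 / 166 bp
and alleles flipped at a per-site error rate.  Second, the subsampling
machinery that takes an existing evidence store and reduces it to a lower
target fetal fraction d and/or a lower median depth, so genotyping accuracy can
be mapped over a (fetal fraction × depth) grid.

Reduction to a target fraction d works per site.  Where a fetal-specific
allele is identifiable (mother homozygous), a proportion N = 1 − d/f of the
fetal-allele reads is discarded (N randomly rounded up or down by its
fractional part), the same number of shared-allele reads — sampled with
probability proportional to their length's frequency under the fetal length
law — have their lengths redrawn from the maternal law, and N new
shared-allele reads with maternal lengths are generated, keeping depth intact.
Where the mother is heterozygous the fetal allele cannot be identified; the
excess fetal mass (1 − d/f)·f of the site's reads is sampled by fetal-length
frequency and made maternal-like: a length redrawn from the maternal law and an
allele redrawn from the maternal genotype (a no-op in distribution for reads
that were maternal anyway, a correction for the fetal ones, so the allelic
imbalance scales down toward d).  ``maternal_het_mode="literal"`` instead
samples the proportion d/f of the reads.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import skewnorm

from .bayes import mendelian_prior
from .fetal_fraction import DEFAULT_MAX_TLEN, FetalFractionProfile, estimate_per_length_ff
from .sites import Category, VariantSite
from .store import ALT, REF, EvidenceStore, FragmentObservation

_BASES = np.array(list("ACGT"))


def _random_round(x: float, rng: np.random.Generator) -> int:
    """Unbiased randomized rounding: floor(x) + 1 with probability frac(x)."""
    lo = math.floor(x)
    return int(lo + (rng.random() < (x - lo)))


@dataclass(frozen=True)
class LengthLaw:
    """Discrete template-length distribution over a bounded support."""

    pmf: tuple  # probability per tlen, index = tlen (0..support_max)
    support_min: int
    support_max: int
    description: str = ""

    @classmethod
    def skew_normal(
        cls, mode: int, scale: float, shape: float, support: tuple[int, int] = (50, 500)
    ) -> "LengthLaw":
        """Discretized skew-normal anchored so the discrete mode sits at `mode`."""
        lo, hi = support
        grid = np.linspace(-4 * scale, 4 * scale, 8001)
        delta = grid[np.argmax(skewnorm.pdf(grid, shape, loc=0.0, scale=scale))]
        x = np.arange(0, hi + 1, dtype=float)
        dens = skewnorm.pdf(x, shape, loc=mode - delta, scale=scale)
        dens[:lo] = 0.0
        dens /= dens.sum()
        return cls(
            pmf=tuple(dens),
            support_min=lo,
            support_max=hi,
            description=f"skewnorm(mode={mode},scale={scale},shape={shape})",
        )

    def _cdf(self) -> np.ndarray:
        return np.cumsum(np.asarray(self.pmf))

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.searchsorted(self._cdf(), rng.random(n), side="right")

    @property
    def mode(self) -> int:
        return int(np.argmax(self.pmf))


def default_fetal_length_law() -> LengthLaw:
    """Left-skewed law peaking at 140 bp (fetal cfDNA is shorter)."""
    return LengthLaw.skew_normal(mode=140, scale=33.0, shape=-4.0)


def default_maternal_length_law() -> LengthLaw:
    """Left-skewed law peaking at the mononucleosomal 166 bp."""
    return LengthLaw.skew_normal(mode=166, scale=30.0, shape=-4.0)


@dataclass
class SimulationConfig:
    """Conditions for one synthetic trio.

    Defaults emulate a clinically relevant first-trimester sample: fetal
    fraction 0.15, mean depth 100, fetal/maternal length modes 140/166 bp, a
    0.2% allele-observation error with a 5% subpopulation of noisy sites at 2%
    (with depressed base/mapping qualities), a 5% subpopulation of
    reference-biased sites where alternate-allele reads are lost to the
    reference at 8% and the surviving ALT reads carry lower mapping quality
    (emulating alignment/capture bias), and a 2% improper-pair rate.
    """

    seed: int
    n_maternal_only: int = 2000
    n_paternal_only: int = 2000
    n_double_het: int = 2000
    n_informative: int = 5000
    n_uninformative: int = 0
    true_ff: float = 0.15
    depth_mean: float = 100.0
    fetal_length_law: LengthLaw = field(default_factory=default_fetal_length_law)
    maternal_length_law: LengthLaw = field(default_factory=default_maternal_length_law)
    error_rate: float = 0.002
    noisy_site_fraction: float = 0.05
    noisy_error_rate: float = 0.02
    biased_site_fraction: float = 0.05
    ref_bias_rate: float = 0.08
    improper_pair_rate: float = 0.02
    indel_fraction: float = 0.0
    chrom: str = "chr1"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory for any stochastic run")
        if not (0.0 < self.true_ff < 1.0):
            raise ValueError("true_ff must lie in (0, 1)")
        if self.total_sites <= 0:
            raise ValueError("configuration requests zero sites")
        for law in (self.fetal_length_law, self.maternal_length_law):
            if abs(sum(law.pmf) - 1.0) > 1e-9:
                raise ValueError("length law pmf must sum to 1")

    @property
    def total_sites(self) -> int:
        return (
            self.n_maternal_only
            + self.n_paternal_only
            + self.n_double_het
            + self.n_informative
            + self.n_uninformative
        )

    def digest(self) -> str:
        blob = {
            k: (v.description if isinstance(v, LengthLaw) else v)
            for k, v in vars(self).items()
        }
        return hashlib.sha256(json.dumps(blob, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class TruthTable:
    """Ground-truth fetal genotypes keyed by site_id, with provenance."""

    genotypes: dict[str, int]
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, site_id: str) -> int:
        return self.genotypes[site_id]

    def __contains__(self, site_id: str) -> bool:
        return site_id in self.genotypes

    def __len__(self) -> int:
        return len(self.genotypes)


_CAT_PARENTS = {
    Category.MATERNAL_ONLY_HET: ((1, 0), (1, 2)),
    Category.PATERNAL_ONLY_HET: ((0, 1), (2, 1)),
    Category.DOUBLE_HET: ((1, 1), (1, 1)),
    Category.FETAL_INFORMATIVE: ((0, 2), (2, 0)),
    Category.UNINFORMATIVE: ((0, 0), (2, 2)),
}


def generate_trio(config: SimulationConfig):
    """Simulate one family: sites, a cfDNA evidence store, and the fetal truth.

    Returns ``(sites, store, truth)``.  Per site the depth is Poisson, each
    fragment is fetal with probability ``true_ff``, its length follows the
    matching length law, and its allele is drawn from the source genotype then
    flipped with the site's error rate.  Identical configs (same seed) give
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    cat_list = (
        [Category.MATERNAL_ONLY_HET] * config.n_maternal_only
        + [Category.PATERNAL_ONLY_HET] * config.n_paternal_only
        + [Category.DOUBLE_HET] * config.n_double_het
        + [Category.FETAL_INFORMATIVE] * config.n_informative
        + [Category.UNINFORMATIVE] * config.n_uninformative
    )
    rng.shuffle(cat_list)

    fetal_cdf = np.cumsum(np.asarray(config.fetal_length_law.pmf))
    maternal_cdf = np.cumsum(np.asarray(config.maternal_length_law.pmf))

    sites: list[VariantSite] = []
    truth_map: dict[str, int] = {}
    store = EvidenceStore(
        metadata={
            "source": "synthetic",
            "config_digest": config.digest(),
            "seed": config.seed,
            "true_ff": config.true_ff,
        }
    )
    n_fetal_total = 0
    n_total = 0
    for idx, cat in enumerate(cat_list):
        pos = 10_000 + idx * 300
        ref_i = rng.integers(4)
        alt_i = (ref_i + 1 + rng.integers(3)) % 4
        ref, alt = str(_BASES[ref_i]), str(_BASES[alt_i])
        if rng.random() < config.indel_fraction:
            if rng.random() < 0.5:
                alt = ref + str(_BASES[rng.integers(4)])  # insertion
            else:
                ref, alt = ref + str(_BASES[rng.integers(4)]), ref  # deletion
        gm, gf = _CAT_PARENTS[cat][rng.integers(2)]
        site = VariantSite(config.chrom, pos, ref, alt, gm, gf)
        assert site.category is cat
        sites.append(site)

        g_fetus = int(rng.random() < gm / 2.0) + int(rng.random() < gf / 2.0)
        truth_map[site.site_id] = g_fetus

        depth = int(rng.poisson(config.depth_mean))
        noisy = rng.random() < config.noisy_site_fraction
        err = config.noisy_error_rate if noisy else config.error_rate
        if depth == 0:
            continue
        is_fetal = rng.random(depth) < config.true_ff
        n_fet = int(is_fetal.sum())
        n_fetal_total += n_fet
        n_total += depth
        tlen = np.empty(depth, dtype=np.int64)
        tlen[is_fetal] = np.searchsorted(fetal_cdf, rng.random(n_fet), side="right")
        tlen[~is_fetal] = np.searchsorted(maternal_cdf, rng.random(depth - n_fet), side="right")
        src_g = np.where(is_fetal, g_fetus, gm)
        is_alt = rng.random(depth) < src_g / 2.0
        is_alt ^= rng.random(depth) < err
        biased = rng.random() < config.biased_site_fraction
        if biased:
            # reference bias: ALT-derived reads lost to REF at ref_bias_rate
            is_alt &= rng.random(depth) >= config.ref_bias_rate
        proper = rng.random(depth) >= config.improper_pair_rate
        tlen[~proper] = 0
        if noisy:
            bq = np.clip(np.rint(rng.normal(26.0, 4.0, depth)), 2, 41).astype(int)
            mq = np.clip(np.rint(rng.normal(45.0, 8.0, depth)), 0, 60).astype(int)
        else:
            bq = np.clip(np.rint(rng.normal(38.0, 3.0, depth)), 2, 41).astype(int)
            mq = np.full(depth, 60)
        if biased:
            # surviving ALT reads align worse: the classic mapping-bias signature
            n_alt_reads = int(is_alt.sum())
            mq[is_alt] = np.minimum(
                mq[is_alt], np.clip(np.rint(rng.normal(48.0, 6.0, n_alt_reads)), 0, 60).astype(int)
            )
        sid = site.site_id
        for j in range(depth):
            store.add(
                FragmentObservation(
                    site_id=sid,
                    allele=ALT if is_alt[j] else REF,
                    tlen=int(tlen[j]),
                    properly_paired=bool(proper[j]),
                    base_quality=int(bq[j]),
                    map_quality=int(mq[j]),
                    fragment_id=f"frag:{idx}:{j}",
                )
            )
    store.metadata["n_fetal_fragments"] = n_fetal_total
    store.metadata["n_fragments"] = n_total
    truth = TruthTable(
        genotypes=truth_map,
        provenance={"config_digest": config.digest(), "seed": config.seed},
    )
    # every truth genotype must be reachable under the Mendelian prior
    for s in sites:
        assert mendelian_prior(s.g_mother, s.g_father).as_array()[truth_map[s.site_id]] > 0
    return sites, store, truth


def _weighted_sample_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, k: int
) -> np.ndarray:
    """Indices of k items sampled without replacement ∝ weights (uniform if all zero)."""
    n = len(weights)
    k = min(k, n)
    if k <= 0:
        return np.empty(0, dtype=int)
    total = weights.sum()
    p = weights / total if total > 0 else None
    return rng.choice(n, size=k, replace=False, p=p)


def reduce_fetal_fraction(
    store: EvidenceStore,
    sites: list[VariantSite],
    profile: FetalFractionProfile,
    d: float,
    seed: int,
    maternal_het_mode: str = "excess-fetal",
) -> EvidenceStore:
    """Rewrite a store so it looks like it was drawn at fetal fraction d.

    The per-site fetal fraction f is the observed paternal-allele share × 2
    where the fetal-specific allele is identifiable (mother homozygous) and
    d < f; otherwise the profile's total fraction is used.  See the module
    docstring for the per-branch procedure.
    """
    if not (0.0 < d < 1.0):
        raise ValueError(f"target fetal fraction d must be in (0, 1), got {d}")
    if maternal_het_mode not in ("excess-fetal", "literal"):
        raise ValueError(f"unknown maternal_het_mode: {maternal_het_mode}")
    rng = np.random.default_rng(seed)
    fetal_pmf = profile.fetal_pmf()
    maternal_cdf = np.cumsum(profile.maternal_pmf())

    def read_weights(obs_list) -> np.ndarray:
        w = np.zeros(len(obs_list))
        for i, o in enumerate(obs_list):
            if 1 <= o.tlen <= profile.max_tlen:
                w[i] = fetal_pmf[o.tlen]
        return w

    def draw_maternal_tlen(n: int) -> np.ndarray:
        return np.searchsorted(maternal_cdf, rng.random(n), side="right")

    out = EvidenceStore(
        metadata={**store.metadata, "reduced_to_ff": d, "reduction_seed": seed}
    )
    site_by_id = {s.site_id: s for s in sites}
    for site_id, obs_list in store.items():
        site = site_by_id.get(site_id)
        if site is None or not obs_list:
            for o in obs_list:
                out.add(o)
            continue
        mat_allele = site.maternal_allele
        if mat_allele is not None:
            # mother homozygous: the other allele is fetal-specific
            fetal_allele = ALT if mat_allele == REF else REF
            fet_idx = [i for i, o in enumerate(obs_list) if o.allele == fetal_allele]
            shared_idx = [i for i, o in enumerate(obs_list) if o.allele != fetal_allele]
            f_site = 2.0 * len(fet_idx) / len(obs_list)
            f_use = f_site if d < f_site else profile.total_ff
            prop = max(0.0, 1.0 - d / f_use) if f_use > 0 else 0.0
            n_drop = min(_random_round(prop * len(fet_idx), rng), len(fet_idx))
            drop = set(np.array(fet_idx)[rng.permutation(len(fet_idx))[:n_drop]].tolist())
            shared_obs = [obs_list[i] for i in shared_idx]
            reassign_local = _weighted_sample_without_replacement(
                rng, read_weights(shared_obs), n_drop
            )
            reassign = {shared_idx[i] for i in reassign_local}
            new_tlens = iter(draw_maternal_tlen(len(reassign)))
            kept = []
            for i, o in enumerate(obs_list):
                if i in drop:
                    continue
                if i in reassign:
                    o = replace(o, tlen=int(max(1, next(new_tlens))), properly_paired=True)
                kept.append(o)
            templates = kept if kept else obs_list
            gen_tlens = draw_maternal_tlen(n_drop)
            for k in range(n_drop):
                tmpl = templates[int(rng.integers(len(templates)))]
                kept.append(
                    FragmentObservation(
                        site_id=site_id,
                        allele=mat_allele,
                        tlen=int(max(1, gen_tlens[k])),
                        properly_paired=True,
                        base_quality=tmpl.base_quality,
                        map_quality=tmpl.map_quality,
                        fragment_id=f"ffred:{site_id}:{k}",
                    )
                )
            for o in kept:
                out.add(o)
        else:
            # mother heterozygous: fetal allele unidentifiable; make length-sampled
            # reads fully maternal-like (maternal length, maternal-genotype allele)
            f_use = profile.total_ff
            if maternal_het_mode == "excess-fetal":
                prop = max(0.0, 1.0 - d / f_use) * f_use
            else:
                prop = min(1.0, d / f_use)
            n_conv = min(_random_round(prop * len(obs_list), rng), len(obs_list))
            conv = set(
                _weighted_sample_without_replacement(rng, read_weights(obs_list), n_conv).tolist()
            )
            new_tlens = iter(draw_maternal_tlen(len(conv)))
            new_alleles = iter(rng.random(len(conv)) < 0.5)
            for i, o in enumerate(obs_list):
                if i in conv:
                    o = replace(
                        o,
                        tlen=int(max(1, next(new_tlens))),
                        properly_paired=True,
                        allele=ALT if next(new_alleles) else REF,
                    )
                out.add(o)
    return out


def downsample_depth(
    store: EvidenceStore, sites: list[VariantSite], target_median: int, seed: int
) -> EvidenceStore:
    """Thin every site's reads by target_median / measured-median.

    Each observation is kept independently with that probability, so the
    resulting per-site depths are binomial and their median lands on the target
    up to sampling noise.
    """
    depths = [len(obs) for _, obs in store.items()]
    if not depths:
        raise ValueError("empty store")
    measured = float(np.median(depths))
    if target_median > measured:
        raise ValueError(
            f"target median depth {target_median} exceeds measured median {measured:g}; "
            "downsampling would be a no-op"
        )
    p = target_median / measured
    rng = np.random.default_rng(seed)
    out = EvidenceStore(
        metadata={**store.metadata, "downsampled_to_median": target_median, "downsample_seed": seed}
    )
    for site_id, obs_list in store.items():
        keep = rng.random(len(obs_list)) < p
        for o, k in zip(obs_list, keep):
            if k:
                out.add(o)
    return out


def grid_experiment(
    sites: list[VariantSite],
    store: EvidenceStore,
    truth: TruthTable,
    ff_values: list[float],
    depth_values: list[int],
    seed: int,
    emission=None,
    min_count: int = 50,
    maternal_het_mode: str = "excess-fetal",
):
    """Accuracy/AUC per category over a (fetal fraction × depth) grid.

    For each cell the base store is reduced to the target fraction, depth-
    downsampled, the fetal-fraction profile re-estimated, all sites genotyped
    in length-dependent mode, and the calls evaluated against truth.  Returns a
    tidy DataFrame (category, ff, depth, accuracy, auc, n_sites).
    """
    import pandas as pd

    from .bayes import EmissionModel, genotype_all
    from .evaluate import evaluate

    if sorted(ff_values) != list(ff_values) or sorted(depth_values) != list(depth_values):
        raise ValueError("ff_values and depth_values must be sorted ascending")
    emission = emission or EmissionModel()
    base_profile = estimate_per_length_ff(store, sites, min_count=min_count)
    rng = np.random.default_rng(seed)
    frames = []
    for ff in ff_values:
        for depth in depth_values:
            s1, s2 = int(rng.integers(2**31)), int(rng.integers(2**31))
            reduced = reduce_fetal_fraction(
                store, sites, base_profile, ff, seed=s1, maternal_het_mode=maternal_het_mode
            )
            thinned = downsample_depth(reduced, sites, depth, seed=s2)
            prof = estimate_per_length_ff(thinned, sites, min_count=min_count)
            results = genotype_all(thinned, sites, prof, emission)
            met = evaluate(results, sites, truth.genotypes)
            met["ff"] = ff
            met["depth"] = depth
            frames.append(met)
    grid = pd.concat(frames, ignore_index=True)
    return grid[["category", "ff", "depth", "accuracy", "auc", "n_sites"]]
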