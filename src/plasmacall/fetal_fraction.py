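"""Fetal-fraction estimation from fragment lengths.

At fetal-informative sites (parents homozygous for different alleles) any
plasma fragment carrying the paternal-specific allele must be fetal-derived,
while fragments carrying the maternal allele are a mixture of maternal
background and the fetus's shared allele.  Counting paternal-allele fragments
(b) against shared-allele fragments (a) gives the total fetal fraction
f = 2b/(a+b) — the factor 2 because the fetus is heterozygous at such sites, so
only half of its fragments display the paternal-specific allele.

Binning the same counts by template length yields a per-length fetal fraction
f_L.  Fetal fragments peak near 140 bp and maternal ones near 166 bp, so
f_140 > f > f_166; the per-length profile is what lets the caller weight each
read's probability of being fetal by its length instead of applying a hard
size cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sites import Category, VariantSite
from .store import EvidenceStore, FragmentObservation

FF_FLOOR = 1e-6
DEFAULT_MAX_TLEN = 500
DEFAULT_MIN_COUNT = 50


class NoInformativeSitesError(ValueError):
    """Raised when no fetal-informative site has evidence.

    Without informative sites the fetal fraction cannot be estimated from the
    data; run the caller in fixed-ff mode with an externally supplied fraction.
    """


@dataclass
class LengthHistogram:
    """Fragment counts per template length 1..max_tlen plus an overflow bucket."""

    origin: str  # "FETAL_LABELED" or "SHARED_LABELED"
    max_tlen: int = DEFAULT_MAX_TLEN
    counts: np.ndarray = field(default=None)  # index 0 unused; index max_tlen+1 = overflow

    def __post_init__(self):
        if self.counts is None:
            self.counts = np.zeros(self.max_tlen + 2, dtype=np.int64)

    def add(self, tlen: int) -> None:
        if 1 <= tlen <= self.max_tlen:
            self.counts[tlen] += 1
        else:
            self.counts[self.max_tlen + 1] += 1

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def pmf(self) -> np.ndarray:
        """Normalized in-range length distribution (overflow excluded)."""
        in_range = self.counts[: self.max_tlen + 1].astype(float)
        s = in_range.sum()
        return in_range / s if s > 0 else in_range


@dataclass
class FetalFractionProfile:
    """Total and per-template-length fetal fractions with fallback rules."""

    total_ff: float
    per_length_ff: np.ndarray  # index by tlen, index 0 unused
    count_fetal: np.ndarray
    count_shared: np.ndarray
    min_count: int = DEFAULT_MIN_COUNT
    max_tlen: int = DEFAULT_MAX_TLEN

    @classmethod
    def constant(cls, total_ff: float, max_tlen: int = DEFAULT_MAX_TLEN) -> "FetalFractionProfile":
        """A flat profile: every length maps to total_ff (fixed-ff mode)."""
        total_ff = float(np.clip(total_ff, FF_FLOOR, 1.0))
        n = max_tlen + 1
        return cls(
            total_ff=total_ff,
            per_length_ff=np.full(n, total_ff),
            count_fetal=np.zeros(n, dtype=np.int64),
            count_shared=np.zeros(n, dtype=np.int64),
            min_count=0,
            max_tlen=max_tlen,
        )

    def lookup(self, obs: FragmentObservation) -> float:
        """Fetal fraction for one observation (see :func:`lookup_ff`)."""
        if obs.properly_paired and 1 <= obs.tlen <= self.max_tlen:
            return float(self.per_length_ff[obs.tlen])
        return self.total_ff

    def lookup_array(self, tlens: np.ndarray, properly_paired: np.ndarray) -> np.ndarray:
        """Vectorized lookup for arrays of tlen / pairing flags."""
        tl = np.asarray(tlens, dtype=np.int64)
        ok = np.asarray(properly_paired, dtype=bool) & (tl >= 1) & (tl <= self.max_tlen)
        out = np.full(tl.shape, self.total_ff, dtype=float)
        out[ok] = self.per_length_ff[tl[ok]]
        return out

    def fetal_pmf(self) -> np.ndarray:
        f = self.count_fetal[: self.max_tlen + 1].astype(float)
        s = f.sum()
        return f / s if s > 0 else f

    def maternal_pmf(self) -> np.ndarray:
        m = self.count_shared[: self.max_tlen + 1].astype(float)
        s = m.sum()
        return m / s if s > 0 else m


def collect_informative_counts(
    store: EvidenceStore, sites: list[VariantSite], max_tlen: int = DEFAULT_MAX_TLEN
):
    """Label fragments at fetal-informative sites as fetal vs shared.

    Returns (fetal LengthHistogram, shared LengthHistogram, a, b) where ``b``
    counts paternal-specific-allele (fetal-labeled) fragments and ``a`` counts
    shared-allele fragments.
    """
    fetal = LengthHistogram(origin="FETAL_LABELED", max_tlen=max_tlen)
    shared = LengthHistogram(origin="SHARED_LABELED", max_tlen=max_tlen)
    informative = [s for s in sites if s.category is Category.FETAL_INFORMATIVE]
    if not informative:
        raise NoInformativeSitesError(
            "no fetal-informative sites: cannot estimate the fetal fraction; "
            "use fixed-ff mode with an external estimate"
        )
    a = b = 0
    for site in informative:
        pat = site.paternal_specific_allele
        for obs in store.observations(site.site_id):
            if obs.allele == pat:
                fetal.add(obs.tlen)
                b += 1
            else:
                shared.add(obs.tlen)
                a += 1
    return fetal, shared, a, b


def estimate_total_ff(a: int, b: int) -> float:
    """Total fetal fraction f = 2b/(a+b), clamped to (1e-6, 1]."""
    if a + b <= 0:
        raise ValueError("cannot estimate fetal fraction from zero informative fragments")
    return float(np.clip(2.0 * b / (a + b), FF_FLOOR, 1.0))


def estimate_per_length_ff(
    store: EvidenceStore,
    sites: list[VariantSite],
    min_count: int = DEFAULT_MIN_COUNT,
    max_tlen: int = DEFAULT_MAX_TLEN,
) -> FetalFractionProfile:
    """Build a per-length fetal-fraction profile from fetal-informative sites.

    Length bins with fewer than ``min_count`` informative fragments fall back
    to the pooled total fraction; per-bin values are clamped to [1e-6, 1] like
    the total.
    """
    fetal, shared, a, b = collect_informative_counts(store, sites, max_tlen=max_tlen)
    total_ff = estimate_total_ff(a, b)
    b_l = fetal.counts[: max_tlen + 1].astype(float)
    a_l = shared.counts[: max_tlen + 1].astype(float)
    n_l = a_l + b_l
    per = np.full(max_tlen + 1, total_ff, dtype=float)
    ok = n_l >= max(min_count, 1)
    per[ok] = np.clip(2.0 * b_l[ok] / n_l[ok], FF_FLOOR, 1.0)
    return FetalFractionProfile(
        total_ff=total_ff,
        per_length_ff=per,
        count_fetal=fetal.counts[: max_tlen + 1].copy(),
        count_shared=shared.counts[: max_tlen + 1].copy(),
        min_count=min_count,
        max_tlen=max_tlen,
    )


def lookup_ff(profile: FetalFractionProfile, obs: FragmentObservation) -> float:
    """Fetal fraction used for one read.

    Properly paired reads with 1 <= tlen <= max_tlen use the per-length value;
    improperly paired reads or fragments longer than max_tlen (500 bp) fall
    back to the total fraction.
    """
    return profile.lookup(obs)


def write_profile(profile: FetalFractionProfile, path) -> None:
    """Serialize as TSV (tlen, count_fetal, count_shared, ff) + JSON header."""
    path = Path(path)
    lines = ["tlen\tcount_fetal\tcount_shared\tff"]
    for tlen in range(1, profile.max_tlen + 1):
        lines.append(
            f"{tlen}\t{int(profile.count_fetal[tlen])}\t{int(profile.count_shared[tlen])}"
            f"\t{float(profile.per_length_ff[tlen])!r}"
        )
    path.write_text("\n".join(lines) + "\n")
    header = {
        "total_ff": repr(float(profile.total_ff)),
        "min_count": profile.min_count,
        "max_tlen": profile.max_tlen,
    }
    Path(str(path) + ".json").write_text(json.dumps(header, sort_keys=True) + "\n")


def read_profile(path) -> FetalFractionProfile:
    path = Path(path)
    header = json.loads(Path(str(path) + ".json").read_text())
    max_tlen = int(header["max_tlen"])
    per = np.zeros(max_tlen + 1)
    cf = np.zeros(max_tlen + 1, dtype=np.int64)
    cs = np.zeros(max_tlen + 1, dtype=np.int64)
    with open(path) as fh:
        next(fh)  # header row
        for line in fh:
            tlen, c_f, c_s, ff = line.rstrip("\n").split("\t")
            i = int(tlen)
            cf[i], cs[i], per[i] = int(c_f), int(c_s), float(ff)
    return FetalFractionProfile(
        total_ff=float(header["total_ff"]),
        per_length_ff=per,
        count_fetal=cf,
        count_shared=cs,
        min_count=int(header["min_count"]),
        max_tlen=max_tlen,
    )
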