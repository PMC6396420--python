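"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from plasmacall.fetal_fraction import FetalFractionProfile
from plasmacall.sites import VariantSite
from plasmacall.store import ALT, REF, EvidenceStore, FragmentObservation


def make_site(gm, gf, pos=100, chrom="chr1", ref="A", alt="G") -> VariantSite:
    return VariantSite(chrom, pos, ref, alt, gm, gf)


def make_obs(
    site_id,
    allele=REF,
    tlen=166,
    properly_paired=True,
    base_quality=38,
    map_quality=60,
    fragment_id=None,
    idx=0,
) -> FragmentObservation:
    return FragmentObservation(
        site_id=site_id,
        allele=allele,
        tlen=tlen,
        properly_paired=properly_paired,
        base_quality=base_quality,
        map_quality=map_quality,
        fragment_id=fragment_id or f"frag:{idx}",
    )


def store_of(observations) -> EvidenceStore:
    store = EvidenceStore()
    store.add_many(observations)
    return store


@pytest.fixture
def flat_profile() -> FetalFractionProfile:
    """Constant fetal fraction 0.15 at every template length."""
    return FetalFractionProfile.constant(0.15)


@pytest.fixture
def sloped_profile() -> FetalFractionProfile:
    """Per-length profile rising linearly from 0.30 at 50 bp to 0.05 at 500 bp."""
    max_tlen = 500
    per = np.full(max_tlen + 1, 0.15)
    tl = np.arange(50, max_tlen + 1)
    per[50:] = np.clip(0.30 - 0.25 * (tl - 50) / 450.0, 1e-6, 1.0)
    return FetalFractionProfile(
        total_ff=0.15,
        per_length_ff=per,
        count_fetal=np.zeros(max_tlen + 1, dtype=np.int64),
        count_shared=np.zeros(max_tlen + 1, dtype=np.int64),
        min_count=0,
        max_tlen=max_tlen,
    )
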