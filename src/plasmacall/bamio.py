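"""Per-fragment allele extraction from cfDNA alignments.

For every parental variant site, each read pair overlapping the site yields at
most one observation: the allele it supports, the absolute template length
(the cfDNA fragment size proxy), pairing status and qualities.  Mates that
disagree about the allele discard the whole fragment.  SNP support is the base
identity at the site; indel support requires the read's CIGAR-expanded local
haplotype over the reference span of the variant to match exactly one of the
two allele sequences.
"""

from __future__ import annotations

import logging

import pysam

from .sites import VariantSite, VarType
from .store import ALT, REF, EvidenceStore, FragmentObservation

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 20
DEFAULT_MIN_BASEQ = 13


def _snp_allele(read: pysam.AlignedSegment, site: VariantSite):
    """(allele, base_quality) supported by one read at a SNP, or (None, 0)."""
    pos0 = site.pos - 1
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos == pos0:
            base = read.query_sequence[qpos]
            bq = read.query_qualities[qpos]
            if base == site.ref:
                return REF, bq
            if base == site.alt:
                return ALT, bq
            return None, 0
    return None, 0


def _indel_allele(read: pysam.AlignedSegment, site: VariantSite):
    """Exact-match local-haplotype assignment for an indel.

    The read must align a base at the variant position and at the first
    reference base past the REF span, so insertions at the window edge are
    fully contained.  The spanned query sequence must equal REF or ALT exactly;
    anything else (partial spans, third haplotypes) is discarded.  Base quality
    is the minimum over the spanned bases.
    """
    pos0 = site.pos - 1
    end0 = pos0 + len(site.ref)
    q_start = q_end = None
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos == pos0:
            q_start = qpos
        elif rpos == end0:
            q_end = qpos
            break
    if q_start is None or q_end is None or q_end <= q_start:
        return None, 0
    hap = read.query_sequence[q_start:q_end]
    bq = min(read.query_qualities[q_start:q_end])
    if hap == site.ref:
        return REF, bq
    if hap == site.alt:
        return ALT, bq
    return None, 0


def extract_observations(
    alignments,
    sites: list[VariantSite],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
    reference=None,
) -> EvidenceStore:
    """Build the evidence store from an indexed BAM/CRAM.

    Duplicate-flagged, secondary, supplementary and low-MAPQ reads are skipped;
    a base (or indel haplotype) below ``min_baseq`` is ignored.  Each fragment
    (read-pair name) contributes at most one observation per site; fragments
    whose mates disagree are dropped.  Template length is stored as an absolute
    value, with tlen 0 treated as unavailable (improperly paired).
    """
    af = pysam.AlignmentFile(str(alignments), reference_filename=reference and str(reference))
    try:
        if not af.has_index():
            raise OSError(f"{alignments}: alignment file must be indexed")
        store = EvidenceStore(
            metadata={
                "source_alignments": str(alignments),
                "min_mapq": min_mapq,
                "min_baseq": min_baseq,
            }
        )
        references = set(af.references)
        for site in sites:
            if site.chrom not in references:
                logger.warning("site %s: contig not in alignment file, skipped", site.site_id)
                continue
            pos0 = site.pos - 1
            if pos0 >= af.get_reference_length(site.chrom):
                logger.warning("site %s beyond contig bounds, skipped", site.site_id)
                continue
            window_end = pos0 + len(site.ref) + 1
            assign = _snp_allele if site.var_type is VarType.SNP else _indel_allele
            fragments: dict[str, dict] = {}
            for read in af.fetch(site.chrom, pos0, window_end):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_duplicate
                    or read.is_qcfail
                    or read.mapping_quality < min_mapq
                    or read.query_sequence is None
                ):
                    continue
                allele, bq = assign(read, site)
                if allele is None or bq < min_baseq:
                    continue
                info = fragments.setdefault(
                    read.query_name,
                    {"alleles": set(), "bq": 0, "mq": read.mapping_quality, "tlen": 0, "pp": False},
                )
                info["alleles"].add(allele)
                info["bq"] = max(info["bq"], int(bq))
                info["mq"] = min(info["mq"], read.mapping_quality)
                tlen = abs(read.template_length)
                if tlen > 0:
                    info["tlen"] = tlen
                    info["pp"] = info["pp"] or read.is_proper_pair
            for name in sorted(fragments):
                info = fragments[name]
                if len(info["alleles"]) != 1:
                    continue  # mates disagree: fragment discarded
                tlen = info["tlen"]
                store.add(
                    FragmentObservation(
                        site_id=site.site_id,
                        allele=next(iter(info["alleles"])),
                        tlen=tlen,
                        properly_paired=bool(info["pp"] and tlen > 0),
                        base_quality=info["bq"],
                        map_quality=int(info["mq"]),
                        fragment_id=name,
                    )
                )
        return store
    finally:
        af.close()
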