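"""VCF input of parental genotypes and VCF output of fetal calls.

Parental variants come as one single-sample VCF per parent; a site is usable
only when both parents have a record at the position (a homozygous-reference
record counts), the REF alleles agree, and the locus is biallelic.  Everything
else is dropped with a counted reason.  Fetal calls go out as a single-sample
VCF 4.2 ("FETUS") carrying the three genotype posteriors, the site category,
the cfDNA depth and the fetal-fraction mode per call.
"""

from __future__ import annotations

import logging
import re
from collections import Counter

import pysam
from cyvcf2 import VCF

from .bayes import PosteriorResult, LENGTH_DEPENDENT
from .sites import GT_STRINGS, VariantSite
from .store import EvidenceStore

logger = logging.getLogger(__name__)

_ACGT = re.compile(r"^[ACGT]+$")


def _read_single_sample_vcf(path) -> dict:
    """(chrom, pos) -> (ref, alt_or_None, genotype int) for one parent."""
    vcf = VCF(str(path))
    if len(vcf.samples) != 1:
        raise ValueError(f"{path}: expected exactly one sample with GT, found {vcf.samples}")
    records: dict[tuple[str, int], tuple] = {}
    dropped: Counter = Counter()
    chrom_order: list[str] = []
    seen_chroms = set()
    for v in vcf:
        key = (v.CHROM, v.POS)
        if v.CHROM not in seen_chroms:
            seen_chroms.add(v.CHROM)
            chrom_order.append(v.CHROM)
        if key in records:
            dropped["duplicate_position"] += 1
            continue
        alts = [a for a in v.ALT if a != "."]
        if len(alts) > 1:
            dropped["multiallelic"] += 1
            continue
        alt = alts[0] if alts else None
        if not _ACGT.match(v.REF) or (alt is not None and not _ACGT.match(alt)):
            dropped["non_acgt_allele"] += 1
            continue
        a, b = v.genotypes[0][0], v.genotypes[0][1]
        if a < 0 or b < 0:
            dropped["missing_gt"] += 1
            continue
        gt = int(a != 0) + int(b != 0)
        if alt is None and gt != 0:
            dropped["alt_genotype_without_alt_allele"] += 1
            continue
        records[key] = (v.REF, alt, gt)
    vcf.close()
    return {"records": records, "dropped": dropped, "chrom_order": chrom_order}


def load_parental_variants(maternal_vcf, paternal_vcf):
    """Load and pair the parental VCFs into VariantSites.

    Returns ``(sites, dropped)`` where ``dropped`` is a Counter of exclusion
    reasons (multiallelic records, REF mismatches between the files, sites
    absent from one parent, ...).  Sites are sorted by (chrom, pos); a parent
    whose record is homozygous-reference (no ALT) adopts the other parent's ALT
    allele.
    """
    mom = _read_single_sample_vcf(maternal_vcf)
    dad = _read_single_sample_vcf(paternal_vcf)
    dropped = mom["dropped"] + dad["dropped"]
    chrom_rank: dict[str, int] = {}
    for c in mom["chrom_order"] + dad["chrom_order"]:
        chrom_rank.setdefault(c, len(chrom_rank))

    sites: list[VariantSite] = []
    all_keys = set(mom["records"]) | set(dad["records"])
    for key in sorted(all_keys, key=lambda k: (chrom_rank[k[0]], k[1])):
        m_rec, d_rec = mom["records"].get(key), dad["records"].get(key)
        if m_rec is None or d_rec is None:
            dropped["absent_in_other_parent"] += 1
            continue
        (m_ref, m_alt, gm), (d_ref, d_alt, gf) = m_rec, d_rec
        if m_ref != d_ref:
            dropped["ref_mismatch"] += 1
            continue
        if m_alt is not None and d_alt is not None and m_alt != d_alt:
            dropped["alt_mismatch"] += 1
            continue
        alt = m_alt if m_alt is not None else d_alt
        if alt is None:
            dropped["no_alt_allele"] += 1
            continue
        sites.append(VariantSite(key[0], key[1], m_ref, alt, gm, gf))
    if dropped:
        logger.info("dropped parental records: %s", dict(dropped))
    return sites, dropped


def _fetal_header(chroms: list[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##source=plasmacall")
    for c in chroms:
        header.add_line(f"##contig=<ID={c}>")
    header.add_line('##INFO=<ID=NOOBS,Number=0,Type=Flag,Description="No cfDNA observations; posterior equals the Mendelian prior">')
    header.add_line('##INFO=<ID=TIE,Number=0,Type=Flag,Description="Exact posterior tie broken toward the earlier genotype">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Called fetal genotype (max posterior)">')
    header.add_line('##FORMAT=<ID=GP,Number=G,Type=Float,Description="Posterior probabilities of fetal genotypes 0/0,0/1,1/1, rounded to 6 decimals">')
    header.add_line('##FORMAT=<ID=LL,Number=3,Type=Float,Description="Log-likelihoods log P(data|G) of fetal genotypes 0/0,0/1,1/1">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Number of cfDNA fragment observations at the site">')
    header.add_line('##FORMAT=<ID=CAT,Number=1,Type=String,Description="Trio inheritance category of the site">')
    header.add_line('##FORMAT=<ID=FFM,Number=1,Type=String,Description="Fetal-fraction mode used (LENGTH_DEPENDENT or FIXED)">')
    header.add_sample("FETUS")
    return header


_GT_TUPLES = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def write_fetal_vcf(results: list[PosteriorResult], sites: list[VariantSite], path) -> None:
    """Write fetal genotype calls as a single-sample VCF 4.2.

    ``results`` must align one-to-one with ``sites`` (same order); any mismatch
    raises.  Output is timestamp-free so identical inputs give identical bytes.
    """
    if len(results) != len(sites):
        raise ValueError(f"{len(results)} results for {len(sites)} sites")
    chroms: list[str] = []
    for s in sites:
        if s.chrom not in chroms:
            chroms.append(s.chrom)
    header = _fetal_header(chroms)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site, res in zip(sites, results):
            if res.site_id != site.site_id:
                raise ValueError(f"result {res.site_id} does not match site {site.site_id}")
            rec = out.new_record(contig=site.chrom, start=site.pos - 1, alleles=(site.ref, site.alt))
            sample = rec.samples["FETUS"]
            sample["GT"] = _GT_TUPLES[res.called]
            sample["GP"] = tuple(round(q, 6) for q in res.posteriors)
            sample["LL"] = tuple(float(x) for x in res.log_likelihoods)
            sample["DP"] = res.n_obs
            sample["CAT"] = site.category.value
            sample["FFM"] = res.ff_mode
            if res.n_obs == 0:
                rec.info["NOOBS"] = True
            if res.tie:
                rec.info["TIE"] = True
            out.write(rec)


def read_fetal_vcf(path):
    """Parse a fetal VCF back into (site tuples, posterior tuples, genotypes).

    Returns a list of dicts; used by the evaluation CLI and round-trip tests.
    """
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            sample = rec.samples["FETUS"]
            gt = sum(1 for a in sample["GT"] if a)
            out.append(
                {
                    "chrom": rec.contig,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "called": gt,
                    "posteriors": tuple(float(x) for x in sample["GP"]),
                    "log_likelihoods": tuple(float(x) for x in sample["LL"]),
                    "depth": int(sample["DP"]),
                    "category": sample["CAT"],
                    "ff_mode": sample["FFM"],
                    "noobs": "NOOBS" in rec.info,
                }
            )
    return out


def write_truth_vcf(truth_genotypes: dict[str, int], sites: list[VariantSite], path) -> None:
    """Single-sample VCF of true fetal genotypes (simulated ground truth)."""
    header = pysam.VariantHeader()
    header.add_line("##source=plasmacall-synthetic-truth")
    chroms: list[str] = []
    for s in sites:
        if s.chrom not in chroms:
            chroms.append(s.chrom)
    for c in chroms:
        header.add_line(f"##contig=<ID={c}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="True fetal genotype">')
    header.add_sample("FETUS")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in sites:
            if site.site_id not in truth_genotypes:
                continue
            rec = out.new_record(contig=site.chrom, start=site.pos - 1, alleles=(site.ref, site.alt))
            rec.samples["FETUS"]["GT"] = _GT_TUPLES[truth_genotypes[site.site_id]]
            out.write(rec)


def read_truth_vcf(path) -> dict[str, int]:
    truth = {}
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            gt = sum(1 for a in rec.samples["FETUS"]["GT"] if a)
            truth[f"{rec.contig}:{rec.pos}:{rec.ref}:{rec.alts[0]}"] = gt
    return truth


def parental_vcf_from_sites(sites: list[VariantSite], parent: str, sample: str, path) -> None:
    """Write one parent's genotypes at `sites` as a single-sample VCF.

    Round-trip helper: loading the two written parents reproduces the sites.
    """
    header = pysam.VariantHeader()
    header.add_line("##source=plasmacall-synthetic-parent")
    chroms: list[str] = []
    for s in sites:
        if s.chrom not in chroms:
            chroms.append(s.chrom)
    for c in chroms:
        header.add_line(f"##contig=<ID={c}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in sites:
            g = site.g_mother if parent == "mother" else site.g_father
            rec = out.new_record(contig=site.chrom, start=site.pos - 1, alleles=(site.ref, site.alt))
            rec.samples[sample]["GT"] = _GT_TUPLES[g]
            out.write(rec)
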