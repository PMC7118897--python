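"""Single-nucleotide substitution profiling.

Classifies somatic single-base substitutions from a VCF into the 96
trinucleotide-context classes.  Substitutions with a purine reference
base are folded onto the pyrimidine strand: both the base change and its
5'/3' context are reverse-complemented before classification, so a
variant and its reverse-complement representation land in the same
class.  Flanking bases come from the reference genome, not the VCF.
"""

from __future__ import annotations

import logging

import pysam
from pyfaidx import Fasta

from .matrix import FeatureProfile, ProfilingResult, RecordTally
from .seq import BASES, complement

log = logging.getLogger(__name__)

PYRIMIDINES = ("C", "T")


class ReferenceAccessor:
    """1-based single-base lookup over an indexed FASTA.

    Returns an uppercase base in {A,C,G,T,N}; ``None`` for out-of-range
    positions; raises ``KeyError`` naming the contig when it is absent.
    """

    def __init__(self, fasta_path):
        self._fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta

    def base(self, chrom: str, pos: int) -> str | None:
        if chrom not in self._fasta:
            raise KeyError(f"contig {chrom!r} not present in the reference")
        if pos < 1 or pos > len(self._fasta[chrom]):
            return None
        base = self._fasta[chrom][pos - 1]
        return base if base in BASES else "N"


def canonical_substitution(ref_base: str, alt_base: str) -> str:
    """Map an ordered base pair onto one of the six pyrimidine-reference
    substitution classes (C>A, C>G, C>T, T>A, T>C, T>G)."""
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref_base not in BASES or alt_base not in BASES:
        raise ValueError(f"non-ACGT base in substitution {ref_base}>{alt_base}")
    if ref_base == alt_base:
        raise ValueError(f"REF and ALT are identical: {ref_base}")
    if ref_base in PYRIMIDINES:
        return f"{ref_base}>{alt_base}"
    return f"{complement(ref_base)}>{complement(alt_base)}"


def trinucleotide_class(
    ref_base: str, alt_base: str, five_prime: str, three_prime: str
) -> str:
    """Feature id ("X[R>A]Y") for a substitution with its flanking bases.

    Purine-reference substitutions are reverse-complemented together with
    their context (5'/3' swap plus complementation).
    """
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    five_prime, three_prime = five_prime.upper(), three_prime.upper()
    for b in (ref_base, alt_base, five_prime, three_prime):
        if b not in BASES:
            raise ValueError(f"non-ACGT base in trinucleotide context: {b!r}")
    sub = canonical_substitution(ref_base, alt_base)
    if ref_base not in PYRIMIDINES:
        five_prime, three_prime = complement(three_prime), complement(five_prime)
    return f"{five_prime}[{sub}]{three_prime}"


def profile_snv(
    vcf_path,
    reference: ReferenceAccessor | str,
    sample_id: str,
    pass_only: bool = True,
) -> ProfilingResult:
    """Scan a somatic VCF and count substitutions per trinucleotide class.

    Acceptance rules: single-base REF and ALT only (multi-allelic records
    are decomposed and each single-base ALT counted independently); by
    default only PASS/unfiltered records; the VCF REF must match the
    reference base at that position; records with an N flank or at a
    contig edge are skipped.  Every skipped allele is tallied by reason,
    so accepted + skipped equals the number of candidate alleles.
    """
    if not isinstance(reference, ReferenceAccessor):
        reference = ReferenceAccessor(reference)
    profile = FeatureProfile.zeros(sample_id, "SNV")
    tally = RecordTally()
    try:
        vcf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read VCF {vcf_path}: {exc}") from exc
    with vcf:
        for rec in vcf:
            filters = list(rec.filter.keys())
            if pass_only and filters and filters != ["PASS"]:
                tally.skip("non_pass_filter")
                continue
            if rec.ref is None or len(rec.ref) != 1 or rec.ref not in BASES:
                tally.skip("non_snv_ref")
                continue
            for alt in rec.alts or ():
                if alt is None or len(alt) != 1 or alt.upper() not in BASES:
                    tally.skip("non_snv_alt")
                    continue
                ref_at = reference.base(rec.chrom, rec.pos)
                if ref_at != rec.ref.upper():
                    tally.skip("ref_mismatch" if ref_at else "out_of_range")
                    continue
                five = reference.base(rec.chrom, rec.pos - 1)
                three = reference.base(rec.chrom, rec.pos + 1)
                if five is None or three is None:
                    tally.skip("contig_edge")
                    continue
                if "N" in (five, three):
                    tally.skip("n_context")
                    continue
                profile.add(trinucleotide_class(rec.ref, alt, five, three))
                tally.accepted += 1
    if tally.skipped:
        log.info(
            "SNV profiling %s: accepted %d, skipped %s",
            sample_id, tally.accepted, dict(tally.skipped),
        )
    return ProfilingResult(profile, tally)
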