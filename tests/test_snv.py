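"""Substitution classification and VCF profiling.

The 192 raw (substitution, context) combinations must fold 2-to-1 onto
the 96 pyrimidine-reference classes; the brute-force oracle here applies
reverse complementation independently of the implementation.
"""

from collections import Counter
from itertools import product

import numpy as np
import pytest

from cancersig.catalogs import build_snv_catalog
from cancersig.fixtures import make_reference, make_snv_vcf
from cancersig.seq import complement
from cancersig.snv import (
    ReferenceAccessor,
    canonical_substitution,
    profile_snv,
    trinucleotide_class,
)

BASES = "ACGT"


def oracle_class(ref, alt, five, three):
    """Independent classification: complement-fold purine references."""
    if ref in "AG":
        ref, alt = complement(ref), complement(alt)
        five, three = complement(three), complement(five)
    return f"{five}[{ref}>{alt}]{three}"


def test_canonical_substitution_is_two_to_one_onto_six_classes():
    mapping = {}
    for ref, alt in product(BASES, repeat=2):
        if ref == alt:
            continue
        mapping[(ref, alt)] = canonical_substitution(ref, alt)
    assert len(mapping) == 12
    counts = Counter(mapping.values())
    assert set(counts) == {"C>A", "C>G", "C>T", "T>A", "T>C", "T>G"}
    assert all(v == 2 for v in counts.values())
    # complement pairs share a class
    for (ref, alt), cls in mapping.items():
        assert mapping[(complement(ref), complement(alt))] == cls


def test_canonical_substitution_examples_and_errors():
    assert canonical_substitution("T", "C") == "T>C"
    assert canonical_substitution("C", "A") == "C>A"
    assert canonical_substitution("G", "T") == "C>A"
    with pytest.raises(ValueError):
        canonical_substitution("C", "C")
    with pytest.raises(ValueError):
        canonical_substitution("N", "A")


def test_trinucleotide_class_exhaustive_against_oracle():
    """All 192 combinations agree with the oracle; each of the 96 classes
    receives exactly two raw combinations (strand symmetry)."""
    catalog_ids = {f.feature_id for f in build_snv_catalog()}
    hits = Counter()
    for ref, alt, five, three in product(BASES, repeat=4):
        if ref == alt:
            continue
        got = trinucleotide_class(ref, alt, five, three)
        assert got == oracle_class(ref, alt, five, three)
        assert got in catalog_ids
        hits[got] += 1
    assert len(hits) == 96
    assert all(v == 2 for v in hits.values())


def test_trinucleotide_worked_example_and_purine_fold():
    assert trinucleotide_class("T", "C", "G", "G") == "G[T>C]G"
    assert trinucleotide_class("C", "T", "A", "A") == "A[C>T]A"
    assert trinucleotide_class("A", "G", "C", "T") == "A[T>C]G"


def test_profile_counts_planted_multiset_exactly(tmp_path, reference, reference_fasta):
    rng = np.random.default_rng(20)
    ids = [f.feature_id for f in build_snv_catalog()]
    planted = dict(Counter(rng.choice(ids, size=50).tolist()))
    truth = make_snv_vcf(reference, planted, seed=21, out_path=tmp_path / "t.vcf")
    result = profile_snv(tmp_path / "t.vcf", reference_fasta, "S1")
    observed = {k: v for k, v in result.profile.counts.items() if v}
    assert observed == {k: float(v) for k, v in truth.items()}
    assert result.tally.accepted == 50
    assert result.tally.total == 50
    assert result.profile.total() == 50


def test_strand_symmetric_representations_land_in_same_class(tmp_path, reference, reference_fasta):
    planted = {"G[T>C]G": 2, "A[C>T]A": 3}
    make_snv_vcf(reference, planted, 30, tmp_path / "pyr.vcf", purine_strand=False)
    make_snv_vcf(reference, planted, 31, tmp_path / "pur.vcf", purine_strand=True)
    pyr = profile_snv(tmp_path / "pyr.vcf", reference_fasta, "S1").profile.counts
    pur = profile_snv(tmp_path / "pur.vcf", reference_fasta, "S1").profile.counts
    assert pyr == pur


def test_empty_vcf_gives_all_zero_profile(tmp_path, reference, reference_fasta):
    make_snv_vcf(reference, {}, 5, tmp_path / "empty.vcf")
    result = profile_snv(tmp_path / "empty.vcf", reference_fasta, "S1")
    assert result.profile.total() == 0
    assert result.tally.total == 0


def test_skip_rules_are_tallied_not_dropped(tmp_path, reference, reference_fasta):
    """Non-PASS, REF-mismatch, indel and contig-edge records are skipped
    with reasons; accepted + skipped reconciles with input size."""
    seq = reference.sequences["chr1"]
    pos_mismatch = 500
    wrong_ref = next(b for b in BASES if b != seq[pos_mismatch - 1])
    alt = next(b for b in BASES if b not in (wrong_ref, seq[pos_mismatch - 1]))
    edge_ref = seq[0]
    edge_alt = next(b for b in BASES if b != edge_ref)
    r1000, r2000 = seq[999], seq[1999]
    extra = [
        f"chr1\t{pos_mismatch}\t.\t{wrong_ref}\t{alt}\t.\tPASS\t.",
        f"chr1\t1\t.\t{edge_ref}\t{edge_alt}\t.\tPASS\t.",  # 5' base out of range
        f"chr1\t1000\t.\t{r1000}\t{'A' if r1000 != 'A' else 'C'}\t.\tq10\t.",  # filtered
        f"chr1\t2000\t.\t{r2000}ACG\t{r2000}\t.\tPASS\t.",  # indel REF
    ]
    make_snv_vcf(reference, {"G[T>C]G": 1}, 40, tmp_path / "t.vcf", extra_records=extra)
    result = profile_snv(tmp_path / "t.vcf", reference_fasta, "S1")
    assert result.tally.accepted == 1
    assert result.tally.skipped["ref_mismatch"] == 1
    assert result.tally.skipped["contig_edge"] == 1
    assert result.tally.skipped["non_pass_filter"] == 1
    assert result.tally.skipped["non_snv_ref"] == 1
    assert result.tally.total == 5


def test_n_context_skipped(tmp_path):
    ref = make_reference(seed=2, contigs=("chr1",), length=5000, n_positions=(("chr1", 999),))
    fasta = ref.write(tmp_path / "ref.fa")
    seq = ref.sequences["chr1"]
    assert seq[998] == "N"
    base = seq[999]
    alt = next(b for b in BASES if b != base)
    extra = [f"chr1\t1000\t.\t{base}\t{alt}\t.\tPASS\t."]
    make_snv_vcf(ref, {}, 3, tmp_path / "t.vcf", extra_records=extra)
    result = profile_snv(tmp_path / "t.vcf", fasta, "S1")
    assert result.tally.skipped["n_context"] == 1
    assert result.tally.accepted == 0


def test_missing_contig_is_hard_error(tmp_path, reference, reference_fasta):
    extra = ["chrMISSING\t100\t.\tA\tC\t.\tPASS\t."]
    make_snv_vcf(reference, {}, 6, tmp_path / "t.vcf", extra_records=extra)
    with pytest.raises(KeyError, match="chrMISSING"):
        profile_snv(tmp_path / "t.vcf", reference_fasta, "S1")


def test_reference_accessor_contract(reference, reference_fasta):
    acc = ReferenceAccessor(reference_fasta)
    assert acc.base("chr1", 1) == reference.sequences["chr1"][0]
    assert acc.base("chr1", 0) is None
    assert acc.base("chr1", 10**9) is None
    with pytest.raises(KeyError):
        acc.base("nope", 1)
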