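"""Fixed feature catalogs for the three mutation groups.

The unified profile is a stack of three fixed catalogs: 96 single-base
substitution classes in trinucleotide context, 32 structural-variant
classes (4 event types x 8 log10 size bins) and 18 microsatellite
repeat-unit classes (16 canonical 1-3-mer unit patterns plus two
pattern-free classes for unit sizes 4 and 5).  Catalog order is
deterministic so that output tables are byte-stable across runs.
"""

from __future__ import annotations

from typing import NamedTuple

from .seq import BASES, canonical_unit_classes

SNV = "SNV"
SV = "SV"
MSI = "MSI"
GROUPS = (SNV, SV, MSI)

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

SV_CLASSES = ("deletion", "duplication", "inversion", "translocation")
SV_SIZE_BINS = (
    "100-1K",
    "1K-10K",
    "10K-100K",
    "100K-1M",
    "1M-10M",
    "10M-100M",
    "100M-1000M",
    "whole-chrom",
)


class FeatureDef(NamedTuple):
    """One row of the profile table.

    ``variant_type`` plays the COSMIC "Substitution Type" column role,
    ``subgroup`` the "Trinucleotide" role and ``feature_id`` the
    "Somatic Mutation Type" role; ``feature_id`` is unique across the
    full 146-feature catalog.
    """

    group: str
    variant_type: str
    subgroup: str
    feature_id: str


def build_snv_catalog() -> list[FeatureDef]:
    """The 96 substitution classes: 6 pyrimidine-reference substitutions
    x 4 5' bases x 4 3' bases, ordered substitution-major then 5' then 3'."""
    catalog = []
    for sub in SUBSTITUTION_CLASSES:
        ref = sub[0]
        for five in BASES:
            for three in BASES:
                catalog.append(
                    FeatureDef(SNV, sub, f"{five}{ref}{three}", f"{five}[{sub}]{three}")
                )
    return catalog


def build_sv_catalog() -> list[FeatureDef]:
    """The 32 structural classes: 4 event types x 8 size bins."""
    return [
        FeatureDef(SV, cls, size, f"{cls}:{size}")
        for cls in SV_CLASSES
        for size in SV_SIZE_BINS
    ]


def build_msi_catalog() -> list[FeatureDef]:
    """The 18 microsatellite classes.

    16 canonical repeat-unit patterns of size 1-3 (closure of all 1-3-mers
    under rotation/reverse-complement canonicalization) plus the two
    pattern-free size classes ``unit4`` and ``unit5``.
    """
    units = canonical_unit_classes(3) + ["unit4", "unit5"]
    return [FeatureDef(MSI, "repeat", unit, f"repeat:{unit}") for unit in units]


def build_full_catalog() -> list[FeatureDef]:
    """All 146 features in canonical group order SNV, SV, MSI."""
    return build_snv_catalog() + build_sv_catalog() + build_msi_catalog()


def catalog_for_group(group: str) -> list[FeatureDef]:
    builders = {SNV: build_snv_catalog, SV: build_sv_catalog, MSI: build_msi_catalog}
    try:
        return builders[group]()
    except KeyError:
        raise ValueError(f"unknown mutation group: {group!r}") from None
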