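"""Structural-variant profiling.

Classifies SV records (deletion, duplication, inversion, translocation)
into 8 log10 size bins.  Deletion/duplication/inversion size is the
number of bases lost/gained/inverted (END - POS).  Translocation size is
the distance between the origin and destination breakpoints: a 100 bp
segment moved from 20 Mb to 25 Mb on one chromosome is a 5 Mb event, and
any inter-chromosomal event has infinite size, which lands it in the
whole-chromosome bin.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

import pysam

from .catalogs import SV_SIZE_BINS
from .matrix import FeatureProfile, ProfilingResult, RecordTally

log = logging.getLogger(__name__)

INFINITE = math.inf
MIN_EVENT_SIZE = 100  # catalog starts at 100 bp; smaller events are logged

_SVTYPE_MAP = {
    "DEL": "deletion",
    "DUP": "duplication",
    "INV": "inversion",
    "TRA": "translocation",
    "BND": "translocation",
}

_BND_MATE_RE = re.compile(r"[\[\]]([^\[\]:]+):(\d+)[\[\]]")


@dataclass
class SvEvent:
    """A classified structural event ready for size-binning."""

    chrom: str
    pos: int
    sv_class: str
    end: int | None = None
    chr2: str | None = None

    @property
    def inter_chromosomal(self) -> bool:
        return self.chr2 is not None and self.chr2 != self.chrom


def classify_sv_type(svtype: str | None) -> str:
    """Map an SVTYPE INFO tag onto the four event classes; DUP subtypes
    (e.g. DUP:TANDEM) count as duplication; TRA and BND are translocations."""
    if not svtype:
        raise ValueError("missing SVTYPE tag")
    base = svtype.upper().split(":")[0]
    try:
        return _SVTYPE_MAP[base]
    except KeyError:
        raise ValueError(f"unknown SVTYPE {svtype!r}") from None


def event_size(event: SvEvent) -> float:
    """Event size in base pairs, or INFINITE for inter-chromosomal events."""
    if event.inter_chromosomal:
        return INFINITE
    if event.end is None:
        raise ValueError(f"intra-chromosomal event at {event.chrom}:{event.pos} lacks END")
    size = abs(event.end - event.pos)
    if size <= 0:
        raise ValueError(
            f"non-positive event size {size} at {event.chrom}:{event.pos}-{event.end}"
        )
    return float(size)


def size_bin(size: float, contig_length: int | None = None) -> str:
    """One of the 8 size bins for an event size in bp.

    Finite bins are half-open, lower-inclusive decades [10^k, 10^(k+1))
    for k=2..8.  Infinite sizes, sizes >= 1e9 and intra-chromosomal events
    spanning at least the declared contig length fall in the
    whole-chromosome bin.  Sizes below 100 bp are below the catalog.
    """
    if size == INFINITE:
        return SV_SIZE_BINS[-1]
    if size < MIN_EVENT_SIZE:
        raise ValueError(f"event size {size} below the 100 bp catalog floor")
    if contig_length is not None and size >= contig_length:
        return SV_SIZE_BINS[-1]
    k = int(math.floor(math.log10(size)))
    if k > 8:
        return SV_SIZE_BINS[-1]
    return SV_SIZE_BINS[k - 2]


def parse_bnd_mate(alt: str) -> tuple[str, int] | None:
    """Mate (contig, position) from a breakend ALT like ``N[chr2:321682[``."""
    m = _BND_MATE_RE.search(alt)
    if m is None:
        return None
    return m.group(1), int(m.group(2))


def _record_event(rec, tally: RecordTally) -> SvEvent | None:
    """Build an SvEvent from a VCF record; tally and return None on skip."""
    svtype = rec.info.get("SVTYPE")
    try:
        sv_class = classify_sv_type(svtype)
    except ValueError:
        tally.skip("missing_svtype" if not svtype else "unknown_svtype")
        return None

    alt = (rec.alts or ("",))[0] or ""
    mate = parse_bnd_mate(alt)
    if sv_class == "translocation" and mate is not None:
        # breakend pair: count only the record ordered first of the pair
        if (mate[0], mate[1]) < (rec.chrom, rec.pos):
            tally.skip("breakend_mate")
            return None
        chr2 = rec.info.get("CHR2", mate[0])
        return SvEvent(rec.chrom, rec.pos, sv_class, end=mate[1], chr2=chr2)

    chr2 = rec.info.get("CHR2", rec.chrom)
    end = rec.stop if rec.stop and rec.stop > 0 else None
    if end is None or end == rec.pos:
        svlen = rec.info.get("SVLEN")
        if isinstance(svlen, tuple):
            svlen = svlen[0]
        if svlen:
            end = rec.pos + abs(int(svlen))
    return SvEvent(rec.chrom, rec.pos, sv_class, end=end, chr2=chr2)


def profile_sv(vcf_path, sample_id: str) -> ProfilingResult:
    """Scan an SV VCF (SVTYPE/END/CHR2 tags or BND mate notation) and
    count events per (class, size bin).

    Breakend mate pairs are counted once.  Records with an unknown or
    missing SVTYPE, a non-positive size, or a size below 100 bp are
    skipped and tallied, so accepted + skipped = total records.
    """
    profile = FeatureProfile.zeros(sample_id, "SV")
    tally = RecordTally()
    try:
        vcf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read VCF {vcf_path}: {exc}") from exc
    with vcf:
        contig_lengths = {
            name: contig.length for name, contig in vcf.header.contigs.items()
        }
        for rec in vcf:
            event = _record_event(rec, tally)
            if event is None:
                continue
            try:
                size = event_size(event)
            except ValueError:
                tally.skip("bad_size")
                continue
            try:
                bin_label = size_bin(size, contig_lengths.get(event.chrom))
            except ValueError:
                tally.skip("below_100bp")
                continue
            profile.add(f"{event.sv_class}:{bin_label}")
            tally.accepted += 1
    if tally.skipped:
        log.info(
            "SV profiling %s: accepted %d, skipped %s",
            sample_id, tally.accepted, dict(tally.skipped),
        )
    return ProfilingResult(profile, tally)
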