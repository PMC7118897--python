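"""Microsatellite-instability profiling.

Quantifies unstable microsatellite loci (as reported by an upstream MSI
caller such as MSIsensor) per canonical repeat-unit class: 16 canonical
1-3-mer unit patterns (equivalence classes under cyclic rotation and
reverse complementation) plus the pattern-free size classes unit4/unit5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .matrix import FeatureProfile, ProfilingResult, RecordTally
from .seq import canonical_repeat_unit

log = logging.getLogger(__name__)

__all__ = ["MsiLocus", "canonical_repeat_unit", "parse_msisensor_line", "profile_msi"]


@dataclass
class MsiLocus:
    chrom: str
    pos: int
    left_flank: str
    repeat_unit: str
    repeat_times: int
    right_flank: str


def parse_msisensor_line(line: str) -> MsiLocus:
    """Parse one MSIsensor-style somatic-site row:
    chromosome, location, left flank, repeat unit, repeat times, right flank
    (whitespace- or tab-delimited; extra trailing columns ignored)."""
    parts = line.split()
    if len(parts) < 6:
        raise ValueError(f"expected >= 6 whitespace-delimited fields, got {len(parts)}")
    chrom, pos, left, unit, times, right = parts[:6]
    return MsiLocus(chrom, int(pos), left, unit.upper(), int(times), right)


def profile_msi(msisensor_path, sample_id: str) -> ProfilingResult:
    """Count unstable loci per canonical repeat-unit class.

    A header line (second field non-numeric) is skipped without being
    tallied as a data row.  Malformed rows and units outside the 1-5 bp
    ACGT alphabet are skipped with a logged tally, so accepted + skipped
    equals the number of data rows.
    """
    path = Path(msisensor_path)
    profile = FeatureProfile.zeros(sample_id, "MSI")
    tally = RecordTally()
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise OSError(f"cannot read MSI table {path}: {exc}") from exc
    for lineno, line in enumerate(lines, 1):
        if not line.strip():
            continue
        fields = line.split()
        if lineno == 1 and len(fields) >= 2 and not fields[1].isdigit():
            continue  # header row
        try:
            locus = parse_msisensor_line(line)
            label = canonical_repeat_unit(locus.repeat_unit)
        except ValueError as exc:
            tally.skip("malformed_row")
            log.debug("MSI row %d skipped: %s", lineno, exc)
            continue
        profile.add(f"repeat:{label}")
        tally.accepted += 1
    if tally.skipped:
        log.info(
            "MSI profiling %s: accepted %d, skipped %s",
            sample_id, tally.accepted, dict(tally.skipped),
        )
    return ProfilingResult(profile, tally)
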