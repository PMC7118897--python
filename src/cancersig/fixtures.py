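"""Deterministic synthetic inputs for every pipeline stage.

Generates a mini reference genome, somatic SNV and SV VCFs, MSI locus
tables and planted-signature cohorts with known ground truth, so the
whole workflow is testable without external data.  Everything is emitted
through the public file formats (FASTA/VCF/tab tables) so the real
parsers are exercised, and every generator is seed-deterministic.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .catalogs import build_full_catalog, build_msi_catalog, build_snv_catalog, build_sv_catalog
from .matrix import FeatureMatrix
from .seq import BASES, complement, revcomp, rotations

# per-sample event totals for cohort-scale fixtures
DEFAULT_EVENTS = {"SNV": 5000, "SV": 200, "MSI": 100}


# ----------------------------------------------------------------- reference

@dataclass
class ReferenceFixture:
    sequences: dict[str, str]

    def write(self, path) -> Path:
        path = Path(path)
        with path.open("w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        return path

    def triplet_positions(self) -> dict[tuple[str, str, str], list[tuple[str, int]]]:
        """All (5', ref, 3') -> [(chrom, 1-based pos)] interior positions."""
        index: dict[tuple[str, str, str], list[tuple[str, int]]] = {}
        for chrom, seq in self.sequences.items():
            for i in range(1, len(seq) - 1):
                key = (seq[i - 1], seq[i], seq[i + 1])
                if "N" in key:
                    continue
                index.setdefault(key, []).append((chrom, i + 1))
        return index


def make_reference(
    seed: int,
    contigs: tuple[str, ...] = ("chr1", "chr2"),
    length: int = 20000,
    n_positions: tuple[tuple[str, int], ...] = (),
) -> ReferenceFixture:
    """Random ACGT reference; optional N injection at recorded positions."""
    if length < 3:
        raise ValueError("contig length must be at least 3")
    rng = np.random.default_rng(seed)
    sequences = {}
    for name in contigs:
        seq = rng.choice(list(BASES), size=length)
        sequences[name] = "".join(seq)
    for chrom, pos in n_positions:
        s = sequences[chrom]
        sequences[chrom] = s[: pos - 1] + "N" + s[pos:]
    return ReferenceFixture(sequences)


# ----------------------------------------------------------------- VCF text

def _write_vcf(path, contigs: dict[str, int], body_lines: list[str]) -> Path:
    path = Path(path)
    header = ["##fileformat=VCFv4.2"]
    header += [f"##contig=<ID={c},length={l}>" for c, l in contigs.items()]
    filters = {line.split("\t")[6] for line in body_lines} - {"PASS", "."}
    header += [f'##FILTER=<ID={f},Description="planted">' for f in sorted(filters)]
    header += [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=CHR2,Number=1,Type=String,Description="Partner chromosome">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Breakend mate">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    path.write_text("\n".join(header + body_lines) + "\n")
    return path


def make_snv_vcf(
    reference: ReferenceFixture,
    planted: dict[str, int] | list[str],
    seed: int,
    out_path,
    purine_strand: bool = False,
    extra_records: list[str] = (),
) -> Counter:
    """Plant substitutions realizing the requested trinucleotide classes.

    ``planted`` maps feature ids ("G[T>C]G") to counts.  Each variant is
    placed at a reference position whose flanks realize the class; with
    ``purine_strand`` the reverse-complement representation is emitted
    instead (same class by strand symmetry).  Returns the ground-truth
    class counts; ``extra_records`` are appended verbatim (for skip-rule
    tests) and are not part of the ground truth.
    """
    if isinstance(planted, list):
        planted = dict(Counter(planted))
    valid = {f.feature_id for f in build_snv_catalog()}
    unknown = set(planted) - valid
    if unknown:
        raise ValueError(f"unknown SNV feature ids: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    index = reference.triplet_positions()
    used: set[tuple[str, int]] = set()
    records = []
    truth: Counter = Counter()
    for fid, count in sorted(planted.items()):
        five, ref, alt, three = fid[0], fid[2], fid[4], fid[6]
        if purine_strand:
            ref, alt = complement(ref), complement(alt)
            five, three = complement(three), complement(five)
        sites = [p for p in index.get((five, ref, three), []) if p not in used]
        if len(sites) < count:
            raise ValueError(
                f"reference too small to realize {count} x {fid} "
                f"({len(sites)} sites available); use a longer reference"
            )
        chosen = rng.choice(len(sites), size=count, replace=False)
        for i in chosen:
            chrom, pos = sites[int(i)]
            used.add((chrom, pos))
            records.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.")
            truth[fid] += 1
    records += list(extra_records)
    records.sort(key=lambda r: (r.split("\t")[0], int(r.split("\t")[1])))
    contigs = {c: len(s) for c, s in reference.sequences.items()}
    _write_vcf(out_path, contigs, records)
    return truth


# -------------------------------------------------------------------- SV VCF

@dataclass
class PlantedSv:
    sv_class: str            # deletion | duplication | inversion | translocation
    size: float              # bp, or math.inf for inter-chromosomal

    def feature_id(self) -> str:
        from .sv import size_bin

        return f"{self.sv_class}:{size_bin(self.size)}"


_SV_TYPE_TAG = {"deletion": "DEL", "duplication": "DUP", "inversion": "INV"}


def make_sv_vcf(
    planted: list[PlantedSv],
    seed: int,
    out_path,
    contig_length: int = 2_000_000_000,
    extra_records: list[str] = (),
) -> Counter:
    """Plant SV events on two synthetic contigs.

    Intra-chromosomal events carry SVTYPE/END (translocations also CHR2);
    inter-chromosomal translocations (size = inf) are written as breakend
    mate pairs, which the profiler must count once.  Returns ground-truth
    feature counts.
    """
    rng = np.random.default_rng(seed)
    contigs = {"chrA": contig_length, "chrB": contig_length}
    records = []
    truth: Counter = Counter()
    for i, ev in enumerate(planted):
        truth[ev.feature_id()] += 1
        if ev.sv_class == "translocation" and math.isinf(ev.size):
            pos1 = int(rng.integers(1000, contig_length // 2))
            pos2 = int(rng.integers(1000, contig_length // 2))
            records.append(
                f"chrA\t{pos1}\tbnd_{i}a\tN\tN[chrB:{pos2}[\t.\tPASS\t"
                f"SVTYPE=BND;MATEID=bnd_{i}b"
            )
            records.append(
                f"chrB\t{pos2}\tbnd_{i}b\tN\tN]chrA:{pos1}]\t.\tPASS\t"
                f"SVTYPE=BND;MATEID=bnd_{i}a"
            )
            continue
        size = int(ev.size)
        # keep END within htslib's int32 INFO limit for billion-bp events
        hi = max(1001, min(contig_length - size, 500_000_000))
        pos = int(rng.integers(1000, hi))
        end = pos + size
        if ev.sv_class == "translocation":
            records.append(
                f"chrA\t{pos}\ttra_{i}\tN\t<TRA>\t.\tPASS\t"
                f"SVTYPE=TRA;END={end};CHR2=chrA"
            )
        else:
            tag = _SV_TYPE_TAG[ev.sv_class]
            records.append(
                f"chrA\t{pos}\tsv_{i}\tN\t<{tag}>\t.\tPASS\tSVTYPE={tag};END={end}"
            )
    records += list(extra_records)
    records.sort(key=lambda r: (r.split("\t")[0], int(r.split("\t")[1])))
    _write_vcf(out_path, contigs, records)
    return truth


# ----------------------------------------------------------------- MSI table

def make_msi_table(
    planted: list[str] | dict[str, int],
    seed: int,
    out_path,
    extra_rows: list[str] = (),
) -> Counter:
    """Plant unstable loci whose repeat units canonicalize to the
    requested classes (catalog subgroup labels, e.g. "AC" or "unit4").

    A concrete unit is drawn among the rotations/reverse-complement
    rotations of the class so canonicalization is genuinely exercised.
    """
    if isinstance(planted, list):
        planted = dict(Counter(planted))
    valid = {f.subgroup for f in build_msi_catalog()}
    unknown = set(planted) - valid
    if unknown:
        raise ValueError(f"unknown MSI classes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = ["chromosome\tlocation\tleft_flank\trepeat_unit\trepeat_times\tright_flank"]
    truth: Counter = Counter()
    pos = 1000
    for label, count in sorted(planted.items()):
        if label == "unit4":
            variants = ["".join(rng.choice(list(BASES), size=4)) for _ in range(count)]
        elif label == "unit5":
            variants = ["".join(rng.choice(list(BASES), size=5)) for _ in range(count)]
        else:
            pool = sorted(set(rotations(label) + rotations(revcomp(label))))
            variants = [pool[int(i)] for i in rng.integers(0, len(pool), size=count)]
        for unit in variants:
            times = int(rng.integers(5, 20))
            rows.append(f"chr1\t{pos}\tACGTA\t{unit}\t{times}\tTACGT")
            truth[label] += 1
            pos += 100
    rows += list(extra_rows)
    Path(out_path).write_text("\n".join(rows) + "\n")
    return truth


# ---------------------------------------------------------- planted cohorts

@dataclass
class PlantedCohort:
    P0: np.ndarray               # features x k true signatures
    E0: np.ndarray               # k x n true exposure fractions
    counts: np.ndarray           # features x n multinomial event counts
    matrix: FeatureMatrix        # counts normalized per column (fractions)
    events_per_sample: int
    seed: int


def make_planted_cohort(
    k: int,
    n_samples: int,
    separation: float = 0.3,
    events_per_sample: int = 5000,
    seed: int = 0,
    support_size: int = 25,
) -> PlantedCohort:
    """Cohort with k planted signatures and multinomial sampling noise.

    Each true signature is a Dirichlet draw concentrated on a random
    feature subset; generation retries until all pairwise cosines fall
    below ``separation``.  Per-sample counts are multinomial draws of
    ``events_per_sample`` events from the mixed profile P0 @ E0[:, j].
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_samples <= k:
        raise ValueError("need more samples than signatures")
    catalog = build_full_catalog()
    n_features = len(catalog)
    rng = np.random.default_rng(seed)
    for _attempt in range(200):
        P0 = np.zeros((n_features, k))
        for j in range(k):
            support = rng.choice(n_features, size=support_size, replace=False)
            P0[support, j] = rng.dirichlet(np.full(support_size, 0.5))
        if k == 1:
            break
        U = P0 / np.linalg.norm(P0, axis=0)
        sim = U.T @ U
        if np.max(sim[~np.eye(k, dtype=bool)]) < separation:
            break
    else:
        raise ValueError(
            f"could not realize pairwise cosine < {separation} for k={k}"
        )
    E0 = rng.dirichlet(np.full(k, 0.5), size=n_samples).T
    mix = P0 @ E0
    counts = np.column_stack(
        [rng.multinomial(events_per_sample, mix[:, j]) for j in range(n_samples)]
    ).astype(float)
    fractions = counts / events_per_sample
    samples = [f"S{j:03d}" for j in range(n_samples)]
    matrix = FeatureMatrix(catalog, samples, fractions)
    return PlantedCohort(P0, E0, counts, matrix, events_per_sample, seed)


# -------------------------------------------------------------- toy presets

def write_toy_cohort(out_dir, seed: int, n_samples: int = 3) -> dict:
    """Ready-to-run toy cohort: reference FASTA plus per-sample SNV VCF,
    SV VCF and MSI table, with the ground truth serialized alongside."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    reference = make_reference(seed, contigs=("chr1", "chr2"), length=30000)
    ref_path = reference.write(out_dir / "reference.fa")

    snv_ids = [f.feature_id for f in build_snv_catalog()]
    sv_defs = build_sv_catalog()
    msi_labels = [f.subgroup for f in build_msi_catalog()]

    manifest = {"seed": seed, "reference": str(ref_path), "samples": {}}
    for s in range(n_samples):
        sample = f"TOY{s:02d}"
        snv_plant = dict(
            Counter(rng.choice(snv_ids, size=60).tolist())
        )
        snv_truth = make_snv_vcf(
            reference, snv_plant, seed + 11 * s, out_dir / f"{sample}.snv.vcf"
        )
        events = []
        for _ in range(12):
            d = sv_defs[int(rng.integers(len(sv_defs)))]
            if d.subgroup == "whole-chrom":
                events.append(PlantedSv("translocation", math.inf))
            else:
                low = 10 ** (list(sv_defs).index(d) % 8 + 2)
                events.append(PlantedSv(d.variant_type, float(low * 2)))
        sv_truth = make_sv_vcf(events, seed + 13 * s, out_dir / f"{sample}.sv.vcf")
        msi_plant = dict(Counter(rng.choice(msi_labels, size=15).tolist()))
        msi_truth = make_msi_table(
            msi_plant, seed + 17 * s, out_dir / f"{sample}.msi.txt"
        )
        manifest["samples"][sample] = {
            "snv_vcf": str(out_dir / f"{sample}.snv.vcf"),
            "sv_vcf": str(out_dir / f"{sample}.sv.vcf"),
            "msi_table": str(out_dir / f"{sample}.msi.txt"),
            "snv_truth": dict(snv_truth),
            "sv_truth": dict(sv_truth),
            "msi_truth": dict(msi_truth),
        }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
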