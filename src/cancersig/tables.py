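"""Tab-delimited profile/signature tables in the COSMIC-style layout.

Column 1 is the variant type (COSMIC "Substitution Type" role), column 2
the variant subgroup ("Trinucleotide" role), column 3 the feature id
("Somatic Mutation Type" role); column 4 onward holds one sample — or,
for a signature-probability table, one signature — per column.  The same
layout therefore serves profiles, merged matrices and COSMIC/WTSI-format
signature tables supplied for refit-only runs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .catalogs import FeatureDef, GROUPS, build_full_catalog
from .matrix import FeatureMatrix, FeatureProfile, SignatureMatrix

HEADER = ("Variant type", "Variant subgroup", "Feature ID")


class ProfileTableError(ValueError):
    """Malformed profile/signature table."""


def _full_index() -> dict[str, FeatureDef]:
    return {f.feature_id: f for f in build_full_catalog()}


def write_profile_table(matrix, path) -> None:
    """Write a FeatureMatrix/SignatureMatrix (or list of same-group
    FeatureProfiles) as a COSMIC-layout tab-delimited table.

    Values are printed with 17 significant digits so a read/write
    round-trip is stable to 1e-12 and output is byte-identical for
    identical inputs.
    """
    if isinstance(matrix, list):
        matrix = FeatureMatrix.from_profiles(matrix)
    if isinstance(matrix, SignatureMatrix):
        columns = matrix.signatures
    else:
        columns = matrix.samples
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(HEADER + tuple(columns)) + "\n")
        for i, feat in enumerate(matrix.features):
            row = [feat.variant_type, feat.subgroup, feat.feature_id]
            row += [format(v, ".17g") for v in matrix.values[i]]
            fh.write("\t".join(row) + "\n")


def read_profile_table(path) -> FeatureMatrix:
    """Read a COSMIC-layout table back into a FeatureMatrix.

    Rows are re-ordered to canonical catalog order.  Unknown feature ids,
    negative values and malformed headers are rejected with the offending
    row/column named.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ProfileTableError(f"{path}: unreadable table: {exc}") from exc
    if df.shape[1] < 4:
        raise ProfileTableError(
            f"{path}: expected at least 4 tab-delimited columns, found {df.shape[1]}"
        )
    if tuple(df.columns[:3]) != HEADER:
        raise ProfileTableError(
            f"{path}: malformed header {tuple(df.columns[:3])!r}, expected {HEADER!r}"
        )
    samples = list(df.columns[3:])
    if len(set(samples)) != len(samples):
        raise ProfileTableError(f"{path}: duplicate sample columns")

    index = _full_index()
    features: list[FeatureDef] = []
    rows = np.empty((len(df), len(samples)), dtype=float)
    for i, rec in enumerate(df.itertuples(index=False)):
        fid = rec[2]
        feat = index.get(fid)
        if feat is None:
            raise ProfileTableError(f"{path}: row {i + 2}: unknown feature id {fid!r}")
        features.append(feat)
        for j, sample in enumerate(samples):
            raw = rec[3 + j]
            try:
                v = float(raw)
            except (TypeError, ValueError):
                raise ProfileTableError(
                    f"{path}: row {i + 2}, column {sample!r}: "
                    f"non-numeric value {raw!r} for feature {fid!r}"
                ) from None
            if not np.isfinite(v) or v < 0:
                raise ProfileTableError(
                    f"{path}: row {i + 2}, column {sample!r}: "
                    f"negative or non-finite value {v!r} for feature {fid!r}"
                )
            rows[i, j] = v
    ids = [f.feature_id for f in features]
    if len(set(ids)) != len(ids):
        raise ProfileTableError(f"{path}: duplicate feature rows")

    # canonical order: group order SNV, SV, MSI, catalog order within group
    order = {f.feature_id: i for i, f in enumerate(build_full_catalog())}
    perm = sorted(range(len(features)), key=lambda i: order[features[i].feature_id])
    features = [features[i] for i in perm]
    return FeatureMatrix(features, samples, rows[perm])


def as_signature_matrix(matrix: FeatureMatrix) -> SignatureMatrix:
    """Reinterpret a table's sample columns as signature columns
    (COSMIC/WTSI signature-probability input)."""
    sig = SignatureMatrix(matrix.features, list(matrix.samples), matrix.values)
    sig.validate_stochastic()
    return sig


def profiles_from_matrix(matrix: FeatureMatrix) -> dict[str, dict[str, FeatureProfile]]:
    """Split a (possibly multi-group) count table into per-sample,
    per-group FeatureProfiles; absent groups are omitted."""
    out: dict[str, dict[str, FeatureProfile]] = {s: {} for s in matrix.samples}
    for g in GROUPS:
        mask = [f.group == g for f in matrix.features]
        feats = [f for f in matrix.features if f.group == g]
        if not feats:
            continue
        block = matrix.values[np.array(mask)]
        for j, sample in enumerate(matrix.samples):
            prof = FeatureProfile.zeros(sample, g)
            for f, v in zip(feats, block[:, j]):
                prof.counts[f.feature_id] = float(v)
            out[sample][g] = prof
    return out


def read_weights_config(path) -> "FeatureWeights":
    """Read the feature-selection (group weight) config: lines of
    ``GROUP<TAB or spaces>weight``; groups SNV/SV/MSI; must sum to 1."""
    from .matrix import FeatureWeights

    weights = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2 or parts[0].upper() not in GROUPS:
            raise ProfileTableError(
                f"{path}: line {lineno}: expected 'SNV|SV|MSI <weight>', got {line!r}"
            )
        weights[parts[0].upper()] = float(parts[1])
    missing = set(GROUPS) - set(weights)
    if missing:
        raise ProfileTableError(f"{path}: missing weight for group(s) {sorted(missing)}")
    return FeatureWeights(snv=weights["SNV"], sv=weights["SV"], msi=weights["MSI"])
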