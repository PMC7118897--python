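"""In-memory containers shared by every pipeline stage.

A :class:`FeatureProfile` holds per-sample raw counts for one mutation
group; counts stay raw until the merge stage so that burden metrics
(TMB, SVB) remain computable.  :class:`FeatureMatrix` is the
features-x-samples table M, :class:`SignatureMatrix` the features-x-k
probability table P, and :class:`ExposureMatrix` the k-x-samples table E.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalogs import FeatureDef, GROUPS, SNV, SV, MSI, catalog_for_group

COLSUM_TOL = 1e-9


@dataclass
class FeatureProfile:
    """Per-sample counts over one group's fixed feature catalog."""

    sample_id: str
    group: str
    counts: dict[str, float]

    @classmethod
    def zeros(cls, sample_id: str, group: str) -> "FeatureProfile":
        return cls(sample_id, group, {f.feature_id: 0.0 for f in catalog_for_group(group)})

    def add(self, feature_id: str, n: float = 1.0) -> None:
        if feature_id not in self.counts:
            raise KeyError(f"feature {feature_id!r} not in the {self.group} catalog")
        self.counts[feature_id] += n

    def total(self) -> float:
        return float(sum(self.counts.values()))

    def vector(self) -> np.ndarray:
        return np.array(
            [self.counts[f.feature_id] for f in catalog_for_group(self.group)], dtype=float
        )

    def validate(self) -> None:
        catalog_ids = {f.feature_id for f in catalog_for_group(self.group)}
        if set(self.counts) != catalog_ids:
            extra = set(self.counts) - catalog_ids
            missing = catalog_ids - set(self.counts)
            raise ValueError(
                f"profile keys do not match the {self.group} catalog "
                f"(extra={sorted(extra)[:3]}, missing={sorted(missing)[:3]})"
            )
        for fid, c in self.counts.items():
            if not np.isfinite(c) or c < 0:
                raise ValueError(f"negative or non-finite count for feature {fid!r}: {c}")


@dataclass
class RecordTally:
    """Accounting of input records: accepted + skipped (by reason) = total."""

    accepted: int = 0
    skipped: Counter = field(default_factory=Counter)

    def skip(self, reason: str) -> None:
        self.skipped[reason] += 1

    @property
    def n_skipped(self) -> int:
        return sum(self.skipped.values())

    @property
    def total(self) -> int:
        return self.accepted + self.n_skipped


@dataclass
class ProfilingResult:
    """A profile together with its record accounting."""

    profile: FeatureProfile
    tally: RecordTally


@dataclass(frozen=True)
class FeatureWeights:
    """Relative weight of each mutation group in the merged profile.

    Defaults follow the 7:2:1 SNV:SV:MSI weighting; each group block of a
    merged column sums to its weight, capping the fraction any one
    mutation mode can contribute regardless of raw event counts.
    """

    snv: float = 0.7
    sv: float = 0.2
    msi: float = 0.1

    def __post_init__(self) -> None:
        for w in (self.snv, self.sv, self.msi):
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"group weight out of [0,1]: {w}")
        if abs(self.snv + self.sv + self.msi - 1.0) > COLSUM_TOL:
            raise ValueError(
                f"group weights must sum to 1, got {self.snv + self.sv + self.msi}"
            )

    def for_group(self, group: str) -> float:
        return {SNV: self.snv, SV: self.sv, MSI: self.msi}[group]


def _check_features_values(features, n_cols, values, col_kind):
    values = np.asarray(values, dtype=float)
    if values.shape != (len(features), n_cols):
        raise ValueError(
            f"values shape {values.shape} does not match "
            f"{len(features)} features x {n_cols} {col_kind}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite entries in matrix")
    if np.any(values < 0):
        raise ValueError("negative entries in matrix")
    return values


@dataclass
class FeatureMatrix:
    """Features x samples matrix (counts for single-group profiles, or
    column-stochastic fractions after merging)."""

    features: list[FeatureDef]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        ids = [f.feature_id for f in self.features]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature ids")
        self.values = _check_features_values(
            self.features, len(self.samples), self.values, "samples"
        )

    @classmethod
    def from_profiles(cls, profiles: list[FeatureProfile]) -> "FeatureMatrix":
        """Stack same-group profiles column-wise in the given sample order."""
        groups = {p.group for p in profiles}
        if len(groups) != 1:
            raise ValueError(f"profiles span multiple groups: {sorted(groups)}")
        catalog = catalog_for_group(groups.pop())
        samples = [p.sample_id for p in profiles]
        values = np.column_stack([p.vector() for p in profiles])
        return cls(catalog, samples, values)

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.samples)

    def group_block(self, group: str) -> np.ndarray:
        mask = np.array([f.group == group for f in self.features])
        return self.values[mask]

    def groups(self) -> list[str]:
        return [g for g in GROUPS if any(f.group == g for f in self.features)]

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.samples.index(sample_id)]

    def validate_stochastic(self, weights: "FeatureWeights | None" = None) -> None:
        """Check column sums equal 1 and, if weights given, group-block sums."""
        colsums = self.values.sum(axis=0)
        bad = np.where(np.abs(colsums - 1.0) > COLSUM_TOL)[0]
        if bad.size:
            j = bad[0]
            raise ValueError(
                f"column {self.samples[j]!r} sums to {colsums[j]!r}, expected 1"
            )
        if weights is not None:
            for g in self.groups():
                target = weights.for_group(g)
                sums = self.group_block(g).sum(axis=0)
                bad = np.where(np.abs(sums - target) > COLSUM_TOL)[0]
                # all-zero blocks are allowed under the zero-fill merge policy
                bad = [j for j in bad if sums[j] != 0.0]
                if bad:
                    j = bad[0]
                    raise ValueError(
                        f"{g} block of column {self.samples[j]!r} sums to "
                        f"{sums[j]!r}, expected {target}"
                    )


@dataclass
class SignatureMatrix:
    """Features x k signature-probability matrix P; columns sum to 1."""

    features: list[FeatureDef]
    signatures: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_features_values(
            self.features, len(self.signatures), self.values, "signatures"
        )

    @property
    def k(self) -> int:
        return len(self.signatures)

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.signatures)

    def validate_stochastic(self) -> None:
        colsums = self.values.sum(axis=0)
        bad = np.where(np.abs(colsums - 1.0) > COLSUM_TOL)[0]
        if bad.size:
            j = bad[0]
            raise ValueError(
                f"signature {self.signatures[j]!r} sums to {colsums[j]!r}, expected 1"
            )


@dataclass
class ExposureMatrix:
    """Signatures x samples non-negative exposures E."""

    signatures: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_features_values(
            [(s,) for s in self.signatures], len(self.samples), self.values, "samples"
        )

    def normalized(self) -> "ExposureMatrix":
        """Per-column fractions; all-zero columns stay zero."""
        sums = self.values.sum(axis=0)
        out = np.divide(
            self.values, sums, out=np.zeros_like(self.values), where=sums > 0
        )
        return ExposureMatrix(self.signatures, self.samples, out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.signatures, columns=self.samples)
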