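"""Merge per-sample SNV/SV/MSI profiles into one weighted feature matrix.

Within each mutation group a sample's counts are normalized to fractions
summing to 1 and then scaled by the group weight (default 7:2:1 for
SNV:SV:MSI), so every merged column sums to 1 and every group block sums
to its weight.  This caps the contribution of any single mutation mode —
a hypermutated sample's substitutions can never drown out its structural
or microsatellite features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalogs import GROUPS, build_full_catalog, catalog_for_group
from .matrix import FeatureMatrix, FeatureProfile, FeatureWeights


@dataclass
class MergeConfig:
    weights: FeatureWeights = field(default_factory=FeatureWeights)
    missing_group_policy: str = "error"  # "error" | "zero-fill"

    def __post_init__(self) -> None:
        if self.missing_group_policy not in ("error", "zero-fill"):
            raise ValueError(
                f"missing_group_policy must be 'error' or 'zero-fill', "
                f"got {self.missing_group_policy!r}"
            )


def merge_profiles(
    profiles: dict[str, dict[str, FeatureProfile]],
    config: MergeConfig | None = None,
) -> FeatureMatrix:
    """Build the merged matrix M from ``{sample: {group: profile}}``.

    Under the ``error`` policy every sample must carry a profile with a
    positive total for every group; under ``zero-fill`` an absent or
    empty group becomes a zero block and the remaining groups are
    re-normalized so the column still sums to 1 (keeping M
    column-stochastic for factorization).
    """
    config = config or MergeConfig()
    if not profiles:
        raise ValueError("no samples to merge")
    samples = list(profiles)
    catalog = build_full_catalog()
    values = np.zeros((len(catalog), len(samples)))

    offsets: dict[str, slice] = {}
    start = 0
    for g in GROUPS:
        n = len(catalog_for_group(g))
        offsets[g] = slice(start, start + n)
        start += n

    for j, sample in enumerate(samples):
        by_group = profiles[sample]
        col = np.zeros(len(catalog))
        present_weight = 0.0
        for g in GROUPS:
            prof = by_group.get(g)
            if prof is not None:
                prof.validate()
                if prof.sample_id != sample:
                    raise ValueError(
                        f"profile sample id {prof.sample_id!r} does not match key {sample!r}"
                    )
            total = prof.total() if prof is not None else 0.0
            w = config.weights.for_group(g)
            if w == 0.0:
                continue  # zero-weight group contributes nothing either way
            if total <= 0:
                if config.missing_group_policy == "error":
                    what = "no profile" if prof is None else "zero total count"
                    raise ValueError(f"sample {sample!r}: {what} for group {g}")
                continue  # zero-fill: block stays 0, re-normalized below
            col[offsets[g]] = prof.vector() / total * w
            present_weight += w
        if present_weight <= 0:
            raise ValueError(f"sample {sample!r}: all groups empty, cannot normalize")
        if present_weight < 1.0 - 1e-12:
            col /= present_weight  # re-normalize around zero-filled groups
        values[:, j] = col

    merged = FeatureMatrix(catalog, samples, values)
    merged.validate_stochastic()
    return merged
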