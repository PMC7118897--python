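"""Per-sample signature reports, burden metrics and cohort weight tables.

For each sample the observed profile is decomposed against the signature
matrix by non-negative least squares; the report shows the exposure pie
chart, the observed profile, the reconstruction P.e and the residual
(observed - reconstruction).  Cohort-level exposures are written to
``normalized_weights.txt`` as percentages, one row per sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

from .decipher import RefitResult, refit_exposures
from .matrix import ExposureMatrix, FeatureProfile, SignatureMatrix

ASSOCIATION_THRESHOLD = 0.30   # strict ">" rule: 30% exactly is not associated
TMB_MBP_DENOMINATOR = 30.0     # exome-scale Mbp heuristic; override for WGS

_GROUP_COLORS = {"SNV": "#1f77b4", "SV": "#d62728", "MSI": "#2ca02c"}


@dataclass
class SampleReport:
    sample_id: str
    signatures: list[str]
    exposure_fractions: np.ndarray
    observed: np.ndarray
    reconstructed: np.ndarray
    residual: np.ndarray
    error: float


def associated_signatures(
    exposure_fractions, signatures=None, threshold: float = ASSOCIATION_THRESHOLD
) -> set[str]:
    """Signatures whose exposure fraction strictly exceeds the threshold.

    A sample is called associated with a signature only when the
    signature explains more than 30% of its profile; a fraction of
    exactly 0.30 (or the 26% near-miss) is excluded.
    """
    fractions = np.asarray(
        list(exposure_fractions.values())
        if isinstance(exposure_fractions, dict)
        else exposure_fractions,
        dtype=float,
    )
    if np.any(fractions < 0) or np.any(fractions > 1):
        raise ValueError("exposure fractions must lie in [0, 1]")
    if isinstance(exposure_fractions, dict):
        signatures = list(exposure_fractions)
    if signatures is None:
        signatures = [f"Signature {i + 1}" for i in range(len(fractions))]
    return {s for s, f in zip(signatures, fractions) if f > threshold}


def _require_counts(profile: FeatureProfile) -> None:
    for fid, c in profile.counts.items():
        if abs(c - round(c)) > 1e-9:
            raise ValueError(
                f"profile for {profile.sample_id!r} holds non-integer value "
                f"{c!r} at {fid!r}; burden metrics need raw counts, "
                "not fraction-normalized profiles"
            )


def tmb(snv_profile: FeatureProfile, mbp: float = TMB_MBP_DENOMINATOR) -> float:
    """Tumor mutation burden: total substitutions / 30 (exome Mbp scale)."""
    if snv_profile.group != "SNV":
        raise ValueError(f"TMB needs an SNV profile, got {snv_profile.group}")
    _require_counts(snv_profile)
    return snv_profile.total() / mbp


def svb(sv_profile: FeatureProfile) -> float:
    """Structural variation burden: total somatic structural events."""
    if sv_profile.group != "SV":
        raise ValueError(f"SVB needs an SV profile, got {sv_profile.group}")
    _require_counts(sv_profile)
    return sv_profile.total()


def build_sample_report(
    sample_id: str, P: SignatureMatrix, observed: np.ndarray
) -> tuple[SampleReport, RefitResult]:
    """Refit one observed profile against P and assemble the report data."""
    refit = refit_exposures(P, observed)
    report = SampleReport(
        sample_id=sample_id,
        signatures=list(P.signatures),
        exposure_fractions=refit.fractions,
        observed=np.asarray(observed, dtype=float),
        reconstructed=refit.reconstruction,
        residual=refit.residual,
        error=refit.error,
    )
    return report, refit


def _profile_axes(ax, P: SignatureMatrix, vector: np.ndarray, title: str) -> None:
    colors = [_GROUP_COLORS.get(f.group, "#7f7f7f") for f in P.features]
    ax.bar(range(len(vector)), vector, color=colors, width=0.8)
    ax.set_title(title)
    ax.set_xlim(-1, len(vector))
    ax.set_xlabel("feature (SNV blue / SV red / MSI green)")
    ax.set_ylabel("fraction")


def render_report(
    sample_id: str,
    P: SignatureMatrix,
    observed: np.ndarray,
    out_path,
) -> SampleReport:
    """Write the 4-page PDF report for one sample.

    Page 1: pie chart of exposure fractions; page 2: observed profile;
    page 3: reconstruction from the fitted signature mix; page 4: the
    residual (observed - reconstruction).  Returns the underlying
    numeric report so callers can write the machine-readable annex.
    """
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.backends.backend_pdf import PdfPages

    observed = np.asarray(observed, dtype=float)
    if observed.shape != (len(P.features),):
        raise ValueError(
            f"observed profile length {observed.shape} does not match "
            f"P with {len(P.features)} features"
        )
    report, _ = build_sample_report(sample_id, P, observed)

    with PdfPages(out_path) as pdf:
        fig, ax = plt.subplots(figsize=(8, 6))
        nonzero = report.exposure_fractions > 1e-6
        if nonzero.any():
            ax.pie(
                report.exposure_fractions[nonzero],
                labels=[s for s, nz in zip(report.signatures, nonzero) if nz],
                autopct="%1.1f%%",
            )
        ax.set_title(f"{sample_id}: mutational signature components")
        pdf.savefig(fig)
        plt.close(fig)

        for vector, title in (
            (report.observed, f"{sample_id}: observed profile"),
            (report.reconstructed, f"{sample_id}: reconstructed profile"),
            (report.residual, f"{sample_id}: residual (error {report.error:.4g})"),
        ):
            fig, ax = plt.subplots(figsize=(11, 4))
            _profile_axes(ax, P, vector, title)
            pdf.savefig(fig)
            plt.close(fig)
    return report


def write_normalized_weights(E: ExposureMatrix, out_path) -> None:
    """Write per-sample signature percentages (one row per sample, one
    column per signature, 4 decimal places; rows sum to 100)."""
    En = E.normalized()
    percents = np.round(En.values.T * 100.0, 4)
    # largest-remainder correction: rounded rows must still sum to 100
    for i in range(percents.shape[0]):
        if percents[i].sum() > 0:
            percents[i, int(np.argmax(percents[i]))] += 100.0 - percents[i].sum()
    df = pd.DataFrame(percents, index=En.samples, columns=En.signatures)
    df.index.name = "Sample"
    df.to_csv(out_path, sep="\t", float_format="%.4f")


def read_normalized_weights(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_sample_table(reports: list[SampleReport], out_path) -> None:
    """Machine-readable annex: exposures and reconstruction error per sample."""
    rows = []
    for r in reports:
        row = {"Sample": r.sample_id, "ReconstructionError": r.error}
        row.update(dict(zip(r.signatures, r.exposure_fractions)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False, float_format="%.6g")
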