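"""Sample- and variant-level quality control and target-region construction.

Thresholds default to the study values and live in :class:`QcThresholds`
so that a config file can override any of them. A QC report lists *every*
failed rule, not just the first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, asdict
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, EvaluationError
from .regions import IntervalSet
from .types import CnvCall, VariantRecord


@dataclass(frozen=True)
class QcThresholds:
    """All QC cutoffs, defaulting to the published rules."""

    min_tumor_coverage: float = 60.0
    min_normal_coverage: float = 20.0
    min_snp_correlation: float = 0.80
    max_gnomad_fraction: float = 0.70
    min_tumor_content: float = 0.30
    min_variant_depth: float = 20.0  # both tumor and normal
    min_vaf: float = 0.05  # strict >
    min_alt_reads: int = 3
    min_cnv_loglikelihood: float = 100.0  # strict >
    # tumor-content rule: 2 x median of the top-k VAFs, capped at 1
    tumor_content_top_k: int = 15
    tumor_content_multiplier: float = 2.0
    exon_padding: int = 2

    @classmethod
    def from_yaml(cls, path) -> "QcThresholds":
        """Override any threshold from a YAML mapping; unknown keys error."""
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown QC threshold key(s): {sorted(unknown)}")
        return cls(**payload)


@dataclass(frozen=True)
class SampleQcMetrics:
    """Pre-computed per-sample QC inputs (the tool runs downstream of
    alignment; coverages and SNP correlation are consumed, not recomputed)."""

    sample_id: str
    tumor_coverage: float | None
    normal_coverage: float | None
    snp_correlation: float | None
    gnomad_fraction: float | None
    tumor_content: float | None  # None = undefined (no somatic variants)


@dataclass(frozen=True)
class SampleQcReport:
    sample_id: str
    passed: bool
    reasons: tuple[str, ...]
    needs_manual_review: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


def sample_qc(
    metrics: SampleQcMetrics, thresholds: QcThresholds = QcThresholds()
) -> SampleQcReport:
    """Apply the four sample-level rules; fail on any violated rule.

    An undefined tumor content (no somatic variants) does not auto-fail the
    sample: it is flagged for manual review, mirroring visual inspection of
    such samples.
    """
    required = {
        "tumor_coverage": metrics.tumor_coverage,
        "normal_coverage": metrics.normal_coverage,
        "snp_correlation": metrics.snp_correlation,
        "gnomad_fraction": metrics.gnomad_fraction,
    }
    missing = [name for name, value in required.items() if value is None]
    if missing:
        raise ConfigurationError(
            f"sample {metrics.sample_id}: missing QC metric(s) {missing}; "
            "no default pass"
        )
    reasons: list[str] = []
    if metrics.tumor_coverage < thresholds.min_tumor_coverage:
        reasons.append("tumor_coverage")
    if metrics.normal_coverage < thresholds.min_normal_coverage:
        reasons.append("normal_coverage")
    if metrics.snp_correlation < thresholds.min_snp_correlation:
        reasons.append("snp_correlation")
    if metrics.gnomad_fraction > thresholds.max_gnomad_fraction:
        reasons.append("gnomad_contamination")
    needs_review = metrics.tumor_content is None
    if not needs_review and metrics.tumor_content < thresholds.min_tumor_content:
        reasons.append("tumor_content")
    return SampleQcReport(
        sample_id=metrics.sample_id,
        passed=not reasons,
        reasons=tuple(reasons),
        needs_manual_review=needs_review,
    )


def variant_qc(
    variants: Sequence[VariantRecord], thresholds: QcThresholds = QcThresholds()
) -> list[VariantRecord]:
    """Keep variants with depth >= 20x in both samples, VAF strictly > 5%
    and at least three supporting reads."""
    return [
        v
        for v in variants
        if v.tumor_depth >= thresholds.min_variant_depth
        and v.normal_depth >= thresholds.min_variant_depth
        and v.vaf > thresholds.min_vaf
        and v.alt_reads >= thresholds.min_alt_reads
    ]


def cnv_qc(
    cnvs: Sequence[CnvCall], thresholds: QcThresholds = QcThresholds()
) -> list[CnvCall]:
    """Keep CNV calls with loglikelihood strictly > 100."""
    return [c for c in cnvs if c.loglikelihood > thresholds.min_cnv_loglikelihood]


def estimate_tumor_content(
    variants: Sequence[VariantRecord],
    thresholds: QcThresholds = QcThresholds(),
) -> float | None:
    """Tumor content from the median of the 15 highest VAFs.

    Heterozygous clonal variants in a diploid tumor sit at VAF ~ purity/2,
    so the median of the top VAFs is doubled and capped at 1. Returns
    ``None`` (undefined, manual review) when no variants are available.
    Order-invariant and deterministic.
    """
    if not variants:
        return None
    vafs = np.sort([v.vaf for v in variants])[::-1]
    top = vafs[: thresholds.tumor_content_top_k]
    return min(1.0, thresholds.tumor_content_multiplier * float(np.median(top)))


def study_target_region(
    normal_coverage_tracks: Sequence[IntervalSet],
    exons: IntervalSet,
    thresholds: QcThresholds = QcThresholds(),
) -> IntervalSet:
    """Per-study target region: bases covered >=20x in at least half of the
    normal samples, intersected with exons padded by 2 bases each side."""
    if not normal_coverage_tracks:
        raise ConfigurationError("study_target_region needs >= 1 coverage track")
    if exons.total_bases == 0:
        import warnings

        warnings.warn("empty exon set: target region is empty", stacklevel=2)
        return IntervalSet()
    covered = IntervalSet.majority_covered(normal_coverage_tracks)
    return covered.intersection(exons.pad(thresholds.exon_padding))


def common_target_region(study_regions: Sequence[IntervalSet]) -> IntervalSet:
    """Exact intersection of all study-specific target regions."""
    return IntervalSet.intersect_all(study_regions)
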