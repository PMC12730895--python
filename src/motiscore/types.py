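"""Domain types: somatic calls, repertoire/antigen inputs, biomarker panels,
cohort tables and the serializable score model.

Conventions
-----------
* Variant positions are 1-based (VCF convention); genomic intervals are
  0-based half-open (BED convention). :func:`pos_to_interval_coord` is the
  single conversion point.
* A missing biomarker is ``None`` — never silently zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import IntegrityError, VocabularyError, AlignmentError

#: Ordered impact vocabulary, least to most severe. "Nonsynonymous" for the
#: mutation-burden biomarker means strictly more severe than
#: ``protein_altering``.
IMPACT_LEVELS = ("synonymous_or_lower", "protein_altering", "moderate", "high")
NONSYNONYMOUS_IMPACTS = frozenset({"moderate", "high"})

VARIANT_KINDS = ("SNV", "indel")

HLA_LOCI = ("A", "B", "C")

#: Candidate biomarkers in canonical order. The combined chemokine marker is
#: computed but is not a default fit candidate.
CONTINUOUS_BIOMARKERS = (
    "tmb",
    "neoantigen_burden",
    "tcr_entropy",
    "hed",
    "pdl1_cpm",
    "b2m_cpm",
)
CATEGORICAL_BIOMARKERS = ("resistance_flag", "response_flag")
CANDIDATE_BIOMARKERS = (
    "tmb",
    "neoantigen_burden",
    "tcr_entropy",
    "resistance_flag",
    "response_flag",
    "hed",
    "pdl1_cpm",
    "b2m_cpm",
)

OUTCOMES = ("responder", "non_responder", "unknown")


def pos_to_interval_coord(pos: int) -> int:
    """Convert a 1-based variant position to a 0-based interval coordinate."""
    return pos - 1


@dataclass(frozen=True)
class VariantRecord:
    """A QC-relevant view of one annotated somatic SNV/indel call."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    vaf: float
    alt_reads: int
    tumor_depth: int
    normal_depth: int
    impact: str
    cmc_annotated: bool = False
    in_gnomad: bool = False
    kind: str = "SNV"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise IntegrityError(f"variant position must be >= 1, got {self.pos}")
        if not 0.0 <= self.vaf <= 1.0:
            raise IntegrityError(f"VAF must be in [0, 1], got {self.vaf}")
        if min(self.alt_reads, self.tumor_depth, self.normal_depth) < 0:
            raise IntegrityError("read counts must be non-negative")
        if self.impact not in IMPACT_LEVELS:
            raise VocabularyError(
                f"unknown impact label {self.impact!r}; expected one of {IMPACT_LEVELS}"
            )
        if self.kind not in VARIANT_KINDS:
            raise VocabularyError(f"unknown variant kind {self.kind!r}")
        # VAF, depth and supporting reads must agree within rounding; VAFs are
        # typically reported at two decimals, so allow two reads of slack.
        if abs(self.vaf * self.tumor_depth - self.alt_reads) > 2.0:
            raise IntegrityError(
                f"inconsistent variant support: vaf={self.vaf} x depth="
                f"{self.tumor_depth} != alt_reads={self.alt_reads}"
            )


@dataclass(frozen=True)
class CnvCall:
    """A somatic copy-number call (0-based half-open interval).

    ``genes`` is the overlapping-gene annotation carried by annotated CNV
    tables; gene-level deletion checks resolve against it.
    """

    chrom: str
    start: int
    end: int
    copy_number: int
    clonality: float
    loglikelihood: float
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise IntegrityError(
                f"malformed interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.copy_number < 0:
            raise IntegrityError("copy number must be >= 0")
        if not 0.0 <= self.clonality <= 1.0:
            raise IntegrityError(f"clonality must be in [0, 1], got {self.clonality}")

    @property
    def is_homozygous_deletion(self) -> bool:
        return self.copy_number == 0


@dataclass(frozen=True)
class TcrClone:
    chain: str  # "alpha" | "beta"
    cdr3: str
    count: int

    def __post_init__(self) -> None:
        if self.chain not in ("alpha", "beta"):
            raise VocabularyError(f"unknown TCR chain {self.chain!r}")
        if self.count < 1:
            raise IntegrityError("clone count must be >= 1")


def parse_hla_allele(name: str) -> tuple[str, str]:
    """Normalize a 4-digit class-I allele name; return (locus, normalized).

    Accepts ``"A*02:01"`` and ``"HLA-A*02:01"``.
    """
    clean = name.strip()
    if clean.upper().startswith("HLA-"):
        clean = clean[4:]
    if "*" not in clean:
        raise VocabularyError(f"not a 4-digit HLA allele name: {name!r}")
    locus = clean.split("*", 1)[0].upper()
    if locus not in HLA_LOCI:
        raise VocabularyError(
            f"HLA locus {locus!r} not in class I loci {HLA_LOCI} ({name!r})"
        )
    return locus, f"{locus}*{clean.split('*', 1)[1]}"


@dataclass(frozen=True)
class NeoantigenCandidate:
    peptide: str
    hla_allele: str
    median_affinity_nm: float
    rna_reads: int

    def __post_init__(self) -> None:
        if self.median_affinity_nm <= 0:
            raise IntegrityError("binding affinity must be positive (nM)")
        if self.rna_reads < 0:
            raise IntegrityError("RNA read support must be >= 0")
        parse_hla_allele(self.hla_allele)  # validates locus

    @property
    def locus(self) -> str:
        return parse_hla_allele(self.hla_allele)[0]


@dataclass
class HlaGenotype:
    """Class-I genotype with per-locus allele pair, loss calls and aligned
    binding-groove sequences.

    ``lost_allele`` maps a locus to the index (0/1) of the allele called lost
    in the tumor, or ``None``. The boolean per-locus view required by
    downstream consumers is :attr:`loss_flags`.
    """

    alleles: Mapping[str, tuple[str, str]]
    lost_allele: dict[str, int | None] = field(default_factory=dict)
    groove_seqs: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized = {}
        for locus, pair in self.alleles.items():
            a1 = parse_hla_allele(pair[0])
            a2 = parse_hla_allele(pair[1])
            if a1[0] != locus or a2[0] != locus:
                raise IntegrityError(
                    f"alleles {pair} do not belong to locus {locus}"
                )
            normalized[locus] = (a1[1], a2[1])
        self.alleles = normalized
        self.lost_allele = {
            locus: self.lost_allele.get(locus) for locus in self.alleles
        }
        for locus, pair in self.groove_seqs.items():
            if len(pair[0]) != len(pair[1]):
                raise AlignmentError(
                    f"groove sequences at locus {locus} have unequal aligned "
                    f"lengths {len(pair[0])} != {len(pair[1])}"
                )

    @property
    def loss_flags(self) -> dict[str, bool]:
        return {locus: idx is not None for locus, idx in self.lost_allele.items()}

    def retained_allele(self, locus: str) -> str | None:
        """The allele kept after a loss at ``locus``; None if no loss."""
        idx = self.lost_allele.get(locus)
        if idx is None:
            return None
        return self.alleles[locus][1 - idx]

    def is_homozygous(self, locus: str) -> bool:
        a1, a2 = self.alleles[locus]
        return a1 == a2


@dataclass
class BiomarkerPanel:
    """Per-sample values of the candidate immunogenicity biomarkers.

    ``None`` marks a biomarker whose inputs were unavailable.
    """

    tmb: float | None = None
    neoantigen_burden: float | None = None
    tcr_entropy: float | None = None
    resistance_flag: int | None = None
    response_flag: int | None = None
    hed: float | None = None
    pdl1_cpm: float | None = None
    b2m_cpm: float | None = None
    cxcl_combined: float | None = None

    def __post_init__(self) -> None:
        if self.resistance_flag not in (None, -1, 0):
            raise IntegrityError("resistance_flag must be -1 or 0")
        if self.response_flag not in (None, 0, 1):
            raise IntegrityError("response_flag must be 0 or 1")
        for name in ("tmb", "neoantigen_burden", "tcr_entropy", "hed",
                     "pdl1_cpm", "b2m_cpm"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise IntegrityError(f"{name} must be >= 0, got {value}")

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def missing(self) -> tuple[str, ...]:
        return tuple(name for name, v in self.as_dict().items() if v is None)


class CohortTable:
    """Samples x (biomarker panel, outcome, survival) table.

    Thin, validated wrapper around a :class:`pandas.DataFrame` with one row
    per sample. Fitting requires binary outcomes; ``unknown`` rows are
    allowed only for scoring.
    """

    REQUIRED = ("sample_id", "outcome")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        for col in self.REQUIRED:
            if col not in frame.columns:
                raise IntegrityError(f"cohort table lacks column {col!r}")
        if frame["sample_id"].duplicated().any():
            dupes = frame.loc[frame["sample_id"].duplicated(), "sample_id"]
            raise IntegrityError(f"duplicate sample_id(s): {sorted(set(dupes))}")
        bad = set(frame["outcome"]) - set(OUTCOMES)
        if bad:
            raise VocabularyError(f"unknown outcome label(s): {sorted(bad)}")
        for optional in ("survival_time", "event", "cancer_type"):
            if optional not in frame.columns:
                frame[optional] = pd.NA
        if (pd.to_numeric(frame["survival_time"], errors="coerce") < 0).any():
            raise IntegrityError("survival_time must be >= 0")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_panels(
        cls,
        panels: Mapping[str, BiomarkerPanel],
        clinical: pd.DataFrame,
    ) -> "CohortTable":
        rows = []
        for sample_id, panel in panels.items():
            row = {"sample_id": sample_id}
            row.update(panel.as_dict())
            rows.append(row)
        panel_frame = pd.DataFrame(rows)
        merged = panel_frame.merge(clinical, on="sample_id", how="left")
        merged["outcome"] = merged["outcome"].fillna("unknown")
        return cls(merged)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def biomarker_columns(self) -> list[str]:
        return [c for c in CANDIDATE_BIOMARKERS if c in self.frame.columns]

    def labeled(self) -> pd.DataFrame:
        """Rows with a binary outcome (the fitting subset)."""
        return self.frame[self.frame["outcome"].isin(("responder", "non_responder"))]

    def responder_mask(self) -> pd.Series:
        labeled = self.labeled()
        return labeled["outcome"] == "responder"

    def values(self, biomarker: str) -> pd.Series:
        if biomarker not in self.frame.columns:
            raise IntegrityError(f"cohort table lacks biomarker {biomarker!r}")
        return pd.to_numeric(self.frame[biomarker], errors="coerce")


MODEL_SCHEMA_VERSION = 1


@dataclass
class ScoreModel:
    """Fitted score: selected biomarkers, normalized -log10-p weights,
    discovery-cohort standardization constants and the decision cutoff."""

    selected: list[str]
    p_values: dict[str, float]
    weights: dict[str, float]
    means: dict[str, float]
    sds: dict[str, float]
    cutoff: float | None = None
    provenance: dict = field(default_factory=dict)
    schema_version: int = MODEL_SCHEMA_VERSION

    def validate(self) -> None:
        if not self.selected:
            raise IntegrityError("model has no selected biomarkers")
        for mapping, label in (
            (self.p_values, "p_values"),
            (self.weights, "weights"),
            (self.means, "means"),
            (self.sds, "sds"),
        ):
            missing = [b for b in self.selected if b not in mapping]
            if missing:
                raise IntegrityError(f"model {label} missing entries for {missing}")
        total = math.fsum(self.weights[b] for b in self.selected)
        if abs(total - 1.0) > 1e-9:
            raise IntegrityError(f"weights sum to {total!r}, expected 1 within 1e-9")
        if any(self.weights[b] <= 0 for b in self.selected):
            raise IntegrityError("all weights must be > 0")
        if any(self.sds[b] <= 0 for b in self.selected):
            raise IntegrityError("all standardization SDs must be > 0")
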