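"""Derivation of the candidate immunogenicity biomarkers.

Eight candidates enter model fitting: mutation burden (TMB), neoantigen
burden, TCR alpha-chain repertoire entropy, a checkpoint-resistance flag
(-1/0), a checkpoint-response flag (0/1), HLA evolutionary divergence (HED),
and PDL1/B2M expression in CPM. The combined C-X-C chemokine marker is
computed as well but is not a default fit candidate.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _data
from .errors import (
    AlignmentError,
    ConfigurationError,
    DataConsistencyError,
    EvaluationError,
    IntegrityError,
)
from .regions import IntervalSet
from .types import (
    BiomarkerPanel,
    CnvCall,
    HLA_LOCI,
    HlaGenotype,
    NeoantigenCandidate,
    NONSYNONYMOUS_IMPACTS,
    TcrClone,
    VariantRecord,
    parse_hla_allele,
    pos_to_interval_coord,
)


class GranthamMatrix:
    """Symmetric 20x20 amino-acid distance table."""

    def __init__(self, frame: pd.DataFrame | None = None):
        frame = _data.grantham_frame() if frame is None else frame
        values = frame.to_numpy(dtype=float)
        if not np.allclose(values, values.T):
            raise IntegrityError("Grantham matrix must be symmetric")
        if not np.all(np.diag(values) == 0):
            raise IntegrityError("Grantham matrix diagonal must be zero")
        if (values < 0).any():
            raise IntegrityError("Grantham distances must be >= 0")
        self._frame = frame

    def distance(self, a: str, b: str) -> float:
        try:
            return float(self._frame.at[a, b])
        except KeyError as exc:
            raise IntegrityError(f"unknown amino acid in pair ({a!r}, {b!r})") from exc

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return self.distance(*pair)


def compute_tmb(
    variants: Sequence[VariantRecord], region: IntervalSet
) -> float:
    """Nonsynonymous mutations per megabase of the target region.

    A variant counts when its impact is strictly more severe than
    "protein altering" (levels ``moderate``/``high``) and it lies inside
    the region.
    """
    if region.total_bases == 0:
        raise EvaluationError("TMB undefined on an empty target region")
    n = sum(
        1
        for v in variants
        if v.impact in NONSYNONYMOUS_IMPACTS
        and region.contains(v.chrom, pos_to_interval_coord(v.pos))
    )
    return n / (region.total_bases / 1e6)


def neoantigen_burden(
    candidates: Sequence[NeoantigenCandidate],
    genotype: HlaGenotype,
    max_affinity_nm: float = 500.0,
    min_rna_reads: int = 1,
) -> int:
    """Count of candidates binding below 500 nM with RNA support, restricted
    to the retained allele at loci with an allele loss."""
    count = 0
    for cand in candidates:
        locus, allele = parse_hla_allele(cand.hla_allele)
        if allele not in genotype.alleles.get(locus, ()):
            raise DataConsistencyError(
                f"candidate allele {allele} absent from genotype at locus {locus}"
            )
        if not (cand.median_affinity_nm < max_affinity_nm):
            continue
        if cand.rna_reads < min_rna_reads:
            continue
        retained = genotype.retained_allele(locus)
        if retained is not None and allele != retained:
            continue
        count += 1
    return count


def tcr_entropy(clones: Sequence[TcrClone], min_count: int = 2) -> float:
    """Shannon entropy (nats) of alpha-chain clone frequencies.

    Only alpha-chain clones observed at least twice enter; with zero or one
    retained clone the entropy is 0 by convention.
    """
    counts = np.array(
        [c.count for c in clones if c.chain == "alpha" and c.count >= min_count],
        dtype=float,
    )
    if len(counts) <= 1:
        return 0.0
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _deleterious_small_variants(
    variants: Sequence[VariantRecord], genes: frozenset[str]
) -> list[VariantRecord]:
    return [
        v
        for v in variants
        if _data.resolve_gene_symbol(v.gene) in genes
        and (v.impact == "high" or v.cmc_annotated)
    ]


def _homozygous_deletions(
    cnvs: Sequence[CnvCall], genes: frozenset[str]
) -> list[CnvCall]:
    return [
        c
        for c in cnvs
        if c.is_homozygous_deletion
        and genes & {_data.resolve_gene_symbol(g) for g in c.genes}
    ]


def resistance_flag(
    variants: Sequence[VariantRecord],
    cnvs: Sequence[CnvCall],
    tumor_clonality: float,
    main_clone_fraction: float = 0.8,
) -> int:
    """-1 if a deleterious main-clone alteration hits B2M or the antigen
    processing machinery (TAP1/TAP2/TAPBP/CIITA/CALR/CANX), else 0.

    Deleterious means a homozygous deletion, or an SNV/indel with high impact
    or a curated driver (CMC) annotation. Main-clone means VAF (or CNV
    clonality) >= 80% of the tumor clonality; subclonal hits are ignored.
    """
    if not 0.0 < tumor_clonality <= 1.0:
        raise ConfigurationError(
            f"tumor clonality must be in (0, 1], got {tumor_clonality}"
        )
    genes = frozenset(_data.gene_lists()["resistance_genes"])
    threshold = main_clone_fraction * tumor_clonality
    for v in _deleterious_small_variants(variants, genes):
        if v.vaf >= threshold:
            return -1
    for c in _homozygous_deletions(cnvs, genes):
        if c.clonality >= threshold:
            return -1
    return 0


def response_flag(
    variants: Sequence[VariantRecord], cnvs: Sequence[CnvCall]
) -> int:
    """1 if LRP1B carries a high-impact + CMC-annotated SNV/indel or a
    homozygous deletion — any clonality; variants of unclear significance
    (missing either annotation) do not count."""
    genes = frozenset(_data.gene_lists()["response_genes"])
    for v in variants:
        if (
            _data.resolve_gene_symbol(v.gene) in genes
            and v.impact == "high"
            and v.cmc_annotated
        ):
            return 1
    if _homozygous_deletions(cnvs, genes):
        return 1
    return 0


def detect_allele_loss(
    genotype: HlaGenotype,
    cnvs: Sequence[CnvCall],
    read_ratios: Mapping[str, tuple[float, float]],
    min_cnv_clonality: float = 0.25,
    max_ratio_deviation: float = 0.40,
) -> dict[str, int | None]:
    """Call per-locus HLA allele loss.

    A locus loses one allele when a deleting CNV (copy number < 2)
    overlapping that HLA gene has clonality >= 25%, or when the per-allele
    tumor/normal assigned-read ratios ``(r1, r2)`` deviate by more than 40%
    (``|r1 - r2| / max(r1, r2) > 0.40``). The allele with the smaller read
    ratio is the lost one. Returns locus -> lost allele index (or None).
    """
    result: dict[str, int | None] = {}
    for locus in genotype.alleles:
        r = read_ratios.get(locus)
        if r is None or min(r) <= 0:
            raise ConfigurationError(
                f"positive per-allele read ratios required at locus {locus}"
            )
        hla_gene = f"HLA-{locus}"
        cnv_loss = any(
            c.copy_number < 2
            and c.clonality >= min_cnv_clonality
            and hla_gene in c.genes
            for c in cnvs
        )
        deviation = abs(r[0] - r[1]) / max(r)
        if cnv_loss or deviation > max_ratio_deviation:
            result[locus] = int(np.argmin(r))
        else:
            result[locus] = None
    return result


def hed(
    genotype: HlaGenotype, matrix: GranthamMatrix | None = None
) -> dict[str, float]:
    """HLA evolutionary divergence per class-I locus and their mean.

    Per locus: 0 for homozygous or loss-flagged loci; otherwise the mean
    per-aligned-site Grantham distance between the two binding-groove
    sequences (gap positions excluded). The sample value is the mean over
    loci A, B, C.
    """
    matrix = matrix or GranthamMatrix()
    per_locus: dict[str, float] = {}
    for locus, (a1, a2) in genotype.alleles.items():
        if genotype.is_homozygous(locus) or genotype.lost_allele.get(locus) is not None:
            per_locus[locus] = 0.0
            continue
        seqs = genotype.groove_seqs.get(locus)
        if seqs is None:
            raise AlignmentError(f"no groove sequences for locus {locus}")
        s1, s2 = seqs
        if len(s1) != len(s2):
            raise AlignmentError(
                f"groove sequences at locus {locus} differ in aligned length"
            )
        sites = [(x, y) for x, y in zip(s1, s2) if x != "-" and y != "-"]
        if not sites:
            raise AlignmentError(f"no aligned residues at locus {locus}")
        per_locus[locus] = float(
            np.mean([matrix.distance(x, y) for x, y in sites])
        )
    per_locus["mean"] = float(np.mean([per_locus[l] for l in genotype.alleles]))
    return per_locus


def groove_sequences_for(
    genotype_alleles: Mapping[str, tuple[str, str]],
) -> dict[str, tuple[str, str]]:
    """Look up packaged aligned groove sequences for a genotype."""
    table = _data.hla_groove_table()
    out = {}
    for locus, (a1, a2) in genotype_alleles.items():
        try:
            out[locus] = (table[a1], table[a2])
        except KeyError as exc:
            raise DataConsistencyError(
                f"allele {exc.args[0]} absent from the packaged groove table"
            ) from exc
    return out


def cpm(counts: pd.DataFrame, sample: str, gene: str) -> float:
    """Counts-per-million of one gene in one sample's library."""
    if sample not in counts.columns:
        raise IntegrityError(f"sample {sample!r} absent from count matrix")
    total = counts[sample].sum()
    if total <= 0:
        raise IntegrityError(f"sample {sample!r} has zero library size")
    gene = _data.resolve_gene_symbol(gene)
    if gene not in counts.index:
        raise IntegrityError(f"gene {gene!r} absent from count matrix")
    return 1e6 * float(counts.at[gene, sample]) / float(total)


def expression_markers(counts: pd.DataFrame, sample: str) -> tuple[float, float]:
    """(PDL1 CPM, B2M CPM) for one sample."""
    markers = _data.gene_lists()["expression_markers"]
    return cpm(counts, sample, markers["pdl1"]), cpm(counts, sample, markers["b2m"])


def cxcl_combined(
    counts: pd.DataFrame, sample: str, pseudocount: float = 1.0
) -> float:
    """Mean log2 fold change of CXCL9/10/11 CPM versus the cohort median CPM
    of each gene (pseudocount added to numerator and denominator)."""
    genes = _data.gene_lists()["cxcl_genes"]
    missing = [g for g in genes if g not in counts.index]
    if missing:
        raise IntegrityError(f"gene(s) absent from count matrix: {missing}")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise IntegrityError("count matrix contains zero-library samples")
    cpm_frame = counts.loc[genes].div(totals, axis=1) * 1e6
    medians = cpm_frame.median(axis=1)
    fold = np.log2((cpm_frame[sample] + pseudocount) / (medians + pseudocount))
    return float(fold.mean())


def build_panel(
    *,
    variants: Sequence[VariantRecord] | None = None,
    cnvs: Sequence[CnvCall] | None = None,
    region: IntervalSet | None = None,
    clones: Sequence[TcrClone] | None = None,
    candidates: Sequence[NeoantigenCandidate] | None = None,
    genotype: HlaGenotype | None = None,
    counts: pd.DataFrame | None = None,
    sample: str | None = None,
    tumor_clonality: float | None = None,
    grantham: GranthamMatrix | None = None,
) -> BiomarkerPanel:
    """Compose a per-sample panel from whatever inputs are available.

    Fields whose inputs are missing stay ``None`` (tracked by the panel's
    ``missing`` property), never silently zero. Variants are expected to be
    QC-filtered already.
    """
    panel = BiomarkerPanel()
    if variants is not None and region is not None:
        panel.tmb = compute_tmb(variants, region)
    if variants is not None and cnvs is not None:
        panel.response_flag = response_flag(variants, cnvs)
        if tumor_clonality is not None:
            panel.resistance_flag = resistance_flag(variants, cnvs, tumor_clonality)
    if clones is not None:
        panel.tcr_entropy = tcr_entropy(clones)
    if candidates is not None and genotype is not None:
        panel.neoantigen_burden = neoantigen_burden(candidates, genotype)
    if genotype is not None and genotype.groove_seqs:
        panel.hed = hed(genotype, grantham)["mean"]
    if counts is not None and sample is not None:
        panel.pdl1_cpm, panel.b2m_cpm = expression_markers(counts, sample)
        if all(g in counts.index for g in _data.gene_lists()["cxcl_genes"]):
            panel.cxcl_combined = cxcl_combined(counts, sample)
    return panel
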