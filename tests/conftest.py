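import numpy as np
import pandas as pd
import pytest

from motiscore import BiomarkerPanel, CohortTable, IntervalSet, VariantRecord


def make_variant(
    chrom="chr1",
    pos=100,
    gene="GENE1",
    vaf=0.30,
    tumor_depth=100,
    normal_depth=60,
    alt_reads=None,
    impact="moderate",
    cmc=False,
    in_gnomad=False,
    kind="SNV",
):
    if alt_reads is None:
        alt_reads = round(vaf * tumor_depth)
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref="A",
        alt="T",
        gene=gene,
        vaf=vaf,
        alt_reads=alt_reads,
        tumor_depth=tumor_depth,
        normal_depth=normal_depth,
        impact=impact,
        cmc_annotated=cmc,
        in_gnomad=in_gnomad,
        kind=kind,
    )


@pytest.fixture
def one_mb_region():
    return IntervalSet.from_tuples([("chr1", 0, 1_000_000)])


def make_cohort(
    rng: np.random.Generator,
    n_per_group: int = 50,
    shifts: dict | None = None,
    flag_prevalences: dict | None = None,
) -> CohortTable:
    """Two-group cohort with standard-normal continuous biomarkers plus the
    requested responder-group location shifts / flag prevalences."""
    shifts = shifts or {}
    flag_prevalences = flag_prevalences or {}
    n = 2 * n_per_group
    responder = np.zeros(n, dtype=bool)
    responder[:n_per_group] = True
    frame = pd.DataFrame({"sample_id": [f"S{i:04d}" for i in range(n)]})
    for name in ("tmb", "neoantigen_burden", "tcr_entropy", "hed", "pdl1_cpm", "b2m_cpm"):
        values = rng.standard_normal(n) + shifts.get(name, 0.0) * responder
        frame[name] = values - values.min() + 0.01  # biomarkers are >= 0
    for name, value in (("resistance_flag", -1), ("response_flag", 1)):
        p_non, p_resp = flag_prevalences.get(name, (0.1, 0.1))
        prev = np.where(responder, p_resp, p_non)
        frame[name] = np.where(rng.random(n) < prev, value, 0)
    frame["outcome"] = np.where(responder, "responder", "non_responder")
    return CohortTable(frame)
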