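"""Seeded synthetic-cohort generator.

Two levels are emulated:

* **panel level** — per-sample biomarker panels for two outcome groups with
  configurable location shifts (continuous markers, Gaussian copula for
  correlated pairs) and prevalence differences (binary flags), plus
  exponential survival with a planted group hazard ratio;
* **raw level** — desk-scale variant/CNV/clone/neoantigen/count/HLA files
  that parse through the package's readers and whose derived biomarkers
  match the planted ground truth.

Defaults mirror the discovery-study conditions: 225 samples, 98 responders,
mutation burden and repertoire entropy as the strongest outcome-associated
markers, neoantigen burden strongly correlated with mutation burden (and so
pruned), rare resistance events. Realism targets the parsers and formulas,
not sequence biology.

A single root seed is expanded into named, order-independent streams so the
same seed and config always produce byte-identical outputs.
"""

from __future__ import annotations

import json
import math
import zlib
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError
from . import io as mio
from .biomarkers import tcr_entropy
from .regions import IntervalSet
from .types import (
    CnvCall,
    CohortTable,
    HlaGenotype,
    NeoantigenCandidate,
    TcrClone,
    VariantRecord,
)


def stream(seed: int, *names: str) -> np.random.Generator:
    """Independent, order-insensitive random stream derived from the root
    seed and a name path (counter-based via CRC32 of the names)."""
    keys = [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *keys]))


# -- configuration -----------------------------------------------------------

class ContinuousSpec(BaseModel):
    family: Literal["lognormal", "normal"]
    mean: float  # latent mean (log scale for lognormal), non-responders
    sd: float = Field(gt=0)
    responder_shift: float = 0.0  # in latent SD units


class FlagSpec(BaseModel):
    family: Literal["bernoulli"] = "bernoulli"
    prevalence_non_responder: float = Field(ge=0, le=1)
    prevalence_responder: float = Field(ge=0, le=1)
    present_value: int = 1  # -1 for the resistance flag


class SurvivalSpec(BaseModel):
    baseline_hazard: float = Field(default=1.0 / 400.0, gt=0)  # events/day
    hazard_ratio: float = Field(default=0.48, gt=0)  # high- vs low-score group
    censoring_rate: float = Field(default=0.2, ge=0, le=1)


def _default_biomarkers() -> dict:
    return {
        "tmb": ContinuousSpec(family="lognormal", mean=1.6, sd=1.0, responder_shift=0.7),
        "neoantigen_burden": ContinuousSpec(family="lognormal", mean=3.0, sd=1.0, responder_shift=0.6),
        "tcr_entropy": ContinuousSpec(family="normal", mean=4.0, sd=1.2, responder_shift=0.65),
        "hed": ContinuousSpec(family="normal", mean=6.0, sd=2.0, responder_shift=0.05),
        "pdl1_cpm": ContinuousSpec(family="lognormal", mean=2.5, sd=1.0, responder_shift=0.45),
        "b2m_cpm": ContinuousSpec(family="lognormal", mean=6.5, sd=0.7, responder_shift=0.05),
        "resistance_flag": FlagSpec(prevalence_non_responder=0.015, prevalence_responder=0.005, present_value=-1),
        "response_flag": FlagSpec(prevalence_non_responder=0.18, prevalence_responder=0.38, present_value=1),
    }


class SimConfig(BaseModel):
    """Panel-level simulation settings; the seed is mandatory."""

    seed: int
    n_samples: int = Field(default=225, gt=0)
    responder_fraction: float = Field(default=98 / 225, ge=0, le=1)
    biomarkers: dict[str, ContinuousSpec | FlagSpec] = Field(
        default_factory=_default_biomarkers
    )
    correlations: list[tuple[str, str, float]] = Field(
        default_factory=lambda: [("tmb", "neoantigen_burden", 0.8)]
    )
    survival: SurvivalSpec = Field(default_factory=SurvivalSpec)

    @model_validator(mode="after")
    def _check_correlations(self) -> "SimConfig":
        for a, b, rho in self.correlations:
            for name in (a, b):
                spec = self.biomarkers.get(name)
                if spec is None or isinstance(spec, FlagSpec):
                    raise ConfigurationError(
                        f"correlation pair ({a}, {b}) references a missing or "
                        f"non-continuous biomarker {name!r}"
                    )
            if not -1 < rho < 1:
                raise ConfigurationError(f"target Spearman rho must be in (-1, 1), got {rho}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def _latent_correlation(config: SimConfig, names: list[str]) -> np.ndarray:
    """Pearson correlation of the Gaussian copula achieving the target
    Spearman rho (r = 2 sin(pi rho / 6)); must be positive semi-definite."""
    k = len(names)
    corr = np.eye(k)
    for a, b, rho in config.correlations:
        r = 2.0 * math.sin(math.pi * rho / 6.0)
        i, j = names.index(a), names.index(b)
        corr[i, j] = corr[j, i] = r
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise ConfigurationError(
            f"correlation spec is not positive semi-definite "
            f"(min eigenvalue {eigvals.min():.3g})"
        )
    return corr


def simulate_panels(config: SimConfig) -> CohortTable:
    """Draw a cohort of biomarker panels with planted outcome effects."""
    n = config.n_samples
    n_resp = int(round(config.responder_fraction * n))
    responder = np.zeros(n, dtype=bool)
    responder[:n_resp] = True
    stream(config.seed, "panel", "outcome").shuffle(responder)

    continuous = [
        name for name, spec in config.biomarkers.items()
        if isinstance(spec, ContinuousSpec)
    ]
    corr = _latent_correlation(config, continuous)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(continuous)))
    z = stream(config.seed, "panel", "continuous").standard_normal((n, len(continuous)))
    z = z @ chol.T

    frame = pd.DataFrame({"sample_id": [f"S{i:04d}" for i in range(n)]})
    for j, name in enumerate(continuous):
        spec = config.biomarkers[name]
        latent = spec.mean + spec.sd * (z[:, j] + spec.responder_shift * responder)
        values = np.exp(latent) if spec.family == "lognormal" else np.maximum(latent, 0.0)
        frame[name] = values
    for name, spec in config.biomarkers.items():
        if not isinstance(spec, FlagSpec):
            continue
        prev = np.where(
            responder, spec.prevalence_responder, spec.prevalence_non_responder
        )
        draws = stream(config.seed, "panel", "flag", name).random(n)
        frame[name] = np.where(draws < prev, spec.present_value, 0)
    frame["outcome"] = np.where(responder, "responder", "non_responder")
    frame["cancer_type"] = "synthetic"
    return CohortTable(frame)


def simulate_survival(
    config: SimConfig, high_group: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with the configured group hazard ratio and
    independent censoring at the configured rate.

    A censored subject's observed time is a uniform fraction of its latent
    event time, so the censoring fraction equals the configured rate in
    expectation; at rate 1 no events remain.
    """
    x = np.asarray(high_group, dtype=int)
    spec = config.survival
    rng = stream(config.seed, "survival")
    hazard = spec.baseline_hazard * np.power(spec.hazard_ratio, x)
    event_times = rng.exponential(1.0 / hazard)
    censored = rng.random(len(x)) < spec.censoring_rate
    observed = np.where(censored, event_times * rng.random(len(x)), event_times)
    return observed, ~censored


# -- raw-level simulation ----------------------------------------------------

class RawSampleConfig(BaseModel):
    """Planted raw inputs for one sample (minimal realism: random CDR3 and
    peptide strings; the targets are the parsers and the derivations)."""

    seed: int
    sample_id: str = "SIM0001"
    region_mb: float = Field(default=2.0, gt=0)
    n_nonsynonymous: int = 12  # in-region, QC-passing
    n_synonymous: int = 6
    n_out_of_region: int = 4  # nonsynonymous but off-target
    n_fail_qc: int = 3  # fail depth/VAF/support filters
    clone_counts: tuple[int, ...] = (8, 8, 8, 8, 8, 8, 8, 8)
    n_singleton_clones: int = 5
    n_beta_clones: int = 4
    n_neoantigens_pass: int = 7
    n_neoantigens_fail: int = 4
    plant_resistance: bool = False  # clonal high-impact B2M variant
    plant_response: bool = False  # high-impact + CMC LRP1B variant
    tumor_clonality: float = 0.5
    library_size: int = 1_000_000
    pdl1_count: int = 500
    b2m_count: int = 4000


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def simulate_raw_sample(config: RawSampleConfig, out_dir: str | Path) -> dict:
    """Write one sample's raw files plus ``truth.json``; return the truth.

    Derivations on the written files reproduce the planted values exactly
    (counts, flags, burden) or to floating tolerance (entropy, CPM).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    region_bases = int(config.region_mb * 1e6)
    region = IntervalSet.from_tuples([("chr1", 0, region_bases)])
    rng = stream(config.seed, "raw", config.sample_id)

    def _variant(chrom, pos, impact, gene="GENE1", cmc=False, vaf=None,
                 tumor_depth=None, normal_depth=None, alt_reads=None):
        tumor_depth = int(tumor_depth if tumor_depth is not None else rng.integers(80, 200))
        normal_depth = int(normal_depth if normal_depth is not None else rng.integers(40, 120))
        vaf_target = float(vaf if vaf is not None else rng.uniform(0.10, 0.60))
        alt = int(alt_reads if alt_reads is not None else max(3, round(vaf_target * tumor_depth)))
        return VariantRecord(
            chrom=chrom, pos=int(pos), ref="A", alt="T", gene=gene,
            vaf=alt / tumor_depth, alt_reads=alt, tumor_depth=tumor_depth,
            normal_depth=normal_depth, impact=impact, cmc_annotated=cmc,
        )

    variants: list[VariantRecord] = []
    positions = rng.choice(region_bases - 1, size=config.n_nonsynonymous, replace=False) + 1
    for i, pos in enumerate(positions):
        impact = "high" if i % 3 == 0 else "moderate"
        variants.append(_variant("chr1", pos, impact))
    for _ in range(config.n_synonymous):
        variants.append(_variant("chr1", int(rng.integers(1, region_bases)), "synonymous_or_lower"))
    for _ in range(config.n_out_of_region):
        variants.append(_variant("chr2", int(rng.integers(1, region_bases)), "moderate"))
    for _ in range(config.n_fail_qc):  # below depth and support thresholds
        variants.append(
            _variant("chr1", int(rng.integers(1, region_bases)), "moderate",
                     tumor_depth=15, normal_depth=10, vaf=0.2, alt_reads=3)
        )
    if config.plant_resistance:
        variants.append(
            _variant("chr1", int(rng.integers(1, region_bases)), "high", gene="B2M",
                     vaf=0.9 * config.tumor_clonality, tumor_depth=100,
                     alt_reads=round(0.9 * config.tumor_clonality * 100))
        )
    if config.plant_response:
        variants.append(
            _variant("chr1", int(rng.integers(1, region_bases)), "high",
                     gene="LRP1B", cmc=True)
        )

    cnvs = [
        CnvCall("chr1", 1000, 50_000, copy_number=3, clonality=0.6,
                loglikelihood=250.0, genes=("GENE2",)),
        CnvCall("chr1", 60_000, 80_000, copy_number=1, clonality=0.3,
                loglikelihood=40.0, genes=("GENE3",)),  # fails CNV QC
    ]

    clones = [
        TcrClone("alpha", _random_peptide(rng, 14), int(c))
        for c in config.clone_counts
    ]
    clones += [
        TcrClone("alpha", _random_peptide(rng, 14), 1)
        for _ in range(config.n_singleton_clones)
    ]
    clones += [
        TcrClone("beta", _random_peptide(rng, 15), int(rng.integers(2, 9)))
        for _ in range(config.n_beta_clones)
    ]

    alleles = {"A": ("A*01:01", "A*02:01"), "B": ("B*07:02", "B*08:01"),
               "C": ("C*04:01", "C*07:01")}
    flat_alleles = [a for pair in alleles.values() for a in pair]
    candidates = [
        NeoantigenCandidate(
            peptide=_random_peptide(rng, 9),
            hla_allele=flat_alleles[i % len(flat_alleles)],
            median_affinity_nm=float(rng.uniform(20, 450)),
            rna_reads=int(rng.integers(1, 40)),
        )
        for i in range(config.n_neoantigens_pass)
    ]
    for i in range(config.n_neoantigens_fail):
        weak_affinity = i % 2 == 0
        candidates.append(
            NeoantigenCandidate(
                peptide=_random_peptide(rng, 9),
                hla_allele=flat_alleles[i % len(flat_alleles)],
                median_affinity_nm=float(rng.uniform(500, 5000)) if weak_affinity else 100.0,
                rna_reads=int(rng.integers(1, 40)) if weak_affinity else 0,
            )
        )

    filler = max(0, config.library_size - config.pdl1_count - config.b2m_count)
    counts = pd.DataFrame(
        {config.sample_id: [config.pdl1_count, config.b2m_count, filler]},
        index=pd.Index(["CD274", "B2M", "FILLER1"], name="gene"),
    )

    mio.write_variants(variants, out / "variants.tsv")
    mio.write_cnvs(cnvs, out / "cnvs.tsv")
    mio.write_clones_airr(clones, out / "clones.airr.tsv")
    mio.write_neoantigens(candidates, out / "neoantigens.tsv")
    mio.write_hla(alleles, out / "hla.tsv")
    counts.reset_index().to_csv(out / "counts.tsv", sep="\t", index=False)
    mio.write_intervals(region, out / "region.bed")

    truth = {
        "sample_id": config.sample_id,
        "tmb": config.n_nonsynonymous / config.region_mb
        + (config.plant_resistance + config.plant_response) / config.region_mb,
        "tcr_entropy": tcr_entropy(clones),
        "neoantigen_burden": config.n_neoantigens_pass,
        "resistance_flag": -1 if config.plant_resistance else 0,
        "response_flag": 1 if config.plant_response else 0,
        "pdl1_cpm": 1e6 * config.pdl1_count / config.library_size,
        "b2m_cpm": 1e6 * config.b2m_count / config.library_size,
        "tumor_clonality": config.tumor_clonality,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return truth


def simulate_cohort_dir(config: SimConfig, out_dir: str | Path) -> CohortTable:
    """Write panels.tsv, clinical.tsv and truth.json as `fit` expects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_panels(config)
    high = (cohort.frame["outcome"] == "responder").astype(int).to_numpy()
    times, events = simulate_survival(config, high)
    clinical = pd.DataFrame(
        {
            "sample_id": cohort.frame["sample_id"],
            "recist": np.where(cohort.frame["outcome"] == "responder", "PR", "PD"),
            "survival_time": np.round(times, 3),
            "event": events.astype(int),
            "cancer_type": cohort.frame["cancer_type"],
        }
    )
    mio.write_panels(cohort, out / "panels.tsv")
    clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    truth = {
        "seed": config.seed,
        "n_samples": config.n_samples,
        "n_responders": int((cohort.frame["outcome"] == "responder").sum()),
        "planted_effects": {
            name: spec.model_dump() for name, spec in config.biomarkers.items()
        },
        "correlations": [list(c) for c in config.correlations],
        "survival": config.survival.model_dump(),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    # survival columns also live on the cohort for in-memory use
    cohort.frame["survival_time"] = times
    cohort.frame["event"] = events
    return cohort
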