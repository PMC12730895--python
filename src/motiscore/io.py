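"""Readers and writers for the external formats the tool touches.

Dialects are column-name mappings with sensible defaults (AIRR rearrangement
TSV, TRUST4-style report TSV, a tidy variant TSV, VCF via pysam, BED3+,
counts TSV, clinical TSV) — overridable because upstream pipelines disagree
on column names. Every reader validates against the domain-type invariants
and reports malformed rows with line numbers; nothing is silently coerced.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, MotiscoreError, VocabularyError
from .regions import IntervalSet
from .types import (
    CnvCall,
    CohortTable,
    MODEL_SCHEMA_VERSION,
    NeoantigenCandidate,
    ScoreModel,
    TcrClone,
    VariantRecord,
    parse_hla_allele,
)
from ._data import vep_impact_table

# -- variants ----------------------------------------------------------------

VARIANT_TSV_COLUMNS = (
    "chrom", "pos", "ref", "alt", "gene", "vaf", "alt_reads",
    "tumor_depth", "normal_depth", "impact",
)
VARIANT_TSV_OPTIONAL = ("cmc_annotated", "in_gnomad", "kind")

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False}


def _parse_bool(value, line: int, column: str) -> bool:
    key = str(value).strip().lower()
    if key not in _BOOL_MAP:
        raise FormatError(f"line {line}: column {column!r} is not boolean: {value!r}")
    return _BOOL_MAP[key]


def impact_from_consequence(term: str) -> str:
    """Map a VEP consequence term to the packaged 4-level ordered impact."""
    table = vep_impact_table()
    # comma/ampersand-joined terms: most severe wins
    levels = {"synonymous_or_lower": 0, "protein_altering": 1, "moderate": 2, "high": 3}
    parts = [p.strip() for p in term.replace("&", ",").split(",") if p.strip()]
    mapped = []
    for part in parts:
        if part in levels:  # already an impact level
            mapped.append(part)
        elif part in table:
            mapped.append(table[part])
        else:
            raise VocabularyError(f"unknown consequence/impact term {part!r}")
    if not mapped:
        raise VocabularyError(f"empty impact annotation {term!r}")
    return max(mapped, key=levels.__getitem__)


def read_variants(
    path: str | Path,
    dialect: str = "tsv",
    column_map: Mapping[str, str] | None = None,
) -> list[VariantRecord]:
    """Read annotated somatic small-variant calls (TSV dialect or VCF)."""
    if dialect == "tsv":
        return _read_variants_tsv(Path(path), column_map or {})
    if dialect == "vcf":
        return _read_variants_vcf(Path(path), column_map or {})
    raise FormatError(f"unknown variant dialect {dialect!r}")


def _read_variants_tsv(path: Path, column_map: Mapping[str, str]) -> list[VariantRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    rename = {v: k for k, v in column_map.items()}
    frame = frame.rename(columns=rename)
    missing = [c for c in VARIANT_TSV_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    records: list[VariantRecord] = []
    errors: list[str] = []
    for i, row in frame.iterrows():
        line = i + 2  # header is line 1
        try:
            records.append(
                VariantRecord(
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    ref=str(row["ref"]),
                    alt=str(row["alt"]),
                    gene=str(row["gene"]),
                    vaf=float(row["vaf"]),
                    alt_reads=int(row["alt_reads"]),
                    tumor_depth=int(row["tumor_depth"]),
                    normal_depth=int(row["normal_depth"]),
                    impact=impact_from_consequence(str(row["impact"])),
                    cmc_annotated=_parse_bool(row.get("cmc_annotated", "false"), line, "cmc_annotated"),
                    in_gnomad=_parse_bool(row.get("in_gnomad", "false"), line, "in_gnomad"),
                    kind=str(row.get("kind", "SNV")),
                )
            )
        except (MotiscoreError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        kind = VocabularyError if any("impact" in e or "consequence" in e for e in errors) else FormatError
        raise kind(f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors))
    return records


def write_variants(records: Sequence[VariantRecord], path: str | Path) -> None:
    frame = pd.DataFrame([asdict(r) for r in records])
    frame = frame[list(VARIANT_TSV_COLUMNS) + list(VARIANT_TSV_OPTIONAL)]
    frame.to_csv(path, sep="\t", index=False)


_VCF_INFO_DEFAULTS = {
    "gene": "GENE", "vaf": "VAF", "alt_reads": "ALT_READS",
    "tumor_depth": "TDP", "normal_depth": "NDP", "impact": "CSQ_IMPACT",
    "cmc_annotated": "CMC", "in_gnomad": "GNOMAD",
}


def _read_variants_vcf(path: Path, column_map: Mapping[str, str]) -> list[VariantRecord]:
    import pysam

    keys = dict(_VCF_INFO_DEFAULTS, **column_map)
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            for field in ("gene", "vaf", "alt_reads", "tumor_depth", "normal_depth", "impact"):
                if keys[field] not in info:
                    raise FormatError(
                        f"{path}: record at {rec.chrom}:{rec.pos} lacks INFO key "
                        f"{keys[field]!r} (for {field})"
                    )
            def _scalar(value):
                return value[0] if isinstance(value, tuple) else value

            ref = rec.ref
            alt = rec.alts[0] if rec.alts else "."
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    gene=str(_scalar(info[keys["gene"]])),
                    vaf=float(_scalar(info[keys["vaf"]])),
                    alt_reads=int(_scalar(info[keys["alt_reads"]])),
                    tumor_depth=int(_scalar(info[keys["tumor_depth"]])),
                    normal_depth=int(_scalar(info[keys["normal_depth"]])),
                    impact=impact_from_consequence(str(_scalar(info[keys["impact"]]))),
                    cmc_annotated=bool(info.get(keys["cmc_annotated"], False)),
                    in_gnomad=bool(info.get(keys["in_gnomad"], False)),
                    kind="SNV" if len(ref) == 1 and len(alt) == 1 else "indel",
                )
            )
    return records


# -- intervals (BED) ---------------------------------------------------------

def read_intervals(path: str | Path) -> IntervalSet:
    """BED3+ to a merged interval set (0-based half-open; adjacent merged)."""
    tuples = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path} line {line_no}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(
                    f"{path} line {line_no}: start {start} >= end {end}"
                )
            tuples.append((chrom, start, end))
    return IntervalSet.from_tuples(tuples)


def write_intervals(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals.intervals():
            fh.write(f"{chrom}\t{start}\t{end}\n")


# -- CNVs --------------------------------------------------------------------

CNV_TSV_COLUMNS = ("chrom", "start", "end", "copy_number", "clonality", "loglikelihood")


def read_cnvs(path: str | Path) -> list[CnvCall]:
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in CNV_TSV_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    calls = []
    for i, row in frame.iterrows():
        genes = tuple(
            g for g in str(row.get("genes", "") or "").split(";") if g and g != "nan"
        )
        try:
            calls.append(
                CnvCall(
                    chrom=str(row["chrom"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    copy_number=int(row["copy_number"]),
                    clonality=float(row["clonality"]),
                    loglikelihood=float(row["loglikelihood"]),
                    genes=genes,
                )
            )
        except (MotiscoreError, ValueError) as exc:
            raise FormatError(f"{path} line {i + 2}: {exc}") from exc
    return calls


def write_cnvs(calls: Sequence[CnvCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        row = asdict(c)
        row["genes"] = ";".join(c.genes)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- TCR clones --------------------------------------------------------------

_CLONE_DIALECTS = {
    "airr": {"chain": "locus", "cdr3": "junction_aa", "count": "duplicate_count"},
    "trust4": {"chain": "V", "cdr3": "CDR3aa", "count": "#count"},
}
_CHAIN_PREFIXES = {"TRA": "alpha", "TRB": "beta"}


def read_clones(
    path: str | Path,
    dialect: str = "airr",
    column_map: Mapping[str, str] | None = None,
) -> list[TcrClone]:
    """AIRR rearrangement TSV or TRUST4-style report to typed clones.

    The chain is resolved from the locus (AIRR) or the V-gene name (TRUST4);
    non-alpha/beta chains are skipped. Unknown columns are preserved but
    ignored.
    """
    if dialect not in _CLONE_DIALECTS:
        raise FormatError(f"unknown clone dialect {dialect!r}")
    cols = dict(_CLONE_DIALECTS[dialect], **(column_map or {}))
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [v for v in cols.values() if v not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    clones = []
    for i, row in frame.iterrows():
        chain_raw = str(row[cols["chain"]]).upper()
        chain = next(
            (name for prefix, name in _CHAIN_PREFIXES.items()
             if chain_raw.startswith(prefix)),
            None,
        )
        if chain is None:
            continue
        try:
            clones.append(
                TcrClone(chain=chain, cdr3=str(row[cols["cdr3"]]),
                         count=int(float(row[cols["count"]])))
            )
        except (MotiscoreError, ValueError) as exc:
            raise FormatError(f"{path} line {i + 2}: {exc}") from exc
    return clones


def write_clones_airr(clones: Sequence[TcrClone], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "locus": ["TRA" if c.chain == "alpha" else "TRB" for c in clones],
            "junction_aa": [c.cdr3 for c in clones],
            "duplicate_count": [c.count for c in clones],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


# -- neoantigen candidates ---------------------------------------------------

NEOANTIGEN_COLUMNS = ("peptide", "hla_allele", "median_affinity_nm", "rna_reads")


def read_neoantigens(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[NeoantigenCandidate]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    rename = {v: k for k, v in (column_map or {}).items()}
    frame = frame.rename(columns=rename)
    missing = [c for c in NEOANTIGEN_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    out = []
    for i, row in frame.iterrows():
        try:
            out.append(
                NeoantigenCandidate(
                    peptide=str(row["peptide"]),
                    hla_allele=str(row["hla_allele"]),
                    median_affinity_nm=float(row["median_affinity_nm"]),
                    rna_reads=int(row["rna_reads"]),
                )
            )
        except (MotiscoreError, ValueError) as exc:
            raise FormatError(f"{path} line {i + 2}: {exc}") from exc
    return out


def write_neoantigens(cands: Sequence[NeoantigenCandidate], path: str | Path) -> None:
    pd.DataFrame([asdict(c) for c in cands]).to_csv(path, sep="\t", index=False)


# -- HLA genotypes -----------------------------------------------------------

def read_hla(path: str | Path) -> dict[str, tuple[str, str]]:
    """TSV with columns locus, allele1, allele2 -> normalized allele pairs."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("locus", "allele1", "allele2"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    out = {}
    for _, row in frame.iterrows():
        locus = str(row["locus"]).upper()
        out[locus] = (
            parse_hla_allele(row["allele1"])[1],
            parse_hla_allele(row["allele2"])[1],
        )
    return out


def write_hla(alleles: Mapping[str, tuple[str, str]], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {"locus": locus, "allele1": pair[0], "allele2": pair[1]}
            for locus, pair in alleles.items()
        ]
    )
    frame.to_csv(path, sep="\t", index=False)


# -- counts and clinical -----------------------------------------------------

def read_counts(path: str | Path, gene_column: str = "gene") -> pd.DataFrame:
    """Gene x sample raw count matrix; genes as index."""
    frame = pd.read_csv(path, sep="\t")
    if gene_column not in frame.columns:
        raise FormatError(f"{path}: missing gene-id column {gene_column!r}")
    frame = frame.set_index(gene_column)
    if frame.index.duplicated().any():
        raise IntegrityError(f"{path}: duplicate gene ids")
    values = frame.to_numpy()
    if (values < 0).any():
        raise IntegrityError(f"{path}: negative count entries")
    return frame


RECIST_MAP = {
    "CR": "responder",
    "PR": "responder",
    "SD": "non_responder",
    "PD": "non_responder",
}


def map_recist(label: str) -> str:
    """CR/PR -> responder, SD/PD -> non_responder, anything else unknown."""
    clean = str(label).strip()
    if clean in ("responder", "non_responder", "unknown"):
        return clean
    return RECIST_MAP.get(clean.upper(), "unknown")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Clinical TSV -> frame with sample_id, outcome, survival_time, event
    and any extra columns (cancer_type, ici flag) preserved."""
    frame = pd.read_csv(path, sep="\t")
    if "sample_id" not in frame.columns:
        raise FormatError(f"{path}: missing mandatory column 'sample_id'")
    if frame["sample_id"].duplicated().any():
        dupes = sorted(set(frame.loc[frame["sample_id"].duplicated(), "sample_id"]))
        raise IntegrityError(f"{path}: duplicate sample_id(s) {dupes}")
    source = "recist" if "recist" in frame.columns else "outcome"
    if source not in frame.columns:
        raise FormatError(f"{path}: needs a 'recist' or 'outcome' column")
    frame["outcome"] = frame[source].map(map_recist)
    if "event" in frame.columns:
        frame["event"] = frame["event"].map(
            lambda v: v if pd.isna(v) else bool(int(v))
        )
    return frame


def read_cohort(panels_path: str | Path, clinical_path: str | Path) -> CohortTable:
    panels = pd.read_csv(panels_path, sep="\t")
    if "sample_id" not in panels.columns:
        raise FormatError(f"{panels_path}: missing mandatory column 'sample_id'")
    clinical = read_clinical(clinical_path)
    merged = panels.merge(
        clinical.drop(columns=[c for c in ("recist",) if c in clinical.columns]),
        on="sample_id",
        how="left",
    )
    merged["outcome"] = merged["outcome"].fillna("unknown")
    return CohortTable(merged)


def write_panels(cohort: CohortTable, path: str | Path) -> None:
    cols = ["sample_id"] + cohort.biomarker_columns()
    if "cxcl_combined" in cohort.frame.columns:
        cols.append("cxcl_combined")
    cohort.frame[cols].to_csv(path, sep="\t", index=False)


# -- model serialization -----------------------------------------------------

def save_model(model: ScoreModel, path: str | Path) -> None:
    model.validate()
    payload = {
        "schema_version": model.schema_version,
        "selected": model.selected,
        "p_values": model.p_values,
        "weights": model.weights,
        "means": model.means,
        "sds": model.sds,
        "cutoff": model.cutoff,
        "provenance": model.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_model(path: str | Path) -> ScoreModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise FormatError(
            f"{path}: unsupported model schema version {version!r}"
        )
    model = ScoreModel(
        selected=list(payload["selected"]),
        p_values={k: float(v) for k, v in payload["p_values"].items()},
        weights={k: float(v) for k, v in payload["weights"].items()},
        means={k: float(v) for k, v in payload["means"].items()},
        sds={k: float(v) for k, v in payload["sds"].items()},
        cutoff=None if payload.get("cutoff") is None else float(payload["cutoff"]),
        provenance=payload.get("provenance", {}),
    )
    model.validate()  # tampered weights/sds -> IntegrityError
    return model
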