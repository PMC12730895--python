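"""Loaders for packaged reference tables.

* ``grantham.tsv`` — 20x20 amino-acid distance matrix generated from the
  classical composition/polarity/molecular-volume formula
  (alpha=1.833, beta=0.1018, gamma=0.000399, rho=50.723), integer-rounded.
* ``vep_impact.tsv`` — VEP consequence term -> 4-level ordered impact.
* ``hla_grooves_synthetic.tsv`` — SYNTHETIC aligned binding-groove sequences
  per 4-digit class-I allele. This is a seeded random stand-in with realistic
  pairwise divergence, packaged so that allele-divergence arithmetic is fully
  testable; it does not contain real IMGT/HLA sequence.
* ``gene_lists.yaml`` — resistance/response gene sets and symbol aliases.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
import yaml


def _path(name: str):
    return resources.files("motiscore.data").joinpath(name)


@lru_cache(maxsize=None)
def grantham_frame() -> pd.DataFrame:
    with resources.as_file(_path("grantham.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col=0)


@lru_cache(maxsize=None)
def vep_impact_table() -> dict[str, str]:
    with resources.as_file(_path("vep_impact.tsv")) as p:
        frame = pd.read_csv(p, sep="\t")
    return dict(zip(frame["consequence"], frame["impact"]))


@lru_cache(maxsize=None)
def hla_groove_table() -> dict[str, str]:
    with resources.as_file(_path("hla_grooves_synthetic.tsv")) as p:
        frame = pd.read_csv(p, sep="\t")
    return dict(zip(frame["allele"], frame["groove_seq"]))


@lru_cache(maxsize=None)
def gene_lists() -> dict:
    with resources.as_file(_path("gene_lists.yaml")) as p:
        return yaml.safe_load(p.read_text())


def resolve_gene_symbol(symbol: str) -> str:
    """Map known aliases (CALX->CANX, PDL1->CD274) to canonical symbols."""
    return gene_lists()["gene_aliases"].get(symbol, symbol)
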