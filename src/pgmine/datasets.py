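"""Packaged survey tables for the MMETSP dinoflagellate collection.

Three small TSV fixtures transcribed from the published survey of the
42 MMETSP dinoflagellate transcriptomes make the summarization logic
testable without downloading any external data:

* growth-condition metadata for the 42 transcriptomes (15 genera,
  19 species, culture light/photoperiod/nutrient/salinity columns);
* per-transcriptome assembly statistics (sequence counts, contig
  length extremes, N50) — one transcriptome has no reported values and
  loads as missing;
* the boolean species x enzyme-function presence matrix for the
  fourteen species in which at least one prostaglandin-metabolism
  function was annotated.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd

from .vocabulary import FUNCTION_ORDER


def _read(name: str, **kwargs) -> pd.DataFrame:
    text = resources.files("pgmine.data").joinpath(name).read_text()
    return pd.read_csv(StringIO(text), sep="\t", **kwargs)


def load_growth_conditions() -> pd.DataFrame:
    """42 transcriptomes with genus, species, MMETSP code and culture metadata."""
    return _read("dinoflagellate_growth_conditions.tsv", dtype=str)


def load_assembly_statistics() -> pd.DataFrame:
    """Per-transcriptome assembly statistics, indexed by MMETSP code."""
    df = _read("dinoflagellate_assembly_stats.tsv")
    return df.set_index("mmetsp_code")


def load_species_presence() -> pd.DataFrame:
    """Boolean species x function presence matrix (vocabulary column order)."""
    df = _read("species_function_presence.tsv", index_col=0)
    df = df[FUNCTION_ORDER].astype(bool)
    df.index.name = "species"
    return df
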