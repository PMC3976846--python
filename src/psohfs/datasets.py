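"""Bundled reference fixtures for the 27-syndrome HCC configuration.

Two text fixtures ship with the package:

* ``hcc_syndrome_groups.json`` — the 147-symptom / 27-group arrangement
  (names, sizes, exclusivity).  Member symptom names are documented only
  for four groups; the rest are synthetic placeholders.
* ``syndrome_ranking_reference.csv`` — the published per-syndrome relevance
  statistics (mcc, pe) together with the fr scores and ranks they induce.
  The mcc/pe columns are inputs for recomputation; fr and rank are the
  reference outputs.

``OPTIMAL_SUBSET_BITSTRING`` is the reported optimal syndrome subset: 24 of
the 27 syndromes, dropping lip color, tongue color and coated tongue color.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .hierarchy import GroupSpec, read_group_specs

__all__ = [
    "load_group_specs",
    "load_ranking_reference",
    "OPTIMAL_SUBSET_BITSTRING",
]

OPTIMAL_SUBSET_BITSTRING = "001101111111111111111111111"


def _data_path(name: str):
    return resources.files("psohfs.data").joinpath(name)


def load_group_specs() -> list[GroupSpec]:
    """The 27-group / 147-symptom grouping fixture."""
    with resources.as_file(_data_path("hcc_syndrome_groups.json")) as path:
        return read_group_specs(path)


def load_ranking_reference() -> pd.DataFrame:
    """Reference relevance statistics: name, abbreviation, size, mcc, pe,
    fr, rank — one row per syndrome, 27 rows."""
    with resources.as_file(_data_path("syndrome_ranking_reference.csv")) as path:
        return pd.read_csv(path)
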