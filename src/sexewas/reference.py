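"""Reference meta-analysis tables for worked examples and concordance checks.

Two small tables of published inverse-variance meta-analysis results from a
large sex-stratified EWAS of AD neuropathology in prefrontal cortex are
bundled with the package:

- ``stratified_top_cpgs``: the ten most significant CpGs in each sex that
  are highly significant in that sex (FDR < 0.05) but not in the other
  (P > 0.05), with female and male effect estimates.
- ``interaction_cpgs``: the fourteen CpGs with a significant sex-by-Braak
  interaction, with per-sex and interaction estimates.

These illustrate the complementarity of the two analyses: top stratified
hits mostly share their direction of effect across sexes, while
interaction hits almost always have opposite directions.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("sexewas.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


def stratified_top_cpgs() -> pd.DataFrame:
    """Top sex-specific CpGs from the stratified reference meta-analysis."""
    return _load("stratified_top_cpgs.tsv")


def interaction_cpgs() -> pd.DataFrame:
    """CpGs with a significant sex-by-Braak interaction in the reference study."""
    return _load("interaction_cpgs.tsv")
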