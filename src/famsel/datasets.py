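"""Packaged reference fixtures.

``haplotype_panel.tsv`` transcribes the published 45 three-locus DLA
haplotypes with per-breed frequencies in 10 purebred and 4 mixed-breed
groups.  The haplotype triples, the per-row frequency values and the
per-breed sample sizes are verbatim from the published table; the placement of
each frequency in its breed column was reconstructed by constraint
satisfaction (strictly increasing column order within a row, column sums of
one, and integer copy counts out of 2n gene copies), because the extracted
table text does not preserve the column alignment.  Rows with breed label
``NA`` are the table's unassigned-haplotype remainders.

``breed_groups.tsv`` holds the study design: breed groups with offspring
and family counts (430 puppies, 110 families, mean litter 3.9).
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .types import Haplotype

__all__ = ["load_haplotype_table", "load_breed_table", "breed_panels",
           "pooled_panel"]


def _data(name: str):
    return resources.files("famsel").joinpath("data", name)


def load_haplotype_table(include_unassigned: bool = False) -> pd.DataFrame:
    """Long-format haplotype panel: drb1 dqa1 dqb1 breed frequency count."""
    with resources.as_file(_data("haplotype_panel.tsv")) as p:
        df = pd.read_csv(p, sep="\t", keep_default_na=False,
                         dtype={"drb1": str, "dqa1": str, "dqb1": str})
    if not include_unassigned:
        df = df[df.drb1 != "NA"].reset_index(drop=True)
    return df


def load_breed_table() -> pd.DataFrame:
    """Breed groups with offspring/family counts and sampling metadata."""
    with resources.as_file(_data("breed_groups.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def breed_panels(normalize: bool = True) -> dict:
    """Per-breed haplotype frequency panels for simulation.

    Returns ``{breed_code: {Haplotype: frequency}}``.  Unassigned (NA)
    remainders are dropped; with ``normalize`` each breed's frequencies are
    rescaled to sum to exactly one.
    """
    df = load_haplotype_table()
    panels = {}
    for code, grp in df.groupby("breed"):
        total = grp["frequency"].sum()
        panels[code] = {
            Haplotype(r.drb1, r.dqa1, r.dqb1):
                (r.frequency / total if normalize else r.frequency)
            for r in grp.itertuples()
        }
    return panels


def pooled_panel() -> dict:
    """Copy-count-weighted pooled frequency panel over all breed groups."""
    df = load_haplotype_table()
    counts = df.groupby(["drb1", "dqa1", "dqb1"])["count"].sum()
    total = counts.sum()
    return {Haplotype(*key): c / total for key, c in counts.items()}
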