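"""Trait tables: raw per-record values (g·m⁻²) and derived per-species log means.

Comparative statistics run on the log scale (one value ``l`` per species, the
mean of log-transformed records); raw-scale values are kept for descriptive
summaries such as the among/within-species variance partition.
"""
from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .phylo import Phylogeny

__all__ = ["TraitTable", "read_trait_table", "GROWTH_FORMS", "WOODY_FORMS", "HERB_FORMS"]

WOODY_FORMS = {"shrub", "tree", "woody"}
HERB_FORMS = {"forb", "graminoid", "herb", "herbaceous"}
GROWTH_FORMS = WOODY_FORMS | HERB_FORMS


class TraitTable:
    """Replicate-level trait records with per-species derived quantities.

    Parameters
    ----------
    records
        DataFrame with columns ``species``, ``value`` (raw trait, > 0) and
        optionally ``growth_form`` and ``site``.
    """

    def __init__(self, records: pd.DataFrame):
        required = {"species", "value"}
        if not required.issubset(records.columns):
            raise ValueError(f"trait table needs columns {sorted(required)}")
        records = records.copy()
        records["value"] = records["value"].astype(float)
        if (records["value"] <= 0).any():
            bad = records.loc[records["value"] <= 0, "species"].unique()
            raise ValueError(f"non-positive trait values for: {list(bad)[:5]}")
        if "growth_form" in records.columns:
            forms = set(records["growth_form"].dropna().unique())
            unknown = forms - GROWTH_FORMS
            if unknown:
                raise ValueError(f"unknown growth forms: {sorted(unknown)}")
        self.data = records.reset_index(drop=True)

    # -- derived per-species views -------------------------------------
    @property
    def species(self) -> list[str]:
        return list(self.data["species"].unique())

    @property
    def log_means(self) -> pd.Series:
        """Per-species mean of log-transformed records (the analysis scale)."""
        return np.log(self.data["value"]).groupby(self.data["species"]).mean()

    @property
    def raw_means(self) -> pd.Series:
        return self.data.groupby("species")["value"].mean()

    def growth_form_of(self) -> pd.Series:
        if "growth_form" not in self.data.columns:
            raise ValueError("trait table has no growth_form column")
        return self.data.groupby("species")["growth_form"].first()

    def species_in_class(self, cls: str) -> list[str]:
        """Species whose growth form falls in ``'woody'`` or ``'herbaceous'``."""
        target = WOODY_FORMS if cls == "woody" else HERB_FORMS
        forms = self.growth_form_of()
        return list(forms.index[forms.isin(target)])

    def subset(self, species: Iterable[str]) -> "TraitTable":
        keep = set(species)
        return TraitTable(self.data[self.data["species"].isin(keep)])

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str) -> None:
        self.data.to_csv(path, index=False)


def read_trait_table(path: str) -> TraitTable:
    """Read a CSV with header ``species,value[,growth_form][,site]``."""
    return TraitTable(pd.read_csv(path))


def aligned_values(traits, tree: Phylogeny) -> np.ndarray:
    """Per-species analysis-scale values aligned with ``tree.tip_labels``.

    Accepts a :class:`TraitTable` (log means are used), a mapping/Series of
    already-transformed values, or an array in tip order.
    """
    labels = tree.tip_labels
    if isinstance(traits, TraitTable):
        series = traits.log_means
    elif isinstance(traits, pd.Series):
        series = traits
    elif isinstance(traits, Mapping):
        series = pd.Series(traits)
    else:
        arr = np.asarray(traits, dtype=float)
        if arr.shape != (len(labels),):
            raise ValueError("trait array length does not match tip count")
        return arr
    missing = [t for t in labels if t not in series.index]
    if missing:
        raise ValueError(f"traits missing for tips: {missing[:10]}")
    return series.reindex(labels).to_numpy(dtype=float)
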