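"""Corpora datasets: per-individual (age, cumulative corpora count) records.

The raw input of the pipeline is a cross-sectional sample of dead
females, each with an independent age estimate (years) and a count of
ovarian corpora (corpora lutea + corpora albicantia), optionally with a
pregnancy indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_REQUIRED_COLUMNS = ("id", "age", "corpora")


@dataclass
class CorporaDataset:
    """A single species' individual records.

    ``data`` has columns ``id`` (individual identifier), ``age``
    (years, finite and non-negative), ``corpora`` (non-negative
    integer) and optionally ``pregnant`` (0/1).
    """

    species: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        self.data = self.data.reset_index(drop=True)
        ages = np.asarray(self.data["age"], dtype=float)
        if not np.all(np.isfinite(ages)) or np.any(ages < 0):
            raise ValueError("ages must be finite and non-negative")
        corpora = np.asarray(self.data["corpora"], dtype=float)
        if np.any(corpora < 0) or np.any(corpora != np.round(corpora)):
            raise ValueError("corpora counts must be non-negative integers")
        self.data["age"] = ages
        self.data["corpora"] = corpora.astype(int)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def ages(self) -> np.ndarray:
        return self.data["age"].to_numpy(dtype=float)

    @property
    def corpora(self) -> np.ndarray:
        return self.data["corpora"].to_numpy(dtype=int)

    @property
    def has_pregnancy(self) -> bool:
        return "pregnant" in self.data.columns

    def subset(self, mask) -> "CorporaDataset":
        return CorporaDataset(self.species, self.data.loc[mask].copy())

    def drop_ids(self, ids) -> "CorporaDataset":
        keep = ~self.data["id"].isin(set(ids))
        return self.subset(keep)


def write_corpora_csv(datasets, path) -> None:
    """Write one or more datasets to the shared CSV dialect.

    Header is ``species,id,age,corpora[,pregnant]``; the pregnancy
    column appears only if at least one dataset carries it.
    """
    if isinstance(datasets, CorporaDataset):
        datasets = [datasets]
    frames = []
    any_preg = any(ds.has_pregnancy for ds in datasets)
    for ds in datasets:
        frame = ds.data.copy()
        frame.insert(0, "species", ds.species)
        if any_preg and "pregnant" not in frame.columns:
            frame["pregnant"] = np.nan
        frames.append(frame)
    combined = pd.concat(frames, ignore_index=True)
    cols = ["species", "id", "age", "corpora"] + (["pregnant"] if any_preg else [])
    combined[cols].to_csv(path, index=False)


def read_corpora_csv(path) -> dict:
    """Read the CSV dialect back into ``{species: CorporaDataset}``."""
    frame = pd.read_csv(path)
    if "species" not in frame.columns:
        raise ValueError(f"{path}: missing 'species' column")
    out = {}
    for species, group in frame.groupby("species", sort=False):
        sub = group.drop(columns=["species"]).copy()
        if "pregnant" in sub.columns and sub["pregnant"].isna().all():
            sub = sub.drop(columns=["pregnant"])
        out[str(species)] = CorporaDataset(str(species), sub)
    return out
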