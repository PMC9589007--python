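"""Core data containers: intensity matrices and gene-set collections.

An :class:`IntensityMatrix` wraps a proteins x samples :class:`pandas.DataFrame`
of abundances where missing cells are ``NaN``; the observed/missing mask is
derived from the values (mask true <=> value present). ``scale`` records
whether values are raw intensities or log2-transformed, since several pipeline
stages are only defined on the log2 scale.

A :class:`GeneSetCollection` is an ordered name -> members mapping with
optional per-set descriptions, round-trippable through the GMT format
(tab-separated: name, description, member genes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["IntensityMatrix", "GeneSetCollection", "read_gmt", "write_gmt"]


@dataclass
class IntensityMatrix:
    """Proteins x samples abundance matrix with explicit missingness.

    Parameters
    ----------
    values
        DataFrame indexed by protein (or gene) identifier with one column per
        sample; ``NaN`` marks a missing cell.
    tissue
        Label of the tissue the matrix was measured in.
    scale
        ``"raw"`` (positive intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    tissue: str = ""
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        if not self.values.index.is_unique:
            raise ValueError("protein identifiers must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample identifiers must be unique")
        if self.scale == "raw":
            with np.errstate(invalid="ignore"):
                if (self.values.to_numpy() < 0).any():
                    raise ValueError("raw-scale matrix contains negative values")

    # -- basic introspection -------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean observed-mask, True where a value is present."""
        return self.values.notna()

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), tissue=self.tissue, scale=self.scale)

    # -- I/O -----------------------------------------------------------------
    def to_tsv(self, path: str | Path, protein_col: str = "protein_id") -> None:
        out = self.values.copy()
        out.index.name = protein_col
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        tissue: str = "",
        scale: str = "log2",
        protein_col: str = "protein_id",
    ) -> "IntensityMatrix":
        df = pd.read_csv(path, sep="\t")
        if protein_col not in df.columns:
            raise ValueError(f"expected a {protein_col!r} first column in {path}")
        df = df.set_index(protein_col)
        return cls(df.astype(float), tissue=tissue, scale=scale)


class GeneSetCollection:
    """Named gene sets with membership, backed by an insertion-ordered dict.

    Set names are unique and members are stored as ordered, de-duplicated
    tuples; empty sets are rejected.
    """

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]] | None = None,
        descriptions: Mapping[str, str] | None = None,
        name: str = "",
    ) -> None:
        self.name = name
        self._sets: dict[str, tuple[str, ...]] = {}
        self.descriptions: dict[str, str] = {}
        if sets:
            for set_name, members in sets.items():
                self.add(set_name, members, (descriptions or {}).get(set_name, ""))

    def add(self, set_name: str, members: Iterable[str], description: str = "") -> None:
        if set_name in self._sets:
            raise ValueError(f"duplicate gene-set name: {set_name!r}")
        uniq = tuple(dict.fromkeys(members))
        if not uniq:
            raise ValueError(f"gene set {set_name!r} has no members")
        self._sets[set_name] = uniq
        self.descriptions[set_name] = description

    # -- mapping protocol ----------------------------------------------------
    def __getitem__(self, set_name: str) -> tuple[str, ...]:
        return self._sets[set_name]

    def __contains__(self, set_name: str) -> bool:
        return set_name in self._sets

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def items(self):
        return self._sets.items()

    def keys(self):
        return self._sets.keys()

    def members(self, set_name: str) -> tuple[str, ...]:
        return self._sets[set_name]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for members in self._sets.values():
            out.update(members)
        return out

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: self._sets[n] for n in names},
            {n: self.descriptions[n] for n in names},
            name=self.name,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self._sets == other._sets and self.descriptions == other.descriptions

    def __repr__(self) -> str:
        return f"GeneSetCollection({self.name!r}, n_sets={len(self)})"


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT (one line per set: name, description, members)."""
    with open(path, "w") as fh:
        for set_name, members in collection.items():
            desc = collection.descriptions.get(set_name, "")
            fh.write("\t".join([set_name, desc, *members]) + "\n")


def read_gmt(path: str | Path, name: str = "") -> GeneSetCollection:
    """Read a GMT file; lines with fewer than three fields are rejected."""
    collection = GeneSetCollection(name=name or Path(path).stem)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            collection.add(fields[0], fields[2:], fields[1])
    return collection


@dataclass
class RunManifest:
    """Record of a pipeline run: config hash, stage row counts, versions."""

    config_hash: str
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    versions: dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, **info) -> None:
        self.stages[stage] = info

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "stages": self.stages,
                    "versions": self.versions,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
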