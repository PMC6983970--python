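"""Core data containers shared by all pipeline stages.

All tabular I/O is plain TSV:

* expression / mutation matrices: first column is the gene identifier
  (header ``gene``), remaining columns are sample identifiers;
* survival tables: columns ``sample``, ``time``, ``event``.

Lines starting with ``#`` are treated as comments (the pipeline stamps a
config hash there).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "SurvivalTable", "MutationMatrix"]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log-scale expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_ids: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"gene {exc.args[0]!r} not present") from None

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(gene_ids)
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids), self.values[idx])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[s] for s in sample_ids], dtype=int)
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df = self.to_frame()
            df.index.name = "gene"
            df.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float))


@dataclass
class SurvivalTable:
    """Per-sample follow-up time (positive) and event indicator (1 = death)."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length must match sample_ids")
        _check_unique(self.sample_ids, "sample")
        if np.any(self.time <= 0) or not np.all(np.isfinite(self.time)):
            raise ValueError("survival times must be positive and finite")
        if not np.all(np.isin(self.event, [0, 1])):
            raise ValueError("event indicator must be 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def align(self, sample_ids: Sequence[str]) -> "SurvivalTable":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[s] for s in sample_ids], dtype=int)
        return SurvivalTable(list(sample_ids), self.time[idx], self.event[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": self.sample_ids, "time": self.time, "event": self.event})

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SurvivalTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(list(df["sample"].astype(str)), df["time"].to_numpy(float), df["event"].to_numpy(int))


@dataclass
class MutationMatrix:
    """Binary genes x samples mutation status matrix."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=int)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("mutation matrix shape mismatch")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isin(self.values, [0, 1])):
            raise ValueError("mutation matrix must be binary")

    def mutated_samples(self, gene_id: str) -> list[str]:
        row = self.values[self.gene_ids.index(gene_id)]
        return [s for s, v in zip(self.sample_ids, row) if v == 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df = self.to_frame()
            df.index.name = "gene"
            df.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(int))

    @classmethod
    def from_maf_lite(cls, path: str | Path, sample_ids: Sequence[str] | None = None) -> "MutationMatrix":
        """Collapse a MAF-lite table (columns gene, sample[, class]) to binary."""
        df = pd.read_csv(path, sep="\t", comment="#")
        genes = sorted(df["gene"].astype(str).unique())
        samples = list(sample_ids) if sample_ids is not None else sorted(df["sample"].astype(str).unique())
        sidx = {s: i for i, s in enumerate(samples)}
        mat = np.zeros((len(genes), len(samples)), dtype=int)
        gidx = {g: i for i, g in enumerate(genes)}
        for g, s in zip(df["gene"].astype(str), df["sample"].astype(str)):
            if s in sidx:
                mat[gidx[g], sidx[s]] = 1
        return cls(genes, samples, mat)
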