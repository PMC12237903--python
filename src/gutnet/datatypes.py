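"""Core containers shared across the pipeline.

An :class:`OtuTable` is the universal input: an integer count matrix of
OTUs (rows) by samples (columns), optionally annotated with a gut-location
("site") label per sample.  Correlation inference produces a
:class:`CorrelationResult`; thresholding its p-values yields a flat edge
catalog (a pandas DataFrame with columns ``otu_a, otu_b, r, p, site``)
that feeds the meta-analysis, network and specificity stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

EDGE_COLUMNS = ["otu_a", "otu_b", "r", "p", "site"]


class OtuTable:
    """Integer OTU-by-sample count table.

    Parameters
    ----------
    counts:
        2-D non-negative integer array, OTUs x samples, or a DataFrame
        (index = OTU ids, columns = sample ids).
    otu_ids, sample_ids:
        Identifiers; required when ``counts`` is a bare array.
    sites:
        Optional per-sample site label (e.g. ileum/cecum/feces).
    """

    def __init__(self, counts, otu_ids=None, sample_ids=None, sites=None):
        if isinstance(counts, pd.DataFrame):
            df = counts
        else:
            arr = np.asarray(counts)
            if otu_ids is None:
                otu_ids = [f"OTU_{i + 1}" for i in range(arr.shape[0])]
            if sample_ids is None:
                sample_ids = [f"S{j + 1}" for j in range(arr.shape[1])]
            df = pd.DataFrame(arr, index=list(otu_ids), columns=list(sample_ids))
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(values < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        self.df = df.astype(np.int64)
        if sites is not None:
            sites = pd.Series(list(sites), index=self.df.columns)
        self.sites = sites

    # -- basic accessors -------------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def n_otus(self) -> int:
        return self.df.shape[0]

    @property
    def n_samples(self) -> int:
        return self.df.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions (columns sum to 1)."""
        totals = self.df.sum(axis=0)
        if (totals == 0).any():
            bad = totals.index[totals == 0].tolist()
            raise ValueError(f"samples with zero total count: {bad}")
        return self.df / totals

    def mean_relative_abundance(self) -> pd.Series:
        """Mean over samples of per-sample proportions, per OTU."""
        return self.relative_abundance().mean(axis=1)

    def select_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        return OtuTable(self.df.loc[list(otu_ids)], sites=self.sites)

    def __eq__(self, other):
        return isinstance(other, OtuTable) and self.df.equals(other.df)

    def __repr__(self):
        return f"OtuTable({self.n_otus} OTUs x {self.n_samples} samples)"


@dataclass
class CorrelationResult:
    """SparCC point estimate and bootstrap p-values for one site."""

    otu_ids: list[str]
    rho: np.ndarray
    p: np.ndarray | None = None
    settings: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        d = len(self.otu_ids)
        if self.rho.shape != (d, d):
            raise ValueError("rho shape does not match otu_ids")
        if self.p is not None:
            self.p = np.asarray(self.p, dtype=float)
            if self.p.shape != (d, d):
                raise ValueError("p shape does not match otu_ids")

    def rho_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.otu_ids, columns=self.otu_ids)

    def p_frame(self) -> pd.DataFrame:
        if self.p is None:
            raise ValueError("no p-values computed")
        return pd.DataFrame(self.p, index=self.otu_ids, columns=self.otu_ids)


def edge_catalog(records: Sequence[tuple] | pd.DataFrame | None = None) -> pd.DataFrame:
    """Build a canonical edge catalog (``otu_a < otu_b`` lexicographically)."""
    if records is None or (not isinstance(records, pd.DataFrame) and len(records) == 0):
        return pd.DataFrame(columns=EDGE_COLUMNS)
    df = pd.DataFrame(records, columns=EDGE_COLUMNS) if not isinstance(records, pd.DataFrame) else records.copy()
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"edge catalog missing columns: {missing}")
    a = df["otu_a"].astype(str)
    b = df["otu_b"].astype(str)
    swap = a > b
    df.loc[swap, ["otu_a", "otu_b"]] = df.loc[swap, ["otu_b", "otu_a"]].to_numpy()
    return df[EDGE_COLUMNS].reset_index(drop=True)


class TaxonomyMap:
    """OTU id -> Greengenes-style 7-rank lineage string.

    Lineages look like ``k__Bacteria; p__Firmicutes; ...; g__Prevotella; s__``;
    unknown ranks are present but empty.
    """

    RANKS = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]
    PREFIXES = ["k__", "p__", "c__", "o__", "f__", "g__", "s__"]

    def __init__(self, lineages: Mapping[str, str]):
        self.lineages = dict(lineages)

    def __getitem__(self, otu_id: str) -> str:
        return self.lineages[otu_id]

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)

    def ranks(self, otu_id: str) -> dict[str, str]:
        """Parse a lineage into rank -> name (empty string when unannotated)."""
        parts = [p.strip() for p in self.lineages[otu_id].split(";")]
        if len(parts) > 7:
            raise ValueError(f"lineage for {otu_id} has more than 7 ranks")
        out = {}
        for rank, prefix, part in zip(self.RANKS, self.PREFIXES, parts + [""] * (7 - len(parts))):
            name = part[len(prefix):] if part.startswith(prefix) else part
            out[rank] = name.strip()
        return out

    def taxon(self, otu_id: str, rank: str = "genus", fallback: bool = True) -> str:
        """Name at ``rank``, falling back to the lowest annotated rank above it.

        Returns ``"Unclassified"`` when nothing is annotated or the OTU is
        missing from the map.
        """
        if otu_id not in self.lineages:
            return "Unclassified"
        ranks = self.ranks(otu_id)
        if rank not in self.RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        idx = self.RANKS.index(rank)
        if ranks[rank]:
            return ranks[rank]
        if not fallback:
            return "Unclassified"
        for r in reversed(self.RANKS[:idx]):
            if ranks[r]:
                return ranks[r]
        return "Unclassified"
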