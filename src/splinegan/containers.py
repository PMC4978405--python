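"""Core data containers shared across the pipeline.

The universal input is a :class:`TimecourseExperiment`: a genes x samples
matrix of log-scale expression values plus per-sample annotations assigning
each sample to a group (control / treatment), a sampling time in hours and a
replicate identifier.  Gene identity is the plain symbol string,
case-sensitive, with exactly one expression row per gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx
import numpy as np
import pandas as pd

GROUP_CONTROL = "control"
GROUP_TREATMENT = "treatment"
REQUIRED_ANNOTATION_COLUMNS = ("group", "time", "replicate")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Order-independent representation of an undirected edge."""
    return (a, b) if a <= b else (b, a)


@dataclass
class TimecourseExperiment:
    """Expression matrix plus per-sample group/time/replicate annotations.

    Parameters
    ----------
    values
        genes x samples DataFrame of real numbers (log2-scale intensities).
        NaN marks a missing measurement; rows containing NaN are excluded
        from model fitting downstream, with a logged count.
    annotations
        One row per sample (index = sample id) with columns ``group``
        (``control`` or ``treatment``), ``time`` (hours, > 0) and
        ``replicate``.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dup}")
        missing_cols = [c for c in REQUIRED_ANNOTATION_COLUMNS if c not in self.annotations.columns]
        if missing_cols:
            raise ValidationError(f"sample sheet lacks required columns: {missing_cols}")
        unknown = set(self.values.columns) - set(self.annotations.index)
        if unknown:
            raise ValidationError(f"samples missing from sample sheet: {sorted(unknown)}")
        # align annotation order to the matrix column order
        self.annotations = self.annotations.loc[list(self.values.columns)].copy()
        groups = set(self.annotations["group"])
        bad = groups - {GROUP_CONTROL, GROUP_TREATMENT}
        if bad:
            raise ValidationError(
                f"unknown group labels {sorted(bad)}; map labels to "
                f"'{GROUP_CONTROL}'/'{GROUP_TREATMENT}' when reading the sheet"
            )
        times = pd.to_numeric(self.annotations["time"], errors="coerce")
        if times.isna().any():
            raise ValidationError("non-numeric time values in sample sheet")
        if (times <= 0).any():
            raise ValidationError("sampling times must be positive hours")
        self.annotations["time"] = times.astype(float)
        for g in groups:
            t = self.annotations.loc[self.annotations["group"] == g, "time"]
            if t.nunique() < 2:
                raise ValidationError(f"group '{g}' has fewer than 2 distinct time points")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def times(self, group: str | None = None) -> np.ndarray:
        """Per-sample times (hours), optionally restricted to one group."""
        ann = self.annotations
        if group is not None:
            ann = ann[ann["group"] == group]
        return ann["time"].to_numpy(float)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.annotations.index[self.annotations["group"] == group])

    def group_indicator(self) -> np.ndarray:
        """0 for control samples, 1 for treatment, in sample order."""
        return (self.annotations["group"] == GROUP_TREATMENT).to_numpy(int)

    def complete_genes_mask(self) -> pd.Series:
        return ~self.values.isna().any(axis=1)

    def drop_incomplete_genes(self) -> tuple["TimecourseExperiment", int]:
        """Remove gene rows containing missing values.

        Returns the filtered experiment and the number of dropped genes.
        """
        mask = self.complete_genes_mask()
        n_dropped = int((~mask).sum())
        if n_dropped == 0:
            return self, 0
        return TimecourseExperiment(self.values.loc[mask], self.annotations), n_dropped

    def subset_genes(self, genes: Iterable[str]) -> "TimecourseExperiment":
        genes = list(genes)
        missing = set(genes) - set(self.values.index)
        if missing:
            raise ValidationError(f"genes absent from the matrix: {sorted(missing)}")
        return TimecourseExperiment(self.values.loc[genes], self.annotations)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathway name -> member symbols), e.g. from a GMT file."""

    sets: dict[str, set[str]]
    source: str = ""

    def __post_init__(self) -> None:
        empty = [name for name, genes in self.sets.items() if not genes]
        if empty:
            raise ValidationError(f"empty gene sets: {empty}")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class ReferenceNetwork:
    """Undirected, simple reference interactome over gene symbols."""

    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        canon = set()
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"self-loop on '{a}' in reference network")
            canon.add(canonical_edge(a, b))
        self.edges = canon

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> tuple["ReferenceNetwork", int]:
        """Build from raw pairs; returns (network, number of self-loops dropped)."""
        edges, dropped = set(), 0
        for a, b in pairs:
            if a == b:
                dropped += 1
                continue
            edges.add(canonical_edge(a, b))
        return cls(edges), dropped

    @property
    def nodes(self) -> set[str]:
        return {n for e in self.edges for n in e}

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_edge(a, b) in self.edges

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.edges)

    def subnetwork(self, nodes: Iterable[str]) -> "ReferenceNetwork":
        nodes = set(nodes)
        return ReferenceNetwork({e for e in self.edges if e[0] in nodes and e[1] in nodes})


@dataclass
class Gan:
    """Reconstructed gene association network.

    ``edges`` is a DataFrame with columns ``gene_a``, ``gene_b``, ``pcor``
    and ``prob`` (posterior edge probability); only pairs meeting the
    probability threshold are present and isolated input genes are dropped,
    so the node set is the union of edge endpoints.
    """

    edges: pd.DataFrame
    threshold: float
    n_input_genes: int = 0

    @property
    def nodes(self) -> set[str]:
        if self.edges.empty:
            return set()
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def is_empty(self) -> bool:
        return self.edges.empty

    def edge_set(self) -> set[tuple[str, str]]:
        return {canonical_edge(a, b) for a, b in zip(self.edges["gene_a"], self.edges["gene_b"])}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, pcor=float(row.pcor), prob=float(row.prob))
        return g
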