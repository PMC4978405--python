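"""Readers and writers for every external representation the pipeline touches.

Formats: tab-separated expression matrices and sample sheets, GMT gene-set
collections (Broad convention), two-column edge lists / SIF for networks,
and GraphML export of reconstructed networks.  All text is UTF-8 with '.'
decimal separators; matrices are written with full float precision so
write -> read round-trips are lossless.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .containers import (
    Gan,
    GeneSetCollection,
    ReferenceNetwork,
    TimecourseExperiment,
    ValidationError,
)

logger = logging.getLogger(__name__)

MISSING_TOKENS = ("NA", "")


class ParseError(ValueError):
    """Raised when a file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# expression matrix


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene symbols, header = sample ids).

    Missing values may be encoded as ``NA`` or an empty field and become NaN.
    Any other non-numeric cell is a parse error naming the offending
    row/column; duplicated gene symbols are a validation error.
    """
    out = pd.read_csv(
        path, sep="\t", index_col=0, na_values=list(MISSING_TOKENS),
        keep_default_na=False, float_precision="round_trip",
    )
    if out.index.duplicated().any():
        dup = out.index[out.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene symbol(s) in {path}: {dup}")
    for col in out.columns:
        if out[col].dtype == object:  # an unparseable token; locate it
            coerced = pd.to_numeric(out[col], errors="coerce")
            bad = coerced.isna() & out[col].notna()
            gene = out.index[bad][0]
            raise ParseError(
                f"non-numeric value {out.loc[gene, col]!r} at gene {gene!r}, "
                f"sample {col!r} in {path}"
            )
    out.index.name = "gene"
    return out.astype(float)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.17g", index_label="gene")


# ---------------------------------------------------------------------------
# sample sheet


def read_sample_sheet(
    path: str | Path,
    control_label: str = "control",
    treatment_label: str = "treatment",
) -> pd.DataFrame:
    """Read per-sample annotations (columns: sample, group, time, replicate).

    Group labels in the file are arbitrary strings; ``control_label`` and
    ``treatment_label`` name which of them plays which role and are mapped
    onto the canonical ``control``/``treatment`` values.
    """
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "group", "time", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ParseError(f"sample sheet {path} lacks column(s): {sorted(missing)}")
    if sheet["sample"].duplicated().any():
        raise ValidationError(f"duplicate sample ids in {path}")
    mapping = {control_label: "control", treatment_label: "treatment"}
    unknown = set(sheet["group"]) - set(mapping)
    if unknown:
        raise ValidationError(
            f"group label(s) {sorted(unknown)} in {path} match neither "
            f"control label {control_label!r} nor treatment label {treatment_label!r}"
        )
    ann = pd.DataFrame(
        {
            "group": sheet["group"].map(mapping).to_numpy(),
            "time": pd.to_numeric(sheet["time"], errors="coerce").to_numpy(),
            "replicate": sheet["replicate"].to_numpy(),
        },
        index=pd.Index(sheet["sample"], name="sample"),
    )
    if ann["time"].isna().any():
        bad = ann.index[ann["time"].isna()][0]
        raise ParseError(f"non-numeric time for sample {bad!r} in {path}")
    return ann


def write_sample_sheet(annotations: pd.DataFrame, path: str | Path) -> None:
    out = annotations.reset_index()
    out.columns = ["sample", *annotations.columns]
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_experiment(
    expression_path: str | Path,
    sample_sheet_path: str | Path,
    control_label: str = "control",
    treatment_label: str = "treatment",
) -> TimecourseExperiment:
    """Assemble a validated experiment from an expression TSV and sample sheet."""
    matrix = read_expression(expression_path)
    annotations = read_sample_sheet(sample_sheet_path, control_label, treatment_label)
    return TimecourseExperiment(matrix, annotations)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line as name, description, members (tab-separated)."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = {g for g in fields[2:] if g}
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# reference network / edge lists


def read_reference_network(path: str | Path) -> ReferenceNetwork:
    """Read an undirected edge list (2-column TSV, optional header) or SIF.

    SIF rows carry a relation token in the middle column, which is ignored.
    Edges are deduplicated order-independently; self-loops are dropped with
    a logged count.
    """
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: fewer than 2 symbols on edge row")
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) >= 3:
                # SIF: source relation target [more targets...]; relation ignored
                pairs.extend((fields[0], t) for t in fields[2:])
            else:
                pairs.append((fields[0], fields[1]))
    network, dropped = ReferenceNetwork.from_pairs(pairs)
    if dropped:
        logger.info("dropped %d self-loop(s) while reading %s", dropped, path)
    return network


def _looks_like_header(fields: list[str]) -> bool:
    lowered = [f.lower() for f in fields[:2]]
    return lowered in (["gene_a", "gene_b"], ["source", "target"], ["from", "to"], ["node1", "node2"])


def write_reference_network(network: ReferenceNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene_a", "gene_b"])
        for a, b in sorted(network.edges):
            writer.writerow([a, b])


GRAPH_FORMATS = ("edge_list", "graphml")


def write_graph(gan: Gan, path: str | Path, format: str = "edge_list") -> None:
    """Write a reconstructed network with its edge attributes (pcor, prob)."""
    if format not in GRAPH_FORMATS:
        raise ValueError(f"unknown graph format {format!r}; expected one of {GRAPH_FORMATS}")
    if format == "graphml":
        nx.write_graphml(gan.to_networkx(), path)
        return
    out = gan.edges.sort_values(["gene_a", "gene_b"]) if not gan.edges.empty else gan.edges
    out.to_csv(path, sep="\t", index=False, float_format="%.17g",
               columns=["gene_a", "gene_b", "pcor", "prob"])


def read_gan_edges(path: str | Path, threshold: float = 0.95) -> Gan:
    """Re-load a Gan previously written as an edge list."""
    table = pd.read_csv(path, sep="\t")
    required = {"gene_a", "gene_b", "pcor", "prob"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"{path} lacks column(s): {sorted(missing)}")
    return Gan(edges=table, threshold=threshold, n_input_genes=0)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")


def read_gene_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text(encoding="utf-8").splitlines() if line.strip()]
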