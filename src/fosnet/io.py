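"""Readers and writers for summary tables, cohort tables, and networks.

File conventions:

* Summary table: CSV with columns ``region, full_name, subdivision,
  <group>_mean, <group>_sem`` per group, preceded by a sidecar comment line
  ``# n_per_group: G1=n1,G2=n2,...`` carrying per-group animal counts.
* Cohort table: wide CSV/TSV with ``animal_id, group, <region...>`` and any
  of the optional behavior/TH columns.
* Networks: GraphML, GEXF, or a 3-column TSV edge list.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import (
    BEHAVIOR_COLUMNS,
    DEFAULT_GROUPS,
    CohortMatrix,
    GroupSummaryTable,
    RegionInfo,
    SchemaError,
    ValidationError,
)

__all__ = [
    "load_group_summary",
    "load_reference_summary",
    "write_group_summary",
    "read_cohort",
    "write_cohort",
    "write_network",
    "read_network",
    "NETWORK_FORMATS",
]

NETWORK_FORMATS = ("graphml", "gexf", "tsv")

_N_SIDECAR_PREFIX = "# n_per_group:"


def _parse_n_sidecar(line: str) -> dict[str, int]:
    body = line[len(_N_SIDECAR_PREFIX):].strip()
    out: dict[str, int] = {}
    for item in body.split(","):
        group, _, value = item.strip().partition("=")
        if not value:
            raise SchemaError(f"malformed n_per_group sidecar entry {item!r}")
        out[group.strip()] = int(value)
    return out


def load_group_summary(path: str | Path) -> GroupSummaryTable:
    """Read a region x group mean/SEM summary table from CSV.

    The first line must be the ``# n_per_group:`` sidecar; the CSV header
    follows. Group membership is inferred from the ``<group>_mean`` columns.

    Raises
    ------
    SchemaError
        If a required column or the sidecar line is missing.
    ValidationError
        If a cell is blank or negative (the message names region and group).
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith(_N_SIDECAR_PREFIX):
            raise SchemaError(
                f"{path.name}: missing '{_N_SIDECAR_PREFIX}' sidecar line"
            )
        n = _parse_n_sidecar(first)
        df = pd.read_csv(fh)

    for col in ("region", "full_name", "subdivision"):
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing column {col!r}")
    groups = [c[: -len("_mean")] for c in df.columns if c.endswith("_mean")]
    if not groups:
        raise SchemaError(f"{path.name}: no '<group>_mean' columns found")
    for g in groups:
        if f"{g}_sem" not in df.columns:
            raise SchemaError(f"{path.name}: missing column {g + '_sem'!r}")

    regions = [
        RegionInfo(row.region, row.full_name, row.subdivision)
        for row in df.itertuples()
    ]
    mean = pd.DataFrame(
        {g: df[f"{g}_mean"].to_numpy(dtype=float) for g in groups},
        index=df["region"],
    )
    sem = pd.DataFrame(
        {g: df[f"{g}_sem"].to_numpy(dtype=float) for g in groups},
        index=df["region"],
    )
    mean.index.name = sem.index.name = "region"
    return GroupSummaryTable(regions=regions, groups=groups, mean=mean,
                             sem=sem, n={g: n[g] for g in groups})


def load_reference_summary() -> GroupSummaryTable:
    """The packaged 30-region, 4-group c-Fos count summary (n = 6/group).

    Means and SEMs are c-Fos-positive cells per counting frame for untreated
    (Naive), MPTP-lesioned, acupuncture-treated (Acu), and sham-acupuncture
    (Sham) mice.
    """
    ref = resources.files("fosnet.data").joinpath("table1.csv")
    with resources.as_file(ref) as path:
        return load_group_summary(path)


def write_group_summary(table: GroupSummaryTable, path: str | Path) -> None:
    """Inverse of :func:`load_group_summary`."""
    path = Path(path)
    rows = []
    for info in table.regions:
        row: dict[str, object] = {
            "region": info.abbreviation,
            "full_name": info.full_name,
            "subdivision": info.subdivision,
        }
        for g in table.groups:
            row[f"{g}_mean"] = table.mean.at[info.abbreviation, g]
            row[f"{g}_sem"] = table.sem.at[info.abbreviation, g]
        rows.append(row)
    sidecar = ",".join(f"{g}={table.n[g]}" for g in table.groups)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"{_N_SIDECAR_PREFIX} {sidecar}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_cohort(
    path: str | Path,
    regions: Sequence[str] | None = None,
    groups: Sequence[str] = DEFAULT_GROUPS,
    allow_unknown_columns: bool = False,
) -> CohortMatrix:
    """Read a wide per-animal cohort table (CSV or TSV by extension).

    Parameters
    ----------
    regions
        Expected region abbreviations. When ``None``, every column that is
        neither ``animal_id``/``group`` nor a known behavior column is taken
        to be a region.
    allow_unknown_columns
        When ``regions`` is given, keep (rather than reject) columns outside
        the region/behavior vocabulary.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    for col in ("animal_id", "group"):
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing column {col!r}")
    df = df.set_index("animal_id")
    df.index = df.index.astype(str)

    special = {"group", *BEHAVIOR_COLUMNS}
    if regions is None:
        region_list = [c for c in df.columns if c not in special]
    else:
        region_list = list(regions)
        unknown = [c for c in df.columns if c not in special and c not in region_list]
        if unknown and not allow_unknown_columns:
            raise SchemaError(
                f"{path.name}: unknown region columns {unknown}; pass "
                "allow_unknown_columns=True to keep them"
            )
    if not region_list:
        raise SchemaError(f"{path.name}: no region columns found")
    return CohortMatrix(data=df, regions=region_list, groups=list(groups))


def write_cohort(cohort: CohortMatrix, path: str | Path) -> None:
    """Write a cohort as wide delimited text (TSV for .tsv, else CSV)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    cols = ["group"] + list(cohort.regions) + cohort.behavior_columns
    out = cohort.data[cols].copy()
    out.index.name = "animal_id"
    out.to_csv(path, sep=sep)


def write_network(graph, path: str | Path, format: str = "graphml") -> None:
    """Persist a thresholded graph with node and edge attributes.

    Accepts either a :class:`~fosnet.network.ThresholdedGraph` or a bare
    ``networkx.Graph``. GraphML/GEXF round-trip topology, weights, and
    attributes; the TSV edge list keeps only ``source, target, weight``.
    """
    g = graph if isinstance(graph, nx.Graph) else getattr(graph, "graph", None)
    if not isinstance(g, nx.Graph):
        raise TypeError("write_network expects a ThresholdedGraph or nx.Graph")
    if format not in NETWORK_FORMATS:
        raise ValueError(
            f"unsupported format {format!r}; supported formats: {NETWORK_FORMATS}"
        )
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "gexf":
        nx.write_gexf(g, path)
    else:
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["source", "target", "weight"])
            for u, v, data in sorted(g.edges(data=True)):
                writer.writerow([u, v, f"{data.get('weight', 1.0):.6f}"])


def read_network(path: str | Path, format: str | None = None) -> nx.Graph:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    if format is None:
        format = {".graphml": "graphml", ".gexf": "gexf", ".tsv": "tsv"}.get(
            path.suffix.lower(), "graphml"
        )
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "gexf":
        return nx.read_gexf(path)
    if format == "tsv":
        g = nx.Graph()
        with path.open("r", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            if header[:3] != ["source", "target", "weight"]:
                raise SchemaError(f"{path.name}: not a fosnet edge-list TSV")
            for source, target, weight in reader:
                g.add_edge(source, target, weight=float(weight))
        return g
    raise ValueError(
        f"unsupported format {format!r}; supported formats: {NETWORK_FORMATS}"
    )
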