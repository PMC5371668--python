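"""Reading, writing and genus-collapsing taxa-by-sample count tables.

The native format is the QIIME-classic TSV export: first column
``taxonomy`` holding a semicolon-separated, rank-prefixed lineage
(``k__...; p__...; ...; g__...``), remaining columns one sample each.
Comment lines start with ``#``; per-sample metadata may be embedded as
``#meta<TAB><field><TAB>v1<TAB>v2...`` header lines.  BIOM 1.0 (JSON
flavor) tables are read-supported.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .models import AbundanceTable, TimeSeriesProfile

__all__ = [
    "read_table",
    "write_table",
    "collapse_to_genus",
    "to_relative",
    "parse_lineage",
    "genus_of",
]

RANK_ORDER = ["k", "p", "c", "o", "f", "g", "s"]


def parse_lineage(lineage: str) -> dict[str, str]:
    """Split a rank-prefixed lineage string into a rank -> name mapping."""
    ranks: dict[str, str] = {}
    for part in lineage.split(";"):
        part = part.strip()
        if "__" in part:
            prefix, _, name = part.partition("__")
            prefix = prefix.strip().lower()
            if prefix in RANK_ORDER:
                ranks[prefix] = name.strip()
    return ranks


def genus_of(lineage: str) -> str:
    """Collapse label for one lineage: the genus, or ``unclassified_<rank>``.

    Labels that carry no rank prefixes at all (e.g. output of a previous
    collapse) are passed through unchanged, which makes collapsing
    idempotent.
    """
    if "__" not in lineage:
        return lineage.strip()
    ranks = parse_lineage(lineage)
    if not ranks:
        raise ValueError(f"lineage has no parsable ranks: {lineage!r}")
    if ranks.get("g"):
        return ranks["g"]
    for rank in reversed(RANK_ORDER):
        if rank != "s" and ranks.get(rank):
            return f"unclassified_{ranks[rank]}"
    raise ValueError(f"lineage has no named rank: {lineage!r}")


def _read_tsv(path: str) -> AbundanceTable:
    header: list[str] | None = None
    meta_fields: dict[str, list[str]] = {}
    taxa: list[str] = []
    rows: list[list[int]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#meta\t"):
                parts = line.split("\t")
                meta_fields[parts[1]] = parts[2:]
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                if header[0].lower() not in ("taxonomy", "taxon", "#otu id"):
                    raise ValueError(
                        f"line {lineno}: first column must be 'taxonomy', got {header[0]!r}"
                    )
                continue
            if len(parts) != len(header):
                raise ValueError(
                    f"line {lineno}: ragged row ({len(parts)} fields, expected {len(header)})"
                )
            taxa.append(parts[0])
            values = []
            for col, raw in zip(header[1:], parts[1:]):
                try:
                    val = float(raw)
                except ValueError:
                    raise ValueError(
                        f"line {lineno}: non-numeric count {raw!r} in column {col!r}"
                    ) from None
                if val < 0:
                    raise ValueError(
                        f"line {lineno}: negative count in row {parts[0]!r}, column {col!r}"
                    )
                if val != int(val):
                    raise ValueError(
                        f"line {lineno}: non-integer count {raw!r} in column {col!r}"
                    )
                values.append(int(val))
            rows.append(values)
    if header is None:
        raise ValueError(f"{path}: no header line found")
    samples = header[1:]
    counts = pd.DataFrame(rows, index=taxa, columns=samples, dtype=np.int64)
    metadata = None
    if meta_fields:
        metadata = pd.DataFrame(index=samples)
        for field_name, values in meta_fields.items():
            if len(values) != len(samples):
                raise ValueError(
                    f"#meta {field_name}: {len(values)} values for {len(samples)} samples"
                )
            try:
                metadata[field_name] = [float(v) for v in values]
            except ValueError:
                metadata[field_name] = values
    return AbundanceTable(counts=counts, metadata=metadata)


def _read_biom_json(path: str) -> AbundanceTable:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    taxa = []
    for row in doc["rows"]:
        md = row.get("metadata") or {}
        tax = md.get("taxonomy")
        if isinstance(tax, list):
            taxa.append("; ".join(tax))
        elif tax:
            taxa.append(str(tax))
        else:
            taxa.append(row["id"])
    samples = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(taxa), len(samples)))
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"], dtype=float)
    else:  # sparse: [row, col, value] triples
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    if (mat < 0).any():
        bad = np.argwhere(mat < 0)[0]
        raise ValueError(
            f"negative count in row {taxa[bad[0]]!r}, column {samples[bad[1]]!r}"
        )
    counts = pd.DataFrame(mat.astype(np.int64), index=taxa, columns=samples)
    metadata = None
    col_md = [c.get("metadata") or {} for c in doc["columns"]]
    if any(col_md):
        metadata = pd.DataFrame(col_md, index=samples)
    return AbundanceTable(counts=counts, metadata=metadata)


def read_table(path: str, format: str = "tsv") -> AbundanceTable:
    """Read an abundance table from ``tsv`` or ``biom-json``."""
    if format == "tsv":
        return _read_tsv(path)
    if format in ("biom-json", "biom"):
        return _read_biom_json(path)
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom-json'")


def write_table(table: AbundanceTable, path: str) -> None:
    """Write the TSV dialect read back by :func:`read_table`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# taxa-by-sample counts\n")
        if table.metadata is not None:
            meta = table.metadata.loc[table.samples]
            for field_name in meta.columns:
                values = "\t".join(f"{v:g}" if isinstance(v, float) else str(v) for v in meta[field_name])
                fh.write(f"#meta\t{field_name}\t{values}\n")
        fh.write("taxonomy\t" + "\t".join(table.samples) + "\n")
        for taxon, row in table.counts.iterrows():
            fh.write(taxon + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def collapse_to_genus(table: AbundanceTable) -> AbundanceTable:
    """Sum rows sharing a genus; unnamed genera become ``unclassified_<rank>``.

    Idempotent: already-collapsed labels pass through unchanged.  Column
    sums are conserved.
    """
    labels = [genus_of(t) for t in table.taxa]
    collapsed = table.counts.groupby(labels, sort=False).sum()
    collapsed.index.name = None
    return AbundanceTable(counts=collapsed, metadata=table.metadata)


def to_relative(
    table: AbundanceTable, average_replicates: bool = True
) -> TimeSeriesProfile | pd.DataFrame:
    """Convert counts to per-sample proportions.

    When the table carries ``time`` metadata a :class:`TimeSeriesProfile`
    is returned, ordered by time; replicate samples at one time point are
    aggregated by the arithmetic mean of their relative abundances
    (``average_replicates=False`` keeps one column per sample and returns
    a DataFrame instead).
    """
    totals = table.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total count: {list(zero.index)}")
    props = table.counts / totals

    has_time = table.metadata is not None and "time" in table.metadata.columns
    if not has_time:
        return props
    times = table.metadata.loc[table.samples, "time"].astype(float)
    if average_replicates:
        grouped = props.T.groupby(times.values).mean().T
        grouped = grouped[sorted(grouped.columns)]
        grouped = grouped / grouped.sum(axis=0)  # guard mean-of-simplex drift
        return TimeSeriesProfile(
            taxa=list(grouped.index),
            times=np.asarray(grouped.columns, dtype=float),
            abundances=grouped.to_numpy(),
        )
    order = np.argsort(times.values, kind="stable")
    if len(set(times.values)) != len(times):
        return props.iloc[:, order]
    ordered = props.iloc[:, order]
    return TimeSeriesProfile(
        taxa=list(ordered.index),
        times=np.sort(times.values),
        abundances=ordered.to_numpy(),
    )
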