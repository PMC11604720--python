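"""Reading count tables and sample metadata from disk.

Counts: TSV/CSV with samples in rows (first column = sample IDs, header row
of taxon IDs), or a BIOM v1 JSON table (which stores taxa ("observations")
in rows and samples in columns; it is transposed on load). Metadata: TSV/CSV
with the sample ID in the first column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import AbundanceTable

__all__ = ["read_counts", "read_metadata", "read_study", "write_matrix_tsv"]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_counts(path) -> AbundanceTable:
    """Load a samples x taxa count table from TSV/CSV or BIOM v1 JSON."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".biom":
        return _read_biom_v1(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs in {path.name}: {dupes[:5]}")
    arr = df.apply(pd.to_numeric, errors="coerce")
    if arr.isna().any().any():
        bad = arr.columns[arr.isna().any()].tolist()
        raise ValueError(f"non-numeric counts in columns: {bad[:5]}")
    return AbundanceTable.from_dataframe(arr)


def _read_biom_v1(path: Path) -> AbundanceTable:
    """Minimal BIOM v1 (JSON) reader, dense and sparse layouts."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_url") and "biom-format" not in doc["format_url"]:
        raise ValueError(f"{path.name} does not look like a BIOM v1 file")
    n_obs, n_samp = doc["shape"]
    data = np.zeros((n_obs, n_samp))
    if doc.get("matrix_type") == "dense":
        data[:] = np.asarray(doc["data"], dtype=float)
    else:
        for r, c, v in doc["data"]:
            data[int(r), int(c)] = v
    taxa = [row["id"] for row in doc["rows"]]
    samples = [col["id"] for col in doc["columns"]]
    return AbundanceTable(data.T, samples, taxa)


def read_metadata(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    md = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if md.index.has_duplicates:
        dupes = md.index[md.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs in {path.name}: {dupes[:5]}")
    return md


def read_study(counts_path, metadata_path) -> tuple[AbundanceTable, pd.DataFrame]:
    """Load and align a counts table with its sample metadata.

    Samples appearing in only one of the two files are reported by name.
    """
    table = read_counts(counts_path)
    metadata = read_metadata(metadata_path)
    missing = [s for s in table.sample_ids if s not in metadata.index]
    if missing:
        raise ValueError(f"metadata missing for samples: {missing[:10]}")
    extra = [s for s in metadata.index if s not in set(table.sample_ids)]
    if extra:
        raise ValueError(f"metadata rows without counts: {extra[:10]}")
    return table, metadata.loc[table.sample_ids]


def write_matrix_tsv(matrix: np.ndarray, labels, path) -> None:
    """Write a square labelled matrix (distance/kernel) as TSV."""
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path, sep="\t")
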