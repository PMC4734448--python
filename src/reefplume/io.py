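"""Reading and writing OTU tables, metadata and gridded fields.

OTU tables are exchanged as BIOM 1.0 (JSON) or as plain TSV with
``taxonomy``, ``copy_number`` and ``domain`` annotation columns; gridded
tracer and exposure fields go to NetCDF via xarray.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .diversity import OtuTable
from .transport import ConfigError

__all__ = [
    "write_biom_json",
    "read_biom_json",
    "write_otu_tsv",
    "read_otu_tsv",
    "write_tsv",
]

_ANNOT = ["taxonomy", "copy_number", "domain"]


def write_biom_json(table: OtuTable, path, generated_by: str = "reefplume") -> None:
    """Write an OTU table as sparse BIOM 1.0 JSON.

    BIOM stores observations (OTUs) as rows and samples as columns; the
    in-memory layout is transposed on the way out and back in.
    """
    path = Path(path)
    otus = table.otu_ids
    samples = table.sample_ids
    counts = table.counts.to_numpy().T  # OTUs x samples
    data = [
        [int(i), int(j), float(counts[i, j])]
        for i, j in zip(*np.nonzero(counts))
    ]
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": generated_by,
        "date": datetime.now(timezone.utc).isoformat(),
        "matrix_type": "sparse",
        "matrix_element_type": "float",
        "shape": [len(otus), len(samples)],
        "rows": [
            {
                "id": o,
                "metadata": {
                    "taxonomy": table.taxonomy.get(o),
                    "copy_number": float(table.copy_number.get(o)),
                    "domain": table.domain.get(o),
                },
            }
            for o in otus
        ],
        "columns": [{"id": s, "metadata": None} for s in samples],
        "data": data,
    }
    path.write_text(json.dumps(doc))


def read_biom_json(path) -> OtuTable:
    doc = json.loads(Path(path).read_text())
    if "shape" not in doc or "data" not in doc:
        raise ConfigError(f"{path} is not a BIOM 1.0 JSON file")
    n_otus, n_samples = doc["shape"]
    otus = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    counts = np.zeros((n_otus, n_samples))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            counts[int(i), int(j)] = v
    else:
        counts = np.asarray(doc["data"], dtype=float)
    meta = [r.get("metadata") or {} for r in doc["rows"]]
    return OtuTable(
        counts=pd.DataFrame(counts.T, index=samples, columns=otus),
        taxonomy=pd.Series([m.get("taxonomy", "") for m in meta], index=otus),
        copy_number=pd.Series([float(m.get("copy_number", 1.0)) for m in meta], index=otus),
        domain=pd.Series([m.get("domain", "prokaryote") for m in meta], index=otus),
    )


def write_otu_tsv(table: OtuTable, path) -> None:
    """TSV with one row per OTU: id, annotations, then per-sample counts."""
    df = pd.DataFrame(
        {
            "taxonomy": table.taxonomy.reindex(table.otu_ids),
            "copy_number": table.copy_number.reindex(table.otu_ids),
            "domain": table.domain.reindex(table.otu_ids),
        }
    )
    df = pd.concat([df, table.counts.T], axis=1)
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")


def read_otu_tsv(path) -> OtuTable:
    df = pd.read_csv(path, sep="\t", index_col="otu_id")
    missing = [c for c in _ANNOT if c not in df.columns]
    if missing:
        raise ConfigError(f"OTU TSV missing columns: {missing}")
    sample_cols = [c for c in df.columns if c not in _ANNOT]
    counts = df[sample_cols].T.astype(float)
    counts.columns.name = None
    counts.index.name = None
    return OtuTable(
        counts=counts,
        taxonomy=df["taxonomy"],
        copy_number=df["copy_number"].astype(float),
        domain=df["domain"],
    )


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
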