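"""Readers and writers for the plain-text formats the pipeline exchanges.

Count tables are stored either as TSV (features x samples, integer cells,
matching the layout most amplicon workflows emit) or as BIOM v1, which is
a JSON document; growth and metadata tables as TSV with ISO-8601 dates;
ground truth and run manifests as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from rhizolink.containers import CountTable


# -- TSV ---------------------------------------------------------------------

def write_counts_tsv(table: CountTable, counts_path, metadata_path=None) -> None:
    """Write counts (features x samples) and optionally metadata as TSV."""
    table.counts.T.to_csv(counts_path, sep="\t", index_label="feature_id")
    if metadata_path is not None:
        table.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_counts_tsv(counts_path, metadata_path) -> CountTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col="feature_id").T
    counts.index.name = "sample_id"
    counts.columns.name = None
    metadata = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    return CountTable(counts.astype(np.int64), metadata)


# -- BIOM v1 (JSON) ----------------------------------------------------------

def write_biom_v1(table: CountTable, path) -> None:
    """Write a minimal dense BIOM v1 (JSON) OTU table."""
    counts = table.counts
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "rhizolink",
        "date": "",
        "matrix_type": "dense",
        "matrix_element_type": "int",
        "shape": [counts.shape[1], counts.shape[0]],  # observations x samples
        "rows": [{"id": f, "metadata": None} for f in counts.columns],
        "columns": [
            {"id": s, "metadata": table.metadata.loc[s].to_dict()}
            for s in counts.index
        ],
        "data": counts.T.to_numpy().astype(int).tolist(),
    }
    Path(path).write_text(json.dumps(doc, default=_json_default))


def read_biom_v1(path) -> CountTable:
    doc = json.loads(Path(path).read_text())
    features = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    if doc["matrix_type"] == "dense":
        mat = np.asarray(doc["data"], dtype=np.int64).T  # -> samples x features
    else:  # sparse triplets [row, col, value]
        mat = np.zeros((len(samples), len(features)), dtype=np.int64)
        for r, c, v in doc["data"]:
            mat[c, r] = v
    counts = pd.DataFrame(mat, index=pd.Index(samples, name="sample_id"), columns=features)
    metadata = pd.DataFrame(
        [c.get("metadata") or {} for c in doc["columns"]],
        index=pd.Index(samples, name="sample_id"),
    )
    return CountTable(counts, metadata)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))
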