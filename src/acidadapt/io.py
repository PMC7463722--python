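"""Readers and writers for the plain-text formats the pipeline exchanges.

Tabular data travels as TSV (counts, design, expression, clinical,
results), ranked lists as two-column RNK files, gene-set collections as
GMT, and pipeline reports as deterministic JSON (sorted keys, fixed
separators) so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from acidadapt.rrho import RankedGeneList, make_ranked_list


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_design(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cell_line": str, "ph": str})


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


read_expression = read_counts
write_expression = write_counts


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"patient_id": str, "cancer_type": str})


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_rnk(path) -> RankedGeneList:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "score"], comment="#")
    return make_ranked_list(pd.Series(df["score"].to_numpy(float), index=df["gene_id"].astype(str)))


def write_rnk(ranked: RankedGeneList, path) -> None:
    with open(path, "w") as fh:
        for gene, score in zip(ranked.gene_ids, ranked.scores):
            fh.write(f"{gene}\t{score:.10g}\n")


def read_gmt(path) -> dict[str, set]:
    collection: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if name in collection:
                raise ValueError(f"duplicate gene set name {name!r}")
            collection[name] = set(members)
    return collection


def write_gmt(collection: dict[str, set], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(collection):
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = [_jsonify(v) for v in obj]
        return sorted(items) if isinstance(obj, (set, frozenset)) else items
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def dumps_report(report: dict) -> str:
    """Canonical JSON text: sorted keys, stable separators, trailing newline."""
    return json.dumps(_jsonify(report), sort_keys=True, indent=2) + "\n"


def write_json_report(report: dict, path) -> None:
    Path(path).write_text(dumps_report(report))
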