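"""Plain-text readers/writers: TSV tables, square distance matrices,
embeddings, Newick trees, and YAML config round-tripping."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import DistanceMatrix, TreeNode

from .ordination import Embedding
from .synthetic import DesignSpec, EffectSpec

__all__ = [
    "write_count_table", "read_count_table",
    "write_metadata", "read_metadata",
    "write_distance_matrix", "read_distance_matrix",
    "write_embedding", "read_embedding",
    "write_tree", "read_tree",
    "write_config", "read_config",
]


def write_count_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="sample_id")


def read_count_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_distance_matrix(D: DistanceMatrix, path) -> None:
    pd.DataFrame(D.data, index=D.ids, columns=D.ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])


def write_embedding(E: Embedding, path, diagnostics_path=None) -> None:
    frame = E.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# method={E.method}\tdimension={E.dimension}\n")
        frame.to_csv(fh, sep="\t", index_label="sample_id")
    if diagnostics_path is not None:
        with open(diagnostics_path, "w") as fh:
            json.dump(_jsonable(E.diagnostics), fh, indent=1)


def read_embedding(path) -> Embedding:
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(kv.split("=", 1) for kv in header.lstrip("# ").split("\t"))
        frame = pd.read_csv(fh, sep="\t", index_col=0)
    return Embedding(
        [str(i) for i in frame.index], frame.to_numpy(),
        meta.get("method", "unknown"), int(meta["dimension"]),
    )


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_config(design: DesignSpec, effects: EffectSpec, path,
                 extra: dict | None = None) -> None:
    """YAML config mirroring the DesignSpec/EffectSpec field names."""
    doc = {"design": _jsonable(design.to_dict()),
           "effects": _jsonable(effects.to_dict())}
    if extra:
        doc.update(_jsonable(extra))
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_config(path) -> tuple[DesignSpec, EffectSpec, dict]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    design = DesignSpec.from_dict(doc["design"])
    effects = EffectSpec.from_dict(doc["effects"])
    extra = {k: v for k, v in doc.items() if k not in ("design", "effects")}
    return design, effects, extra
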