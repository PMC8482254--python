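"""Readers and writers for the pipeline's plain-text on-disk formats.

Formats: JSONL (one object per line) for posts, tweets and labeled corpora;
TSV edge lists for the community link graph; GeoJSON for areas. All writes
use sorted keys so identical in-memory objects serialize byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable


def read_jsonl(path) -> list[dict]:
    path = Path(path)
    try:
        with path.open("r", encoding="utf-8") as fh:
            return [json.loads(line) for line in fh if line.strip()]
    except OSError as exc:  # pragma: no cover - passthrough with context
        raise OSError(f"failed reading JSONL at {path}: {exc}") from exc


def write_jsonl(records: Iterable[dict], path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_edge_list(path) -> list[tuple[str, str]]:
    """Read a "src<TAB>dst" edge list; blank lines ignored."""
    path = Path(path)
    edges = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            src, dst = line.split("\t")
            edges.append((src, dst))
    return edges


def write_edge_list(edges: Iterable[tuple[str, str]], path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for src, dst in edges:
            fh.write(f"{src}\t{dst}\n")


def read_json(path) -> dict:
    with Path(path).open("r", encoding="utf-8") as fh:
        return json.load(fh)


def write_json(obj, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1)
        fh.write("\n")
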