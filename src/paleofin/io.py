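"""File-format readers and writers: Newick trees, record tables, TPS files.

All tabular formats are long-format UTF-8 CSV with '.' decimal separator.
Tree pools are one Newick string per line and are streamed rather than
loaded wholesale.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import dendropy
import numpy as np
import pandas as pd

from .errors import InputError, ParseError

__all__ = [
    "read_newick",
    "read_newick_string",
    "write_newick",
    "read_newick_list",
    "iter_newick_pool",
    "write_newick_pool",
    "read_records_csv",
    "write_records_csv",
    "read_tps",
    "write_tps",
]

_NEWICK_KW = dict(
    schema="newick",
    preserve_underscores=True,
    suppress_internal_node_taxa=True,
)


def read_newick_string(s: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(data=s, **_NEWICK_KW)
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = True  # package convention: trees are rooted as written
    return tree


def read_newick(path) -> dendropy.Tree:
    """Read a single tree; polytomies and zero branch lengths are allowed."""
    text = Path(path).read_text()
    return read_newick_string(text)


def read_newick_list(path) -> list[dendropy.Tree]:
    """Read all trees in a multi-Newick file (small files only)."""
    return list(iter_newick_pool(path))


def iter_newick_pool(path) -> Iterator[dendropy.Tree]:
    """Stream trees from a one-Newick-per-line pool file."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                tree = dendropy.Tree.get(data=line, **_NEWICK_KW)
            except Exception as exc:
                raise ParseError(f"malformed Newick at line {lineno}: {exc}") from exc
            tree.is_rooted = True
            yield tree


def tree_to_newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def write_newick(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(tree_to_newick_string(tree) + "\n")


def write_newick_pool(trees: Iterable[dendropy.Tree], path) -> None:
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(tree_to_newick_string(tree) + "\n")


# ---------------------------------------------------------------------------
# record tables

RECORD_COLUMNS = [
    "species",
    "speed",
    "Length",
    "Mode",
    "Cond",
    "LocType",
    "Group",
    "HeWiCF",
    "CircCF",
    "RoundCF",
    "SolCF",
    "AR",
]


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("species", "speed", "Length") if c not in df.columns]
    if missing:
        raise InputError(f"records table missing required columns: {missing}")
    return df


def write_records_csv(df: pd.DataFrame, path) -> None:
    cols = [c for c in RECORD_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, columns=cols, index=False)


# ---------------------------------------------------------------------------
# TPS landmark files


def write_tps(configs: dict[str, np.ndarray], path) -> None:
    """Write landmark configurations as TPS blocks (LM=, rows, ID=)."""
    lines = []
    for label, pts in configs.items():
        pts = np.asarray(pts, dtype=float)
        lines.append(f"LM={len(pts)}")
        for x, y in pts:
            lines.append(f"{x:.10g} {y:.10g}")
        lines.append(f"ID={label}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tps(path) -> dict[str, np.ndarray]:
    configs: dict[str, np.ndarray] = {}
    current: list | None = None
    expected = 0
    label = None
    idx = 0
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            if current is not None:
                raise ParseError("TPS block started before previous block closed")
            expected = int(line.split("=", 1)[1])
            current = []
        elif upper.startswith("ID="):
            if current is None or len(current) != expected:
                raise ParseError("TPS block has wrong number of coordinate rows")
            label = line.split("=", 1)[1]
            configs[label] = np.array(current, dtype=float)
            current = None
        elif current is not None:
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"bad TPS coordinate row: {raw!r}")
            current.append((float(parts[0]), float(parts[1])))
        else:
            raise ParseError(f"unexpected TPS line: {raw!r}")
        idx += 1
    if current is not None:
        # block without ID= line: store under a positional key
        if len(current) != expected:
            raise ParseError("unterminated TPS block with wrong row count")
        configs[f"config_{len(configs)}"] = np.array(current, dtype=float)
    return configs
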