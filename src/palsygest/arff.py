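"""Minimal ARFF reader/writer for gesture feature tables.

Emits the classic dialect: space-separated ``@attribute`` declarations,
comma-separated ``@data`` rows, no sparse format.  The table schema is the
29 numeric features, the nominal class {0..5}, and three string provenance
columns (grade, subject, provenance).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import GestureDataset, N_CLASSES
from .features import FEATURE_NAMES

__all__ = ["ArffFormatError", "write_arff", "read_arff"]

DEFAULT_RELATION = "palsy_gestures"


class ArffFormatError(ValueError):
    """Malformed ARFF content; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        suffix = f" (line {line})" if line is not None else ""
        super().__init__(message + suffix)


def write_arff(ds: GestureDataset, path: str | Path,
               relation: str = DEFAULT_RELATION) -> None:
    df = ds.to_frame()
    lines = [f"@relation {relation}", ""]
    for name in FEATURE_NAMES:
        lines.append(f"@attribute {name} numeric")
    class_domain = ",".join(str(c) for c in range(N_CLASSES))
    lines.append(f"@attribute label {{{class_domain}}}")
    for col in ("grade", "subject", "provenance"):
        lines.append(f"@attribute {col} string")
    lines.append("")
    lines.append("@data")
    for _, row in df.iterrows():
        vals = [repr(float(row[name])) for name in FEATURE_NAMES]
        vals.append(str(int(row["label"])))
        vals.extend(f"'{row[c]}'" for c in ("grade", "subject", "provenance"))
        lines.append(",".join(vals))
    Path(path).write_text("\n".join(lines) + "\n")


def _strip_quotes(tok: str) -> str:
    tok = tok.strip()
    if len(tok) >= 2 and tok[0] == tok[-1] and tok[0] in "'\"":
        return tok[1:-1]
    return tok


def read_arff(path: str | Path) -> GestureDataset:
    """Parse an ARFF feature table back into a dataset.

    Validates the section structure and the attribute schema; raises
    :class:`ArffFormatError` with a line number on malformed input.
    """
    attributes: list[tuple[str, str]] = []
    data_rows: list[list[str]] = []
    in_data = False
    data_seen = False
    relation_seen = False
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if not in_data:
            if low.startswith("@relation"):
                relation_seen = True
            elif low.startswith("@attribute"):
                parts = line.split(None, 2)
                if len(parts) < 3:
                    raise ArffFormatError("incomplete @attribute declaration", lineno)
                attributes.append((_strip_quotes(parts[1]), parts[2].strip()))
            elif low.startswith("@data"):
                if not relation_seen:
                    raise ArffFormatError("@data before @relation", lineno)
                in_data = True
                data_seen = True
            else:
                raise ArffFormatError(f"unexpected header line {line!r}", lineno)
        else:
            data_rows.append([_strip_quotes(t) for t in line.split(",")])
            if len(data_rows[-1]) != len(attributes):
                raise ArffFormatError(
                    f"row has {len(data_rows[-1])} values, expected {len(attributes)}",
                    lineno,
                )
    if not data_seen:
        raise ArffFormatError("missing @data section")

    names = [a[0] for a in attributes]
    for i, feat in enumerate(FEATURE_NAMES):
        if i >= len(names) or names[i] != feat:
            raise ArffFormatError(
                f"attribute {i} must be {feat!r}, got {names[i] if i < len(names) else None!r}"
            )
    if "label" not in names:
        raise ArffFormatError("missing 'label' attribute")
    label_decl = attributes[names.index("label")][1].replace(" ", "")
    expected_domain = "{" + ",".join(str(c) for c in range(N_CLASSES)) + "}"
    if label_decl != expected_domain:
        raise ArffFormatError(
            f"label domain {label_decl!r} does not match the {N_CLASSES} gesture classes"
        )

    df = pd.DataFrame(data_rows, columns=names)
    for feat in FEATURE_NAMES:
        df[feat] = df[feat].astype(float)
    df["label"] = df["label"].astype(int)
    if np.any((df["label"] < 0) | (df["label"] >= N_CLASSES)):
        raise ArffFormatError("label outside the declared nominal domain")
    return GestureDataset.from_frame(df)
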