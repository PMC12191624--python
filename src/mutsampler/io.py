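"""Ratings-table I/O and the adapter for externally deposited data.

The canonical on-disk dialect is a CSV with header
``subject_id, condition, domain, query_id, target, evidence, rating``
(evidence serialized as ``"X=1,YB=0"``, empty for marginal queries) and an
initial ``#``-comment line recording the seed and config hash that
produced the file, so every artifact is traceable to its inputs.

Externally deposited ratings rarely use these column names, so
:func:`read_ratings` accepts a :class:`ColumnMapping` that renames
columns and optionally rescales responses (e.g. 0-1 probabilities to the
0-100 slider scale).  Validation reports offending rows by line number.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import pandas as pd

__all__ = [
    "RATINGS_COLUMNS",
    "RatingsValidationError",
    "ColumnMapping",
    "config_hash",
    "write_ratings",
    "read_ratings",
]

RATINGS_COLUMNS = (
    "subject_id",
    "condition",
    "domain",
    "query_id",
    "target",
    "evidence",
    "rating",
)

REQUIRED_COLUMNS = ("subject_id", "condition", "query_id", "rating")


class RatingsValidationError(ValueError):
    """Raised when a ratings file fails validation; message lists rows."""


@dataclass(frozen=True)
class ColumnMapping:
    """Maps external column names onto the canonical ratings fields.

    ``columns`` maps canonical field -> external column name; fields not
    listed are assumed to already use the canonical name.  ``transforms``
    maps canonical field -> callable applied to the column after renaming
    (e.g. ``{"rating": lambda r: 100*r}`` for 0-1 responses).
    ``constants`` fills fields absent from the file (e.g. a single-domain
    deposit).
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    transforms: Mapping[str, Callable] = field(default_factory=dict)
    constants: Mapping[str, object] = field(default_factory=dict)

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.rename(columns={v: k for k, v in self.columns.items()}).copy()
        for col, value in self.constants.items():
            out[col] = value
        for col, fn in self.transforms.items():
            if col in out.columns:
                out[col] = out[col].map(fn)
        return out


def config_hash(config: object) -> str:
    """Short stable hash of any JSON-serializable configuration object."""
    text = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_ratings(
    ratings: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: object | None = None,
) -> None:
    """Write a ratings table in the canonical dialect, with a provenance
    comment line (seed + config hash) that readers skip."""
    path = Path(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in ratings.columns]
    if missing:
        raise ValueError(f"ratings table lacks required columns {missing}")
    cols = [c for c in RATINGS_COLUMNS if c in ratings.columns]
    meta = f"# mutsampler ratings seed={seed} config_hash={config_hash(config)}\n"
    with open(path, "w") as fh:
        fh.write(meta)
        ratings[cols].to_csv(fh, index=False)


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise RatingsValidationError(f"missing required columns: {missing}")
    problems = []
    ratings = pd.to_numeric(df["rating"], errors="coerce")
    bad_numeric = df.index[ratings.isna()]
    for i in bad_numeric:
        problems.append(f"row {i + 2}: rating {df.loc[i, 'rating']!r} is not numeric")
    out_of_range = df.index[(ratings < 0) | (ratings > 100)]
    for i in out_of_range:
        problems.append(f"row {i + 2}: rating {ratings[i]} outside [0, 100]")
    dup = df.duplicated(subset=["subject_id", "query_id"], keep=False)
    for i in df.index[dup]:
        problems.append(
            f"row {i + 2}: duplicate (subject_id, query_id) = "
            f"({df.loc[i, 'subject_id']}, {df.loc[i, 'query_id']})"
        )
    if problems:
        shown = "\n".join(problems[:20])
        more = f"\n... and {len(problems) - 20} more" if len(problems) > 20 else ""
        raise RatingsValidationError(f"invalid ratings table:\n{shown}{more}")
    df = df.copy()
    df["rating"] = ratings.astype(float)
    return df


def read_ratings(
    path: str | Path, mapping: ColumnMapping | None = None
) -> pd.DataFrame:
    """Read and validate a ratings CSV (canonical dialect or mapped).

    Row numbers in error messages count from 1 at the header line, i.e.
    they match what a text editor shows for a file without the provenance
    comment.
    """
    df = pd.read_csv(path, comment="#", dtype={"evidence": str})
    if mapping is not None:
        df = mapping.apply(df)
    if "evidence" in df.columns:
        df["evidence"] = df["evidence"].fillna("")
    return _validate(df)
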