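"""Variable schemas for mixed-type tabular microdata.

A :class:`TableSchema` declares, for every column of a table, how the
perturbation machinery should treat it:

``continuous``
    real-valued; modelled with smoothed empirical or parametric CDFs.
``empirical``
    numeric but heavily tied (ages, counts, rounded survey amounts);
    perturbed through a smoothed empirical CDF so output stays numeric.
``binary``
    two-level; perturbed as a discrete target over codes {0, 1}.
``nominal``
    multi-level categorical; levels are mapped to a fixed integer coding
    (recorded in the schema so releases are reproducible) and perturbed as a
    discrete target over those codes.

One column may be flagged as a survey-weight column; it is used to weight
CDF and model fits but is never itself perturbed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

__all__ = ["ColumnSpec", "TableSchema", "VARIABLE_TYPES"]

VARIABLE_TYPES = ("continuous", "empirical", "binary", "nominal")


@dataclass
class ColumnSpec:
    """Declaration for one column."""

    name: str
    type: str
    levels: list | None = None  # nominal only; order fixes the integer coding
    weight_column: bool = False

    def __post_init__(self):
        if not self.weight_column and self.type not in VARIABLE_TYPES:
            raise ValueError(
                f"unknown variable type {self.type!r} for column {self.name!r};"
                f" expected one of {VARIABLE_TYPES}"
            )

    @property
    def is_discrete(self) -> bool:
        return self.type in ("binary", "nominal")

    def codes(self, values: pd.Series) -> pd.Series:
        """Map raw values to the fixed integer coding."""
        if self.type == "binary":
            levels = self.levels if self.levels is not None else [0, 1]
        else:
            levels = self.levels
        if levels is None:
            raise ValueError(f"nominal column {self.name!r} has no declared levels")
        mapping = {lev: i for i, lev in enumerate(levels)}
        unknown = set(values.unique()) - set(mapping)
        if unknown:
            raise ValueError(f"column {self.name!r} has undeclared levels {sorted(unknown)!r}")
        return values.map(mapping)

    def labels(self, codes) -> pd.Series:
        levels = self.levels if self.levels is not None else [0, 1]
        return pd.Series(codes).map(dict(enumerate(levels)))


@dataclass
class TableSchema:
    """Ordered collection of column specs covering a table."""

    columns: list[ColumnSpec] = field(default_factory=list)

    def __post_init__(self):
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise ValueError("duplicate column names in schema")
        if sum(c.weight_column for c in self.columns) > 1:
            raise ValueError("at most one weight column is allowed")

    def __iter__(self):
        return iter(self.columns)

    def __len__(self):
        return len(self.columns)

    def __getitem__(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def weight_column(self) -> str | None:
        for c in self.columns:
            if c.weight_column:
                return c.name
        return None

    @property
    def variable_names(self) -> list[str]:
        """Names of perturbable (non-weight) columns, in declared order."""
        return [c.name for c in self.columns if not c.weight_column]

    def validate_frame(self, df: pd.DataFrame) -> None:
        missing = [c.name for c in self.columns if c.name not in df.columns]
        if missing:
            raise ValueError(f"schema columns missing from data: {missing}")
        sub = df[[c.name for c in self.columns]]
        if sub.isna().any().any():
            raise ValueError("missing values are not supported; complete data required")

    # --- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "columns": [
                {
                    "name": c.name,
                    "type": c.type,
                    **({"levels": list(c.levels)} if c.levels is not None else {}),
                    **({"weight_column": True} if c.weight_column else {}),
                }
                for c in self.columns
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TableSchema":
        cols = [
            ColumnSpec(
                name=e["name"],
                type=e.get("type", "continuous"),
                levels=e.get("levels"),
                weight_column=bool(e.get("weight_column", False)),
            )
            for e in d["columns"]
        ]
        return cls(cols)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = json.dumps(self.to_dict(), indent=2)
        path.write_text(text + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TableSchema":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yml", ".yaml"):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))
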