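"""The samples x variables feature table and its on-disk CSV form.

A :class:`FeatureTable` holds a matrix of peak areas (one row per sample,
one column per metabolite peak), string sample/variable identifiers, a group
label per sample, and two optional per-variable flags: ``identified_mask``
(is the peak an identified metabolite) and ``truth`` (does the variable carry
a simulated group effect; used only by tests, never by evaluation code).

On disk a table is a plain CSV whose first two columns are ``sample_id`` and
``group`` followed by one column per variable, plus an optional JSON sidecar
``<name>.meta.json`` carrying the per-variable flags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["FeatureTable", "read_feature_table", "write_feature_table"]


@dataclass(frozen=True)
class FeatureTable:
    """Immutable samples x variables intensity matrix with metadata.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_variables)
        Peak-area intensities. Must be finite; generation produces strictly
        positive values, but preprocessed (centred/scaled) tables may hold
        arbitrary finite floats.
    sample_ids, variable_ids : arrays of unique strings.
    groups : array of per-sample group names (strings). Binary analyses
        require exactly two distinct groups; see :attr:`labels`.
    identified_mask : optional boolean array, one flag per variable.
    truth : optional boolean array, one flag per variable (simulation ground
        truth; carried through but never consumed by evaluation stages).
    group_levels : optional pair fixing which group maps to label 0 and 1.
        When absent, the sorted group names are used.
    """

    values: np.ndarray
    sample_ids: np.ndarray
    variable_ids: np.ndarray
    groups: np.ndarray
    identified_mask: np.ndarray | None = None
    truth: np.ndarray | None = None
    group_levels: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        for name in ("sample_ids", "variable_ids", "groups"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=object))
        for name in ("identified_mask", "truth"):
            val = getattr(self, name)
            if val is not None:
                object.__setattr__(self, name, np.asarray(val, dtype=bool))
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D samples x variables matrix")
        n, p = self.values.shape
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values contain missing or non-finite entries")
        if len(self.sample_ids) != n:
            raise ValidationError(f"sample_ids has {len(self.sample_ids)} entries, expected {n}")
        if len(self.variable_ids) != p:
            raise ValidationError(f"variable_ids has {len(self.variable_ids)} entries, expected {p}")
        if len(self.groups) != n:
            raise ValidationError(f"groups has {len(self.groups)} entries, expected {n}")
        for name, ids in (("sample_ids", self.sample_ids), ("variable_ids", self.variable_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
                raise ValidationError(f"duplicate entry {dup!r} in {name}")
        for name in ("identified_mask", "truth"):
            val = getattr(self, name)
            if val is not None and len(val) != p:
                raise ValidationError(f"{name} has {len(val)} entries, expected {p}")
        if self.group_levels is not None:
            a, b = self.group_levels
            present = set(self.groups)
            for g in (a, b):
                if g not in present:
                    raise ValidationError(f"group_levels names absent group {g!r}")
            if a == b:
                raise ValidationError(f"group_levels repeats group {a!r}")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def group_names(self) -> tuple[str, ...]:
        """Distinct group names in order of first appearance."""
        return tuple(dict.fromkeys(self.groups))

    @property
    def labels(self) -> np.ndarray:
        """Binary 0/1 labels; valid only when exactly two groups are present."""
        levels = self.group_levels
        if levels is None:
            names = sorted(set(self.groups))
            if len(names) != 2:
                raise ValidationError(
                    f"table has {len(names)} group(s) {names}; a binary analysis case "
                    "is required (use assemble_case to pick two groups)"
                )
            levels = (names[0], names[1])
        return (self.groups == levels[1]).astype(int)

    # ------------------------------------------------------------------
    def replace(self, **changes) -> "FeatureTable":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(changes)
        return FeatureTable(**current)

    def with_values(self, values: np.ndarray) -> "FeatureTable":
        return self.replace(values=values)

    def select_samples(self, index: np.ndarray) -> "FeatureTable":
        """Row subset (boolean mask or integer index); order preserved."""
        return self.replace(
            values=self.values[index],
            sample_ids=self.sample_ids[index],
            groups=self.groups[index],
        )

    def select_variables(self, which: Sequence[str] | np.ndarray) -> "FeatureTable":
        """Column subset by boolean mask or by variable ids (given order kept)."""
        which = np.asarray(which)
        if which.dtype == bool:
            idx = np.flatnonzero(which)
        else:
            pos = {v: i for i, v in enumerate(self.variable_ids)}
            missing = [str(v) for v in which if v not in pos]
            if missing:
                raise ValidationError(f"unknown variable id(s): {missing}")
            idx = np.array([pos[v] for v in which], dtype=int)
        return self.replace(
            values=self.values[:, idx],
            variable_ids=self.variable_ids[idx],
            identified_mask=None if self.identified_mask is None else self.identified_mask[idx],
            truth=None if self.truth is None else self.truth[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.variable_ids))
        df.insert(0, "group", list(self.groups))
        df.insert(0, "sample_id", list(self.sample_ids))
        return df


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """Write ``path`` as CSV and a ``<stem>.meta.json`` sidecar with flags."""
    path = Path(path)
    table.to_dataframe().to_csv(path, index=False)
    meta = {
        "variable_ids": [str(v) for v in table.variable_ids],
        "identified_mask": None
        if table.identified_mask is None
        else [bool(b) for b in table.identified_mask],
        "truth": None if table.truth is None else [bool(b) for b in table.truth],
        "group_levels": None if table.group_levels is None else list(table.group_levels),
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature-table CSV (and its sidecar, if present).

    Malformed input is rejected with the offending sample id or CSV line
    number in the message.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str})
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValidationError(f"{path.name}: missing required column '{col}'")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path.name}: duplicate sample_id {dup.iloc[0]!r}")
    var_cols = [c for c in df.columns if c not in ("sample_id", "group")]
    if not var_cols:
        raise ValidationError(f"{path.name}: no variable columns found")
    numeric = df[var_cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df[var_cols].notna()
    if bad.to_numpy().any():
        row = int(np.flatnonzero(bad.any(axis=1))[0])
        col = bad.columns[bad.iloc[row].to_numpy()][0]
        # +2: one for the header line, one for 1-based numbering
        raise ValidationError(
            f"{path.name}: non-numeric value in column '{col}' at line {row + 2}"
        )
    if numeric.isna().to_numpy().any():
        row = int(np.flatnonzero(numeric.isna().any(axis=1))[0])
        raise ValidationError(f"{path.name}: missing value at line {row + 2}")

    identified = truth = None
    levels = None
    sidecar = path.with_suffix(".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta.get("variable_ids") and list(meta["variable_ids"]) != var_cols:
            raise ValidationError(f"{sidecar.name}: variable ids disagree with {path.name}")
        if meta.get("identified_mask") is not None:
            identified = np.asarray(meta["identified_mask"], dtype=bool)
        if meta.get("truth") is not None:
            truth = np.asarray(meta["truth"], dtype=bool)
        if meta.get("group_levels") is not None:
            levels = tuple(meta["group_levels"])
    return FeatureTable(
        values=numeric.to_numpy(dtype=float),
        sample_ids=df["sample_id"].to_numpy(dtype=object),
        variable_ids=np.asarray(var_cols, dtype=object),
        groups=df["group"].to_numpy(dtype=object),
        identified_mask=identified,
        truth=truth,
        group_levels=levels,  # type: ignore[arg-type]
    )
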