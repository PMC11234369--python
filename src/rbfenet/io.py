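"""Shared data model and tabular I/O.

All free energies are held internally in kcal/mol.  Readers convert at the
boundary: a row whose ``unit`` column declares kJ/mol is divided by 4.184.
Ligand, target and force-field labels are opaque case-sensitive strings.

Sign convention for an edge A→B::

    ΔΔG(A→B) = ΔG_bind(B) − ΔG_bind(A)

so reversing an edge negates its ΔΔG.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: exact thermochemical calorie conversion, kJ per kcal
KJ_PER_KCAL = 4.184

EDGE_COLUMNS = ["target", "ligand_a", "ligand_b", "forcefield", "repeat", "ddg_calc"]


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """Parsed data violates a model invariant."""


@dataclass(frozen=True)
class EdgeRecord:
    """One repeat of one alchemical perturbation under one force field."""

    target: str
    ligand_a: str
    ligand_b: str
    forcefield: str
    repeat: int
    ddg_calc: float  # kcal/mol
    ddg_exp: float | None = None  # kcal/mol

    def __post_init__(self) -> None:
        if self.ligand_a == self.ligand_b:
            raise ValidationError(
                f"self-edge {self.ligand_a!r} -> {self.ligand_b!r} on {self.target!r}"
            )


@dataclass(frozen=True)
class ExperimentalRecord:
    """Experimental absolute binding free energy of one ligand."""

    target: str
    ligand: str
    dg_exp: float  # kcal/mol


@dataclass(frozen=True)
class ParameterAssignment:
    """Force-field parameter multiset assigned to one ligand.

    ``parameters`` is a multiset: a parameter applied to three atoms of the
    ligand appears with count 3.  Perturbation analysis compares counts, not
    mere membership.
    """

    target: str
    ligand: str
    parameters: Counter = field(default_factory=Counter)


@dataclass
class BenchmarkDataset:
    """Everything one benchmark analysis consumes.

    ``edges`` and ``experiments`` are tidy DataFrames (long layout, one row per
    observation); ``assignments`` maps (target, ligand) to a parameter Counter;
    ``leg_alphas`` optionally carries per-leg overlap diagnostics with columns
    target, ligand_a, ligand_b, forcefield, repeat, leg, alpha.
    """

    edges: pd.DataFrame
    experiments: pd.DataFrame
    assignments: dict[tuple[str, str], Counter] | None = None
    leg_alphas: pd.DataFrame | None = None

    def validate(self) -> None:
        missing = set(EDGE_COLUMNS) - set(self.edges.columns)
        if missing:
            raise FormatError(f"edge table lacks columns {sorted(missing)}")
        if len(self.experiments):
            known = set(zip(self.experiments["target"], self.experiments["ligand"]))
            for col in ("ligand_a", "ligand_b"):
                pairs = set(zip(self.edges["target"], self.edges[col]))
                orphans = pairs - known
                if orphans:
                    raise ValidationError(
                        f"edge ligands missing from experiments: {sorted(orphans)[:5]}"
                    )


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: Path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def _convert_units(df: pd.DataFrame, value_cols: Iterable[str]) -> pd.DataFrame:
    """Convert rows flagged kJ/mol to kcal/mol and drop the unit column."""
    if "unit" not in df.columns:
        return df
    unit = df["unit"].astype(str).str.strip().str.lower()
    bad = ~unit.isin({"kcal/mol", "kj/mol"})
    if bad.any():
        raise FormatError(f"unrecognized unit values: {sorted(df.loc[bad, 'unit'].unique())}")
    kj = unit == "kj/mol"
    df = df.copy()
    for col in value_cols:
        if col in df.columns:
            df.loc[kj, col] = df.loc[kj, col] / KJ_PER_KCAL
    return df.drop(columns=["unit"])


def read_edges(path: str | Path, dialect: str = "long_csv") -> pd.DataFrame:
    """Read per-repeat edge ΔΔG values.

    Parameters
    ----------
    path
        CSV file.  ``long_csv``: one row per (target, edge, forcefield,
        repeat) with columns target, ligand_a, ligand_b, forcefield, repeat,
        ddg_calc[, ddg_exp][, unit].  ``per_ff_csv``: wide layout with one
        ΔΔG column per force field; every non-key column is taken to be a
        force-field label.
    dialect
        ``"long_csv"`` (canonical) or ``"per_ff_csv"``.

    Returns
    -------
    DataFrame in the long layout, ΔΔG in kcal/mol.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if dialect == "long_csv":
        _require_columns(df, EDGE_COLUMNS, path)
    elif dialect == "per_ff_csv":
        keys = ["target", "ligand_a", "ligand_b", "repeat"]
        _require_columns(df, keys, path)
        value_cols = [c for c in df.columns if c not in keys + ["unit", "ddg_exp"]]
        if not value_cols:
            raise FormatError(f"{path}: no force-field columns found")
        id_cols = keys + [c for c in ("ddg_exp", "unit") if c in df.columns]
        df = df.melt(
            id_vars=id_cols, value_vars=value_cols,
            var_name="forcefield", value_name="ddg_calc",
        ).dropna(subset=["ddg_calc"])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    for col in ("ddg_calc", "ddg_exp"):
        if col in df.columns:
            numeric = pd.to_numeric(df[col], errors="coerce")
            bad = numeric.isna() & df[col].notna()
            if bad.any():
                row = int(bad.idxmax())
                raise FormatError(f"{path}: non-numeric {col} at row {row + 2}")
            df[col] = numeric
    df = _convert_units(df, ["ddg_calc", "ddg_exp"])
    if not np.isfinite(df["ddg_calc"].to_numpy(dtype=float)).all():
        raise ValidationError(f"{path}: non-finite ddg_calc values")
    if (df["ligand_a"] == df["ligand_b"]).any():
        raise ValidationError(f"{path}: self-edges present")
    dup = df.duplicated(subset=["target", "ligand_a", "ligand_b", "forcefield", "repeat"])
    if dup.any():
        raise ValidationError(f"{path}: duplicate repeat indices, e.g. row {int(dup.idxmax()) + 2}")
    df["repeat"] = df["repeat"].astype(int)
    return df.reset_index(drop=True)


def read_experimental(path: str | Path) -> pd.DataFrame:
    """Read experimental affinities (target, ligand, dg_exp[, unit])."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["target", "ligand", "dg_exp"], path)
    df["dg_exp"] = pd.to_numeric(df["dg_exp"])
    df = _convert_units(df, ["dg_exp"])
    dup = df.duplicated(subset=["target", "ligand"])
    if dup.any():
        keys = df.loc[dup, ["target", "ligand"]].itertuples(index=False, name=None)
        raise ValidationError(f"duplicate experimental records for {sorted(set(keys))}")
    return df.reset_index(drop=True)


def read_parameter_assignments(path: str | Path) -> dict[tuple[str, str], Counter]:
    """Read per-ligand force-field parameter lists.

    Accepts a CSV (columns target, ligand, parameters with a ";"-delimited
    multiset) or a YAML mapping ``{target: {ligand: [param, ...]}}``.  A ligand
    with an empty parameter list is kept (with a logged warning), because a
    ligand genuinely may use no tracked parameters.
    """
    path = Path(path)
    if path.suffix.lower() in {".yml", ".yaml"}:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        out: dict[tuple[str, str], Counter] = {}
        for target, ligands in data.items():
            for ligand, params in (ligands or {}).items():
                out[(str(target), str(ligand))] = Counter(str(p) for p in (params or []))
        return out
    df = pd.read_csv(path, keep_default_na=False)
    _require_columns(df, ["target", "ligand", "parameters"], path)
    out = {}
    for i, row in enumerate(df.itertuples(index=False)):
        if not str(row.ligand).strip():
            raise FormatError(f"{path}: row {i + 2} has no ligand label")
        raw = str(row.parameters).strip()
        params = Counter(p.strip() for p in raw.split(";") if p.strip())
        if not params:
            logger.warning("ligand %s/%s has an empty parameter list", row.target, row.ligand)
        out[(str(row.target), str(row.ligand))] = params
    return out


def read_workset(path: str | Path, temperature: float = 298.0):
    """Read one leg's work values: two-column CSV (direction, work).

    ``direction`` ∈ {forward, reverse}; reverse rows hold the raw work of the
    B→A transition.  Work in kcal/mol unless a ``unit`` column says kJ/mol.
    """
    from .neq import WorkSet  # local import to avoid a cycle

    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["direction", "work"], path)
    df["work"] = pd.to_numeric(df["work"])
    df = _convert_units(df, ["work"])
    direction = df["direction"].astype(str).str.strip().str.lower()
    bad = ~direction.isin({"forward", "reverse"})
    if bad.any():
        raise FormatError(f"{path}: bad direction values {sorted(df.loc[bad, 'direction'])}")
    return WorkSet(
        forward_work=df.loc[direction == "forward", "work"].to_numpy(),
        reverse_work=df.loc[direction == "reverse", "work"].to_numpy(),
        temperature=temperature,
    )


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV; ``read_csv(write(x)) == x`` on values.

    Floats are written with ``repr`` precision so the round trip is exact to
    well below 1e-12 relative.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, index=False)


def assignments_to_frame(assignments: Mapping[tuple[str, str], Counter]) -> pd.DataFrame:
    """Serialize parameter assignments to the CSV layout used on disk."""
    rows = [
        {
            "target": t,
            "ligand": l,
            "parameters": ";".join(p for p, c in sorted(cnt.items()) for _ in range(c)),
        }
        for (t, l), cnt in sorted(assignments.items())
    ]
    return pd.DataFrame(rows, columns=["target", "ligand", "parameters"])
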