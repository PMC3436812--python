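"""Expression-table container, readers/writers and preprocessing.

The on-disk format is a plain delimited text table (comma or tab) with a
header row: reserved columns ``cell_id`` and ``stage`` plus one column per
gene. Values are expected on a log-like scale (e.g. Ct-derived qPCR values);
no log transform is applied here. Normalization to endogenous controls
subtracts, for each cell, the mean of that cell's housekeeping-gene values
from every gene (the standard delta-Ct convention with e.g. Actb and Gapdh
as controls).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidInputError

RESERVED_COLUMNS = ("cell_id", "stage")


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with identifiers and stage labels."""

    values: np.ndarray
    cell_ids: list[str]
    gene_names: list[str]
    stage_of_cell: np.ndarray
    stage_order: list = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.stage_of_cell = np.asarray(self.stage_of_cell)
        n, d = self.values.shape
        if len(self.cell_ids) != n:
            raise InvalidInputError("cell_ids length does not match values")
        if len(self.gene_names) != d:
            raise InvalidInputError("gene_names length does not match values")
        if self.stage_of_cell.shape[0] != n:
            raise InvalidInputError("stage_of_cell length does not match values")
        dup = _duplicates(self.cell_ids)
        if dup:
            raise InvalidInputError(f"duplicate cell id(s): {dup}")
        dup = _duplicates(self.gene_names)
        if dup:
            raise InvalidInputError(f"duplicate gene name(s): {dup}")
        if not self.stage_order:
            self.stage_order = list(dict.fromkeys(self.stage_of_cell.tolist()))
        unknown = set(self.stage_of_cell.tolist()) - set(self.stage_order)
        if unknown:
            raise InvalidInputError(f"stage label(s) outside the declared order: {sorted(map(str, unknown))}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, name: str) -> int:
        try:
            return self.gene_names.index(name)
        except ValueError:
            raise InvalidInputError(f"gene {name!r} not present") from None

    def subset_stages(self, stages) -> "ExpressionMatrix":
        """New matrix restricted to the given stages (order preserved)."""
        stages = list(stages)
        unknown = [s for s in stages if s not in self.stage_order]
        if unknown:
            raise InvalidInputError(f"unknown stage label(s): {unknown}")
        mask = np.isin(self.stage_of_cell, stages)
        return ExpressionMatrix(
            values=self.values[mask].copy(),
            cell_ids=[c for c, m in zip(self.cell_ids, mask) if m],
            gene_names=list(self.gene_names),
            stage_of_cell=self.stage_of_cell[mask].copy(),
            stage_order=[s for s in self.stage_order if s in stages],
            provenance=self.provenance + [f"subset_stages({stages})"],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.gene_names)
        df.insert(0, "stage", self.stage_of_cell)
        df.insert(0, "cell_id", self.cell_ids)
        return df


def _duplicates(items) -> list:
    seen, dup = set(), []
    for it in items:
        if it in seen and it not in dup:
            dup.append(it)
        seen.add(it)
    return dup


def write_expression_table(matrix: ExpressionMatrix, path, delimiter: str = "\t"):
    matrix.to_frame().to_csv(path, sep=delimiter, index=False)


def read_expression_table(
    path,
    delimiter: str | None = None,
    cells_as_rows: bool = True,
    id_column: str = "cell_id",
    stage_column: str = "stage",
    stage_order=None,
    impute_missing_at: float | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression table.

    The delimiter is auto-detected from the header line (tab wins over comma)
    unless forced. With ``cells_as_rows=False`` the table is transposed after
    reading (genes as rows; the id/stage columns must then be header rows).
    Empty fields (not-detected reactions) are rejected unless
    ``impute_missing_at`` supplies a limit-of-detection constant to fill them
    with; unparseable text is always an error.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    if delimiter is None:
        header = path.open().readline()
        delimiter = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if not cells_as_rows:
        df = df.set_index(df.columns[0]).T.reset_index(names=id_column)
    for col in (id_column, stage_column):
        if col not in df.columns:
            raise InvalidInputError(f"required column {col!r} missing from {path.name}")
    cell_ids = df[id_column].astype(str).tolist()
    stages = df[stage_column].to_numpy()
    gene_cols = [c for c in df.columns if c not in (id_column, stage_column)]
    if not gene_cols:
        raise InvalidInputError("no gene columns found")
    values = np.empty((len(df), len(gene_cols)))
    for j, col in enumerate(gene_cols):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise InvalidInputError(
                f"unparseable value {df[col].iloc[i]!r} at row {cell_ids[i]!r}, column {col!r}"
            )
        if parsed.isna().any():
            if impute_missing_at is None:
                i = int(np.flatnonzero(parsed.isna().to_numpy())[0])
                raise InvalidInputError(
                    f"missing value at row {cell_ids[i]!r}, column {col!r} "
                    "(set impute_missing_at to fill not-detected values)")
            parsed = parsed.fillna(impute_missing_at)
        values[:, j] = parsed.to_numpy(dtype=float)
    provenance = [f"read({path.name})"]
    if impute_missing_at is not None:
        provenance.append(f"impute_missing_at({impute_missing_at})")
    return ExpressionMatrix(
        values=values,
        cell_ids=cell_ids,
        gene_names=gene_cols,
        stage_of_cell=stages,
        stage_order=list(stage_order) if stage_order else [],
        provenance=provenance,
    )


def normalize_to_controls(matrix: ExpressionMatrix, control_gene_names) -> ExpressionMatrix:
    """Subtract each cell's mean housekeeping-control level from all its genes.

    Control genes are retained; when exactly these genes are used as controls
    their per-cell mean is zero after normalization. Returns a new matrix.
    """
    control_gene_names = list(control_gene_names)
    if not control_gene_names:
        raise InvalidInputError("at least one control gene required")
    idx = [matrix.gene_index(g) for g in control_gene_names]
    ref = matrix.values[:, idx].mean(axis=1, keepdims=True)
    return replace(
        matrix,
        values=matrix.values - ref,
        cell_ids=list(matrix.cell_ids),
        gene_names=list(matrix.gene_names),
        stage_of_cell=matrix.stage_of_cell.copy(),
        stage_order=list(matrix.stage_order),
        provenance=matrix.provenance + [f"normalize_to_controls({control_gene_names})"],
    )


@dataclass
class RunConfig:
    """Flat run configuration mirrored by the CLI flags."""

    latent_dim: int = 2
    kernel: str = "rbf"
    signal_variance: float = 1.0
    lengthscale: float = 1.0
    rq_shape: float = 2.0
    bias_variance: float = 0.0
    noise_precision: float = 100.0
    gamma: object = 0.0           # scalar or {stage label: value}
    max_iterations: int = 1000
    objective_tolerance: float = 1e-6
    parameter_tolerance: float = 1e-6
    seed: int = 0
    stages_included: list = field(default_factory=list)   # empty = all
    control_genes: list = field(default_factory=list)
    metric: str = "euclidean"
    grid_resolution: int = 20

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidInputError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path):
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
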