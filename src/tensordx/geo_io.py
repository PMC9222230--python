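"""Series-matrix ingestion, 6-mode tensor assembly, and per-sample normalization.

Expression values arrive as GEO-style series-matrix tables, one file per
tissue: ``!``-prefixed metadata lines, then a probe x sample table delimited
by ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` with an
``ID_REF`` first column.  The full experiment is a 6-mode tensor

    x[i, j, k, m, s, t]

indexed by probe i, time point j, replicate k, treatment m, strain s and
tissue t.  Before decomposition every sample fiber (fixed j,k,m,s,t) is
centred over probes and rescaled so its sum of squares equals the number of
probes N:

    sum_i x_ijkmst = 0,        sum_i x_ijkmst^2 = N.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

MODE_NAMES = ("probe", "time", "replicate", "treatment", "strain", "tissue")


class SeriesMatrixFormatError(ValueError):
    """The file does not follow the series-matrix dialect."""


class SeriesMatrixParseError(ValueError):
    """A table cell could not be parsed as a number."""


class AssemblyError(ValueError):
    """The sample designs do not form a valid full factorial grid."""


class NormalizationError(ValueError):
    """A sample fiber cannot be normalized (zero variance)."""


@dataclass(frozen=True)
class SampleDesign:
    """Position of one sample in the (tissue, time, replicate, treatment, strain) grid."""

    sample_id: str
    tissue: str
    time_index: int
    replicate_index: int
    treatment_index: int
    strain_index: int

    def cell(self) -> tuple[int, int, int, int]:
        return (self.time_index, self.replicate_index,
                self.treatment_index, self.strain_index)


@dataclass
class ExpressionTensor:
    """A labelled 6-mode expression array.

    ``values`` has shape (probes, times, replicates, treatments, strains,
    tissues); ``probe_ids`` labels mode 0 and ``axis_labels`` maps each of
    the remaining mode names to its ordered level labels.
    """

    values: np.ndarray
    probe_ids: list[str]
    axis_labels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 6:
            raise ValueError(f"expected a 6-mode array, got {self.values.ndim} modes")
        if self.values.shape[0] != len(self.probe_ids):
            raise ValueError("mode-0 length does not match probe_ids")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def mode_names(self) -> tuple[str, ...]:
        return MODE_NAMES

    def copy(self) -> "ExpressionTensor":
        return ExpressionTensor(self.values.copy(), list(self.probe_ids),
                                {k: list(v) for k, v in self.axis_labels.items()})


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _split_fields(line: str) -> list[str]:
    return [f.strip().strip('"') for f in line.rstrip("\n").split("\t")]


def parse_series_matrix(path: str | Path) -> tuple[pd.DataFrame, dict[str, list[list[str]]]]:
    """Parse one series-matrix file.

    Returns the probe x sample table (probe IDs as index, sample IDs as
    columns) and all metadata lines keyed by field name; repeated keys such
    as ``!Sample_characteristics_ch1`` accumulate one entry per line.
    """
    metadata: dict[str, list[list[str]]] = {}
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with _open_text(path) as fh:
        for line in fh:
            stripped = line.rstrip("\n")
            if not stripped:
                continue
            if stripped.startswith("!series_matrix_table_begin"):
                saw_begin, in_table = True, True
                continue
            if stripped.startswith("!series_matrix_table_end"):
                saw_end, in_table = True, False
                continue
            if in_table:
                table_lines.append(stripped)
            elif stripped.startswith("!"):
                fields = _split_fields(stripped)
                metadata.setdefault(fields[0].lstrip("!"), []).append(fields[1:])
    if not (saw_begin and saw_end):
        raise SeriesMatrixFormatError(
            f"{path}: missing !series_matrix_table_begin/_end delimiters")
    if not table_lines:
        raise SeriesMatrixFormatError(f"{path}: empty table block")

    header = _split_fields(table_lines[0])
    if header[0] != "ID_REF":
        raise SeriesMatrixFormatError(f"{path}: table header must start with ID_REF")
    sample_ids = header[1:]
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    for line in table_lines[1:]:
        fields = _split_fields(line)
        probe_ids.append(fields[0])
        row = []
        for col, cell in zip(sample_ids, fields[1:]):
            if cell in ("", "NA", "null"):
                row.append(np.nan)      # missing value; assembly decides
                continue
            try:
                row.append(float(cell))
            except ValueError:
                raise SeriesMatrixParseError(
                    f"{path}: non-numeric value {cell!r} at probe "
                    f"{fields[0]!r}, sample {col!r}") from None
        if len(row) != len(sample_ids):
            raise SeriesMatrixFormatError(
                f"{path}: row {fields[0]!r} has {len(row)} values, "
                f"expected {len(sample_ids)}")
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.Index(probe_ids, name="ID_REF"),
                         columns=sample_ids)
    return table, metadata


# Default regex rules for recovering the design from sample metadata.  The
# synthetic writer emits "!Sample_characteristics_ch1" lines in exactly this
# canonical encoding; real GEO series vary, so the rules are configurable.
DEFAULT_DESIGN_RULES: dict[str, str] = {
    "tissue": r"tissue:\s*(\S+)",
    "time_index": r"time:\s*(\d+)",
    "replicate_index": r"replicate:\s*(\d+)",
    "treatment_index": r"treatment:\s*(\d+)",
    "strain_index": r"strain:\s*(\d+)",
}


def load_design_rules(path: str | Path) -> dict[str, str]:
    """Read field -> regex design-mapping rules from a YAML file."""
    with open(path) as fh:
        rules = yaml.safe_load(fh)
    if not isinstance(rules, dict):
        raise ValueError(f"{path}: design rules must be a mapping")
    missing = set(DEFAULT_DESIGN_RULES) - set(rules)
    if missing:
        raise ValueError(f"{path}: missing design rule(s): {sorted(missing)}")
    return {k: str(v) for k, v in rules.items()}


def designs_from_metadata(metadata: dict[str, list[list[str]]],
                          rules: dict[str, str] | None = None) -> list[SampleDesign]:
    """Extract one :class:`SampleDesign` per sample from parsed metadata.

    Every rule's regex is searched across all metadata lines; the first
    capturing group of the first match wins for each sample.
    """
    rules = dict(DEFAULT_DESIGN_RULES if rules is None else rules)
    id_rows = metadata.get("Sample_geo_accession") or metadata.get("Sample_title")
    if not id_rows:
        raise SeriesMatrixFormatError(
            "metadata lacks Sample_geo_accession/Sample_title lines")
    sample_ids = id_rows[0]
    n = len(sample_ids)
    per_sample_text: list[list[str]] = [[] for _ in range(n)]
    for key, lines in metadata.items():
        if not key.startswith("Sample_"):
            continue
        for line in lines:
            for i, cell in enumerate(line[:n]):
                per_sample_text[i].append(cell)
    designs = []
    for i, sid in enumerate(sample_ids):
        found: dict[str, str] = {}
        for fieldname, pattern in rules.items():
            for cell in per_sample_text[i]:
                m = re.search(pattern, cell)
                if m:
                    found[fieldname] = m.group(1)
                    break
            else:
                raise SeriesMatrixFormatError(
                    f"sample {sid!r}: no metadata cell matches rule "
                    f"{fieldname}={pattern!r}")
        designs.append(SampleDesign(
            sample_id=sid,
            tissue=found["tissue"],
            time_index=int(found["time_index"]),
            replicate_index=int(found["replicate_index"]),
            treatment_index=int(found["treatment_index"]),
            strain_index=int(found["strain_index"]),
        ))
    return designs


def assemble_tensor(tables: Sequence[pd.DataFrame],
                    designs: Sequence[SampleDesign],
                    impute_missing: bool = False) -> ExpressionTensor:
    """Assemble per-tissue probe x sample tables into the labelled 6-mode tensor.

    The probe set is the intersection across tables, in first-table order.
    Placement is keyed entirely by each sample's design, never by column
    order.  Missing values (NaN cells) are rejected unless
    ``impute_missing`` replaces them with the probe's within-table mean.
    Raises :class:`AssemblyError` on duplicate or missing design cells or
    an empty probe intersection.
    """
    if not tables:
        raise AssemblyError("no tables given")
    tables = list(tables)
    for ti, table in enumerate(tables):
        if table.isna().any().any():
            if not impute_missing:
                raise AssemblyError(
                    f"table {ti} contains missing values; pass "
                    "impute_missing=True for per-probe mean imputation")
            means = table.mean(axis=1)
            tables[ti] = table.apply(lambda col: col.fillna(means))
    probes = list(tables[0].index)
    probe_sets = [set(t.index) for t in tables[1:]]
    probes = [p for p in probes if all(p in s for s in probe_sets)]
    if not probes:
        raise AssemblyError("empty probe intersection across tables")

    tissues: list[str] = []
    for d in designs:
        if d.tissue not in tissues:
            tissues.append(d.tissue)
    sample_to_table: dict[str, int] = {}
    for ti, table in enumerate(tables):
        for col in table.columns:
            sample_to_table[col] = ti

    n_time = 1 + max(d.time_index for d in designs)
    n_rep = 1 + max(d.replicate_index for d in designs)
    n_trt = 1 + max(d.treatment_index for d in designs)
    n_str = 1 + max(d.strain_index for d in designs)
    shape = (len(probes), n_time, n_rep, n_trt, n_str, len(tissues))
    values = np.full(shape, np.nan)

    seen: set[tuple] = set()
    for d in designs:
        if d.sample_id not in sample_to_table:
            raise AssemblyError(f"design sample {d.sample_id!r} not found in any table")
        t = tissues.index(d.tissue)
        cell = d.cell() + (t,)
        if cell in seen:
            raise AssemblyError(
                f"duplicated design cell {cell} (sample {d.sample_id!r})")
        seen.add(cell)
        col = tables[sample_to_table[d.sample_id]].loc[probes, d.sample_id]
        values[(slice(None),) + cell] = col.to_numpy(dtype=float)

    if np.isnan(values).any():
        missing = int(np.isnan(values[0]).sum())
        raise AssemblyError(
            f"design grid incomplete: {missing} of {int(np.prod(shape[1:]))} "
            "sample cells unfilled")
    axis_labels = {
        "time": [str(j) for j in range(n_time)],
        "replicate": [str(k) for k in range(n_rep)],
        "treatment": [str(m) for m in range(n_trt)],
        "strain": [str(s) for s in range(n_str)],
        "tissue": tissues,
    }
    return ExpressionTensor(values, probes, axis_labels)


def normalize(tensor: ExpressionTensor) -> ExpressionTensor:
    """Centre and rescale every sample fiber to mean 0, sum of squares N.

    Idempotent: a normalized fiber has scale factor exactly 1 on a second
    pass.  Raises :class:`NormalizationError` for a zero-variance fiber.
    """
    x = tensor.values
    n = x.shape[0]
    centred = x - x.mean(axis=0, keepdims=True)
    ss = (centred ** 2).sum(axis=0)
    if np.any(ss <= 0):
        fiber = np.argwhere(ss <= 0)[0]
        raise NormalizationError(
            "zero-variance sample fiber at (time, replicate, treatment, "
            f"strain, tissue) = {tuple(int(v) for v in fiber)}")
    out = centred * np.sqrt(n / ss)
    return ExpressionTensor(out, list(tensor.probe_ids),
                            {k: list(v) for k, v in tensor.axis_labels.items()})


def log2_transform(tensor: ExpressionTensor, pseudocount: float = 1.0
                   ) -> ExpressionTensor:
    """Optional log2(x + pseudocount) for linear-scale inputs (requires
    x > -pseudocount everywhere); the pipeline default is no transform."""
    x = tensor.values
    if np.any(x + pseudocount <= 0):
        raise ValueError("log2 transform requires values > -pseudocount")
    return ExpressionTensor(np.log2(x + pseudocount), list(tensor.probe_ids),
                            {k: list(v) for k, v in tensor.axis_labels.items()})


def is_normalized(tensor: ExpressionTensor, rtol: float = 1e-6) -> bool:
    x = tensor.values
    n = x.shape[0]
    mean_ok = np.allclose(x.mean(axis=0), 0.0, atol=rtol)
    ss_ok = np.allclose((x ** 2).sum(axis=0), n, rtol=rtol)
    return bool(mean_ok and ss_ok)


def save_tensor(tensor: ExpressionTensor, path: str | Path) -> None:
    """Serialize tensor + labels to a single .npz archive."""
    labels = {f"labels_{k}": np.asarray(v, dtype=str)
              for k, v in tensor.axis_labels.items()}
    np.savez_compressed(path, values=tensor.values,
                        probe_ids=np.asarray(tensor.probe_ids, dtype=str),
                        **labels)


def load_tensor(path: str | Path) -> ExpressionTensor:
    with np.load(path, allow_pickle=False) as npz:
        values = npz["values"]
        probe_ids = [str(p) for p in npz["probe_ids"]]
        axis_labels = {key[len("labels_"):]: [str(v) for v in npz[key]]
                       for key in npz.files if key.startswith("labels_")}
    return ExpressionTensor(values, probe_ids, axis_labels)
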