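"""Tabular input/output.

All tables are plain TSV: tab-separated, UTF-8, header row, "." decimal, no
quoting. Floats are written with 12 significant digits so that write/read
round-trips are lossless at the precision any downstream consumer uses.
Result tables can also be written as JSON (one object per record, keys equal
to the TSV column names).
"""

from __future__ import annotations

import dataclasses
import json
import math
import tomllib
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd

from .records import ExperimentRecord, RunConfig, TaxonRecord, ValidationError

_FLOAT_FORMAT = "%.17g"  # shortest-exact is not available via printf; 17 round-trips


class FormatError(ValueError):
    """A table file is structurally malformed (missing column, bad cell)."""


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in required:
        if column not in frame.columns:
            raise FormatError(f"{path}: missing required column {column!r}")
    return frame

def _parse(value: str, kind: type, path, row: int, column: str):
    try:
        if kind is int:
            return int(value)
        return float(value)
    except ValueError as exc:
        raise FormatError(
            f"{path}: row {row + 2}: non-numeric value {value!r} in column "
            f"{column!r}"
        ) from exc


def _opt_float(frame: pd.DataFrame, column: str, path, row: int) -> float | None:
    if column not in frame.columns:
        return None
    raw = frame[column].iloc[row].strip()
    if raw == "":
        return None
    return _parse(raw, float, path, row, column)


def read_experiments(path: str | Path) -> list[ExperimentRecord]:
    """Read the experiment metadata table (one row per DTE experiment)."""

    frame = _read_tsv(path, ["experiment_id", "n_wells", "inoculum_lambda"])
    records = []
    seen: set[str] = set()
    for i in range(len(frame)):
        exp_id = frame["experiment_id"].iloc[i].strip()
        if exp_id in seen:
            raise ValidationError(f"{path}: duplicate experiment_id {exp_id!r}")
        seen.add(exp_id)
        positive: int | None = None
        if "positive_wells" in frame.columns:
            raw = frame["positive_wells"].iloc[i].strip()
            if raw != "":
                positive = _parse(raw, int, path, i, "positive_wells")
        records.append(
            ExperimentRecord(
                experiment_id=exp_id,
                n_wells=_parse(frame["n_wells"].iloc[i], int, path, i, "n_wells"),
                inoculum_lambda=_parse(
                    frame["inoculum_lambda"].iloc[i], float, path, i,
                    "inoculum_lambda",
                ),
                positive_wells=positive,
                in_situ_salinity=_opt_float(frame, "in_situ_salinity", path, i),
                medium_salinity=_opt_float(frame, "medium_salinity", path, i),
            )
        )
    return records


def read_taxa(path: str | Path) -> list[TaxonRecord]:
    """Read the per-taxon table: fractional abundance and pure-well counts."""

    frame = _read_tsv(
        path, ["experiment_id", "taxon_id", "rel_abundance", "observed_pure_wells"]
    )
    records = []
    seen: set[tuple[str, str]] = set()
    for i in range(len(frame)):
        key = (
            frame["experiment_id"].iloc[i].strip(),
            frame["taxon_id"].iloc[i].strip(),
        )
        if key in seen:
            raise ValidationError(f"{path}: duplicate (experiment, taxon) pair {key}")
        seen.add(key)
        records.append(
            TaxonRecord(
                experiment_id=key[0],
                taxon_id=key[1],
                rel_abundance=_parse(
                    frame["rel_abundance"].iloc[i], float, path, i, "rel_abundance"
                ),
                observed_pure_wells=_parse(
                    frame["observed_pure_wells"].iloc[i], int, path, i,
                    "observed_pure_wells",
                ),
            )
        )
    return records


def check_taxa_against_experiments(
    taxa: Iterable[TaxonRecord], experiments: Iterable[ExperimentRecord]
) -> None:
    """Cross-table invariant: pure wells cannot exceed the experiment's wells."""

    wells = {e.experiment_id: e.n_wells for e in experiments}
    for t in taxa:
        if t.experiment_id not in wells:
            raise ValidationError(
                f"taxon {t.taxon_id} references unknown experiment "
                f"{t.experiment_id!r}"
            )
        if t.observed_pure_wells > wells[t.experiment_id]:
            raise ValidationError(
                f"{t.experiment_id}/{t.taxon_id}: observed_pure_wells="
                f"{t.observed_pure_wells} exceeds n_wells={wells[t.experiment_id]}"
            )


def average_replicate_abundances(
    table: pd.DataFrame, replicate_map: dict[str, str]
) -> pd.DataFrame:
    """Average per-sample abundances over replicate groups.

    ``table`` is samples x taxa (rows indexed by sample id); ``replicate_map``
    sends each sample id to its experiment. Returns experiments x taxa with
    the arithmetic mean over each group (biological duplicates in the common
    case; any group size is averaged the same way).
    """

    missing = [s for s in replicate_map if s not in table.index]
    if missing:
        raise KeyError(f"samples in replicate_map absent from table: {missing}")
    if (table.to_numpy() < 0).any():
        raise ValidationError("abundances must be non-negative")
    groups = pd.Series(replicate_map)
    subset = table.loc[groups.index]
    return subset.groupby(groups).mean()


def _record_to_dict(record: Any) -> dict[str, Any]:
    if dataclasses.is_dataclass(record):
        return dataclasses.asdict(record)
    return dict(record)


def write_table(
    rows: Sequence[Any], path: str | Path, fmt: str = "tsv"
) -> None:
    """Write records (dataclasses or mappings) as TSV or JSON.

    An empty sequence yields an empty file (header cannot be inferred); use
    ``write_records`` with a record type for a header-only file.
    """

    dicts = [_record_to_dict(r) for r in rows]
    _write_dicts(dicts, list(dicts[0].keys()) if dicts else [], path, fmt)


def write_records(
    records: Sequence[Any],
    path: str | Path,
    fmt: str = "tsv",
    record_type: type | None = None,
) -> None:
    """Like :func:`write_table` but keeps the schema for empty inputs."""

    if not records and record_type is None:
        raise ValidationError("empty table needs record_type to emit a header")
    columns = [
        f.name
        for f in dataclasses.fields(record_type if record_type else type(records[0]))
    ]
    _write_dicts([_record_to_dict(r) for r in records], columns, path, fmt)


def _write_dicts(
    dicts: list[dict[str, Any]], columns: list[str], path: str | Path, fmt: str
) -> None:
    path = Path(path)
    if fmt == "tsv":
        frame = pd.DataFrame(dicts, columns=columns)
        frame.to_csv(
            path, sep="\t", index=False, float_format=_FLOAT_FORMAT,
            encoding="utf-8", lineterminator="\n",
        )
    elif fmt == "json":
        path.write_text(
            json.dumps(dicts, indent=1, allow_nan=True, default=_json_default)
            + "\n",
            encoding="utf-8",
        )
    else:
        raise ValidationError(f"unknown format {fmt!r}; expected 'tsv' or 'json'")


def _json_default(value: Any) -> Any:
    if isinstance(value, float) and math.isnan(value):
        return None
    raise TypeError(f"not JSON serializable: {value!r}")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a result table back (TSV with type inference)."""

    return pd.read_csv(path, sep="\t")


def frame_to_records(frame: pd.DataFrame, record_type: type) -> list[Any]:
    """Rebuild dataclass records from a round-tripped table."""

    field_names = [f.name for f in dataclasses.fields(record_type)]
    records = []
    for row in frame.itertuples(index=False):
        kwargs = {k: v for k, v in zip(frame.columns, row) if k in field_names}
        for k, v in list(kwargs.items()):
            if isinstance(v, float) and math.isnan(v):
                kwargs[k] = None
        records.append(record_type(**kwargs))
    return records


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Build a RunConfig from a flat TOML file plus explicit overrides.

    Keys mirror the RunConfig fields; unknown keys are an error. Overrides
    (e.g. CLI flags) win over file values, which win over defaults.
    """

    values: dict[str, Any] = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(
                f"{path}: unknown config keys {sorted(unknown)}; "
                f"expected a subset of {sorted(known)}"
            )
        values.update(data)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
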