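"""CSV telemetry read/write with provenance stamping, and seed fan-out."""

from __future__ import annotations

import zlib
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["SchemaError", "write_trace", "read_trace", "child_seed"]


class SchemaError(ValueError):
    """CSV header does not match the expected schema."""


def child_seed(master_seed: int, module: str) -> int:
    """Deterministic per-module child seed below 2**31.

    Derived by stable hashing of the module name so adding a module never
    perturbs the streams of existing ones.
    """
    return (int(master_seed) * 1_000_003 + zlib.crc32(module.encode())) % (2**31 - 1)


def write_trace(
    records: pd.DataFrame, path: str | Path, *, seed: int | None = None
) -> None:
    """Write records as UTF-8 CSV with a provenance comment header line."""
    path = Path(path)
    stamp = f"# optocord v{__version__}"
    if seed is not None:
        stamp += f" seed={seed}"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(stamp + "\n")
        records.to_csv(fh, index=False, float_format="%.9g", lineterminator="\n")


def read_trace(
    path: str | Path, expected_columns: list[str] | None = None
) -> pd.DataFrame:
    """Read a trace CSV, skipping provenance comments; checks the schema."""
    df = pd.read_csv(path, comment="#")
    if expected_columns is not None and list(df.columns) != list(expected_columns):
        raise SchemaError(
            f"{path}: header {list(df.columns)} != expected {expected_columns}"
        )
    return df
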