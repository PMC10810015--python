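"""Structured output writing and run provenance records."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field

import pandas as pd

__all__ = ["write_outputs", "RunRecord", "sigfig"]

FORMATS = ("csv", "json")


def sigfig(value, digits: int = 6):
    """Round a float to ``digits`` significant digits (identity otherwise)."""
    if isinstance(value, float):
        return float(f"{value:.{digits}g}")
    return value


def write_outputs(records, fmt: str, path) -> None:
    """Write records (list of dicts or DataFrame) as CSV or JSON.

    Column order is deterministic (first-record field order) and
    numbers are formatted to 6 significant digits in both formats, so
    the JSON mirrors the CSV field for field.
    """
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    if isinstance(records, pd.DataFrame):
        records = records.to_dict("records")
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    columns = list(records[0].keys())
    rounded = [{k: sigfig(r[k]) for k in columns} for r in records]
    if fmt == "csv":
        df = pd.DataFrame(rounded, columns=columns)
        df.to_csv(path, index=False, float_format="%.6g")
    elif hasattr(path, "write"):
        json.dump(rounded, path, indent=1)
        path.write("\n")
    else:
        with open(path, "w") as fh:
            json.dump(rounded, fh, indent=1)
            fh.write("\n")


@dataclass
class RunRecord:
    """Provenance of one CLI invocation.

    Identical config hash + seed imply identical output files; the
    timestamp is informational and never written into data outputs.
    """

    command: str
    config_hash: str
    seed: int | None
    version: str
    output_paths: tuple = ()
    timestamp: float = field(default_factory=time.time)

    @classmethod
    def create(cls, command, cal, seed, outputs=()):
        from . import __version__

        digest = hashlib.sha256(
            json.dumps(cal.to_dict(), sort_keys=True).encode()
        ).hexdigest()
        return cls(
            command=command,
            config_hash=digest,
            seed=seed,
            version=__version__,
            output_paths=tuple(str(p) for p in outputs),
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)
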