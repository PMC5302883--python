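"""Machine-readable analysis reports and their schema.

Reports are plain JSON documents validated against the schema shipped at
``pigmentnoise/schema/report.schema.json``.  Validation here is a minimal
built-in check of the schema's structural constraints (required keys, types,
no extraneous top-level keys), sufficient for the report's flat layout.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Any

from . import __version__
from .errors import DataError

SCHEMA_VERSION = 1


def load_schema() -> dict[str, Any]:
    """The published JSON schema for analysis reports."""
    text = resources.files("pigmentnoise").joinpath("schema/report.schema.json").read_text()
    return json.loads(text)


def new_report(seed: int, parameters: dict[str, Any]) -> dict[str, Any]:
    return {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": int(seed),
        "parameters": parameters,
        "stages": {},
    }


def validate_report(report: dict[str, Any]) -> None:
    """Raise :class:`DataError` if the report does not satisfy the schema."""
    schema = load_schema()
    required = schema["required"]
    missing = [k for k in required if k not in report]
    if missing:
        raise DataError(f"report missing required keys: {missing}")
    extra = set(report) - set(schema["properties"])
    if extra:
        raise DataError(f"report has unexpected top-level keys: {sorted(extra)}")
    if report["schema_version"] != SCHEMA_VERSION:
        raise DataError(
            f"report schema_version {report['schema_version']!r} != {SCHEMA_VERSION}"
        )
    if not isinstance(report["package_version"], str):
        raise DataError("package_version must be a string")
    if not isinstance(report["seed"], int):
        raise DataError("seed must be an integer")
    for key in ("parameters", "stages"):
        if not isinstance(report[key], dict):
            raise DataError(f"{key} must be an object")
    for name, stage in report["stages"].items():
        if not isinstance(stage, dict):
            raise DataError(f"stage {name!r} must be an object")
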