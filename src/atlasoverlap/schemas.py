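"""Minimal JSON-Schema validation for the shipped metadata schema.

Covers the subset of JSON Schema the in-repo schema file uses: ``type``
(including type lists), ``properties`` / ``required`` /
``additionalProperties``, ``items`` / ``minItems``, ``enum``, ``minimum`` /
``maximum``, and ``$ref`` into ``$defs``.  Errors carry a JSON-pointer-like
path to the offending value.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Any

__all__ = ["SchemaValidationError", "validate", "load_schema"]

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "boolean": bool,
    "null": type(None),
}


class SchemaValidationError(ValueError):
    """An instance violates the schema; message includes the value path."""


def load_schema(name: str = "relation_metadata.schema.json") -> dict:
    """Load a schema document shipped with the package."""
    text = resources.files("atlasoverlap").joinpath("schemas", name).read_text()
    return json.loads(text)


def _check_type(instance: Any, expected: str, path: str) -> None:
    if expected == "number":
        ok = isinstance(instance, (int, float)) and not isinstance(instance, bool)
    elif expected == "integer":
        ok = isinstance(instance, int) and not isinstance(instance, bool)
    else:
        ok = isinstance(instance, _TYPES[expected])
    if not ok:
        raise SchemaValidationError(f"{path or '/'}: expected {expected}, got {type(instance).__name__}")


def validate(instance: Any, schema: dict, root: dict | None = None, path: str = "") -> None:
    """Validate ``instance`` against ``schema``; raise on the first violation."""
    root = root if root is not None else schema
    if "$ref" in schema:
        ref = schema["$ref"]
        if not ref.startswith("#/$defs/"):
            raise ValueError(f"unsupported $ref {ref!r}")
        validate(instance, root["$defs"][ref.split("/")[-1]], root, path)
        return
    expected = schema.get("type")
    if expected is not None:
        types = expected if isinstance(expected, list) else [expected]
        for t in types:
            try:
                _check_type(instance, t, path)
                break
            except SchemaValidationError:
                continue
        else:
            raise SchemaValidationError(
                f"{path or '/'}: expected one of {types}, got {type(instance).__name__}"
            )
    if "enum" in schema and instance not in schema["enum"]:
        raise SchemaValidationError(f"{path or '/'}: {instance!r} not in {schema['enum']}")
    if isinstance(instance, (int, float)) and not isinstance(instance, bool):
        if "minimum" in schema and instance < schema["minimum"]:
            raise SchemaValidationError(f"{path or '/'}: {instance} < minimum {schema['minimum']}")
        if "maximum" in schema and instance > schema["maximum"]:
            raise SchemaValidationError(f"{path or '/'}: {instance} > maximum {schema['maximum']}")
    if isinstance(instance, dict):
        for key in schema.get("required", []):
            if key not in instance:
                raise SchemaValidationError(f"{path or '/'}: missing required property {key!r}")
        props = schema.get("properties", {})
        for key, value in instance.items():
            if key in props:
                validate(value, props[key], root, f"{path}/{key}")
            elif schema.get("additionalProperties", True) is False:
                raise SchemaValidationError(f"{path or '/'}: unexpected property {key!r}")
    if isinstance(instance, list):
        if "minItems" in schema and len(instance) < schema["minItems"]:
            raise SchemaValidationError(f"{path or '/'}: fewer than {schema['minItems']} items")
        if "items" in schema:
            for k, item in enumerate(instance):
                validate(item, schema["items"], root, f"{path}/{k}")
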