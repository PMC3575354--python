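"""Feature-value plumbing shared by the schema and store layers.

A feature value is a primitive (bool, int, float, str), a :class:`Ref` to
another instance in the same document store, or a list of strings or refs.
The JSON document dialect encodes a reference as ``{"$ref": <id>}``.
"""

from __future__ import annotations

from typing import Any, NamedTuple


class Ref(NamedTuple):
    """An id-reference to another annotation instance in the same store."""

    id: int

    def __repr__(self) -> str:  # keep store dumps short
        return f"Ref({self.id})"


def encode_value(value: Any) -> Any:
    """Encode an in-memory feature value into the JSON dialect."""
    if isinstance(value, Ref):
        return {"$ref": value.id}
    if isinstance(value, list):
        return [encode_value(v) for v in value]
    return value


def decode_value(value: Any) -> Any:
    """Decode a JSON-dialect feature value into its in-memory form."""
    if isinstance(value, dict):
        if set(value) == {"$ref"} and isinstance(value["$ref"], int):
            return Ref(value["$ref"])
        raise ValueError(f"not a valid feature value: {value!r}")
    if isinstance(value, list):
        return [decode_value(v) for v in value]
    return value
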