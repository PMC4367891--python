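"""Enzyme Commission (EC) numbers.

An EC number is a four-field identifier for an enzymatic reaction class,
e.g. ``4.2.1.109`` (5-methylthioribulose-1-phosphate dehydratase).  Partially
specified numbers use ``-`` wildcards, which may only occupy a contiguous
suffix: ``1.1.-.-`` is a valid sub-subclass wildcard, ``1.-.1.1`` is not.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import total_ordering

__all__ = ["ECNumber", "ECParseError", "normalize_ec"]

_EC_PREFIX = re.compile(r"^\s*(?:EC\s*:?\s*)?", re.IGNORECASE)


class ECParseError(ValueError):
    """Raised when a string cannot be interpreted as an EC number."""


@total_ordering
@dataclass(frozen=True)
class ECNumber:
    """A validated four-field EC number; ``None`` fields are wildcards.

    Invariants enforced at construction: the first field is a concrete
    integer >= 1, and wildcards occupy a contiguous suffix.
    """

    fields: tuple[int | None, int | None, int | None, int | None]

    def __post_init__(self) -> None:
        if len(self.fields) != 4:
            raise ECParseError(f"EC number needs 4 fields, got {len(self.fields)}")
        if not isinstance(self.fields[0], int) or self.fields[0] < 1:
            raise ECParseError(f"EC class field must be a positive integer: {self.fields!r}")
        seen_wildcard = False
        for f in self.fields:
            if f is None:
                seen_wildcard = True
            else:
                if seen_wildcard:
                    raise ECParseError(
                        f"wildcards must form a contiguous suffix: {self.fields!r}"
                    )
                if not isinstance(f, int) or f < 0:
                    raise ECParseError(f"EC fields must be non-negative integers: {self.fields!r}")

    @property
    def is_wildcard(self) -> bool:
        return any(f is None for f in self.fields)

    def matches(self, other: "ECNumber", prefix_wildcards: bool = False) -> bool:
        """Exact equality by default; with ``prefix_wildcards`` a wildcard
        field in *self* matches any value in *other*."""
        if not prefix_wildcards:
            return self == other
        return all(a is None or a == b for a, b in zip(self.fields, other.fields))

    def sort_key(self) -> tuple[tuple[int, int], ...]:
        # concrete fields sort before wildcards at the same position
        return tuple((0, f) if f is not None else (1, 0) for f in self.fields)

    def __lt__(self, other: object) -> bool:
        if not isinstance(other, ECNumber):
            return NotImplemented
        return self.sort_key() < other.sort_key()

    def __str__(self) -> str:
        return ".".join("-" if f is None else str(f) for f in self.fields)

    def __repr__(self) -> str:
        return f"ECNumber({self})"

    @classmethod
    def from_string(cls, text: str) -> "ECNumber":
        return normalize_ec(text)


def normalize_ec(text: str) -> ECNumber:
    """Parse a string like ``"4.2.1.109"``, ``" ec 1.1.1.1 "`` or ``"1.1.-.-"``
    into a canonical :class:`ECNumber`.

    Raises :class:`ECParseError` on malformed input (wrong field count,
    non-numeric concrete field, non-contiguous wildcards), naming the
    offending text.
    """
    if text is None or not text.strip():
        raise ECParseError("empty EC number string")
    body = _EC_PREFIX.sub("", text.strip(), count=1).strip()
    parts = body.split(".")
    if len(parts) != 4:
        raise ECParseError(f"expected 4 dot-separated fields in EC number {text!r}")
    fields: list[int | None] = []
    for part in parts:
        part = part.strip()
        if part in ("-", "", "*"):
            fields.append(None)
        elif part.isdigit():
            fields.append(int(part))
        else:
            raise ECParseError(f"non-numeric field {part!r} in EC number {text!r}")
    try:
        return ECNumber(tuple(fields))  # type: ignore[arg-type]
    except ECParseError as exc:
        raise ECParseError(f"{exc} (from {text!r})") from None
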