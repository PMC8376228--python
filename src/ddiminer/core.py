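"""Canonical identifier pairs.

Protein and domain identifiers are plain token strings compared by raw
lexicographic byte order (so ``"Q10" < "Q9"``).  Unordered pairs — both
protein-protein interactions (PPIs) and domain-domain interactions (DDIs) —
are stored canonically with the smaller identifier first; self-pairs are
allowed and denote self-interactions (for domains: homo-DDIs).
"""

from __future__ import annotations

from .errors import ValidationError

#: A canonical (sorted) pair of domain accessions.
DDIKey = tuple[str, str]

#: A canonical (sorted) pair of protein identifiers.
OrderedPPI = tuple[str, str]


def _validate_token(value: str, kind: str) -> None:
    if not value or any(c.isspace() for c in value):
        raise ValidationError(f"invalid {kind} identifier: {value!r}")


def canonical_ppi(a: str, b: str) -> OrderedPPI:
    """Order a protein pair alphanumerically (left <= right) to avoid redundancy."""
    _validate_token(a, "protein")
    _validate_token(b, "protein")
    return (a, b) if a <= b else (b, a)


def canonical_ddi(a: str, b: str) -> DDIKey:
    """Order a domain pair alphanumerically; (d, d) is a homo-DDI."""
    _validate_token(a, "domain")
    _validate_token(b, "domain")
    return (a, b) if a <= b else (b, a)
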