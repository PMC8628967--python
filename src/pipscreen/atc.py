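"""ATC (Anatomical Therapeutic Chemical) code grammar and prefix matching.

A full level-5 ATC code has seven characters: anatomical main group (one
letter), therapeutic subgroup (two digits), pharmacological subgroup (one
letter), chemical subgroup (one letter), chemical substance (two digits),
e.g. ``C03CA01`` (furosemide).  Truncations at any classification level are
valid *class prefixes* (``C03C`` = loop diuretics).  Prescriptions must carry
full level-5 codes; rule files may use prefixes for class-level criteria.
"""

from __future__ import annotations

import re
from typing import Iterable

# Level-1 letter, 2 digits, then optionally letter, letter, 2 digits.
_ATC_RE = re.compile(r"^[A-V](\d{2}([A-Z]([A-Z](\d{2})?)?)?)?$")
_ATC_LEVEL5_RE = re.compile(r"^[A-V]\d{2}[A-Z]{2}\d{2}$")


def is_valid_atc(code: str) -> bool:
    """True if *code* is a syntactically valid ATC code or class prefix."""
    return bool(_ATC_RE.match(code))


def is_level5(code: str) -> bool:
    """True if *code* is a full 7-character chemical-substance code."""
    return bool(_ATC_LEVEL5_RE.match(code))


def atc_matches(code: str, prefixes: Iterable[str]) -> bool:
    """True if *code* falls under any of the given codes/class prefixes."""
    return any(code.startswith(p) for p in prefixes)


def validate_atc(code: str, *, level5: bool = False) -> str:
    """Return *code* if valid, else raise ``ValueError``."""
    if level5:
        if not is_level5(code):
            raise ValueError(f"not a valid level-5 ATC code: {code!r}")
    elif not is_valid_atc(code):
        raise ValueError(f"not a valid ATC code or prefix: {code!r}")
    return code
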