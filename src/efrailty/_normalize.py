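"""Code and text normalization primitives.

Shared by the terminology dictionary (entries are stored normalized) and the
matching engine (records are normalized before comparison), so that
"428.0" vs "4280" and "Atrial Fib." vs "atrial fib" unify.  Re-exported as
part of the matching engine's public surface.
"""

from __future__ import annotations

import re
import unicodedata

# '#' is clinician shorthand for "fracture" and must survive normalization
# as a matchable token; every other non-alphanumeric maps to a space.
_PUNCT_RE = re.compile(r"[^0-9a-z#\s]+")
_WS_RE = re.compile(r"\s+")


def normalize_code(raw: str | None) -> str:
    """Normalize a clinical code: trim, uppercase, drop dots and inner spaces.

    "428.0" and "4280" normalize identically; an empty result means the
    field carried no usable code.
    """
    if raw is None:
        return ""
    # drop ALL whitespace before dots, or dot removal could expose stray
    # whitespace at the edges and break idempotence
    return "".join(raw.split()).upper().replace(".", "")


def normalize_text(raw: str | None) -> str:
    """Normalize free text for phrase matching.

    Lowercases, folds diacritics to ASCII, maps punctuation (except '#') to
    spaces and collapses whitespace.  Deterministic and idempotent.
    """
    if raw is None:
        return ""
    text = unicodedata.normalize("NFKD", raw)
    text = text.encode("ascii", "ignore").decode("ascii")
    text = text.lower()
    text = _PUNCT_RE.sub(" ", text)
    return _WS_RE.sub(" ", text).strip()


def tokens_of(normalized: str) -> list[str]:
    """Token list of an already-normalized text (split on single spaces)."""
    return normalized.split() if normalized else []
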