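"""Text normalization and fuzzy matching primitives shared across the pipeline.

Clinical text messages are informal: typos ("disfunction"/"dysfunction"),
inconsistent casing and stray punctuation are the norm. Every comparison in
the pipeline therefore goes through the same normalization (case-fold, strip
punctuation, collapse whitespace) and, where configured, an edit-distance
based fuzzy score.
"""

from __future__ import annotations

import re

import edlib

_PUNCT_RE = re.compile(r"[^\w\s]")
_WS_RE = re.compile(r"\s+")


def normalize_ws(text: str) -> str:
    """Collapse runs of whitespace and strip the ends; casing is preserved."""
    return _WS_RE.sub(" ", text).strip()


def normalize_text(text: str) -> str:
    """Canonical form used for matching: case-folded, punctuation stripped,
    whitespace collapsed."""
    return normalize_ws(_PUNCT_RE.sub(" ", text.casefold()))


# normalize_phrase is the same canonicalization; the alias marks intent at call
# sites that compare annotator phrases rather than whole messages.
normalize_phrase = normalize_text


def fuzzy_substring_score(needle: str, haystack: str) -> float:
    """Best normalized alignment score of ``needle`` against any substring of
    ``haystack`` (infix alignment), in [0, 1]; 1.0 iff ``needle`` occurs exactly.

    Both arguments are expected to be pre-normalized. Empty needle scores 0.
    """
    if not needle:
        return 0.0
    if needle in haystack:
        return 1.0
    if not haystack:
        return 0.0
    dist = edlib.align(needle, haystack, mode="HW", task="distance")["editDistance"]
    return max(0.0, 1.0 - dist / len(needle))


def fuzzy_similarity(a: str, b: str) -> float:
    """Symmetric normalized edit similarity of two phrases, in [0, 1]."""
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return max(0.0, 1.0 - dist / max(len(a), len(b)))
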