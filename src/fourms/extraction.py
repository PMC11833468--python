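"""Structured 4M expression extraction: contract, parsing, validation, and the
deterministic lexicon reference extractor.

The four extraction classes are the Age-Friendly Health Systems 4M concepts:
What Matters (preferences, goals of care), Medication, Mentation (cognition,
behaviour), and Mobility. An extractor — in production a generative language
model behind an adapter, in tests the lexicon extractor — maps a message to a
structured JSON object ``{class: [phrase, ...]}``. This module parses that
output defensively (model output can be malformed), screens each phrase
against the source message for hallucinations, and derives the binary and
count representations used for evaluation.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Protocol, Sequence

from ._text import fuzzy_similarity, fuzzy_substring_score, normalize_text
from .corpus import Message

logger = logging.getLogger(__name__)


class MClass(str, Enum):
    """The four 4M-framework extraction classes."""

    WHAT_MATTERS = "what_matters"
    MEDICATION = "medication"
    MENTATION = "mentation"
    MOBILITY = "mobility"


M_CLASSES: tuple[MClass, ...] = tuple(MClass)

#: Decoding parameters passed opaquely to generative extractor plug-ins. The
#: defaults are the greedy, locally-reproducible settings used for clinical
#: extraction (inert for deterministic extractors like the lexicon one).
@dataclass(frozen=True)
class DecodingConfig:
    temperature: float = 0.0
    top_p: float = 0.9
    top_k: int = 40
    repeat_penalty: float | None = None
    seed: int = 418


DEFAULT_PROMPT_TEMPLATE = (
    "Extract every word or phrase in the message below that expresses one of "
    "the 4M concepts (what_matters, medication, mentation, mobility). Respond "
    "with a JSON object mapping each concept to the list of verbatim phrases; "
    "use an empty list when a concept is absent.\n\nMessage: {text}"
)


class Extractor(Protocol):
    """Plug-in contract: (prompt template, message text, decoding) -> raw text."""

    def __call__(self, prompt_template: str, text: str, decoding: DecodingConfig) -> str: ...


@dataclass
class ExtractionResult:
    """Per-message structured extraction with derived binary/count vectors.

    ``counts`` always equals the validated span-list lengths; ``counts_raw``
    preserves the pre-validation counts so hallucination screening is
    auditable. A message with no 4M content has all counts zero.
    """

    message_id: str
    spans: dict[MClass, list[str]] = field(default_factory=dict)
    counts_raw: dict[MClass, int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    error: bool = False
    raw: str | None = None

    def __post_init__(self) -> None:
        for c in M_CLASSES:
            self.spans.setdefault(c, [])
            self.counts_raw.setdefault(c, len(self.spans[c]))

    @property
    def counts(self) -> dict[MClass, int]:
        return {c: len(self.spans[c]) for c in M_CLASSES}

    @property
    def binary(self) -> dict[MClass, int]:
        return {c: int(len(self.spans[c]) > 0) for c in M_CLASSES}

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


def _error_result(message_id: str, raw: str, reason: str) -> ExtractionResult:
    return ExtractionResult(
        message_id=message_id,
        spans={c: [] for c in M_CLASSES},
        counts_raw={c: 0 for c in M_CLASSES},
        flags=[f"parse_error: {reason}"],
        error=True,
        raw=raw,
    )


def _canon_class(key: str) -> MClass | None:
    canon = key.strip().casefold().replace("-", "_").replace(" ", "_")
    try:
        return MClass(canon)
    except ValueError:
        return None


def parse_extraction_output(raw: str, message_id: str) -> ExtractionResult:
    """Parse one extractor's raw structured output.

    Missing classes default to empty lists; unexpected keys are flagged but
    tolerated. Anything that is not a JSON object yields an error result that
    carries the raw blob for audit, with all counts zero — the pipeline must
    survive malformed model output.
    """
    try:
        payload = json.loads(raw)
    except (json.JSONDecodeError, TypeError) as exc:
        return _error_result(message_id, raw, str(exc))
    if not isinstance(payload, dict):
        return _error_result(message_id, raw, f"expected object, got {type(payload).__name__}")
    spans: dict[MClass, list[str]] = {c: [] for c in M_CLASSES}
    flags: list[str] = []
    for key, value in payload.items():
        m_class = _canon_class(str(key))
        if m_class is None:
            flags.append(f"unexpected_key: {key}")
            continue
        if isinstance(value, str):
            value = [value]
            flags.append(f"scalar_value_coerced: {key}")
        if not isinstance(value, list):
            flags.append(f"invalid_value: {key}")
            continue
        spans[m_class].extend(str(v) for v in value if str(v).strip())
    return ExtractionResult(
        message_id=message_id,
        spans=spans,
        counts_raw={c: len(spans[c]) for c in M_CLASSES},
        flags=flags,
        raw=raw,
    )


def validate_spans(
    result: ExtractionResult, message: Message, similarity_floor: float = 0.85
) -> ExtractionResult:
    """Hallucination screen: drop spans not grounded in the message text.

    Each span is scored by the best fuzzy alignment of its normalized form
    against any substring of the normalized message text; spans scoring below
    ``similarity_floor`` are flagged ``hallucination`` and excluded from the
    counts. A floor of 1.0 requires an exact (normalized) substring; the
    default 0.85 tolerates typo variants such as "disfunction"/"dysfunction".
    """
    if result.message_id != message.message_id:
        raise ValueError(
            f"result {result.message_id!r} does not belong to message {message.message_id!r}"
        )
    if not 0.0 <= similarity_floor <= 1.0:
        raise ValueError("similarity_floor must lie in [0, 1]")
    haystack = normalize_text(message.text)
    kept: dict[MClass, list[str]] = {c: [] for c in M_CLASSES}
    flags = list(result.flags)
    for c in M_CLASSES:
        for span in result.spans[c]:
            score = fuzzy_substring_score(normalize_text(span), haystack)
            if score >= similarity_floor and score > 0.0:
                kept[c].append(span)
            else:
                flags.append(f"hallucination:{c.value}:{span}")
    return ExtractionResult(
        message_id=result.message_id,
        spans=kept,
        counts_raw=dict(result.counts_raw),
        flags=flags,
        error=result.error,
        raw=result.raw,
    )


@dataclass
class Lexicon:
    """Class-keyed phrase bank; the reference extractor's vocabulary.

    Phrases must be non-empty and unique across classes (a phrase naming two
    4M concepts would make the reference extraction ill-defined).
    """

    entries: dict[MClass, set[str]]
    match_mode: str = "exact"  # "exact" | "fuzzy"
    _index: tuple | None = field(default=None, init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: dict[str, MClass] = {}
        for c, phrases in self.entries.items():
            for p in phrases:
                norm = normalize_text(p)
                if not norm:
                    raise ValueError(f"empty lexicon phrase in class {c.value}")
                if norm in seen and seen[norm] != c:
                    raise ValueError(
                        f"phrase {p!r} assigned to both {seen[norm].value} and {c.value}"
                    )
                seen[norm] = c

    def normalized_entries(self) -> dict[MClass, list[str]]:
        return {c: sorted({normalize_text(p) for p in self.entries.get(c, set())}) for c in M_CLASSES}

    def match_index(self) -> tuple[dict[MClass, list[str]], dict[MClass, dict[str, list[list[str]]]]]:
        """Normalized phrases plus a first-token index (cached: scanning a
        message is then linear in its length, not in the lexicon size)."""
        if self._index is None:
            norm = self.normalized_entries()
            index: dict[MClass, dict[str, list[list[str]]]] = {}
            for c, phrases in norm.items():
                by_first: dict[str, list[list[str]]] = {}
                for p in phrases:
                    toks = p.split()
                    by_first.setdefault(toks[0], []).append(toks)
                for cand in by_first.values():
                    cand.sort(key=len, reverse=True)  # longest-match-first
                index[c] = by_first
            self._index = (norm, index)
        return self._index


def _match_window(window: str, phrase: str, mode: str) -> bool:
    if mode == "exact":
        return window == phrase
    return fuzzy_similarity(window, phrase) >= 0.85


def lexicon_extract(message: Message, lexicon: Lexicon) -> ExtractionResult:
    """Deterministic reference extraction: every lexicon phrase occurring in
    the message, longest-match-first and non-overlapping within a class.

    Matching is token-aligned on normalized text, so phrases never match
    inside words. Duplicate occurrences of the same phrase count separately.
    """
    tokens = normalize_text(message.text).split()
    spans: dict[MClass, list[str]] = {c: [] for c in M_CLASSES}
    normalized, index = lexicon.match_index()
    for c, phrases in normalized.items():
        if not phrases:
            continue
        by_first = index[c]
        occupied = [False] * len(tokens)
        i = 0
        while i < len(tokens):
            matched = False
            for p_toks in by_first.get(tokens[i], []):
                j = i + len(p_toks)
                if j <= len(tokens) and tokens[i:j] == p_toks and not any(occupied[i:j]):
                    spans[c].append(" ".join(p_toks))
                    occupied[i:j] = [True] * len(p_toks)
                    i = j
                    matched = True
                    break
            if not matched:
                i += 1
        if lexicon.match_mode == "fuzzy":
            # second pass: fuzzy windows for phrases missed exactly
            for p in phrases:
                p_toks = p.split()
                for i in range(len(tokens) - len(p_toks) + 1):
                    if any(occupied[i : i + len(p_toks)]):
                        continue
                    window = " ".join(tokens[i : i + len(p_toks)])
                    if window != p and _match_window(window, p, "fuzzy"):
                        spans[c].append(window)
                        occupied[i : i + len(p_toks)] = [True] * len(p_toks)
    return ExtractionResult(
        message_id=message.message_id,
        spans=spans,
        counts_raw={c: len(spans[c]) for c in M_CLASSES},
    )


class LexiconExtractor:
    """Lexicon extraction wrapped in the extractor plug-in contract: emits the
    structured JSON an LLM adapter would, so it exercises the full parse path."""

    def __init__(self, lexicon: Lexicon):
        self.lexicon = lexicon

    def __call__(self, prompt_template: str, text: str, decoding: DecodingConfig) -> str:
        msg = Message("_", "_", "_", "nursing_staff", "nursing_staff",
                      _dt.datetime(2000, 1, 1), text or "-")
        result = lexicon_extract(msg, self.lexicon)
        return json.dumps({c.value: result.spans[c] for c in M_CLASSES})


def run_extractor(
    messages: Sequence[Message],
    extractor: Extractor,
    decoding: DecodingConfig | None = None,
    prompt_template: str = DEFAULT_PROMPT_TEMPLATE,
) -> list[ExtractionResult]:
    """Run an extractor plug-in over a corpus with fault isolation: a plug-in
    failure on one message yields an error result for that message and the
    run continues. Returns one result per message, in corpus order."""
    decoding = decoding or DecodingConfig()
    results: list[ExtractionResult] = []
    failures = 0
    for m in messages:
        try:
            raw = extractor(prompt_template, m.text, decoding)
        except Exception as exc:  # fault isolation is the contract
            failures += 1
            res = _error_result(m.message_id, "", f"extractor raised: {exc}")
            res.flags.append("extractor_error")
            results.append(res)
            continue
        results.append(parse_extraction_output(raw, m.message_id))
    logger.info("ran extractor over %d messages (%d failures)", len(messages), failures)
    return results


def validate_all(
    results: Iterable[ExtractionResult],
    messages: Mapping[str, Message] | Sequence[Message],
    similarity_floor: float = 0.85,
) -> list[ExtractionResult]:
    """Apply :func:`validate_spans` to every result against its source message."""
    if not isinstance(messages, Mapping):
        messages = {m.message_id: m for m in messages}
    return [validate_spans(r, messages[r.message_id], similarity_floor) for r in results]


def write_results(results: Iterable[ExtractionResult], path) -> None:
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8") as fh:
        for r in results:
            fh.write(
                json.dumps(
                    {
                        "message_id": r.message_id,
                        "spans": {c.value: r.spans[c] for c in M_CLASSES},
                        "counts_raw": {c.value: r.counts_raw[c] for c in M_CLASSES},
                        "flags": r.flags,
                        "error": r.error,
                    }
                )
                + "\n"
            )


def load_results(path) -> list[ExtractionResult]:
    from pathlib import Path

    results = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            results.append(
                ExtractionResult(
                    message_id=rec["message_id"],
                    spans={MClass(k): list(v) for k, v in rec["spans"].items()},
                    counts_raw={MClass(k): int(v) for k, v in rec["counts_raw"].items()},
                    flags=list(rec.get("flags", [])),
                    error=bool(rec.get("error", False)),
                )
            )
    return results
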