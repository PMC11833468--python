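"""Synthetic corpus generator with full ground-truth bookkeeping.

Real nursing-home message corpora are private, so every pipeline stage is
exercised on generated data that carries the statistical structure the
pipeline assumes: short (~10-60 word) clinical messages; four expression
classes with class-imbalanced frequencies (medication-heavy); a fraction of
messages with no 4M content at all; a planted four-level cluster hierarchy
per class (level-1 cluster counts default to 8/9/4/4); transfer events with
messages placed inside or outside the 14-day pre-transfer window by design;
a sender/receiver role mix; and two simulated annotators with a controlled
disagreement rate. Everything is deterministic under the configured seed,
and the generator records exactly what it planted so downstream measurements
can be checked against ground truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np

from ._text import fuzzy_similarity, normalize_phrase
from .agreement import AnnotationSet, GoldRecord, diff_annotations
from .corpus import Message, ROLES, TransferEvent
from .extraction import M_CLASSES, ExtractionResult, Lexicon, MClass

_EPOCH = datetime(2016, 1, 1, 8, 0)

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CLASS_RATES = {
    MClass.WHAT_MATTERS: 0.25,
    MClass.MEDICATION: 0.70,   # medication dominates, as in real 4M corpora
    MClass.MENTATION: 0.20,
    MClass.MOBILITY: 0.15,
}
DEFAULT_ROLE_MIX = {
    "nursing_staff": 0.45,
    "aprn": 0.30,
    "physician": 0.10,
    "other_staff": 0.15,
}
DEFAULT_LEVEL1_COUNTS = (8, 9, 4, 4)  # what_matters, medication, mentation, mobility


@dataclass
class GeneratorConfig:
    """Study-condition knobs for the synthetic corpus; the defaults are the
    conditions every recovery and identity check runs under."""

    n_messages: int = 500
    n_residents: int = 60
    n_events: int = 90
    class_rates: dict[MClass, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_RATES))
    zero_content_fraction: float = 0.30
    level1_counts: tuple[int, int, int, int] = DEFAULT_LEVEL1_COUNTS
    branching: tuple[int, int, int] = (2, 2, 2)  # children per node at L1->L2, L2->L3, L3->L4
    phrases_per_leaf: int = 7
    embed_dim: int = 32
    noise_sigma: float = 1.0
    centroid_separation: float = 5.0  # Euclidean gap between sibling leaf centroids
    role_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ROLE_MIX))
    annotator_disagreement_rate: float = 0.10
    perturb_fraction: float = 0.0  # share of disagreements that are typo variants, not drops
    linked_fraction: float = 0.70  # messages intentionally inside a transfer window
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.role_mix.values()) - 1.0) > 1e-9:
            raise ValueError("role_mix probabilities must sum to 1")
        if not 0.0 <= self.zero_content_fraction <= 1.0:
            raise ValueError("zero_content_fraction must lie in [0, 1]")
        if self.noise_sigma <= 0 or self.centroid_separation <= 0:
            raise ValueError("noise_sigma and centroid_separation must be positive")
        if any(b < 1 for b in self.branching):
            raise ValueError("branching factors must be >= 1")
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")
        if not 0.0 <= self.annotator_disagreement_rate <= 0.5:
            raise ValueError("annotator_disagreement_rate must lie in [0, 0.5]")


# ---------------------------------------------------------------------------
# Vocabulary: the planted four-level phrase hierarchy
# ---------------------------------------------------------------------------

_TOPICS: dict[MClass, list[str]] = {
    MClass.WHAT_MATTERS: ["comfort", "hospice", "wishes", "goals", "preference",
                          "chaplain", "dignity", "visitation", "advance", "legacy"],
    MClass.MEDICATION: ["insulin", "warfarin", "lasix", "morphine", "antibiotic",
                        "lisinopril", "seroquel", "potassium", "tylenol", "eliquis",
                        "metoprolol"],
    MClass.MENTATION: ["confusion", "delirium", "agitation", "memory", "orientation",
                       "mood"],
    MClass.MOBILITY: ["gait", "ambulation", "walker", "balance", "wheelchair",
                      "bedrest"],
}
_BANK2 = ["morning", "evening", "weekly", "daily", "overnight", "routine", "urgent",
          "bedside"]
_BANK3 = ["dose", "pattern", "review", "response", "level", "trend", "note", "plan"]
_BANK4 = ["increase", "decrease", "hold", "resume", "watch", "adjust", "report",
          "verify"]
_VARIANTS = ["pending", "today", "tomorrow", "ongoing", "repeated", "initial",
             "final", "updated", "confirmed", "noted", "charted", "flagged"]

_FILLERS = [
    "please see the note in the chart",
    "thank you for the update",
    "will follow up with the on call provider",
    "received and acknowledged",
    "can you confirm the room number",
    "the lab results were faxed this afternoon",
    "no new orders at this time",
    "please call the front desk when available",
    "the paperwork was sent over yesterday",
    "copy that i will let the team know",
    "reminder that the care conference is on thursday",
    "the supply order arrived this morning",
    "see previous message for details",
    "charge nurse has been notified",
    "appointment was rescheduled for next week",
]


def _extend_bank(bank: list[str], needed: int, stem: str) -> list[str]:
    out = list(bank)
    i = 1
    while len(out) < needed:
        out.append(f"{stem}{i}")
        i += 1
    return out


@dataclass
class Leaf:
    """One planted leaf cluster: its hierarchy path and member phrases."""

    m_class: MClass
    leaf_id: int
    path: tuple[int, int, int, int]  # cluster index at levels 1..4
    phrases: list[str]


@dataclass
class Vocabulary:
    """Planted hierarchy + phrase bank; doubles as the reference lexicon."""

    leaves: dict[MClass, list[Leaf]]
    phrase_info: dict[str, tuple[MClass, int, tuple[int, int, int, int]]]

    @property
    def lexicon(self) -> Lexicon:
        return Lexicon(
            entries={c: {p for leaf in self.leaves[c] for p in leaf.phrases}
                     for c in M_CLASSES}
        )

    def phrases_of_class(self, m_class: MClass) -> list[str]:
        return [p for leaf in self.leaves[m_class] for p in leaf.phrases]

    def level_labels(self, m_class: MClass, level: int) -> dict[str, int]:
        """Ground-truth cluster id per phrase at one hierarchy level (1..4),
        encoded as the rank of the path prefix."""
        prefixes = sorted({leaf.path[:level] for leaf in self.leaves[m_class]})
        rank = {p: i for i, p in enumerate(prefixes)}
        return {
            phrase: rank[leaf.path[:level]]
            for leaf in self.leaves[m_class]
            for phrase in leaf.phrases
        }


def make_vocabulary(config: GeneratorConfig) -> Vocabulary:
    """Deterministic phrase bank with the configured hierarchy shape.

    A phrase is ``"<topic> <time> <aspect> <action> <variant>"``; the topic
    word is unique to its level-1 cluster and class, so phrases never collide
    across classes, and the filler bank is vetted to contain none of them.
    """
    b1, b2, b3 = config.branching
    bank2 = _extend_bank(_BANK2, b1, "slot")
    bank3 = _extend_bank(_BANK3, b2, "facet")
    bank4 = _extend_bank(_BANK4, b3, "step")
    variants = _extend_bank(_VARIANTS, config.phrases_per_leaf, "item")
    leaves: dict[MClass, list[Leaf]] = {c: [] for c in M_CLASSES}
    phrase_info: dict[str, tuple[MClass, int, tuple[int, int, int, int]]] = {}
    for c, l1_count in zip(M_CLASSES, config.level1_counts):
        topics = _extend_bank(_TOPICS[c], l1_count, f"{c.value.replace('_', '')}topic")
        leaf_id = 0
        for i1 in range(l1_count):
            for i2 in range(b1):
                for i3 in range(b2):
                    for i4 in range(b3):
                        phrases = [
                            f"{topics[i1]} {bank2[i2]} {bank3[i3]} {bank4[i4]} {variants[v]}"
                            for v in range(config.phrases_per_leaf)
                        ]
                        # global L2/L3/L4 indices within the class
                        path = (i1, i1 * b1 + i2, (i1 * b1 + i2) * b2 + i3,
                                ((i1 * b1 + i2) * b2 + i3) * b3 + i4)
                        leaf = Leaf(c, leaf_id, path, phrases)
                        leaves[c].append(leaf)
                        for p in phrases:
                            norm = normalize_phrase(p)
                            if norm in phrase_info:
                                raise RuntimeError(f"vocabulary collision for {p!r}")
                            phrase_info[norm] = (c, leaf_id, path)
                        leaf_id += 1
    vocab = Vocabulary(leaves, phrase_info)
    # vet the filler bank: no filler may contain a planted phrase
    for filler in _FILLERS:
        for norm in phrase_info:
            if norm in normalize_phrase(filler):
                raise RuntimeError(f"filler {filler!r} collides with planted phrase")
    return vocab


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything the generator planted, for consumer-side verification."""

    message_spans: dict[str, list[tuple[str, MClass, int]]]  # msg -> (phrase, class, leaf)
    intended_links: dict[str, list[str]]  # event_id -> message_ids
    role_tally: dict[str, int]  # sender role -> planted expression count
    class_totals: dict[MClass, int]

    def gold_records(self) -> list[GoldRecord]:
        """The planted spans as a reconciled gold standard (provenance 'both')."""
        gold = []
        for message_id in sorted(self.message_spans):
            spans: dict[MClass, list[str]] = {c: [] for c in M_CLASSES}
            for phrase, c, _leaf in self.message_spans[message_id]:
                spans[c].append(phrase)
            gold.append(
                GoldRecord(message_id, spans,
                           {c: ["both"] * len(spans[c]) for c in M_CLASSES})
            )
        return gold

    def save(self, path: str | Path) -> None:
        import json

        with Path(path).open("w", encoding="utf-8") as fh:
            for message_id in sorted(self.message_spans):
                fh.write(json.dumps({
                    "message_id": message_id,
                    "spans": [
                        {"phrase": p, "class": c.value, "leaf": leaf}
                        for p, c, leaf in self.message_spans[message_id]
                    ],
                }) + "\n")


@dataclass
class SyntheticCorpus:
    config: GeneratorConfig
    vocabulary: Vocabulary
    messages: list[Message]
    events: list[TransferEvent]
    truth: GroundTruth

    @property
    def lexicon(self) -> Lexicon:
        return self.vocabulary.lexicon


def _draw_role(rng: np.random.Generator, mix: dict[str, float]) -> str:
    roles = sorted(mix)
    return str(rng.choice(roles, p=[mix[r] for r in roles]))


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate messages, transfer events, and the intended link table.

    Every planted phrase appears verbatim in its message text; a configured
    fraction of messages carries no 4M content; message timestamps are placed
    inside or outside the 14-day pre-transfer window by design, and events of
    one resident are spaced > 6 weeks apart so the intended link table is
    unambiguous.
    """
    rng = np.random.default_rng(config.seed)
    vocab = make_vocabulary(config)
    residents = [f"r{i:04d}" for i in range(config.n_residents)]
    facility = {r: f"nh{(i % 12):02d}" for i, r in enumerate(residents)}

    events: list[TransferEvent] = []
    events_by_resident: dict[str, list[TransferEvent]] = {r: [] for r in residents}
    for j in range(config.n_events):
        r = residents[int(rng.integers(config.n_residents))]
        k = len(events_by_resident[r])
        t = (_EPOCH + timedelta(days=45 * k + int(rng.integers(0, 20)),
                                minutes=int(rng.integers(0, 24 * 60))))
        e = TransferEvent(f"e{j:04d}", r, t.replace(second=0, microsecond=0))
        events.append(e)
        events_by_resident[r].append(e)

    classes = list(M_CLASSES)
    rates = np.array([config.class_rates[c] for c in classes])
    messages: list[Message] = []
    message_spans: dict[str, list[tuple[str, MClass, int]]] = {}
    intended: dict[str, list[str]] = {e.event_id: [] for e in events}
    role_tally = {r: 0 for r in ROLES}
    class_totals = {c: 0 for c in M_CLASSES}
    window = timedelta(days=14)

    for i in range(config.n_messages):
        message_id = f"m{i:05d}"
        r = residents[int(rng.integers(config.n_residents))]
        sender = _draw_role(rng, config.role_mix)
        receiver = _draw_role(rng, config.role_mix)

        # timestamp and intended linkage
        r_events = events_by_resident[r]
        linked_event: TransferEvent | None = None
        if r_events and rng.random() < config.linked_fraction:
            linked_event = r_events[int(rng.integers(len(r_events)))]
            offset = int(rng.integers(0, 14 * 24 * 60))  # minutes before transfer
            ts = linked_event.transfer_time - timedelta(minutes=offset)
        else:
            for _attempt in range(20):
                ts = _EPOCH + timedelta(days=int(rng.integers(0, 700)),
                                        minutes=int(rng.integers(0, 24 * 60)))
                if all(not (e.transfer_time - window < ts <= e.transfer_time)
                       for e in r_events):
                    break
            else:
                ts = _EPOCH - timedelta(days=100 + i)
        ts = ts.replace(second=0, microsecond=0)
        for e in r_events:
            if e.transfer_time - window < ts <= e.transfer_time:
                intended[e.event_id].append(message_id)

        # planted content
        spans: list[tuple[str, MClass, int]] = []
        if rng.random() >= config.zero_content_fraction:
            counts = rng.poisson(rates)
            if counts.sum() == 0:
                c_forced = rng.choice(len(classes), p=rates / rates.sum())
                counts[c_forced] = 1
            for ci, c in enumerate(classes):
                for _ in range(int(counts[ci])):
                    # avoid planting two distinct-but-fuzzily-identical phrases
                    # of one class in one message: annotator reconciliation
                    # could not tell them apart (exact repeats are fine)
                    chosen = [normalize_phrase(p) for p, cc, _ in spans if cc == c]
                    for _attempt in range(20):
                        leaf = vocab.leaves[c][int(rng.integers(len(vocab.leaves[c])))]
                        phrase = leaf.phrases[int(rng.integers(len(leaf.phrases)))]
                        norm = normalize_phrase(phrase)
                        if all(p == norm or fuzzy_similarity(p, norm) < 0.80
                               for p in chosen):
                            break
                    else:
                        # exhausted: repeat an already chosen phrase exactly
                        spans.append(next(s for s in spans if s[1] == c))
                        continue
                    spans.append((phrase, c, leaf.leaf_id))

        filler = _FILLERS[int(rng.integers(len(_FILLERS)))]
        parts = [filler] + [p for p, _, _ in spans]
        if len(parts) == 1 and rng.random() < 0.5:
            parts.append(_FILLERS[int(rng.integers(len(_FILLERS)))])
        text = ". ".join(parts)

        messages.append(Message(message_id, r, facility[r], sender, receiver, ts, text))
        message_spans[message_id] = spans
        role_tally[sender] += len(spans)
        for _, c, _leaf in spans:
            class_totals[c] += 1

    truth = GroundTruth(message_spans, intended, role_tally, class_totals)
    return SyntheticCorpus(config, vocab, messages, events, truth)


# ---------------------------------------------------------------------------
# Synthetic embedder
# ---------------------------------------------------------------------------

def _hash_seed(seed: int, text: str) -> int:
    digest = hashlib.sha256(f"{seed}:{text}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


def _sibling_directions(rng: np.random.Generator, k: int, dim: int) -> np.ndarray:
    """k approximately maximally separated unit directions (orthonormal via QR
    when k <= dim, random unit vectors otherwise)."""
    if k <= dim:
        A = rng.normal(size=(dim, k))
        Q, _ = np.linalg.qr(A)
        return Q[:, :k].T
    V = rng.normal(size=(k, dim))
    return V / np.linalg.norm(V, axis=1, keepdims=True)


class SyntheticEmbedder:
    """Deterministic stand-in for a sentence embedder.

    Each planted phrase maps to its leaf-cluster centroid plus isotropic
    Gaussian noise with total standard deviation ``noise_sigma`` (noise keyed
    by phrase hash and seed, so identical texts embed identically). Centroids
    are laid out recursively from the origin: sibling offsets at hierarchy
    level ℓ have magnitude ``centroid_separation * 1.4^(4-ℓ)`` along mutually
    orthogonal directions. The gentle decay keeps both geometries the
    pipeline relies on: Euclidean distances grow with how high in the
    hierarchy two expressions split (Ward recovers the planted levels), and
    cosine similarity tracks shared ancestry (same-leaf phrases sit above the
    0.95 dedup threshold, anything that splits at level 3 or higher sits
    well below it). Unplanted text maps to a deterministic pseudo-random
    unit vector.
    """

    _LEVEL_RATIO = 1.4

    def __init__(self, config: GeneratorConfig, vocabulary: Vocabulary):
        self.config = config
        self.vocabulary = vocabulary
        self.dim = config.embed_dim
        sep = config.centroid_separation
        rng = np.random.default_rng(_hash_seed(config.seed, "embedder-centroids"))
        self._leaf_centroids: dict[tuple[MClass, int], np.ndarray] = {}
        for c in M_CLASSES:
            # classes share the origin: per-class hierarchies live in nearly
            # orthogonal random subspaces, and clustering is per class anyway
            centers: dict[tuple[int, ...], np.ndarray] = {(): np.zeros(self.dim)}
            for level in range(1, 5):
                prefixes = sorted({leaf.path[:level] for leaf in vocabulary.leaves[c]})
                by_parent: dict[tuple[int, ...], list[tuple[int, ...]]] = {}
                for p in prefixes:
                    by_parent.setdefault(p[:-1] if level > 1 else (), []).append(p)
                for parent, children in sorted(by_parent.items()):
                    dirs = _sibling_directions(rng, len(children), self.dim)
                    off = sep * self._LEVEL_RATIO ** (4 - level)
                    for d, child in zip(dirs, children):
                        centers[child] = centers[parent] + d * off
            for leaf in vocabulary.leaves[c]:
                self._leaf_centroids[(c, leaf.leaf_id)] = centers[leaf.path]
        self._cache: dict[str, np.ndarray] = {}

    def __call__(self, text: str) -> np.ndarray:
        norm = normalize_phrase(text)
        if norm in self._cache:
            return self._cache[norm]
        info = self.vocabulary.phrase_info.get(norm)
        rng = np.random.default_rng(_hash_seed(self.config.seed, norm))
        if info is not None:
            c, leaf_id, _path = info
            noise = rng.normal(0.0, self.config.noise_sigma / np.sqrt(self.dim), self.dim)
            v = self._leaf_centroids[(c, leaf_id)] + noise
        else:
            v = rng.normal(size=self.dim)
            v = v / np.linalg.norm(v)
        self._cache[norm] = v
        return v


def synthetic_embedder(config: GeneratorConfig, vocabulary: Vocabulary | None = None) -> SyntheticEmbedder:
    return SyntheticEmbedder(config, vocabulary or make_vocabulary(config))


# ---------------------------------------------------------------------------
# Annotator simulation and extractor corruption
# ---------------------------------------------------------------------------

def _typo(phrase: str, rng: np.random.Generator) -> str:
    if len(phrase) < 4:
        return phrase + "x"
    i = int(rng.integers(1, len(phrase) - 1))
    return phrase[:i] + phrase[i + 1 :]


def simulate_annotators(
    truth: GroundTruth,
    disagreement_rate: float,
    seed: int,
    perturb_fraction: float = 0.0,
) -> tuple[AnnotationSet, AnnotationSet, dict[tuple[str, str, str], str]]:
    """Two annotators derived from the planted spans plus the adjudications
    that restore them.

    Each annotator independently disagrees on a span with the given rate
    (dropping it, or — for a ``perturb_fraction`` share — recording a typo
    variant instead). The both-drop event is resampled so that at least one
    annotator always retains every planted span; truth-derived adjudications
    then reproduce the planted gold counts exactly.
    """
    if not 0.0 <= disagreement_rate <= 0.5:
        raise ValueError("disagreement_rate must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    rec_a: dict[str, dict[MClass, list[str]]] = {}
    rec_b: dict[str, dict[MClass, list[str]]] = {}
    for message_id in sorted(truth.message_spans):
        a_rec = rec_a.setdefault(message_id, {c: [] for c in M_CLASSES})
        b_rec = rec_b.setdefault(message_id, {c: [] for c in M_CLASSES})
        for phrase, c, _leaf in truth.message_spans[message_id]:
            while True:
                a_dis = rng.random() < disagreement_rate
                b_dis = rng.random() < disagreement_rate
                a_drop = a_dis and rng.random() >= perturb_fraction
                b_drop = b_dis and rng.random() >= perturb_fraction
                if not (a_drop and b_drop):
                    break
            if not a_drop:
                a_rec[c].append(_typo(phrase, rng) if a_dis else phrase)
            if not b_drop:
                b_rec[c].append(_typo(phrase, rng) if b_dis else phrase)
    a = AnnotationSet("A", rec_a)
    b = AnnotationSet("B", rec_b)
    adjudications = true_adjudications(truth, a, b)
    return a, b, adjudications


def true_adjudications(
    truth: GroundTruth, a: AnnotationSet, b: AnnotationSet
) -> dict[tuple[str, str, str], str]:
    """Adjudicate every A/B difference against the planted spans: accept a
    difference iff its phrase (fuzzily) corresponds to a planted span."""
    from ._text import fuzzy_similarity

    report = diff_annotations(a, b)
    decisions: dict[tuple[str, str, str], str] = {}
    for d in report.items:
        planted = [
            normalize_phrase(p)
            for p, c, _leaf in truth.message_spans.get(d.message_id, [])
            if c == d.m_class
        ]
        norm = normalize_phrase(d.phrase)
        ok = any(fuzzy_similarity(norm, p) >= 0.85 for p in planted)
        decisions[d.key()] = "accept" if ok else "reject"
    return decisions


def corrupt_results(
    results: Sequence[ExtractionResult],
    vocabulary: Vocabulary,
    seed: int,
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    message_ids: Sequence[str] | None = None,
) -> list[ExtractionResult]:
    """Plant extractor errors into (validated) results.

    Rate mode: per message × class, a present class is wiped with probability
    ``fn_rate`` (false negative) and an absent class gains one spurious
    vocabulary phrase with probability ``fp_rate`` (false positive).
    Targeted mode (``message_ids``): each listed message is changed exactly
    once — its first span is dropped, or a spurious span is added if it had
    none — so the number of discrepant messages is exact by construction.
    """
    rng = np.random.default_rng(seed)
    targeted = set(message_ids) if message_ids is not None else None
    out: list[ExtractionResult] = []
    for r in results:
        spans = {c: list(r.spans[c]) for c in M_CLASSES}
        flags = list(r.flags)
        if targeted is not None:
            if r.message_id in targeted:
                for c in M_CLASSES:
                    if spans[c]:
                        spans[c] = spans[c][1:]
                        break
                else:
                    c = M_CLASSES[int(rng.integers(len(M_CLASSES)))]
                    phrases = vocabulary.phrases_of_class(c)
                    spans[c].append(phrases[int(rng.integers(len(phrases)))])
                flags.append("planted_discrepancy")
        else:
            for c in M_CLASSES:
                if spans[c]:
                    if rng.random() < fn_rate:
                        spans[c] = []
                        flags.append(f"planted_fn:{c.value}")
                elif rng.random() < fp_rate:
                    phrases = vocabulary.phrases_of_class(c)
                    spans[c].append(phrases[int(rng.integers(len(phrases)))])
                    flags.append(f"planted_fp:{c.value}")
        out.append(
            ExtractionResult(r.message_id, spans,
                             {c: len(spans[c]) for c in M_CLASSES}, flags)
        )
    return out


def analytic_kappa(prevalence: float, fp_rate: float, fn_rate: float) -> float:
    """Cohen's κ implied by planting binary errors at the given rates on gold
    with the given prevalence (closed form from the expected 2×2 table)."""
    pi = prevalence
    p11 = pi * (1.0 - fn_rate)
    p01 = (1.0 - pi) * fp_rate
    p00 = (1.0 - pi) * (1.0 - fp_rate)
    p_o = p11 + p00
    pred1 = p11 + p01
    p_e = pred1 * pi + (1.0 - pred1) * (1.0 - pi)
    if abs(1.0 - p_e) < 1e-12:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)
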