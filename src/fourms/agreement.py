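"""Dual-annotator reconciliation, the extraction metric battery, the
performance gate, and preference-pair construction.

Evaluation follows the two-representation design used for span-extraction
studies of clinical messages: each message × class is scored both as a binary
presence decision (recall, F1, ROC AUC, Cohen's κ) and as an expression count
(Spearman ρ with midrank ties, Cohen's κ on binned counts, MAE). Cohen's κ is
the headline statistic with a κ ≥ 0.60 acceptance gate ("moderate"
agreement). Disagreements between the extractor and the reconciled gold
standard become chosen/rejected preference pairs, the input file of
preference-optimization fine-tuning (e.g. ORPO) — the training itself is out
of scope here.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from ._text import fuzzy_similarity, normalize_phrase
from .corpus import Message
from .extraction import M_CLASSES, ExtractionResult, MClass

#: Default count bins for the binned κ: {0}, {1}, {2}, {3+}.
DEFAULT_BINS: tuple[int, ...] = (0, 1, 2, 3)
#: Agreement gate: κ at or above this is "moderate" agreement, accepted.
KAPPA_GATE = 0.60
#: Two annotator phrases at or above this fuzzy similarity are the same phrase.
PHRASE_MATCH_FLOOR = 0.85


# ---------------------------------------------------------------------------
# Annotations, differences, reconciliation
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSet:
    """One annotator's per-message, per-class phrase lists."""

    annotator_id: str
    records: dict[str, dict[MClass, list[str]]]

    def spans(self, message_id: str, m_class: MClass) -> list[str]:
        return self.records.get(message_id, {}).get(m_class, [])


@dataclass
class Difference:
    """A (message, class, phrase) present in exactly one annotator's set."""

    message_id: str
    m_class: MClass
    phrase: str
    side: str  # "A" | "B"

    def key(self) -> tuple[str, str, str]:
        return (self.message_id, self.m_class.value, normalize_phrase(self.phrase))


@dataclass
class DiffReport:
    per_class: dict[MClass, int]
    items: list[Difference]


@dataclass
class GoldRecord:
    """Reconciled per-message expression lists; zero counts are meaningful
    (a message without 4M content is recorded as zero, not missing)."""

    message_id: str
    spans: dict[MClass, list[str]]
    provenance: dict[MClass, list[str]]  # per-phrase: both | A_only_accepted | B_only_accepted

    @property
    def counts(self) -> dict[MClass, int]:
        return {c: len(self.spans[c]) for c in M_CLASSES}

    @property
    def binary(self) -> dict[MClass, int]:
        return {c: int(len(self.spans[c]) > 0) for c in M_CLASSES}


def _match_phrases(
    a_phrases: Sequence[str], b_phrases: Sequence[str]
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy best-first matching of two phrase lists under normalized fuzzy
    similarity ≥ PHRASE_MATCH_FLOOR. Returns (pairs, unmatched_a, unmatched_b)."""
    norm_a = [normalize_phrase(p) for p in a_phrases]
    norm_b = [normalize_phrase(p) for p in b_phrases]
    scored = []
    for i, na in enumerate(norm_a):
        for j, nb in enumerate(norm_b):
            s = fuzzy_similarity(na, nb)
            if s >= PHRASE_MATCH_FLOOR:
                scored.append((s, i, j))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for s, i, j in scored:
        if i not in used_a and j not in used_b:
            pairs.append((i, j))
            used_a.add(i)
            used_b.add(j)
    return (
        pairs,
        [i for i in range(len(a_phrases)) if i not in used_a],
        [j for j in range(len(b_phrases)) if j not in used_b],
    )


def diff_annotations(a: AnnotationSet, b: AnnotationSet) -> DiffReport:
    """List every (message, class, phrase) present in exactly one annotator's
    set under normalized fuzzy phrase matching — the adjudication worklist."""
    per_class = {c: 0 for c in M_CLASSES}
    items: list[Difference] = []
    for message_id in sorted(set(a.records) | set(b.records)):
        for c in M_CLASSES:
            _, only_a, only_b = _match_phrases(a.spans(message_id, c), b.spans(message_id, c))
            for i in only_a:
                items.append(Difference(message_id, c, a.spans(message_id, c)[i], "A"))
            for j in only_b:
                items.append(Difference(message_id, c, b.spans(message_id, c)[j], "B"))
            per_class[c] += len(only_a) + len(only_b)
    return DiffReport(per_class, items)


def reconcile(
    a: AnnotationSet,
    b: AnnotationSet,
    adjudications: Mapping[tuple[str, str, str], str],
) -> list[GoldRecord]:
    """Build the gold standard: phrases both annotators agree on, plus the
    adjudicated-accept side of every difference.

    ``adjudications`` maps a difference key ``(message_id, class value,
    normalized phrase)`` to ``"accept"`` or ``"reject"``; every difference
    must be adjudicated or reconciliation aborts listing the missing items.
    """
    report = diff_annotations(a, b)
    missing = [d for d in report.items if d.key() not in adjudications]
    if missing:
        listing = ", ".join(f"{d.message_id}/{d.m_class.value}/{d.phrase}" for d in missing[:10])
        raise ValueError(f"{len(missing)} unadjudicated difference(s): {listing}")
    accepted: dict[tuple[str, MClass], list[tuple[str, str]]] = {}
    for d in report.items:
        if adjudications[d.key()] == "accept":
            tag = "A_only_accepted" if d.side == "A" else "B_only_accepted"
            accepted.setdefault((d.message_id, d.m_class), []).append((d.phrase, tag))
    gold: list[GoldRecord] = []
    for message_id in sorted(set(a.records) | set(b.records)):
        spans: dict[MClass, list[str]] = {c: [] for c in M_CLASSES}
        prov: dict[MClass, list[str]] = {c: [] for c in M_CLASSES}
        for c in M_CLASSES:
            a_list = a.spans(message_id, c)
            pairs, _, _ = _match_phrases(a_list, b.spans(message_id, c))
            for i, _j in sorted(pairs):
                spans[c].append(a_list[i])  # annotator A's wording is canonical
                prov[c].append("both")
            for phrase, tag in accepted.get((message_id, c), []):
                spans[c].append(phrase)
                prov[c].append(tag)
        gold.append(GoldRecord(message_id, spans, prov))
    return gold


def load_annotations(path: str | Path) -> dict[str, AnnotationSet]:
    """Read a delimited annotation file (annotator_id, message_id, class, phrase)."""
    sets: dict[str, AnnotationSet] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            s = sets.setdefault(row["annotator_id"], AnnotationSet(row["annotator_id"], {}))
            rec = s.records.setdefault(row["message_id"], {c: [] for c in M_CLASSES})
            if row["class"]:  # blank class = sentinel for a no-content message
                rec[MClass(row["class"])].append(row["phrase"])
    return sets


def write_annotations(sets: Iterable[AnnotationSet], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["annotator_id", "message_id", "class", "phrase"])
        for s in sets:
            for message_id in sorted(s.records):
                rows = [
                    (c.value, phrase)
                    for c in M_CLASSES
                    for phrase in s.records[message_id].get(c, [])
                ]
                # keep messages without any expression in the universe
                for class_value, phrase in rows or [("", "")]:
                    writer.writerow([s.annotator_id, message_id, class_value, phrase])


# ---------------------------------------------------------------------------
# Metric battery
# ---------------------------------------------------------------------------

def _categorical_kappa(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Cohen's κ on categorical labels; returns (kappa, degenerate_flag).

    κ = (p_o − p_e)/(1 − p_e) with p_e from the marginal products. When the
    chance agreement p_e is 1 (both raters constant) κ is undefined; the
    convention here is 1.0 for perfect agreement, 0.0 otherwise, flagged.
    """
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValueError("empty vectors")
    labels = np.unique(np.concatenate([x, y]))
    lx = np.searchsorted(labels, x)
    ly = np.searchsorted(labels, y)
    k = len(labels)
    table = np.zeros((k, k))
    np.add.at(table, (lx, ly), 1.0)
    n = x.size
    p_o = np.trace(table) / n
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if abs(1.0 - p_e) < 1e-12:
        return (1.0 if p_o == 1.0 else 0.0), True
    return float((p_o - p_e) / (1.0 - p_e)), False


def cohen_kappa(x: Sequence[int], y: Sequence[int]) -> float:
    """Chance-corrected agreement of two label vectors (binary or categorical)."""
    kappa, degenerate = _categorical_kappa(np.asarray(x), np.asarray(y))
    if degenerate:
        warnings.warn("degenerate kappa: chance agreement is 1", stacklevel=2)
    return kappa


def binary_metrics(
    pred: Sequence[int], gold: Sequence[int], scores: Sequence[float] | None = None
) -> dict[str, float | None]:
    """Binary presence metrics: recall, F1, ROC AUC, κ, plus accuracy and
    precision as supplementary values.

    ``scores`` is the ranking score for AUC (midrank ties); it defaults to
    ``pred`` itself. AUC is reported as ``None`` when the gold vector is
    single-class (undefined).
    """
    pred = np.asarray(pred, dtype=int)
    gold = np.asarray(gold, dtype=int)
    if pred.shape != gold.shape:
        raise ValueError("length mismatch between pred and gold")
    tp = int(np.sum((pred == 1) & (gold == 1)))
    fp = int(np.sum((pred == 1) & (gold == 0)))
    fn = int(np.sum((pred == 0) & (gold == 1)))
    tn = int(np.sum((pred == 0) & (gold == 0)))
    recall = tp / (tp + fn) if tp + fn else None
    precision = tp / (tp + fp) if tp + fp else None
    f1 = (
        2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else None
    )
    kappa, _ = _categorical_kappa(pred, gold)
    if gold.min() == gold.max():
        auc = None
    else:
        auc = float(roc_auc_score(gold, np.asarray(scores if scores is not None else pred, dtype=float)))
    return {
        "recall": recall,
        "f1": f1,
        "auc": auc,
        "kappa": kappa,
        "accuracy": (tp + tn) / pred.size,
        "precision": precision,
    }


def bin_counts(counts: Sequence[int], bins: Sequence[int] = DEFAULT_BINS) -> np.ndarray:
    """Map non-negative counts to ordinal bin labels; ``bins`` holds the left
    edge of each bin (last bin open-ended). Default: {0},{1},{2},{3+}."""
    edges = np.asarray(bins)
    if edges[0] != 0 or np.any(np.diff(edges) <= 0):
        raise ValueError("bins must start at 0 and strictly increase")
    return np.searchsorted(edges, np.asarray(counts, dtype=int), side="right") - 1


def count_metrics(
    pred_counts: Sequence[int],
    gold_counts: Sequence[int],
    bins: Sequence[int] = DEFAULT_BINS,
) -> dict[str, float | None]:
    """Count-level metrics: Spearman ρ (midrank ties), κ on binned counts, MAE.

    Spearman is ``None`` when either vector is constant (undefined).
    """
    pred = np.asarray(pred_counts, dtype=int)
    gold = np.asarray(gold_counts, dtype=int)
    if pred.shape != gold.shape:
        raise ValueError("length mismatch between pred and gold counts")
    if pred.min() == pred.max() or gold.min() == gold.max():
        rho = None
    else:
        rho = float(stats.spearmanr(pred, gold).statistic)
    kappa_binned, _ = _categorical_kappa(bin_counts(pred, bins), bin_counts(gold, bins))
    mae = float(np.mean(np.abs(pred - gold)))
    return {"spearman_rho": rho, "kappa_binned": kappa_binned, "mae": mae}


@dataclass
class MetricReport:
    """Per-class metric battery plus pooled agreement and the κ ≥ 0.60 gate."""

    per_class: dict[MClass, dict[str, float | None]]
    overall_kappa: float
    macro_kappa: float
    n_messages: int
    kappa_gate: float = KAPPA_GATE
    bins: tuple[int, ...] = DEFAULT_BINS
    warnings: list[str] = field(default_factory=list)

    @property
    def per_class_gate(self) -> dict[MClass, bool]:
        return {c: (self.per_class[c]["kappa"] or 0.0) >= self.kappa_gate for c in M_CLASSES}

    @property
    def passes_gate(self) -> bool:
        """True when the pooled κ and every per-class κ clear the gate."""
        return self.overall_kappa >= self.kappa_gate and all(self.per_class_gate.values())

    def to_frame(self) -> pd.DataFrame:
        """Human-readable table: metric rows × class columns."""
        rows = ["recall", "f1", "auc", "kappa", "spearman_rho", "kappa_binned", "mae",
                "accuracy", "precision"]
        data = {c.value: [self.per_class[c].get(r) for r in rows] for c in M_CLASSES}
        return pd.DataFrame(data, index=rows)

    def to_dict(self) -> dict:
        return {
            "per_class": {c.value: self.per_class[c] for c in M_CLASSES},
            "overall_kappa": self.overall_kappa,
            "macro_kappa": self.macro_kappa,
            "n_messages": self.n_messages,
            "kappa_gate": self.kappa_gate,
            "bins": list(self.bins),
            "passes_gate": self.passes_gate,
            "warnings": self.warnings,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate(
    results: Iterable[ExtractionResult],
    gold: Sequence[GoldRecord],
    bins: Sequence[int] = DEFAULT_BINS,
    kappa_gate: float = KAPPA_GATE,
) -> MetricReport:
    """Score extractor output against the gold standard over the gold message
    set.

    The pooled ("overall") κ is micro-pooled: one binary decision per
    message × class, flattened across the four classes; the macro average of
    per-class κ is reported alongside for transparency. AUC ranks messages by
    the validated count (higher count = stronger evidence of presence).
    """
    by_id = {r.message_id: r for r in results}
    missing = [g.message_id for g in gold if g.message_id not in by_id]
    if missing:
        raise ValueError(f"no extraction result for gold message(s): {missing[:5]}")
    order = sorted(g.message_id for g in gold)
    gold_by_id = {g.message_id: g for g in gold}
    per_class: dict[MClass, dict[str, float | None]] = {}
    warn: list[str] = []
    pooled_pred: list[int] = []
    pooled_gold: list[int] = []
    kappas: list[float] = []
    for c in M_CLASSES:
        pred_bin = [by_id[i].binary[c] for i in order]
        gold_bin = [gold_by_id[i].binary[c] for i in order]
        pred_cnt = [by_id[i].counts[c] for i in order]
        gold_cnt = [gold_by_id[i].counts[c] for i in order]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            metrics = binary_metrics(pred_bin, gold_bin, scores=pred_cnt)
            metrics.update(count_metrics(pred_cnt, gold_cnt, bins))
        warn.extend(f"{c.value}: {w.message}" for w in caught)
        if metrics["auc"] is None:
            warn.append(f"{c.value}: auc undefined (gold single-class)")
        per_class[c] = metrics
        pooled_pred.extend(pred_bin)
        pooled_gold.extend(gold_bin)
        kappas.append(metrics["kappa"])
    overall, degenerate = _categorical_kappa(np.asarray(pooled_pred), np.asarray(pooled_gold))
    if degenerate:
        warn.append("overall: degenerate pooled kappa")
    return MetricReport(
        per_class=per_class,
        overall_kappa=overall,
        macro_kappa=float(np.mean(kappas)),
        n_messages=len(order),
        kappa_gate=kappa_gate,
        bins=tuple(bins),
        warnings=warn,
    )


# ---------------------------------------------------------------------------
# Preference pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreferencePair:
    """One chosen/rejected training example for preference optimization."""

    prompt: str
    chosen: str
    rejected: str
    message_id: str


def render_structured(spans: Mapping[MClass, Sequence[str]]) -> str:
    """Canonical structured-output rendering shared by gold and extractor
    sides, so pairs are format-consistent."""
    return json.dumps({c.value: list(spans.get(c, [])) for c in M_CLASSES})


def _normalized_spans(spans: Mapping[MClass, Sequence[str]]) -> dict[str, list[str]]:
    return {c.value: sorted(normalize_phrase(p) for p in spans.get(c, [])) for c in M_CLASSES}


def build_preference_pairs(
    results: Iterable[ExtractionResult],
    gold: Sequence[GoldRecord],
    messages: Mapping[str, Message] | Sequence[Message],
    prompt_template: str,
) -> list[PreferencePair]:
    """Emit one chosen/rejected pair per gold message where the (validated)
    extractor output differs from the gold spans; exact agreement emits none.
    The chosen side is the gold record rendered through the same structured
    schema the extractor uses."""
    if not isinstance(messages, Mapping):
        messages = {m.message_id: m for m in messages}
    by_id = {r.message_id: r for r in results}
    pairs: list[PreferencePair] = []
    for g in sorted(gold, key=lambda g: g.message_id):
        r = by_id.get(g.message_id)
        if r is None:
            continue
        if _normalized_spans(r.spans) == _normalized_spans(g.spans):
            continue
        chosen = render_structured(g.spans)
        rejected = r.raw if (r.error and r.raw) else render_structured(r.spans)
        pairs.append(
            PreferencePair(
                prompt=prompt_template.format(text=messages[g.message_id].text),
                chosen=chosen,
                rejected=rejected,
                message_id=g.message_id,
            )
        )
    return pairs


def split_pairs(
    pairs: Sequence[PreferencePair], n_validation: int, seed: int
) -> tuple[list[PreferencePair], list[PreferencePair]]:
    """Reproducible train/validation split, grouped by message so no message
    leaks across the two sets."""
    if n_validation >= len(pairs):
        raise ValueError(f"n_validation={n_validation} must be < number of pairs ({len(pairs)})")
    by_message: dict[str, list[PreferencePair]] = {}
    for p in pairs:
        by_message.setdefault(p.message_id, []).append(p)
    ids = sorted(by_message)
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    val_ids: set[str] = set()
    n_val = 0
    for mid in ids:
        if n_val >= n_validation:
            break
        if n_val + len(by_message[mid]) <= n_validation:
            val_ids.add(mid)
            n_val += len(by_message[mid])
    if n_val != n_validation:
        raise ValueError("cannot reach the requested validation size without splitting a message")
    train = [p for p in pairs if p.message_id not in val_ids]
    val = [p for p in pairs if p.message_id in val_ids]
    return train, val


def write_pairs(pairs: Iterable[PreferencePair], path: str | Path) -> None:
    """Preference-tuning interchange file: one JSON record per line with
    prompt/chosen/rejected keys."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for p in pairs:
            fh.write(
                json.dumps(
                    {"prompt": p.prompt, "chosen": p.chosen, "rejected": p.rejected,
                     "message_id": p.message_id}
                )
                + "\n"
            )


def load_pairs(path: str | Path) -> list[PreferencePair]:
    pairs = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                pairs.append(PreferencePair(rec["prompt"], rec["chosen"], rec["rejected"],
                                            rec["message_id"]))
    return pairs
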