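"""Message corpus handling: loading, deduplication, and transfer-event linkage.

The unit of analysis is a short clinical text message exchanged between
nursing-home staff roles. Messages are linked to nursing-home-to-hospital
transfer events when they fall inside a configurable pre-transfer window
(default 14 days), mirroring the data model of transfer-centred communication
studies.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Literal, Sequence

from ._text import normalize_ws

ROLES = ("nursing_staff", "aprn", "physician", "other_staff")

MESSAGE_COLUMNS = (
    "message_id",
    "resident_id",
    "facility_id",
    "sender_role",
    "receiver_role",
    "timestamp",
    "text",
)
EVENT_COLUMNS = ("event_id", "resident_id", "transfer_time")

Dialect = Literal["csv", "jsonl"]
DedupKey = Literal["all_fields", "resident_time_text"]


class CorpusFormatError(ValueError):
    """Raised for fatally malformed corpus files (missing file/columns)."""


@dataclass(frozen=True)
class Message:
    """One clinical text message with sender/receiver role metadata."""

    message_id: str
    resident_id: str
    facility_id: str
    sender_role: str
    receiver_role: str
    timestamp: datetime
    text: str


@dataclass(frozen=True)
class TransferEvent:
    """One nursing-home-to-hospital resident transfer."""

    event_id: str
    resident_id: str
    transfer_time: datetime


@dataclass
class LinkedCorpus:
    """Messages joined to transfer events through the pre-transfer window."""

    messages: list[Message]
    events: list[TransferEvent]
    links: dict[str, list[str]]  # event_id -> message_ids, input order
    window_days: int = 14

    def message_index(self) -> dict[str, Message]:
        return {m.message_id: m for m in self.messages}


def _parse_timestamp(raw: str) -> datetime:
    ts = datetime.fromisoformat(raw.strip())
    if ts.tzinfo is not None:
        raise ValueError("timezone-aware timestamps are not supported")
    return ts


def _row_to_message(row: dict[str, str]) -> Message:
    text = normalize_ws(str(row["text"]))
    if not text:
        raise ValueError("empty text")
    sender, receiver = row["sender_role"].strip(), row["receiver_role"].strip()
    for role in (sender, receiver):
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
    return Message(
        message_id=str(row["message_id"]).strip(),
        resident_id=str(row["resident_id"]).strip(),
        facility_id=str(row["facility_id"]).strip(),
        sender_role=sender,
        receiver_role=receiver,
        timestamp=_parse_timestamp(str(row["timestamp"])),
        text=text,
    )


def _iter_rows(path: Path, dialect: Dialect, columns: Sequence[str]):
    if dialect == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in columns if c not in header]
            if missing:
                raise CorpusFormatError(f"{path}: missing required column(s) {missing}")
            yield from reader
    elif dialect == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    row = json.loads(line)
                    missing = [c for c in columns if c not in row]
                    if missing:
                        raise CorpusFormatError(
                            f"{path}: missing required key(s) {missing}"
                        )
                    yield row
    else:  # pragma: no cover - guarded by Literal typing
        raise CorpusFormatError(f"unknown dialect {dialect!r}")


def load_messages(
    path: str | Path, dialect: Dialect = "csv"
) -> tuple[list[Message], list[dict]]:
    """Parse a message file.

    Returns ``(messages, rejects)``: malformed rows (bad timestamp, empty
    text, unknown role) are collected as reject records carrying the original
    row and a reason; they are never silently dropped. A missing file or a
    missing required column is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise CorpusFormatError(f"message file not found: {path}")
    messages: list[Message] = []
    rejects: list[dict] = []
    for row in _iter_rows(path, dialect, MESSAGE_COLUMNS):
        try:
            messages.append(_row_to_message(row))
        except ValueError as exc:
            reason = "unparseable timestamp" if "isoformat" in str(exc).lower() else str(exc)
            rejects.append({"row": dict(row), "reason": reason})
    return messages, rejects


def write_messages(messages: Iterable[Message], path: str | Path, dialect: Dialect = "csv") -> None:
    path = Path(path)
    rows = [
        {
            "message_id": m.message_id,
            "resident_id": m.resident_id,
            "facility_id": m.facility_id,
            "sender_role": m.sender_role,
            "receiver_role": m.receiver_role,
            "timestamp": m.timestamp.isoformat(timespec="minutes"),
            "text": m.text,
        }
        for m in messages
    ]
    if dialect == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(MESSAGE_COLUMNS))
            writer.writeheader()
            writer.writerows(rows)
    else:
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")


def load_events(path: str | Path, dialect: Dialect = "csv") -> list[TransferEvent]:
    path = Path(path)
    if not path.exists():
        raise CorpusFormatError(f"event file not found: {path}")
    events = []
    for row in _iter_rows(path, dialect, EVENT_COLUMNS):
        events.append(
            TransferEvent(
                event_id=str(row["event_id"]).strip(),
                resident_id=str(row["resident_id"]).strip(),
                transfer_time=_parse_timestamp(str(row["transfer_time"])),
            )
        )
    return events


def write_events(events: Iterable[TransferEvent], path: str | Path, dialect: Dialect = "csv") -> None:
    path = Path(path)
    rows = [
        {
            "event_id": e.event_id,
            "resident_id": e.resident_id,
            "transfer_time": e.transfer_time.isoformat(timespec="minutes"),
        }
        for e in events
    ]
    if dialect == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(EVENT_COLUMNS))
            writer.writeheader()
            writer.writerows(rows)
    else:
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")


def write_rejects(rejects: Iterable[dict], path: str | Path) -> None:
    """Reject report: one JSON record per line with the original row + reason."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in rejects:
            fh.write(json.dumps(rec) + "\n")


def _dedup_signature(message: Message, key: DedupKey) -> tuple:
    text = normalize_ws(message.text)
    if key == "all_fields":
        return (
            message.message_id,
            message.resident_id,
            message.facility_id,
            message.sender_role,
            message.receiver_role,
            message.timestamp,
            text,
        )
    if key == "resident_time_text":
        return (message.resident_id, message.timestamp, text)
    raise ValueError(f"unknown dedup key {key!r}")


def dedupe_messages(
    messages: Sequence[Message], key: DedupKey = "all_fields"
) -> tuple[list[Message], int]:
    """Remove duplicate messages, retaining the first occurrence in input order.

    The default key requires every field to be identical (after whitespace
    normalization of the text), which cannot merge distinct clinical events;
    ``resident_time_text`` is the looser alternative for feeds that re-issue
    message ids.
    """
    seen: set[tuple] = set()
    kept: list[Message] = []
    for m in messages:
        sig = _dedup_signature(m, key)
        if sig not in seen:
            seen.add(sig)
            kept.append(m)
    return kept, len(messages) - len(kept)


def link_to_transfers(
    messages: Sequence[Message],
    events: Sequence[TransferEvent],
    window_days: int = 14,
) -> LinkedCorpus:
    """Link each message to the transfer events of the same resident whose
    pre-transfer window contains it.

    The window is the half-open interval ``(transfer_time - window_days,
    transfer_time]``: a message sent at the transfer instant is linked, the
    same instant ``window_days`` earlier is not. A message may link to several
    events of the same resident.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    window = timedelta(days=window_days)
    by_resident: dict[str, list[Message]] = {}
    for m in messages:
        by_resident.setdefault(m.resident_id, []).append(m)
    links: dict[str, list[str]] = {}
    for e in events:
        lo = e.transfer_time - window
        links[e.event_id] = [
            m.message_id
            for m in by_resident.get(e.resident_id, [])
            if lo < m.timestamp <= e.transfer_time
        ]
    return LinkedCorpus(list(messages), list(events), links, window_days)
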