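"""Mailbox ingestion and message-file output.

Messages are read from a standard mbox file, a directory of RFC-822 ``.eml``
files, or a directory of plain-text files with ``Date:``-style header lines.
After ingestion the corpus is sorted by posting date (ties broken by original
mailbox order) and messages receive consecutive integer identifiers starting
at 1 in that order, so identifiers are stable across re-reads.
"""

from __future__ import annotations

import email
import email.policy
import email.utils
import logging
import mailbox
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Optional

logger = logging.getLogger(__name__)

FORMATS = ("mbox", "eml-dir", "txt-dir")


@dataclass(frozen=True)
class RawMessage:
    """One posted email message as ingested, before any cleaning."""

    id: int
    date: Optional[datetime]
    author: str
    subject: str
    body: str

    @property
    def undated(self) -> bool:
        return self.date is None


@dataclass
class Corpus:
    """A date-ordered collection of messages with consecutive ids 1..N."""

    messages: list[RawMessage] = field(default_factory=list)
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.messages)

    def __iter__(self) -> Iterator[RawMessage]:
        return iter(self.messages)

    def __getitem__(self, i: int) -> RawMessage:
        return self.messages[i]

    @property
    def span(self) -> Optional[tuple[datetime, datetime]]:
        dates = [m.date for m in self.messages if m.date is not None]
        if not dates:
            return None
        return min(dates), max(dates)

    def author_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.messages:
            counts[m.author] = counts.get(m.author, 0) + 1
        return counts


def _naive(dt: Optional[datetime]) -> Optional[datetime]:
    """Normalise aware datetimes to naive UTC so the corpus sorts cleanly."""
    if dt is None:
        return None
    if dt.tzinfo is not None:
        dt = dt.astimezone(timezone.utc).replace(tzinfo=None)
    return dt


def _parse_date(value: str) -> Optional[datetime]:
    value = value.strip()
    if not value:
        return None
    try:
        dt = email.utils.parsedate_to_datetime(value)
        if dt is not None:
            return _naive(dt)
    except (TypeError, ValueError):
        pass
    for fmt in (None,):  # ISO 8601 fallback
        try:
            return _naive(datetime.fromisoformat(value))
        except ValueError:
            continue
    return None


def _first_text_part(msg: email.message.Message) -> str:
    if msg.is_multipart():
        for part in msg.walk():
            if part.get_content_type() == "text/plain" and not part.is_multipart():
                payload = part.get_payload(decode=True)
                if payload is not None:
                    charset = part.get_content_charset() or "utf-8"
                    return payload.decode(charset, errors="replace")
        return ""
    payload = msg.get_payload(decode=True)
    if payload is None:
        return msg.get_payload() if isinstance(msg.get_payload(), str) else ""
    charset = msg.get_content_charset() or "utf-8"
    return payload.decode(charset, errors="replace")


def _from_email_message(msg: email.message.Message) -> tuple[Optional[datetime], str, str, str]:
    date = _parse_date(msg.get("Date", "") or "")
    author = (msg.get("From", "") or "").strip()
    subject = (msg.get("Subject", "") or "").strip()
    body = _first_text_part(msg)
    return date, author, subject, body


def _parse_txt_file(text: str) -> tuple[Optional[datetime], str, str, str]:
    """Plain-text message: leading ``Header: value`` lines, blank line, body."""
    date: Optional[datetime] = None
    author = ""
    subject = ""
    lines = text.splitlines()
    i = 0
    for i, line in enumerate(lines):
        if not line.strip():
            i += 1
            break
        key, _, value = line.partition(":")
        key = key.strip().lower()
        if key == "date":
            date = _parse_date(value)
        elif key in ("from", "author"):
            author = value.strip()
        elif key == "subject":
            subject = value.strip()
        else:  # not a header line: body starts here
            break
    body = "\n".join(lines[i:])
    return date, author, subject, body


def read_mailbox(path: str | os.PathLike, format: str = "mbox") -> Corpus:
    """Ingest a mailbox and return a date-sorted, id-assigned :class:`Corpus`.

    Unparseable messages are skipped with a logged warning (counted in
    ``Corpus.n_skipped``); messages lacking a parseable date are placed at
    the end of the corpus in original mailbox order and flagged via
    ``RawMessage.undated``.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown mailbox format {format!r}; expected one of {FORMATS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))

    parsed: list[tuple[Optional[datetime], str, str, str]] = []
    n_skipped = 0

    if format == "mbox":
        box = mailbox.mbox(str(path))
        try:
            for key in box.keys():
                try:
                    parsed.append(_from_email_message(box[key]))
                except Exception as exc:  # malformed message
                    n_skipped += 1
                    logger.warning("skipping unparseable message %s: %s", key, exc)
        finally:
            box.close()
    else:
        suffix = ".eml" if format == "eml-dir" else ".txt"
        files = sorted(p for p in path.iterdir() if p.suffix.lower() == suffix)
        for p in files:
            try:
                text = p.read_text(encoding="utf-8", errors="replace")
                if format == "eml-dir":
                    msg = email.message_from_string(text)
                    parsed.append(_from_email_message(msg))
                else:
                    parsed.append(_parse_txt_file(text))
            except Exception as exc:
                n_skipped += 1
                logger.warning("skipping unparseable file %s: %s", p, exc)

    dated = [(i, rec) for i, rec in enumerate(parsed) if rec[0] is not None]
    undated = [(i, rec) for i, rec in enumerate(parsed) if rec[0] is None]
    dated.sort(key=lambda item: (item[1][0], item[0]))  # stable: date, mailbox order
    if undated:
        logger.warning("%d message(s) lack a parseable date; placed at corpus end", len(undated))

    messages = []
    for new_id, (_, (date, author, subject, body)) in enumerate(dated + undated, start=1):
        messages.append(RawMessage(id=new_id, date=date, author=author, subject=subject, body=body))
    corpus = Corpus(messages=messages, n_skipped=n_skipped)
    logger.info("ingested %d message(s), skipped %d", len(corpus), n_skipped)
    return corpus


def message_filename(msg) -> str:
    """``YYYYMMDD_<id>.txt``; undated messages use ``00000000``."""
    stamp = msg.date.strftime("%Y%m%d") if msg.date is not None else "00000000"
    return f"{stamp}_{msg.id}.txt"


def write_message_file(msg, folder: str | os.PathLike) -> str:
    """Write a cleaned message to ``folder`` and return the filename.

    Writing the same message twice is idempotent; an existing file with the
    same name but different content signals a duplicated id and raises.
    """
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    name = message_filename(msg)
    target = folder / name
    content = msg.text if hasattr(msg, "text") else msg.body
    if target.exists():
        existing = target.read_text(encoding="utf-8")
        if existing != content:
            raise FileExistsError(
                f"{target} exists with different content: duplicated message id?"
            )
        return name
    target.write_text(content, encoding="utf-8")
    return name


def write_mbox(messages: Iterable, path: str | os.PathLike) -> int:
    """Serialise messages (Raw or Clean) to an mbox file; returns the count."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    box = mailbox.mbox(str(path))
    n = 0
    try:
        for m in messages:
            em = email.message.EmailMessage()
            if getattr(m, "date", None) is not None:
                em["Date"] = email.utils.format_datetime(m.date)
            em["From"] = getattr(m, "author", "") or "unknown"
            em["Subject"] = getattr(m, "subject", "") or ""
            em.set_content(m.text if hasattr(m, "text") else m.body)
            box.add(em)
            n += 1
        box.flush()
    finally:
        box.close()
    return n
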