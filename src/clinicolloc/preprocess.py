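"""Message cleaning: reply/forward stripping, boilerplate removal, deidentification.

Email bodies on practitioner mailing lists carry heavy noise — quoted
replies, forwarded blocks, signatures with self-promotional text, virus/spam
notices, mail-client boilerplate, advertisements and image placeholders —
that obscures content and distorts token frequencies. This module removes
those noise classes with an editable rule set, then deletes listed names and
places, producing the clean text every downstream stage (tokenisation,
collocation discovery, retrieval) operates on.

Cleaning is idempotent by construction: every rule is applied to a fixpoint
and no rule can manufacture text that a later pass would match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

# deliberately short (<4 letters) so the token length filter drops it
PLACEHOLDER = "xx"

GROUPS = (
    "quoted-reply",
    "attribution",
    "forwarded-block",
    "signature-delim",
    "signature-hint",
    "virus-notice",
    "client-notice",
    "advertisement",
    "embedded-image",
)

_SIG_HEURISTIC_MAX_LINES = 6


@dataclass
class NoiseRuleSet:
    """Named, individually switchable groups of noise patterns.

    Each group maps to a list of compiled regexes; semantics per group are
    documented in ``data/noise_patterns.txt``. Disable a group by listing it
    in ``disabled``.
    """

    patterns: dict[str, list[re.Pattern]] = field(default_factory=dict)
    disabled: set[str] = field(default_factory=set)

    def active(self, group: str) -> list[re.Pattern]:
        if group in self.disabled:
            return []
        return self.patterns.get(group, [])

    def disable(self, *groups: str) -> "NoiseRuleSet":
        self.disabled.update(groups)
        return self

    @classmethod
    def from_lines(cls, lines: Iterable[str]) -> "NoiseRuleSet":
        patterns: dict[str, list[re.Pattern]] = {g: [] for g in GROUPS}
        for lineno, line in enumerate(lines, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            group, _, pat = line.partition("\t")
            group = group.strip()
            if not pat or group not in GROUPS:
                raise ValueError(f"noise pattern file line {lineno}: bad group or missing pattern")
            patterns.setdefault(group, []).append(re.compile(pat))
        return cls(patterns=patterns)

    @classmethod
    def from_file(cls, path: str | Path) -> "NoiseRuleSet":
        return cls.from_lines(Path(path).read_text(encoding="utf-8").splitlines())

    @classmethod
    def default(cls) -> "NoiseRuleSet":
        text = resources.files("clinicolloc.data").joinpath("noise_patterns.txt").read_text("utf-8")
        return cls.from_lines(text.splitlines())


@dataclass
class CleanMessage:
    """A message after noise stripping and deidentification."""

    id: int
    date: Optional[object]
    text: str
    removal_log: list[tuple[str, int]] = field(default_factory=list)
    author: str = ""
    subject: str = ""


def _match_any(patterns: list[re.Pattern], line: str, search: bool) -> bool:
    return any((p.search(line) if search else p.match(line)) for p in patterns)


def strip_reply_content(body: str, rules: Optional[NoiseRuleSet] = None) -> str:
    """Remove quoted lines, reply attributions, and forwarded blocks.

    Quoted lines (leading ``>`` / ``|``) and "On ... wrote:" attribution
    lines are dropped individually; a forwarded-message marker drops
    everything from that line to the end. Surviving lines keep their order.
    """
    rules = rules or NoiseRuleSet.default()
    quoted = rules.active("quoted-reply")
    attrib = rules.active("attribution")
    fwd = rules.active("forwarded-block")
    out = []
    for line in body.splitlines():
        if _match_any(fwd, line, search=False):
            break
        if _match_any(quoted, line, search=False):
            continue
        if _match_any(attrib, line, search=False):
            continue
        out.append(line)
    return "\n".join(out)


def strip_boilerplate(
    body: str, rules: Optional[NoiseRuleSet] = None
) -> tuple[str, list[tuple[str, int]]]:
    """Remove signatures, notices, advertisements and image placeholders.

    Returns the surviving text and a removal log of ``(rule, chars removed)``
    entries, one per rule firing.
    """
    rules = rules or NoiseRuleSet.default()
    log: list[tuple[str, int]] = []

    # image placeholders: delete matched spans (to a fixpoint)
    for pat in rules.active("embedded-image"):
        while True:
            new, n = pat.subn("", body)
            if n == 0:
                break
            log.append(("embedded-image", len(body) - len(new)))
            body = new

    # line-drop rules: any line containing a match is removed
    lines = body.splitlines()
    kept = []
    for line in lines:
        dropped = False
        for group in ("virus-notice", "client-notice", "advertisement"):
            if _match_any(rules.active(group), line, search=True):
                log.append((group, len(line) + 1))
                dropped = True
                break
        if not dropped:
            kept.append(line)
    lines = kept

    # signature delimiter: truncate from the first "-- " line to the end
    delim = rules.active("signature-delim")
    for i, line in enumerate(lines):
        if _match_any(delim, line, search=False):
            removed = sum(len(l) + 1 for l in lines[i:])
            log.append(("signature-delim", removed))
            lines = lines[:i]
            break

    # heuristic: a short trailing block (after the last blank line) holding a
    # phone number, URL, or professional credential is a signature; loop to a
    # fixpoint so cleaning stays idempotent
    hints = rules.active("signature-hint")
    if hints:
        while lines and not lines[-1].strip():
            lines.pop()
        while True:
            blank_idx = None
            for i in range(len(lines) - 1, -1, -1):
                if not lines[i].strip():
                    blank_idx = i
                    break
            if blank_idx is None:
                break
            block = lines[blank_idx + 1 :]
            if not block or len(block) > _SIG_HEURISTIC_MAX_LINES:
                break
            if not any(_match_any(hints, l, search=True) for l in block):
                break
            log.append(("signature-heuristic", sum(len(l) + 1 for l in block)))
            lines = lines[:blank_idx]

    return "\n".join(lines), log


def _word_pattern(words: Iterable[str]) -> Optional[re.Pattern]:
    words = sorted({w.strip().lower() for w in words if w.strip()}, key=len, reverse=True)
    words = [w for w in words if w != PLACEHOLDER]
    if not words:
        return None
    alt = "|".join(re.escape(w) for w in words)
    # whole-word: letter/non-letter transitions on both sides
    return re.compile(rf"(?<![^\W\d_])(?:{alt})(?![^\W\d_])", re.IGNORECASE)


def deidentify(
    text: str,
    names: Iterable[str] = (),
    places: Iterable[str] = (),
    placeholder: str = PLACEHOLDER,
) -> str:
    """Replace whole-word occurrences of listed names/places with a placeholder.

    Matching is case-insensitive and whole-word only ("smithing" survives a
    listed "smith"); empty lists are the identity transform.
    """
    for wordlist in (names, places):
        pat = _word_pattern(wordlist)
        if pat is not None:
            text = pat.sub(placeholder, text)
    return text


def normalize_whitespace(text: str) -> str:
    """Collapse runs of spaces/tabs, strip line edges, squeeze blank lines."""
    lines = [" ".join(line.split()) for line in text.splitlines()]
    out: list[str] = []
    for line in lines:
        if not line and (not out or not out[-1]):
            continue
        out.append(line)
    while out and not out[-1]:
        out.pop()
    return "\n".join(out)


def clean_message(
    raw,
    rules: Optional[NoiseRuleSet] = None,
    names: Iterable[str] = (),
    places: Iterable[str] = (),
) -> CleanMessage:
    """Full cleaning pipeline for one message.

    Composition: reply/forward stripping, then boilerplate removal, then
    deidentification, then whitespace normalisation (runs collapsed to a
    single space, line breaks preserved).
    """
    rules = rules or NoiseRuleSet.default()
    log: list[tuple[str, int]] = []
    # noise rules can interact (e.g. deleting an image placeholder can leave
    # a quoted-looking line), so the stripping core runs to a fixpoint
    text = raw.body
    for _ in range(10):
        before = text
        stripped = strip_reply_content(text, rules)
        if len(stripped) != len(text):
            log.append(("reply-content", len(text) - len(stripped)))
        text, boiler_log = strip_boilerplate(stripped, rules)
        log.extend(boiler_log)
        if text == before:
            break
    text = deidentify(text, names, places)
    text = normalize_whitespace(text)
    return CleanMessage(
        id=raw.id,
        date=raw.date,
        text=text,
        removal_log=log,
        author=getattr(raw, "author", ""),
        subject=getattr(raw, "subject", ""),
    )


def clean_corpus(corpus, rules=None, names=(), places=()) -> list[CleanMessage]:
    rules = rules or NoiseRuleSet.default()
    return [clean_message(m, rules, names, places) for m in corpus]
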