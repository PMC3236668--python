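"""KWIC (keyword-in-context) concordance lines.

A concordance previews how a target word is used: each whole-word occurrence
is rendered as one fixed-width line of surrounding text with the target
centred, in corpus order. Useful for informally confirming that a
discovered token or collocation retrieves sensible message content.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

DEFAULT_WIDTH = 80
DEFAULT_MAX_LINES = 25


@dataclass(frozen=True)
class ConcordanceLine:
    message_id: int
    line: str
    target_start: int
    target_end: int


def _whole_word(target: str) -> re.Pattern:
    return re.compile(
        rf"(?<![^\W\d_]){re.escape(target)}(?![^\W\d_])", re.IGNORECASE
    )


def kwic(
    messages: Iterable,
    target: str,
    width: int = DEFAULT_WIDTH,
    max_lines: int = DEFAULT_MAX_LINES,
) -> list[ConcordanceLine]:
    """Concordance lines for ``target`` over cleaned messages, corpus order.

    Each line is exactly ``width`` characters, the matched word centred with
    the left context getting ``(width - len(target)) // 2`` characters;
    edges are space-padded. Returns at most ``max_lines`` lines.
    """
    if width < len(target) + 2:
        raise ValueError("width must be at least len(target) + 2")
    if max_lines < 1:
        raise ValueError("max_lines must be >= 1")
    pat = _whole_word(target)
    out: list[ConcordanceLine] = []
    for msg in messages:
        if len(out) >= max_lines:
            break
        flat = msg.text.replace("\n", " ")
        for m in pat.finditer(flat):
            left_len = (width - (m.end() - m.start())) // 2
            right_len = width - left_len - (m.end() - m.start())
            left = flat[max(0, m.start() - left_len) : m.start()].rjust(left_len)
            right = flat[m.end() : m.end() + right_len].ljust(right_len)
            line = left + flat[m.start() : m.end()] + right
            out.append(
                ConcordanceLine(
                    message_id=msg.id,
                    line=line,
                    target_start=left_len,
                    target_end=left_len + (m.end() - m.start()),
                )
            )
            if len(out) >= max_lines:
                break
    return out
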