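"""The classification scheme (categories -> phrases/keywords) and the keyword rule.

Classifying discovered collocations into clinical categories is a human,
consensus-based step; its product — a lexicon of categories, optional
subcategories, 2–3-word phrases and single-word keywords — is an input file
here. This module loads and validates that file and implements the keyword
extraction rule: a keyword is any word occurring at least twice across the
full set of selected collocations, where spelling variants (plaque/plaques)
and user-declared closely-related words (cardiac/myocardial) each count as
an occurrence of the same class.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import yaml


class LexiconError(ValueError):
    pass


@dataclass
class Category:
    name: str
    phrases: list[tuple[str, ...]] = field(default_factory=list)
    keywords: list[str] = field(default_factory=list)
    # subcategory name -> {"phrases": [...], "keywords": [...]}; entries are
    # also folded into the flat phrase/keyword lists above
    subcategories: dict[str, dict] = field(default_factory=dict)


@dataclass
class Lexicon:
    categories: dict[str, Category] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.categories

    def __getitem__(self, name: str) -> Category:
        return self.categories[name]

    @property
    def n_phrases(self) -> int:
        return sum(len(c.phrases) for c in self.categories.values())

    @property
    def n_keyword_instances(self) -> int:
        """Keyword slots summed over categories (a keyword may recur)."""
        return sum(len(c.keywords) for c in self.categories.values())

    @property
    def unique_keywords(self) -> set[str]:
        return {k for c in self.categories.values() for k in c.keywords}

    def summary(self):
        """Per-category phrase/keyword tallies in the layout of the headline
        distribution table (counts plus rounded percentages of the totals)."""
        import pandas as pd
        from .report import percent

        total_p = self.n_phrases
        total_k = self.n_keyword_instances
        rows = []
        for name, cat in self.categories.items():
            rows.append(
                {
                    "category": name,
                    "n_phrases": len(cat.phrases),
                    "pct_phrases": percent(len(cat.phrases), total_p, 0) if total_p else 0.0,
                    "n_keywords": len(cat.keywords),
                    "pct_keywords": percent(len(cat.keywords), total_k, 0) if total_k else 0.0,
                }
            )
        rows.append(
            {
                "category": "Total",
                "n_phrases": total_p,
                "pct_phrases": 100.0 if total_p else 0.0,
                "n_keywords": total_k,
                "pct_keywords": 100.0 if total_k else 0.0,
            }
        )
        return pd.DataFrame(rows)


def _check_phrase(words: tuple[str, ...], where: str) -> tuple[str, ...]:
    if not (2 <= len(words) <= 3):
        raise LexiconError(f"{where}: phrase must have 2 or 3 words, got {len(words)}")
    return tuple(w.lower() for w in words)


def _add_entry(cat: Category, sub: Optional[str], words: tuple[str, ...], where: str) -> None:
    if len(words) == 1:
        kw = words[0].lower()
        cat.keywords.append(kw)
        if sub:
            cat.subcategories.setdefault(sub, {"phrases": [], "keywords": []})["keywords"].append(kw)
    else:
        phrase = _check_phrase(words, where)
        if phrase in cat.phrases:
            raise LexiconError(f"{where}: duplicate phrase {' '.join(phrase)!r} in {cat.name!r}")
        cat.phrases.append(phrase)
        if sub:
            cat.subcategories.setdefault(sub, {"phrases": [], "keywords": []})["phrases"].append(phrase)


def _load_lines(text: str) -> Lexicon:
    """Line-oriented format: ``category / subcategory`` headers, then one
    phrase (2–3 words) or keyword (1 word) per line; ``#`` comments."""
    lex = Lexicon()
    cat: Optional[Category] = None
    sub: Optional[str] = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            header = line[1:-1]
            cat_name, _, sub_name = header.partition("/")
            cat_name = cat_name.strip().lower()
            sub = sub_name.strip().lower() or None
            cat = lex.categories.setdefault(cat_name, Category(name=cat_name))
            continue
        if cat is None:
            raise LexiconError(f"line {lineno}: entry before any [category] header")
        words = tuple(line.lower().split())
        if len(words) > 3:
            raise LexiconError(f"line {lineno}: phrase has {len(words)} words (max 3)")
        _add_entry(cat, sub, words, f"line {lineno}")
    return lex


def _load_yaml(text: str) -> Lexicon:
    data = yaml.safe_load(text)
    lex = Lexicon()
    if not data:
        return lex
    if not isinstance(data, dict):
        raise LexiconError("lexicon YAML must map category names to entries")
    for cat_name, body in data.items():
        cat = Category(name=str(cat_name).lower())
        lex.categories[cat.name] = cat
        body = body or {}
        groups: list[tuple[Optional[str], dict]] = [(None, body)]
        for sub_name, sub_body in (body.get("subcategories") or {}).items():
            groups.append((str(sub_name).lower(), sub_body or {}))
        for sub, group in groups:
            for item in group.get("phrases") or []:
                words = tuple(str(item).lower().split())
                if len(words) < 2 or len(words) > 3:
                    raise LexiconError(
                        f"category {cat.name!r}: phrase {item!r} must have 2 or 3 words"
                    )
                _add_entry(cat, sub, words, f"category {cat.name!r}")
            for item in group.get("keywords") or []:
                _add_entry(cat, sub, (str(item),), f"category {cat.name!r}")
    return lex


def load_lexicon(path: str | Path) -> Lexicon:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yml", ".yaml"):
        return _load_yaml(text)
    return _load_lines(text)


@dataclass
class EquivalenceMap:
    """Disjoint sets of tokens treated as one keyword-occurrence class."""

    classes: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        index: dict[str, int] = {}
        for i, cls in enumerate(self.classes):
            cls = frozenset(w.lower() for w in cls)
            self.classes[i] = cls
            if seen & cls:
                raise LexiconError(f"equivalence classes overlap on {sorted(seen & cls)}")
            seen |= cls
            for w in cls:
                index[w] = i
        self._index = index

    def class_of(self, token: str) -> Optional[frozenset[str]]:
        i = self._index.get(token.lower())
        return None if i is None else self.classes[i]

    @classmethod
    def from_file(cls, path: str | Path) -> "EquivalenceMap":
        """One class per line, members whitespace-separated; ``#`` comments."""
        classes = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            classes.append(frozenset(line.lower().split()))
        return cls(classes=classes)


def _plural_stem(token: str) -> str:
    """Fold simple plural variants: plaques -> plaque, boxes -> box."""
    if token.endswith(("ses", "xes", "zes", "ches", "shes")) and len(token) > 4:
        return token[:-2]
    if token.endswith("s") and not token.endswith("ss") and len(token) > 3:
        return token[:-1]
    return token


def extract_keywords(
    collocations: Iterable,
    equiv: Optional[EquivalenceMap] = None,
    merge_plurals: bool = True,
) -> set[str]:
    """Words occurring at least twice across all collocation word slots.

    Occurrences are counted per equivalence class: user-declared classes
    from ``equiv`` first, then (optionally) a simple plural-suffix fold,
    with unmapped tokens as singleton classes. Each qualifying class emits
    its lexicographically first observed member as the keyword.
    """
    class_counts: Counter = Counter()
    members: dict[object, set[str]] = {}
    for coll in collocations:
        words = coll.words if hasattr(coll, "words") else tuple(coll)
        for w in words:
            w = w.lower()
            cls = equiv.class_of(w) if equiv is not None else None
            if cls is not None:
                key: object = ("equiv", cls)
            elif merge_plurals:
                key = ("stem", _plural_stem(w))
            else:
                key = ("tok", w)
            class_counts[key] += 1
            members.setdefault(key, set()).add(w)
    return {min(members[key]) for key, n in class_counts.items() if n >= 2}


def validate_lexicon(lex: Lexicon, collocations: Iterable) -> dict:
    """Cross-check the human scheme against discovered collocations.

    Lexicon phrases absent from the discovered set are warnings (the scheme
    may legitimately include phrases from earlier runs), reported alongside
    per-category tallies.
    """
    discovered = set()
    for coll in collocations:
        discovered.add(coll.words if hasattr(coll, "words") else tuple(coll))
    missing: dict[str, list[tuple[str, ...]]] = {}
    for name, cat in lex.categories.items():
        absent = [p for p in cat.phrases if p not in discovered]
        if absent:
            missing[name] = absent
    return {
        "missing_phrases": missing,
        "n_phrases": lex.n_phrases,
        "n_categories": len(lex.categories),
        "n_keyword_instances": lex.n_keyword_instances,
        "n_unique_keywords": len(lex.unique_keywords),
    }
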