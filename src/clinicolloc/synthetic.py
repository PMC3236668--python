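"""Seeded synthetic mailing-list corpora with ground-truth manifests.

The study corpus — 14,576 messages posted by a ~450-subscriber dental
mailing list over roughly one year, with heavily skewed per-author posting
counts and bodies mixing prose, quoted replies, signatures, advertisements
and virus notices — is private. This generator emulates its statistical and
structural properties so every pipeline stage is testable: author
participation is drawn from a Zipf law whose exponent is calibrated so the
top 5% of subscribers contribute a configured share of messages (50% by
default), bodies are innocuous filler prose with clinical phrases and
keywords planted at controlled character gaps, and noise blocks are drawn
verbatim from the families the cleaning rules target. A manifest records
every planted item and noise block, making retrieval recall/precision
exactly scorable. The same seed always regenerates byte-identical output.

The generator makes no attempt at realistic dental discourse; only the
properties the pipeline depends on are emulated.
"""

from __future__ import annotations

import json
import random
from collections import Counter
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from typing import Iterable, Optional, Sequence, Union

from .corpus_io import Corpus, RawMessage
from .lexicon import Category, Lexicon

# ---------------------------------------------------------------------------
# vocabularies: filler prose is disjoint from planted clinical vocabulary so
# the manifest is the exact ground truth (no accidental matches)

FILLER_VOCAB: tuple[str, ...] = (
    "weekend", "garden", "coffee", "weather", "football", "holiday",
    "cousin", "kitchen", "market", "bicycle", "painting", "sunset",
    "concert", "picnic", "library", "mountain", "harbor", "recipe",
    "blanket", "lantern", "meadow", "orchard", "pottery", "sailing",
    "theater", "village", "window", "journal", "evening", "morning",
    "thanks", "everyone", "wonderful", "yesterday", "tomorrow", "question",
)

# short connective junk used to realise exact character gaps between planted
# phrase words; none of these can match a planted word or survive the token
# length filter
_GAP_JUNK = "of the and for near with note "

CATEGORY_NAMES = (
    "systemic disease", "endodontics", "orthodontics", "periodontics",
    "restorative dentistry", "oral and maxillofacial surgery",
    "other oral diseases", "radiology", "causative agent", "medication",
    "materials", "basic sciences", "research",
)


def demo_lexicon() -> Lexicon:
    """A small classification scheme over clinical vocabulary disjoint from
    the filler prose; keywords are disjoint from phrase words so phrase and
    keyword plantings never cross-match."""
    spec = {
        "systemic disease": (
            [("herpes", "zoster"), ("glucose", "homeostasis", "inflammation")],
            ["mercury"],
        ),
        "endodontics": (
            [("fistula", "filled", "obturation"), ("irreversible", "pulpitis", "apical")],
            ["apicoectomy"],
        ),
        "medication": (
            [("intravenous", "bisphosphonates"), ("prescribed", "amoxicillin", "hydrocodone")],
            ["proinflammatory"],
        ),
        "causative agent": ([("mutans", "streptococci")], ["biofilm"]),
        "periodontics": ([("supragingival", "scaling", "prophylaxis")], ["gingivitis"]),
    }
    lex = Lexicon()
    for name, (phrases, keywords) in spec.items():
        lex.categories[name] = Category(name=name, phrases=list(phrases), keywords=list(keywords))
    return lex


NOISE_BLOCKS = {
    "quoted-reply": "> thanks for the update everyone\n> see you at the meeting",
    "forwarded-block": "-----Original Message-----\nthe forwarded content follows here",
    "signature": "-- \nDr. Pat Example, DDS\nwww.example-dental-practice.com\n(555) 123-4567",
    "virus-notice": "No virus found in this outgoing message. Checked by AVG.",
    "client-notice": "Sent from my iPhone",
    "advertisement": "Special offer for subscribers, visit our website today. Click here to unsubscribe.",
    "embedded-image": "[image: molar_radiograph_0012.jpg]",
}

DEFAULT_NOISE_PROBS = {
    "quoted-reply": 0.30,
    "signature": 0.40,
    "virus-notice": 0.10,
    "client-notice": 0.10,
    "advertisement": 0.08,
    "embedded-image": 0.05,
    "forwarded-block": 0.05,
}

DEFAULT_GAPS = (1, 10, 40, 75, 100, 150)  # cycled; 150 exceeds the 100-char bound


@dataclass
class PlantingPlan:
    """One clinical item to plant: a phrase tuple or a keyword string."""

    category: str
    item: Union[tuple[str, ...], str]
    n: int
    gaps: tuple[int, ...] = DEFAULT_GAPS
    n_in_quoted: int = 0  # of n, instances planted inside a quoted block

    @property
    def kind(self) -> str:
        return "phrase" if isinstance(self.item, tuple) else "keyword"


def default_plantings(n_messages: int, lexicon: Optional[Lexicon] = None) -> list[PlantingPlan]:
    lexicon = lexicon or demo_lexicon()
    quota = max(6, n_messages // 100)
    plans = []
    for name, cat in lexicon.categories.items():
        for phrase in cat.phrases:
            plans.append(PlantingPlan(category=name, item=tuple(phrase), n=quota))
        for kw in cat.keywords:
            plans.append(PlantingPlan(category=name, item=kw, n=quota, gaps=(0,)))
    return plans


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults mirror the corpus being emulated: 14,576 messages from a
    ~450-subscriber list (245 of whom post) between 2008-04-18 and
    2009-05-28, with the top 5% of subscribers contributing 50% of traffic.
    """

    seed: int = 0
    n_subscribers: int = 450
    n_posting: int = 245
    n_messages: int = 14576
    start: datetime = datetime(2008, 4, 18)
    end: datetime = datetime(2009, 5, 28)
    top_frac: float = 0.05
    top_share: float = 0.50
    noise_probs: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_PROBS))
    plantings: Optional[list[PlantingPlan]] = None  # None -> default plan
    filler_vocab: tuple[str, ...] = FILLER_VOCAB
    max_gap_reference: int = 100

    def __post_init__(self):
        for k, p in self.noise_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"noise probability {k}={p} outside [0, 1]")
        if not 0 < self.top_frac <= 1 or not 0 <= self.top_share <= 1:
            raise ValueError("top_frac must be in (0,1], top_share in [0,1]")


@dataclass
class PlantedItem:
    kind: str  # "phrase" | "keyword"
    category: str
    words: tuple[str, ...]
    span: tuple[int, int]  # character span in the raw body
    gaps: list[int] = field(default_factory=list)  # inclusive char gaps, phrase only
    in_noise: bool = False

    def retrievable(self, max_gap: int) -> bool:
        if self.in_noise:
            return False
        if self.kind == "phrase":
            return all(g <= max_gap for g in self.gaps)
        return True


@dataclass
class ManifestEntry:
    id: int
    date: str
    author: str
    items: list[PlantedItem] = field(default_factory=list)
    noise: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class Manifest:
    entries: dict[int, ManifestEntry] = field(default_factory=dict)

    def planted(self, kind: Optional[str] = None) -> Iterable[tuple[int, PlantedItem]]:
        for mid, entry in self.entries.items():
            for item in entry.items:
                if kind is None or item.kind == kind:
                    yield mid, item

    def to_json(self) -> str:
        payload = {
            str(mid): {
                "id": e.id,
                "date": e.date,
                "author": e.author,
                "items": [asdict(i) for i in e.items],
                "noise": [list(n) for n in e.noise],
            }
            for mid, e in self.entries.items()
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Manifest":
        raw = json.loads(text)
        entries = {}
        for key, e in raw.items():
            items = [
                PlantedItem(
                    kind=i["kind"],
                    category=i["category"],
                    words=tuple(i["words"]),
                    span=tuple(i["span"]),
                    gaps=list(i["gaps"]),
                    in_noise=i["in_noise"],
                )
                for i in e["items"]
            ]
            entries[int(key)] = ManifestEntry(
                id=e["id"], date=e["date"], author=e["author"],
                items=items, noise=[tuple(n) for n in e["noise"]],
            )
        return cls(entries=entries)


# ---------------------------------------------------------------------------
# author participation


def author_allocation(config: SimConfig) -> list[int]:
    """Messages per posting author (descending), calibrated so the top
    ``round(top_frac * n_subscribers)`` authors hold ``top_share`` of traffic.

    Weights follow a Zipf law 1/rank**s; the exponent is found by bisection
    against the configured top share, then messages are apportioned by
    largest remainder with a one-message floor so every posting author posts.
    """
    n = config.n_posting
    total = config.n_messages
    if total == 0 or n == 0:
        return [0] * n
    if total < n:
        n = total  # fewer messages than would-be posters
    k = max(1, round(config.top_frac * config.n_subscribers))
    k = min(k, n)

    # the one-message floor takes n messages off the top; aim the weighted
    # apportionment of the remainder so the floored total still hits top_share
    spare = total - n
    if spare <= 0:
        return sorted([1] * total + [0] * (config.n_posting - total), reverse=True)
    target = min(1.0, max(0.0, (config.top_share * total - k) / spare))

    def share(s: float) -> float:
        w = [1.0 / (r ** s) for r in range(1, n + 1)]
        return sum(w[:k]) / sum(w)

    lo, hi = 0.0, 8.0
    if share(hi) < target:
        s = hi
    else:
        for _ in range(60):
            mid = (lo + hi) / 2
            if share(mid) < target:
                lo = mid
            else:
                hi = mid
        s = (lo + hi) / 2

    weights = [1.0 / (r ** s) for r in range(1, n + 1)]
    wsum = sum(weights)
    quotas = [spare * w / wsum for w in weights]
    counts = [1 + int(q) for q in quotas]
    remainder = total - sum(counts)
    order = sorted(range(n), key=lambda i: (quotas[i] - int(quotas[i]), -i), reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    counts.sort(reverse=True)
    return counts + [0] * (config.n_posting - n)


def top_share_realized(counts: Sequence[int], config: SimConfig) -> float:
    """Fraction of messages posted by the top ``top_frac`` of subscribers."""
    total = sum(counts)
    if total == 0:
        return 0.0
    k = max(1, round(config.top_frac * config.n_subscribers))
    ranked = sorted(counts, reverse=True)
    return sum(ranked[:k]) / total


# ---------------------------------------------------------------------------
# body assembly


def _gap_text(gap: int) -> str:
    """Inter-word text of exactly ``max(gap, 1)`` characters, single-spaced
    (whitespace normalisation must not change its length)."""
    gap = max(gap, 1)
    if gap == 1:
        return " "
    mid = (_GAP_JUNK * (gap // len(_GAP_JUNK) + 2))[: gap - 2]
    if mid.startswith(" "):
        mid = "." + mid[1:]
    if mid.endswith(" "):
        mid = mid[:-1] + "."
    return " " + mid + " "


def _filler_sentence(rng: random.Random, vocab: Sequence[str]) -> str:
    n = rng.randint(5, 11)
    return " ".join(rng.choice(vocab) for _ in range(n)) + "."


def _planted_line(
    item: Union[tuple[str, ...], str], gap: int, rng: random.Random, vocab: Sequence[str]
) -> tuple[str, tuple[int, int], list[int]]:
    """Build a line containing the planted item; returns (line, span within
    line, inclusive gaps)."""
    lead = rng.choice(vocab) + " "
    tail = " " + rng.choice(vocab) + "."
    if isinstance(item, str):
        line = lead + item + tail
        return line, (len(lead), len(lead) + len(item)), []
    words = list(item)
    if len(words) == 2 and rng.random() < 0.5:
        words = words[::-1]  # retrieval is order-free
    parts = [words[0]]
    gaps = []
    for w in words[1:]:
        gt = _gap_text(gap)
        gaps.append(len(gt))
        parts.append(gt)
        parts.append(w)
    body = "".join(parts)
    line = lead + body + tail
    return line, (len(lead), len(lead) + len(body)), gaps


def generate_corpus(config: SimConfig) -> tuple[Corpus, Manifest]:
    """Generate a corpus and its ground-truth manifest.

    Raises ``ValueError`` for infeasible planting quotas (more plantings of
    one item than messages).
    """
    rng = random.Random(config.seed)
    n = config.n_messages
    plans = config.plantings if config.plantings is not None else default_plantings(n)
    for plan in plans:
        if plan.n > n:
            raise ValueError(
                f"planting quota {plan.n} for {plan.item!r} exceeds {n} messages"
            )
        if plan.n_in_quoted > plan.n:
            raise ValueError("n_in_quoted exceeds planting quota")

    if n == 0:
        return Corpus(), Manifest()

    # dates ascending; ids 1..N in date order by construction
    span = (config.end - config.start).total_seconds()
    stamps = sorted(rng.random() * span for _ in range(n))
    dates = [config.start + timedelta(seconds=s) for s in stamps]

    counts = author_allocation(config)
    labels = [f"author{i + 1:04d}" for i, c in enumerate(counts) for _ in range(c)]
    rng.shuffle(labels)

    # planting assignment: message index -> list of (plan, gap, in_quoted)
    assignments: dict[int, list[tuple[PlantingPlan, int, bool]]] = {}
    for plan in plans:
        targets = rng.sample(range(n), plan.n)
        for j, t in enumerate(targets):
            gap = plan.gaps[j % len(plan.gaps)]
            in_quoted = j < plan.n_in_quoted
            assignments.setdefault(t, []).append((plan, gap, in_quoted))

    messages: list[RawMessage] = []
    manifest = Manifest()
    vocab = config.filler_vocab
    for idx in range(n):
        mid = idx + 1
        lines: list[str] = []
        items: list[PlantedItem] = []
        noise: list[tuple[str, int, int]] = []

        for _ in range(rng.randint(1, 3)):
            lines.append(_filler_sentence(rng, vocab))

        for plan, gap, in_quoted in assignments.get(idx, []):
            line, (s, e), gaps = _planted_line(plan.item, gap, rng, vocab)
            if in_quoted:
                line = "> " + line
                s, e = s + 2, e + 2
            line_start = sum(len(l) + 1 for l in lines)
            lines.append(line)
            words = plan.item if isinstance(plan.item, tuple) else (plan.item,)
            items.append(
                PlantedItem(
                    kind=plan.kind,
                    category=plan.category,
                    words=tuple(words),
                    span=(line_start + s, line_start + e),
                    gaps=gaps,
                    in_noise=in_quoted,
                )
            )
            if in_quoted:
                noise.append(("quoted-reply", line_start, line_start + len(line)))

        lines.append(_filler_sentence(rng, vocab))

        # noise blocks at the tail (forwarded block last: it truncates to end)
        tail_order = ("quoted-reply", "embedded-image", "advertisement",
                      "virus-notice", "client-notice", "signature", "forwarded-block")
        for cls in tail_order:
            if rng.random() < config.noise_probs.get(cls, 0.0):
                block = NOISE_BLOCKS[cls]
                start = sum(len(l) + 1 for l in lines)
                lines.extend(block.splitlines())
                noise.append((cls, start, start + len(block)))

        body = "\n".join(lines)
        author = labels[idx]
        messages.append(
            RawMessage(id=mid, date=dates[idx], author=author, subject="list message", body=body)
        )
        manifest.entries[mid] = ManifestEntry(
            id=mid, date=dates[idx].isoformat(), author=author, items=items, noise=noise
        )

    return Corpus(messages=messages), manifest


# ---------------------------------------------------------------------------
# scoring


@dataclass
class ScoreReport:
    recall: float
    precision: float
    phrase_recall: float
    phrase_precision: float
    keyword_recall: float
    keyword_precision: float
    n_retrievable: int
    n_retrieved_true: int
    n_false_positive: int
    per_category: dict = field(default_factory=dict)


def _key(kind: str, mid: int, words: tuple[str, ...]) -> tuple:
    if kind == "phrase":
        return (mid, frozenset(words))
    return (mid, " ".join(words))


def score_against_manifest(retrieval, manifest: Manifest, max_gap: int) -> ScoreReport:
    """Recall/precision of a RetrievalSet against the generator's manifest.

    Recall counts retrievable plantings (all gaps within ``max_gap``,
    outside noise) that were retrieved; predictions with no corresponding
    planting are false positives. Vacuous cases score 1.0.
    """
    corpus_ids = set(manifest.entries)
    for m in retrieval.matches:
        if m.message_id not in corpus_ids:
            raise ValueError(f"match references message id {m.message_id} absent from manifest")

    stats = {}
    cat_detail: dict[tuple[str, str], Counter] = {}
    for kind in ("phrase", "keyword"):
        expected: Counter = Counter()
        categories: dict[tuple, str] = {}
        for mid, item in manifest.planted(kind):
            if item.retrievable(max_gap):
                key = _key(kind, mid, item.words)
                expected[key] += 1
                categories[key] = item.category
        predicted: Counter = Counter()
        for m in retrieval.matches:
            if m.kind != kind:
                continue
            words = m.query if isinstance(m.query, tuple) else tuple(m.query.split())
            key = _key(kind, m.message_id, words)
            predicted[key] += 1
            categories.setdefault(key, m.category)
        tp = fp = fn = 0
        for key in set(expected) | set(predicted):
            t = min(expected[key], predicted[key])
            tp += t
            fp += predicted[key] - t
            fn += expected[key] - t
            c = cat_detail.setdefault((categories.get(key, "?"), kind), Counter())
            c.update(tp=t, fp=predicted[key] - t, fn=expected[key] - t)
        stats[kind] = (tp, fp, fn)

    def ratio(a: int, b: int) -> float:
        return a / b if b else 1.0

    p_tp, p_fp, p_fn = stats["phrase"]
    k_tp, k_fp, k_fn = stats["keyword"]
    tp, fp, fn = p_tp + k_tp, p_fp + k_fp, p_fn + k_fn
    return ScoreReport(
        recall=ratio(tp, tp + fn),
        precision=ratio(tp, tp + fp),
        phrase_recall=ratio(p_tp, p_tp + p_fn),
        phrase_precision=ratio(p_tp, p_tp + p_fp),
        keyword_recall=ratio(k_tp, k_tp + k_fn),
        keyword_precision=ratio(k_tp, k_tp + k_fp),
        n_retrievable=tp + fn,
        n_retrieved_true=tp,
        n_false_positive=fp,
        per_category={k: dict(v) for k, v in cat_detail.items()},
    )
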