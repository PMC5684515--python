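"""High-precision retrieval of pregnancy-indicating posts.

The retrieval stage mirrors how a keyword-tracking collection API is used in
practice: a cheap seed-term prefilter (substring containment over the
lowercased text, which also catches hashtag forms such as ``#pregnant``)
followed by 14 case-insensitive regular-expression query patterns applied to
normalized text.  Each pattern realization embeds at least one seed term, so
the prefilter is a necessary condition for any pattern match.

Pattern realizations are derived from published simplified forms:

* ``a & b`` (terms joined by "and", any order) becomes a conjunction of
  lookaheads;
* "exact sequence with whitespace or punctuations in between" becomes the
  terms in order separated by ``\\W+``;
* the first-person time-phrase pattern (id 1) requires a time unit followed by
  "pregnant" plus a first-person marker anywhere in the post, and its time
  class includes day/days: retrieved samples include posts where the
  first-person marker follows the time phrase ("... two days pregnant ...
  'i'm getting big'"), so an ordered realization would miss posts the
  deployed query demonstrably collected.

Normalization: lowercase, Unicode apostrophes mapped to ASCII ``'``, and
whitespace runs collapsed to single spaces.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .posts import Post

DEFAULT_SEED_TERMS = frozenset({"pregnancy", "pregnant", "baby", "family", "mom"})

_APOSTROPHES = str.maketrans({"’": "'", "‘": "'", "ʼ": "'", "`": "'"})
_WS_RUN = re.compile(r"\s+")

_FIRST_PERSON = r"(?:i am|i'm|im)"
_TIME_UNIT = r"(?:days?|weeks?|months?)"

#: (pattern_id, simplified_form, realized_expression, notes)
DEFAULT_PATTERN_TABLE: list[tuple[int, str, str, str]] = [
    (
        1,
        "(im|i am|i'm).*[time].*pregnant",
        rf"\A(?=.*\b{_FIRST_PERSON}\b)(?=.*\b{_TIME_UNIT}\b.*\bpregnant\b)",
        "Time can be day, days, week, weeks, month or months; the first-person "
        "marker may occur anywhere in the post (retrieved samples include "
        "posts where it follows the time phrase).",
    ),
    (
        2,
        "baby & arriving",
        r"\A(?=.*\bbaby\b)(?=.*\barriving\b)",
        "Both terms present, any order.",
    ),
    (
        3,
        "baby coming soon",
        r"\bbaby\W+coming\W+soon\b",
        "Exact sequence with whitespace or punctuation in between.",
    ),
    (
        4,
        "been.*[time] & since & i & pregnant",
        rf"\A(?=.*\bbeen\b[\W\d]*{_TIME_UNIT}\b)(?=.*\bsince\b)(?=.*\bi\b)"
        r"(?=.*\bpregnant\b)",
        "Time can be day, days, week, weeks, month or months; exact sequence "
        "for 'been [number] time' with whitespace, digits or punctuation in "
        "between; remaining terms any order.",
    ),
    (
        5,
        "growing & baby & belly",
        r"\A(?=.*\bgrowing\b)(?=.*\bbaby\b)(?=.*\bbelly\b)",
        "All three terms present, any order.",
    ),
    (
        6,
        "(im|i am|i'm) expecting.*baby",
        rf"\b{_FIRST_PERSON}\W+expecting\b.*\bbaby\b",
        "Exact sequence for the first-person marker plus 'expecting'; 'baby' "
        "anywhere after.",
    ),
    (
        7,
        "(im|i am|i'm) going to (b|be) a mom",
        rf"\b{_FIRST_PERSON}\W+going\W+to\W+(?:be|b)\W+a\W+mom\b",
        "Exact sequence with whitespace or punctuation in between.",
    ),
    (
        8,
        "(im|i am|i'm) having a baby",
        rf"\b{_FIRST_PERSON}\W+having\W+a\W+baby\b",
        "Exact sequence.",
    ),
    (
        9,
        "i (hav|have) been pregnant",
        r"\bi\W+(?:have|hav)\W+been\W+pregnant\b",
        "Exact sequence.",
    ),
    (
        10,
        "(ive|i've) been pregnant",
        r"\b(?:i've|ive)\W+been\W+pregnant\b",
        "Exact sequence.",
    ),
    (
        11,
        'adding & one & "our family"',
        r"\A(?=.*\badding\b)(?=.*\bone\b)(?=.*\bour\W+family\b)",
        "Exact sequence for 'our family'; remaining terms any order.",
    ),
    (
        12,
        "my pregnancy",
        r"\bmy\W+pregnancy\b",
        "Exact sequence with whitespace or punctuation in between.",
    ),
    (
        13,
        "(im|i am|i'm) going to have a baby",
        rf"\b{_FIRST_PERSON}\W+going\W+to\W+have\W+a\W+baby\b",
        "Exact sequence.",
    ),
    (
        14,
        "our family.*growing.*(2|two) feet",
        r"\bour\W+family\b.*\bgrowing\b.*\b(?:2|two)\W+feet\b",
        "Terms in order, any material in between.",
    ),
]


class PatternConfigError(ValueError):
    """Raised when a pattern configuration entry cannot be compiled."""


def normalize_text(text: str) -> str:
    """Lowercase, map Unicode apostrophes to ``'`` and collapse whitespace."""
    return _WS_RUN.sub(" ", text.lower().translate(_APOSTROPHES)).strip()


@dataclass(frozen=True)
class QueryPattern:
    pattern_id: int
    simplified_form: str
    realized_expression: str
    notes: str = ""
    _compiled: re.Pattern = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        try:
            compiled = re.compile(self.realized_expression, re.IGNORECASE)
        except re.error as exc:
            raise PatternConfigError(
                f"pattern {self.pattern_id}: cannot compile "
                f"{self.realized_expression!r}: {exc}"
            ) from exc
        object.__setattr__(self, "_compiled", compiled)

    def matches(self, normalized_text: str) -> bool:
        return self._compiled.search(normalized_text) is not None


@dataclass(frozen=True)
class PatternMatch:
    post_id: str
    matched_pattern_ids: frozenset[int]


@dataclass
class PatternRegistry:
    patterns: list[QueryPattern]
    seed_terms: frozenset[str] = DEFAULT_SEED_TERMS

    def __post_init__(self) -> None:
        self.seed_terms = frozenset(t.lower() for t in self.seed_terms)
        ids = [p.pattern_id for p in self.patterns]
        if len(ids) != len(set(ids)):
            raise PatternConfigError(f"duplicate pattern ids in registry: {ids}")

    def pattern_ids(self) -> list[int]:
        return [p.pattern_id for p in self.patterns]

    def __len__(self) -> int:
        return len(self.patterns)


def compile_pattern_registry(config: list[dict] | str | Path | None = None) -> PatternRegistry:
    """Build a registry from a config (list of entries or JSON file path); the
    default registry holds the 14 stock patterns and the five seed terms."""
    if config is None:
        patterns = [
            QueryPattern(pid, simp, expr, notes)
            for pid, simp, expr, notes in DEFAULT_PATTERN_TABLE
        ]
        return PatternRegistry(patterns)
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            config = json.load(fh)
    if not config:
        raise PatternConfigError("pattern config is empty")
    patterns = []
    for entry in config:
        try:
            patterns.append(
                QueryPattern(
                    pattern_id=int(entry["pattern_id"]),
                    simplified_form=entry["simplified_form"],
                    realized_expression=entry["realized_expression"],
                    notes=entry.get("notes", ""),
                )
            )
        except KeyError as exc:
            raise PatternConfigError(f"pattern entry missing key {exc}: {entry}") from exc
    return PatternRegistry(patterns)


def write_pattern_config(registry: PatternRegistry, path: str | Path) -> None:
    entries = [
        {
            "pattern_id": p.pattern_id,
            "simplified_form": p.simplified_form,
            "realized_expression": p.realized_expression,
            "notes": p.notes,
        }
        for p in registry.patterns
    ]
    Path(path).write_text(json.dumps(entries, indent=2) + "\n", encoding="utf-8")


def prefilter_by_seeds(text: str, registry: PatternRegistry) -> bool:
    """True iff the lowercased text contains any seed term as a substring."""
    lowered = text.lower()
    return any(seed in lowered for seed in registry.seed_terms)


def match_patterns(post: Post, registry: PatternRegistry) -> PatternMatch | None:
    """All pattern ids firing on the normalized text; None when none fire."""
    normalized = normalize_text(post.text)
    fired = frozenset(
        p.pattern_id for p in registry.patterns if p.matches(normalized)
    )
    return PatternMatch(post.id, fired) if fired else None


def latin_fraction(text: str) -> float:
    """Fraction of characters in the printable Latin-1 range."""
    if not text:
        return 1.0
    ok = sum(1 for c in text if c == "\n" or 0x20 <= ord(c) <= 0xFF)
    return ok / len(text)


@dataclass
class ScanResult:
    matches: list[tuple[Post, PatternMatch]]
    frequency_table: pd.DataFrame
    n_input: int
    n_prefiltered: int
    n_matched: int
    n_rejects: int


def scan_corpus(
    posts: Iterable[Post],
    registry: PatternRegistry,
    *,
    latin_filter: bool = False,
    latin_threshold: float = 0.8,
) -> ScanResult:
    """Prefilter, pattern-match and tally a corpus.

    Posts failing the seed prefilter are never pattern-tested.  The frequency
    table has one row per registry pattern with its match count and relative
    frequency (percent of matched posts; a post matching several patterns is
    counted once per pattern, so percentages may sum past 100).
    """
    counts = {pid: 0 for pid in registry.pattern_ids()}
    matches: list[tuple[Post, PatternMatch]] = []
    n_input = n_prefiltered = n_rejects = 0
    for post in posts:
        n_input += 1
        if post.text is None:
            n_rejects += 1
            continue
        if latin_filter and latin_fraction(post.text) < latin_threshold:
            n_rejects += 1
            continue
        if not prefilter_by_seeds(post.text, registry):
            continue
        n_prefiltered += 1
        match = match_patterns(post, registry)
        if match is None:
            continue
        matches.append((post, match))
        for pid in match.matched_pattern_ids:
            counts[pid] += 1
    n_matched = len(matches)
    table = pd.DataFrame(
        {
            "pattern_id": registry.pattern_ids(),
            "simplified_form": [p.simplified_form for p in registry.patterns],
            "count": [counts[pid] for pid in registry.pattern_ids()],
        }
    )
    table["relative_frequency_percent"] = (
        100.0 * table["count"] / n_matched if n_matched else 0.0
    )
    return ScanResult(matches, table, n_input, n_prefiltered, n_matched, n_rejects)
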