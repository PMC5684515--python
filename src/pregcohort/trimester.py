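"""Rule-based gestational-age inference from pregnancy-progress statements.

Users frequently post explicit progress statements ("25 weeks pregnant",
"6 weeks into the pregnancy").  The detector scans each post for the seed
terms "pregnant"/"pregnancy", collects the tokens in a symmetric context
window around the seed (default 6 tokens on each side), and emits a progress
mention when the window holds both a temporal unit (week/month/day) and a
number mention.  The number-unit pair (nearest number preceding the unit)
yields the gestational week:

* week unit: the quantity itself, plus days/7 when a day pair co-occurs
  ("39 weeks and 6 days");
* month unit (used only when no week pair exists): quantity x 4.345, the mean
  number of weeks per calendar month;
* day unit alone: accepted only in "since"-style phrasings, as quantity / 7.

Mentions converting outside [1, 45] gestational weeks are rejected.  The
pregnancy start date of a timeline is the median of the per-mention
candidates (post timestamp minus 7 x gestational week days), with the median
absolute deviation reported so callers can drop unreliable estimates (jokes,
quotes and third-person statements produce dispersed candidates).  Trimester
boundaries: first = weeks 1-12, second = weeks 13-27, third = week 28 to
birth, with a 40-week term for the post-birth boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable

import numpy as np

from .features import preprocess
from .posts import Post, Timeline

WEEKS_PER_MONTH = 4.345

PHASES = ("pre", "T1", "T2", "T3", "post")
TRIMESTER_PHASES = ("T1", "T2", "T3")

SEED_TERMS = ("pregnant", "pregnancy")

_UNIT_OF = {
    "week": "week", "weeks": "week", "wk": "week", "wks": "week",
    "month": "month", "months": "month",
    "day": "day", "days": "day",
}

_ONES = "one two three four five six seven eight nine".split()
_TEENS = ("ten eleven twelve thirteen fourteen fifteen sixteen seventeen "
          "eighteen nineteen").split()
_NUMBER_WORDS: dict[str, int] = {w: i + 1 for i, w in enumerate(_ONES)}
_NUMBER_WORDS.update({w: i + 10 for i, w in enumerate(_TEENS)})
for tens_word, tens_val in (("twenty", 20), ("thirty", 30), ("forty", 40)):
    _NUMBER_WORDS[tens_word] = tens_val
    for ones_word, ones_val in zip(_ONES, range(1, 10)):
        _NUMBER_WORDS[f"{tens_word}-{ones_word}"] = tens_val + ones_val
        _NUMBER_WORDS[f"{tens_word}{ones_word}"] = tens_val + ones_val

_DIGITS = re.compile(r"^(\d+(?:\.\d+)?)(?:st|nd|rd|th)?$")
_SEGMENT = re.compile(r"\d+|[a-z']+")

#: vocabulary for greedy segmentation of hashtag letter runs
_HASHTAG_VOCAB = sorted(
    {"week", "weeks", "month", "months", "day", "days",
     "pregnant", "pregnancy", "to", "go", "left"},
    key=len,
    reverse=True,
)


def _segment_letter_run(run: str) -> list[str]:
    """Greedy longest-prefix split of a hashtag letter run over the temporal
    vocabulary; unknown stretches are kept whole."""
    out: list[str] = []
    buffer = ""
    i = 0
    while i < len(run):
        for word in _HASHTAG_VOCAB:
            if run.startswith(word, i):
                if buffer:
                    out.append(buffer)
                    buffer = ""
                out.append(word)
                i += len(word)
                break
        else:
            buffer += run[i]
            i += 1
    if buffer:
        out.append(buffer)
    return out


def parse_number(token: str) -> float | None:
    """Numeric value of a digit string, ordinal or number word; else None."""
    m = _DIGITS.match(token)
    if m:
        return float(m.group(1))
    value = _NUMBER_WORDS.get(token)
    if value is None and token.endswith(("st", "nd", "rd", "th")):
        value = _NUMBER_WORDS.get(token[:-2])
    return float(value) if value is not None else None


@dataclass(frozen=True)
class TrimesterRule:
    t1_end_week: float = 12.0
    t2_end_week: float = 27.0
    term_length_weeks: float = 40.0
    min_week: float = 1.0
    max_week: float = 45.0


@dataclass(frozen=True)
class ExtractionConfig:
    window: int = 6
    window_mode: str = "per_side"  # or "total"
    hashtag_segmentation: bool = False
    countdown_phrases: bool = False
    rule: TrimesterRule = field(default_factory=TrimesterRule)


@dataclass(frozen=True)
class ProgressMention:
    post_id: str
    seed_term: str
    quantity: float
    unit: str  # week | month | day
    window_tokens: tuple[str, ...]
    gestational_week: float
    timestamp: datetime


class MentionRejected(ValueError):
    """A number/unit pair converts outside the plausible gestational range."""


def gestational_weeks(quantity: float, unit: str, rule: TrimesterRule | None = None) -> float:
    """Convert a quantity/unit pair to gestational weeks; reject values
    outside [min_week, max_week]."""
    rule = rule or TrimesterRule()
    if unit == "week":
        weeks = quantity
    elif unit == "month":
        weeks = quantity * WEEKS_PER_MONTH
    elif unit == "day":
        weeks = quantity / 7.0
    else:
        raise ValueError(f"unknown unit {unit!r}")
    if not rule.min_week <= weeks <= rule.max_week:
        raise MentionRejected(
            f"{quantity} {unit}(s) -> {weeks:.2f} weeks outside "
            f"[{rule.min_week}, {rule.max_week}]"
        )
    return weeks


def assign_trimester(week: float, rule: TrimesterRule | None = None) -> int:
    """Trimester ordinal for a gestational week: 1 through week 12, 2 through
    week 27, 3 afterwards."""
    rule = rule or TrimesterRule()
    if not rule.min_week <= week <= rule.max_week:
        raise ValueError(f"week {week} outside [{rule.min_week}, {rule.max_week}]")
    if week <= rule.t1_end_week:
        return 1
    if week <= rule.t2_end_week:
        return 2
    return 3


def _tokenize(text: str, config: ExtractionConfig) -> list[str]:
    seq = preprocess(text)
    if not config.hashtag_segmentation:
        return seq.tokens
    tokens: list[str] = []
    for tok, marker in zip(seq.tokens, seq.markers):
        if marker == "#":
            for piece in _SEGMENT.findall(tok):
                if piece.isdigit():
                    tokens.append(piece)
                else:
                    tokens.extend(_segment_letter_run(piece))
        else:
            tokens.append(tok)
    return tokens


def extract_progress_mentions(
    post: Post, config: ExtractionConfig | None = None
) -> list[ProgressMention]:
    """Progress mentions from one post: one per seed occurrence whose context
    window holds a temporal unit with a preceding number mention."""
    config = config or ExtractionConfig()
    tokens = _tokenize(post.text, config)
    half = config.window if config.window_mode == "per_side" else config.window // 2
    mentions: list[ProgressMention] = []
    for i, tok in enumerate(tokens):
        if tok not in SEED_TERMS:
            continue
        lo, hi = max(0, i - half), min(len(tokens), i + half + 1)
        window = tokens[lo:hi]
        pairs: dict[str, float] = {}
        countdown = False
        for j in range(lo, hi):
            unit = _UNIT_OF.get(tokens[j])
            if unit is None:
                continue
            number = None
            for p in range(j - 1, lo - 1, -1):
                number = parse_number(tokens[p])
                if number is not None:
                    break
            if number is None:
                continue
            if unit not in pairs:
                pairs[unit] = number
                if config.countdown_phrases and (
                    tokens[j + 1 : j + 3] == ["to", "go"]
                    or tokens[j + 1 : j + 2] in (["left"], ["togo"])
                ):
                    countdown = True
        if not pairs:
            continue
        if "week" in pairs:
            unit, quantity = "week", pairs["week"] + pairs.get("day", 0.0) / 7.0
        elif "month" in pairs:
            unit, quantity = "month", pairs["month"]
        elif "since" in window:  # day-only: accepted in "since"-style phrasing
            unit, quantity = "day", pairs["day"]
        else:
            continue
        try:
            if countdown and unit == "week":
                quantity = config.rule.term_length_weeks - quantity
            weeks = gestational_weeks(quantity, unit, config.rule)
        except MentionRejected:
            continue
        mentions.append(
            ProgressMention(
                post_id=post.id,
                seed_term=tok,
                quantity=quantity,
                unit=unit,
                window_tokens=tuple(window),
                gestational_week=weeks,
                timestamp=post.timestamp,
            )
        )
    return mentions


@dataclass
class PregnancyEstimate:
    user_id: str
    start_date: datetime
    supporting_mentions: list[ProgressMention]
    dispersion_days: float


def estimate_pregnancy_start(
    timeline: Timeline, config: ExtractionConfig | None = None
) -> PregnancyEstimate | None:
    """Median of per-mention start-date candidates; None when the timeline
    contains no valid progress mention."""
    config = config or ExtractionConfig()
    mentions: list[ProgressMention] = []
    for post in timeline:
        mentions.extend(extract_progress_mentions(post, config))
    if not mentions:
        return None
    candidates = np.array(
        [
            (m.timestamp - timedelta(days=7.0 * m.gestational_week)).timestamp()
            for m in mentions
        ]
    )
    median = float(np.median(candidates))
    mad_days = float(np.median(np.abs(candidates - median))) / 86400.0
    start = datetime.fromtimestamp(median, tz=mentions[0].timestamp.tzinfo)
    return PregnancyEstimate(
        user_id=timeline.user_id,
        start_date=start,
        supporting_mentions=mentions,
        dispersion_days=mad_days,
    )


def phase_of_elapsed_weeks(weeks: float, rule: TrimesterRule | None = None) -> str:
    """Pregnancy phase for a time offset from the start date, in weeks."""
    rule = rule or TrimesterRule()
    if weeks < rule.min_week:
        return "pre"
    if weeks <= rule.t1_end_week:
        return "T1"
    if weeks <= rule.t2_end_week:
        return "T2"
    if weeks <= rule.term_length_weeks:
        return "T3"
    return "post"


def categorize_timeline(
    timeline: Timeline,
    estimate: PregnancyEstimate,
    rule: TrimesterRule | None = None,
) -> dict[str, str]:
    """Phase label (pre, T1, T2, T3, post) for every post, from the elapsed
    weeks between the estimated start date and the post timestamp."""
    rule = rule or TrimesterRule()
    phases: dict[str, str] = {}
    for post in timeline:
        elapsed = (post.timestamp - estimate.start_date).total_seconds() / (7 * 86400)
        phases[post.id] = phase_of_elapsed_weeks(elapsed, rule)
    return phases


def analyze_timelines(
    timelines: Iterable[Timeline], config: ExtractionConfig | None = None
) -> dict[str, tuple[PregnancyEstimate | None, dict[str, str]]]:
    """Start estimate plus per-post phases for each timeline (phases empty
    when no estimate could be made)."""
    config = config or ExtractionConfig()
    out: dict[str, tuple[PregnancyEstimate | None, dict[str, str]]] = {}
    for tl in timelines:
        est = estimate_pregnancy_start(tl, config)
        phases = categorize_timeline(tl, est, config.rule) if est else {}
        out[tl.user_id] = (est, phases)
    return out
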