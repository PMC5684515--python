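"""Gestational-age rules: extraction worked examples, unit conversions,
boundary mapping, start-date estimation and timeline categorization."""

from datetime import datetime, timedelta, timezone

import pytest

from pregcohort.posts import Post, Timeline
from pregcohort.trimester import (
    ExtractionConfig,
    MentionRejected,
    TrimesterRule,
    assign_trimester,
    categorize_timeline,
    estimate_pregnancy_start,
    extract_progress_mentions,
    gestational_weeks,
    parse_number,
    phase_of_elapsed_weeks,
)

TS = datetime(2017, 3, 1, tzinfo=timezone.utc)


def post(text, ts=TS, pid="p1", uid="u1"):
    return Post(pid, uid, ts, text)


# -- extraction -------------------------------------------------------------


@pytest.mark.parametrize(
    "text,quantity,unit,seed",
    [
        ("6 weeks into the pregnancy", 6.0, "week", "pregnancy"),
        ("Looking forward to #oneborneveryminute, love baby shows even if "
         "I am 25 weeks pregnant", 25.0, "week", "pregnant"),
        ("im six weeks pregnant today", 6.0, "week", "pregnant"),
        ("i am 2 months pregnant", 2.0, "month", "pregnant"),
        ("the 25th week of pregnancy treating me well", 25.0, "week", "pregnancy"),
    ],
)
def test_extracts_number_unit_seed(text, quantity, unit, seed):
    mentions = extract_progress_mentions(post(text))
    assert len(mentions) == 1
    m = mentions[0]
    assert (m.quantity, m.unit, m.seed_term) == (quantity, unit, seed)


@pytest.mark.parametrize(
    "text",
    [
        "love my baby so much",          # no seed term
        "pregnant",                      # no number/unit in window
        "pregnant and happy today",      # still no number
        "week 6 of the new job",         # no seed term
    ],
)
def test_no_mention_cases(text):
    assert extract_progress_mentions(post(text)) == []


def test_week_plus_day_combination():
    (m,) = extract_progress_mentions(
        post("im currently 39 weeks and 6 days pregnant")
    )
    assert m.gestational_week == pytest.approx(39 + 6 / 7)


def test_day_unit_requires_since_phrasing():
    accepted = extract_progress_mentions(post("been 10 days since i got pregnant"))
    assert len(accepted) == 1
    assert accepted[0].gestational_week == pytest.approx(10 / 7)
    rejected = extract_progress_mentions(post("10 days pregnant lol"))
    assert rejected == []


def test_number_outside_window_is_not_paired():
    text = "been 21 days since i found out that im pregnant"
    # "21" sits more than 6 tokens before the seed
    assert extract_progress_mentions(post(text)) == []


def test_hashtag_segmentation_opt_in():
    text = "i am not burnt as i am mainly inside #37weekspregnant"
    assert extract_progress_mentions(post(text)) == []
    config = ExtractionConfig(hashtag_segmentation=True)
    (m,) = extract_progress_mentions(post(text), config)
    assert m.gestational_week == 37.0


def test_countdown_phrase_opt_in():
    text = "nothing like a tiny baby reminder of my pregnancy #10weekstogo"
    config = ExtractionConfig(hashtag_segmentation=True, countdown_phrases=True)
    (m,) = extract_progress_mentions(post(text), config)
    assert m.gestational_week == pytest.approx(30.0)  # 40-week term minus 10


def test_number_words_and_ordinals():
    assert parse_number("six") == 6
    assert parse_number("twenty-five") == 25
    assert parse_number("25th") == 25
    assert parse_number("hello") is None


# -- conversions and boundaries --------------------------------------------


def test_gestational_week_conversions():
    assert gestational_weeks(25, "week") == 25
    assert gestational_weeks(6, "month") == pytest.approx(26.07, abs=0.01)
    assert gestational_weeks(14, "day") == 2.0
    with pytest.raises(MentionRejected):
        gestational_weeks(50, "week")
    with pytest.raises(MentionRejected):
        gestational_weeks(2, "day")  # below one week


@pytest.mark.parametrize(
    "week,trimester",
    [(1, 1), (12, 1), (13, 2), (27, 2), (28, 3), (36, 3), (45, 3)],
)
def test_trimester_boundaries(week, trimester):
    assert assign_trimester(week) == trimester


def test_trimester_out_of_range_errors():
    for week in (0, 0.5, 46):
        with pytest.raises(ValueError):
            assign_trimester(week)


def test_assign_trimester_is_monotone():
    weeks = [1 + 0.5 * i for i in range(89)]  # 1 .. 45
    values = [assign_trimester(w) for w in weeks]
    assert values == sorted(values)


# -- start estimation -------------------------------------------------------


def test_single_mention_start_arithmetic():
    (est) = estimate_pregnancy_start(
        Timeline("u1", [post("im 25 weeks pregnant", ts=TS)])
    )
    assert est.start_date == TS - timedelta(days=175)
    assert est.dispersion_days == 0.0
    assert est.start_date < est.supporting_mentions[0].timestamp


def test_consistent_mentions_have_zero_dispersion():
    p1 = post("im 10 weeks pregnant", ts=TS, pid="a")
    p2 = post("im 12 weeks pregnant", ts=TS + timedelta(days=14), pid="b")
    est = estimate_pregnancy_start(Timeline("u1", [p1, p2]))
    assert est.dispersion_days == pytest.approx(0.0)
    assert est.start_date == TS - timedelta(days=70)


def test_median_is_robust_to_one_outlier():
    good = [
        post(f"im {w} weeks pregnant", ts=TS + timedelta(days=7 * (w - 10)), pid=f"g{w}")
        for w in (10, 12, 14)
    ]
    joke = post("ive been pregnant 40 weeks forever", ts=TS, pid="joke")
    est = estimate_pregnancy_start(Timeline("u1", good + [joke]))
    assert abs((est.start_date - (TS - timedelta(days=70))).days) <= 1


def test_no_mentions_returns_none():
    assert estimate_pregnancy_start(Timeline("u1", [post("hello world")])) is None


# -- categorization ---------------------------------------------------------


def test_phase_of_elapsed_weeks_rules():
    assert phase_of_elapsed_weeks(-2) == "pre"
    assert phase_of_elapsed_weeks(0.5) == "pre"
    assert phase_of_elapsed_weeks(10) == "T1"
    assert phase_of_elapsed_weeks(20) == "T2"
    assert phase_of_elapsed_weeks(30) == "T3"
    assert phase_of_elapsed_weeks(43) == "post"


def test_categorize_timeline_boundary_posts():
    start = TS
    mention = post("im 10 weeks pregnant", ts=start + timedelta(days=70), pid="m")
    others = {
        "before": post("old news", ts=start - timedelta(days=30), pid="before"),
        "week10": post("filler", ts=start + timedelta(days=70), pid="week10"),
        "week43": post("filler", ts=start + timedelta(days=301), pid="week43"),
    }
    tl = Timeline("u1", [mention, *others.values()])
    est = estimate_pregnancy_start(tl)
    phases = categorize_timeline(tl, est)
    assert phases["before"] == "pre"
    assert phases["week10"] == "T1"
    assert phases["week43"] == "post"


def test_phases_are_monotone_along_timeline():
    start = TS
    posts = [post("im 8 weeks pregnant", ts=start + timedelta(days=56), pid="m")]
    posts += [
        post("filler", ts=start + timedelta(days=d), pid=f"f{d}")
        for d in (-20, 10, 80, 150, 250, 300)
    ]
    tl = Timeline("u1", posts)
    phases = categorize_timeline(tl, estimate_pregnancy_start(tl))
    order = {"pre": 0, "T1": 1, "T2": 2, "T3": 3, "post": 4}
    ranks = [order[phases[p.id]] for p in tl]
    assert ranks == sorted(ranks)


def test_custom_term_length():
    rule = TrimesterRule(term_length_weeks=42)
    assert phase_of_elapsed_weeks(41, rule) == "T3"
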