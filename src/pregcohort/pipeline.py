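"""End-to-end cohort discovery: prefilter -> pattern match -> classify ->
roster -> longitudinal analyses.

The detection funnel is strictly narrowing: input posts >= posts passing the
seed prefilter >= pattern-matched posts >= positively classified posts; the
cohort roster holds every user owning at least one positively classified
matched post, with full provenance (triggering post ids, pattern ids,
classifier scores, detection date).  Storage is flat JSONL/CSV so a run is
reproducible byte-for-byte from its inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import PIT, ClassifierModel
from .features import FeatureResources, featurize_corpus
from .medications import DrugLexicon, count_drug_mentions
from .patterns import PatternRegistry, ScanResult, compile_pattern_registry, scan_corpus
from .posts import Post, Timeline, dedupe_posts
from .trimester import ExtractionConfig, analyze_timelines


@dataclass
class RosterEntry:
    user_id: str
    post_ids: list[str]
    pattern_ids: list[int]
    scores: list[float]
    detection_date: str  # ISO date of the earliest triggering post

    def to_record(self) -> dict:
        return {
            "user_id": self.user_id,
            "post_ids": self.post_ids,
            "pattern_ids": self.pattern_ids,
            "scores": self.scores,
            "detection_date": self.detection_date,
        }


@dataclass
class CohortRoster:
    entries: dict[str, RosterEntry] = field(default_factory=dict)

    def user_ids(self) -> list[str]:
        return sorted(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def write_jsonl(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for uid in self.user_ids():
                fh.write(json.dumps(self.entries[uid].to_record(), sort_keys=True) + "\n")


@dataclass
class DetectionReport:
    n_input: int
    n_deduped: int
    n_prefiltered: int
    n_matched: int
    n_classified_positive: int
    n_users: int
    n_rejects: int
    frequency_table: pd.DataFrame

    def stage_counts(self) -> dict[str, int]:
        return {
            "input": self.n_input,
            "deduped": self.n_deduped,
            "prefiltered": self.n_prefiltered,
            "matched": self.n_matched,
            "classified_positive": self.n_classified_positive,
            "roster_users": self.n_users,
        }


def run_detection(
    posts: Iterable[Post],
    model: ClassifierModel,
    resources: FeatureResources,
    registry: PatternRegistry | None = None,
    *,
    blocks: Sequence[str] | None = None,
    dedupe: bool = True,
    latin_filter: bool = False,
) -> tuple[CohortRoster, DetectionReport]:
    """Run the detection funnel over a post stream.

    Every roster entry is traceable: its post ids re-verify under
    ``match_patterns`` and ``model.predict`` in isolation.
    """
    registry = registry or compile_pattern_registry()
    posts = list(posts)
    n_input = len(posts)
    if dedupe:
        posts = dedupe_posts(posts)
    n_deduped = len(posts)
    scan: ScanResult = scan_corpus(posts, registry, latin_filter=latin_filter)
    matched_posts = [p for p, _m in scan.matches]
    if matched_posts:
        kwargs = {"blocks": blocks} if blocks else {}
        X = featurize_corpus(matched_posts, resources, **kwargs)
        labels, scores = model.predict(X)
    else:
        labels, scores = [], []
    roster = CohortRoster()
    n_positive = 0
    for (post, match), label, score in zip(scan.matches, labels, scores):
        if label != PIT:
            continue
        n_positive += 1
        entry = roster.entries.get(post.user_id)
        if entry is None:
            entry = RosterEntry(
                user_id=post.user_id,
                post_ids=[],
                pattern_ids=[],
                scores=[],
                detection_date=post.timestamp.date().isoformat(),
            )
            roster.entries[post.user_id] = entry
        entry.post_ids.append(post.id)
        entry.pattern_ids.extend(
            pid for pid in sorted(match.matched_pattern_ids)
            if pid not in entry.pattern_ids
        )
        entry.scores.append(float(score))
        entry.detection_date = min(
            entry.detection_date, post.timestamp.date().isoformat()
        )
    report = DetectionReport(
        n_input=n_input,
        n_deduped=n_deduped,
        n_prefiltered=scan.n_prefiltered,
        n_matched=scan.n_matched,
        n_classified_positive=n_positive,
        n_users=len(roster),
        n_rejects=scan.n_rejects,
        frequency_table=scan.frequency_table,
    )
    return roster, report


@dataclass
class TimelineAnalysisResult:
    estimates: pd.DataFrame        # user_id, start_date, n_mentions, dispersion_days
    phases: dict[str, dict[str, str]]  # user_id -> post_id -> phase
    medication_counts: pd.DataFrame
    detectable_fraction: float
    missing_users: list[str]


def run_timeline_analysis(
    roster: CohortRoster,
    timelines: Mapping[str, Timeline],
    lexicon: DrugLexicon,
    config: ExtractionConfig | None = None,
) -> TimelineAnalysisResult:
    """Trimester and medication analyses over the roster's timelines.

    Users without a timeline are reported as missing, not fatal.  The
    detectable fraction is the share of analyzed roster users whose timeline
    yields a pregnancy-start estimate.
    """
    config = config or ExtractionConfig()
    missing = [uid for uid in roster.user_ids() if uid not in timelines]
    available = [timelines[uid] for uid in roster.user_ids() if uid in timelines]
    analyzed = analyze_timelines(available, config)
    rows = []
    phases: dict[str, dict[str, str]] = {}
    n_detectable = 0
    for uid, (estimate, post_phases) in analyzed.items():
        if estimate is None:
            rows.append(
                {"user_id": uid, "start_date": None, "n_mentions": 0,
                 "dispersion_days": float("nan")}
            )
            continue
        n_detectable += 1
        phases[uid] = post_phases
        rows.append(
            {
                "user_id": uid,
                "start_date": estimate.start_date.date().isoformat(),
                "n_mentions": len(estimate.supporting_mentions),
                "dispersion_days": estimate.dispersion_days,
            }
        )
    estimates = pd.DataFrame(
        rows, columns=["user_id", "start_date", "n_mentions", "dispersion_days"]
    )
    med_counts = count_drug_mentions(available, phases, lexicon)
    fraction = n_detectable / len(available) if available else 0.0
    return TimelineAnalysisResult(
        estimates=estimates,
        phases=phases,
        medication_counts=med_counts,
        detectable_fraction=fraction,
        missing_users=missing,
    )
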