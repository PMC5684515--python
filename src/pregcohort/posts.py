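"""Core post and timeline containers plus JSON-lines input/output.

A post is the atomic unit everywhere in the pipeline: an opaque id, the
authoring user's id, a UTC timestamp and the raw text.  A timeline is the
time-ordered sequence of one user's posts and is the unit of longitudinal
analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Post:
    id: str
    user_id: str
    timestamp: datetime
    text: str

    def __post_init__(self) -> None:
        if self.timestamp.tzinfo is None:
            object.__setattr__(
                self, "timestamp", self.timestamp.replace(tzinfo=timezone.utc)
            )


@dataclass
class Timeline:
    """All posts by one user, sorted ascending by timestamp."""

    user_id: str
    posts: list[Post] = field(default_factory=list)

    def __post_init__(self) -> None:
        for p in self.posts:
            if p.user_id != self.user_id:
                raise ValueError(
                    f"post {p.id} belongs to {p.user_id}, not {self.user_id}"
                )
        self.posts.sort(key=lambda p: p.timestamp)

    def __len__(self) -> int:
        return len(self.posts)

    def __iter__(self) -> Iterator[Post]:
        return iter(self.posts)


def post_to_record(post: Post) -> dict:
    return {
        "id": post.id,
        "user_id": post.user_id,
        "created_at": post.timestamp.isoformat(),
        "text": post.text,
    }


def record_to_post(record: dict) -> Post:
    return Post(
        id=str(record["id"]),
        user_id=str(record["user_id"]),
        timestamp=datetime.fromisoformat(record["created_at"]),
        text=record["text"],
    )


def read_posts_jsonl(path: str | Path, *, rejects: list | None = None) -> Iterator[Post]:
    """Stream posts from a JSONL file; malformed lines are logged, skipped and
    appended to *rejects* when a list is supplied."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                yield record_to_post(json.loads(line))
            except (json.JSONDecodeError, KeyError, ValueError, TypeError) as exc:
                logger.warning("skipping malformed record at line %d: %s", lineno, exc)
                if rejects is not None:
                    rejects.append((lineno, line))


def write_posts_jsonl(posts: Iterable[Post], path: str | Path) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for post in posts:
            fh.write(json.dumps(post_to_record(post), ensure_ascii=False) + "\n")
            n += 1
    return n


def group_timelines(posts: Iterable[Post]) -> dict[str, Timeline]:
    """Group a post stream into per-user timelines."""
    by_user: dict[str, list[Post]] = {}
    for post in posts:
        by_user.setdefault(post.user_id, []).append(post)
    return {uid: Timeline(uid, plist) for uid, plist in by_user.items()}


def dedupe_posts(posts: Iterable[Post]) -> list[Post]:
    """Collapse duplicates (same user_id + text) to the earliest timestamp.

    Retweet-style noise produces exact user/text duplicates; keeping the
    earliest copy preserves the announcement time.
    """
    best: dict[tuple[str, str], Post] = {}
    order: list[tuple[str, str]] = []
    for post in posts:
        key = (post.user_id, post.text)
        if key not in best:
            best[key] = post
            order.append(key)
        elif post.timestamp < best[key].timestamp:
            best[key] = post
    return [best[k] for k in order]
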