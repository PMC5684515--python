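"""A small curated sample of annotated posts.

Twenty retrieval-positive posts with their consensus annotations: ``True``
marks a real first-person pregnancy indication, ``False`` a false positive
(third-person, figurative or hypothetical phrasing) that the query patterns
nevertheless retrieve.  Every text is matched by at least one default query
pattern; the sample covers all 14 patterns on the positive side and is useful
for demos, smoke tests and documentation.
"""

from __future__ import annotations

from datetime import datetime, timezone

from .posts import Post

#: (text, is_pregnancy_indication)
SAMPLE_ANNOTATED_TEXTS: list[tuple[str, bool]] = [
    ("one month today (give or take) I am going to be a mom...I can not wait "
     "to see what my baby girl looks like :-)", True),
    ("So I thought I would let Twitter know that I am expecting a baby in "
     "eight months!!!", True),
    ("this belly and the sweet baby growing inside is the best christmas gift "
     "I could ever ask for!!! Merry Christmas e...", True),
    ("been 3 weeks since I've heard bebes heart or seen it. So sometimes I "
     "don't feel pregnant but this new stretch mark is proving otherwise", True),
    ("Just s few short months from adding another one to our family!", True),
    ("Ready for Christmas and pumped to announce that baby boy **** will be "
     "arriving May 2017! #MC3", True),
    ("Pregnancy announcement Our family is growing by 2 feet and 1 heart", True),
    ("Hoping & praying for a solution to income issues. Baby coming soon! "
     "Need better #job & better #pay", True),
    ("i literally cannot wrap my head around the fact that I am going to have "
     "a baby in 16 days or less..", True),
    ("so I am having a baby and super excited", True),
    ("swear since I have been pregnant everyone's forgot about me and doesn't "
     "involve me in anything", True),
    ("well... im currently 39 weeks and 6 days pregnant... you can come any "
     "time now sweetie", True),
    ("i just took my pregnancy cravings to a whole new level: I put ranch on "
     "my macaroni and cheese. #Yummmmmmmm", True),
    ("i'm so crafty since I've been pregnant before I couldn't even color a "
     "rainbow.", True),
    ("forever amazed at the number of women that ask me when I am going to "
     "have a baby instead of asking me about my career goals.", False),
    ("i swear I've been pregnant for 2 years now. #theobesityneedstostop "
     "#ineedwine", False),
    ("I'm having a baby JB day and it's killing me. I love him so much "
     "@justinbieber", False),
    ("my sister is five weeks and three days pregnant. I’m going to be an "
     "auntie oh my god", False),
    ("girls will be two days pregnant already posting pictures talking bout "
     "“I’m getting big.”", False),
    ("Cant believe im having a baby brother!", False),
]


def sample_posts() -> list[Post]:
    """The curated sample as Post objects (synthetic ids/users/timestamps)."""
    t0 = datetime(2016, 12, 1, tzinfo=timezone.utc)
    return [
        Post(id=f"sample-{i:02d}", user_id=f"sample-user-{i:02d}",
             timestamp=t0.replace(day=1 + i), text=text)
        for i, (text, _label) in enumerate(SAMPLE_ANNOTATED_TEXTS)
    ]


def sample_labels() -> list[bool]:
    return [label for _text, label in SAMPLE_ANNOTATED_TEXTS]
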