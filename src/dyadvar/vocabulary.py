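"""Controlled vocabulary of behavior codes for mother-infant dyadic coding.

The study design codes 26 behaviors per dyad-month: 15 infant behaviors
(postural, locomotor, vocal, and three dyadic play frames) and 11 maternal
behaviors (physical handling, object mediation, speech, and touch). The
order of :data:`ALL_CODES` is the canonical variable order of every panel
and therefore the default Cholesky ordering downstream.
"""

from __future__ import annotations

INFANT_CODES: tuple[str, ...] = (
    "Stand (Object support)",
    "Stand (Mother help)",
    "Stand Independently",
    "Sit (Object support)",
    "Sit (Mother help)",
    "Sit Independently",
    "Lie (All)",
    "Lie Still",
    "Babble",
    "Cry",
    "Reach",
    "Crawl",
    "Play (Passive)",
    "Play (Motor-Social)",
    "Play (Object)",
)

MATERNAL_CODES: tuple[str, ...] = (
    "Rocks/Jiggles",
    "Lifts Infant",
    "Assists Locomotion",
    "Stimulates Gross Motor",
    "Shifts Infant",
    "Holds Object",
    "Points to Object",
    "Offers Object",
    "Manipulates Object",
    "Speech to Infant",
    "Affectionate Touch",
)

ALL_CODES: tuple[str, ...] = INFANT_CODES + MATERNAL_CODES

GROUPS: tuple[str, ...] = ("boy", "girl")

#: Valid encodings of a behavior code into a monthly value.
ENCODINGS: tuple[str, ...] = ("duration_seconds", "occurrence_count")


def canonical_group(label: str) -> str:
    """Canonicalize a group label (case-insensitive) to ``boy``/``girl``."""
    g = str(label).strip().lower()
    if g not in GROUPS:
        raise ValueError(f"unknown group label {label!r}; expected one of {GROUPS}")
    return g
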