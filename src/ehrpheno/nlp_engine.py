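"""Rule-based detection of sarcopenia, cachexia and frailty mentions in clinical notes.

The detector is deliberately transparent: a lexicon of surface forms
(grammatical variants plus single-edit misspellings), word-boundary matching,
and a NegEx-style sentence-bounded trigger window for negation, third-person
attribution and hedging.  No statistical NER, no coreference.

Labels follow the clinical chart-review convention:

* ``positive`` — the note author attributes the condition to the patient;
* ``negative`` — the condition is negated ("not sarcopenic") or refers to
  someone other than the patient ("her frail mother");
* ``uncertain`` — hedged ("possible cachexia", "frailty?").
"""

from __future__ import annotations

import bisect
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

CONDITIONS = ("sarcopenia", "cachexia", "frailty")

#: Default surface forms per condition (lowercase; grammatical variants).
DEFAULT_CANONICAL_FORMS: dict[str, tuple[str, ...]] = {
    "sarcopenia": ("sarcopenia", "sarcopenic"),
    "cachexia": ("cachexia", "cachectic"),
    "frailty": ("frailty", "frail"),
}

#: Common English words that a single-character edit of a lexicon form may
#: produce; such variants are dropped to bound false positives.
STOP_WORDS = frozenset(
    """
    a an and are as at be but by for from had has have he her his i in is it
    its not of on or she that the their them they this to was we were will
    with you
    fail fails failed rail rails trail trails grail flail frill brain
    braille cache caches cachet cachets
    """.split()
)

ALPHABET = "abcdefghijklmnopqrstuvwxyz"

LABEL_POSITIVE = "positive"
LABEL_NEGATIVE = "negative"
LABEL_UNCERTAIN = "uncertain"
MENTION_LABELS = (LABEL_POSITIVE, LABEL_NEGATIVE, LABEL_UNCERTAIN)

# NegEx-style triggers.  Pre-triggers act within 5 tokens before the term,
# post-triggers within 5 tokens after, both bounded by the sentence.
PRE_NEGATION_TRIGGERS = (
    "no",
    "not",
    "without",
    "denies",
    "no evidence of",
    "ruled out",
    "negative for",
)
POST_NEGATION_TRIGGERS = (
    "was not present",
    "is absent",
)
#: Kinship / caregiver cues: a term in the same sentence as one of these is
#: attributed to someone other than the patient.
THIRD_PERSON_CUES = (
    "mother",
    "father",
    "sister",
    "brother",
    "wife",
    "husband",
    "son",
    "daughter",
    "grandmother",
    "grandfather",
    "aunt",
    "uncle",
    "caregiver",
    "family member",
)
HEDGE_TRIGGERS = ("possible", "possibly", "questionable", "may have", "?")

#: Hedge adjacency: tokens before / after the term considered "adjacent".
_HEDGE_PRE_WINDOW = 3
_HEDGE_POST_WINDOW = 2
_NEGATION_WINDOW = 5

_TOKEN_RE = re.compile(r"\w+|\?")
_SENTENCE_SPLIT_RE = re.compile(r"[.;!?](?:\s+|$)|\n+")


def edit_distance_one(word: str) -> set[str]:
    """All strings at Damerau edit distance exactly 1 from ``word``
    (substitution, deletion, insertion, adjacent transposition)."""
    splits = [(word[:i], word[i:]) for i in range(len(word) + 1)]
    deletes = {a + b[1:] for a, b in splits if b}
    transposes = {a + b[1] + b[0] + b[2:] for a, b in splits if len(b) > 1}
    replaces = {a + c + b[1:] for a, b in splits if b for c in ALPHABET}
    inserts = {a + c + b for a, b in splits for c in ALPHABET}
    return (deletes | transposes | replaces | inserts) - {word}


@dataclass(frozen=True)
class Lexicon:
    """Surface-form → condition lookup, including misspelling variants.

    ``forms`` maps every detectable lowercase surface form to its condition.
    Canonical forms always survive variant generation (closure); variants
    colliding with a stop word or with another condition's neighbourhood are
    dropped deterministically.
    """

    forms: Mapping[str, str]
    canonical: Mapping[str, tuple[str, ...]]
    max_edit_distance: int

    def __contains__(self, form: str) -> bool:
        return form.lower() in self.forms

    def condition_of(self, form: str) -> str | None:
        return self.forms.get(form.lower())

    def __len__(self) -> int:
        return len(self.forms)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "max_edit_distance": self.max_edit_distance,
            "canonical": {c: list(v) for c, v in self.canonical.items()},
            "forms": dict(sorted(self.forms.items())),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "Lexicon":
        payload = json.loads(Path(path).read_text())
        return cls(
            forms=payload["forms"],
            canonical={c: tuple(v) for c, v in payload["canonical"].items()},
            max_edit_distance=payload["max_edit_distance"],
        )


def build_lexicon(
    canonical_forms: Mapping[str, Sequence[str]] | None = None,
    max_edit_distance: int = 1,
) -> Lexicon:
    """Build the detection lexicon.

    Misspelling variants (edit distance 1) are generated only for forms longer
    than 5 characters; shorter forms ("frail") are too close to ordinary
    English to expand safely.
    """
    if canonical_forms is None:
        canonical_forms = DEFAULT_CANONICAL_FORMS
    if max_edit_distance not in (0, 1):
        raise ValueError(f"max_edit_distance must be 0 or 1, got {max_edit_distance}")
    canon: dict[str, tuple[str, ...]] = {}
    for condition, forms in canonical_forms.items():
        forms = tuple(f.lower() for f in forms)
        if not forms:
            raise ValueError(f"empty canonical form list for condition {condition!r}")
        canon[condition] = forms

    mapping: dict[str, str] = {}
    for condition, forms in canon.items():
        for form in forms:
            if mapping.get(form, condition) != condition:
                raise ValueError(f"canonical form {form!r} shared by two conditions")
            mapping[form] = condition

    if max_edit_distance == 1:
        canonical_set = set(mapping)
        variant_owner: dict[str, set[str]] = {}
        for condition, forms in canon.items():
            for form in forms:
                if len(form) <= 5:
                    continue
                for variant in edit_distance_one(form):
                    if variant in STOP_WORDS or variant in canonical_set:
                        continue
                    variant_owner.setdefault(variant, set()).add(condition)
        for variant in sorted(variant_owner):
            owners = variant_owner[variant]
            if len(owners) == 1:  # cross-condition collisions dropped
                mapping[variant] = next(iter(owners))

    return Lexicon(forms=mapping, canonical=canon, max_edit_distance=max_edit_distance)


@dataclass
class Mention:
    """One detected appearance of a condition term in a note.

    ``start``/``end`` are 0-based half-open character offsets into the note
    text; ``offset_in_sentence`` locates the term within ``sentence`` so that
    classification is a pure function of the sentence.
    """

    note_id: str
    patient_id: str
    condition: str
    start: int
    end: int
    form: str
    sentence: str
    offset_in_sentence: int
    label: str | None = None


def sentence_spans(text: str) -> list[tuple[int, int]]:
    """Half-open character spans of sentences.

    Sentences break on ``. ; ! ?`` followed by whitespace (or end of text) and
    on newlines — clinical notes are newline-heavy.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENTENCE_SPLIT_RE.finditer(text):
        end = m.start() + (1 if text[m.start()] in ".;!?" else 0)
        if end > start:
            spans.append((start, end))
        start = m.end()
    if start < len(text):
        spans.append((start, len(text)))
    return spans


def find_mentions(
    text: str,
    lexicon: Lexicon,
    note_id: str = "",
    patient_id: str = "",
) -> list[Mention]:
    """Find all non-overlapping, word-boundary-delimited lexicon matches.

    Matching is case-insensitive and punctuation-tolerant.  Because every
    lexicon form is a single alphabetic token, scanning maximal word tokens
    and looking each up in the lexicon is exactly equivalent to
    boundary-anchored longest-match regex search, and runs in linear time.
    """
    if not text:
        return []
    spans = sentence_spans(text)
    sentence_starts = [s for s, _ in spans]
    mentions: list[Mention] = []
    for tok in re.finditer(r"\w+", text):
        form = tok.group(0).lower()
        condition = lexicon.forms.get(form)
        if condition is None:
            continue
        i = bisect.bisect_right(sentence_starts, tok.start()) - 1
        s_start, s_end = spans[i] if 0 <= i < len(spans) else (0, len(text))
        mentions.append(
            Mention(
                note_id=note_id,
                patient_id=patient_id,
                condition=condition,
                start=tok.start(),
                end=tok.end(),
                form=form,
                sentence=text[s_start:s_end],
                offset_in_sentence=tok.start() - s_start,
            )
        )
    return mentions


def _phrase_in_tokens(tokens: Sequence[str], phrase: str) -> bool:
    parts = phrase.split()
    n = len(parts)
    return any(list(tokens[i : i + n]) == parts for i in range(len(tokens) - n + 1))


def classify_mention(mention: Mention) -> str:
    """Assign positive / negative / uncertain to a mention.

    Order of precedence: negation trigger in window → negative; third-person
    cue in sentence → negative; hedge adjacent → uncertain; else positive.
    The function depends only on the mention's sentence.
    """
    sentence = mention.sentence.lower()
    toks = [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(sentence)]
    words = [t for t, _ in toks]
    # index of the term token within the sentence token list
    term_idx = 0
    for i, (_, pos) in enumerate(toks):
        if pos == mention.offset_in_sentence:
            term_idx = i
            break
        if pos > mention.offset_in_sentence:
            term_idx = max(0, i - 1)
            break
    else:
        term_idx = max(0, len(toks) - 1)

    pre = words[max(0, term_idx - _NEGATION_WINDOW) : term_idx]
    post = words[term_idx + 1 : term_idx + 1 + _NEGATION_WINDOW]
    for trigger in PRE_NEGATION_TRIGGERS:
        if _phrase_in_tokens(pre, trigger):
            return LABEL_NEGATIVE
    for trigger in POST_NEGATION_TRIGGERS:
        if _phrase_in_tokens(post, trigger):
            return LABEL_NEGATIVE
    for cue in THIRD_PERSON_CUES:
        if _phrase_in_tokens(words, cue):
            return LABEL_NEGATIVE
    hedge_pre = words[max(0, term_idx - _HEDGE_PRE_WINDOW) : term_idx]
    hedge_post = words[term_idx + 1 : term_idx + 1 + _HEDGE_POST_WINDOW]
    for hedge in HEDGE_TRIGGERS:
        if _phrase_in_tokens(hedge_pre, hedge) or _phrase_in_tokens(hedge_post, hedge):
            return LABEL_UNCERTAIN
    return LABEL_POSITIVE


def scan_notes(notes: Iterable[Mapping], lexicon: Lexicon) -> list[Mention]:
    """Run detection + classification over note records.

    ``notes`` yields mappings with ``note_id``, ``patient_id`` and ``text``
    (e.g. rows of notes.jsonl).  Returns labelled mentions ordered by
    (note_id, span start).
    """
    out: list[Mention] = []
    for note in notes:
        for mention in find_mentions(
            note["text"], lexicon, note_id=str(note["note_id"]), patient_id=str(note["patient_id"])
        ):
            mention.label = classify_mention(mention)
            out.append(mention)
    return out


def mentions_to_frame(mentions: Sequence[Mention]):
    """Mentions as a DataFrame with the mentions.csv column contract."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "note_id": m.note_id,
                "patient_id": m.patient_id,
                "condition": m.condition,
                "start": m.start,
                "end": m.end,
                "form": m.form,
                "label": m.label,
            }
            for m in mentions
        ],
        columns=["note_id", "patient_id", "condition", "start", "end", "form", "label"],
    )
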