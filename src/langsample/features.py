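"""Discourse measures computed from a parsed language sample.

Ten analysis measures (grouped by the latent factor each belongs to) plus
five descriptive measures:

==================  =====================================================
Factor / group      Measure
==================  =====================================================
Semantic            percent nouns, percent verbs, pronoun index
Syntax              verb index, proposition density, grammatical
                    complexity
Lexical             type-token ratio, number of unique words, semantic
                    unit count (SUID)
Fluency             maze index
Descriptive         total words, total semantic units, MLU, words per
                    minute, semantic units per minute
==================  =====================================================

All content measures are computed over non-maze material only: tokens inside
retraces, filled pauses, and other non-word vocalizations contribute to the
maze counts and to nothing else.  Ratios with a zero denominator are
reported as missing (``None``), never as zero.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, fields
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml

from .chat_io import Transcript

__all__ = [
    "ContentUnitLexicon",
    "default_lexicon",
    "CountSummary",
    "FeatureVector",
    "tally_counts",
    "match_semantic_units",
    "iter_unit_mentions",
    "derive_features",
    "extract_features",
    "feature_table",
    "FEATURE_COLUMNS",
    "MEASURE_NAMES",
]

_WORD_POS = (
    "noun",
    "verb",
    "pronoun",
    "adjective",
    "adverb",
    "preposition",
    "conjunction",
    "determiner",
    "other",
)

#: The ten factor-analysis measures, in documented order.
MEASURE_NAMES = (
    "percent_nouns",
    "percent_verbs",
    "pronoun_index",
    "verb_index",
    "proposition_density",
    "grammatical_complexity",
    "type_token_ratio",
    "unique_words",
    "semantic_unit_count",
    "maze_index",
)


class ContentUnitLexicon:
    """Maps content-unit identifiers to trigger lemma patterns.

    Each trigger is a tuple of lemmas; a unit is matched when any of its
    triggers occurs contiguously in a C-unit's non-maze lemma sequence.
    """

    def __init__(self, units: Mapping[str, Sequence[Sequence[str] | str]]):
        if not units:
            raise ValueError("lexicon must contain at least one unit")
        self.units: dict[str, tuple[tuple[str, ...], ...]] = {}
        for unit_id, patterns in units.items():
            parsed = []
            for pat in patterns:
                words = (pat,) if isinstance(pat, str) else tuple(pat)
                if not words or any(not w for w in words):
                    raise ValueError(f"unit {unit_id!r}: empty trigger pattern")
                parsed.append(tuple(w.lower() for w in words))
            if not parsed:
                raise ValueError(f"unit {unit_id!r} has no trigger patterns")
            self.units[unit_id] = tuple(parsed)

    def __len__(self) -> int:
        return len(self.units)

    def __contains__(self, unit_id: str) -> bool:
        return unit_id in self.units

    def trigger_words(self) -> set[str]:
        """Every lemma appearing in any trigger pattern."""
        return {w for pats in self.units.values() for pat in pats for w in pat}

    def single_word_units(self) -> dict[str, str]:
        """Units that have at least one single-lemma trigger (unit -> lemma)."""
        out = {}
        for unit_id, pats in self.units.items():
            for pat in pats:
                if len(pat) == 1:
                    out[unit_id] = pat[0]
                    break
        return out

    @classmethod
    def from_yaml(cls, path) -> "ContentUnitLexicon":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(doc["units"] if "units" in doc else doc)


def default_lexicon() -> ContentUnitLexicon:
    """The packaged Cookie Theft content-unit checklist."""
    ref = importlib.resources.files("langsample").joinpath("data/cookie_theft.yaml")
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return ContentUnitLexicon(doc["units"])


@dataclass
class CountSummary:
    """Raw tallies over one transcript; numerators and denominators for the
    discourse measures."""

    total_words: int
    unique_words: int
    n_utterances: int
    nouns: int
    verbs: int
    pronouns: int
    adjectives: int
    adverbs: int
    prepositions: int
    conjunctions: int
    determiners: int
    other_words: int
    filled_pauses: int
    unfilled_pauses: int
    repetitions: int
    revisions: int
    false_starts: int
    embedding_relations: int
    total_relations: int
    matched_content_units: int
    duration_s: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"{f.name} must be non-negative")
        if self.unique_words > self.total_words:
            raise ValueError("unique_words cannot exceed total_words")
        if self.embedding_relations > self.total_relations:
            raise ValueError("embedding_relations cannot exceed total_relations")
        pos_total = (
            self.nouns + self.verbs + self.pronouns + self.adjectives
            + self.adverbs + self.prepositions + self.conjunctions
            + self.determiners + self.other_words
        )
        if pos_total != self.total_words:
            raise ValueError("POS counts must sum to total_words")


@dataclass
class FeatureVector:
    """The measure values for one sample; ``None`` marks an undefined ratio."""

    percent_nouns: float | None
    percent_verbs: float | None
    pronoun_index: float | None
    verb_index: float | None
    proposition_density: float | None
    grammatical_complexity: float | None
    type_token_ratio: float | None
    unique_words: float
    semantic_unit_count: float
    maze_index: float | None
    mlu: float | None
    words_per_minute: float | None
    semantic_units_per_minute: float | None
    total_words: float
    total_semantic_units: float

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


FEATURE_COLUMNS = tuple(f.name for f in fields(FeatureVector))


def _cunit_lemmas(cu) -> list[str]:
    return [t.lemma for t in cu.content_tokens()]


def iter_unit_mentions(t: Transcript, lexicon: ContentUnitLexicon) -> Iterator[str]:
    """Yield content-unit ids in order of occurrence (with repeats).

    Matching scans each C-unit's non-maze lemma sequence; multi-word triggers
    must occur on adjacent lemmas within one C-unit.
    """
    for cu in t.cunits:
        lemmas = _cunit_lemmas(cu)
        for i in range(len(lemmas)):
            for unit_id, patterns in lexicon.units.items():
                for pat in patterns:
                    if tuple(lemmas[i : i + len(pat)]) == pat:
                        yield unit_id
                        break


def match_semantic_units(t: Transcript, lexicon: ContentUnitLexicon) -> set[str]:
    """The set of content units mentioned at least once in the sample."""
    return set(iter_unit_mentions(t, lexicon))


def tally_counts(t: Transcript, lexicon: ContentUnitLexicon) -> CountSummary:
    """Tally words, POS classes, mazes, relations, and content units.

    Raises ``ValueError("empty sample")`` when the transcript contains no
    non-maze words at all.
    """
    t.validate()
    pos_counts = {p: 0 for p in _WORD_POS}
    surfaces: set[str] = set()
    total_words = 0
    maze = {k: 0 for k in ("filled_pause", "unfilled_pause", "repetition",
                           "revision", "false_start")}
    embed = total_rel = 0
    for cu in t.cunits:
        for tok in cu.content_tokens():
            total_words += 1
            pos_counts[tok.pos] += 1
            surfaces.add(tok.surface)
        for ev in cu.maze_events:
            maze[ev.kind] += 1
        for rel in cu.relations:
            total_rel += 1
            embed += rel.is_embedding
    if total_words == 0:
        raise ValueError("empty sample: transcript has no non-maze words")
    return CountSummary(
        total_words=total_words,
        unique_words=len(surfaces),
        n_utterances=len(t.cunits),
        nouns=pos_counts["noun"],
        verbs=pos_counts["verb"],
        pronouns=pos_counts["pronoun"],
        adjectives=pos_counts["adjective"],
        adverbs=pos_counts["adverb"],
        prepositions=pos_counts["preposition"],
        conjunctions=pos_counts["conjunction"],
        determiners=pos_counts["determiner"],
        other_words=pos_counts["other"],
        filled_pauses=maze["filled_pause"],
        unfilled_pauses=maze["unfilled_pause"],
        repetitions=maze["repetition"],
        revisions=maze["revision"],
        false_starts=maze["false_start"],
        embedding_relations=embed,
        total_relations=total_rel,
        matched_content_units=len(match_semantic_units(t, lexicon)),
        duration_s=t.duration_s,
    )


def derive_features(
    c: CountSummary, include_unfilled_pauses: bool = False
) -> FeatureVector:
    """Turn raw tallies into the measure values.

    ``include_unfilled_pauses`` optionally adds unfilled pauses to the maze
    index numerator; the default follows the index's stated definition
    (filled pauses, false starts, revisions, and repetitions only).
    """
    if c.total_words <= 0:
        raise ValueError("total_words must be positive")
    if c.n_utterances <= 0:
        raise ValueError("n_utterances must be positive")
    ref = c.nouns + c.pronouns
    propositions = c.verbs + c.adjectives + c.adverbs + c.prepositions + c.conjunctions
    maze_num = c.filled_pauses + c.false_starts + c.revisions + c.repetitions
    if include_unfilled_pauses:
        maze_num += c.unfilled_pauses
    return FeatureVector(
        percent_nouns=100.0 * c.nouns / c.total_words,
        percent_verbs=100.0 * c.verbs / c.total_words,
        pronoun_index=(c.pronouns / ref) if ref > 0 else None,
        verb_index=c.verbs / c.n_utterances,
        proposition_density=propositions / c.total_words,
        grammatical_complexity=(
            c.embedding_relations / c.total_relations if c.total_relations > 0 else None
        ),
        type_token_ratio=c.unique_words / c.total_words,
        unique_words=float(c.unique_words),
        semantic_unit_count=float(c.matched_content_units),
        maze_index=maze_num / c.n_utterances,
        mlu=c.total_words / c.n_utterances,
        words_per_minute=60.0 * c.total_words / c.duration_s,
        semantic_units_per_minute=60.0 * c.matched_content_units / c.duration_s,
        total_words=float(c.total_words),
        total_semantic_units=float(c.matched_content_units),
    )


def extract_features(
    t: Transcript,
    lexicon: ContentUnitLexicon | None = None,
    include_unfilled_pauses: bool = False,
) -> FeatureVector:
    """Full pipeline for one transcript: tally, match, derive."""
    if lexicon is None:
        lexicon = default_lexicon()
    return derive_features(
        tally_counts(t, lexicon), include_unfilled_pauses=include_unfilled_pauses
    )


def feature_table(
    transcripts: Iterable[Transcript],
    lexicon: ContentUnitLexicon | None = None,
    include_unfilled_pauses: bool = False,
) -> pd.DataFrame:
    """One row per (participant, visit); missing measures become NaN.

    Column order is ``participant_id``, ``visit_id``, then
    :data:`FEATURE_COLUMNS`.
    """
    if lexicon is None:
        lexicon = default_lexicon()
    rows = []
    for t in transcripts:
        fv = extract_features(t, lexicon, include_unfilled_pauses)
        row = {"participant_id": t.participant_id, "visit_id": t.visit_id}
        row.update(fv.as_dict())
        rows.append(row)
    df = pd.DataFrame(rows, columns=["participant_id", "visit_id", *FEATURE_COLUMNS])
    return df
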