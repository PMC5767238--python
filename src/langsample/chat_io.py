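"""Reading and writing of C-unit-segmented transcripts in a CHAT-style dialect.

The dialect supported here is a deliberately small subset of CHAT as used for
picture-description language samples:

* header lines ``@Begin``, ``@Participants``, ``@ID`` (``participant|visit``),
  ``@Duration`` (sample length in seconds, including examiner prompts) and
  ``@End``;
* one main line per C-unit (``*PAR:``), with the utterance terminator
  (``.``, ``?`` or ``!``) as the final item;
* examiner prompts on ``*INV:`` lines (counted, never analyzed);
* disfluency ("maze") coding on the main line:

  - ``&-um``          filled pause (non-word filler token),
  - ``(.)``           unfilled pause (no token),
  - ``word [/]`` or ``<w1 w2> [/]``   repetition retrace,
  - ``[//]``          revision retrace,
  - ``[/-]``          false start;

* a morphology tier ``%mor:`` with one ``pos|lemma`` entry per non-maze word,
  and a grammatical-relation tier ``%gra:`` with one ``dep|head|LABEL`` entry
  per non-maze word (1-based indices within the non-maze word sequence,
  head ``0`` marking the root).

Tokens are lower-cased at parse time and utterance terminators are not
tokens.  Retraced/repeated material and fillers are flagged ``in_maze`` and
excluded from the morphology and relation tiers, mirroring how language
sample analysis programs treat mazes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

__all__ = [
    "POS_TAGS",
    "MAZE_KINDS",
    "EMBEDDING_LABELS",
    "ChatError",
    "ChatParseError",
    "Token",
    "MazeEvent",
    "GrammaticalRelation",
    "CUnit",
    "Transcript",
    "parse_chat",
    "write_chat",
    "percent_agreement",
    "default_tagger",
]

#: Closed part-of-speech vocabulary.  ``nonword`` covers fillers and other
#: vocalizations that never count as words.
POS_TAGS = frozenset(
    {
        "noun",
        "verb",
        "pronoun",
        "adjective",
        "adverb",
        "preposition",
        "conjunction",
        "determiner",
        "other",
        "nonword",
    }
)

MAZE_KINDS = (
    "filled_pause",
    "unfilled_pause",
    "repetition",
    "revision",
    "false_start",
)

#: Grammatical-relation labels that mark a syntactic embedding (clausal
#: subjects, complements, and clausal modifiers, following the label scheme
#: of dependency annotation for language samples).
EMBEDDING_LABELS = frozenset(
    {"CSUBJ", "COMP", "XCOMP", "CMOD", "XMOD", "CPRED", "CJCT", "XJCT"}
)

_RETRACE_MARKS = {"[/]": "repetition", "[//]": "revision", "[/-]": "false_start"}
_MARK_FOR_KIND = {v: k for k, v in _RETRACE_MARKS.items()}
_TERMINATORS = (".", "?", "!")
_PROMPT_TEXT = "do you see anything else going on ?"


class ChatError(ValueError):
    """Invalid transcript content or structure."""


class ChatParseError(ChatError):
    """Malformed document; the message names the offending line."""


@dataclass(frozen=True)
class Token:
    surface: str
    lemma: str
    pos: str
    in_maze: bool = False
    is_filled_pause: bool = False

    def __post_init__(self) -> None:
        if not self.surface:
            raise ChatError("token surface must be non-empty")
        if self.pos not in POS_TAGS:
            raise ChatError(f"unknown POS tag {self.pos!r}")
        if self.is_filled_pause and self.pos != "nonword":
            raise ChatError("filled pauses must carry the 'nonword' POS tag")


@dataclass(frozen=True)
class MazeEvent:
    """One disfluency event.

    ``start``/``end`` delimit the half-open token span the event covers within
    its C-unit; an unfilled pause covers no tokens (``start == end`` gives the
    insertion point).
    """

    kind: str
    cunit_index: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in MAZE_KINDS:
            raise ChatError(f"unknown maze kind {self.kind!r}")
        if self.start < 0 or self.end < self.start:
            raise ChatError("invalid maze token span")
        if self.kind == "unfilled_pause" and self.end != self.start:
            raise ChatError("unfilled pauses cover no tokens")
        if self.kind != "unfilled_pause" and self.end == self.start:
            raise ChatError(f"{self.kind} maze must cover at least one token")


@dataclass(frozen=True)
class GrammaticalRelation:
    label: str
    head_index: int
    dependent_index: int
    is_embedding: bool = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.head_index == self.dependent_index:
            raise ChatError("a relation cannot link a token to itself")
        if self.is_embedding is None:
            object.__setattr__(self, "is_embedding", self.label in EMBEDDING_LABELS)


@dataclass
class CUnit:
    """A communication unit: an independent clause and all its modifiers."""

    tokens: list[Token] = field(default_factory=list)
    relations: list[GrammaticalRelation] = field(default_factory=list)
    maze_events: list[MazeEvent] = field(default_factory=list)
    terminator: str = "."

    def content_tokens(self) -> list[Token]:
        """Non-maze word tokens (the material all content measures use)."""
        return [t for t in self.tokens if not t.in_maze and t.pos != "nonword"]

    def non_maze_indices(self) -> list[int]:
        return [i for i, t in enumerate(self.tokens) if not t.in_maze]

    def validate(self, index: int) -> None:
        if self.terminator not in _TERMINATORS:
            raise ChatError(f"C-unit {index}: bad terminator {self.terminator!r}")
        has_content = any(
            not t.in_maze and not t.is_filled_pause for t in self.tokens
        )
        if not has_content and not self.maze_events:
            raise ChatError(f"C-unit {index}: no content and no maze events")
        n = len(self.tokens)
        non_maze = set(self.non_maze_indices())
        for rel in self.relations:
            for idx in (rel.head_index, rel.dependent_index):
                if not 0 <= idx < n:
                    raise ChatError(f"C-unit {index}: relation index {idx} out of range")
                if idx not in non_maze:
                    raise ChatError(
                        f"C-unit {index}: relation references maze token {idx}"
                    )
        for ev in self.maze_events:
            if ev.cunit_index != index:
                raise ChatError(f"C-unit {index}: maze event indexed {ev.cunit_index}")
            if ev.end > n:
                raise ChatError(f"C-unit {index}: maze span exceeds token count")


@dataclass
class Transcript:
    participant_id: str
    visit_id: str
    duration_s: float
    cunits: list[CUnit] = field(default_factory=list)
    prompts: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ChatError("duration_s must be positive")
        if not self.cunits:
            raise ChatError("transcript has no C-units")
        for i, cu in enumerate(self.cunits):
            cu.validate(i)

    def all_tokens(self) -> list[Token]:
        return [t for cu in self.cunits for t in cu.tokens]


# ---------------------------------------------------------------------------
# Parsing


def default_tagger(surfaces: Sequence[str]) -> list[tuple[str, str]]:
    """Fallback POS tagger used when a document carries no morphology tier.

    A minimal closed-class lookup: function words are recognized from small
    tables, everything else is tagged ``noun``.  It exists so untiered
    documents remain parseable; measure-quality tagging should come from the
    morphology tier.
    """
    closed = {
        "pronoun": {"i", "you", "he", "she", "it", "we", "they", "me", "him",
                    "her", "us", "them", "this", "that", "these", "those"},
        "determiner": {"the", "a", "an", "his", "my", "your", "their", "its"},
        "preposition": {"in", "on", "at", "of", "to", "from", "with", "by",
                        "over", "under", "off", "out"},
        "conjunction": {"and", "or", "but", "because", "while", "so", "if"},
        "verb": {"is", "are", "was", "were", "be", "been", "has", "have", "had"},
    }
    out = []
    for s in surfaces:
        pos = next((p for p, words in closed.items() if s in words), "noun")
        out.append((pos, s))
    return out


def _parse_main_line(
    line: str, lineno: int, cunit_index: int
) -> tuple[CUnit, list[int]]:
    """Parse one ``*PAR:`` line into a CUnit with POS tags left unassigned.

    Returns the C-unit and the indices of its non-maze tokens (tier targets).
    Token POS is provisionally ``other``/``nonword`` and fixed up later from
    the %mor tier or the tagger.
    """
    body = line.split(":", 1)[1].strip()
    items = re.findall(
        r"<|>|\[/-\]|\[//\]|\[/\]|\(\.\)|&-[^\s<>\[\]]+|[.?!]$|[.?!](?=\s)|[^\s<>\[\]]+",
        body,
    )
    tokens: list[Token] = []
    events: list[MazeEvent] = []
    terminator: str | None = None
    group_start: int | None = None
    group_span: tuple[int, int] | None = None  # most recently closed <...> group
    last_plain: int | None = None

    def fail(msg: str) -> ChatParseError:
        return ChatParseError(f"line {lineno}: {msg}: {line.strip()!r}")

    for item in items:
        if terminator is not None:
            raise fail("material after utterance terminator")
        if group_span is not None and item not in _RETRACE_MARKS:
            raise fail("retrace group must be followed by a retrace marker")
        if item in _TERMINATORS:
            terminator = item
        elif item == "<":
            if group_start is not None:
                raise fail("nested retrace group")
            group_start = len(tokens)
        elif item == ">":
            if group_start is None:
                raise fail("unmatched '>'")
            if len(tokens) == group_start:
                raise fail("empty retrace group")
            group_span = (group_start, len(tokens))
            group_start = None
        elif item in _RETRACE_MARKS:
            kind = _RETRACE_MARKS[item]
            if group_span is not None:
                span = group_span
                group_span = None
            elif last_plain is not None and last_plain == len(tokens) - 1:
                span = (last_plain, len(tokens))
            else:
                raise fail(f"{item} without preceding retraced material")
            start, end = span
            if any(tok.is_filled_pause for tok in tokens[span[0] : span[1]]):
                raise fail("fillers inside retrace groups are not supported")
            tokens[start:end] = [
                replace(tok, in_maze=True, pos="other", lemma=tok.surface)
                if not tok.is_filled_pause
                else tok
                for tok in tokens[start:end]
            ]
            events.append(MazeEvent(kind, cunit_index, start, end))
            last_plain = None
        elif item == "(.)":
            events.append(
                MazeEvent("unfilled_pause", cunit_index, len(tokens), len(tokens))
            )
        elif item.startswith("&-"):
            word = item[2:].lower()
            if not word:
                raise fail("empty filler")
            i = len(tokens)
            tokens.append(Token(word, word, "nonword", in_maze=True, is_filled_pause=True))
            events.append(MazeEvent("filled_pause", cunit_index, i, i + 1))
        else:
            word = item.lower()
            last_plain = len(tokens)
            tokens.append(Token(word, word, "other"))

    if group_start is not None:
        raise fail("unterminated retrace group")
    if group_span is not None:
        raise fail("retrace group without a retrace marker")
    if terminator is None:
        raise fail("missing utterance terminator")

    cu = CUnit(tokens=tokens, terminator=terminator, maze_events=events)
    non_maze = [i for i, t in enumerate(tokens) if not t.in_maze]
    return cu, non_maze


def _apply_mor(
    cu: CUnit, non_maze: list[int], mor_line: str, lineno: int
) -> None:
    entries = mor_line.split(":", 1)[1].split()
    if len(entries) != len(non_maze):
        raise ChatParseError(
            f"line {lineno}: %mor has {len(entries)} entries for "
            f"{len(non_maze)} non-maze tokens"
        )
    for idx, entry in zip(non_maze, entries):
        if "|" not in entry:
            raise ChatParseError(f"line {lineno}: bad %mor entry {entry!r}")
        pos, lemma = entry.split("|", 1)
        if pos not in POS_TAGS:
            raise ChatParseError(f"line {lineno}: unknown POS {pos!r}")
        tok = cu.tokens[idx]
        cu.tokens[idx] = replace(tok, pos=pos, lemma=lemma.lower())


def _apply_gra(cu: CUnit, non_maze: list[int], gra_line: str, lineno: int) -> None:
    entries = gra_line.split(":", 1)[1].split()
    if len(entries) != len(non_maze):
        raise ChatParseError(
            f"line {lineno}: %gra has {len(entries)} entries for "
            f"{len(non_maze)} non-maze tokens"
        )
    relations = []
    for k, entry in enumerate(entries):
        parts = entry.split("|")
        if len(parts) != 3:
            raise ChatParseError(f"line {lineno}: bad %gra entry {entry!r}")
        dep, head, label = int(parts[0]), int(parts[1]), parts[2]
        if dep != k + 1:
            raise ChatParseError(
                f"line {lineno}: %gra entries must be in token order"
            )
        if head == 0:
            continue  # root carries no incoming relation
        if not 1 <= head <= len(non_maze):
            raise ChatParseError(f"line {lineno}: %gra head {head} out of range")
        relations.append(
            GrammaticalRelation(
                label=label,
                head_index=non_maze[head - 1],
                dependent_index=non_maze[k],
            )
        )
    cu.relations = relations


def parse_chat(
    text: str,
    tagger: Callable[[Sequence[str]], list[tuple[str, str]]] = default_tagger,
) -> Transcript:
    """Parse a CHAT-dialect document into a :class:`Transcript`.

    ``tagger`` supplies ``(pos, lemma)`` pairs for non-maze tokens of
    utterances that lack a %mor tier.
    """
    if not text.strip():
        raise ChatParseError("empty document")
    participant_id = visit_id = None
    duration: float | None = None
    cunits: list[CUnit] = []
    pending: tuple[CUnit, list[int], bool] | None = None  # cu, non_maze, has_mor
    prompts = 0

    def finish_pending() -> None:
        nonlocal pending
        if pending is None:
            return
        cu, non_maze, has_mor = pending
        if not has_mor and non_maze:
            tags = tagger([cu.tokens[i].surface for i in non_maze])
            for idx, (pos, lemma) in zip(non_maze, tags):
                cu.tokens[idx] = replace(cu.tokens[idx], pos=pos, lemma=lemma)
        pending = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line:
            continue
        if line.startswith("@"):
            key, _, value = line.partition(":")
            value = value.strip()
            if key == "@ID":
                if "|" not in value:
                    raise ChatParseError(f"line {lineno}: @ID must be 'participant|visit'")
                participant_id, visit_id = value.split("|", 1)
            elif key == "@Duration":
                try:
                    duration = float(value)
                except ValueError:
                    raise ChatParseError(f"line {lineno}: bad @Duration {value!r}")
        elif line.startswith("*PAR:"):
            finish_pending()
            cu, non_maze = _parse_main_line(line, lineno, len(cunits))
            cunits.append(cu)
            pending = (cu, non_maze, False)
        elif line.startswith("*INV:"):
            finish_pending()
            prompts += 1
        elif line.startswith("%mor:"):
            if pending is None:
                raise ChatParseError(f"line {lineno}: %mor without a main line")
            cu, non_maze, _ = pending
            _apply_mor(cu, non_maze, line, lineno)
            pending = (cu, non_maze, True)
        elif line.startswith("%gra:"):
            if pending is None:
                raise ChatParseError(f"line {lineno}: %gra without a main line")
            cu, non_maze, has_mor = pending
            _apply_gra(cu, non_maze, line, lineno)
        elif line.startswith("*") or line.startswith("%"):
            raise ChatParseError(f"line {lineno}: unsupported tier {line.split(':')[0]!r}")
    finish_pending()

    if not cunits:
        raise ChatParseError("document contains no participant utterances")
    if duration is None:
        raise ChatError("missing @Duration header")
    if participant_id is None:
        raise ChatError("missing @ID header")

    t = Transcript(
        participant_id=participant_id,
        visit_id=visit_id,
        duration_s=duration,
        cunits=cunits,
        prompts=prompts,
    )
    t.validate()
    return t


# ---------------------------------------------------------------------------
# Writing


def _format_duration(d: float) -> str:
    return repr(float(d))


def _write_main_line(cu: CUnit) -> str:
    spans = {}  # start index -> retrace event
    unfilled_at: dict[int, int] = {}
    for ev in cu.maze_events:
        if ev.kind == "unfilled_pause":
            unfilled_at[ev.start] = unfilled_at.get(ev.start, 0) + 1
        elif ev.kind != "filled_pause":
            if ev.start in spans:
                raise ChatError("overlapping maze spans cannot be written")
            spans[ev.start] = ev
    items: list[str] = []
    i = 0
    n = len(cu.tokens)
    while i <= n:
        items.extend(["(.)"] * unfilled_at.get(i, 0))
        if i == n:
            break
        if i in spans:
            ev = spans[i]
            words = [t.surface for t in cu.tokens[ev.start : ev.end]]
            group = words[0] if len(words) == 1 else "<" + " ".join(words) + ">"
            items.append(f"{group} {_MARK_FOR_KIND[ev.kind]}")
            i = ev.end
            continue
        tok = cu.tokens[i]
        items.append(f"&-{tok.surface}" if tok.is_filled_pause else tok.surface)
        i += 1
    items.append(cu.terminator)
    return "*PAR:\t" + " ".join(items)


def _write_tiers(cu: CUnit) -> list[str]:
    non_maze = cu.non_maze_indices()
    lines = []
    if non_maze:
        mor = " ".join(f"{cu.tokens[i].pos}|{cu.tokens[i].lemma}" for i in non_maze)
        lines.append("%mor:\t" + mor)
    if cu.relations:
        pos_of = {abs_i: k + 1 for k, abs_i in enumerate(non_maze)}
        incoming = {rel.dependent_index: rel for rel in cu.relations}
        entries = []
        for k, abs_i in enumerate(non_maze):
            rel = incoming.get(abs_i)
            if rel is None:
                entries.append(f"{k + 1}|0|ROOT")
            else:
                entries.append(f"{k + 1}|{pos_of[rel.head_index]}|{rel.label}")
        lines.append("%gra:\t" + " ".join(entries))
    return lines


def write_chat(t: Transcript) -> str:
    """Serialize a transcript; ``parse_chat(write_chat(t))`` reproduces ``t``."""
    t.validate()
    lines = [
        "@Begin",
        "@Participants:\tPAR Participant, INV Investigator",
        f"@ID:\t{t.participant_id}|{t.visit_id}",
        f"@Duration:\t{_format_duration(t.duration_s)}",
    ]
    for cu in t.cunits:
        lines.append(_write_main_line(cu))
        lines.extend(_write_tiers(cu))
    lines.extend(f"*INV:\t{_PROMPT_TEXT}" for _ in range(t.prompts))
    lines.append("@End")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Reliability


def _align_agreement(a: Sequence[str], b: Sequence[str]) -> float:
    """Percent agreement over a global minimum-edit-distance alignment.

    Unit costs for insertion, deletion, and substitution.  Among minimum-cost
    alignments the one with the most matched columns is used (ties fall
    toward aligning tokens rather than gapping them), and agreement is
    ``100 * matches / alignment_length`` where the alignment length counts
    matches, substitutions, and gaps.
    """
    n, m = len(a), len(b)
    if n == 0 and m == 0:
        return 100.0
    # DP over (cost, -matches, length); tuple order encodes the tie-break.
    prev = [(j, 0, j) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [(i, 0, i)]
        ai = a[i - 1]
        for j in range(1, m + 1):
            match = ai == b[j - 1]
            diag = prev[j - 1]
            best = (diag[0] + (0 if match else 1), diag[1] - (1 if match else 0), diag[2] + 1)
            up = (prev[j][0] + 1, prev[j][1], prev[j][2] + 1)
            left = (cur[j - 1][0] + 1, cur[j - 1][1], cur[j - 1][2] + 1)
            cur.append(min(best, up, left))
        prev = cur
    cost, neg_matches, length = prev[m]
    return 100.0 * (-neg_matches) / length


def _coding_sequence(t: Transcript, lexicon) -> list[str]:
    """Content-unit codes in order of first mention (semantic-coding level)."""
    from .features import iter_unit_mentions

    seen: set[str] = set()
    out: list[str] = []
    for unit in iter_unit_mentions(t, lexicon):
        if unit not in seen:
            seen.add(unit)
            out.append(unit)
    return out


def percent_agreement(
    a: Transcript,
    b: Transcript,
    level: str = "transcription",
    lexicon=None,
) -> float:
    """Inter-rater percent agreement between two transcripts of one sample.

    ``level`` selects what is aligned: ``"transcription"`` aligns the full
    spoken token sequence (mazes included — raters can disagree about
    disfluencies too); ``"semantic_coding"`` aligns the sequences of
    content-unit codes each rater's transcript triggers.
    """
    if (a.participant_id, a.visit_id) != (b.participant_id, b.visit_id):
        raise ChatError(
            "reliability requires transcripts of the same participant and visit"
        )
    a.validate()
    b.validate()
    if level == "transcription":
        seq_a = [t.surface for t in a.all_tokens()]
        seq_b = [t.surface for t in b.all_tokens()]
    elif level == "semantic_coding":
        if lexicon is None:
            from .features import default_lexicon

            lexicon = default_lexicon()
        seq_a = _coding_sequence(a, lexicon)
        seq_b = _coding_sequence(b, lexicon)
    else:
        raise ValueError(f"unknown agreement level {level!r}")
    if not seq_a and not seq_b:
        raise ChatError("nothing to align at this level")
    return _align_agreement(seq_a, seq_b)
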