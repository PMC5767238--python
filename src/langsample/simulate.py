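"""Synthetic data with known ground truth.

Two generators:

* :func:`generate_transcript` builds a picture-description transcript from a
  :class:`TranscriptPlan` whose composition (POS counts per C-unit, maze
  schedule, embeddings, content units, unique-word target) is fully known,
  together with the closed-form feature values the plan implies.  The pair
  is an exact oracle for the extraction pipeline: parsing the written
  document and deriving features must reproduce the plan's values.

* :func:`simulate_cohort_scores` draws a two-visit longitudinal cohort whose
  factor scores follow the subject-intercept mixed model, with fixed-effect
  vectors defaulting to the published final models for each factor.  The
  default cohort composition (200 cognitively healthy / 64 eMCI subjects,
  visits about two years apart, eMCI subjects older and more often male)
  preserves the confounding structure the covariate-adjusted analyses must
  handle.

Both generators are deterministic under their seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chat_io import CUnit, GrammaticalRelation, MazeEvent, Token, Transcript
from .features import ContentUnitLexicon, FeatureVector, default_lexicon
from .factors import FACTOR_NAMES

__all__ = [
    "CUnitPlan",
    "TranscriptPlan",
    "generate_transcript",
    "random_plan",
    "simulate_transcripts",
    "REFERENCE_BETAS",
    "SimCohortConfig",
    "simulate_cohort_scores",
]

_CONTENT_POS = (
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

# Seed word pools per POS; pools are extended programmatically when a plan
# needs more distinct words, and filtered at generation time against the
# lexicon's trigger words so no vocabulary word accidentally scores a
# content unit.
_POOLS: dict[str, tuple[str, ...]] = {
    "noun": ("table", "chair", "floor", "hand", "foot", "cup", "door", "wall",
             "house", "tree", "dog", "cat", "book", "car", "hat", "shoe",
             "lamp", "clock", "road", "bird"),
    "verb": ("stand", "sit", "walk", "hold", "see", "look", "go", "come",
             "put", "open", "close", "climb", "smile", "point", "carry", "lean"),
    "pronoun": ("he", "she", "it", "they", "we", "you", "i", "them", "him", "her"),
    "adjective": ("big", "small", "tall", "short", "old", "young", "red",
                  "blue", "happy", "busy", "wet", "full"),
    "adverb": ("quickly", "slowly", "there", "here", "now", "again", "almost",
               "away", "still", "very"),
    "preposition": ("near", "beside", "behind", "above", "below", "toward",
                    "between", "into", "onto", "across"),
    "conjunction": ("and", "but", "or", "because", "while", "so", "although"),
    "determiner": ("the", "a", "an", "this", "that", "some", "every", "each"),
    "other": ("well", "okay", "yes", "no", "right", "oh"),
}

_EMBED_LABEL = "CMOD"
_PLAIN_LABELS = ("SUBJ", "OBJ", "JCT", "DET", "MOD", "COORD")


@dataclass(frozen=True)
class CUnitPlan:
    """Composition of one C-unit: non-maze word counts by POS, the number of
    embedding relations, the maze events to insert, and the content units to
    mention (each consumes one noun slot)."""

    pos_counts: Mapping[str, int]
    embeddings: int = 0
    mazes: tuple[str, ...] = ()
    content_units: tuple[str, ...] = ()

    @property
    def n_words(self) -> int:
        return sum(self.pos_counts.values())

    @property
    def n_relations(self) -> int:
        # One %gra entry per word with exactly one root: w - 1 relations.
        return max(self.n_words - 1, 0)


@dataclass(frozen=True)
class TranscriptPlan:
    cunits: tuple[CUnitPlan, ...]
    unique_words: int
    duration_s: float
    seed: int
    participant_id: str = "sim"
    visit_id: str = "v1"

    def validate(self, lexicon: ContentUnitLexicon) -> None:
        if not self.cunits:
            raise ValueError("plan has no C-units")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        single = lexicon.single_word_units()
        units: list[str] = []
        for i, cu in enumerate(self.cunits):
            for pos, cnt in cu.pos_counts.items():
                if pos not in _CONTENT_POS:
                    raise ValueError(f"C-unit {i}: unknown POS {pos!r}")
                if cnt < 0:
                    raise ValueError(f"C-unit {i}: negative count for {pos!r}")
            if cu.n_words == 0 and not cu.mazes:
                raise ValueError(f"C-unit {i}: no words and no mazes")
            if cu.embeddings > cu.n_relations:
                raise ValueError(
                    f"C-unit {i}: {cu.embeddings} embeddings exceed "
                    f"{cu.n_relations} available relations"
                )
            if len(cu.content_units) > cu.pos_counts.get("noun", 0):
                raise ValueError(
                    f"C-unit {i}: more content units than noun slots"
                )
            for u in cu.content_units:
                if u not in single:
                    raise ValueError(
                        f"C-unit {i}: unit {u!r} lacks a single-word trigger"
                    )
            units.extend(cu.content_units)
        if len(set(units)) != len(units):
            raise ValueError("content units must be distinct across the plan")
        lo, hi = self.unique_bounds()
        if not lo <= self.unique_words <= hi:
            raise ValueError(
                f"unique_words={self.unique_words} outside feasible "
                f"range [{lo}, {hi}]"
            )

    def pos_totals(self) -> dict[str, int]:
        totals = {p: 0 for p in _CONTENT_POS}
        for cu in self.cunits:
            for pos, cnt in cu.pos_counts.items():
                totals[pos] += cnt
        return totals

    def n_units(self) -> int:
        return sum(len(cu.content_units) for cu in self.cunits)

    def unique_bounds(self) -> tuple[int, int]:
        totals = self.pos_totals()
        n_units = self.n_units()
        leftover = dict(totals)
        leftover["noun"] -= n_units
        lo = n_units + sum(1 for v in leftover.values() if v > 0)
        hi = n_units + sum(leftover.values())
        return lo, hi

    def maze_counts(self) -> dict[str, int]:
        counts = {k: 0 for k in ("filled_pause", "unfilled_pause", "repetition",
                                 "revision", "false_start")}
        for cu in self.cunits:
            for kind in cu.mazes:
                counts[kind] += 1
        return counts

    def feature_vector(self) -> FeatureVector:
        """Closed-form feature values implied by the plan (the test oracle)."""
        totals = self.pos_totals()
        total_words = sum(totals.values())
        if total_words == 0:
            raise ValueError("plan has no words; features undefined")
        n_utt = len(self.cunits)
        maze = self.maze_counts()
        n_units = self.n_units()
        embed = sum(cu.embeddings for cu in self.cunits)
        total_rel = sum(cu.n_relations for cu in self.cunits)
        ref = totals["noun"] + totals["pronoun"]
        propositions = (
            totals["verb"] + totals["adjective"] + totals["adverb"]
            + totals["preposition"] + totals["conjunction"]
        )
        maze_num = (
            maze["filled_pause"] + maze["false_start"]
            + maze["revision"] + maze["repetition"]
        )
        return FeatureVector(
            percent_nouns=100.0 * totals["noun"] / total_words,
            percent_verbs=100.0 * totals["verb"] / total_words,
            pronoun_index=(totals["pronoun"] / ref) if ref > 0 else None,
            verb_index=totals["verb"] / n_utt,
            proposition_density=propositions / total_words,
            grammatical_complexity=(embed / total_rel) if total_rel > 0 else None,
            type_token_ratio=self.unique_words / total_words,
            unique_words=float(self.unique_words),
            semantic_unit_count=float(n_units),
            maze_index=maze_num / n_utt,
            mlu=total_words / n_utt,
            words_per_minute=60.0 * total_words / self.duration_s,
            semantic_units_per_minute=60.0 * n_units / self.duration_s,
            total_words=float(total_words),
            total_semantic_units=float(n_units),
        )


def _word_pool(pos: str, needed: int, forbidden: set[str]) -> list[str]:
    """``needed`` distinct surfaces for one POS class, avoiding ``forbidden``
    words (lexicon triggers) and words of other classes (pools are disjoint
    by construction, synthesized names stay disjoint via the POS prefix)."""
    words = [w for w in _POOLS[pos] if w not in forbidden]
    for k in itertools.count():
        if len(words) >= needed:
            break
        cand = f"{pos}{k}"
        if cand not in forbidden:
            words.append(cand)
    return words[:needed]


def _allocate_uniques(
    plan: TranscriptPlan, rng: np.random.Generator
) -> dict[str, int]:
    """Distribute the plan's unique-word target over POS classes (beyond the
    content-unit triggers, which are all distinct nouns)."""
    totals = plan.pos_totals()
    leftover = dict(totals)
    leftover["noun"] -= plan.n_units()
    alloc = {p: (1 if leftover[p] > 0 else 0) for p in _CONTENT_POS}
    extra = plan.unique_words - plan.n_units() - sum(alloc.values())
    classes = [p for p in _CONTENT_POS if leftover[p] > alloc[p]]
    rng.shuffle(classes)
    for p in classes:
        if extra <= 0:
            break
        take = min(extra, leftover[p] - alloc[p])
        alloc[p] += take
        extra -= take
    return alloc


def generate_transcript(
    plan: TranscriptPlan, lexicon: ContentUnitLexicon | None = None
) -> tuple[Transcript, FeatureVector]:
    """Realize a plan as a transcript, returning it with the plan's
    closed-form feature vector.

    The transcript is deterministic under ``plan.seed``.  Unique-word targets
    are met by drawing distinct vocabulary words per POS class until the
    target is reached and then reusing words within their class; content
    units are mentioned through their single-word triggers, which occupy
    noun slots and are kept disjoint from the ordinary vocabulary.
    """
    if lexicon is None:
        lexicon = default_lexicon()
    plan.validate(lexicon)
    _check_lexicon_for_generation(lexicon)
    rng = np.random.default_rng(plan.seed)
    forbidden = lexicon.trigger_words()
    single = lexicon.single_word_units()

    alloc = _allocate_uniques(plan, rng)
    totals = plan.pos_totals()
    # Per-class word sequences: distinct words first, then cycle.
    sequences: dict[str, list[str]] = {}
    for pos in _CONTENT_POS:
        m = totals[pos] - (plan.n_units() if pos == "noun" else 0)
        u = alloc[pos]
        if m == 0:
            sequences[pos] = []
            continue
        distinct = _word_pool(pos, u, forbidden)
        seq = list(distinct)
        for k in range(m - u):
            seq.append(distinct[k % u])
        sequences[pos] = seq
    iters = {pos: iter(seq) for pos, seq in sequences.items()}

    filler_words = ("um", "uh", "er")
    maze_filler = "hm"
    cunits: list[CUnit] = []
    for ci, cu_plan in enumerate(plan.cunits):
        words: list[tuple[str, str, str]] = []  # (surface, lemma, pos)
        for unit in cu_plan.content_units:
            trig = single[unit]
            words.append((trig, trig, "noun"))
        for pos in _CONTENT_POS:
            n = cu_plan.pos_counts.get(pos, 0) - (
                len(cu_plan.content_units) if pos == "noun" else 0
            )
            for _ in range(n):
                w = next(iters[pos])
                words.append((w, w, pos))
        order = rng.permutation(len(words))
        words = [words[i] for i in order]

        tokens = [Token(s, l, p) for s, l, p in words]
        events: list[MazeEvent] = []
        # Insert maze events at random token boundaries, front to back.
        for kind in cu_plan.mazes:
            at = int(rng.integers(0, len(tokens) + 1))
            if kind == "unfilled_pause":
                events.append(MazeEvent(kind, ci, at, at))
            elif kind == "filled_pause":
                w = filler_words[int(rng.integers(0, len(filler_words)))]
                tokens.insert(
                    at, Token(w, w, "nonword", in_maze=True, is_filled_pause=True)
                )
                events = [_shift(e, at, 1) for e in events]
                events.append(MazeEvent(kind, ci, at, at + 1))
            else:
                # Retraces repeat the following word when one exists.
                src = tokens[at].surface if at < len(tokens) and not tokens[at].in_maze else maze_filler
                tokens.insert(at, Token(src, src, "other", in_maze=True))
                events = [_shift(e, at, 1) for e in events]
                events.append(MazeEvent(kind, ci, at, at + 1))
        events.sort(key=lambda e: (e.start, e.end))

        non_maze = [i for i, t in enumerate(tokens) if not t.in_maze]
        relations = []
        n_rel = cu_plan.n_relations
        labels = [_EMBED_LABEL] * cu_plan.embeddings + [
            _PLAIN_LABELS[k % len(_PLAIN_LABELS)]
            for k in range(n_rel - cu_plan.embeddings)
        ]
        for k in range(n_rel):
            relations.append(
                GrammaticalRelation(
                    label=labels[k],
                    head_index=non_maze[k + 1],
                    dependent_index=non_maze[k],
                )
            )
        cunits.append(
            CUnit(tokens=tokens, relations=relations, maze_events=events)
        )

    t = Transcript(
        participant_id=plan.participant_id,
        visit_id=plan.visit_id,
        duration_s=plan.duration_s,
        cunits=cunits,
        prompts=0,
    )
    t.validate()
    return t, plan.feature_vector()


def _shift(ev: MazeEvent, at: int, by: int) -> MazeEvent:
    if ev.start >= at:
        return replace(ev, start=ev.start + by, end=ev.end + by)
    return ev


def _check_lexicon_for_generation(lexicon: ContentUnitLexicon) -> None:
    """Reject lexicons whose multi-word triggers could fire accidentally when
    single-word triggers of other units land adjacently."""
    singles = set(lexicon.single_word_units().values())
    for unit_id, pats in lexicon.units.items():
        for pat in pats:
            if len(pat) > 1 and all(w in singles for w in pat):
                raise ValueError(
                    f"unit {unit_id!r}: multi-word trigger {pat} is composed "
                    "entirely of single-word triggers; generation would be "
                    "ambiguous"
                )


def random_plan(
    rng: np.random.Generator,
    lexicon: ContentUnitLexicon | None = None,
    max_cunits: int = 8,
    seed: int | None = None,
) -> TranscriptPlan:
    """A random valid plan; used for property tests of the extraction oracle."""
    if lexicon is None:
        lexicon = default_lexicon()
    single = sorted(lexicon.single_word_units())
    n_cunits = int(rng.integers(2, max_cunits + 1))
    n_units_total = int(rng.integers(0, min(len(single), 2 * n_cunits) + 1))
    unit_ids = [str(u) for u in rng.choice(single, size=n_units_total, replace=False)]
    cunits = []
    for _ in range(n_cunits):
        counts = {
            "noun": int(rng.integers(1, 5)),
            "verb": int(rng.integers(0, 4)),
            "pronoun": int(rng.integers(0, 3)),
            "adjective": int(rng.integers(0, 3)),
            "adverb": int(rng.integers(0, 2)),
            "preposition": int(rng.integers(0, 3)),
            "conjunction": int(rng.integers(0, 2)),
            "determiner": int(rng.integers(0, 3)),
        }
        n_words = sum(counts.values())
        take = min(len(unit_ids), int(rng.integers(0, counts["noun"] + 1)))
        units = tuple(unit_ids[:take])
        del unit_ids[:take]
        n_mazes = int(rng.integers(0, 4))
        kinds = ("filled_pause", "unfilled_pause", "repetition", "revision",
                 "false_start")
        mazes = tuple(kinds[int(k)] for k in rng.integers(0, len(kinds), n_mazes))
        cunits.append(
            CUnitPlan(
                pos_counts=counts,
                embeddings=int(rng.integers(0, n_words)),
                mazes=mazes,
                content_units=units,
            )
        )
    plan = TranscriptPlan(
        cunits=tuple(cunits),
        unique_words=0,
        duration_s=float(rng.uniform(30.0, 90.0)),
        seed=int(rng.integers(0, 2**31 - 1)) if seed is None else seed,
    )
    lo, hi = plan.unique_bounds()
    plan = replace(plan, unique_words=int(rng.integers(lo, hi + 1)))
    plan.validate(lexicon)
    return plan


def simulate_transcripts(
    n: int, seed: int, lexicon: ContentUnitLexicon | None = None
) -> list[tuple[TranscriptPlan, Transcript, FeatureVector]]:
    """Generate ``n`` random planned transcripts, deterministically."""
    if lexicon is None:
        lexicon = default_lexicon()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        plan = random_plan(rng, lexicon)
        plan = replace(plan, participant_id=f"sim{i:04d}", visit_id="v1")
        t, fv = generate_transcript(plan, lexicon)
        out.append((plan, t, fv))
    return out


# ---------------------------------------------------------------------------
# Cohort simulation

#: Published final-model fixed effects per factor (terms absent from a
#: factor's final model are simply not generated for it).
REFERENCE_BETAS: dict[str, dict[str, float]] = {
    "semantic": {
        "intercept": 0.0,
        "age_centered": -0.001,
        "sex": -0.09,
        "literacy": -0.28,
        "dx": -0.07,
        "age_centered:dx": -0.04,
    },
    "syntax": {
        "intercept": 0.0,
        "age_centered": -0.01,
        "sex": -0.24,
        "literacy": 0.75,
        "dx": -0.19,
    },
    "lexical": {
        "intercept": 0.0,
        "age_centered": -0.02,
        "sex": -0.15,
        "literacy": -2.7,
        "dx": 0.28,
    },
    "fluency": {
        "intercept": 0.0,
        "age_centered": 0.01,
        "sex": 0.57,
        "literacy": -0.70,
        "dx": -0.23,
        "age_centered:dx": -0.03,
    },
}


@dataclass(frozen=True)
class SimCohortConfig:
    """Cohort-generator settings.

    Covariate defaults mirror the study sample: 200 cognitively healthy and
    64 eMCI subjects seen twice about two years apart, eMCI subjects older
    (baseline 64.2 vs 61.1 years) and more often male (44% vs 30%), literacy
    a reading standard score of 106.7 (SD 9.3) in both groups.  Literacy
    enters the linear predictor z-scored over the generated sample — the
    generator's literacy scaling convention.  The random-intercept SD of 0.7
    and residual SD of 0.5 give a visit-to-visit intraclass correlation of
    about 0.66, consistent with factor scores that are stable across visits
    in cognitively unimpaired adults, and reproduce the reported precision
    of the between-subject effects.
    """

    n_ch: int = 200
    n_emci: int = 64
    visits: int = 2
    gap_mean_years: float = 2.0
    gap_sd_years: float = 1.5
    min_gap_years: float = 0.5
    age_mean_ch: float = 61.1
    age_sd_ch: float = 6.5
    age_mean_emci: float = 64.2
    age_sd_emci: float = 5.9
    male_prob_ch: float = 0.30
    male_prob_emci: float = 0.44
    literacy_mean: float = 106.7
    literacy_sd: float = 9.3
    cesd_mean: float = 6.0
    cesd_sd: float = 5.0
    anxiety_prob: float = 0.10
    sleep_mean: float = 7.0
    sleep_sd: float = 1.5
    betas: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {f: dict(REFERENCE_BETAS[f]) for f in FACTOR_NAMES}
    )
    tau: float = 0.7
    sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ch < 2 or self.n_emci < 2:
            raise ValueError("each diagnosis group needs at least two subjects")
        if self.tau <= 0 or self.sigma <= 0:
            raise ValueError("tau and sigma must be positive")
        if self.visits < 1:
            raise ValueError("at least one visit per subject")
        known = {"intercept", "age_centered", "sex", "literacy", "dx",
                 "age_centered:dx", "sex:dx", "literacy:dx",
                 "cesd", "anxiety", "sleep"}
        for factor, bs in self.betas.items():
            if factor not in FACTOR_NAMES:
                raise ValueError(f"unknown factor {factor!r}")
            unknown = set(bs) - known
            if unknown:
                raise ValueError(f"{factor}: unknown beta terms {sorted(unknown)}")


def simulate_cohort_scores(cfg: SimCohortConfig | None = None) -> pd.DataFrame:
    """Draw one cohort of factor-score records from the mixed model.

    Returns one row per subject-visit with identifiers, covariates, diagnosis,
    and the four factor scores.  Each factor's scores follow
    ``y = x'beta + b_i + e`` with independent subject intercepts and residuals
    per factor.  Centered age uses age rounded to two decimals minus 63.
    """
    if cfg is None:
        cfg = SimCohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n_sub = cfg.n_ch + cfg.n_emci
    dx = np.concatenate([np.zeros(cfg.n_ch), np.ones(cfg.n_emci)])
    age0 = np.where(
        dx == 0,
        rng.normal(cfg.age_mean_ch, cfg.age_sd_ch, n_sub),
        rng.normal(cfg.age_mean_emci, cfg.age_sd_emci, n_sub),
    )
    male = (
        rng.random(n_sub) < np.where(dx == 0, cfg.male_prob_ch, cfg.male_prob_emci)
    ).astype(float)
    literacy = rng.normal(cfg.literacy_mean, cfg.literacy_sd, n_sub)
    cesd = np.clip(rng.normal(cfg.cesd_mean, cfg.cesd_sd, n_sub), 0.0, None)
    anxiety = (rng.random(n_sub) < cfg.anxiety_prob).astype(float)
    sleep = rng.normal(cfg.sleep_mean, cfg.sleep_sd, n_sub)
    gaps = np.clip(
        rng.normal(cfg.gap_mean_years, cfg.gap_sd_years, (n_sub, cfg.visits - 1)),
        cfg.min_gap_years,
        None,
    ) if cfg.visits > 1 else np.zeros((n_sub, 0))

    # z-scored over the records table (the analysis-side convention), so the
    # generating coefficient and the refit coefficient share one scale
    lit_rep = np.repeat(literacy, cfg.visits)
    lit_z = (literacy - lit_rep.mean()) / lit_rep.std(ddof=1)

    ages = np.empty((n_sub, cfg.visits))
    ages[:, 0] = age0
    for j in range(1, cfg.visits):
        ages[:, j] = ages[:, j - 1] + gaps[:, j - 1]
    agec = np.round(ages, 2) - 63.0

    intercepts = {f: rng.normal(0.0, cfg.tau, n_sub) for f in FACTOR_NAMES}
    noise = {f: rng.normal(0.0, cfg.sigma, (n_sub, cfg.visits)) for f in FACTOR_NAMES}

    # subject-major record layout: every subject's visits are consecutive
    v = cfg.visits
    rep = lambda a: np.repeat(a, v)
    covariate_values = {
        "intercept": np.ones(n_sub * v),
        "age_centered": agec.ravel(),
        "sex": rep(male),
        "literacy": rep(lit_z),
        "dx": rep(dx),
        "age_centered:dx": agec.ravel() * rep(dx),
        "sex:dx": rep(male) * rep(dx),
        "literacy:dx": rep(lit_z) * rep(dx),
        "cesd": rep(cesd),
        "anxiety": rep(anxiety),
        "sleep": rep(sleep),
    }

    out = pd.DataFrame(
        {
            "subject_id": np.repeat([f"S{i:04d}" for i in range(n_sub)], v),
            "visit": np.tile(np.arange(1, v + 1), n_sub),
            "age_years": np.round(ages.ravel(), 2),
            "sex": np.where(rep(male) == 1.0, "male", "female"),
            "literacy": rep(literacy),
            "dx": np.where(rep(dx) == 1.0, "eMCI", "CH"),
            "cesd": rep(cesd),
            "anxiety": rep(anxiety).astype(int),
            "sleep": rep(sleep),
        }
    )
    for f in FACTOR_NAMES:
        eta = np.zeros(n_sub * v)
        for term, b in cfg.betas.get(f, {}).items():
            eta = eta + b * covariate_values[term]
        out[f] = eta + rep(intercepts[f]) + noise[f].ravel()
    return out
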