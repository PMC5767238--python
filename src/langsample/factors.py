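"""Latent factor scores from the discourse measures.

Each of the four constructs — Semantic, Syntax, Lexical, Fluency — is scored
as a weighted sum of standardized measures:

    factor = sign * sum_m  w_m * (x_m - mean_m) / sd_m

with the standardization constants taken from a reference sample.  The
Semantic and Fluency factors are multiplied by -1 so that, for every factor,
higher scores mean better performance (a raw Semantic composite rises with
pronoun use and falls with noun use; the raw Fluency composite rises with
disfluency).

The loading weights are configuration, not estimates made here: the default
configuration uses equal-magnitude weights within each factor, with the
measure's raw direction encoded in the weight's sign.  Replace them via YAML
when calibrated loadings are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .features import FeatureVector

__all__ = [
    "FACTOR_NAMES",
    "FactorWeights",
    "FactorScores",
    "default_weights",
    "calibrate_reference",
    "score_factors",
    "score_table",
]

FACTOR_NAMES = ("semantic", "syntax", "lexical", "fluency")

#: Default loadings.  Signs encode each measure's raw direction within its
#: construct (e.g. the raw Semantic composite increases with pronoun use and
#: verb percentage and decreases with noun percentage); magnitudes are equal
#: within a factor.
DEFAULT_LOADINGS: dict[str, dict[str, float]] = {
    "semantic": {"pronoun_index": 1.0, "percent_verbs": 1.0, "percent_nouns": -1.0},
    "syntax": {"verb_index": 1.0, "proposition_density": 1.0, "grammatical_complexity": 1.0},
    "lexical": {"type_token_ratio": 1.0, "unique_words": 1.0, "semantic_unit_count": 1.0},
    "fluency": {"maze_index": 1.0},
}

#: Directionality convention: Semantic and Fluency are flipped so that higher
#: always means better.
DEFAULT_SIGN_FLIP = {"semantic": -1, "syntax": 1, "lexical": 1, "fluency": -1}


@dataclass
class FactorWeights:
    loadings: dict[str, dict[str, float]]
    sign_flip: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SIGN_FLIP))
    reference_means: dict[str, float] = field(default_factory=dict)
    reference_sds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.loadings) != set(FACTOR_NAMES):
            raise ValueError(f"loadings must cover exactly the factors {FACTOR_NAMES}")
        if set(self.sign_flip) != set(FACTOR_NAMES):
            raise ValueError("sign_flip must cover exactly the four factors")
        if any(s not in (-1, 1) for s in self.sign_flip.values()):
            raise ValueError("sign flips must be +1 or -1")
        seen: dict[str, str] = {}
        for factor, ws in self.loadings.items():
            if not ws:
                raise ValueError(f"factor {factor!r} has no loaded measures")
            for measure in ws:
                if measure in seen:
                    raise ValueError(
                        f"measure {measure!r} loads on both {seen[measure]!r} "
                        f"and {factor!r}"
                    )
                seen[measure] = factor
        for measure, sd in self.reference_sds.items():
            if sd <= 0:
                raise ValueError(f"reference SD for {measure!r} must be positive")

    @property
    def measures(self) -> tuple[str, ...]:
        return tuple(m for ws in self.loadings.values() for m in ws)

    def is_calibrated(self) -> bool:
        return all(
            m in self.reference_means and m in self.reference_sds
            for m in self.measures
        )

    def to_dict(self) -> dict:
        return {
            "loadings": self.loadings,
            "sign_flip": self.sign_flip,
            "reference_means": self.reference_means,
            "reference_sds": self.reference_sds,
        }

    @classmethod
    def from_yaml(cls, path) -> "FactorWeights":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(
            loadings=doc["loadings"],
            sign_flip=doc.get("sign_flip", dict(DEFAULT_SIGN_FLIP)),
            reference_means=doc.get("reference_means", {}),
            reference_sds=doc.get("reference_sds", {}),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class FactorScores:
    """Standardized factor scores; ``None`` when a constituent was missing."""

    semantic: float | None
    syntax: float | None
    lexical: float | None
    fluency: float | None
    missing_measures: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float | None]:
        return {f: getattr(self, f) for f in FACTOR_NAMES}


def default_weights() -> FactorWeights:
    return FactorWeights(
        loadings={f: dict(ws) for f, ws in DEFAULT_LOADINGS.items()}
    )


def _features_frame(features: Iterable[FeatureVector] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    return pd.DataFrame([f.as_dict() for f in features])


def calibrate_reference(
    features: Iterable[FeatureVector] | pd.DataFrame,
    weights: FactorWeights | None = None,
) -> FactorWeights:
    """Fill standardization constants from a reference sample.

    Means and SDs (sample SD, ``ddof=1``) are computed per loaded measure
    over the samples where that measure is present.  A measure that is
    constant across the reference sample cannot be standardized and raises
    an error naming it.
    """
    if weights is None:
        weights = default_weights()
    df = _features_frame(features)
    if len(df) < 2:
        raise ValueError("calibration requires at least two samples")
    means, sds = {}, {}
    for measure in weights.measures:
        if measure not in df.columns:
            raise ValueError(f"reference sample lacks measure {measure!r}")
        vals = pd.to_numeric(df[measure], errors="coerce").dropna()
        if len(vals) < 2:
            raise ValueError(f"measure {measure!r} has fewer than two values")
        sd = float(vals.std(ddof=1))
        if sd == 0.0:
            raise ValueError(f"measure {measure!r} is constant in the reference sample")
        means[measure] = float(vals.mean())
        sds[measure] = sd
    return FactorWeights(
        loadings={f: dict(ws) for f, ws in weights.loadings.items()},
        sign_flip=dict(weights.sign_flip),
        reference_means=means,
        reference_sds=sds,
    )


def score_factors(f: FeatureVector | Mapping[str, float], w: FactorWeights) -> FactorScores:
    """Score one sample.  A missing constituent measure propagates to a
    missing factor score (the remaining weights are never re-normalized)."""
    if not w.is_calibrated():
        raise ValueError("weights lack reference means/SDs; calibrate first")
    values = f.as_dict() if isinstance(f, FeatureVector) else dict(f)
    scores: dict[str, float | None] = {}
    missing: list[str] = []
    for factor in FACTOR_NAMES:
        total = 0.0
        ok = True
        for measure, weight in w.loadings[factor].items():
            x = values.get(measure)
            if x is None or (isinstance(x, float) and np.isnan(x)):
                missing.append(measure)
                ok = False
                continue
            z = (float(x) - w.reference_means[measure]) / w.reference_sds[measure]
            total += weight * z
        scores[factor] = w.sign_flip[factor] * total if ok else None
    return FactorScores(**scores, missing_measures=tuple(missing))


def score_table(
    features: pd.DataFrame, w: FactorWeights, id_columns: tuple[str, ...] = ("participant_id", "visit_id")
) -> pd.DataFrame:
    """Score a feature table; returns id columns plus one column per factor."""
    rows = []
    for _, row in features.iterrows():
        sc = score_factors(row.to_dict(), w)
        out = {c: row[c] for c in id_columns if c in features.columns}
        out.update({k: (np.nan if v is None else v) for k, v in sc.as_dict().items()})
        rows.append(out)
    return pd.DataFrame(rows)
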