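"""Score-threshold calibration from manually labeled organoids.

Given a set of organoid scores labeled positive/negative by a human, the
classification threshold is the empirical quantile (default 95%) of the
*negative* score distribution: the ceil(q*n)-th order statistic of the n
negative scores.  This inverse-ECDF estimator makes the contamination bound
exact for every n: at most floor((1-q)*n) calibration negatives strictly
exceed the fitted threshold, i.e. organoids classified positive contain at
most a (1-q) fraction of the calibration negatives.  Positives play no role
in fitting; they are only used to report sensitivity.

Classification is strict: an organoid is positive iff its score *exceeds*
the threshold; ties are negative.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .plate_io import ValidationError

__all__ = [
    "LabeledScoreSet",
    "ECDF",
    "ThresholdModel",
    "ecdf",
    "fit_threshold",
    "classify",
    "sensitivity_on_labeled",
    "read_labeled_csv",
]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class LabeledScoreSet:
    """Parallel scores and positive/negative labels, with provenance text."""

    scores: list[float]
    labels: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.labels) or len(self.scores) == 0:
            raise ValidationError("scores and labels must have equal length >= 1")
        bad = set(self.labels) - {POSITIVE, NEGATIVE}
        if bad:
            raise ValidationError(f"labels must be positive/negative, got {sorted(bad)}")
        if any(s < 0 for s in self.scores):
            raise ValidationError("scores must be non-negative")

    def subset(self, label: str) -> list[float]:
        return [s for s, l in zip(self.scores, self.labels) if l == label]

    @property
    def negatives(self) -> list[float]:
        return self.subset(NEGATIVE)

    @property
    def positives(self) -> list[float]:
        return self.subset(POSITIVE)


class ECDF:
    """Right-continuous empirical CDF: F(x) = #(values <= x) / n."""

    def __init__(self, values: Iterable[float]):
        vals = np.sort(np.asarray(list(values), dtype=np.float64))
        if vals.size == 0:
            raise ValidationError("ECDF requires at least one value")
        self.x = np.unique(vals)
        self.y = np.searchsorted(vals, self.x, side="right") / vals.size
        self.n = int(vals.size)
        self._sorted = vals

    def __call__(self, x):
        x = np.asarray(x, dtype=np.float64)
        f = np.searchsorted(self._sorted, x, side="right") / self.n
        return float(f) if f.ndim == 0 else f

    @property
    def points(self) -> list[tuple[float, float]]:
        """The step points as sorted (score, cumulative fraction) pairs."""
        return [(float(a), float(b)) for a, b in zip(self.x, self.y)]

    def quantile(self, q: float) -> float:
        """Inverse-ECDF quantile: the ceil(q*n)-th order statistic."""
        if not 0 < q < 1:
            raise ValidationError(f"quantile level must be in (0,1): {q}")
        k = math.ceil(q * self.n)
        return float(self._sorted[k - 1])


def ecdf(values: Sequence[float]) -> ECDF:
    """Build the empirical CDF of a non-empty sample."""
    return ECDF(values)


@dataclass
class ThresholdModel:
    """A calibrated score cutoff, with the ECDF it came from.

    The contamination guarantee holds by construction: at most
    ``floor((1 - quantile_level) * n_negatives)`` calibration negatives
    strictly exceed ``threshold``.
    """

    threshold: float
    quantile_level: float = 0.95
    n_negatives: int = 0
    ecdf_points: list = field(default_factory=list)
    source: str = ""

    def classify_one(self, score: float) -> str:
        return POSITIVE if score > self.threshold else NEGATIVE

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "threshold": self.threshold,
                    "quantile_level": self.quantile_level,
                    "n_negatives": self.n_negatives,
                    "ecdf_points": self.ecdf_points,
                    "source": self.source,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdModel":
        d = json.loads(Path(path).read_text())
        return cls(
            threshold=d["threshold"],
            quantile_level=d["quantile_level"],
            n_negatives=d["n_negatives"],
            ecdf_points=[tuple(p) for p in d.get("ecdf_points", [])],
            source=d.get("source", ""),
        )


def fit_threshold(labeled: LabeledScoreSet, quantile_level: float = 0.95) -> ThresholdModel:
    """Fit the negative-quantile threshold from a labeled score set.

    The threshold is the ceil(q*n)-th order statistic of the negative
    scores.  Requires at least one negative; positives are ignored here.
    """
    negatives = labeled.negatives
    if not negatives:
        raise ValidationError("threshold fitting requires at least one negative")
    if not 0 < quantile_level < 1:
        raise ValidationError(f"quantile_level must be in (0,1): {quantile_level}")
    F = ECDF(negatives)
    return ThresholdModel(
        threshold=F.quantile(quantile_level),
        quantile_level=quantile_level,
        n_negatives=F.n,
        ecdf_points=F.points,
        source=labeled.source,
    )


def classify(scores: Sequence, model: ThresholdModel) -> list[str]:
    """Label each score positive iff it strictly exceeds the threshold.

    Accepts raw numbers or objects with a ``score`` attribute (e.g.
    :class:`~organoscore.scoring.OrganoidScore`); order is preserved.
    """
    out = []
    for s in scores:
        value = getattr(s, "score", s)
        out.append(model.classify_one(float(value)))
    return out


def sensitivity_on_labeled(labeled: LabeledScoreSet, model: ThresholdModel) -> float:
    """Fraction of labeled positives whose score exceeds the threshold."""
    positives = labeled.positives
    if not positives:
        raise ValidationError("sensitivity requires at least one labeled positive")
    return sum(1 for s in positives if s > model.threshold) / len(positives)


def read_labeled_csv(path: str | Path, source: str = "") -> LabeledScoreSet:
    """Load a labeled score set from a CSV with ``score`` and ``label`` columns."""
    df = pd.read_csv(path)
    for col in ("score", "label"):
        if col not in df.columns:
            raise ValidationError(f"labeled CSV needs a '{col}' column: {path}")
    return LabeledScoreSet(
        scores=[float(s) for s in df["score"]],
        labels=[str(l).strip().lower() for l in df["label"]],
        source=source or str(path),
    )
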