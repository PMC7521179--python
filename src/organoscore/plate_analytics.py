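"""Plate-level layouts and statistics.

The unit of analysis for group comparisons is the plate: each 96-well
plate contributes one observation (its positive fraction), mirroring how
differentiation efficiency is reported per plate.  Between-group tests use
the two-sided Mann-Whitney U (exact null distribution when both groups are
small and tie-free, otherwise a tie- and continuity-corrected normal
approximation); Welch's t-test is available as a clearly labeled secondary.

Edge effects — e.g. a temperature gradient near an incubator door that
depresses differentiation on one side of a plate — are detected by counting
positives in the two plate halves (default split: columns 1-6 vs 7-12) and
comparing half counts across the plates of a batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .plate_io import ROWS, ValidationError, well_to_coords

__all__ = [
    "PlateResult",
    "GroupComparison",
    "build_plate_result",
    "half_plate_counts",
    "mann_whitney",
    "welch_t",
    "compare_groups",
    "layout_text",
    "plot_plate",
]

POSITIVE = "positive"
NEGATIVE = "negative"
MISSING = "missing"

_MARKER = {POSITIVE: "+", NEGATIVE: "-", MISSING: "."}


@dataclass
class PlateResult:
    """Classified 8x12 plate: labels per well, counts and positive fraction."""

    plate_id: str
    grid: np.ndarray  # 8x12 object array of {positive, negative, missing}
    scores: dict = field(default_factory=dict)
    n_positive: int = 0
    n_scored: int = 0

    @property
    def positive_fraction(self) -> float:
        return self.n_positive / self.n_scored if self.n_scored else 0.0


def build_plate_result(
    labels: Mapping[str, str],
    scores: Mapping[str, float] | None = None,
    plate_id: str = "",
) -> PlateResult:
    """Assemble a :class:`PlateResult` from per-well labels (and scores).

    Wells absent from ``labels`` are marked missing and excluded from
    ``n_scored``.
    """
    grid = np.full((8, 12), MISSING, dtype=object)
    n_pos = n_scored = 0
    for well, label in labels.items():
        if label not in (POSITIVE, NEGATIVE):
            raise ValidationError(f"label for {well} must be positive/negative: {label}")
        r, c = well_to_coords(well)
        grid[r, c] = label
        n_scored += 1
        n_pos += label == POSITIVE
    return PlateResult(
        plate_id=plate_id,
        grid=grid,
        scores=dict(scores or {}),
        n_positive=n_pos,
        n_scored=n_scored,
    )


def half_plate_counts(
    plate: PlateResult, axis: str = "column", boundary: int | None = None
) -> tuple[int, int]:
    """Count positives in the two halves of a plate.

    ``axis='column'`` splits columns 1..boundary vs the rest (default
    boundary 6, i.e. columns 1-6 vs 7-12); ``axis='row'`` splits rows
    A..boundary vs the rest (default A-D vs E-H).  Missing wells count 0.
    """
    pos = plate.grid == POSITIVE
    if axis == "column":
        b = 6 if boundary is None else boundary
        if not 1 <= b <= 11:
            raise ValidationError(f"column boundary must be in 1..11: {b}")
        return int(pos[:, :b].sum()), int(pos[:, b:].sum())
    if axis == "row":
        b = 4 if boundary is None else boundary
        if not 1 <= b <= 7:
            raise ValidationError(f"row boundary must be in 1..7: {b}")
        return int(pos[:b, :].sum()), int(pos[b:, :].sum())
    raise ValidationError(f"axis must be 'column' or 'row': {axis}")


def mann_whitney(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for group a, p-value).

    The exact null distribution is used when both groups have at most 8
    observations and there are no ties; otherwise the normal approximation
    with tie correction and continuity correction.  Two samples that are
    entirely one tied value give p = 1.0 (the test carries no information).
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        return float(a.size * b.size / 2.0), 1.0
    method = "exact" if (not has_ties and max(a.size, b.size) <= 8) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def welch_t(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance t-test (secondary to the Mann-Whitney U)."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValidationError("Welch's t needs at least 2 observations per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupComparison:
    """Result of comparing two groups of per-plate positive fractions."""

    group_names: tuple[str, str]
    values_a: list[float]
    values_b: list[float]
    u_statistic: float
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float | None = None
    t_p_value: float | None = None

    def summary(self) -> str:
        na, nb = self.group_names
        return (
            f"{na}: {self.mean_a:.3f} ± {self.sd_a:.3f} (n={len(self.values_a)}) vs "
            f"{nb}: {self.mean_b:.3f} ± {self.sd_b:.3f} (n={len(self.values_b)}); "
            f"Mann-Whitney U={self.u_statistic:g}, p={self.p_value:.4g}"
        )

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_names[0],
            "group_b": self.group_names[1],
            "values_a": self.values_a,
            "values_b": self.values_b,
            "u_statistic": self.u_statistic,
            "p_value": self.p_value,
            "mean_a": self.mean_a,
            "sd_a": self.sd_a,
            "mean_b": self.mean_b,
            "sd_b": self.sd_b,
            "t_statistic": self.t_statistic,
            "t_p_value": self.t_p_value,
        }


def _sample_sd(values: np.ndarray) -> float:
    # sample SD (n-1); a single plate has no spread estimate
    return float(np.std(values, ddof=1)) if values.size > 1 else float("nan")


def compare_groups(
    plates_a: Sequence[PlateResult],
    plates_b: Sequence[PlateResult],
    group_names: tuple[str, str] = ("a", "b"),
    per_organoid: bool = False,
    with_t_test: bool = False,
) -> GroupComparison:
    """Compare two groups of plates on their positive fractions.

    Each plate is one observation (its positive fraction), so the sample
    size equals the number of plates, not the number of organoids.  With
    ``per_organoid=True`` the units are instead the individual organoid
    scores pooled across the group's plates (score-distribution comparison).
    """
    if not plates_a or not plates_b:
        raise ValidationError("each group needs at least one plate")
    if per_organoid:
        va = [s for p in plates_a for s in p.scores.values()]
        vb = [s for p in plates_b for s in p.scores.values()]
        if not va or not vb:
            raise ValidationError("per-organoid comparison needs scores on the plates")
    else:
        va = [p.positive_fraction for p in plates_a]
        vb = [p.positive_fraction for p in plates_b]
    u, p = mann_whitney(va, vb)
    a, b = np.asarray(va), np.asarray(vb)
    t_stat = t_p = None
    if with_t_test and a.size >= 2 and b.size >= 2:
        t_stat, t_p = welch_t(va, vb)
    return GroupComparison(
        group_names=group_names,
        values_a=list(map(float, va)),
        values_b=list(map(float, vb)),
        u_statistic=u,
        p_value=p,
        mean_a=float(a.mean()),
        sd_a=_sample_sd(a),
        mean_b=float(b.mean()),
        sd_b=_sample_sd(b),
        t_statistic=t_stat,
        t_p_value=t_p,
    )


def layout_text(plate: PlateResult) -> str:
    """Render the 8x12 layout with '+', '-', '.' for positive/negative/missing."""
    header = "   " + " ".join(f"{c:2d}" for c in range(1, 13))
    lines = [header]
    for i, row in enumerate(ROWS):
        cells = " ".join(f" {_MARKER[plate.grid[i, j]]}" for j in range(12))
        lines.append(f"{row}  {cells}")
    return "\n".join(lines)


def plot_plate(plate: PlateResult, path: str) -> None:
    """Save a PNG heatmap of well scores with positive wells circled."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = np.full((8, 12), np.nan)
    for well, score in plate.scores.items():
        r, c = well_to_coords(well)
        grid[r, c] = score
    fig, ax = plt.subplots(figsize=(7, 5))
    im = ax.imshow(grid, cmap="viridis")
    fig.colorbar(im, ax=ax, label="score")
    for i in range(8):
        for j in range(12):
            if plate.grid[i, j] == POSITIVE:
                ax.add_patch(
                    plt.Circle((j, i), 0.42, fill=False, color="lime", linewidth=2)
                )
    ax.set_xticks(range(12), [str(c) for c in range(1, 13)])
    ax.set_yticks(range(8), list(ROWS))
    ax.set_title(
        f"plate {plate.plate_id}: {plate.n_positive}/{plate.n_scored} positive"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
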