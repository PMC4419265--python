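"""Expression preprocessing for staged differentiation time courses.

The experiment behind this package samples one expression value per gene,
condition, day and replicate.  Three *differentiation stages* are assembled
as composite time courses from (condition, day) combinations: the culture is
switched from one induction medium to the next at fixed days, so the early
part of every stage is shared between conditions while the late part is
condition specific.  Preprocessing consists of

1. quantile normalisation across samples,
2. per-stage one-way ANOVA over time points with Benjamini-Hochberg FDR
   control to keep differentially expressed (DE) genes, and
3. assembly of a replicate-averaged gene x day profile per stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Default induction conditions, in the order the media are introduced.
DEFAULT_CONDITIONS = ("LSB", "LSB/S/F8", "LSB/S/F8/CHIR")

#: Default sampling days of the reference design.
DEFAULT_DAYS = (0, 1, 3, 5, 7, 11, 13)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with per-sample annotations.

    ``values`` is a genes-by-samples DataFrame; ``annotations`` is indexed by
    sample id with columns ``condition``, ``day`` and ``replicate``.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and not np.all(np.isfinite(arr.astype(float))):
            raise ValueError("expression matrix contains non-finite values")
        missing = [c for c in ("condition", "day", "replicate")
                   if c not in self.annotations.columns]
        if missing:
            raise ValueError(f"annotation columns missing: {missing}")
        if list(self.values.columns) != list(self.annotations.index):
            raise ValueError("annotation rows must match sample columns, in order")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.annotations)

    def cell(self, condition: str, day) -> pd.DataFrame:
        """Replicate columns measured at one (condition, day) combination."""
        ann = self.annotations
        mask = (ann["condition"] == condition) & (ann["day"] == day)
        cols = ann.index[mask]
        if len(cols) == 0:
            raise KeyError(f"no samples for condition={condition!r}, day={day}")
        return self.values[cols]


@dataclass(frozen=True)
class StageDesign:
    """A stage as an ordered list of (condition, day) segments."""

    stage_label: str
    segments: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        days = [d for _, d in self.segments]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"stage {self.stage_label}: days must strictly increase")

    @property
    def days(self) -> tuple[float, ...]:
        return tuple(d for _, d in self.segments)


@dataclass
class StageProfile:
    """Replicate-averaged gene x day expression profile for one stage."""

    stage_label: str
    values: pd.DataFrame  # genes x days

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def days(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)

    def subset_genes(self, genes) -> "StageProfile":
        return StageProfile(self.stage_label, self.values.loc[list(genes)])


def default_stage_designs(conditions=DEFAULT_CONDITIONS,
                          days=DEFAULT_DAYS) -> list[StageDesign]:
    """The three composite stage designs of the reference experiment.

    Stage I runs entirely under the first condition; stage II switches to the
    second condition after day 1; stage III additionally switches to the third
    condition after day 3.
    """
    c1, c2, c3 = conditions
    d = list(days)
    return [
        StageDesign("I", tuple((c1, day) for day in d)),
        StageDesign("II", tuple((c1, day) for day in d if day <= 1)
                    + tuple((c2, day) for day in d if day >= 3)),
        StageDesign("III", tuple((c1, day) for day in d if day <= 1)
                    + tuple((c2, day) for day in d if day == 3)
                    + tuple((c3, day) for day in d if day >= 5)),
    ]


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the across-sample mean distribution.

    After the call every column has the same order statistics (the mean of the
    per-sample order statistics); ties within a sample receive the mean of the
    reference values over the tied ranks, which makes the transform idempotent.
    """
    vals = matrix.values.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValueError("quantile normalisation needs at least 2 samples")
    order = np.argsort(vals, axis=0, kind="stable")
    reference = np.take_along_axis(vals, order, axis=0).mean(axis=1)
    ref_csum = np.concatenate([[0.0], np.cumsum(reference)])

    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        sorter = order[:, j]
        col_sorted = vals[sorter, j]
        # runs of tied values share the mean reference over their rank span
        bounds = np.flatnonzero(np.diff(col_sorted) != 0) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [len(col_sorted)]])
        run_means = (ref_csum[ends] - ref_csum[starts]) / (ends - starts)
        out[sorter, j] = np.repeat(run_means, ends - starts)

    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        matrix.annotations,
    )


def normalize_to_baseline(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract, per gene and condition, the day-0 replicate mean.

    Optional control normalisation: expression becomes the change relative to
    the undifferentiated culture at the start of each condition's time course.
    """
    vals = matrix.values.copy()
    ann = matrix.annotations
    for condition in ann["condition"].unique():
        cols = ann.index[ann["condition"] == condition]
        day0 = ann.index[(ann["condition"] == condition) & (ann["day"] == 0)]
        if len(day0) == 0:
            raise ValueError(f"condition {condition!r} has no day-0 samples")
        baseline = vals[day0].mean(axis=1)
        vals[cols] = vals[cols].sub(baseline, axis=0)
    return ExpressionMatrix(vals, ann)


def collapse_probes(values: pd.DataFrame, probe_to_gene: dict[str, str]) -> pd.DataFrame:
    """Collapse probe-level rows to genes, keeping the max-variance probe."""
    known = values.index.intersection(list(probe_to_gene))
    sub = values.loc[known]
    genes = pd.Series({p: probe_to_gene[p] for p in known})
    variance = sub.var(axis=1)
    best = variance.groupby(genes).idxmax()
    collapsed = sub.loc[best.values]
    collapsed.index = best.index
    return collapsed.sort_index()


# ---------------------------------------------------------------------------
# Stage assembly and DE filtering
# ---------------------------------------------------------------------------

def assemble_stage_profile(matrix: ExpressionMatrix, design: StageDesign) -> StageProfile:
    """Average replicates within each (condition, day) segment of the design."""
    columns = {}
    for condition, day in design.segments:
        try:
            cell = matrix.cell(condition, day)
        except KeyError as exc:
            raise KeyError(
                f"stage {design.stage_label}: missing samples for "
                f"(condition={condition!r}, day={day})"
            ) from exc
        columns[day] = cell.mean(axis=1)
    values = pd.DataFrame(columns)
    return StageProfile(design.stage_label, values)


def anova_de_filter(matrix: ExpressionMatrix, design: StageDesign,
                    fdr_threshold: float = 1e-3) -> pd.DataFrame:
    """One-way ANOVA across the stage's time points with BH-FDR selection.

    Groups are the design's (condition, day) cells; observations are the
    replicates within each cell.  Returns a per-gene table with columns
    ``F, p, p_adj, selected``; constant genes get p = 1 with a warning.
    """
    if not (0 < fdr_threshold <= 1):
        raise ValueError("fdr_threshold must be in (0, 1]")
    groups = []
    for condition, day in design.segments:
        cell = matrix.cell(condition, day).to_numpy(dtype=float)
        if cell.shape[1] < 2:
            raise ValueError(
                f"stage {design.stage_label}: (condition={condition!r}, day={day}) "
                f"has {cell.shape[1]} replicate(s); ANOVA needs >= 2"
            )
        groups.append(cell)

    with np.errstate(invalid="ignore", divide="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_stat, p = stats.f_oneway(*groups, axis=1)

    constant = ~np.isfinite(p)
    if constant.any():
        logger.warning("stage %s: %d constant gene(s) assigned p = 1",
                       design.stage_label, int(constant.sum()))
        p = np.where(constant, 1.0, p)
        f_stat = np.where(np.isfinite(f_stat), f_stat, 0.0)

    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame(
        {"F": f_stat, "p": p, "p_adj": p_adj,
         "selected": p_adj < fdr_threshold},
        index=matrix.values.index,
    )
    return table
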