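"""Nodule-surface voltage surveys, oxygen-evolution feasibility and
comparative statistics.

Polymetallic nodules behave as weak galvanic cells ("geo-batteries"): open
circuit potentials measured between two platinum electrodes on a nodule
surface, corrected for the electrode-only seawater background, are compared
against the voltage required to drive the oxygen evolution reaction (OER) —
the 1.23 V thermodynamic water-splitting potential plus an overpotential,
optionally lowered when the reaction proceeds via the lattice-oxygen-mediated
mechanism.  The module also provides the comparative statistics used on
chamber flux tables: one-way ANOVA across chambers/treatments/cruises and
Spearman rank correlations (exact permutation p-values at small n) against
nodule surface area and taxon relative abundances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .constants import FARADAY_C_PER_MOL

__all__ = [
    "VoltageSurvey",
    "SurveyStats",
    "OERAssessment",
    "water_splitting_potential",
    "summarize_survey",
    "assess_oer",
    "AnovaResult",
    "anova_oneway",
    "spearman_correlation",
    "aggregate_taxa",
]


@dataclass
class VoltageSurvey:
    """Replicate surface potentials for one specimen.

    ``potentials`` are the raw recorded voltages; ``background`` is the mean
    electrode-only seawater voltage subtracted to obtain ``corrected``.
    """

    specimen: str
    license_area: str
    temperature: float  # degC
    potentials: np.ndarray
    background: float

    def __post_init__(self) -> None:
        self.potentials = np.atleast_1d(np.asarray(self.potentials, dtype=float))
        if self.potentials.size == 0:
            raise ValueError("survey has no replicate potentials")

    @property
    def corrected(self) -> np.ndarray:
        return self.potentials - self.background

    @property
    def n(self) -> int:
        return int(self.potentials.size)


@dataclass
class SurveyStats:
    """Box-whisker summary of background-corrected potentials."""

    specimen: str
    min: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float
    n: int

    def to_dict(self) -> dict:
        return dict(vars(self))


def _tukey_hinges(values: np.ndarray) -> tuple[float, float]:
    """Lower/upper hinges: medians of the halves, median itself excluded
    from both halves when n is odd."""
    v = np.sort(values)
    n = v.size
    half = n // 2
    lower = v[:half]
    upper = v[n - half:]
    if half == 0:  # single observation
        return float(v[0]), float(v[0])
    return float(np.median(lower)), float(np.median(upper))


def summarize_survey(survey: VoltageSurvey) -> SurveyStats:
    """Order statistics of corrected potentials for a box-whisker plot.

    Quartiles use the Tukey-hinge convention (halves excluding the median),
    matching standard box-plot construction.
    """
    c = survey.corrected
    q1, q3 = _tukey_hinges(c)
    return SurveyStats(
        specimen=survey.specimen,
        min=float(c.min()),
        q1=q1,
        median=float(np.median(c)),
        mean=float(c.mean()),
        q3=q3,
        max=float(c.max()),
        n=survey.n,
    )


def water_splitting_potential(
    gibbs_free_energy_kj_mol: float = 237.1, electrons: int = 2
) -> float:
    """Thermodynamic cell voltage |dG|/(nF) in volts.

    With the standard Gibbs energy of water formation, 237.1 kJ mol-1, and
    the two electrons transferred per water molecule this gives the familiar
    1.23 V water-splitting potential.
    """
    if electrons < 1:
        raise ValueError("electrons must be at least 1")
    return abs(gibbs_free_energy_kj_mol) * 1000.0 / (electrons * FARADAY_C_PER_MOL)


@dataclass
class OERAssessment:
    """Feasibility of the oxygen evolution reaction at observed potentials.

    ``required = thermodynamic + overpotential - mechanism_reduction``;
    the comparison is inclusive (observed max equal to the requirement
    counts as feasible).
    """

    thermodynamic_v: float = 1.23
    overpotential_v: float = 0.37
    mechanism: str = "standard"  # or "lattice-oxygen-mediated"
    mechanism_reduction_v: float = 0.0
    observed_max_v: float = float("nan")
    n_surveys: int = 0

    @property
    def required_v(self) -> float:
        red = self.mechanism_reduction_v if self.mechanism != "standard" else 0.0
        return self.thermodynamic_v + self.overpotential_v - red

    @property
    def feasible(self) -> bool:
        return self.observed_max_v >= self.required_v

    def summary(self) -> str:
        return (
            f"OER requirement ({self.mechanism}): {self.required_v:.3f} V; "
            f"observed max (corrected, {self.n_surveys} surveys): "
            f"{self.observed_max_v:.3f} V -> "
            f"{'feasible' if self.feasible else 'infeasible'}"
        )


def assess_oer(
    surveys: list[VoltageSurvey],
    thermodynamic_v: float = 1.23,
    overpotential_v: float = 0.37,
    mechanism: str = "standard",
    mechanism_reduction_v: float = 0.0,
) -> OERAssessment:
    """Compare the maximum corrected potential to the OER requirement."""
    if not surveys:
        raise ValueError("at least one survey required")
    observed = max(float(s.corrected.max()) for s in surveys)
    return OERAssessment(
        thermodynamic_v=thermodynamic_v,
        overpotential_v=overpotential_v,
        mechanism=mechanism,
        mechanism_reduction_v=mechanism_reduction_v,
        observed_max_v=observed,
        n_surveys=len(surveys),
    )


# ---------------------------------------------------------------------------
# comparative statistics
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float

    def format(self) -> str:
        return f"F{self.df_between},{self.df_within} = {self.f:.3f}, p = {self.p:.3f}"


def anova_oneway(groups: list[np.ndarray]) -> AnovaResult:
    """Classical one-way ANOVA from the sum-of-squares decomposition.

    Computed directly from between/within sums of squares so that the
    degenerate all-equal case returns F = 0, p = 1 (both sums vanish)
    instead of NaN.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must contain at least one observation")
    k = len(groups)
    n_total = sum(g.size for g in groups)
    df_b, df_w = k - 1, n_total - k
    if df_w < 1:
        raise ValueError("no residual degrees of freedom")
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    if ss_between == 0.0:
        return AnovaResult(0.0, df_b, df_w, 1.0)
    if ss_within == 0.0:
        return AnovaResult(math.inf, df_b, df_w, 0.0)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p)


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(np.sum(rx**2) * np.sum(ry**2)))
    if denom == 0.0:
        raise ValueError("zero variance in ranked data")
    return float(np.sum(rx * ry) / denom)


def spearman_correlation(
    x, y, exact_max_n: int = 9
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ranks use average ranks for ties; rho is the Pearson correlation of the
    ranks.  For n <= ``exact_max_n`` the p-value is the exact two-sided
    permutation probability P(|rho_perm| >= |rho_obs|) over all n!
    orderings; for larger n the usual t-approximation with n-2 degrees of
    freedom is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _spearman_rho(rx, ry)
    n = x.size
    if n <= exact_max_n:
        count = 0
        total = 0
        tol = 1e-12
        for perm in permutations(ry):
            r = _spearman_rho(rx, np.asarray(perm))
            if abs(r) >= abs(rho) - tol:
                count += 1
            total += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p


def aggregate_taxa(
    asv_table: pd.DataFrame, rank: str, abundance_col: str = "rel_abund",
    sample_col: str = "sample",
) -> pd.DataFrame:
    """Sum ASV relative abundances by a lineage rank within each sample.

    ``asv_table`` is long-form with one row per (sample, ASV) and a column
    per lineage rank (e.g. ``family``, ``genus``).  Totals are conserved:
    column sums per sample before and after aggregation are identical.
    """
    if rank not in asv_table.columns:
        raise ValueError(f"unknown rank {rank!r}: not a column of the table")
    out = (
        asv_table.groupby([sample_col, rank], dropna=False)[abundance_col]
        .sum()
        .reset_index()
    )
    return out.pivot(index=sample_col, columns=rank, values=abundance_col).fillna(0.0)
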