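"""Cohort-level accounting and association statistics.

Two kinds of quantity summarise a universal screening programme:

* the **screening cascade** — how many patients enter, how many are
  MMR-deficient, how many suspected of Lynch syndrome after somatic causes
  are excluded, how many complete germline testing, how many carry a
  pathogenic mutation — with the observed mutation prevalence and the
  attrition-corrected *predictive frequency*
  ``(n_suspected * n_pathogenic / n_tested) / n_total``, i.e. the yield
  among tested cases extrapolated to every suspected case; and

* **2x2 associations** between patient features and triage groups: the
  cross-product odds ratio with a Woolf (log-normal) confidence interval,
  an exact conditional-likelihood interval for sparse tables, the Pearson
  chi-squared test (no continuity correction by default, matching common
  epidemiological practice), and a pooled-variance Student t test
  computed from group summary statistics.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .triage import GermlineOutcome, GermlineResult, TriageDecision, TriageLabel
from .triage import MmrStatus
from .assay_calls import MethylationStatus, MsiStatus

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "CascadeSummary",
    "SummaryStats",
    "TTestResult",
    "odds_ratio_woolf",
    "odds_ratio_exact",
    "odds_ratio_auto",
    "chi_squared",
    "t_test_summary",
    "cascade_summary",
    "cohort_associations",
    "predictive_frequency",
    "PATTERN_KEYS",
]

#: Canonical keys for the IHC patterns of suspected cases, in report order.
PATTERN_KEYS = (
    "mlh1_unmethylated",
    "msh2_msh6",
    "msh6",
    "pms2",
    "msh6_pms2",
    "msi_normal_ihc",
)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) for group 1 and (c, d) for group 2, exposure yes/no."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError(f"negative cell in 2x2 table: {cells}")
        if sum(cells) <= 0:
            raise ValueError("empty 2x2 table")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def corrected(self) -> "ContingencyTable2x2":
        """Haldane-Anscombe correction: +0.5 on every cell."""
        return ContingencyTable2x2(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)

    def zero_cells(self) -> list[str]:
        return [name for name in "abcd" if getattr(self, name) == 0]


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2: float
    p: float
    method: str  # "woolf" or "exact"


@dataclass(frozen=True)
class SummaryStats:
    """Mean, standard deviation and size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("summary statistics require n >= 2")
        if self.sd <= 0:
            raise ValueError("summary statistics require sd > 0")


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# 2x2 statistics


def chi_squared(
    t: ContingencyTable2x2, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared test on a 2x2 table, 1 df.

    Without continuity correction (the default),
    ``chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``; the optional Yates
    correction subtracts n/2 from ``|ad - bc|`` (floored at zero).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise ValueError(f"zero margin in 2x2 table: {(a, b, c, d)}")
    diff = abs(a * d - b * c)
    if continuity_correction:
        diff = max(diff - t.n / 2.0, 0.0)
    statistic = t.n * diff**2 / math.prod(margins)
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def odds_ratio_woolf(
    t: ContingencyTable2x2,
    alpha: float = 0.05,
    zero_cell_correction: bool = False,
) -> AssociationResult:
    """Cross-product odds ratio with the Woolf (log-normal) CI.

    ``OR = ad/(bc)``;
    ``CI = exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))``.
    Zero cells are an explicit error unless the Haldane-Anscombe +0.5
    correction is opted into.
    """
    zeros = t.zero_cells()
    if zeros:
        if not zero_cell_correction:
            raise ValueError(
                f"zero cell(s) {zeros} in 2x2 table; enable zero_cell_correction "
                "or use odds_ratio_exact"
            )
        t = t.corrected()
    orr = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    z = float(stats.norm.ppf(1 - alpha / 2))
    ci_low = math.exp(math.log(orr) - z * se)
    ci_high = math.exp(math.log(orr) + z * se)
    chi2_stat, p = chi_squared(t)
    return AssociationResult(orr, ci_low, ci_high, chi2_stat, p, method="woolf")


def _log_binom(n: float, k: np.ndarray) -> np.ndarray:
    # gamma-generalised log binomial coefficient; valid for non-integer n
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


class _ConditionalDist:
    """Noncentral-hypergeometric distribution of cell ``a`` given margins.

    Margins may be non-integer (after Haldane correction); the support is
    the integer grid between the margin-implied bounds and binomial
    coefficients are continued via the gamma function.
    """

    def __init__(self, t: ContingencyTable2x2):
        m1 = t.a + t.b  # row-1 total
        n1 = t.a + t.c  # col-1 total
        lo = math.ceil(max(0.0, m1 + n1 - t.n) - 1e-12)
        hi = math.floor(min(m1, n1) + 1e-12)
        if hi < lo:
            raise ValueError("degenerate margins in 2x2 table")
        self.support = np.arange(lo, hi + 1, dtype=float)
        self.logw = _log_binom(m1, self.support) + _log_binom(
            t.n - m1, n1 - self.support
        )
        self.a = t.a
        if hi == lo:
            raise ValueError("degenerate margins: conditional distribution is a point mass")

    def _probs(self, log_psi: float) -> np.ndarray:
        logp = self.logw + self.support * log_psi
        logp -= logp.max()
        p = np.exp(logp)
        return p / p.sum()

    def mean(self, log_psi: float) -> float:
        return float(self._probs(log_psi) @ self.support)

    def sf(self, log_psi: float) -> float:
        """P(X >= a)."""
        return float(self._probs(log_psi)[self.support >= self.a - 1e-12].sum())

    def cdf(self, log_psi: float) -> float:
        """P(X <= a)."""
        return float(self._probs(log_psi)[self.support <= self.a + 1e-12].sum())


def _solve_log_psi(fun, target, lo=-50.0, hi=50.0) -> float:
    g = lambda x: fun(x) - target
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        return math.inf if abs(glo) < abs(ghi) else -math.inf
    return float(optimize.brentq(g, lo, hi, xtol=1e-10))


def odds_ratio_exact(
    t: ContingencyTable2x2,
    alpha: float = 0.05,
    zero_cell_correction: bool = False,
) -> AssociationResult:
    """Conditional maximum-likelihood odds ratio with an exact CI.

    The distribution of the ``a`` cell given both margins is noncentral
    hypergeometric with the odds ratio as noncentrality.  The point
    estimate solves ``E[A | psi] = a``; the confidence limits invert the
    tail probabilities, ``P(A >= a | psi_low) = alpha/2`` and
    ``P(A <= a | psi_high) = alpha/2`` (Fisher/Cornfield exact limits).
    When ``a`` sits on the edge of its support the corresponding limit is
    0 or infinite; the optional Haldane +0.5 correction moves the table
    off the edge and yields finite limits.
    """
    if zero_cell_correction and t.zero_cells():
        t = t.corrected()
    dist = _ConditionalDist(t)
    lo, hi = dist.support[0], dist.support[-1]
    # point estimate
    if t.a <= lo + 1e-12:
        orr = 0.0
    elif t.a >= hi - 1e-12:
        orr = math.inf
    else:
        orr = math.exp(_solve_log_psi(dist.mean, t.a))
    # exact limits: sf increases and cdf decreases in psi
    ci_low = 0.0 if t.a <= lo + 1e-12 else math.exp(
        _solve_log_psi(dist.sf, alpha / 2)
    )
    ci_high = math.inf if t.a >= hi - 1e-12 else math.exp(
        _solve_log_psi(dist.cdf, alpha / 2)
    )
    try:
        chi2_stat, p = chi_squared(t)
    except ValueError:
        chi2_stat, p = float("nan"), float("nan")
    return AssociationResult(orr, ci_low, ci_high, chi2_stat, p, method="exact")


def odds_ratio_auto(
    t: ContingencyTable2x2, alpha: float = 0.05, sparse_threshold: float = 5
) -> AssociationResult:
    """Woolf OR by default; exact conditional OR when any cell is sparse."""
    if any(getattr(t, name) < sparse_threshold for name in "abcd"):
        return odds_ratio_exact(t, alpha=alpha)
    return odds_ratio_woolf(t, alpha=alpha)


def t_test_summary(g1: SummaryStats, g2: SummaryStats) -> TTestResult:
    """Two-sided pooled-variance Student t test from summary statistics."""
    t_stat, p = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=True
    )
    return TTestResult(float(t_stat), g1.n + g2.n - 2, float(p))


# ---------------------------------------------------------------------------
# Screening cascade


@dataclass(frozen=True)
class CascadeSummary:
    """Counts at every node of the screening funnel plus derived fractions."""

    n_total: int
    n_ihc_loss: int
    n_msi: int
    n_concordant: int
    n_discordant: int
    n_mmr_deficient: int
    n_mlh1_loss: int
    n_mlh1_methylated: int
    n_sporadic_methylated: int
    n_epimutation_suspected: int
    n_suspected: int
    n_pending: int
    n_unresolvable: int
    n_tested: int
    n_pathogenic: int
    prevalence_observed: float
    pattern_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        chain = (
            self.n_pathogenic,
            self.n_tested,
            self.n_suspected,
            self.n_mmr_deficient,
            self.n_total,
        )
        if any(x > y for x, y in zip(chain, chain[1:])):
            raise ValueError(f"inconsistent funnel counts: {chain}")


def _pattern_key(decision: TriageDecision) -> str:
    lost = decision.lost
    if not lost:
        return "msi_normal_ihc"
    if "MLH1" in lost:
        return "mlh1_unmethylated"
    if "MSH2" in lost:
        return "msh2_msh6"
    if "MSH6" in lost and "PMS2" in lost:
        return "msh6_pms2"
    if "MSH6" in lost:
        return "msh6"
    return "pms2"


def cascade_summary(
    decisions: Sequence[TriageDecision],
    germline: Optional[Sequence[Sequence[GermlineResult]]] = None,
) -> CascadeSummary:
    """Aggregate per-patient decisions (and germline outcomes) into the funnel.

    ``germline`` is a parallel sequence of per-patient germline results; a
    patient counts as tested when any plan gene has a completed outcome
    and as a carrier when any outcome is pathogenic.  Germline results
    attached to non-suspected patients draw a warning and are ignored.
    """
    if not decisions:
        raise ValueError("empty cohort: cascade and prevalence are undefined")
    if germline is None:
        germline = [()] * len(decisions)
    if len(germline) != len(decisions):
        raise ValueError("germline results must parallel the decisions")

    n_total = len(decisions)
    labels = Counter(d.label for d in decisions)
    n_ihc_loss = sum(bool(d.lost) for d in decisions)
    n_msi = sum(d.msi_status is MsiStatus.MSI for d in decisions)
    n_concordant = sum(
        bool(d.lost) == (d.msi_status is MsiStatus.MSI) for d in decisions
    )
    n_deficient = sum(d.mmr is MmrStatus.DEFICIENT for d in decisions)
    n_mlh1_loss = sum("MLH1" in d.lost for d in decisions)
    n_mlh1_methylated = sum(
        "MLH1" in d.lost and d.meth_tumor is MethylationStatus.METHYLATED
        for d in decisions
    )

    n_tested = 0
    n_pathogenic = 0
    pattern_counts: Counter[str] = Counter()
    for d, results in zip(decisions, germline):
        if d.label is TriageLabel.SUSPECTED_LS:
            pattern_counts[_pattern_key(d)] += 1
            completed = [
                r for r in results if r.outcome is not GermlineOutcome.NOT_DONE
            ]
            if completed:
                n_tested += 1
            if any(r.outcome is GermlineOutcome.PATHOGENIC for r in completed):
                n_pathogenic += 1
        elif results:
            warnings.warn(
                f"germline results for non-suspected patient {d.patient_id}; "
                "excluded from the funnel",
                stacklevel=2,
            )

    return CascadeSummary(
        n_total=n_total,
        n_ihc_loss=n_ihc_loss,
        n_msi=n_msi,
        n_concordant=n_concordant,
        n_discordant=n_total - n_concordant,
        n_mmr_deficient=n_deficient,
        n_mlh1_loss=n_mlh1_loss,
        n_mlh1_methylated=n_mlh1_methylated,
        n_sporadic_methylated=labels[TriageLabel.SPORADIC_METHYLATED],
        n_epimutation_suspected=labels[TriageLabel.CONSTITUTIONAL_EPIMUTATION_SUSPECTED],
        n_suspected=labels[TriageLabel.SUSPECTED_LS],
        n_pending=labels[TriageLabel.PENDING_METHYLATION],
        n_unresolvable=labels[TriageLabel.UNRESOLVABLE],
        n_tested=n_tested,
        n_pathogenic=n_pathogenic,
        prevalence_observed=n_pathogenic / n_total,
        pattern_counts={k: pattern_counts.get(k, 0) for k in PATTERN_KEYS},
    )


def cohort_associations(
    cohort,
    decisions: Sequence[TriageDecision],
    ci_method: str = "auto",
    alpha: float = 0.05,
) -> dict[str, tuple[ContingencyTable2x2, AssociationResult]]:
    """Suspected-vs-rest 2x2 associations for the standard clinical variables.

    For each variable a 2x2 table is built over the patients with the
    variable recorded (missing values shrink the denominator, as in
    clinical tables): (a, b) = exposed/unexposed among suspected cases,
    (c, d) among the remaining patients.  Variables whose table has an
    empty margin are skipped.
    """
    fn = {
        "woolf": odds_ratio_woolf,
        "exact": odds_ratio_exact,
        "auto": odds_ratio_auto,
    }[ci_method]
    suspected_ids = {
        d.patient_id for d in decisions if d.label is TriageLabel.SUSPECTED_LS
    }

    def exposure(name):
        if name == "age_lt_50":
            return lambda p: (p.age < 50) if p.age is not None and p.age >= 0 else None
        return lambda p, _n=name: getattr(p, _n)

    out: dict[str, tuple[ContingencyTable2x2, AssociationResult]] = {}
    for name in ("age_lt_50", "synchronous_ovarian", "til", "lvi", "lus", "rbg",
                 "amii"):
        get = exposure(name)
        a = b = c = d = 0
        for p in cohort:
            val = get(p)
            if val is None:
                continue
            if p.patient_id in suspected_ids:
                a, b = (a + 1, b) if val else (a, b + 1)
            else:
                c, d = (c + 1, d) if val else (c, d + 1)
        try:
            table = ContingencyTable2x2(a, b, c, d)
            out[name] = (table, fn(table, alpha=alpha))
        except ValueError:
            continue
    return out


def predictive_frequency(s: CascadeSummary) -> float:
    """Attrition-corrected mutation prevalence.

    The mutation yield among tested cases is extrapolated to every
    suspected case: ``(n_suspected * n_pathogenic / n_tested) / n_total``.
    """
    if s.n_tested == 0:
        raise ValueError("predictive frequency undefined with no tested patients")
    return (s.n_suspected * s.n_pathogenic / s.n_tested) / s.n_total
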