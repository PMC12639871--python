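"""Cohort screening metrics and Jeffreys-prior Bayesian performance estimates.

Rates are reported as percentages rounded half-up to two decimals and
incidences as 1:N ratios with N rounded to the nearest integer — the
conventions used in newborn-screening reports.  Sensitivity and specificity
from small confirmed cohorts are estimated as Beta posteriors under the
Jeffreys non-informative prior Beta(0.5, 0.5): after x successes in n
trials the posterior is Beta(x + 0.5, n - x + 0.5), whose mean
(x + 0.5)/(n + 1) shrinks the empirical proportion away from the boundary.
Credible intervals are equal-tailed quantiles of that posterior.
"""

from __future__ import annotations

import json
import warnings as _warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

from scipy.stats import beta as beta_dist


@dataclass(frozen=True)
class CohortCounts:
    screened: int
    males: int
    females: int
    initial_positive: int
    recalled_tested: int
    recall_positive: int
    confirmed: int
    confirmed_males: int
    confirmed_females: int
    ohp_threshold_nmol_per_l: float = 12.0

    def __post_init__(self):
        if not (self.confirmed <= self.recall_positive
                <= self.recalled_tested <= self.initial_positive
                <= self.screened):
            raise ValueError("count table violates screening funnel ordering")
        if self.males + self.females != self.screened:
            raise ValueError("males + females must equal screened")

    @classmethod
    def from_json(cls, path_or_handle) -> "CohortCounts":
        if hasattr(path_or_handle, "read"):
            doc = json.load(path_or_handle)
        else:
            with open(path_or_handle) as fh:
                doc = json.load(fh)
        return cls(**doc)

    @classmethod
    def packaged(cls) -> "CohortCounts":
        with resources.files("cahlrs.data").joinpath(
                "cohort_counts.json").open() as fh:
            return cls.from_json(fh)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class PosteriorSummary:
    alpha: float
    beta: float
    mean: float
    cri_low: float
    cri_high: float
    level: float = 0.95

    @property
    def mean_percent(self) -> float:
        """Posterior mean as a percentage rounded half-up to one decimal."""
        return float(Decimal(self.mean * 100).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP))


def rate_percent(numerator: int, denominator: int, dp: int = 2) -> float:
    """100 * numerator/denominator, rounded half-up to dp decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    q = Decimal(1).scaleb(-dp)
    return float((Decimal(numerator) * 100 / Decimal(denominator))
                 .quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class IncidenceRatio:
    cases: int
    population: int
    n: int

    def __str__(self):
        return f"1:{self.n:,}"

    @property
    def text(self):
        return f"1:{self.n}"


def incidence_ratio(cases: int, population: int) -> IncidenceRatio:
    """Incidence as 1:N with N = population/cases rounded to nearest."""
    if cases < 1:
        raise ValueError("incidence undefined for zero cases")
    n = int((Decimal(population) / Decimal(cases))
            .quantize(Decimal(1), rounding=ROUND_HALF_UP))
    return IncidenceRatio(cases, population, n)


def jeffreys_posterior(successes: int, trials: int,
                       level: float = 0.95) -> PosteriorSummary:
    """Beta posterior under the Jeffreys prior with an equal-tailed interval.

    The quantiles come from regularized-incomplete-beta inversion
    (scipy's beta.ppf), accurate well beyond 1e-10.
    """
    if successes < 0 or trials < 0 or successes > trials:
        raise ValueError("need 0 <= successes <= trials")
    a = successes + 0.5
    b = trials - successes + 0.5
    mean = a / (a + b)
    tail = (1 - level) / 2
    lo = float(beta_dist.ppf(tail, a, b))
    hi = float(beta_dist.ppf(1 - tail, a, b))
    return PosteriorSummary(a, b, mean, lo, hi, level)


def confusion_metrics(c: ConfusionCounts, level: float = 0.95) -> dict:
    """Sensitivity/specificity posteriors and the false-positive rate."""
    out: dict = {}
    if c.tp + c.fn >= 1:
        out["sensitivity_posterior"] = jeffreys_posterior(c.tp, c.tp + c.fn,
                                                          level)
    else:
        _warnings.warn("no condition-positive samples; sensitivity omitted")
    if c.tn + c.fp >= 1:
        out["specificity_posterior"] = jeffreys_posterior(c.tn, c.tn + c.fp,
                                                          level)
    else:
        _warnings.warn("no condition-negative samples; specificity omitted")
    if c.fp + c.tn >= 1:
        out["fpr"] = c.fp / (c.fp + c.tn)
    return out


def cohort_metrics(counts: CohortCounts) -> dict:
    """The screening-funnel arithmetic of a cohort count table."""
    m = {
        "initial_positivity_percent":
            rate_percent(counts.initial_positive, counts.screened),
        "recall_rate_percent":
            rate_percent(counts.recalled_tested, counts.initial_positive),
        "recall_positivity_percent":
            rate_percent(counts.recall_positive, counts.recalled_tested),
        "ppv_initial_percent":
            rate_percent(counts.confirmed, counts.initial_positive),
        "ppv_recall_percent":
            rate_percent(counts.confirmed, counts.recall_positive),
        "incidence": incidence_ratio(counts.confirmed, counts.screened),
    }
    if counts.confirmed_males:
        m["incidence_males"] = incidence_ratio(counts.confirmed_males,
                                               counts.males)
    if counts.confirmed_females:
        m["incidence_females"] = incidence_ratio(counts.confirmed_females,
                                                 counts.females)
    return m


def metrics_json(metrics: dict) -> str:
    doc = {}
    for k, v in metrics.items():
        if isinstance(v, IncidenceRatio):
            doc[k] = {"ratio": v.text, "n": v.n}
        elif isinstance(v, PosteriorSummary):
            doc[k] = {"alpha": v.alpha, "beta": v.beta, "mean": v.mean,
                      "cri": [v.cri_low, v.cri_high]}
        else:
            doc[k] = v
    return json.dumps(doc, indent=1, sort_keys=True)


def metrics_text(counts: CohortCounts, metrics: dict) -> str:
    """Text table mirroring the screening-results narrative."""
    lines = [
        f"screened: {counts.screened:,} "
        f"({counts.males:,} male / {counts.females:,} female)",
        f"initial positivity: {metrics['initial_positivity_percent']:.2f}% "
        f"({counts.initial_positive:,}/{counts.screened:,})",
        f"recall rate: {metrics['recall_rate_percent']:.2f}% "
        f"({counts.recalled_tested:,}/{counts.initial_positive:,})",
        f"recall positivity: {metrics['recall_positivity_percent']:.2f}% "
        f"({counts.recall_positive:,}/{counts.recalled_tested:,})",
        f"PPV initial: {metrics['ppv_initial_percent']:.2f}% "
        f"({counts.confirmed}/{counts.initial_positive:,})",
        f"PPV recall: {metrics['ppv_recall_percent']:.2f}% "
        f"({counts.confirmed}/{counts.recall_positive})",
        f"incidence: {metrics['incidence']}",
    ]
    if "incidence_males" in metrics:
        lines.append(f"incidence (males): {metrics['incidence_males']}")
    if "incidence_females" in metrics:
        lines.append(f"incidence (females): {metrics['incidence_females']}")
    return "\n".join(lines) + "\n"
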