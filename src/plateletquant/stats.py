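"""Cohort statistics on per-platelet granule counts.

Per-platelet counts are Poisson-like, so group comparison is rank-based: a
tie-corrected Kruskal–Wallis test across subjects, with Dunn-type pairwise
z-tests on mean ranks (Bonferroni family-wise control) standing in for the
"Kruskal–Wallis multiple comparison" of clinical practice.  Group-level
summaries (mean, SD) treat the *subject mean* as the observation, matching
the dispersion a clinician reports across individuals rather than platelets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

logger = logging.getLogger("plateletquant")


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class SubjectCounts:
    """Per-subject vector of per-platelet granule counts (the statistical unit)."""

    subject_id: str
    group: str  # 'control' or 'patient'
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.size == 0:
            raise InputError("counts must be non-empty")
        if (c < 0).any():
            raise InputError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))


@dataclass(frozen=True)
class PairwiseResult:
    """One Dunn pairwise comparison between two subjects."""

    subject_a: str
    subject_b: str
    z: float
    p_unadjusted: float
    significant: bool


@dataclass(frozen=True)
class KWResult:
    """Kruskal–Wallis outcome with per-group mean ranks and pairwise decisions."""

    H: float
    dof: int
    p_value: float
    mean_rank: dict[str, float]
    pairwise: list[PairwiseResult] = field(default_factory=list)


@dataclass(frozen=True)
class ECDF:
    """Right-continuous empirical CDF with explicit support."""

    support: np.ndarray
    fractions: np.ndarray

    def __call__(self, x: float) -> float:
        i = int(np.searchsorted(self.support, x, side="right"))
        return 0.0 if i == 0 else float(self.fractions[i - 1])


def ecdf(counts: np.ndarray) -> ECDF:
    """Empirical cumulative distribution of a counts vector."""
    c = np.asarray(counts)
    if c.size == 0:
        raise InputError("empty input")
    support, n = np.unique(c, return_counts=True)
    return ECDF(support=support.astype(float), fractions=np.cumsum(n) / c.size)


def _tie_term(pooled: np.ndarray) -> float:
    """sum(t^3 - t) over tied groups of the pooled sample."""
    _, t = np.unique(pooled, return_counts=True)
    return float(np.sum(t.astype(float) ** 3 - t))


def kruskal_wallis(groups: list[np.ndarray]) -> KWResult:
    """Tie-corrected Kruskal–Wallis H with chi-square p (dof = k - 1).

    All-identical observations give H = 0, p = 1.
    """
    if len(groups) < 2:
        raise InputError("need at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise InputError("groups must be non-empty")
    pooled = np.concatenate(arrs)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    H = 0.0
    start = 0
    for gi, a in enumerate(arrs):
        r = ranks[start: start + a.size]
        start += a.size
        rbar = float(r.mean())
        mean_rank[str(gi)] = rbar
        H += a.size * (rbar - (N + 1) / 2.0) ** 2
    H *= 12.0 / (N * (N + 1))
    tie = _tie_term(pooled)
    denom = 1.0 - tie / (N**3 - N)
    if denom <= 0:  # every observation identical
        return KWResult(H=0.0, dof=len(arrs) - 1, p_value=1.0, mean_rank=mean_rank)
    H /= denom
    dof = len(arrs) - 1
    return KWResult(H=float(H), dof=dof, p_value=float(sps.chi2.sf(H, dof)),
                    mean_rank=mean_rank)


def kw_multiple_comparison(
    subjects: list[SubjectCounts], alpha: float = 0.01
) -> KWResult:
    """Kruskal–Wallis across subjects plus Dunn pairwise z-tests.

    Pairwise statistic for subjects a, b with mean ranks Ra, Rb in the pooled
    ranking of N observations:

        z = (Ra - Rb) / sqrt((N(N+1)/12 - T/(12(N-1))) * (1/na + 1/nb))

    with T = sum(t^3 - t) over ties.  Family-wise control is Bonferroni over
    all unordered pairs at the given alpha (alpha = 0.01 corresponds to the
    clinically quoted "99% confidence").  Subjects with fewer than 2 platelets are excluded with
    a warning.
    """
    usable = []
    for s in subjects:
        if s.counts.size < 2:
            logger.warning("subject %s has < 2 platelets; excluded from "
                           "multiple comparison", s.subject_id)
            continue
        usable.append(s)
    if len(usable) < 2:
        raise InputError("need at least two usable subjects")

    kw = kruskal_wallis([s.counts for s in usable])
    mean_rank = {s.subject_id: kw.mean_rank[str(i)] for i, s in enumerate(usable)}

    pooled = np.concatenate([s.counts.astype(float) for s in usable])
    N = pooled.size
    tie = _tie_term(pooled)
    var_term = N * (N + 1) / 12.0 - tie / (12.0 * (N - 1))

    pairs = [(a, b) for i, a in enumerate(usable) for b in usable[i + 1:]]
    m = len(pairs)
    pairwise: list[PairwiseResult] = []
    for a, b in pairs:
        se = np.sqrt(var_term * (1.0 / a.counts.size + 1.0 / b.counts.size))
        z = (mean_rank[a.subject_id] - mean_rank[b.subject_id]) / se if se > 0 else 0.0
        p = 2.0 * float(sps.norm.sf(abs(z)))
        pairwise.append(
            PairwiseResult(
                subject_a=a.subject_id,
                subject_b=b.subject_id,
                z=float(z),
                p_unadjusted=p,
                significant=bool(p < alpha / m),
            )
        )
    return KWResult(H=kw.H, dof=kw.dof, p_value=kw.p_value,
                    mean_rank=mean_rank, pairwise=pairwise)


def group_summary(
    subjects: list[SubjectCounts],
) -> dict[str, dict[str, float | None]]:
    """Per-group mean and SD of *subject mean* counts.

    The subject mean is the unit of analysis; with a single subject the SD is
    undefined and reported as None.
    """
    by_group: dict[str, list[float]] = {}
    for s in subjects:
        by_group.setdefault(s.group, []).append(s.mean)
    if not by_group:
        raise InputError("no subjects")
    out: dict[str, dict[str, float | None]] = {}
    for g, means in sorted(by_group.items()):
        out[g] = {
            "mean": float(np.mean(means)),
            "sd": float(np.std(means, ddof=1)) if len(means) > 1 else None,
            "n_subjects": len(means),
        }
    return out


def sample_size_estimate(
    control: tuple[float, float],
    patient: tuple[float, float],
    alpha: float = 0.01,
    power: float = 0.99,
) -> int | None:
    """Platelets per sample for a one-sample t-test to separate the groups.

    ``control`` and ``patient`` are (mean, SD) summaries of per-platelet
    counts; the test drafts a sample from the control distribution and tests
    against the patient mean, so the control SD sets the effect size.  Returns
    None when the effect size is zero (difference not detectable).  This is a
    reporting utility, not a reproduction of any printed figure.
    """
    mean_c, sd_c = control
    mean_p, _ = patient
    if not sd_c > 0:
        raise InputError("control SD must be positive")
    effect = abs(mean_c - mean_p) / sd_c
    if effect == 0:
        return None
    from statsmodels.stats.power import TTestPower

    n = TTestPower().solve_power(effect_size=effect, alpha=alpha, power=power,
                                 alternative="two-sided")
    return int(np.ceil(float(n)))
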