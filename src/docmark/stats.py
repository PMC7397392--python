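"""Nonparametric prognostic statistics.

Patients are labelled by 6-month functional outcome on the Glasgow
Outcome Scale - Extended (GOS-E, 1-8): a score of 2 or below is
outcome-negative, above 2 outcome-positive. Each patient subgroup's SCR
delta indices are tested against the healthy-control median with a
one-sample Wilcoxon signed-rank test, the two subgroups are compared
with a Mann-Whitney U test, and the healthy word/pseudo-word contrast is
a paired t test complemented by a default-prior (JZS) Bayes factor.

The Wilcoxon and Mann-Whitney tests support two p-value routes:

* ``exact`` — full enumeration of the permutation null (all 2^m sign
  assignments, or all C(n+m, n) group assignments), valid under ties
  because the observed (average) ranks are permuted.
* ``asymptotic`` — normal approximation with tie-corrected variance and
  a continuity correction. This is the default because small-sample
  clinical software commonly reports it (an exact two-sided p at n = 5
  cannot fall below 0.0625, yet values such as p = 0.043 are routinely
  printed); ``exact`` is recommended for n below ~10 when reproducing
  published Z values is not the goal.

Zero differences are dropped before ranking; tied absolute differences
receive average ranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import integrate
from scipy import stats as sps

OUTCOME_NEGATIVE = "outcome_negative"
OUTCOME_POSITIVE = "outcome_positive"
GOSE_THRESHOLD = 2  # <= 2 is outcome-negative

DEFAULT_PRIOR_SCALE = 1.0 / math.sqrt(2.0)

# above this many nonzero differences / total observations, enumeration
# is refused and the caller must use the asymptotic route
_EXACT_WILCOXON_MAX = 20
_EXACT_MW_MAX_TOTAL = 12


@dataclass
class OutcomeLabel:
    subject_id: str
    gose: int
    label: str


@dataclass
class TestResult:
    """Outcome of a rank test. ``statistic`` is W+ (Wilcoxon) or U for
    the first sample (Mann-Whitney); ``z_approx`` is set only on the
    asymptotic route."""

    statistic: float
    p: float
    sided: str
    method: str
    n: int
    z_approx: float | None = None


@dataclass
class BayesResult:
    t: float
    n: int
    prior_scale: float
    bf10: float


def classify_outcome(gose: int, subject_id: str = "") -> OutcomeLabel:
    """Label a patient by the GOS-E threshold rule (<= 2 negative)."""
    gose = int(gose)
    if not 1 <= gose <= 8:
        raise ValueError(f"GOS-E score must be in [1, 8], got {gose}")
    label = OUTCOME_NEGATIVE if gose <= GOSE_THRESHOLD else OUTCOME_POSITIVE
    return OutcomeLabel(subject_id=subject_id, gose=gose, label=label)


def healthy_reference(deltas) -> float:
    """Sample median of the healthy-control delta indices (mean of the
    central two for even n)."""
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("empty delta list")
    return float(np.median(deltas))


def _two_sided_tail(null: np.ndarray, weights: np.ndarray | None, observed: float) -> float:
    """2 * min(P(T <= obs), P(T >= obs)), capped at 1."""
    if weights is None:
        lo = np.mean(null <= observed + 1e-12)
        hi = np.mean(null >= observed - 1e-12)
    else:
        tot = weights.sum()
        lo = weights[null <= observed + 1e-12].sum() / tot
        hi = weights[null >= observed - 1e-12].sum() / tot
    return float(min(1.0, 2.0 * min(lo, hi)))


def _signed_rank_null_pmf(ranks: np.ndarray):
    """Exact null distribution of W+ over all 2^m sign assignments of
    the observed (average) ranks, by convolution over trials.

    Ranks are doubled so average ranks become integers; returns
    ``(support, pmf)`` on the doubled scale.
    """
    doubled = np.round(2.0 * ranks).astype(int)
    pmf = np.zeros(doubled.sum() + 1)
    pmf[0] = 1.0
    total = 0
    for r in doubled:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: pmf.size - r]
        pmf = 0.5 * (pmf + shifted)
        total += r
    return np.arange(total + 1), pmf


def wilcoxon_one_sample(values, reference: float = 0.0, method: str = "asymptotic",
                        continuity: bool = True) -> TestResult:
    """One-sample Wilcoxon signed-rank test of ``values`` against a
    reference value.

    Exact mode computes the full permutation null of W+ over all 2^m
    sign assignments of the observed ranks (m = count of nonzero
    differences; evaluated by convolution, which enumerates the same
    distribution). Asymptotic mode uses the normal approximation with
    tie-corrected variance; ``continuity=False`` reproduces the
    SPSS-style Z commonly seen in clinical reports. Two-sided.
    """
    d = np.asarray(values, dtype=float) - reference
    d = d[d != 0.0]
    m = d.size
    if m == 0:
        raise ValueError("all differences equal the reference; nothing to rank")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if method == "exact":
        if m > _EXACT_WILCOXON_MAX:
            raise ValueError(f"exact mode limited to m <= {_EXACT_WILCOXON_MAX}")
        support, pmf = _signed_rank_null_pmf(ranks)
        p = _two_sided_tail(support.astype(float), pmf, 2.0 * w_plus)
        return TestResult(statistic=w_plus, p=p, sided="two", method="exact", n=m)

    if method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")
    mean = m * (m + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = m * (m + 1) * (2 * m + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        raise ValueError("zero variance after tie correction")
    dev = w_plus - mean
    cc = 0.5 * np.sign(dev) if continuity else 0.0
    z = (dev - cc) / math.sqrt(var) if dev != 0 else 0.0
    p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult(statistic=w_plus, p=min(1.0, p), sided="two",
                      method="asymptotic+cc" if continuity else "asymptotic",
                      n=m, z_approx=float(z))


def mann_whitney(a, b, method: str = "asymptotic", continuity: bool = True) -> TestResult:
    """Mann-Whitney U test between two independent samples.

    ``statistic`` is U for sample ``a``. Exact mode enumerates all
    C(n+m, n) assignments of the pooled (average) ranks and is limited
    to n + m <= 12; otherwise use the tie-corrected normal
    approximation (``continuity=False`` for the SPSS-style Z).
    Two-sided.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = a.size, b.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = float(ranks[:n].sum())
    u_a = r_a - n * (n + 1) / 2.0

    if method == "exact":
        if n + m > _EXACT_MW_MAX_TOTAL:
            raise ValueError(f"exact enumeration limited to n + m <= {_EXACT_MW_MAX_TOTAL}")
        base = n * (n + 1) / 2.0
        null = np.array(
            [ranks[list(idx)].sum() - base for idx in combinations(range(n + m), n)]
        )
        p = _two_sided_tail(null, None, u_a)
        return TestResult(statistic=u_a, p=p, sided="two", method="exact", n=n + m)

    if method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")
    nm = n * m
    mean = nm / 2.0
    big_n = n + m
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (big_n * (big_n - 1))
    var = nm / 12.0 * (big_n + 1 - tie_term)
    if var <= 0:
        # every pooled value tied: U sits exactly at its null mean
        return TestResult(statistic=u_a, p=1.0, sided="two",
                          method="asymptotic (degenerate: all values tied)",
                          n=n + m, z_approx=0.0)
    dev = u_a - mean
    cc = 0.5 * np.sign(dev) if continuity else 0.0
    z = (dev - cc) / math.sqrt(var) if dev != 0 else 0.0
    p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult(statistic=u_a, p=min(1.0, p), sided="two",
                      method="asymptotic+cc" if continuity else "asymptotic",
                      n=n + m, z_approx=float(z))


def paired_t(x, y):
    """Paired-sample t test (two-sided).

    Returns ``(t, df, p)`` for the one-sample t on x - y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance of paired differences")
    n = d.size
    t = float(d.mean() / (sd / math.sqrt(n)))
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    return t, df, p


def jzs_bf10(t: float, n: int, prior_scale: float = DEFAULT_PRIOR_SCALE) -> BayesResult:
    """JZS default Bayes factor (BF10) for a one-sample / paired t value.

    The alternative places a zero-centred Cauchy prior with scale
    ``prior_scale`` on the standardised effect size d; the Bayes factor
    is the ratio of the marginal likelihood of t under that prior
    (noncentral-t likelihood averaged over the prior by adaptive
    quadrature) to the central-t likelihood under the null.
    """
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    n = int(n)
    if n < 2:
        raise ValueError("need n >= 2")
    if not prior_scale > 0:
        raise ValueError("prior_scale must be > 0")
    nu = n - 1
    sqrt_n = math.sqrt(n)

    def integrand(delta):
        return sps.nct.pdf(t, nu, sqrt_n * delta) * sps.cauchy.pdf(delta, 0.0, prior_scale)

    num, _ = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    den = sps.t.pdf(t, nu)
    return BayesResult(t=float(t), n=n, prior_scale=float(prior_scale), bf10=float(num / den))


def spearman(x, y, sided: str = "two"):
    """Spearman rank correlation with a t-approximation p-value.

    rho is the Pearson correlation of the average-ranked data; p uses
    t = rho * sqrt((n-2)/(1-rho^2)) with df = n - 2. ``sided='one'``
    halves the two-sided p when the observed rho lies on the tested
    (positive) side, and reports 1 - p/2 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        p_two = 0.0
    else:
        tstat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p_two = float(2.0 * sps.t.sf(abs(tstat), n - 2))
    if sided == "two":
        return rho, p_two
    if sided == "one":
        return rho, (p_two / 2.0 if rho >= 0 else 1.0 - p_two / 2.0)
    raise ValueError(f"unknown sidedness {sided!r}")


def prognostic_report(healthy_deltas, patient_deltas, patient_gose,
                      method: str = "asymptotic") -> dict:
    """The full prognostic sequence on a scored cohort.

    Computes the healthy-control median delta, tests each outcome
    subgroup's deltas against that median (one-sample Wilcoxon), and
    compares the two subgroups (Mann-Whitney). A missing subgroup is
    flagged rather than raising.
    """
    healthy_deltas = np.asarray(healthy_deltas, dtype=float)
    patient_deltas = np.asarray(patient_deltas, dtype=float)
    if healthy_deltas.size == 0:
        raise ValueError("healthy reference group is empty")
    if patient_deltas.size != len(patient_gose):
        raise ValueError("one GOS-E score required per patient delta")
    labels = np.array([classify_outcome(g).label for g in patient_gose], dtype=object)
    ref = healthy_reference(healthy_deltas)
    report: dict = {
        "healthy_median": ref,
        "n_healthy": int(healthy_deltas.size),
        "method": method,
        "subgroups": {},
        "flags": [],
    }
    groups = {}
    for label in (OUTCOME_POSITIVE, OUTCOME_NEGATIVE):
        vals = patient_deltas[labels == label]
        groups[label] = vals
        entry: dict = {"n": int(vals.size), "median": None, "wilcoxon_vs_healthy_median": None}
        if vals.size == 0:
            report["flags"].append(f"no {label} patients; comparison skipped")
        else:
            entry["median"] = float(np.median(vals))
            try:
                res = wilcoxon_one_sample(vals, ref, method=method)
                entry["wilcoxon_vs_healthy_median"] = res
            except ValueError as exc:
                report["flags"].append(f"{label}: {exc}")
        report["subgroups"][label] = entry
    if groups[OUTCOME_POSITIVE].size and groups[OUTCOME_NEGATIVE].size:
        report["mann_whitney_pos_vs_neg"] = mann_whitney(
            groups[OUTCOME_POSITIVE], groups[OUTCOME_NEGATIVE], method=method
        )
    else:
        report["mann_whitney_pos_vs_neg"] = None
        report["flags"].append("subgroup comparison skipped: a subgroup is empty")
    return report
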