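"""Group statistics: summaries, normality gate, t-tests, independence, Fisher.

The analysis chain mirrors the study design: per-group summaries of the four
features (mean +/- SEM), a Shapiro-Wilk normality gate, two-sample t-tests
for the three group pairs (AN-FA, AN-CA, FA-CA), pairwise R-square maps
assessing how independent the modalities are, and Fisher's combined
probability test over every non-empty modality subset (15 subsets x 3 group
pairs = 45 combined comparisons).

Two conventions are pinned here because they are what reproduces the
published tables from the bundled per-subject data (see docs/methods.md):

* SEM uses the population SD (divisor n); the sample-SD convention does not
  reproduce the published +/- values.
* t-tests use Welch's unequal-variance correction for Z, K and k, but the
  published %R comparisons match the pooled-variance Student t instead —
  the default "published" convention reproduces all 45 table entries, and
  ``convention="welch"`` applies Welch uniformly as the stated methodology.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import GROUPS, MODALITIES, CohortTable

__all__ = [
    "GroupSummary",
    "ComparisonMatrix",
    "IndependenceMap",
    "GROUP_PAIRS",
    "group_summary",
    "summary_table",
    "shapiro_wilk",
    "normality_gate",
    "welch_t",
    "pooled_t",
    "pearson_r2",
    "fisher_combined",
    "significance_category",
    "comparison_matrix",
    "independence_map",
]

GROUP_PAIRS = (("AN", "FA"), ("AN", "CA"), ("FA", "CA"))

#: modality -> t-test flavour that reproduces the published comparisons
PUBLISHED_TEST_CONVENTION = {"Z": "welch", "K": "welch", "k": "welch", "%R": "pooled"}


@dataclass(frozen=True)
class GroupSummary:
    group: str
    modality: str
    n: int
    mean: float
    sem: float  # population-SD convention: std(ddof=0)/sqrt(n)


def group_summary(values, group: str, modality: str) -> GroupSummary:
    """Mean and SEM (population-SD convention) of one feature column."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    return GroupSummary(
        group=group,
        modality=modality,
        n=int(v.size),
        mean=float(v.mean()),
        sem=float(v.std(ddof=0) / np.sqrt(v.size)),
    )


def summary_table(cohort: CohortTable) -> pd.DataFrame:
    """All group x modality summaries of a cohort as a tidy frame."""
    rows = []
    for g in GROUPS:
        for m in MODALITIES:
            v = cohort.values(m, g)
            if v.size:
                s = group_summary(v, g, m)
                rows.append(vars(s))
    return pd.DataFrame(rows)


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p; restricted to 3 <= n <= 50 samples."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 50:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 50, got n={v.size}")
    if np.ptp(v) == 0:
        raise ValueError("W is undefined for a constant sample")
    res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def normality_gate(cohort: CohortTable, alpha: float = 0.05) -> pd.DataFrame:
    """Shapiro-Wilk over every group x modality vector (warn-only gate).

    Vectors failing at ``alpha`` (or with undefined W) are annotated and a
    warning is emitted, but the analysis is never aborted.
    """
    rows = []
    for g in GROUPS:
        for m in MODALITIES:
            v = cohort.values(m, g)
            if v.size == 0:
                continue
            try:
                w, p = shapiro_wilk(v)
                passed = p >= alpha
            except ValueError as exc:
                w, p, passed = np.nan, np.nan, False
                warnings.warn(f"normality gate failed for {g}/{m}: {exc}")
            if not passed and np.isfinite(p):
                warnings.warn(
                    f"normality gate: {g}/{m} Shapiro-Wilk p={p:.3g} < {alpha}"
                )
            rows.append({"group": g, "modality": m, "n": v.size,
                         "W": w, "p": p, "normal": passed})
    return pd.DataFrame(rows)


def _two_sample_t(a, b, equal_var: bool) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 1.0  # identical degenerate samples: no evidence at all
        raise ValueError("zero variance in both samples with unequal means")
    return float(sps.ttest_ind(a, b, equal_var=equal_var).pvalue)


def welch_t(a, b) -> float:
    """Two-tailed Welch t-test p-value (unequal variances, sample SD)."""
    return _two_sample_t(a, b, equal_var=False)


def pooled_t(a, b) -> float:
    """Two-tailed pooled-variance Student t-test p-value."""
    return _two_sample_t(a, b, equal_var=True)


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation == R-square of the least-squares line."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def fisher_combined(pvals) -> float:
    """Fisher's combined probability: X2 = -2 sum(ln p) ~ chi2(2m)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x2 = -2.0 * np.sum(np.log(p))
    return float(sps.chi2.sf(x2, 2 * p.size))


def significance_category(p: float) -> str:
    """Star convention: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _modality_subsets() -> list[tuple[str, ...]]:
    out = []
    for r in range(1, len(MODALITIES) + 1):
        out.extend(itertools.combinations(MODALITIES, r))
    return out


@dataclass(frozen=True)
class ComparisonMatrix:
    """p-values for every modality subset x group pair (45 entries)."""

    entries: dict  # (subset tuple, (group_a, group_b)) -> p
    convention: str

    def p(self, subset, pair) -> float:
        return self.entries[(tuple(subset), tuple(pair))]

    def category(self, subset, pair) -> str:
        return significance_category(self.p(subset, pair))

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (subset, pair), p in self.entries.items():
            rows.append(
                {
                    "modalities": "+".join(subset),
                    "comparison": f"{pair[0]} vs {pair[1]}",
                    "p": p,
                    "category": significance_category(p),
                }
            )
        return pd.DataFrame(rows)


def comparison_matrix(
    cohort: CohortTable, convention: str = "published"
) -> ComparisonMatrix:
    """Single-modality t-tests and Fisher combinations for all 45 comparisons.

    Subsets of size 1 report the two-sample t-test p directly; larger
    subsets combine the (unrounded) member p-values with Fisher's method.

    ``convention="published"`` uses the per-modality t-test flavour that
    reproduces the published comparison table (Welch for Z/K/k, pooled for
    %R); ``convention="welch"`` applies Welch's correction uniformly.
    """
    if convention == "published":
        flavour = PUBLISHED_TEST_CONVENTION
    elif convention == "welch":
        flavour = {m: "welch" for m in MODALITIES}
    else:
        raise ValueError(f"unknown convention {convention!r}")

    sizes = cohort.group_sizes()
    for g in GROUPS:
        if sizes.get(g, 0) < 2:
            raise ValueError(f"group {g!r} needs n >= 2, got {sizes.get(g, 0)}")

    base: dict[tuple[str, tuple[str, str]], float] = {}
    for m in MODALITIES:
        for pair in GROUP_PAIRS:
            a = cohort.values(m, pair[0])
            b = cohort.values(m, pair[1])
            test = welch_t if flavour[m] == "welch" else pooled_t
            base[(m, pair)] = test(a, b)

    entries = {}
    for subset in _modality_subsets():
        for pair in GROUP_PAIRS:
            ps = [base[(m, pair)] for m in subset]
            entries[(subset, pair)] = ps[0] if len(ps) == 1 else fisher_combined(ps)
    return ComparisonMatrix(entries, convention)


@dataclass(frozen=True)
class IndependenceMap:
    """R-square of the pairwise linear fits, per modality pair and group."""

    entries: dict  # ((modality_a, modality_b), group) -> R2

    def r2(self, pair, group) -> float:
        return self.entries[(tuple(pair), group)]

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pair": f"{a}-{b}", "group": g, "r2": v}
            for ((a, b), g), v in self.entries.items()
        ]
        return pd.DataFrame(rows)


def independence_map(cohort: CohortTable) -> IndependenceMap:
    """R-square of every modality pair within every group (6 x 3 entries).

    Low R-square indicates a poor linear relation and hence more independent
    information contributed by the pair.
    """
    entries = {}
    for a, b in itertools.combinations(MODALITIES, 2):
        for g in GROUPS:
            entries[((a, b), g)] = pearson_r2(cohort.values(a, g), cohort.values(b, g))
    return IndependenceMap(entries)
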