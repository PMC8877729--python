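"""Population accounting and normality-gated group comparisons.

Two-group endpoints on animal-level values are tested with a dispatcher:
Shapiro–Wilk on both samples at α=0.05 gates the choice between Welch's
unequal-variance t test (parametric) and the Brunner–Munzel test
(nonparametric); paired contrasts use the paired t test or Wilcoxon's
signed-rank test.  Within a comparison family, p values are pooled and
adjusted by Holm's step-down method.  Proportions get Wilson 95% intervals,
Pearson chi-square comparisons and odds ratios.  Effect size r is reported
for every contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "GROUPS",
    "REACTIVITY_CLASSES",
    "PopulationAccounting",
    "ComparisonResult",
    "population_accounting",
    "accounting_from_counts",
    "proportion_estimate_ci",
    "select_and_run_test",
    "holm_adjust",
    "chi_square_proportions",
    "kruskal_wallis_background",
    "default_families",
    "compare_groups",
]

#: Experimental groups: sham, acute/chronic phase × single/repetitive injury.
GROUPS = ("SH", "AS", "AR", "CS", "CR")

#: The four Nissl/NeuN reactivity classes, in reporting order.
REACTIVITY_CLASSES = ("NT+NN+", "NT+NN-", "NT-NN+", "NT-NN-")


@dataclass(frozen=True)
class PopulationAccounting:
    """Reactivity-class counts and percentages before and after screening.

    Percentages are computed over the sum of the four class counts of the
    same stage and reported rounded to one decimal (raw ratios retained).
    ``declared_total`` allows recording an externally stated detection total;
    any discrepancy with the class-count sum is surfaced, never silently
    reconciled.
    """

    pre_counts: dict[str, int]
    post_counts: dict[str, int]
    declared_total: int | None = None

    @property
    def pre_total(self) -> int:
        return sum(self.pre_counts.values())

    @property
    def post_total(self) -> int:
        return sum(self.post_counts.values())

    @property
    def total_detected(self) -> int:
        return self.declared_total if self.declared_total is not None else self.pre_total

    @property
    def total_excluded(self) -> int:
        return self.total_detected - self.post_total

    def fractions(self, stage: str) -> dict[str, float]:
        counts = self.pre_counts if stage == "pre" else self.post_counts
        total = sum(counts.values())
        return {k: counts[k] / total for k in REACTIVITY_CLASSES}

    def percentages(self, stage: str) -> dict[str, float]:
        return {
            k: round(100.0 * v, 1) for k, v in self.fractions(stage).items()
        }

    @property
    def declared_total_discrepancy(self) -> int:
        """Declared detection total minus the pre-screen class sum (0 if consistent)."""
        if self.declared_total is None:
            return 0
        return self.declared_total - self.pre_total


def accounting_from_counts(
    pre_counts: dict[str, int],
    post_counts: dict[str, int],
    declared_total: int | None = None,
) -> PopulationAccounting:
    """Build the accounting object directly from class counts."""
    for counts in (pre_counts, post_counts):
        missing = set(REACTIVITY_CLASSES) - set(counts)
        if missing:
            raise ValueError(f"missing reactivity classes: {sorted(missing)}")
    return PopulationAccounting(dict(pre_counts), dict(post_counts), declared_total)


def _class_counts(table) -> dict[str, int]:
    nt = table["nt_pos"].to_numpy(dtype=bool)
    nn = table["nn_pos"].to_numpy(dtype=bool)
    return {
        "NT+NN+": int((nt & nn).sum()),
        "NT+NN-": int((nt & ~nn).sum()),
        "NT-NN+": int((~nt & nn).sum()),
        "NT-NN-": int((~nt & ~nn).sum()),
    }


def population_accounting(pre_table, post_table) -> PopulationAccounting:
    """Accounting from pre- and post-screen cell tables with positivity flags."""
    return PopulationAccounting(_class_counts(pre_table), _class_counts(post_table))


def proportion_estimate_ci(
    k: int, n: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Proportion estimate with a Wilson score interval: (estimate, lo, hi)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    lo = 0.0 if k == 0 else max(0.0, float(lo))
    hi = 1.0 if k == n else min(1.0, float(hi))
    return k / n, lo, hi


@dataclass
class ComparisonResult:
    """One statistical contrast."""

    contrast: str
    test: str
    statistic: float
    p_raw: float
    p_holm: float | None = None
    effect_size: float | None = None
    effect_kind: str | None = None
    family: str | None = None
    n: tuple[int, ...] = field(default_factory=tuple)
    flags: list[str] = field(default_factory=list)


def _effect_r_from_t(t: float, df: float) -> float:
    return float(np.sqrt(t**2 / (t**2 + df))) if df > 0 else 0.0


def _effect_r_from_p(p: float, n_total: int) -> float:
    # |Z|/sqrt(N) with Z recovered from the two-sided p value.
    p = min(max(p, np.finfo(float).tiny), 1.0)
    z = sps.norm.isf(p / 2)
    return float(abs(z) / np.sqrt(n_total))


def select_and_run_test(
    sample_a,
    sample_b,
    paired: bool = False,
    contrast: str = "",
    alpha_normality: float = 0.05,
) -> ComparisonResult:
    """Normality-gated two-sample comparison on animal-level values.

    Shapiro–Wilk on each sample at ``alpha_normality`` gates the choice:
    both normal → Welch's t test (or the paired t test for paired data);
    otherwise Brunner–Munzel (or Wilcoxon signed-rank).  Two-sided p; effect
    size r attached (r = sqrt(t²/(t²+df)) for t tests, |Z|/√N otherwise).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 values per sample for the normality gate")
    if paired and len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    flags = []
    n_total = len(a) + len(b)
    if np.ptp(a) == 0 and np.ptp(b) == 0 and (not paired or np.ptp(a - b) == 0):
        if a[0] == b[0] or (paired and np.all(a == b)):
            return ComparisonResult(
                contrast, "degenerate", 0.0, 1.0, None, 0.0, "r",
                n=(len(a), len(b)), flags=["zero-variance"],
            )
    normal = True
    for s in (a, b):
        if np.ptp(s) == 0:
            normal = False
            flags.append("zero-variance-sample")
            break
        if sps.shapiro(s).pvalue < alpha_normality:
            normal = False
    if normal:
        if paired:
            res = sps.ttest_rel(a, b)
            test, df = "pairwise Welch", len(a) - 1
        else:
            res = sps.ttest_ind(a, b, equal_var=False)
            test, df = "Welch", float(res.df)
        stat, p = float(res.statistic), float(res.pvalue)
        r = _effect_r_from_t(stat, df)
    else:
        if paired:
            d = a - b
            if np.all(d == 0):
                return ComparisonResult(
                    contrast, "Wilcoxon signed-rank", 0.0, 1.0, None, 0.0, "r",
                    n=(len(a), len(b)), flags=flags + ["all-differences-zero"],
                )
            res = sps.wilcoxon(a, b)
            test = "Wilcoxon signed-rank"
        else:
            import warnings

            with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = sps.brunnermunzel(a, b)
            test = "Brunner-Munzel"
        stat, p = float(res.statistic), float(res.pvalue)
        if not np.isfinite(p):
            if max(a) < min(b) or max(b) < min(a):
                # complete separation: exact two-sided enumeration bound
                from math import comb

                p = 2.0 / comb(len(a) + len(b), len(a))
                stat = np.sign(np.median(a) - np.median(b)) * np.inf
                flags.append("complete-separation")
            else:
                p, stat = 1.0, 0.0
                flags.append("degenerate-nonparametric")
        r = _effect_r_from_p(p, n_total)
    return ComparisonResult(
        contrast, test, stat, p, None, r, "r", n=(len(a), len(b)), flags=flags
    )


def holm_adjust(p_values) -> list[float]:
    """Holm's step-down adjustment, output order matching input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def chi_square_proportions(
    k1: int, n1: int, k2: int, n2: int, contrast: str = ""
) -> ComparisonResult:
    """Pearson chi-square on the 2×2 table, with the odds ratio as effect size.

    No continuity correction.  OR = (k1·(n2−k2)) / ((n1−k1)·k2); a zero cell
    triggers the Haldane–Anscombe convention (0.5 added to every cell) and is
    flagged.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("n1 and n2 must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("require 0 <= k <= n")
    a, b = float(k1), float(n1 - k1)
    c, d = float(k2), float(n2 - k2)
    n = a + b + c + d
    flags = []
    margins = ((a + b), (c + d), (a + c), (b + d))
    if min(margins[2], margins[3]) == 0:
        stat, p = 0.0, 1.0
        flags.append("degenerate-margin")
    else:
        stat = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
        p = float(sps.chi2.sf(stat, df=1))
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        odds = (a2 * d2) / (b2 * c2)
        flags.append("zero-cell-continuity-corrected-OR")
    else:
        odds = (a * d) / (b * c)
    return ComparisonResult(
        contrast, "Pearson chi-square", float(stat), float(p), None,
        float(odds), "odds_ratio", n=(n1, n2), flags=flags,
    )


def kruskal_wallis_background(samples, contrast: str = "") -> ComparisonResult:
    """Kruskal–Wallis H test across groups (physiological-background style).

    All values identical across groups → H = 0, p = 1 by convention, flagged.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        return ComparisonResult(
            contrast, "Kruskal-Wallis", 0.0, 1.0, None, None, None,
            n=tuple(len(s) for s in samples), flags=["all-identical"],
        )
    res = sps.kruskal(*samples)
    return ComparisonResult(
        contrast, "Kruskal-Wallis", float(res.statistic), float(res.pvalue),
        None, None, None, n=tuple(len(s) for s in samples),
    )


def default_families() -> dict[str, list[tuple[str, str]]]:
    """The standard inter-group contrast family adjusted together per endpoint.

    Sham vs each injured group, single vs repetitive injury at matched time
    points, and acute vs chronic at matched injury mode.
    """
    return {
        "intergroup": [
            ("SH", "AS"), ("SH", "AR"), ("SH", "CS"), ("SH", "CR"),
            ("AS", "AR"), ("CS", "CR"),
            ("AS", "CS"), ("AR", "CR"),
        ]
    }


def compare_groups(
    values_by_group: dict[str, list],
    endpoint: str = "",
    families: dict[str, list[tuple[str, str]]] | None = None,
) -> list[ComparisonResult]:
    """Run the dispatcher on every contrast of a family and Holm-adjust.

    ``values_by_group`` maps group label → animal-level values.  Contrasts
    whose groups are absent are skipped.  Returns one
    :class:`ComparisonResult` per contrast with ``p_holm`` filled in.
    """
    families = families or default_families()
    results: list[ComparisonResult] = []
    for family_name, contrasts in families.items():
        family_results = []
        for g1, g2 in contrasts:
            if g1 not in values_by_group or g2 not in values_by_group:
                continue
            res = select_and_run_test(
                values_by_group[g1], values_by_group[g2],
                contrast=f"{g1} vs {g2}",
            )
            res.family = f"{endpoint}/{family_name}" if endpoint else family_name
            family_results.append(res)
        adjusted = holm_adjust([r.p_raw for r in family_results])
        for res, p_h in zip(family_results, adjusted):
            res.p_holm = p_h
        results.extend(family_results)
    return results


def results_table(results: list[ComparisonResult]):
    """Comparison results as a DataFrame (one row per contrast)."""
    import pandas as pd

    rows = []
    for r in results:
        stars = ""
        p = r.p_holm if r.p_holm is not None else r.p_raw
        for cut, sym in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if p < cut:
                stars = sym
                break
        rows.append(
            {
                "contrast": r.contrast,
                "family": r.family,
                "test": r.test,
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "p_holm": r.p_holm,
                "effect_size": r.effect_size,
                "effect_kind": r.effect_kind,
                "n": "/".join(str(x) for x in r.n),
                "significance": stars,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)
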