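"""Semantic-differential survey analysis.

Experts rate the explanations of both QC approaches on eight bipolar
attribute pairs (7-point Likert).  Because each participant rates ten
images per approach, ratings are first reduced to the subject median
per attribute and approach; the two approaches are then compared per
attribute with the Wilcoxon signed-rank test (exact sign-flip
enumeration for small samples), Bonferroni-corrected over the eight
attributes.  Median confidence intervals use a percentile bootstrap of
the subject-level medians, and post-hoc power for the paired design is
approximated through the noncentral-t with the Wilcoxon asymptotic
relative efficiency (ARE = 0.955) discount.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

ATTRIBUTES = ("understandability", "correctness", "trustworthiness",
              "usefulness", "clarity", "completeness", "simplicity",
              "relevance")
APPROACHES = ("A", "B")

#: exact enumeration is used up to this many pairs (2^n sign patterns)
EXACT_ENUMERATION_MAX_N = 20


def validate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format rating table (participant, item, approach,
    attribute, rating)."""
    required = {"participant", "item", "approach", "attribute", "rating"}
    missing = required - set(ratings.columns)
    if missing:
        raise ValueError(f"ratings table missing columns {sorted(missing)}")
    r = ratings["rating"]
    if not ((r >= 1) & (r <= 7) & (r == r.astype(int))).all():
        raise ValueError("ratings must be integers in 1..7")
    bad = set(ratings["attribute"]) - set(ATTRIBUTES)
    if bad:
        raise ValueError(f"unknown attributes {sorted(bad)}")
    return ratings


def subject_medians(ratings: pd.DataFrame) -> pd.DataFrame:
    """Median rating over items, per participant x attribute x approach.

    Uses the usual midpoint convention for even counts.  Every
    participant/attribute/approach cell must contain at least one
    rating.
    """
    validate_ratings(ratings)
    med = (ratings.groupby(["participant", "attribute", "approach"])
           ["rating"].median().rename("median").reset_index())
    participants = ratings["participant"].unique()
    attrs = ratings["attribute"].unique()
    have = set(map(tuple, med[["participant", "attribute", "approach"]]
                   .to_numpy()))
    for cell in product(participants, attrs, APPROACHES):
        if cell not in have:
            raise ValueError(f"missing ratings for cell {cell}")
    return med


def exact_wilcoxon(a, b) -> tuple[float, float]:
    """Wilcoxon signed-rank test with exact sign-flip enumeration.

    Zero differences are dropped (Wilcoxon's convention); tied absolute
    differences get average ranks.  Returns (W+, two-sided p) where the
    p-value enumerates all 2^n sign assignments for n pairs (normal
    approximation with tie correction beyond
    ``EXACT_ENUMERATION_MAX_N``).
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 pairs")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero: test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_ENUMERATION_MAX_N:
        total = 1 << n
        stats_all = np.zeros(total)
        for bit, r in enumerate(ranks):
            stride = 1 << bit
            # add r to every subset containing this pair with + sign
            pattern = np.arange(total) & stride > 0
            stats_all[pattern] += r
        p_low = np.count_nonzero(stats_all <= w_plus + 1e-9) / total
        p_high = np.count_nonzero(stats_all >= w_plus - 1e-9) / total
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        p = float(stats.wilcoxon(d, zero_method="wilcox",
                                 correction=False, method="approx").pvalue)
    return w_plus, p


def paired_wilcoxon_bonferroni(medians: pd.DataFrame,
                               m_comparisons: int | None = None
                               ) -> pd.DataFrame:
    """Per-attribute paired Wilcoxon tests, Bonferroni-adjusted.

    ``medians`` is the output of :func:`subject_medians`.  ``p_adj`` is
    ``min(1, m * p_raw)`` with ``m`` the number of attributes tested.
    """
    attrs = sorted(medians["attribute"].unique(),
                   key=lambda a: ATTRIBUTES.index(a) if a in ATTRIBUTES else 99)
    m = m_comparisons if m_comparisons is not None else len(attrs)
    wide = medians.pivot_table(index=["participant", "attribute"],
                               columns="approach", values="median")
    rows = []
    for attr in attrs:
        sub = wide.xs(attr, level="attribute")
        stat, p_raw = exact_wilcoxon(sub["A"].to_numpy(), sub["B"].to_numpy())
        p_adj = min(1.0, m * p_raw)
        rows.append({"attribute": attr, "statistic": stat, "p_raw": p_raw,
                     "p_adj": p_adj, "significant": p_adj < 0.05})
    return pd.DataFrame(rows)


def bootstrap_median_ci(values, n_resamples: int = 5000, level: float = 0.95,
                        seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap interval of the median."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_resamples, len(values)))
    meds = np.median(values[idx], axis=1)
    lo, hi = np.quantile(meds, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


@dataclass
class PowerSpec:
    effect_size: float            # Cohen's dz for paired differences
    n_pairs: int
    alpha: float = 0.05
    two_sided: bool = True
    method: str = "wilcoxon_are"  # or "paired_t"
    are: float = 0.955            # Wilcoxon ARE vs the t-test (normal parent)

    def __post_init__(self):
        if self.n_pairs < 2:
            raise ValueError("need n_pairs >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.method not in ("wilcoxon_are", "paired_t"):
            raise ValueError(f"unknown method {self.method!r}")


def posthoc_power(spec: PowerSpec) -> float:
    """Power of the paired test via the noncentral-t approximation.

    For the Wilcoxon method the effective sample size is ARE * n (the
    classical efficiency discount); the paired t-test uses n directly.
    """
    n_eff = spec.are * spec.n_pairs if spec.method == "wilcoxon_are" \
        else float(spec.n_pairs)
    df = n_eff - 1
    nc = spec.effect_size * np.sqrt(n_eff)
    if spec.two_sided:
        crit = stats.t.ppf(1 - spec.alpha / 2, df)
        power = (1 - stats.nct.cdf(crit, df, nc)
                 + stats.nct.cdf(-crit, df, nc))
    else:
        crit = stats.t.ppf(1 - spec.alpha, df)
        power = 1 - stats.nct.cdf(crit, df, nc)
    return float(power)


def describe_similarity(values) -> dict:
    """Median / MAD summary for the 5-point similarity question."""
    v = np.asarray(values, dtype=float)
    med = float(np.median(v))
    return {"median": med, "mad": float(np.median(np.abs(v - med))),
            "n": len(v)}


def preference_shares(choices) -> dict:
    """Percentage share per preference option."""
    s = pd.Series(list(choices))
    return (s.value_counts(normalize=True) * 100).round(2).to_dict()


def simulate_ratings(n_participants: int = 16, n_items: int = 10,
                     seed: int = 0, shift: dict | None = None) -> pd.DataFrame:
    """Synthetic rating table for demos/tests.

    ``shift`` maps attribute -> additive offset of approach B relative
    to approach A (on the 1..7 scale, before clipping).
    """
    rng = np.random.default_rng(seed)
    shift = shift or {}
    rows = []
    for p in range(n_participants):
        base = rng.normal(5.2, 0.6)
        for attr in ATTRIBUTES:
            attr_eff = rng.normal(0, 0.4)
            for item in range(n_items):
                item_eff = rng.normal(0, 0.5)
                for app in APPROACHES:
                    mu = base + attr_eff + item_eff
                    if app == "B":
                        mu += shift.get(attr, 0.0)
                    r = int(np.clip(round(mu + rng.normal(0, 0.7)), 1, 7))
                    rows.append({"participant": f"P{p:02d}", "item": item,
                                 "approach": app, "attribute": attr,
                                 "rating": r})
    return pd.DataFrame(rows)
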