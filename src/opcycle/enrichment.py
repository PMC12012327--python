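"""Fold enrichment and set-overlap statistics for differential peak sets.

Motif enrichment is the ratio of occurrence fractions between a foreground
peak set (e.g. peaks losing accessibility in a knockout) and a background
set (all other peaks), with a one-sided Fisher exact test on the 2x2 table
and a log-ratio normal 95% CI.  Gene-set overlap against an accessibility
peak set is tested with the hypergeometric tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom, norm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentTable",
    "OverlapTable",
    "EnrichmentResult",
    "OverlapResult",
    "fold_enrichment",
    "set_overlap_test",
    "enrichment_from_peaks",
]


@dataclass(frozen=True)
class EnrichmentTable:
    """Motif-positive counts in foreground and background peak sets."""

    k_fg: int
    n_fg: int
    k_bg: int
    n_bg: int

    def __post_init__(self) -> None:
        if self.n_fg <= 0 or self.n_bg <= 0:
            raise ValueError("set totals must be > 0")
        if not 0 <= self.k_fg <= self.n_fg:
            raise ValueError("k_fg must lie in [0, n_fg]")
        if not 0 <= self.k_bg <= self.n_bg:
            raise ValueError("k_bg must lie in [0, n_bg]")


@dataclass(frozen=True)
class OverlapTable:
    """Two gene sets of sizes ``n_a``/``n_b`` drawn from a universe."""

    n_a: int
    n_b: int
    n_overlap: int
    n_universe: int

    def __post_init__(self) -> None:
        if self.n_a > self.n_universe or self.n_b > self.n_universe:
            raise ValueError("set sizes cannot exceed the universe")
        if self.n_overlap > min(self.n_a, self.n_b):
            raise ValueError("overlap cannot exceed the smaller set")
        if self.n_overlap < max(0, self.n_a + self.n_b - self.n_universe):
            raise ValueError("overlap too small for the universe size")


@dataclass(frozen=True)
class EnrichmentResult:
    fold: float
    p: float
    ci_low: float
    ci_high: float
    frac_fg: float
    frac_bg: float


@dataclass(frozen=True)
class OverlapResult:
    p: float
    expected_overlap: float
    jaccard: float


def fold_enrichment(table: EnrichmentTable, ci_level: float = 0.95) -> EnrichmentResult:
    """Fold enrichment of a feature in foreground vs. background peaks.

    fold = (k_fg/n_fg) / (k_bg/n_bg); p is the one-sided Fisher exact
    probability of at least ``k_fg`` foreground positives given the fixed
    margins (enrichment direction only).  The CI is the standard
    log-ratio normal approximation; with ``k_bg = 0`` the fold is
    infinite and the CI degenerate.
    """
    frac_fg = table.k_fg / table.n_fg
    frac_bg = table.k_bg / table.n_bg
    contingency = [
        [table.k_fg, table.n_fg - table.k_fg],
        [table.k_bg, table.n_bg - table.k_bg],
    ]
    _, p = fisher_exact(contingency, alternative="greater")
    if table.k_bg == 0:
        return EnrichmentResult(
            fold=math.inf, p=float(p), ci_low=math.nan, ci_high=math.nan,
            frac_fg=frac_fg, frac_bg=frac_bg,
        )
    fold = frac_fg / frac_bg
    if table.k_fg == 0:
        return EnrichmentResult(
            fold=0.0, p=float(p), ci_low=0.0, ci_high=math.nan,
            frac_fg=frac_fg, frac_bg=frac_bg,
        )
    # SE of log(ratio of proportions), delta method.
    se_log = math.sqrt(
        1 / table.k_fg - 1 / table.n_fg + 1 / table.k_bg - 1 / table.n_bg
    )
    z = norm.ppf(0.5 + ci_level / 2)
    return EnrichmentResult(
        fold=fold,
        p=float(p),
        ci_low=fold * math.exp(-z * se_log),
        ci_high=fold * math.exp(z * se_log),
        frac_fg=frac_fg,
        frac_bg=frac_bg,
    )


def set_overlap_test(table: OverlapTable) -> OverlapResult:
    """Hypergeometric tail test of set overlap.

    p = P(X >= n_overlap) when ``n_a`` draws are taken without
    replacement from a universe containing ``n_b`` marked elements;
    expected overlap is ``n_a * n_b / n_universe``.
    """
    p = float(hypergeom.sf(table.n_overlap - 1, table.n_universe, table.n_b, table.n_a))
    expected = table.n_a * table.n_b / table.n_universe
    union = table.n_a + table.n_b - table.n_overlap
    jaccard = table.n_overlap / union if union > 0 else 0.0
    return OverlapResult(p=p, expected_overlap=expected, jaccard=jaccard)


def enrichment_from_peaks(
    foreground: pd.DataFrame,
    background: pd.DataFrame,
    motifs: list[str] | None = None,
) -> pd.DataFrame:
    """Per-motif enrichment table from motif-annotated peak DataFrames.

    ``foreground``/``background`` carry one boolean column per motif
    (any column beyond the six BED fields, unless ``motifs`` is given).
    Returns a DataFrame with columns motif, k_fg, n_fg, k_bg, n_bg, fold,
    p and Benjamini-Hochberg ``fdr`` across the motif list.
    """
    bed_cols = {"chrom", "start", "end", "name", "score", "strand"}
    if motifs is None:
        motifs = [c for c in foreground.columns if c not in bed_cols]
    if not motifs:
        raise ValueError("no motif columns found")
    rows = []
    for motif in motifs:
        table = EnrichmentTable(
            k_fg=int(foreground[motif].sum()),
            n_fg=len(foreground),
            k_bg=int(background[motif].sum()),
            n_bg=len(background),
        )
        res = fold_enrichment(table)
        rows.append(
            {
                "motif": motif,
                "k_fg": table.k_fg,
                "n_fg": table.n_fg,
                "k_bg": table.k_bg,
                "n_bg": table.n_bg,
                "fold": res.fold,
                "p": res.p,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
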