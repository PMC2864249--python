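"""TPM normalization and the two-library tag-count z test.

With one sequencing library per condition, differential abundance of a tag
between libraries of sizes N1 and N2 is tested by comparing the two
proportions p1 = x1/N1 and p2 = x2/N2 against the pooled proportion
p0 = (x1+x2)/(N1+N2):

    z = (p1 - p2) / sqrt(p0 (1 - p0) (1/N1 + 1/N2))

with a two-sided standard-normal p value — the classic z-score method for
comparing transcript tag counts between two SAGE-style libraries.  Counts
enter the test raw; TPM (x/N * 1e6) is used for reporting and fold changes
only, since the test's variance model requires counts.  Reported TPMs and
fold changes are rounded to one decimal (half away from zero); full
precision is retained internally.
"""

from __future__ import annotations

import math
from typing import Mapping

import pandas as pd
from scipy.stats import norm


def round_report(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (so 5.672 -> 5.7, 0.25 -> 0.3 at 1 digit)."""
    if not math.isfinite(x):
        return x
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def tpm(x: float, n: int) -> float:
    """Transcripts per million: x / N * 1e6."""
    if n <= 0:
        raise ValueError("library size must be positive")
    if not 0 <= x <= n:
        raise ValueError("count must lie in [0, N]")
    return x / n * 1e6


def fold_change(tpm1: float, tpm2: float) -> tuple[float, str]:
    """Ratio >= 1 between two abundances, with direction.

    Returns (ratio, direction) with direction ``up_in_A``/``up_in_B``/
    ``equal``; a single zero side yields ``inf`` with direction flagged
    ``exclusive_A``/``exclusive_B``.  Both sides zero is undefined.
    """
    if tpm1 < 0 or tpm2 < 0:
        raise ValueError("abundances must be non-negative")
    if tpm1 == 0 and tpm2 == 0:
        raise ValueError("fold change undefined when both abundances are zero")
    if tpm2 == 0:
        return math.inf, "exclusive_A"
    if tpm1 == 0:
        return math.inf, "exclusive_B"
    if tpm1 == tpm2:
        return 1.0, "equal"
    if tpm1 > tpm2:
        return tpm1 / tpm2, "up_in_A"
    return tpm2 / tpm1, "up_in_B"


def z_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-proportion z test of tag frequencies between two libraries.

    Returns (z, two-sided p).  ``x1 == x2 == 0`` (or a degenerate pooled
    proportion) yields (0, 1) by convention; equal frequencies yield exactly
    (0, 1).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    p1 = x1 / n1
    p2 = x2 / n2
    p0 = (x1 + x2) / (n1 + n2)
    if p0 <= 0.0 or p0 >= 1.0:
        return 0.0, 1.0
    if p1 == p2:
        return 0.0, 1.0
    se = math.sqrt(p0 * (1 - p0) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = 2.0 * norm.sf(abs(z))
    return z, p


def profile(
    counts: Mapping[str, tuple[int, int]],
    n1: int,
    n2: int,
    alpha: float = 0.01,
    bh: bool = False,
) -> pd.DataFrame:
    """Per-miRNA differential profile, sorted by (p, id).

    ``counts`` maps miRNA id to raw counts (x1, x2).  Output columns:
    mirna_id, x1, x2, tpm1, tpm2, fold_change, direction, z, p,
    significant (p < alpha on the raw p), two_fold (ratio > 2).  With
    ``bh=True`` a Benjamini-Hochberg adjusted column ``p_bh`` is added
    (off by default: the raw-p threshold mirrors single-library practice).
    """
    rows = []
    for mid in sorted(counts):
        x1, x2 = counts[mid]
        t1, t2 = tpm(x1, n1), tpm(x2, n2)
        if x1 == 0 and x2 == 0:
            fc, direction = math.nan, "none"
        else:
            fc, direction = fold_change(t1, t2)
        z, p = z_test(x1, n1, x2, n2)
        rows.append((mid, x1, x2, t1, t2, fc, direction, z, p,
                     p < alpha, bool(fc > 2) if math.isfinite(fc) else x1 + x2 > 0))
    df = pd.DataFrame(rows, columns=["mirna_id", "x1", "x2", "tpm1", "tpm2",
                                     "fold_change", "direction", "z", "p",
                                     "significant", "two_fold"])
    if bh and len(df):
        from statsmodels.stats.multitest import multipletests
        df["p_bh"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df = df.sort_values(["p", "mirna_id"], kind="mergesort").reset_index(drop=True)
    return df


def summarize(df: pd.DataFrame) -> dict[str, int]:
    """Counts of significant and two-fold-changed genes in a profile."""
    return {
        "n_genes": int(len(df)),
        "n_significant": int(df["significant"].sum()) if len(df) else 0,
        "n_two_fold": int(df["two_fold"].sum()) if len(df) else 0,
    }
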