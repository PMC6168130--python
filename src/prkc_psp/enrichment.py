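"""Position-wise residue enrichment and depletion around phosphosites.

Quantitative replacement for two-sample sequence-logo graphics: for every
(offset, residue) cell the occurrence frequency among positive windows is
compared with the frequency among negative windows by a two-proportion z-test
with pooled variance, falling back to Fisher's exact test unless every
expected count exceeds 5 (the fallback is routine with 36 positives).  No multiple-testing
correction is applied by default, matching how logo displays are read; a
Bonferroni option exists.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ALPHABET, DEFAULT_FLANK, WINDOW_LENGTH, PeptideWindow
from .features import window_indices

OFFSETS = tuple(range(-DEFAULT_FLANK, DEFAULT_FLANK + 1))


def _two_proportion_pvalue(k1: int, n1: int, k2: int, n2: int) -> tuple[float, str]:
    """Two-sided p-value for H0: p1 == p2; returns (p, test_used)."""
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    # expected counts under the pooled null decide the test
    pooled = (k1 + k2) / (n1 + n2)
    expected = np.array(
        [
            [n1 * pooled, n1 * (1 - pooled)],
            [n2 * pooled, n2 * (1 - pooled)],
        ]
    )
    if (expected <= 5).any():
        return float(stats.fisher_exact(table, alternative="two-sided")[1]), "fisher"
    p1, p2 = k1 / n1, k2 / n2
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0, "z"
    z = (p1 - p2) / se
    return float(2 * stats.norm.sf(abs(z))), "z"


def positionwise_enrichment(
    pos_windows: Sequence[PeptideWindow],
    neg_windows: Sequence[PeptideWindow],
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-(offset, residue) enrichment table over all 31 window positions.

    Columns: offset (-15..+15, 0 = the central S/T), residue (including the
    padding symbol X), freq_pos, freq_neg, difference, p_value, test,
    direction in {enriched, depleted, n.s.}.  ``direction`` is n.s. exactly
    when the (optionally Bonferroni-adjusted) p-value is >= alpha.
    """
    if not pos_windows or not neg_windows:
        raise ValueError("both window sets must be nonempty")
    idx_pos = window_indices(pos_windows)
    idx_neg = window_indices(neg_windows)
    n1, n2 = len(pos_windows), len(neg_windows)
    n_tests = WINDOW_LENGTH * len(ALPHABET)
    rows = []
    for j, offset in enumerate(OFFSETS):
        counts_pos = np.bincount(idx_pos[:, j], minlength=len(ALPHABET))
        counts_neg = np.bincount(idx_neg[:, j], minlength=len(ALPHABET))
        for a, residue in enumerate(ALPHABET):
            k1, k2 = int(counts_pos[a]), int(counts_neg[a])
            p, test = _two_proportion_pvalue(k1, n1, k2, n2)
            if bonferroni:
                p = min(1.0, p * n_tests)
            f1, f2 = k1 / n1, k2 / n2
            if p < alpha:
                direction = "enriched" if f1 > f2 else "depleted"
            else:
                direction = "n.s."
            rows.append(
                {
                    "offset": offset,
                    "residue": residue,
                    "freq_pos": f1,
                    "freq_neg": f2,
                    "difference": f1 - f2,
                    "p_value": p,
                    "test": test,
                    "direction": direction,
                }
            )
    return pd.DataFrame(rows)


def significant_cells(table: pd.DataFrame) -> pd.DataFrame:
    """The enriched/depleted rows, strongest difference first."""
    sig = table[table["direction"] != "n.s."].copy()
    return sig.reindex(
        sig["difference"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
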