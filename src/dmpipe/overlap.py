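"""Top-k list construction and 2x2 overlap inference between contrasts.

Two per-probe effect vectors (for example fimbrial-vs-proximal in
mutation carriers, and tumour-vs-normal) are each reduced to the k
probes with the greatest increase or decrease, and the overlap of the
two lists over the shared probe universe is tested with a one-sided
Fisher's exact test; the odds ratio carries a 95% Woolf (logit)
confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class OverlapResult:
    """2x2 overlap of two probe lists over a common universe."""

    list_a_name: str
    list_b_name: str
    universe_size: int
    a_size: int
    b_size: int
    overlap: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def top_k_by_delta(effects: pd.Series, k: int = 5000, sign: str = "increase") -> list[str]:
    """The k probes with the largest (or most negative) effect.

    Ties are broken by probe id, lexicographically, so the list is
    deterministic for any input.
    """
    if sign not in ("increase", "decrease"):
        raise ValueError(f"sign must be 'increase' or 'decrease', got {sign!r}")
    if k > len(effects):
        raise ValueError(f"k={k} exceeds universe size {len(effects)}")
    signed = effects if sign == "increase" else -effects
    order = sorted(signed.index, key=lambda pid: (-signed[pid], pid))
    return order[:k]


def contrast_effects(group_a_betas: pd.DataFrame, group_b_betas: pd.DataFrame) -> pd.Series:
    """Per-probe difference of group medians (A minus B).

    Single-column groups reduce to that sample's values, which covers
    one-array cell-line arms.
    """
    if not group_a_betas.index.equals(group_b_betas.index):
        raise ValueError("contrast_effects: probe universes differ between groups")
    if group_a_betas.shape[1] < 1 or group_b_betas.shape[1] < 1:
        raise ValueError("contrast_effects: each group needs >= 1 sample")
    med_a = group_a_betas.median(axis=1)
    med_b = group_b_betas.median(axis=1)
    return (med_a - med_b).rename("effect")


def fisher_overlap(
    list_a: set[str] | list[str],
    list_b: set[str] | list[str],
    universe: set[str] | list[str],
    list_a_name: str = "A",
    list_b_name: str = "B",
) -> OverlapResult:
    """One-sided Fisher test of the overlap between two probe lists.

    The 2x2 table counts probes in both lists, in exactly one, and in
    neither; p is the hypergeometric upper tail (enrichment). The sample
    odds ratio uses the Haldane-Anscombe 0.5 continuity correction when
    any cell is zero, and the 95% CI is the Woolf logit interval on the
    (possibly corrected) cells.
    """
    set_a, set_b, uni = set(list_a), set(list_b), set(universe)
    extra = (set_a | set_b) - uni
    if extra:
        raise ValueError(f"fisher_overlap: {len(extra)} probes outside the universe")
    N = len(uni)
    n11 = len(set_a & set_b)
    n10 = len(set_a - set_b)
    n01 = len(set_b - set_a)
    n00 = N - n11 - n10 - n01
    # enrichment p: P(overlap >= n11) drawing |a| probes from N with |b| marked
    p = float(stats.hypergeom.sf(n11 - 1, N, len(set_b), len(set_a)))
    cells = np.array([n11, n10, n01, n00], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    oratio = (cells[0] * cells[3]) / (cells[1] * cells[2])
    se = float(np.sqrt((1.0 / cells).sum()))
    log_or = float(np.log(oratio))
    return OverlapResult(
        list_a_name=list_a_name,
        list_b_name=list_b_name,
        universe_size=N,
        a_size=len(set_a),
        b_size=len(set_b),
        overlap=n11,
        odds_ratio=float(oratio),
        ci_low=float(np.exp(log_or - 1.96 * se)),
        ci_high=float(np.exp(log_or + 1.96 * se)),
        p=p,
    )
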