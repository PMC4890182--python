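"""Paired differential methylation with empirical-Bayes moderation.

For each group (mutation carriers, controls) the within-subject
fimbrial-minus-proximal difference is computed per CpG and tested with a
moderated one-sample t-statistic: the per-probe residual variance is
shrunk towards a pooled prior estimated by fitting a scaled
inverse-chi-square distribution to the observed variances by moment
matching on the log scale (Smyth's closed-form estimator). Significant
CpGs in carriers but not in controls, further filtered on the median
per-subject difference, form the differentially methylated position
(DMP) list.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import MethylationDataset, ModerationPrior

logger = logging.getLogger(__name__)

__all__ = [
    "paired_differences",
    "moderated_paired_test",
    "bh_fdr",
    "group_dmp_table",
    "call_dmps",
    "heterogeneity_summary",
    "cellline_delta_dmps",
]


def paired_differences(dataset: MethylationDataset, group: str) -> pd.DataFrame:
    """Per-subject fimbrial minus proximal beta differences for one group.

    Returns a probes x subjects DataFrame. Subjects lacking either site
    are excluded (and counted in the log); at least 3 complete pairs are
    required.
    """
    subjects = dataset.paired_subjects(group)
    n_total = dataset.samples[dataset.samples["group"] == group]["subject_id"].nunique()
    if n_total > len(subjects):
        logger.info(
            "paired_differences(%s): excluded %d unpaired of %d subjects",
            group, n_total - len(subjects), n_total,
        )
    if len(subjects) < 3:
        raise ValueError(f"group {group!r} has {len(subjects)} complete pairs; need >= 3")
    fimb = [dataset.sample_id_for(s, "fimbrial") for s in subjects]
    prox = [dataset.sample_id_for(s, "proximal") for s in subjects]
    diffs = dataset.beta[fimb].to_numpy() - dataset.beta[prox].to_numpy()
    return pd.DataFrame(diffs, index=dataset.beta.index, columns=subjects)


def _trigamma_inverse(x: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        step = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + step
        if np.all(np.abs(step) < 1e-10 * y):
            break
    return y


def estimate_prior(s2: np.ndarray, df: int) -> ModerationPrior:
    """Moment-match log sample variances to a scaled inverse-chi-square prior.

    With ``s2_g ~ s0^2 * chi^2_df / df`` scaled by a gene-wise true
    variance drawn from the prior, ``log s2_g`` has excess spread
    ``trigamma(d0/2)`` over the pure chi-square sampling noise
    ``trigamma(df/2)``; matching mean and variance of ``log s2_g`` gives
    the closed-form estimates of ``d0`` and ``s0^2``.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError("degenerate variance distribution: every probe has zero variance")
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) if e.size > 1 else 0.0
    target = evar - float(special.polygamma(1, df / 2.0))
    if target > 0:
        d0 = 2.0 * float(_trigamma_inverse(target))
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # observed spread no larger than sampling noise: infinitely
        # informative prior, every probe shrunk fully to s0^2
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def moderated_paired_test(
    diffs: pd.DataFrame,
    prior: ModerationPrior | None = None,
) -> tuple[pd.Series, pd.Series, ModerationPrior]:
    """Moderated one-sample t-test of each probe's paired differences.

    Parameters
    ----------
    diffs
        probes x subjects matrix of paired differences (>= 3 columns).
    prior
        Optional fixed variance prior; when omitted it is estimated from
        the data. Supplying a tiny ``d0`` recovers the ordinary paired t.

    Returns
    -------
    (t, p, prior) where t and p are per-probe Series and p is two-sided
    from a t distribution with ``d0 + n - 1`` degrees of freedom.
    """
    n = diffs.shape[1]
    if n < 3:
        raise ValueError(f"need >= 3 pairs, got {n}")
    x = diffs.to_numpy(dtype=float)
    mean = x.mean(axis=1)
    s2 = x.var(axis=1, ddof=1)
    df = n - 1
    if prior is None:
        prior = estimate_prior(s2, df)
    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        df_total = prior.d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(s2_post / n)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return (
        pd.Series(t, index=diffs.index, name="t"),
        pd.Series(p, index=diffs.index, name="p"),
        prior,
    )


def bh_fdr(p: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up q-values (monotone, q_i in [p_i, 1])."""
    arr = np.asarray(p, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("NaN p-values passed to bh_fdr")
    if arr.size == 0:
        return p.copy() if isinstance(p, pd.Series) else arr.copy()
    q = multipletests(arr, method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(q, index=p.index, name="q")
    return q


def group_dmp_table(diffs: pd.DataFrame, prior: ModerationPrior | None = None) -> pd.DataFrame:
    """Per-probe statistics for one group's paired differences.

    Columns: n_pairs, mean_diff, s2, t, p, q (BH), median_delta.
    """
    t, p, prior = moderated_paired_test(diffs, prior=prior)
    x = diffs.to_numpy(dtype=float)
    table = pd.DataFrame(
        {
            "n_pairs": diffs.shape[1],
            "mean_diff": x.mean(axis=1),
            "s2": x.var(axis=1, ddof=1),
            "t": t,
            "p": p,
            "q": bh_fdr(p),
            "median_delta": np.median(x, axis=1),
        },
        index=diffs.index,
    )
    table.attrs["prior"] = prior
    return table


def call_dmps(
    dmp_mut: pd.DataFrame,
    dmp_ctrl: pd.DataFrame,
    q_threshold: float = 0.05,
    delta_threshold: float = 0.03,
) -> pd.DataFrame:
    """Set-difference DMP calling with a median-difference threshold.

    A probe is a DMP when it is significant in the carrier group
    (``q < q_threshold``), not significant in controls, and its median
    carrier fimbrial-minus-proximal difference exceeds ``delta_threshold``
    in absolute value (strict inequalities throughout). Direction is
    hyper for a positive median difference, hypo otherwise.
    """
    if not dmp_mut.index.equals(dmp_ctrl.index):
        n_diff = len(set(dmp_mut.index) ^ set(dmp_ctrl.index))
        raise ValueError(f"probe universes differ between groups ({n_diff} probes in symmetric difference)")
    out = dmp_mut.add_suffix("_mut").join(dmp_ctrl.add_suffix("_ctrl"))
    out["sig_mut"] = out["q_mut"] < q_threshold
    out["sig_ctrl"] = out["q_ctrl"] < q_threshold
    out["mut_not_ctrl"] = out["sig_mut"] & ~out["sig_ctrl"]
    out["dmp"] = out["mut_not_ctrl"] & (out["median_delta_mut"].abs() > delta_threshold)
    out["direction"] = np.where(out["median_delta_mut"] > 0, "hyper", "hypo")
    return out


def dmp_lists(dmps: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Hyper- and hypomethylated probe-id lists of the retained DMPs."""
    hit = dmps[dmps["dmp"]]
    hyper = sorted(hit.index[hit["direction"] == "hyper"])
    hypo = sorted(hit.index[hit["direction"] == "hypo"])
    return hyper, hypo


def heterogeneity_summary(
    diffs: pd.DataFrame,
    dmps: pd.DataFrame,
    thresholds: tuple[float, ...] = (0.1, 0.2),
) -> tuple[dict[float, float], pd.DataFrame]:
    """Between-subject spread of the methylation change at called DMPs.

    For each retained DMP, the fraction of subjects whose difference
    exceeds each threshold in the DMP's direction; returns the mean
    fraction per threshold plus the per-DMP fractions.
    """
    hit = dmps[dmps["dmp"]]
    if hit.empty:
        raise ValueError("heterogeneity_summary: no retained DMPs")
    x = diffs.loc[hit.index].to_numpy(dtype=float)
    sign = np.where(hit["direction"].to_numpy() == "hyper", 1.0, -1.0)
    signed = x * sign[:, None]
    per_probe = pd.DataFrame(index=hit.index)
    means: dict[float, float] = {}
    for theta in thresholds:
        frac = (signed > theta).mean(axis=1)
        per_probe[f"frac_subjects_gt_{theta:g}"] = frac
        means[theta] = float(frac.mean())
    return means, per_probe


def cellline_delta_dmps(
    beta_treated: pd.Series,
    beta_control: pd.Series,
    threshold: float,
) -> tuple[list[str], list[str]]:
    """Single-sample treated-vs-control CpG calls at a fixed difference cut.

    hyper: treated - control > threshold; hypo: control - treated >
    threshold (strict). Used for cell-line overexpression contrasts where
    each arm is one array.
    """
    if not beta_treated.index.equals(beta_control.index):
        raise ValueError("cellline_delta_dmps: probe sets differ between arms")
    delta = beta_treated - beta_control
    hyper = sorted(delta.index[delta > threshold])
    hypo = sorted(delta.index[-delta > threshold])
    return hyper, hypo
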