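"""Regulatory-region enrichment with annotation-matched backgrounds.

A test probe list (by default the 1,000 CpGs with the largest median
methylation differences in one direction) is overlapped with each
(tissue, histone-mark) peak track. The expected overlap is estimated
from 1,000 random background probe sets drawn to match the test list's
joint gene-relationship x CpG-island-relationship composition exactly;
enrichment is the upper binomial tail at the pooled background overlap
rate, corrected across tracks by Benjamini-Yekutieli.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import PeakTrackSet, ProbeAnnotation

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


def select_top_probes(dmps: pd.DataFrame, n: int = 1000, direction: str = "hypo") -> list[str]:
    """The n called DMPs with largest |median difference| in one direction.

    Ties at the selection boundary are broken by probe id (lexicographic)
    so the list is deterministic. If fewer than n probes qualify, all are
    returned with a warning.
    """
    if direction not in ("hyper", "hypo"):
        raise ValueError(f"direction must be 'hyper' or 'hypo', got {direction!r}")
    delta_col = "median_delta_mut" if "median_delta_mut" in dmps.columns else "median_delta"
    pool = dmps[dmps["dmp"]] if "dmp" in dmps.columns else dmps
    if "direction" in pool.columns:
        pool = pool[pool["direction"] == direction]
    else:
        pool = pool[pool[delta_col] > 0] if direction == "hyper" else pool[pool[delta_col] <= 0]
    if pool.empty:
        logger.warning("select_top_probes: no %smethylated probes available", direction)
        return []
    order = sorted(pool.index, key=lambda pid: (-abs(pool.at[pid, delta_col]), pid))
    ranked = pool.loc[order]
    if len(ranked) < n:
        logger.warning(
            "select_top_probes: only %d %smethylated probes (requested %d)",
            len(ranked), direction, n,
        )
        return list(ranked.index)
    return list(ranked.index[:n])


def matched_backgrounds(
    test_probes: list[str],
    annotation: ProbeAnnotation,
    n_sets: int = 1000,
    seed: int | np.random.Generator = 0,
) -> list[list[str]]:
    """Random probe sets matching the test list's annotation composition.

    Each background set has the test list's size and its exact per-bin
    count over the joint (gene_relation, cgi_relation) bins; probes are
    drawn uniformly without replacement within each bin from the non-test
    probes, independently across sets.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bins = annotation.matching_bins()
    test_set = set(test_probes)
    unknown = test_set - set(annotation.probe_ids)
    if unknown:
        raise ValueError(f"matched_backgrounds: {len(unknown)} test probes not in annotation")
    test_bins = bins.loc[list(test_probes)]
    need = test_bins.value_counts()
    pools: dict[str, np.ndarray] = {}
    for bin_label, count in need.items():
        pool = bins.index[(bins == bin_label) & ~bins.index.isin(test_set)].to_numpy(dtype=object)
        if len(pool) < count:
            raise ValueError(
                f"matched_backgrounds: bin {bin_label!r} has only {len(pool)} "
                f"non-test probes but the test list needs {count} "
                f"(deficit {count - len(pool)})"
            )
        pools[bin_label] = np.sort(pool.astype(str))
    out: list[list[str]] = []
    for _ in range(n_sets):
        picked: list[str] = []
        for bin_label, count in need.items():
            picked.extend(rng.choice(pools[bin_label], size=count, replace=False))
        out.append(picked)
    return out


def probe_coverage(track: dict[str, np.ndarray], annotation: ProbeAnnotation) -> pd.Series:
    """Boolean per-probe: does the probe's base fall inside the track?

    A probe at 1-based position p overlaps a half-open 0-based interval
    [start, end) iff p - 1 is in [start, end).
    """
    covered = np.zeros(len(annotation), dtype=bool)
    chroms = annotation.table["chrom"].to_numpy()
    pos0 = annotation.table["pos"].to_numpy(dtype=np.int64) - 1
    for chrom in np.unique(chroms):
        ivs = track.get(chrom)
        sel = chroms == chrom
        if ivs is None or len(ivs) == 0:
            continue
        idx = np.searchsorted(ivs[:, 0], pos0[sel], side="right") - 1
        ok = idx >= 0
        ok[ok] = pos0[sel][ok] < ivs[idx[ok], 1]
        covered[sel] = ok
    missing = set(np.unique(chroms)) - set(track)
    if missing and track:
        logger.debug("probe_coverage: chromosomes absent from track: %s", sorted(missing))
    return pd.Series(covered, index=annotation.probe_ids)


def overlap_count(
    probes: list[str],
    track: dict[str, np.ndarray],
    annotation: ProbeAnnotation,
) -> int:
    """Number of distinct probes whose position falls inside the track."""
    coverage = probe_coverage(track, annotation)
    unique = pd.Index(pd.unique(pd.Series(probes, dtype=object)))
    known = unique[unique.isin(coverage.index)]
    if len(known) < len(unique):
        logger.info(
            "overlap_count: %d probes missing from annotation counted as non-overlapping",
            len(unique) - len(known),
        )
    return int(coverage.loc[known].sum())


def enrichment_test(
    observed: int,
    backgrounds: list[int] | np.ndarray,
    n_test: int,
) -> tuple[float, float]:
    """Upper binomial tail of the observed overlap at the background rate.

    The binomial success probability is pooled over all background sets:
    p_hat = (sum of background counts) / (n_sets * n_test); the p-value
    is P(X >= observed) for X ~ Binomial(n_test, p_hat).
    """
    if n_test <= 0:
        raise ValueError("enrichment_test: n_test must be positive")
    backgrounds = np.asarray(backgrounds, dtype=float)
    if backgrounds.size == 0:
        raise ValueError("enrichment_test: need at least one background set")
    if observed > n_test:
        raise ValueError(f"enrichment_test: observed {observed} exceeds n_test {n_test}")
    p_hat = float(backgrounds.sum()) / (backgrounds.size * n_test)
    if observed == 0:
        p = 1.0
    elif p_hat == 0.0:
        logger.warning("enrichment_test: zero background rate with observed > 0; p floored")
        p = P_FLOOR
    else:
        p = float(stats.binom.sf(observed - 1, n_test, p_hat))
    return p, -math.log10(max(p, P_FLOOR))


def by_fdr(p: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Yekutieli q-values (BH with the harmonic-sum penalty)."""
    arr = np.asarray(p, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("NaN p-values passed to by_fdr")
    if arr.size == 0:
        return p.copy() if isinstance(p, pd.Series) else arr.copy()
    q = multipletests(arr, method="fdr_by")[1]
    if isinstance(p, pd.Series):
        return pd.Series(q, index=p.index, name="q")
    return q


def region_enrichment(
    test_probes: list[str],
    annotation: ProbeAnnotation,
    tracks: PeakTrackSet,
    n_sets: int = 1000,
    seed: int | np.random.Generator = 0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full matched-background enrichment of one probe list vs all tracks.

    One background family is drawn once and reused across tracks (the
    backgrounds depend only on the annotation, not on the track); BY
    correction is applied across all (tissue, mark) tests of this list.
    """
    if not test_probes:
        raise ValueError("region_enrichment: empty test probe list")
    backgrounds = matched_backgrounds(test_probes, annotation, n_sets=n_sets, seed=seed)
    probe_pos = pd.Series(np.arange(len(annotation)), index=annotation.probe_ids)
    bg_idx = np.array([probe_pos.loc[bg].to_numpy() for bg in backgrounds])
    test_idx = probe_pos.loc[list(test_probes)].to_numpy()
    n_test = len(test_probes)
    rows = []
    for tissue, mark in sorted(tracks.keys()):
        cov = probe_coverage(tracks[(tissue, mark)], annotation).to_numpy()
        observed = int(cov[test_idx].sum())
        bg_counts = cov[bg_idx].sum(axis=1)
        p, nlp = enrichment_test(observed, bg_counts, n_test)
        rows.append(
            {
                "tissue": tissue,
                "mark": mark,
                "n_test": n_test,
                "observed_overlap": observed,
                "background_mean": float(bg_counts.mean()),
                "background_sd": float(bg_counts.std(ddof=1)) if len(bg_counts) > 1 else 0.0,
                "p": p,
                "neg_log10_p": nlp,
            }
        )
    result = pd.DataFrame(rows)
    result["q"] = by_fdr(result["p"].to_numpy())
    result["significant"] = result["q"] < q_threshold
    return result
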