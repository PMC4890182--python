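"""Quality control and imputation for beta-value matrices.

An entry is *covered* when its detection p-value is at or below the
detection threshold (default 0.05) and the beta value is present.
Samples with poor probe coverage are removed first, then probes with
poor coverage across the remaining samples; entries that still fail
detection afterwards are replaced by probe-space k-nearest-neighbour
imputation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import MethylationDataset

logger = logging.getLogger(__name__)


class QCError(RuntimeError):
    """A QC stage left nothing to analyse, or its inputs are unusable."""


def _coverage_mask(dataset: MethylationDataset, detection_threshold: float) -> pd.DataFrame:
    """Boolean frame: True where an entry counts as covered."""
    observed = dataset.beta.notna()
    if dataset.detection_p is None:
        return observed
    return observed & (dataset.detection_p <= detection_threshold)


def qc_filter(
    dataset: MethylationDataset,
    sample_min_coverage: float = 0.80,
    probe_min_coverage: float = 0.95,
    detection_threshold: float = 0.05,
) -> MethylationDataset:
    """Remove low-coverage samples, then low-coverage probes.

    Samples are removed when the fraction of covered probes is below
    ``sample_min_coverage``; probes are subsequently removed when their
    coverage across the *remaining* samples is below
    ``probe_min_coverage``. The two passes run in exactly that order.
    """
    covered = _coverage_mask(dataset, detection_threshold)

    sample_cov = covered.mean(axis=0)
    keep_samples = sample_cov[sample_cov >= sample_min_coverage].index
    n_dropped_samples = dataset.n_samples - len(keep_samples)
    if len(keep_samples) == 0:
        raise QCError("sample-coverage filter removed every sample")
    if n_dropped_samples:
        logger.info("qc_filter: removed %d low-coverage samples", n_dropped_samples)

    covered = covered[keep_samples]
    probe_cov = covered.mean(axis=1)
    keep_probes = probe_cov[probe_cov >= probe_min_coverage].index
    if len(keep_probes) == 0:
        raise QCError("probe-coverage filter removed every probe")
    if len(keep_probes) < dataset.n_probes:
        logger.info(
            "qc_filter: removed %d low-coverage probes",
            dataset.n_probes - len(keep_probes),
        )

    samples = dataset.samples[dataset.samples["sample_id"].isin(keep_samples)].reset_index(drop=True)
    return MethylationDataset(
        beta=dataset.beta.loc[keep_probes, keep_samples],
        detection_p=None
        if dataset.detection_p is None
        else dataset.detection_p.loc[keep_probes, keep_samples],
        samples=samples,
    )


def knn_impute(
    dataset: MethylationDataset,
    k: int = 5,
    detection_threshold: float = 0.05,
) -> MethylationDataset:
    """Replace failed entries by the mean of the k nearest probe rows.

    Neighbours are probes with complete (fully covered) rows; nearness is
    Euclidean distance between probe rows over the samples where the
    target row is observed. Distance ties are broken by probe id in
    lexicographic order so the result is deterministic. Observed entries
    are untouched.
    """
    covered = _coverage_mask(dataset, detection_threshold).to_numpy()
    if covered.all():
        return dataset.copy()

    beta = dataset.beta.to_numpy(dtype=float).copy()
    probe_ids = dataset.beta.index.to_numpy(dtype=object)
    complete = covered.all(axis=1)
    n_candidates = int(complete.sum())
    if n_candidates < k:
        raise QCError(
            f"knn_impute: only {n_candidates} complete probe rows available "
            f"as neighbour candidates, need k={k}"
        )
    cand_idx = np.flatnonzero(complete)
    cand_ids = probe_ids[cand_idx].astype(str)
    cand_beta = beta[cand_idx]

    # Squared distance over the target row's observed samples, expanded so
    # the candidate cross-term is one matrix product per chunk:
    #   d2(g, c) = sum_obs x^2 - 2 <x0_g, y_c> + (sum_all y_c^2 - sum_miss y_c^2)
    # (x0 has zeros at the target's missing entries; candidates are complete).
    cand_sq = cand_beta**2
    cand_sq_rowsum = cand_sq.sum(axis=1)

    incomplete = np.flatnonzero(~covered.all(axis=1))
    no_obs = [g for g in incomplete if not covered[g].any()]
    if no_obs:
        raise QCError(
            f"knn_impute: probe {probe_ids[no_obs[0]]} has no covered entries "
            "to compute neighbour distances from"
        )
    new_beta = beta.copy()
    x0 = beta[incomplete].copy()
    x0[~covered[incomplete]] = 0.0
    chunk = max(1, int(2**22 // max(len(cand_idx), 1)))
    for lo in range(0, len(incomplete), chunk):
        rows = incomplete[lo : lo + chunk]
        cross = x0[lo : lo + chunk] @ cand_beta.T
        for i, g in enumerate(rows):
            miss = ~covered[g]
            d2 = (
                (beta[g, ~miss] ** 2).sum()
                - 2.0 * cross[i]
                + (cand_sq_rowsum - cand_sq[:, miss].sum(axis=1))
            )
            # exact k nearest with deterministic lexicographic tie-breaks:
            # partition for the kth distance, recompute exact distances for
            # the candidates near it (the expansion above loses exact ties
            # to cancellation noise), then order by (distance, probe id)
            kth = np.partition(d2, k - 1)[k - 1]
            close = np.flatnonzero(d2 <= kth + 1e-7)
            exact = ((cand_beta[close][:, ~miss] - beta[g, ~miss]) ** 2).sum(axis=1)
            close = close[np.lexsort((cand_ids[close], exact))][:k]
            new_beta[g, miss] = cand_beta[close][:, miss].mean(axis=0)

    beta_df = pd.DataFrame(new_beta, index=dataset.beta.index, columns=dataset.beta.columns)
    detp = None
    if dataset.detection_p is not None:
        detp = dataset.detection_p.copy()
        detp_vals = detp.to_numpy(dtype=float)
        detp_vals[~covered] = 0.0  # imputed entries now count as valid
        detp = pd.DataFrame(detp_vals, index=detp.index, columns=detp.columns)
    return MethylationDataset(beta=beta_df, detection_p=detp, samples=dataset.samples.copy())
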