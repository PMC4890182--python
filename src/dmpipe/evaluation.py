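"""Recovery and calibration evaluation of the pipeline on simulated data.

These helpers run the analysis stages on a generated dataset and score
the outcome against the planted truth; they back both the test suite and
the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import GroundTruth, MethylationDataset, ProbeAnnotation
from .dmp import call_dmps, group_dmp_table, paired_differences
from .overlap import fisher_overlap, top_k_by_delta
from .qc import knn_impute, qc_filter
from .simulate import SimulationConfig, simulate_dataset


def run_dmp_stage(
    config: SimulationConfig,
    q_threshold: float = 0.05,
    delta_threshold: float = 0.03,
) -> tuple[MethylationDataset, ProbeAnnotation, GroundTruth, pd.DataFrame, pd.DataFrame]:
    """Simulate, QC, impute and call DMPs; returns intermediates and calls."""
    dataset, annotation, truth = simulate_dataset(config)
    dataset = knn_impute(qc_filter(dataset))
    diffs_mut = paired_differences(dataset, "MUT")
    diffs_ctrl = paired_differences(dataset, "control")
    dmps = call_dmps(
        group_dmp_table(diffs_mut),
        group_dmp_table(diffs_ctrl),
        q_threshold=q_threshold,
        delta_threshold=delta_threshold,
    )
    return dataset, annotation, truth, diffs_mut, dmps


def recovery_metrics(dmps: pd.DataFrame, truth: GroundTruth) -> dict[str, float]:
    """Sensitivity on carrier-only spikes and contamination of the calls.

    Sensitivity counts planted carrier-only spikes recovered among the
    called DMPs (restricted to spikes surviving QC); the false-call
    fraction counts called probes that were never spiked at all.
    """
    called = set(dmps.index[dmps["dmp"]])
    planted = truth.spiked_mut_only & set(dmps.index)
    sensitivity = len(called & planted) / len(planted) if planted else float("nan")
    false_calls = called - truth.all_spiked
    false_fraction = len(false_calls) / len(called) if called else 0.0
    return {
        "n_called": float(len(called)),
        "sensitivity": sensitivity,
        "false_call_fraction": false_fraction,
        "called_fraction_of_probes": len(called) / len(dmps),
    }


def shared_contrast_overlap(
    config: SimulationConfig,
    k: int,
    cancer_noise_sd: float = 0.02,
    shared: bool = True,
) -> dict[str, float]:
    """Top-k overlap between the within-cohort contrast and a second contrast.

    The first effect vector is the median carrier fimbrial-minus-proximal
    difference from a simulated dataset. The second ("cancer") effect
    vector either carries the same planted shifts plus independent noise
    (``shared=True``) or is pure noise (``shared=False``); the top-k
    decrease lists of both vectors are overlapped by Fisher's exact test.
    """
    dataset, annotation, truth, diffs_mut, _ = run_dmp_stage(config)
    fimb_prox_effect = diffs_mut.median(axis=1)
    rng = np.random.default_rng(config.seed + 7_000_003)
    cancer = pd.Series(
        rng.normal(0.0, cancer_noise_sd, len(fimb_prox_effect)),
        index=fimb_prox_effect.index,
    )
    if shared:
        for probe in truth.all_spiked & set(cancer.index):
            sign = 1.0 if truth.direction[probe] == "hyper" else -1.0
            cancer[probe] += sign * config.delta_spike
    universe = set(fimb_prox_effect.index)
    res = fisher_overlap(
        top_k_by_delta(fimb_prox_effect, k=k, sign="decrease"),
        top_k_by_delta(cancer, k=k, sign="decrease"),
        universe,
        list_a_name="fimbrial_vs_proximal",
        list_b_name="cancer_contrast",
    )
    return {"odds_ratio": res.odds_ratio, "p": res.p, "overlap": float(res.overlap)}
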