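"""Synthetic paired methylation datasets with planted differential signal.

The generator emulates the structure of a paired-design 450k study: two
subject groups (mutation carriers and controls), one fimbrial and one
proximal sample per subject, beta values drawn from per-(probe, site,
group) beta distributions around a probe-specific baseline mean, a
designated set of spiked probes whose fimbrial mean is shifted by
+/- delta in the carrier group only (or in both groups), a detection-p
matrix flagging unreliable entries, a single-chromosome probe
annotation with realistic gene/CpG-island category frequencies, toy
gene-set collections, and per-(tissue, mark) peak tracks that can be
made to preferentially cover the spiked probes.

Everything is reproducible from the config seed, and the planted truth
(which probes are spiked, in which direction, and which tracks are
enriched) is returned for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    CGI_RELATIONS,
    GeneSetCollection,
    GroundTruth,
    MethylationDataset,
    PeakTrackSet,
    ProbeAnnotation,
    ValidationError,
)

#: Histone modification marks used for the synthetic peak tracks.
MARK_NAMES = ("H3K4me1", "H3K27me3", "H3K36me3", "H3K4me3", "H3K9me3")

# category frequencies loosely following the 450k manifest composition
_GENE_REL_CATEGORIES = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR")
_GENE_REL_WEIGHTS = (0.13, 0.16, 0.13, 0.08, 0.42, 0.08)
_CGI_WEIGHTS = (0.31, 0.23, 0.10, 0.36)

_PEAK_HALFWIDTH = 200  # bp each side of the probe; < half the minimum probe gap
_MIN_GAP, _MAX_GAP = 800, 1200


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the default study design.

    Defaults describe a cohort of 30 carrier and 30 control subjects
    measured at 20,000 CpGs with 500 carrier-only spiked probes shifted
    by 0.10 beta units, plus a smaller set spiked in both groups.
    """

    n_subjects_mut: int = 30
    n_subjects_ctrl: int = 30
    n_probes: int = 20000
    n_spiked_mut_only: int = 500
    n_spiked_shared: int = 100
    delta_spike: float = 0.10
    #: shape parameters of the per-probe baseline-mean distribution;
    #: 0.85/0.85 gives the bimodal (mostly un/fully methylated) profile
    #: typical of array betas
    base_alpha: float = 0.85
    base_beta: float = 0.85
    #: precision nu of the per-entry beta noise: sd ~= sqrt(m(1-m)/(nu+1))
    precision: float = 200.0
    #: fraction of spiked probes shifted downwards (hypomethylated in
    #: fimbrial tissue), matching the observed hypo-dominant asymmetry
    hypo_fraction: float = 0.81
    missing_rate: float = 0.005
    dropout_sample_rate: float = 0.0
    seed: int = 0
    n_genes: int = 1200
    probes_per_gene_mean: float = 10.0
    n_gene_sets: int = 50
    n_tissues: int = 5
    n_marks: int = 5
    background_coverage: float = 0.10
    peak_enrichment_factor: float = 3.0
    n_enriched_tracks: int = 2

    def __post_init__(self) -> None:
        for name in (
            "n_subjects_mut", "n_subjects_ctrl", "n_probes", "n_genes",
            "n_tissues", "n_marks",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("n_spiked_mut_only", "n_spiked_shared", "n_gene_sets", "n_enriched_tracks"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.n_spiked_mut_only + self.n_spiked_shared > self.n_probes:
            raise ValidationError("n_spiked_mut_only + n_spiked_shared exceeds n_probes")
        if not (0.0 < self.delta_spike < 0.5):
            raise ValidationError("delta_spike must lie in (0, 0.5)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must lie in [0, 1)")
        if not (0.0 <= self.dropout_sample_rate < 1.0):
            raise ValidationError("dropout_sample_rate must lie in [0, 1)")
        if not (0.0 <= self.hypo_fraction <= 1.0):
            raise ValidationError("hypo_fraction must lie in [0, 1]")
        if self.precision <= 0:
            raise ValidationError("precision must be positive")
        if not (0.0 < self.background_coverage < 1.0):
            raise ValidationError("background_coverage must lie in (0, 1)")
        if self.peak_enrichment_factor <= 0:
            raise ValidationError("peak_enrichment_factor must be positive")
        if self.n_marks > len(MARK_NAMES):
            raise ValidationError(f"n_marks must be <= {len(MARK_NAMES)}")


def _probe_ids(n: int) -> np.ndarray:
    return np.array([f"cg{i:08d}" for i in range(1, n + 1)], dtype=object)


def _simulate_annotation(config: SimulationConfig, rng: np.random.Generator) -> ProbeAnnotation:
    n = config.n_probes
    ids = _probe_ids(n)
    gaps = rng.integers(_MIN_GAP, _MAX_GAP + 1, size=n)
    pos = 1000 + np.cumsum(gaps)  # 1-based, strictly increasing

    genes = np.full(n, "", dtype=object)
    gene_rel = np.full(n, "Intergenic", dtype=object)
    cursor = 0
    for g in range(config.n_genes):
        if cursor >= n:
            break
        size = 1 + rng.poisson(max(config.probes_per_gene_mean - 1.0, 0.0))
        size = min(size, n - cursor)
        name = f"GENE{g + 1:05d}"
        for j in range(cursor, cursor + size):
            genes[j] = name
        cursor += size
        cursor += rng.poisson(3)  # intergenic gap between gene loci
    in_gene = genes != ""
    n_in = int(in_gene.sum())
    gene_rel[in_gene] = rng.choice(_GENE_REL_CATEGORIES, size=n_in, p=_GENE_REL_WEIGHTS)
    # a small fraction of gene probes also map to the neighbouring gene
    multi = np.flatnonzero(in_gene)
    multi = multi[rng.random(len(multi)) < 0.03]
    for j in multi:
        other = f"GENE{min(config.n_genes, int(genes[j][4:]) + 1):05d}"
        if other != genes[j]:
            genes[j] = genes[j] + ";" + other

    cgi_rel = rng.choice(CGI_RELATIONS, size=n, p=_CGI_WEIGHTS)
    table = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": pos.astype(np.int64),
            "genes": genes,
            "gene_relation": gene_rel,
            "cgi_relation": cgi_rel,
        },
        index=pd.Index(ids, name="probe_id"),
    )
    return ProbeAnnotation(table=table)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[MethylationDataset, ProbeAnnotation, GroundTruth]:
    """Generate one paired two-group methylation dataset with planted DMPs.

    Each subject contributes a fimbrial and a proximal sample. Spiked
    probes carry a fimbrial-minus-proximal mean shift of
    ``+/- delta_spike`` in the carrier group (carrier-only spikes) or in
    both groups (shared spikes); direction is hypo with probability
    ``hypo_fraction``. Baseline means of spiked probes are kept far
    enough from 0 and 1 that the shifted mean stays inside the unit
    interval, so the planted effect size is not attenuated by clipping.
    """
    rng = np.random.default_rng(config.seed)
    annotation = _simulate_annotation(config, rng)
    ids = annotation.probe_ids.to_numpy(dtype=object)
    n = config.n_probes

    baseline = rng.beta(config.base_alpha, config.base_beta, size=n)
    baseline = np.clip(baseline, 0.02, 0.98)

    n_spiked = config.n_spiked_mut_only + config.n_spiked_shared
    spiked_idx = rng.choice(n, size=n_spiked, replace=False) if n_spiked else np.array([], dtype=int)
    mut_only_idx = spiked_idx[: config.n_spiked_mut_only]
    shared_idx = spiked_idx[config.n_spiked_mut_only:]
    lo, hi = 0.05 + config.delta_spike, 0.95 - config.delta_spike
    baseline[spiked_idx] = rng.uniform(lo, hi, size=n_spiked)
    spike_sign = np.where(rng.random(n_spiked) < config.hypo_fraction, -1.0, 1.0)
    shift = np.zeros(n)
    shift[spiked_idx] = spike_sign * config.delta_spike

    subjects = [f"MUT{i + 1:03d}" for i in range(config.n_subjects_mut)] + [
        f"CTRL{i + 1:03d}" for i in range(config.n_subjects_ctrl)
    ]
    groups = ["MUT"] * config.n_subjects_mut + ["control"] * config.n_subjects_ctrl
    sample_rows = []
    columns = []
    means = []
    shared_mask = np.zeros(n, dtype=bool)
    shared_mask[shared_idx] = True
    mut_only_mask = np.zeros(n, dtype=bool)
    mut_only_mask[mut_only_idx] = True
    for subject, group in zip(subjects, groups):
        spiked_here = shared_mask | (mut_only_mask if group == "MUT" else False)
        fimb_mean = np.where(spiked_here, baseline + shift, baseline)
        for site, mean in (("fimbrial", fimb_mean), ("proximal", baseline)):
            sid = f"{subject}_{'F' if site == 'fimbrial' else 'P'}"
            sample_rows.append(
                {"sample_id": sid, "subject_id": subject, "site": site, "group": group}
            )
            columns.append(sid)
            means.append(mean)

    mean_mat = np.column_stack(means)  # probes x samples
    nu = config.precision
    beta_vals = rng.beta(mean_mat * nu, (1.0 - mean_mat) * nu)
    beta_vals = np.clip(beta_vals, 0.0, 1.0)

    detp = rng.uniform(0.0, 0.01, size=beta_vals.shape)
    fail = rng.random(beta_vals.shape) < config.missing_rate
    detp[fail] = 0.05 + 0.95 * rng.random(int(fail.sum()))
    # sample dropout: a contiguous block of ~25% of probes fails detection,
    # pushing the sample below the 80% coverage QC rule
    n_dropout = int(round(config.dropout_sample_rate * len(columns)))
    if n_dropout:
        victims = rng.choice(len(columns), size=n_dropout, replace=False)
        block = int(np.ceil(0.25 * n))
        for s in victims:
            start = int(rng.integers(0, n - block + 1))
            detp[start : start + block, s] = 0.05 + 0.95 * rng.random(block)

    beta = pd.DataFrame(beta_vals, index=annotation.probe_ids, columns=columns)
    detection_p = pd.DataFrame(detp, index=annotation.probe_ids, columns=columns)
    samples = pd.DataFrame(sample_rows)
    dataset = MethylationDataset(beta=beta, detection_p=detection_p, samples=samples)

    direction = {
        str(ids[j]): ("hypo" if shift[j] < 0 else "hyper") for j in spiked_idx
    }
    truth = GroundTruth(
        spiked_mut_only={str(ids[j]) for j in mut_only_idx},
        spiked_shared={str(ids[j]) for j in shared_idx},
        direction=direction,
    )
    return dataset, annotation, truth


def simulate_peak_tracks(
    annotation: ProbeAnnotation,
    truth: GroundTruth,
    config: SimulationConfig,
) -> PeakTrackSet:
    """Per-(tissue, mark) peak tracks, some enriched over spiked probes.

    Every track covers each probe independently with probability
    ``background_coverage``; the ``n_enriched_tracks`` randomly chosen
    enriched tracks cover *spiked* probes at ``peak_enrichment_factor``
    times that probability instead. Peaks are +/-200 bp around the
    covered probe, which is less than half the minimum inter-probe gap,
    so peaks never reach a neighbouring probe and coverage of each probe
    is exactly its Bernoulli draw. The chosen enriched (tissue, mark)
    pairs are recorded on ``truth``.
    """
    if len(annotation) == 0:
        raise ValidationError("simulate_peak_tracks: empty annotation")
    rng = np.random.default_rng(config.seed + 1_000_003)
    tissues = [f"T{i + 1:02d}" for i in range(config.n_tissues)]
    marks = list(MARK_NAMES[: config.n_marks])
    pairs = [(t, m) for t in tissues for m in marks]
    n_enriched = min(config.n_enriched_tracks, len(pairs))
    enriched_ids = rng.choice(len(pairs), size=n_enriched, replace=False)
    enriched = {pairs[i] for i in enriched_ids}

    pos0 = annotation.table["pos"].to_numpy(dtype=np.int64) - 1
    chrom = "chr1"
    spiked_mask = annotation.probe_ids.isin(truth.all_spiked)
    p0 = config.background_coverage
    p_spiked = min(1.0, config.peak_enrichment_factor * p0)

    tracks: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for pair in pairs:
        prob = np.full(len(annotation), p0)
        if pair in enriched:
            prob[spiked_mask] = p_spiked
        covered = rng.random(len(annotation)) < prob
        centers = pos0[covered]
        starts = np.maximum(centers - _PEAK_HALFWIDTH, 0)
        ends = centers + _PEAK_HALFWIDTH + 1
        tracks[pair] = {chrom: np.column_stack([starts, ends])}
    truth.enriched_tissue_marks = enriched
    return PeakTrackSet(tracks=tracks)


def simulate_gene_sets(
    annotation: ProbeAnnotation,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> GeneSetCollection:
    """Toy named gene sets sampled from the annotation's gene universe."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2_000_003)
    universe = sorted(annotation.gene_universe())
    sets: dict[str, set[str]] = {}
    for i in range(config.n_gene_sets):
        size = int(rng.integers(10, min(51, max(11, len(universe)))))
        members = rng.choice(universe, size=min(size, len(universe)), replace=False)
        sets[f"SET_{i + 1:04d}"] = set(members.tolist())
    return GeneSetCollection(sets=sets, universe=set(universe))
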