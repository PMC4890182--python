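import numpy as np
import pandas as pd
import pytest

from dmpipe import (
    MethylationDataset,
    ProbeAnnotation,
    SimulationConfig,
    simulate_dataset,
)


def make_dataset(beta, detection_p=None, n_subjects=None, probe_ids=None, groups=None):
    """Build a MethylationDataset from raw arrays with a paired sample sheet.

    Columns come in (fimbrial, proximal) pairs per subject; ``groups``
    assigns each subject to MUT/control (defaults to all MUT).
    """
    beta = np.asarray(beta, dtype=float)
    n_probes, n_samples = beta.shape
    assert n_samples % 2 == 0
    n_subjects = n_samples // 2
    groups = groups or ["MUT"] * n_subjects
    probe_ids = probe_ids or [f"cg{i:05d}" for i in range(n_probes)]
    rows, cols = [], []
    for j in range(n_subjects):
        subject = f"S{j:03d}"
        for site, tag in (("fimbrial", "F"), ("proximal", "P")):
            sid = f"{subject}_{tag}"
            rows.append(
                {"sample_id": sid, "subject_id": subject, "site": site, "group": groups[j]}
            )
            cols.append(sid)
    beta_df = pd.DataFrame(beta, index=probe_ids, columns=cols)
    detp_df = None
    if detection_p is not None:
        detp_df = pd.DataFrame(
            np.asarray(detection_p, dtype=float), index=probe_ids, columns=cols
        )
    return MethylationDataset(beta=beta_df, detection_p=detp_df, samples=pd.DataFrame(rows))


def make_annotation(n_probes, probe_ids=None, gene_relation=None, cgi_relation=None, genes=None):
    """Single-chromosome annotation with evenly spaced probes."""
    probe_ids = probe_ids or [f"cg{i:05d}" for i in range(n_probes)]
    table = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": 1000 + 1000 * np.arange(n_probes, dtype=np.int64),
            "genes": genes if genes is not None else [""] * n_probes,
            "gene_relation": gene_relation if gene_relation is not None else ["Body"] * n_probes,
            "cgi_relation": cgi_relation if cgi_relation is not None else ["OpenSea"] * n_probes,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ProbeAnnotation(table=table)


@pytest.fixture(scope="session")
def small_sim():
    """One small spiked dataset shared by read-only tests."""
    config = SimulationConfig(
        n_probes=2000,
        n_subjects_mut=8,
        n_subjects_ctrl=8,
        n_spiked_mut_only=50,
        n_spiked_shared=10,
        n_genes=150,
        seed=11,
    )
    dataset, annotation, truth = simulate_dataset(config)
    return config, dataset, annotation, truth
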