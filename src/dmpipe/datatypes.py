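"""Core containers shared across the pipeline.

The central objects are thin, validated wrappers around pandas DataFrames:
a :class:`MethylationDataset` holds the beta-value matrix (CpG probes x
samples, values in [0, 1]), an optional detection-p matrix of the same
shape, and the paired sample sheet; a :class:`ProbeAnnotation` holds
per-probe genomic coordinates and the gene/CpG-island relationship
categories used for gene mapping and background matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

SITES = ("fimbrial", "proximal")
GROUPS = ("MUT", "control")

#: Probe position relative to gene structure (450k manifest vocabulary,
#: collapsed). "Intergenic" means the probe maps to no gene.
GENE_RELATIONS = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR", "Intergenic")

#: Probe position relative to a CpG island.
CGI_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class MethylationDataset:
    """Beta-value matrix with optional detection p-values and sample sheet.

    Parameters
    ----------
    beta
        DataFrame indexed by probe id, one column per sample id; values
        in [0, 1] (NaN allowed for entries that failed detection).
    detection_p
        Same shape as ``beta``; per-entry array quality score in [0, 1].
        ``None`` means every entry is treated as reliably detected.
    samples
        Sample sheet with columns ``sample_id``, ``subject_id``, ``site``
        (fimbrial/proximal) and ``group`` (MUT/control).
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.beta.index.has_duplicates:
            raise ValidationError("duplicate probe ids in beta matrix")
        if self.beta.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in beta matrix")
        required = {"sample_id", "subject_id", "site", "group"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        if self.samples["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in sample sheet")
        bad_site = set(self.samples["site"]) - set(SITES)
        if bad_site:
            raise ValidationError(f"unknown site labels: {sorted(bad_site)}")
        bad_group = set(self.samples["group"]) - set(GROUPS)
        if bad_group:
            raise ValidationError(f"unknown group labels: {sorted(bad_group)}")
        dup = self.samples.duplicated(subset=["subject_id", "site"])
        if dup.any():
            raise ValidationError("more than one sample per (subject, site)")
        sheet_ids = set(self.samples["sample_id"])
        mat_ids = set(self.beta.columns)
        if sheet_ids != mat_ids:
            raise ValidationError(
                "sample sheet and beta matrix disagree: "
                f"{len(sheet_ids ^ mat_ids)} sample ids differ"
            )
        if self.detection_p is not None:
            if self.detection_p.shape != self.beta.shape:
                raise ValidationError("detection-p matrix shape differs from beta")
            if not self.detection_p.index.equals(self.beta.index) or not (
                self.detection_p.columns.equals(self.beta.columns)
            ):
                raise ValidationError("detection-p matrix axes differ from beta")
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("beta values outside [0, 1]")

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def paired_subjects(self, group: str) -> list[str]:
        """Subjects of ``group`` with samples at both anatomical sites."""
        sub = self.samples[self.samples["group"] == group]
        counts = sub.groupby("subject_id")["site"].nunique()
        return sorted(counts.index[counts == 2])

    def sample_id_for(self, subject_id: str, site: str) -> str:
        row = self.samples[
            (self.samples["subject_id"] == subject_id) & (self.samples["site"] == site)
        ]
        if len(row) != 1:
            raise KeyError(f"no unique sample for ({subject_id}, {site})")
        return row["sample_id"].iloc[0]

    def copy(self) -> "MethylationDataset":
        return MethylationDataset(
            beta=self.beta.copy(),
            detection_p=None if self.detection_p is None else self.detection_p.copy(),
            samples=self.samples.copy(),
        )


@dataclass
class ProbeAnnotation:
    """Per-probe genomic coordinates and annotation categories.

    ``table`` is indexed by probe id with columns ``chrom``, ``pos``
    (1-based), ``genes`` (semicolon-joined gene symbols, empty string for
    intergenic probes), ``gene_relation`` and ``cgi_relation``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "genes", "gene_relation", "cgi_relation"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate probe ids in annotation")
        if len(self.table) and (self.table["pos"] < 1).any():
            raise ValidationError("annotation positions must be >= 1 (1-based)")
        bad = set(self.table["gene_relation"]) - set(GENE_RELATIONS)
        if bad:
            raise ValidationError(f"unknown gene_relation categories: {sorted(bad)}")
        bad = set(self.table["cgi_relation"]) - set(CGI_RELATIONS)
        if bad:
            raise ValidationError(f"unknown cgi_relation categories: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def genes_of(self, probe_id: str) -> list[str]:
        raw = self.table.at[probe_id, "genes"]
        if not isinstance(raw, str) or raw == "":
            return []
        return raw.split(";")

    def gene_universe(self) -> set[str]:
        """All gene symbols carried by at least one probe."""
        out: set[str] = set()
        for raw in self.table["genes"]:
            if isinstance(raw, str) and raw:
                out.update(raw.split(";"))
        return out

    def matching_bins(self) -> pd.Series:
        """Composite (gene_relation, cgi_relation) bin label per probe."""
        return self.table["gene_relation"] + "|" + self.table["cgi_relation"]


@dataclass(frozen=True)
class ModerationPrior:
    """Empirical-Bayes variance prior: ``s^2_g ~ s0^2 * d0 / chi^2_{d0}``.

    ``d0`` is the prior degrees of freedom (``inf`` when the observed
    log-variances show no excess spread over the chi-square sampling
    noise); ``s0_sq`` is the prior variance.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValidationError("prior degrees of freedom d0 must be > 0")
        if not (self.s0_sq > 0):
            raise ValidationError("prior variance s0_sq must be > 0")


@dataclass
class GroundTruth:
    """Planted signal of a simulated dataset, for recovery tests."""

    spiked_mut_only: set[str]
    spiked_shared: set[str]
    direction: dict[str, str]  # probe id -> "hyper" | "hypo"
    enriched_tissue_marks: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.spiked_mut_only & self.spiked_shared:
            raise ValidationError("spiked probe sets must be disjoint")

    @property
    def all_spiked(self) -> set[str]:
        return self.spiked_mut_only | self.spiked_shared


@dataclass
class PeakTrackSet:
    """Genomic interval tracks keyed by (tissue, mark).

    Each track maps chromosome name to an (n, 2) int array of sorted,
    non-overlapping half-open 0-based intervals.
    """

    tracks: dict[tuple[str, str], dict[str, np.ndarray]]

    def __post_init__(self) -> None:
        for key, chroms in self.tracks.items():
            for chrom, arr in chroms.items():
                arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                if len(arr) and (arr[:, 0] >= arr[:, 1]).any():
                    raise ValidationError(f"track {key} {chrom}: start >= end")
                order = np.argsort(arr[:, 0], kind="stable")
                arr = arr[order]
                if len(arr) > 1 and (arr[1:, 0] < arr[:-1, 1]).any():
                    raise ValidationError(f"track {key} {chrom}: overlapping intervals")
                chroms[chrom] = arr

    def keys(self) -> Iterable[tuple[str, str]]:
        return self.tracks.keys()

    def __getitem__(self, key: tuple[str, str]) -> dict[str, np.ndarray]:
        return self.tracks[key]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the gene universe they are tested against."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        if len(self.sets) != len(set(self.sets)):
            raise ValidationError("gene set names must be unique")
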