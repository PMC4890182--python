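"""Readers and writers for the pipeline's plain-text formats.

All tabular formats are TSV. Matrices are written with probe ids as the
row index and sample ids as the header, floats at 6 significant digits
(the declared round-trip precision). Peak tracks use standard BED
(0-based, half-open); gene sets use GMT.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    GeneSetCollection,
    GroundTruth,
    MethylationDataset,
    PeakTrackSet,
    ProbeAnnotation,
    ValidationError,
)

FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------- matrices

def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id", float_format=FLOAT_FMT)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def write_dataset(dataset: MethylationDataset, outdir: str | Path, prefix: str = "") -> dict[str, Path]:
    """Write beta / detection-p / sample sheet; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"beta": outdir / f"{prefix}beta.tsv", "samples": outdir / f"{prefix}samples.tsv"}
    write_matrix(dataset.beta, paths["beta"])
    dataset.samples.to_csv(paths["samples"], sep="\t", index=False)
    if dataset.detection_p is not None:
        paths["detection_p"] = outdir / f"{prefix}detection_p.tsv"
        write_matrix(dataset.detection_p, paths["detection_p"])
    return paths


def read_dataset(
    beta_path: str | Path,
    samples_path: str | Path,
    detection_p_path: str | Path | None = None,
) -> MethylationDataset:
    beta = read_matrix(beta_path)
    samples = pd.read_csv(samples_path, sep="\t", dtype=str)
    detp = read_matrix(detection_p_path) if detection_p_path is not None else None
    return MethylationDataset(beta=beta, detection_p=detp, samples=samples)


# -------------------------------------------------------------- annotation

def write_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="probe_id")


def read_annotation(path: str | Path) -> ProbeAnnotation:
    table = pd.read_csv(path, sep="\t", index_col="probe_id", keep_default_na=False, dtype={"genes": str})
    table["pos"] = table["pos"].astype(int)
    return ProbeAnnotation(table=table)


# --------------------------------------------------------------------- GMT

def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ...

    If ``universe`` is None it defaults to the union of all set members.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            if parts[0] in sets:
                raise ValidationError(f"duplicate gene set name: {parts[0]}")
            sets[parts[0]] = {g for g in parts[2:] if g}
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets=sets, universe=universe)


# --------------------------------------------------------------------- BED

def write_bed(intervals: dict[str, np.ndarray], path: str | Path) -> None:
    """Write {chrom: (n,2) array} as 3-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for start, end in np.asarray(intervals[chrom], dtype=np.int64).reshape(-1, 2):
                fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path: str | Path) -> dict[str, np.ndarray]:
    """Read a 3+ column BED file into {chrom: sorted (n,2) int array}."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"BED line with <3 columns in {path}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            per_chrom.setdefault(chrom, []).append((start, end))
    return {
        chrom: np.array(sorted(ivs), dtype=np.int64).reshape(-1, 2)
        for chrom, ivs in per_chrom.items()
    }


def write_track_set(tracks: PeakTrackSet, outdir: str | Path) -> Path:
    """Write one BED per (tissue, mark) plus a manifest TSV mapping files.

    Returns the manifest path. The manifest has columns
    ``file``, ``tissue``, ``mark``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (tissue, mark), chroms in tracks.tracks.items():
        fname = f"{tissue}__{mark}.bed"
        write_bed(chroms, outdir / fname)
        rows.append({"file": fname, "tissue": tissue, "mark": mark})
    manifest = outdir / "tracks_manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_track_set(manifest_path: str | Path) -> PeakTrackSet:
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t", dtype=str)
    tracks = {}
    for _, row in manifest.iterrows():
        key = (row["tissue"], row["mark"])
        tracks[key] = read_bed(manifest_path.parent / row["file"])
    return PeakTrackSet(tracks=tracks)


# ------------------------------------------------------------ ground truth

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "spiked_mut_only": sorted(truth.spiked_mut_only),
        "spiked_shared": sorted(truth.spiked_shared),
        "direction": truth.direction,
        "enriched_tissue_marks": sorted(list(tm) for tm in truth.enriched_tissue_marks),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        spiked_mut_only=set(payload["spiked_mut_only"]),
        spiked_shared=set(payload["spiked_shared"]),
        direction=dict(payload["direction"]),
        enriched_tissue_marks={tuple(tm) for tm in payload["enriched_tissue_marks"]},
    )


# -------------------------------------------------------------- probe lists

def write_probe_list(probes: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(p + "\n" for p in probes))


def read_probe_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
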