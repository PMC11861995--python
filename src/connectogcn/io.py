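"""Plain-text dataset interchange: one CSV matrix per subject plus a TSV
manifest (subject_id, cohort, sex, file).  Matrices are written in scientific
notation at 17 significant digits, so a write/read round trip reproduces
float64 values exactly."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .synthetic import COHORTS, ConnectomeGraph, make_node_features

__all__ = ["write_dataset", "load_manifest"]

SEX_TOKENS = {"F": 1, "M": 0}
SEX_NAMES = {1: "F", 0: "M"}


def write_dataset(graphs: list[ConnectomeGraph], outdir) -> Path:
    """Write every subject's adjacency and a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.tsv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["subject_id", "cohort", "sex", "file"])
        for g in graphs:
            fname = f"{g.subject_id}.csv"
            np.savetxt(outdir / fname, g.adjacency, fmt="%.17g", delimiter=",")
            writer.writerow([g.subject_id, g.cohort, SEX_NAMES[g.label], fname])
    return manifest


def load_manifest(path, feature_scheme: str = "connectivity_profile") -> list[ConnectomeGraph]:
    """Read a manifest TSV and its matrix files back into graphs.

    Validates symmetry, non-negativity and shape consistency of every matrix,
    rejecting on the first violation with the subject id and offending entry;
    unknown cohort or sex tokens are rejected.
    """
    path = Path(path)
    base = path.parent
    graphs: list[ConnectomeGraph] = []
    n_regions = None
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"subject_id", "cohort", "sex", "file"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"manifest must have columns {sorted(required)}")
        for row in reader:
            sid = row["subject_id"]
            if row["cohort"] not in COHORTS:
                raise ValueError(f"{sid}: unknown cohort token {row['cohort']!r}")
            if row["sex"] not in SEX_TOKENS:
                raise ValueError(f"{sid}: unknown sex token {row['sex']!r}")
            A = np.loadtxt(base / row["file"], delimiter=",", ndmin=2)
            g = ConnectomeGraph(
                adjacency=A,
                node_features=None,
                label=SEX_TOKENS[row["sex"]],
                cohort=row["cohort"],
                subject_id=sid,
            )
            g.validate()
            if n_regions is None:
                n_regions = A.shape[0]
            elif A.shape[0] != n_regions:
                raise ValueError(
                    f"{sid}: matrix is {A.shape[0]}x{A.shape[0]} but dataset uses "
                    f"{n_regions} regions"
                )
            graphs.append(make_node_features(g, feature_scheme))
    if not graphs:
        raise ValueError(f"manifest {path} lists no subjects")
    return graphs
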