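"""Comparison and summary of structural ensembles.

Structures are embedded as binary per-nucleotide paired/unpaired vectors for
PCA; predictions are scored against reference structures (e.g. from
crystallography) with base-pair sensitivity and PPV under exact (i, j)
matching, with an optional one-nucleotide slip relaxation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import DuplexCluster
from .folding import SecondaryStructure
from .io import Interval, ReferenceStructure

__all__ = [
    "StructureEnsemble",
    "structure_vector",
    "ensemble_pca",
    "compare_to_reference",
    "arc_comparison",
    "cluster_explained_by_reference",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StructureEnsemble:
    sampleName: str
    region: Interval
    structures: tuple[SecondaryStructure, ...]

    def __post_init__(self) -> None:
        if not self.structures:
            raise ValueError("ensemble must contain at least one structure")
        for s in self.structures:
            if s.region != self.region:
                raise ValueError(
                    f"structure region {s.region} differs from ensemble region {self.region}"
                )

    @classmethod
    def from_dataset(cls, ds, sampleName: str) -> "StructureEnsemble":
        reg = Interval(*ds.ensembleRegion)
        structs = tuple(
            SecondaryStructure(region=reg, dotbracket=db, dg=dg)
            for db, dg in zip(ds.viennaStructures[sampleName], ds.dgs[sampleName])
        )
        return cls(sampleName=sampleName, region=reg, structures=structs)


def structure_vector(s: SecondaryStructure) -> np.ndarray:
    """Binary vector over the region: 1 where the nucleotide is paired."""
    v = np.zeros(len(s.region), dtype=np.int8)
    for pos, ch in enumerate(s.dotbracket):
        if ch in "()":
            v[pos] = 1
    return v


def ensemble_pca(
    ensembles: list[StructureEnsemble],
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of paired/unpaired structure vectors across ensembles.

    Rows (structures) are mean-centered and decomposed by SVD.  Returns a
    coordinate table (sampleName, structure index, PC columns) and the
    variance-explained fraction per component (summing to 1 when the total
    variance is nonzero; all-identical inputs give all-zero coordinates).
    """
    labels = [
        (e.sampleName, k) for e in ensembles for k in range(len(e.structures))
    ]
    if len(labels) < 2:
        raise ValueError("PCA needs at least 2 structures in total")
    x = np.vstack(
        [structure_vector(s) for e in ensembles for s in e.structures]
    ).astype(float)
    centered = x - x.mean(axis=0)
    u, sv, vt = np.linalg.svd(centered, full_matrices=False)
    coords = u * sv
    var = sv**2
    total = var.sum()
    explained = var / total if total > 0 else np.zeros_like(var)
    df = pd.DataFrame(
        coords, columns=[f"PC{k + 1}" for k in range(coords.shape[1])]
    )
    df.insert(0, "structure", [k for _, k in labels])
    df.insert(0, "sampleName", [s for s, _ in labels])
    return df, explained


def _slipped(pair: tuple[int, int], slip: int) -> set[tuple[int, int]]:
    i, j = pair
    return {
        (i + di, j + dj)
        for di in range(-slip, slip + 1)
        for dj in range(-slip, slip + 1)
    }


def compare_to_reference(
    pred: SecondaryStructure,
    ref: ReferenceStructure,
    region: tuple[int, int] | None = None,
    slip: int = 0,
) -> dict:
    """Base-pair sensitivity and PPV of a prediction against a reference.

    tp = |pred ∩ ref| (exact (i, j) matching by default; ``slip`` allows the
    common ±1 relaxation), sensitivity = tp / |ref pairs in region|,
    ppv = tp / |pred pairs|.  Undefined ratios (empty reference or empty
    prediction) are returned as None with a warning.
    """
    reg = Interval(*region) if region else pred.region
    ref_pairs = ref.pairs_in_region(reg.start, reg.end)
    pred_pairs = pred.pairs
    if slip == 0:
        tp_pairs = pred_pairs & ref_pairs
    else:
        tp_pairs = {p for p in pred_pairs if _slipped(p, slip) & ref_pairs}
    tp = len(tp_pairs)
    fn = len(ref_pairs) - tp
    fp = len(pred_pairs) - tp
    sensitivity = ppv = None
    if ref_pairs:
        sensitivity = tp / len(ref_pairs)
    else:
        warnings.warn("no reference pairs in region; sensitivity undefined")
    if pred_pairs:
        ppv = tp / len(pred_pairs)
    else:
        warnings.warn("empty prediction; PPV undefined")
    return {
        "sensitivity": sensitivity,
        "ppv": ppv,
        "tp": tp,
        "fn": fn,
        "fp": fp,
    }


def arc_comparison(a: SecondaryStructure, b: SecondaryStructure) -> pd.DataFrame:
    """Label every base pair of two structures as shared / a_only / b_only."""
    if a.region != b.region:
        raise ValueError(f"regions differ: {a.region} vs {b.region}")
    pa, pb = a.pairs, b.pairs
    rows = [(i, j, "shared") for i, j in sorted(pa & pb)]
    rows += [(i, j, "a_only") for i, j in sorted(pa - pb)]
    rows += [(i, j, "b_only") for i, j in sorted(pb - pa)]
    return pd.DataFrame(rows, columns=["i", "j", "label"]).sort_values(
        ["i", "j"], ignore_index=True
    )


def cluster_explained_by_reference(
    cluster: DuplexCluster, ref: ReferenceStructure, slack: int = 0
) -> bool:
    """True iff some reference pair falls within the cluster footprints.

    A pair (i, j) explains the cluster when i lies in the L footprint and j
    in the R footprint, each extended by ``slack`` nucleotides.
    """
    l0, l1 = cluster.L_footprint.start - slack, cluster.L_footprint.end + slack
    r0, r1 = cluster.R_footprint.start - slack, cluster.R_footprint.end + slack
    return any(l0 <= i <= l1 and r0 <= j <= r1 for i, j in ref.pairs)
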