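"""Contact matrices from chimeric duplexes.

Each duplex contributes a full rectangle: every cell (i, j) with i in the
left arm and j in the right arm is incremented.  Intra-RNA matrices live in
the upper triangle after orientation normalization; matrices are stored
sparse (scipy COO/CSR) and densified on demand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.io import mmwrite

from .io import Duplex, DuplexDataSet

__all__ = ["ContactMatrix", "make_contact_matrix", "inter_contact_matrix"]


@dataclass
class ContactMatrix:
    tx_row: str
    tx_col: str
    counts: sparse.csr_matrix  # shape (len(tx_row), len(tx_col))
    kind: str = "raw"  # raw | cluster | trimmed

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def total(self) -> int:
        return int(self.counts.sum())

    def transpose(self) -> "ContactMatrix":
        return ContactMatrix(
            tx_row=self.tx_col,
            tx_col=self.tx_row,
            counts=self.counts.T.tocsr(),
            kind=self.kind,
        )

    def to_mtx(self, path: str | Path) -> None:
        mmwrite(str(path), self.counts.tocoo())

    def to_triplets(self, path: str | Path) -> None:
        coo = self.counts.tocoo()
        with open(path, "w") as fh:
            fh.write("row\tcol\tcount\n")
            order = np.lexsort((coo.col, coo.row))
            for k in order:
                # 1-based transcript coordinates in the dump
                fh.write(f"{coo.row[k] + 1}\t{coo.col[k] + 1}\t{int(coo.data[k])}\n")


def _rectangles_to_coo(
    rects: Iterable[tuple[int, int, int, int, int]], shape: tuple[int, int]
) -> sparse.csr_matrix:
    """Accumulate (l_start, l_end, r_start, r_end, weight) rectangles (1-based)."""
    rows, cols, data = [], [], []
    for ls, le, rs, re, w in rects:
        ii, jj = np.meshgrid(
            np.arange(ls - 1, le), np.arange(rs - 1, re), indexing="ij"
        )
        rows.append(ii.ravel())
        cols.append(jj.ravel())
        data.append(np.full(ii.size, w, dtype=np.int64))
    if not rows:
        return sparse.csr_matrix(shape, dtype=np.int64)
    m = sparse.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=shape,
        dtype=np.int64,
    )
    return m.tocsr()


def make_contact_matrix(
    duplexes: Sequence[Duplex], tx_len: int, tx_id: str = "", kind: str = "raw"
) -> ContactMatrix:
    """Build an intra-RNA contact matrix by rectangle fill.

    All duplexes must be intra-RNA on the same transcript and
    orientation-normalized; the matrix total equals sum |L| * |R|.
    """
    rects = []
    for d in duplexes:
        if d.tx_L != d.tx_R:
            raise ValueError(f"read {d.read_id}: inter-RNA duplex in intra-RNA matrix")
        if d.L.end > tx_len or d.R.end > tx_len:
            raise ValueError(
                f"read {d.read_id}: coordinate exceeds transcript length {tx_len}"
            )
        rects.append((d.L.start, d.L.end, d.R.start, d.R.end, 1))
    return ContactMatrix(
        tx_row=tx_id or (duplexes[0].tx_L if duplexes else ""),
        tx_col=tx_id or (duplexes[0].tx_L if duplexes else ""),
        counts=_rectangles_to_coo(rects, (tx_len, tx_len)),
        kind=kind,
    )


def footprint_matrix(
    footprints: Iterable[tuple[int, int, int, int, int]],
    tx_len: int,
    tx_id: str = "",
    kind: str = "cluster",
) -> ContactMatrix:
    """Rectangle-fill matrix from (L_start, L_end, R_start, R_end, weight) footprints."""
    return ContactMatrix(
        tx_row=tx_id,
        tx_col=tx_id,
        counts=_rectangles_to_coo(footprints, (tx_len, tx_len)),
        kind=kind,
    )


def inter_contact_matrix(
    ds: DuplexDataSet,
    tx_a: str,
    tx_b: str,
    sampleName: str | None = None,
) -> ContactMatrix:
    """Rectangular contact matrix between two transcripts.

    Rows index ``tx_a`` positions, columns ``tx_b``; whichever arm of a
    duplex maps to ``tx_a`` supplies the row interval.  Swapping the
    arguments transposes the matrix.
    """
    len_a, len_b = len(ds.sequences[tx_a]), len(ds.sequences[tx_b])
    names = [sampleName] if sampleName else ds.sample_names
    rects = []
    for s in names:
        for d in ds.inputFiles[s]:
            if d.tx_L == tx_a and d.tx_R == tx_b:
                rects.append((d.L.start, d.L.end, d.R.start, d.R.end, 1))
            elif d.tx_L == tx_b and d.tx_R == tx_a and tx_a != tx_b:
                rects.append((d.R.start, d.R.end, d.L.start, d.L.end, 1))
    if not rects:
        warnings.warn(f"no duplexes link {tx_a} and {tx_b}; returning zero matrix")
    return ContactMatrix(
        tx_row=tx_a,
        tx_col=tx_b,
        counts=_rectangles_to_coo(rects, (len_a, len_b)),
        kind="raw",
    )
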