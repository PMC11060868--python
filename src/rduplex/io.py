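"""Reading, writing and the central dataset container.

Chimeric duplexes come in as flat TSV tables (one row per chimeric read,
two aligned arms), transcript sequences as FASTA, and reference structures
as dot-bracket or CT.  All coordinates are 1-based inclusive throughout the
package; BED exports convert to 0-based half-open at the boundary.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "Interval",
    "SampleMeta",
    "Duplex",
    "DuplexDataSet",
    "ReferenceStructure",
    "DuplexSchemaError",
    "DuplexParseError",
    "read_sample_table",
    "read_duplex_file",
    "write_duplex_file",
    "load_dataset",
    "normalize_orientation",
    "read_reference_structure",
    "pairs_to_dotbracket",
    "dotbracket_to_pairs",
]

SAMPLE_TABLE_COLUMNS = ("file", "group", "sample", "sampleName")
DUPLEX_COLUMNS = ("read_id", "tx_L", "L_start", "L_end", "tx_R", "R_start", "R_end")


class DuplexSchemaError(ValueError):
    """A table is missing required columns."""


class DuplexParseError(ValueError):
    """A row of an input table violates the format contract."""


@dataclass(frozen=True, order=True)
class Interval:
    """Closed interval [start, end], 1-based."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"coordinates are 1-based; got start {self.start}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def overlap_len(self, other: "Interval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def positions(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class SampleMeta:
    file: str
    group: str
    sample: int
    sampleName: str

    def __post_init__(self) -> None:
        if self.sample < 1:
            raise ValueError(f"replicate index must be >= 1, got {self.sample}")


@dataclass(frozen=True)
class Duplex:
    """One chimeric read: left arm L and right arm R on one or two transcripts."""

    read_id: str
    tx_L: str
    L: Interval
    tx_R: str
    R: Interval
    sampleName: str = ""
    extras: tuple[str, ...] = ()

    @property
    def intra(self) -> bool:
        return self.tx_L == self.tx_R

    def reverse(self) -> "Duplex":
        """View with arm roles exchanged (used for inter-RNA reporting)."""
        return replace(self, tx_L=self.tx_R, L=self.R, tx_R=self.tx_L, R=self.L)


@dataclass(frozen=True)
class ReferenceStructure:
    """A known set of base pairs for one transcript, e.g. from crystallography."""

    tx_id: str
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j):
                raise ValueError(f"pair ({i},{j}) must satisfy 1 <= i < j")
            if i in seen or j in seen:
                raise ValueError(f"position in pair ({i},{j}) already paired")
            seen.add(i)
            seen.add(j)

    def pairs_in_region(self, start: int, end: int) -> frozenset[tuple[int, int]]:
        return frozenset((i, j) for i, j in self.pairs if start <= i and j <= end)


@dataclass
class DuplexDataSet:
    """Central container mirroring the analysis stages.

    Every slot past ``inputFiles`` starts empty and is filled in place by the
    pipeline stages (clustering, domain calling, folding).  All per-sample
    slots are keyed by ``sampleName``.
    """

    rna_id: str
    samples: list[SampleMeta]
    sequences: dict[str, str]
    inputFiles: dict[str, list[Duplex]]
    matrixList: dict[str, dict[str, object]] = field(default_factory=dict)
    clusterTableList: dict[str, dict[str, list]] = field(default_factory=dict)
    clusterCoords: list = field(default_factory=list)
    viennaStructures: dict[str, list] = field(default_factory=dict)
    dgs: dict[str, list[float]] = field(default_factory=dict)
    interactionTable: object = None
    clusterTableFolded: dict[str, dict[str, object]] = field(default_factory=dict)
    ensembleLog: dict[str, list] = field(default_factory=dict)
    ensembleRegion: tuple[int, int] | None = None

    @property
    def rna_length(self) -> int:
        return len(self.sequences[self.rna_id])

    @property
    def sample_names(self) -> list[str]:
        return [s.sampleName for s in self.samples]

    def intra_duplexes(self, sampleName: str) -> list[Duplex]:
        """Orientation-normalized duplexes with both arms on the RNA of interest."""
        return [
            d
            for d in self.inputFiles[sampleName]
            if d.tx_L == self.rna_id and d.tx_R == self.rna_id
        ]

    def validate(self) -> None:
        names = set(self.sample_names)
        for slot in (
            self.inputFiles,
            self.matrixList,
            self.clusterTableList,
            self.viennaStructures,
            self.dgs,
            self.clusterTableFolded,
        ):
            for key in slot:
                if key not in names:
                    raise ValueError(f"slot keyed by unknown sampleName {key!r}")
        for s, structs in self.viennaStructures.items():
            if s in self.dgs and len(structs) != len(self.dgs[s]):
                raise ValueError(f"viennaStructures/dgs length mismatch for {s!r}")


# ---------------------------------------------------------------------------
# sample table


def read_sample_table(path: str | Path) -> list[SampleMeta]:
    """Read the tab-separated sample metadata table.

    Required columns: file, group, sample, sampleName.  Row order is kept.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in header]
        if missing:
            raise DuplexSchemaError(
                f"sample table {path} is missing required column(s): {', '.join(missing)}"
            )
        metas = []
        for row in reader:
            try:
                rep = int(row["sample"])
            except ValueError as exc:
                raise DuplexParseError(
                    f"sample table {path}: non-integer replicate index {row['sample']!r}"
                ) from exc
            metas.append(
                SampleMeta(
                    file=row["file"],
                    group=row["group"],
                    sample=rep,
                    sampleName=row["sampleName"],
                )
            )
    names = [m.sampleName for m in metas]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise DuplexParseError(f"duplicate sampleName value(s): {', '.join(dupes)}")
    return metas


def write_sample_table(metas: Sequence[SampleMeta], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SAMPLE_TABLE_COLUMNS)
        for m in metas:
            w.writerow([m.file, m.group, m.sample, m.sampleName])


# ---------------------------------------------------------------------------
# duplex tables


def _looks_like_header(fields: list[str]) -> bool:
    # header is optional; a data row always has an integer third field (L_start)
    if len(fields) < 7:
        return False
    try:
        int(fields[2])
        return False
    except ValueError:
        return True


def read_duplex_file(
    path: str | Path, sampleName: str = ""
) -> tuple[list[Duplex], list[str]]:
    """Read a chimeric-duplex TSV.

    Columns: read_id, tx_L, L_start, L_end, tx_R, R_start, R_end; a header row
    is optional and auto-detected.  Extra trailing columns are preserved on the
    records and returned as the second element (their header names, or empty
    strings for headerless files).

    Returns (duplexes, extra_column_names).
    """
    path = Path(path)
    duplexes: list[Duplex] = []
    extra_names: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, fields in enumerate(reader, start=1):
            if not fields or (len(fields) == 1 and not fields[0].strip()):
                continue
            if lineno == 1 and _looks_like_header(fields):
                extra_names = list(fields[7:])
                continue
            if len(fields) < 7:
                raise DuplexParseError(
                    f"{path}:{lineno}: expected >= 7 tab-separated fields, got {len(fields)}"
                )
            read_id, tx_l, tx_r = fields[0], fields[1], fields[4]
            try:
                l_start, l_end = int(fields[2]), int(fields[3])
                r_start, r_end = int(fields[5]), int(fields[6])
            except ValueError as exc:
                raise DuplexParseError(
                    f"{path}:{lineno}: non-integer coordinate in {fields[2:4] + fields[5:7]}"
                ) from exc
            for arm, (s, e) in (("L", (l_start, l_end)), ("R", (r_start, r_end))):
                if s > e:
                    raise DuplexParseError(
                        f"{path}:{lineno}: {arm} arm start {s} > end {e} (read {read_id})"
                    )
                if s < 1:
                    raise DuplexParseError(
                        f"{path}:{lineno}: {arm} arm start {s} < 1 (coordinates are 1-based)"
                    )
            duplexes.append(
                Duplex(
                    read_id=read_id,
                    tx_L=tx_l,
                    L=Interval(l_start, l_end),
                    tx_R=tx_r,
                    R=Interval(r_start, r_end),
                    sampleName=sampleName,
                    extras=tuple(fields[7:]),
                )
            )
    return duplexes, extra_names


def write_duplex_file(
    duplexes: Iterable[Duplex],
    path: str | Path,
    extra_names: Sequence[str] = (),
    header: bool = True,
) -> None:
    """Write duplexes in the TSV dialect accepted by :func:`read_duplex_file`."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if header:
            w.writerow(list(DUPLEX_COLUMNS) + list(extra_names))
        for d in duplexes:
            w.writerow(
                [d.read_id, d.tx_L, d.L.start, d.L.end, d.tx_R, d.R.start, d.R.end]
                + list(d.extras)
            )


def normalize_orientation(d: Duplex, rna_id: str) -> Duplex:
    """Swap arms of intra-RNA duplexes of ``rna_id`` so that L starts 5' of R.

    Inter-RNA duplexes are returned unchanged (they keep the reported arm
    order; use :meth:`Duplex.reverse` for the exchanged view).  Idempotent.
    """
    if d.tx_L == rna_id and d.tx_R == rna_id and d.R.start < d.L.start:
        return replace(d, L=d.R, R=d.L)
    return d


# ---------------------------------------------------------------------------
# dataset assembly


def load_dataset(
    sample_table_path: str | Path, rna_id: str, fasta_path: str | Path
) -> DuplexDataSet:
    """Load sample metadata, duplex tables and sequences into a dataset.

    Duplexes with both arms on ``rna_id`` are orientation-normalized
    (L.start <= R.start); all downstream slots start empty.
    """
    sample_table_path = Path(sample_table_path)
    samples = read_sample_table(sample_table_path)
    sequences = {
        rec.id: str(rec.seq).upper().replace("T", "U")
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    if rna_id not in sequences:
        raise KeyError(
            f"RNA id {rna_id!r} not found in {fasta_path}; "
            f"available: {', '.join(sorted(sequences))}"
        )
    inputFiles: dict[str, list[Duplex]] = {}
    for meta in samples:
        fpath = Path(meta.file)
        if not fpath.is_absolute():
            fpath = sample_table_path.parent / fpath
        duplexes, _ = read_duplex_file(fpath, sampleName=meta.sampleName)
        inputFiles[meta.sampleName] = [normalize_orientation(d, rna_id) for d in duplexes]
    ds = DuplexDataSet(
        rna_id=rna_id, samples=samples, sequences=sequences, inputFiles=inputFiles
    )
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# secondary-structure text formats

_OPEN = "("
_CLOSE = ")"


def dotbracket_to_pairs(db: str, offset: int = 0) -> frozenset[tuple[int, int]]:
    """Stack-match a dot-bracket string into 1-based (i, j) pairs.

    ``offset`` shifts positions (pass region.start - 1 to get transcript
    coordinates for a regional structure).
    """
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(db, start=1):
        if ch == _OPEN:
            stack.append(pos)
        elif ch == _CLOSE:
            if not stack:
                raise DuplexParseError(
                    f"unbalanced bracket: unmatched ')' at position {pos}"
                )
            i = stack.pop()
            pairs.add((i + offset, pos + offset))
        elif ch != ".":
            raise DuplexParseError(f"illegal character {ch!r} at position {pos}")
    if stack:
        raise DuplexParseError(
            f"unbalanced bracket: unmatched '(' at position {stack[-1]}"
        )
    return frozenset(pairs)


def pairs_to_dotbracket(pairs: Iterable[tuple[int, int]], length: int, offset: int = 0) -> str:
    chars = ["."] * length
    for i, j in pairs:
        i, j = i - offset, j - offset
        if not (1 <= i < j <= length):
            raise ValueError(f"pair ({i},{j}) outside structure of length {length}")
        chars[i - 1] = _OPEN
        chars[j - 1] = _CLOSE
    return "".join(chars)


def read_reference_structure(
    path: str | Path, fmt: str = "dotbracket", tx_id: str = ""
) -> ReferenceStructure:
    """Read a reference structure from dot-bracket or CT text.

    Dot-bracket files may carry a FASTA-style ``>name`` line and a sequence
    line before the structure; CT follows the standard 6-column layout.
    """
    path = Path(path)
    if fmt == "dotbracket":
        name = tx_id
        db = None
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = name or line[1:].split()[0]
                continue
            token = line.split()[0]
            if set(token) <= set(".()"):
                db = token
        if db is None:
            raise DuplexParseError(f"{path}: no dot-bracket line found")
        return ReferenceStructure(tx_id=name, pairs=dotbracket_to_pairs(db))
    if fmt == "ct":
        pairs: set[tuple[int, int]] = set()
        name = tx_id
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) > 1:
                name = name or header[1]
            for lineno, line in enumerate(fh, start=2):
                fields = line.split()
                if len(fields) < 6:
                    continue
                i, j = int(fields[0]), int(fields[4])
                if j > 0:
                    pairs.add((min(i, j), max(i, j)))
        return ReferenceStructure(tx_id=name, pairs=frozenset(pairs))
    raise ValueError(f"unknown reference-structure format {fmt!r}")


# ---------------------------------------------------------------------------
# dataset directory (CLI persistence)


def save_dataset_dir(ds: DuplexDataSet, out_dir: str | Path) -> None:
    """Persist the loaded (normalized) dataset as plain-text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metas = []
    for meta in ds.samples:
        fname = f"{meta.sampleName}.duplexes.tsv"
        write_duplex_file(ds.inputFiles[meta.sampleName], out / fname)
        metas.append(replace(meta, file=fname))
    write_sample_table(metas, out / "samples.tsv")
    with open(out / "sequences.fa", "w") as fh:
        for tx, seq in ds.sequences.items():
            fh.write(f">{tx}\n{seq}\n")
    (out / "meta.json").write_text(json.dumps({"rna_id": ds.rna_id}) + "\n")


def load_dataset_dir(dataset_dir: str | Path) -> DuplexDataSet:
    dataset_dir = Path(dataset_dir)
    meta = json.loads((dataset_dir / "meta.json").read_text())
    return load_dataset(
        dataset_dir / "samples.tsv", meta["rna_id"], dataset_dir / "sequences.fa"
    )
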