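"""Synthetic duplex datasets with known ground truth.

Emulates the statistical structure of proximity-ligation chimera data:
crosslinking and random fragmentation of many molecules sharing one in-vivo
structure produce chimeric reads whose arms jitter around the true helix
arms, plus a background of spurious chimeras and, optionally, inter-RNA
chimeras against a second transcript.  Every stage of the pipeline can be
benchmarked against the generating structure and the read -> helix map.

The default specification is the package's reference study condition:
a 600-nt transcript carrying 4 helices (one long-range), 50 reads per helix
per replicate, endpoint jitter of SD 2 nt, ~6% background, 3 replicates,
seed 7.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .io import (
    Duplex,
    Interval,
    ReferenceStructure,
    SampleMeta,
    pairs_to_dotbracket,
    write_duplex_file,
    write_sample_table,
)

__all__ = [
    "SimulationSpec",
    "Helix",
    "make_transcript",
    "make_true_structure",
    "simulate_duplex_dataset",
    "DEFAULT_SPEC",
]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class SimulationSpec:
    tx_len: int = 600
    n_helices: int = 4
    helix_len_range: tuple[int, int] = (6, 12)
    long_range_fraction: float = 0.25
    reads_per_helix: int = 50
    frag_noise_sd: float = 2.0
    background_fraction: float = 0.0625
    n_replicates: int = 3
    seed: int = 7
    inter_rna_reads: int = 0  # optional chimeras against a partner transcript
    partner_len: int = 300
    rna_id: str = "RNA1|synthetic|rRNA"
    partner_id: str = "TXB|synthetic|mRNA"
    gu_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.tx_len < 50:
            raise ValueError(f"tx_len must be >= 50, got {self.tx_len}")
        for name in ("long_range_fraction", "background_fraction", "gu_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_helices", "reads_per_helix", "n_replicates", "inter_rna_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationSpec":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "helix_len_range" in data:
            data["helix_len_range"] = tuple(data["helix_len_range"])
        return cls(**data)


DEFAULT_SPEC = SimulationSpec()


@dataclass(frozen=True)
class Helix:
    helix_id: str
    L: Interval  # left arm
    R: Interval  # right arm

    @property
    def length(self) -> int:
        return len(self.L)

    @property
    def gap(self) -> int:
        return self.R.start - self.L.end - 1

    @property
    def pairs(self) -> frozenset[tuple[int, int]]:
        # ladder: L.start pairs with R.end, etc.
        return frozenset(
            (self.L.start + k, self.R.end - k) for k in range(self.length)
        )


def _place_helices(spec: SimulationSpec, rng: np.random.Generator) -> list[Helix]:
    """Lay out non-crossing helices, one per equal transcript segment.

    Long-range helices put their arms at the segment ends (gap > 100 nt);
    short-range helices sit at a jittered offset with a small loop.
    """
    seg = spec.tx_len // spec.n_helices
    n_long = round(spec.long_range_fraction * spec.n_helices)
    helices = []
    for h in range(spec.n_helices):
        s0 = h * seg + 1
        s1 = (h + 1) * seg
        hlen = int(rng.integers(spec.helix_len_range[0], spec.helix_len_range[1] + 1))
        long_range = h < n_long
        if long_range:
            l = Interval(s0, s0 + hlen - 1)
            r = Interval(s1 - hlen + 1, s1)
            if r.start - l.end - 1 <= 100:
                raise ValueError(
                    f"cannot place long-range helix with gap > 100 nt in a "
                    f"{seg}-nt segment (helix length {hlen})"
                )
        else:
            loop = int(rng.integers(3, 21))
            room = seg - (2 * hlen + loop)
            if room < 1:
                raise ValueError(
                    f"cannot place helix of length {hlen} with loop {loop} in a "
                    f"{seg}-nt segment"
                )
            off = int(rng.integers(0, room))
            l = Interval(s0 + off, s0 + off + hlen - 1)
            r = Interval(l.end + loop + 1, l.end + loop + hlen)
        helices.append(Helix(helix_id=f"h{h + 1}", L=l, R=r))
    return helices


def make_true_structure(
    spec: SimulationSpec = DEFAULT_SPEC,
) -> tuple[ReferenceStructure, list[Helix]]:
    """Non-crossing helix layout and its reference base-pair set (seeded)."""
    rng = np.random.default_rng([spec.seed, 0])
    helices = _place_helices(spec, rng)
    pairs = frozenset(p for h in helices for p in h.pairs)
    return ReferenceStructure(tx_id=spec.rna_id, pairs=pairs), helices


def make_transcript(spec: SimulationSpec = DEFAULT_SPEC) -> str:
    """Random ACGU sequence with helix arms rewritten reverse-complementary.

    GU wobbles are introduced at rate ``gu_rate`` where the drawn base
    allows one.  Deterministic for a fixed spec.
    """
    _, helices = make_true_structure(spec)
    rng = np.random.default_rng([spec.seed, 1])
    bases = np.array(list("ACGU"))
    seq = list(rng.choice(bases, size=spec.tx_len))
    for h in helices:
        for i, j in h.pairs:
            b = str(rng.choice(bases))
            partner = _COMPLEMENT[b]
            if b in "GU" and rng.random() < spec.gu_rate:
                partner = "U" if b == "G" else "G"
            seq[i - 1] = b
            seq[j - 1] = partner
    return "".join(seq)


def _jitter_interval(
    iv: Interval, sd: float, tx_len: int, rng: np.random.Generator
) -> Interval:
    start = iv.start + int(round(rng.normal(0, sd)))
    end = iv.end + int(round(rng.normal(0, sd)))
    start = min(max(1, start), tx_len)
    end = min(max(1, end), tx_len)
    if start > end:
        start, end = end, start
    return Interval(start, end)


def _n_background(spec: SimulationSpec) -> int:
    signal = spec.n_helices * spec.reads_per_helix
    if spec.background_fraction >= 1:
        raise ValueError("background_fraction must be < 1")
    total = signal / (1 - spec.background_fraction)
    return int(round(spec.background_fraction * total))


def simulate_replicate(
    spec: SimulationSpec, helices: list[Helix], replicate: int, sampleName: str
) -> tuple[list[Duplex], dict[str, str]]:
    """Duplex reads for one replicate plus the read -> helix truth map."""
    rng = np.random.default_rng([spec.seed, 2, replicate])
    duplexes: list[Duplex] = []
    truth: dict[str, str] = {}
    k = 0
    for h in helices:
        for _ in range(spec.reads_per_helix):
            k += 1
            rid = f"{sampleName}.r{k:05d}"
            L = _jitter_interval(h.L, spec.frag_noise_sd, spec.tx_len, rng)
            R = _jitter_interval(h.R, spec.frag_noise_sd, spec.tx_len, rng)
            if R.start < L.start:
                L, R = R, L
            duplexes.append(
                Duplex(rid, spec.rna_id, L, spec.rna_id, R, sampleName=sampleName)
            )
            truth[rid] = h.helix_id
    for _ in range(_n_background(spec)):
        k += 1
        rid = f"{sampleName}.r{k:05d}"
        arms = []
        for _ in range(2):
            alen = int(rng.integers(10, 31))
            start = int(rng.integers(1, spec.tx_len - alen + 2))
            arms.append(Interval(start, start + alen - 1))
        arms.sort(key=lambda iv: (iv.start, iv.end))
        duplexes.append(
            Duplex(rid, spec.rna_id, arms[0], spec.rna_id, arms[1], sampleName=sampleName)
        )
        truth[rid] = "background"
    for _ in range(spec.inter_rna_reads):
        k += 1
        rid = f"{sampleName}.r{k:05d}"
        # partner arm confined to a fixed central window of the partner
        alen = int(rng.integers(10, 31))
        start = int(rng.integers(1, spec.tx_len - alen + 2))
        p0 = spec.partner_len // 3
        pstart = int(rng.integers(p0, p0 + 51))
        duplexes.append(
            Duplex(
                rid,
                spec.rna_id,
                Interval(start, start + alen - 1),
                spec.partner_id,
                Interval(pstart, pstart + alen - 1),
                sampleName=sampleName,
            )
        )
        truth[rid] = "inter"
    return duplexes, truth


def simulate_duplex_dataset(
    spec: SimulationSpec = DEFAULT_SPEC, out_dir: str | Path = "fixtures"
) -> Path:
    """Write a complete synthetic dataset: sample table, duplex TSVs, FASTA,
    truth dot-bracket and read -> helix truth tables.  Byte-identical output
    for a fixed spec."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref, helices = make_true_structure(spec)
    seq = make_transcript(spec)
    rng_partner = np.random.default_rng([spec.seed, 3])
    partner_seq = "".join(rng_partner.choice(list("ACGU"), size=spec.partner_len))
    metas = []
    for rep in range(1, spec.n_replicates + 1):
        sname = f"s{rep}"
        duplexes, truth = simulate_replicate(spec, helices, rep, sname)
        fname = f"{sname}.duplexes.tsv"
        write_duplex_file(duplexes, out / fname)
        with open(out / f"{sname}.truth.tsv", "w") as fh:
            fh.write("read_id\thelix_id\n")
            for rid in sorted(truth):
                fh.write(f"{rid}\t{truth[rid]}\n")
        metas.append(SampleMeta(file=fname, group="wt", sample=rep, sampleName=sname))
    write_sample_table(metas, out / "samples.tsv")
    with open(out / "sequences.fa", "w") as fh:
        fh.write(f">{spec.rna_id}\n{seq}\n")
        if spec.inter_rna_reads:
            fh.write(f">{spec.partner_id}\n{partner_seq}\n")
    db = pairs_to_dotbracket(ref.pairs, spec.tx_len)
    (out / "truth_structure.db").write_text(f">{spec.rna_id}\n{seq}\n{db}\n")
    with open(out / "truth_helices.tsv", "w") as fh:
        fh.write("helix_id\tL_start\tL_end\tR_start\tR_end\n")
        for h in helices:
            fh.write(f"{h.helix_id}\t{h.L.start}\t{h.L.end}\t{h.R.start}\t{h.R.end}\n")
    with open(out / "spec.yaml", "w") as fh:
        yaml.safe_dump(
            {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(spec).items()
            },
            fh,
            sort_keys=True,
        )
    return out
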