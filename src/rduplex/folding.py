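"""Constraint derivation and structural-ensemble folding.

Stage one folds every trimmed duplex cluster: short-range clusters as the
contiguous transcript region spanning both arms, long-range clusters as the
two arm sequences joined by an artificial linker that is prohibited from
pairing.  The cross-arm base pairs of each cluster fold become one atomic
hard *constraint* carrying the cluster's read support.

Stage two builds a per-sample structural ensemble: the region of interest is
folded repeatedly (100 times by default); in each iteration eligible
constraints are drawn uniformly at random without replacement, a drawn
constraint is accepted only if its nucleotide footprint is disjoint from all
previously accepted ones, and the region is refolded with every accepted
pair enforced as a hard constraint.  Mutually exclusive constraints — the
signature of alternative in-vivo topologies — thus end up in different
ensemble members.

Two folding engines implement one contract: the thermodynamic ViennaRNA
(RNAfold) backend, and a deterministic Nussinov maximum-pairing stub whose
free energy is minus the pair count (used for testing; the two are never
mixed in one ensemble).
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import DuplexCluster
from .io import DuplexDataSet, Interval, dotbracket_to_pairs, pairs_to_dotbracket

__all__ = [
    "SecondaryStructure",
    "Constraint",
    "FoldingEngineError",
    "ConstraintError",
    "NussinovEngine",
    "ViennaEngine",
    "get_engine",
    "nussinov_fold",
    "fold_with_constraints",
    "fold_cluster",
    "build_constraint_table",
    "ensemble_fold",
]

log = logging.getLogger(__name__)

DEFAULT_N_STRUCTURES = 100  # ensemble size
DEFAULT_MIN_SUPPORT = 10  # reads backing an ensemble-eligible constraint
DEFAULT_SHORT_RANGE_GAP = 10  # nt; above this the linker path is taken
DEFAULT_LINKER = "N" * 10
MIN_LOOP = 3  # minimum hairpin loop length (nt between a pair)

_CANONICAL = {"AU", "UA", "GC", "CG", "GU", "UG"}


class FoldingEngineError(RuntimeError):
    """The folding backend failed or could not satisfy the constraints."""


class ConstraintError(ValueError):
    """A hard constraint violates the folding model (loop, alphabet, nesting)."""


@dataclass(frozen=True)
class SecondaryStructure:
    """A dot-bracket structure for a transcript region, with free energy."""

    region: Interval
    dotbracket: str
    dg: float

    def __post_init__(self) -> None:
        if len(self.dotbracket) != len(self.region):
            raise ValueError(
                f"dot-bracket length {len(self.dotbracket)} != region length {len(self.region)}"
            )

    @property
    def pairs(self) -> frozenset[tuple[int, int]]:
        """Base pairs in 1-based transcript coordinates."""
        return dotbracket_to_pairs(self.dotbracket, offset=self.region.start - 1)


@dataclass(frozen=True)
class Constraint:
    """Atomic set of base pairs derived from folding one cluster."""

    constraint_id: str
    source_cluster_id: str
    pairs: frozenset[tuple[int, int]]
    support: int

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("constraint support must be >= 1")
        for i, j in self.pairs:
            if not i < j:
                raise ValueError(f"pair ({i},{j}) must satisfy i < j")

    @property
    def footprint(self) -> frozenset[int]:
        return frozenset(p for pair in self.pairs for p in pair)

    @property
    def empty(self) -> bool:
        return not self.pairs


# ---------------------------------------------------------------------------
# Nussinov stub engine


@functools.cache
def _dp_kernel():
    # JIT-compiled on first use; pure-numpy fallback would be O(n^3) Python
    from numba import njit

    @njit(cache=False)
    def fill(w):  # pragma: no cover - compiled
        n = w.shape[0]
        dp = np.zeros((n + 1, n + 1), dtype=np.int64)
        for span in range(MIN_LOOP + 1, n):
            for i in range(n - span):
                j = i + span
                best = dp[i + 1, j]
                for k in range(i + MIN_LOOP + 1, j + 1):
                    if w[i, k] > 0:
                        cand = w[i, k] + dp[i + 1, k - 1] + dp[k + 1, j]
                        if cand > best:
                            best = cand
                dp[i, j] = best
        return dp

    return fill


def _validate_hard_pairs(
    n: int,
    hard_pairs: frozenset[tuple[int, int]],
    forbidden: frozenset[int],
) -> None:
    used: set[int] = set()
    for i, j in hard_pairs:
        if not (1 <= i < j <= n):
            raise ConstraintError(f"hard pair ({i},{j}) outside sequence of length {n}")
        if j - i <= MIN_LOOP:
            raise ConstraintError(
                f"hard pair ({i},{j}) violates the minimum hairpin loop of {MIN_LOOP}"
            )
        if i in forbidden or j in forbidden:
            raise ConstraintError(f"hard pair ({i},{j}) touches a forbidden position")
        if i in used or j in used:
            raise ConstraintError(f"hard pairs share nucleotide in ({i},{j})")
        used.update((i, j))
    # nestedness: no two pairs may cross
    sp = sorted(hard_pairs)
    for a in range(len(sp)):
        for b in range(a + 1, len(sp)):
            (i1, j1), (i2, j2) = sp[a], sp[b]
            if i1 < i2 < j1 < j2:
                raise ConstraintError(
                    f"hard pairs ({i1},{j1}) and ({i2},{j2}) cross (pseudoknot)"
                )


def nussinov_fold(
    sequence: str,
    hard_pairs: frozenset[tuple[int, int]] = frozenset(),
    forbidden_positions: frozenset[int] = frozenset(),
) -> SecondaryStructure:
    """Maximum base-pair structure by dynamic programming (test/stub engine).

    Canonical pairs AU/GC/GU, minimum hairpin loop of 3 nt; hard pairs are
    forced (they may be non-canonical), forbidden positions never pair.
    Ties are broken toward pairing the 5'-most base with its 5'-most
    admissible partner.  dg is minus the pair count.
    """
    seq = sequence.upper().replace("T", "U")
    n = len(seq)
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ConstraintError(f"sequence contains non-ACGUN character(s): {sorted(bad)}")
    hard_pairs = frozenset(hard_pairs)
    forbidden = frozenset(forbidden_positions)
    _validate_hard_pairs(n, hard_pairs, forbidden)
    hard_of = {}
    for i, j in hard_pairs:
        hard_of[i] = j
        hard_of[j] = i

    bonus = n + 1  # any structure missing a hard pair scores below any containing all
    w = np.zeros((n, n), dtype=np.int64)
    for i in range(1, n + 1):
        for j in range(i + MIN_LOOP + 1, n + 1):
            if (i, j) in hard_pairs:
                w[i - 1, j - 1] = 1 + bonus
                continue
            if i in forbidden or j in forbidden or i in hard_of or j in hard_of:
                continue
            if seq[i - 1] + seq[j - 1] in _CANONICAL:
                w[i - 1, j - 1] = 1
    dp = _dp_kernel()(w)

    pairs: set[tuple[int, int]] = set()

    def trace(i: int, j: int) -> None:  # 0-based inclusive interval
        while i < j:
            target = dp[i, j]
            if target == 0:
                return
            paired = False
            for k in range(i + MIN_LOOP + 1, j + 1):
                if w[i, k] > 0 and w[i, k] + dp[i + 1, k - 1] + dp[k + 1, j] == target:
                    pairs.add((i + 1, k + 1))
                    trace(i + 1, k - 1)
                    i = k + 1
                    paired = True
                    break
            if not paired:
                i += 1

    trace(0, n - 1)
    assert hard_pairs <= pairs
    db = pairs_to_dotbracket(pairs, n)
    return SecondaryStructure(region=Interval(1, n), dotbracket=db, dg=-float(len(pairs)))


class NussinovEngine:
    """Deterministic maximum-pairing stub engine (dg = minus pair count)."""

    name = "stub"

    def fold(
        self,
        sequence: str,
        hard_pairs: frozenset[tuple[int, int]] = frozenset(),
        forbidden_positions: frozenset[int] = frozenset(),
        reactivities: list[float] | None = None,
    ) -> SecondaryStructure:
        if reactivities is not None:
            log.warning("stub engine ignores reactivities")
        return nussinov_fold(sequence, hard_pairs, forbidden_positions)


class ViennaEngine:
    """Thermodynamic MFE engine backed by the ViennaRNA (RNAfold) bindings.

    Hard pairs are enforced base pairs, forbidden positions are forced
    unpaired, and reactivities enter as Deigan-style pseudo-energy soft
    constraints (slope/intercept in kcal/mol).
    """

    name = "vienna"

    def __init__(self, shape_slope: float = 1.8, shape_intercept: float = -0.6):
        self.shape_slope = shape_slope
        self.shape_intercept = shape_intercept

    def fold(
        self,
        sequence: str,
        hard_pairs: frozenset[tuple[int, int]] = frozenset(),
        forbidden_positions: frozenset[int] = frozenset(),
        reactivities: list[float] | None = None,
    ) -> SecondaryStructure:
        import RNA

        seq = sequence.upper().replace("T", "U")
        n = len(seq)
        _validate_hard_pairs(n, frozenset(hard_pairs), frozenset(forbidden_positions))
        fc = RNA.fold_compound(seq)
        for p in sorted(forbidden_positions):
            fc.hc_add_up(p)
        for i, j in sorted(hard_pairs):
            fc.hc_add_bp(
                i, j, RNA.CONSTRAINT_CONTEXT_ALL_LOOPS | RNA.CONSTRAINT_CONTEXT_ENFORCE
            )
        if reactivities is not None:
            if len(reactivities) != n:
                raise ValueError(
                    f"reactivity profile length {len(reactivities)} != sequence length {n}"
                )
            if any(r < 0 for r in reactivities if r is not None):
                raise ValueError("reactivities must be nonnegative (use None for missing)")
            vals = [-1.0 if r is None else float(r) for r in reactivities]
            fc.sc_add_SHAPE_deigan(vals, self.shape_slope, self.shape_intercept)
        try:
            db, dg = fc.mfe()
        except Exception as exc:  # backend failure
            raise FoldingEngineError(f"ViennaRNA mfe failed: {exc}") from exc
        got = dotbracket_to_pairs(db)
        missing = frozenset(hard_pairs) - got
        if missing:
            raise FoldingEngineError(
                f"backend could not satisfy hard pair(s) {sorted(missing)}"
            )
        return SecondaryStructure(region=Interval(1, n), dotbracket=db, dg=float(dg))


def get_engine(name: str) -> NussinovEngine | ViennaEngine:
    if name == "stub":
        return NussinovEngine()
    if name == "vienna":
        return ViennaEngine()
    raise ValueError(f"unknown folding engine {name!r} (expected 'stub' or 'vienna')")


def fold_with_constraints(
    engine,
    sequence: str,
    hard_pairs: frozenset[tuple[int, int]] = frozenset(),
    reactivities: list[float] | None = None,
    forbidden_positions: frozenset[int] = frozenset(),
) -> SecondaryStructure:
    """Fold a sequence with hard base-pair constraints (and optional reactivities)."""
    s = engine.fold(
        sequence,
        hard_pairs=frozenset(hard_pairs),
        forbidden_positions=frozenset(forbidden_positions),
        reactivities=reactivities,
    )
    assert frozenset(hard_pairs) <= s.pairs
    return s


# ---------------------------------------------------------------------------
# cluster folding -> constraints


def fold_cluster(
    cluster: DuplexCluster,
    sequence: str,
    engine,
    short_range_gap: int = DEFAULT_SHORT_RANGE_GAP,
    linker: str = DEFAULT_LINKER,
) -> Constraint:
    """Fold one trimmed cluster and extract its cross-arm base pairs.

    Short-range clusters (consensus gap <= ``short_range_gap`` nt) fold the
    contiguous region spanning both footprints; long-range clusters fold
    left-arm + linker + right-arm with the linker prohibited from pairing,
    mapping pair indices back to transcript coordinates.  Only pairs joining
    the L footprint to the R footprint are kept; a cluster whose fold has no
    cross-arm pairs yields an empty (flagged) constraint.
    """
    L, R = cluster.L_footprint, cluster.R_footprint
    if R.end > len(sequence):
        raise ValueError(
            f"cluster {cluster.cluster_id} footprint exceeds transcript length {len(sequence)}"
        )
    gap = cluster.gap
    pairs: set[tuple[int, int]] = set()
    if gap <= short_range_gap:
        sub = sequence[L.start - 1 : R.end]
        s = engine.fold(sub)
        off = L.start - 1
        for i, j in s.pairs:
            ti, tj = i + off, j + off
            if L.start <= ti <= L.end and R.start <= tj <= R.end:
                pairs.add((ti, tj))
    else:
        left = sequence[L.start - 1 : L.end]
        right = sequence[R.start - 1 : R.end]
        construct = left + linker + right
        nl, nk = len(left), len(linker)
        forbidden = frozenset(range(nl + 1, nl + nk + 1))
        s = engine.fold(construct, forbidden_positions=forbidden)
        for i, j in s.pairs:
            if i > nl or j <= nl + nk:  # touches linker or not cross-arm
                continue
            ti = L.start - 1 + i
            tj = R.start - 1 + (j - nl - nk)
            pairs.add((ti, tj))
    if not pairs:
        log.warning("cluster %s: fold yields no cross-arm pairs", cluster.cluster_id)
    return Constraint(
        constraint_id=f"ct.{cluster.cluster_id}",
        source_cluster_id=cluster.cluster_id,
        pairs=frozenset(pairs),
        support=cluster.size,
    )


def build_constraint_table(
    ds: DuplexDataSet,
    engine,
    min_support: int = DEFAULT_MIN_SUPPORT,
    short_range_gap: int = DEFAULT_SHORT_RANGE_GAP,
    linker: str = DEFAULT_LINKER,
) -> DuplexDataSet:
    """Fold every trimmed cluster; populate the interaction/constraint table.

    Rows: (sampleName, constraint_id, i, j, support, eligible).  Constraints
    with support < ``min_support`` stay in the table flagged ineligible for
    the ensemble; empty constraints are excluded.  The per-cluster predicted
    pair sets go to the ``clusterTableFolded`` slot.
    """
    seq = ds.sequences[ds.rna_id]
    rows = []
    for s in ds.sample_names:
        tables = ds.clusterTableList.get(s, {})
        if "trimmed" not in tables:
            raise ValueError(f"no trimmed clusters for sample {s!r}; run trim_clusters first")
        folded: dict[str, Constraint] = {}
        for c in tables["trimmed"]:
            ct = fold_cluster(
                c, seq, engine, short_range_gap=short_range_gap, linker=linker
            )
            folded[c.cluster_id] = ct
            for i, j in sorted(ct.pairs):
                rows.append((s, ct.constraint_id, i, j, ct.support, ct.support >= min_support))
        ds.clusterTableFolded[s] = folded
    ds.interactionTable = pd.DataFrame(
        rows, columns=["sampleName", "constraint_id", "i", "j", "support", "eligible"]
    )
    return ds


# ---------------------------------------------------------------------------
# ensemble generation


def _eligible_constraints(
    ds: DuplexDataSet, sampleName: str, region: Interval
) -> list[Constraint]:
    out = []
    for ct in ds.clusterTableFolded.get(sampleName, {}).values():
        if ct.empty:
            continue
        if not all(region.start <= p <= region.end for p in ct.footprint):
            continue
        out.append(ct)
    table = ds.interactionTable
    eligible_ids = set(
        table.loc[
            (table["sampleName"] == sampleName) & table["eligible"], "constraint_id"
        ]
    )
    return sorted(
        (c for c in out if c.constraint_id in eligible_ids),
        key=lambda c: c.constraint_id,
    )


def ensemble_fold(
    ds: DuplexDataSet,
    region: tuple[int, int],
    engine,
    n_structures: int = DEFAULT_N_STRUCTURES,
    max_constraints: int = 5,
    seed: int = 0,
    reactivities: list[float] | None = None,
) -> DuplexDataSet:
    """Generate a per-sample structural ensemble by sequential constraint addition.

    Each of the ``n_structures`` iterations draws eligible constraints
    uniformly at random without replacement; a draw is accepted only if its
    footprint shares no nucleotide with previously accepted constraints
    (conflicting draws are discarded for that iteration only), stopping at
    ``max_constraints`` acceptances or exhaustion.  The region is folded with
    all accepted pairs as hard constraints; structures and free energies are
    appended to the ``viennaStructures``/``dgs`` slots, accepted constraint
    ids per iteration to ``ensembleLog``.  Bit-reproducible for a fixed seed.
    """
    if ds.interactionTable is None:
        raise ValueError("interactionTable empty; run build_constraint_table first")
    reg = Interval(*region)
    if reg.end > ds.rna_length:
        raise ValueError(f"region {region} outside transcript of length {ds.rna_length}")
    sub = ds.sequences[ds.rna_id][reg.start - 1 : reg.end]
    off = reg.start - 1
    for si, s in enumerate(ds.sample_names):
        eligible = _eligible_constraints(ds, s, reg)
        if not eligible:
            log.warning("sample %s: no eligible constraints; unconstrained ensemble", s)
        structures: list[str] = []
        dgs: list[float] = []
        log_rows: list[list[str]] = []
        cache: dict[frozenset[str], SecondaryStructure] = {}
        for it in range(n_structures):
            rng = np.random.default_rng([seed, si, it])
            accepted: list[Constraint] = []
            occupied: set[int] = set()
            for k in rng.permutation(len(eligible)):
                ct = eligible[int(k)]
                if occupied & ct.footprint:
                    continue  # conflicting draw discarded for this iteration
                accepted.append(ct)
                occupied |= ct.footprint
                if len(accepted) >= max_constraints:
                    break
            key = frozenset(c.constraint_id for c in accepted)
            if key not in cache:
                hard = frozenset(
                    (i - off, j - off) for c in accepted for (i, j) in c.pairs
                )
                cache[key] = engine.fold(sub, hard_pairs=hard, reactivities=reactivities)
            st = cache[key]
            structures.append(st.dotbracket)
            dgs.append(st.dg)
            log_rows.append(sorted(c.constraint_id for c in accepted))
        ds.viennaStructures[s] = structures
        ds.dgs[s] = dgs
        ds.ensembleLog[s] = log_rows
    ds.ensembleRegion = (reg.start, reg.end)
    return ds


def write_vienna_file(
    ds: DuplexDataSet, sampleName: str, path, name_prefix: str = "structure"
) -> None:
    """Write a sample's ensemble as a multi-record vienna file."""
    reg = ds.ensembleRegion
    sub = ds.sequences[ds.rna_id][reg[0] - 1 : reg[1]]
    with open(path, "w") as fh:
        for k, (db, dg) in enumerate(zip(ds.viennaStructures[sampleName], ds.dgs[sampleName]), 1):
            fh.write(f">{name_prefix}_{k}\n{sub}\n{db} ({dg:.2f})\n")
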