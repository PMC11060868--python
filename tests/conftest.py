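import numpy as np
import pytest

from rduplex import io
from rduplex.synthetic import DEFAULT_SPEC, SimulationSpec, simulate_duplex_dataset


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The reference synthetic dataset: 600-nt transcript, 4 helices
    (one long-range), 50 reads/helix, jitter SD 2 nt, ~6% background,
    3 replicates, seed 7."""
    out = tmp_path_factory.mktemp("fixture") / "sim"
    simulate_duplex_dataset(DEFAULT_SPEC, out)
    return out


@pytest.fixture(scope="session")
def dataset(fixture_dir):
    return io.load_dataset(
        fixture_dir / "samples.tsv", DEFAULT_SPEC.rna_id, fixture_dir / "sequences.fa"
    )


@pytest.fixture(scope="session")
def truth(fixture_dir):
    """read_id -> helix_id maps per sample, and the helix arm table."""
    import csv

    maps = {}
    for s in ("s1", "s2", "s3"):
        with open(fixture_dir / f"{s}.truth.tsv") as fh:
            maps[s] = {r["read_id"]: r["helix_id"] for r in csv.DictReader(fh, delimiter="\t")}
    helices = []
    with open(fixture_dir / "truth_helices.tsv") as fh:
        for r in csv.DictReader(fh, delimiter="\t"):
            helices.append(
                {
                    "helix_id": r["helix_id"],
                    "L": (int(r["L_start"]), int(r["L_end"])),
                    "R": (int(r["R_start"]), int(r["R_end"])),
                }
            )
    return maps, helices


@pytest.fixture(scope="session")
def clustered_dataset(dataset):
    """The fixture dataset taken through clustering + trimming once."""
    from rduplex.clustering import cluster_duplexes, trim_clusters

    cluster_duplexes(dataset, min_cluster_size=5)
    trim_clusters(dataset)
    return dataset


def random_duplexes(n, tx_len, rng, sampleName="s1", tx="RNA1|synthetic|rRNA"):
    """Random orientation-normalized intra-RNA duplexes (shared helper)."""
    out = []
    for k in range(n):
        alen1 = int(rng.integers(5, 20))
        alen2 = int(rng.integers(5, 20))
        s1 = int(rng.integers(1, tx_len - alen1 - alen2 - 10))
        s2 = int(rng.integers(s1, tx_len - alen2 + 1))
        a = io.Interval(s1, min(s1 + alen1 - 1, tx_len))
        b = io.Interval(s2, min(s2 + alen2 - 1, tx_len))
        if b.start < a.start:
            a, b = b, a
        out.append(io.Duplex(f"r{k:04d}", tx, a, tx, b, sampleName=sampleName))
    return out
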