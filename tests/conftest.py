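import pytest

from bacpool import kmermask, simulate


@pytest.fixture(scope="session")
def chimera_pool():
    """A 3-clone pool with shared repeat families and one injected chimera
    of each kind, plus truth-derived read membership."""
    truth = simulate.simulate_pool(
        n_bacs=3,
        insert_length_range=(60_000, 70_000),
        depth=8,
        fragmentation=4,
        repeat_config=simulate.default_repeat_library(0),
        defects=simulate.DefectSpec(
            0, 0, 3, ("repeat_only", "nonrep_to_rep", "nonrep_to_nonrep")
        ),
        seed=3,
    )
    membership = simulate.assign_reads_to_contigs(truth, seed=3)
    return {
        "truth": truth,
        "membership": membership,
        "read_bacs": {r.read_id: r.bac_id for r in truth.reads},
        "lengths": {c: len(s) for c, s in truth.contigs.items()},
    }


@pytest.fixture(scope="session")
def pool_kmer_index(chimera_pool):
    return kmermask.build_kmer_index(chimera_pool["truth"].reads, k=20)


@pytest.fixture(scope="session")
def mp_pool():
    """A repeat-free 3-clone pool with a mate-pair library, for placement
    and scaffolding tests."""
    return simulate.simulate_pool(
        n_bacs=3,
        insert_length_range=(60_000, 70_000),
        depth=0.01,
        n_pairs=2500,
        fragmentation=5,
        repeat_config=[],
        seed=2,
    )
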