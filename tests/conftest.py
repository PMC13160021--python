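import numpy as np
import pytest

from taxalign import fm_index as fm
from taxalign import simulate as sim
from taxalign.reference_db import ReferenceChunk, ReferenceSequence, TaxonomyMap


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def naive_locate(members: list[tuple[str, str]], pattern: str) -> list[tuple[str, int]]:
    """Sliding-window substring search over (accession, sequence) members."""
    hits = []
    for accession, seq in members:
        start = 0
        while True:
            i = seq.find(pattern, start)
            if i < 0:
                break
            hits.append((accession, i))
            start = i + 1
    return sorted(hits)


def make_chunk(seqs: dict[str, str], taxids: dict[str, int] | None = None) -> ReferenceChunk:
    members = [
        ReferenceSequence(acc, (taxids or {}).get(acc, 1000), seq)
        for acc, seq in seqs.items()
    ]
    return ReferenceChunk(0, members)


def simple_taxonomy(species_to_genus: dict[int, int]) -> TaxonomyMap:
    t = TaxonomyMap()
    for sp, ge in species_to_genus.items():
        t.taxid_to_parent[sp] = ge
        t.rank_of[sp] = "species"
        t.rank_of[ge] = "genus"
        t.taxid_to_name[sp] = f"sp{sp}"
        t.taxid_to_name[ge] = f"g{ge}"
    return t


@pytest.fixture(scope="session")
def community():
    """Five annotated 30 kb genomes, their taxonomy, and a built index."""
    genomes = [
        sim.generate_genome(taxid=1001 + i, length=30_000, n_genes=15, seed=500 + i)
        for i in range(5)
    ]
    taxonomy = sim.build_taxonomy(genomes)
    refs = [ReferenceSequence(g.accession, g.taxid, g.sequence) for g in genomes]
    index = fm.build_fm_index(ReferenceChunk(0, refs))
    return genomes, taxonomy, refs, index


@pytest.fixture(scope="session")
def community_reads(community):
    genomes, taxonomy, refs, index = community
    profile = sim.community_profile([g.taxid for g in genomes], seed=7)
    reads, truths = sim.simulate_reads(genomes, profile, 1500, sub_rate=0.005, seed=13)
    return reads, truths, profile
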