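import numpy as np
import pytest

from genelossclock.pangenome import StrainGenome, build_pangenome, classify_pangenes
from genelossclock.simulate import SimConfig, simulate


def small_config(seed: int = 11, **overrides) -> SimConfig:
    """A quick-to-simulate species: 10 strains, ~90 ancestral genes."""
    cfg = SimConfig(
        n_strains=10,
        n_genes_per_class={"constrained": 45, "relaxed": 27, "volatile": 18},
        hgt_rate=40.0,
        gene_length_range=(120, 400),
        seed=seed,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


@pytest.fixture(scope="session")
def small_sim():
    return simulate(small_config())


@pytest.fixture(scope="session")
def small_pangenome(small_sim):
    genomes, _, _ = small_sim
    pg = build_pangenome(genomes, seed=0)
    return classify_pangenes(pg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_cds(rng, n_codons: int) -> str:
    """Random stop-free CDS for ad-hoc genomes."""
    from genelossclock.simulate import _sample_gene
    from genelossclock.codon import decode_codons

    return decode_codons(_sample_gene(rng, n_codons, 0.0))


def toy_genome(strain_id: str, seqs: dict[str, str]) -> StrainGenome:
    return StrainGenome(strain_id=strain_id, genes=sorted(seqs.items()), species_id="toy")
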