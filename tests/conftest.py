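import numpy as np
import pytest

from oxytrait.dataio import Alphabet, Dataset, GenomeRecord, SequenceRecord, Taxonomy
from oxytrait.synthgen import SynthConfig, generate_dataset

TERNARY = ("Aerobe", "Anaerobe", "Facultative")


def make_genome(
    genome_id: str,
    proteins: list[str],
    cds: list[str] | None = None,
    genomic: list[str] | None = None,
    taxonomy: dict | None = None,
    label: str | None = None,
    completeness: float | None = None,
) -> GenomeRecord:
    """Hand-rolled genome for unit tests."""
    prot_recs = [
        SequenceRecord(f"{genome_id}_p{i}", p, Alphabet.PROTEIN)
        for i, p in enumerate(proteins)
    ]
    cds = cds if cds is not None else ["ATG" * len(p) for p in proteins]
    cds_recs = [
        SequenceRecord(f"{genome_id}_c{i}", c, Alphabet.DNA) for i, c in enumerate(cds)
    ]
    genomic = genomic if genomic is not None else ["".join(cds)]
    gen_recs = [
        SequenceRecord(f"{genome_id}_g{i}", g, Alphabet.DNA)
        for i, g in enumerate(genomic)
    ]
    return GenomeRecord(
        genome_id=genome_id,
        genomic=gen_recs,
        cds_nt=cds_recs,
        proteins=prot_recs,
        taxonomy=Taxonomy(taxonomy or {}),
        raw_label=label,
        label=label,
        completeness=completeness,
    )


@pytest.fixture(scope="session")
def planted_dataset() -> Dataset:
    """300 genomes with a strong class-composition signal (no clade signal)."""
    config = SynthConfig(
        taxonomy_shape={
            "phylum": 3, "class": 2, "order": 1,
            "family": 5, "genus": 1, "species": 2,
        },
        genomes_per_species=5,
        composition_effect=0.08,
        phenotype_conservation_rank="family",
        genes_per_genome=200,
        mean_gene_length=250,
        seed=7,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def clade_dataset() -> Dataset:
    """Labels and composition both inherited at the family rank only."""
    config = SynthConfig(
        taxonomy_shape={
            "phylum": 2, "class": 2, "order": 1,
            "family": 4, "genus": 2, "species": 2,
        },
        genomes_per_species=2,
        composition_effect=0.0,
        clade_effect=0.12,
        clade_effect_rank="family",
        phenotype_conservation_rank="family",
        phenotype_flip_prob=0.0,
        genes_per_genome=40,
        mean_gene_length=120,
        seed=11,
    )
    return generate_dataset(config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
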