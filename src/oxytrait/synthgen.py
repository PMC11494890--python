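"""Synthetic labeled genome datasets with controllable signal structure.

The generator plants the two signals a real oxygen-phenotype dataset
carries, each behind its own dial:

* a *compositional* signal (``composition_effect``): class-dependent
  amino-acid usage, modeled on the observation that aerobic proteomes
  deplete redox-active sulfur residues (cysteine, methionine) relative to
  anaerobic ones. Anaerobes are enriched, aerobes depleted, facultative
  organisms sit in between.
* a *phylogenetic* signal: phenotypes are inherited within clades at a
  conservation rank (``phenotype_flip_prob`` controls label noise), and
  clades can carry their own composition offsets (``clade_effect``) so
  that sequence features encode clade identity even with no direct
  class-composition link.

Proteins are i.i.d. draws from the resulting per-genome amino-acid
distribution; CDS are reverse-translated with synonymous codons biased
toward a class-specific GC target, and the genomic sequence is the
shuffled CDS concatenation with random intergenic spacers. Depth-profile
fixtures plant an exact (optionally noisy) log-linear relation between
the chemical ratio [O2]/[H2S] and the community aerobe/anaerobe ratio.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .dataio import (
    RANKS,
    Alphabet,
    Dataset,
    GenomeRecord,
    SequenceRecord,
    Taxonomy,
    ternary_to_binary,
    write_fasta,
)
from .features import AA_ALPHABET

__all__ = [
    "SynthConfig",
    "generate_taxonomy",
    "assign_phenotypes",
    "generate_genome",
    "generate_dataset",
    "generate_depth_fixture",
    "write_dataset_fasta",
]

CLASSES = ("Aerobe", "Anaerobe", "Facultative")

# Standard codon table (no stop codons: CDS are emitted without them).
CODON_TABLE: Mapping[str, tuple[str, ...]] = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}

# Class-dependent shift direction in AA-frequency space: redox-active
# sulfur residues carry the signal; the remaining residues absorb the
# compensating probability mass so the vector sums to zero.
_SHIFT = np.zeros(20)
_SHIFT[AA_ALPHABET.index("C")] = 0.5
_SHIFT[AA_ALPHABET.index("M")] = 0.5
_others = np.array([i for i in range(20) if _SHIFT[i] == 0])
_SHIFT[_others] = -1.0 / len(_others)

_CLASS_SIGN = {"Aerobe": -1.0, "Facultative": 0.0, "Anaerobe": +1.0}


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the generator.

    ``taxonomy_shape`` gives the number of children per node at each rank
    below domain; the number of genomes is the product of the shape
    values times ``genomes_per_species``.
    """

    taxonomy_shape: Mapping[str, int] = field(
        default_factory=lambda: {
            "phylum": 2, "class": 2, "order": 1,
            "family": 2, "genus": 1, "species": 2,
        }
    )
    genomes_per_species: int = 2
    phenotype_conservation_rank: str | None = "family"
    phenotype_flip_prob: float = 0.0
    class_priors: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    composition_effect: float = 0.05
    clade_effect: float = 0.0
    clade_effect_rank: str = "family"
    genes_per_genome: int = 50
    mean_gene_length: int = 150
    gc_target: Mapping[str, float] = field(
        default_factory=lambda: {"Aerobe": 0.60, "Anaerobe": 0.40, "Facultative": 0.50}
    )
    intergenic_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_priors) - 1.0) > 1e-9:
            raise ValueError("class_priors must sum to 1")
        if self.composition_effect < 0 or self.clade_effect < 0:
            raise ValueError("effect sizes must be non-negative")
        unknown = set(self.taxonomy_shape) - set(RANKS[1:])
        if unknown:
            raise ValueError(f"taxonomy_shape has unknown ranks: {sorted(unknown)}")
        for r in RANKS[1:]:
            if self.taxonomy_shape.get(r, 1) < 1:
                raise ValueError(f"taxonomy_shape[{r!r}] must be >= 1")


def generate_taxonomy(config: SynthConfig) -> pd.DataFrame:
    """Balanced nested taxonomy table: one row per genome, columns
    genome_id plus the seven ranks."""
    shape = [config.taxonomy_shape.get(r, 1) for r in RANKS[1:]]
    rows = []
    counters = [0] * 6

    def recurse(level: int, path: list[str]) -> None:
        if level == 6:
            for _ in range(config.genomes_per_species):
                gid = f"G{len(rows):05d}"
                rows.append([gid, "Bacteria", *path])
            return
        rank_letter = RANKS[1 + level][0].upper()
        for _ in range(shape[level]):
            counters[level] += 1
            name = f"{rank_letter}{counters[level]:03d}"
            recurse(level + 1, path + [name])

    recurse(0, [])
    return pd.DataFrame(rows, columns=["genome_id", *RANKS])


def assign_phenotypes(taxonomy: pd.DataFrame, config: SynthConfig) -> pd.Series:
    """Draw one ternary label per conservation-rank taxon from the class
    priors, inherit it within the taxon, then independently flip each
    genome's label to a uniformly random *other* class with
    ``phenotype_flip_prob``. A conservation rank of None assigns labels
    i.i.d. per genome (a purely compositional, taxonomy-free signal)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    priors = np.asarray(config.class_priors)
    rank = config.phenotype_conservation_rank
    if rank is None:
        labels = rng.choice(CLASSES, size=len(taxonomy), p=priors)
    else:
        if rank not in taxonomy.columns:
            raise ValueError(f"conservation rank {rank!r} not in taxonomy")
        taxa = sorted(taxonomy[rank].unique())
        taxon_label = {t: rng.choice(CLASSES, p=priors) for t in taxa}
        labels = np.array([taxon_label[t] for t in taxonomy[rank]], dtype=object)
    flip = rng.random(len(labels)) < config.phenotype_flip_prob
    labels = np.asarray(labels, dtype=object)
    for i in np.nonzero(flip)[0]:
        labels[i] = rng.choice([c for c in CLASSES if c != labels[i]])
    labels = [str(c) for c in labels]
    return pd.Series(labels, index=taxonomy["genome_id"].values, name="label")


def _clade_offset(clade: str, config: SynthConfig) -> np.ndarray:
    """Deterministic zero-sum composition offset for one clade."""
    if config.clade_effect == 0:
        return np.zeros(20)
    digest = hashlib.sha256(f"{config.seed}:{clade}".encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
    v = rng.normal(size=20)
    v -= v.mean()
    v /= np.abs(v).sum()  # L1 norm 1 -> total variation = clade_effect / 2
    return config.clade_effect * v


def _aa_distribution(
    label: str, config: SynthConfig, clade: str | None, clip: bool = False
) -> np.ndarray:
    base = np.full(20, 0.05)
    p = base + _CLASS_SIGN[label] * config.composition_effect * _SHIFT
    if clade is not None:
        p = p + _clade_offset(clade, config)
    if p.min() < 0:
        if not clip:
            raise ValueError(
                "composition/clade effects drive amino-acid probabilities "
                f"negative (min {p.min():.4f}); reduce the effect or pass clip=True"
            )
        p = np.clip(p, 1e-6, None)
    return p / p.sum()


def _codon_weights(gc_target: float) -> dict[str, np.ndarray]:
    """Per-AA synonymous-codon probabilities biased toward a GC target."""
    out = {}
    for aa, options in CODON_TABLE.items():
        gc_counts = np.array([sum(c in "GC" for c in cod) for cod in options])
        w = gc_target**gc_counts * (1 - gc_target) ** (3 - gc_counts)
        out[aa] = w / w.sum()
    return out


def _reverse_translate_codes(
    codes: np.ndarray, weights: dict[str, np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    """Vectorized reverse translation of AA index codes to codon strings."""
    codons = np.empty(codes.size, dtype="<U3")
    for a_idx, aa in enumerate(AA_ALPHABET):
        pos = np.nonzero(codes == a_idx)[0]
        if pos.size:
            options = np.array(CODON_TABLE[aa])
            codons[pos] = options[rng.choice(len(options), size=pos.size, p=weights[aa])]
    return codons


def generate_genome(
    genome_id: str,
    label: str,
    config: SynthConfig,
    seed: int,
    taxonomy: Taxonomy | None = None,
    clade: str | None = None,
    clip: bool = False,
) -> GenomeRecord:
    """One genome whose composition reflects its class (and clade)."""
    if label not in CLASSES:
        raise ValueError(f"unknown label {label!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    p_aa = _aa_distribution(label, config, clade, clip=clip)
    gc = config.gc_target[label]
    weights = _codon_weights(gc)
    aa = np.array(list(AA_ALPHABET))
    lengths = rng.integers(
        config.mean_gene_length // 2,
        config.mean_gene_length * 3 // 2 + 1,
        size=config.genes_per_genome,
    )
    codes = rng.choice(20, size=int(lengths.sum()), p=p_aa)
    codons = _reverse_translate_codes(codes, weights, rng)
    proteins, cds = [], []
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    for g in range(config.genes_per_genome):
        lo, hi = bounds[g], bounds[g + 1]
        prot = "".join(aa[codes[lo:hi]])
        proteins.append(SequenceRecord(f"{genome_id}_p{g:04d}", prot, Alphabet.PROTEIN))
        cds.append(
            SequenceRecord(
                f"{genome_id}_c{g:04d}", "".join(codons[lo:hi]), Alphabet.DNA
            )
        )
    # genomic contig: shuffled CDS order with random intergenic spacers
    order = rng.permutation(len(cds))
    total_cds_len = sum(len(c) for c in cds)
    spacer_len = max(
        int(config.intergenic_fraction * total_cds_len / max(len(cds), 1)), 1
    )
    p_base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    parts = []
    for i in order:
        parts.append("".join(rng.choice(bases, size=spacer_len, p=p_base)))
        parts.append(cds[i].residues)
    parts.append("".join(rng.choice(bases, size=spacer_len, p=p_base)))
    genomic = [SequenceRecord(f"{genome_id}_contig1", "".join(parts), Alphabet.DNA)]
    return GenomeRecord(
        genome_id=genome_id,
        genomic=genomic,
        cds_nt=cds,
        proteins=proteins,
        taxonomy=taxonomy or Taxonomy(),
        raw_label=label,
        label=label,
        completeness=1.0,
    )


def generate_dataset(config: SynthConfig, name: str = "synthetic") -> Dataset:
    """Taxonomy -> phenotypes -> genomes, all driven by ``config.seed``."""
    tax_table = generate_taxonomy(config)
    labels = assign_phenotypes(tax_table, config)
    seeds = np.random.SeedSequence([config.seed, 3]).generate_state(len(tax_table))
    records = []
    for i, row in tax_table.iterrows():
        gid = row["genome_id"]
        taxonomy = Taxonomy({r: row[r] for r in RANKS})
        clade = row[config.clade_effect_rank] if config.clade_effect > 0 else None
        records.append(
            generate_genome(
                gid,
                labels[gid],
                config,
                seed=int(seeds[i]) % (2**31),
                taxonomy=taxonomy,
                clade=clade,
            )
        )
    return Dataset(records, name=name)


def write_dataset_fasta(dataset: Dataset, outdir: str | Path,
                        config: SynthConfig | None = None) -> Path:
    """Write one FASTA trio per genome plus a dataio-compatible manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in dataset:
        paths = {}
        for part, seqs in (
            ("genomic", rec.genomic), ("cds", rec.cds_nt), ("protein", rec.proteins)
        ):
            fname = f"{rec.genome_id}.{part}.fasta"
            write_fasta(seqs, outdir / fname)
            paths[part] = fname
        rows.append(
            {
                "genome_id": rec.genome_id,
                "genomic_fasta": paths["genomic"],
                "cds_fasta": paths["cds"],
                "protein_fasta": paths["protein"],
                **{r: rec.taxonomy.at(r) or "" for r in RANKS},
                "raw_label": rec.raw_label or "",
                "completeness": "" if rec.completeness is None else rec.completeness,
            }
        )
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    if config is not None:
        cfg = asdict(config)
        cfg["taxonomy_shape"] = dict(config.taxonomy_shape)
        cfg["gc_target"] = dict(config.gc_target)
        (outdir / "synth_config.json").write_text(json.dumps(cfg, indent=1) + "\n")
    return manifest


def generate_depth_fixture(
    n_depths: int = 20,
    slope: float = 1.0,
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    log_ratio_span: float = 6.0,
    genome_config: SynthConfig | None = None,
):
    """Depth-profile fixture with a planted log-linear redox relation.

    Depths span a gradient over which log10([O2]/[H2S]) falls linearly
    across ``log_ratio_span`` orders of magnitude; the community
    log10(aerobe/anaerobe) ratio equals ``slope * log10([O2]/[H2S]) +
    intercept`` plus Gaussian noise. Returns ``(abundance, chemistry,
    mags)``: a sample x MAG relative-abundance table whose rows sum to 1,
    a depth/o2/h2s chemistry table, and a three-MAG dataset (one genome
    per class, labels attached) generated under ``genome_config``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    depths = np.linspace(10.0, 10.0 + 10.0 * (n_depths - 1), n_depths)
    x = np.linspace(log_ratio_span / 2, -log_ratio_span / 2, n_depths)
    # split the log ratio between the two species so [O2] falls and
    # [H2S] rises with depth while [O2]/[H2S] = 10**x exactly
    o2 = 250.0 * 10.0 ** ((x - x.max()) / 2)    # uM, decreasing with depth
    h2s = o2 / 10.0**x                          # uM, increasing with depth
    y = slope * x + intercept + rng.normal(0.0, noise_sd, size=n_depths)
    ratio = 10.0**y
    fac = 0.10  # small constant facultative share
    a_aer = (1 - fac) * ratio / (1 + ratio)
    a_ana = (1 - fac) / (1 + ratio)

    cfg = genome_config or SynthConfig(genes_per_genome=20, mean_gene_length=100)
    mags = Dataset(
        [
            generate_genome(f"MAG_{label}", label, cfg, seed=seed + 11 + i)
            for i, label in enumerate(CLASSES)
        ],
        name="depth_fixture_mags",
    )
    samples = [f"S{i:03d}" for i in range(n_depths)]
    abundance = pd.DataFrame(
        {
            "MAG_Aerobe": a_aer,
            "MAG_Anaerobe": a_ana,
            "MAG_Facultative": np.full(n_depths, fac),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    chemistry = pd.DataFrame(
        {"depth": depths, "o2": o2, "h2s": h2s},
        index=pd.Index(samples, name="sample_id"),
    )
    return abundance, chemistry, mags
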