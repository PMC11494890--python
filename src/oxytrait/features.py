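"""Annotation-free genome features.

Feature sets:

* genomic nucleotide k-mers (k = 1..5) over the assembled contigs,
* CDS nucleotide k-mers (k = 1..5),
* amino-acid k-mers (k = 1..3) over the translated proteome,
* gene count (number of coding sequences),
* twelve "chemical" descriptors: ORF count, genomic GC content, mean
  C/N/O/S atoms per amino-acid monomer and per RNA nucleotide monomer,
  and the average carbon oxidation state (Z_C) of the pooled protein and
  RNA-coding residue formulas.

K-mers are counted with overlapping windows (stride 1); any window
containing a character outside the canonical alphabet (ACGT for DNA, the
20 standard residues for protein) is skipped. Feature vectors always span
the full lexicographic alphabet^k space so dimensionality is independent
of which k-mers were observed.

Z_C is the average oxidation state of carbon obtained by electronegativity
bookkeeping: hydrogen donates one electron to carbon, while N, O and S
each withdraw (two for O and S, three for N on average in biomolecules),
and phosphorus (never bonded to carbon in nucleotides) contributes
nothing:

    Z_C = (z - n_H + 3*n_N + 2*n_O + 2*n_S) / n_C

Z_C is invariant to adding or removing water, so the free-monomer and
polymerized-residue conventions agree; elemental means use the residue
(polymerized) convention because the polymer is the molecule the genome
actually encodes.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import Alphabet, Dataset, GenomeRecord, SequenceRecord

__all__ = [
    "FeatureSpec",
    "FeatureMatrix",
    "ElementalFormula",
    "DNA_ALPHABET",
    "AA_ALPHABET",
    "count_kmers",
    "kmer_feature_vector",
    "gc_content",
    "zc",
    "monomer_formula",
    "chemical_feature_vector",
    "gene_count_feature",
    "build_feature_matrix",
    "CHEMICAL_FEATURE_NAMES",
    "AA_RESIDUE_FORMULAS",
    "RNA_RESIDUE_FORMULAS",
]

DNA_ALPHABET = "ACGT"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_KINDS = ("genomic_nt_kmer", "cds_nt_kmer", "aa_kmer", "chemical", "gene_count")
_NORMS = ("raw_count", "frequency")

CHEMICAL_FEATURE_NAMES = (
    "orf_count",
    "gc_content",
    "aa_mean_C",
    "aa_mean_N",
    "aa_mean_O",
    "aa_mean_S",
    "nt_mean_C",
    "nt_mean_N",
    "nt_mean_O",
    "nt_mean_S",
    "zc_protein",
    "zc_rna",
)


@dataclass(frozen=True)
class FeatureSpec:
    """A named, reproducible description of one feature set."""

    kind: str
    k: int | None = None
    normalization: str = "frequency"
    collapse_revcomp: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.normalization not in _NORMS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.kind in ("genomic_nt_kmer", "cds_nt_kmer"):
            if self.k is None or not 1 <= self.k <= 5:
                raise ValueError(f"{self.kind} requires k in 1..5, got {self.k}")
        elif self.kind == "aa_kmer":
            if self.k is None or not 1 <= self.k <= 3:
                raise ValueError(f"aa_kmer requires k in 1..3, got {self.k}")
            if self.collapse_revcomp:
                raise ValueError("collapse_revcomp only applies to nucleotide k-mers")
        else:
            if self.k is not None:
                raise ValueError(f"{self.kind} takes no k (got {self.k})")
            if self.collapse_revcomp:
                raise ValueError("collapse_revcomp only applies to nucleotide k-mers")

    @property
    def name(self) -> str:
        parts = [self.kind]
        if self.k is not None:
            parts.append(str(self.k))
        parts.append(self.normalization)
        if self.collapse_revcomp:
            parts.append("canonical")
        return ":".join(parts)

    @property
    def alphabet(self) -> str | None:
        if self.kind in ("genomic_nt_kmer", "cds_nt_kmer"):
            return DNA_ALPHABET
        if self.kind == "aa_kmer":
            return AA_ALPHABET
        return None

    def feature_names(self) -> list[str]:
        """Full, ordered feature-name enumeration for this spec."""
        if self.kind == "chemical":
            return list(CHEMICAL_FEATURE_NAMES)
        if self.kind == "gene_count":
            return ["gene_count"]
        names = [
            "".join(t) for t in itertools.product(self.alphabet, repeat=self.k)
        ]
        if self.collapse_revcomp:
            names = sorted({min(km, _revcomp(km)) for km in names})
        return names

    @classmethod
    def from_string(cls, text: str, normalization: str = "frequency") -> "FeatureSpec":
        """Parse compact specs like ``aa_kmer:3`` or ``chemical``."""
        parts = text.split(":")
        kind = parts[0]
        k = int(parts[1]) if len(parts) > 1 else None
        return cls(kind=kind, k=k, normalization=normalization)


def _revcomp(kmer: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[c] for c in reversed(kmer))


# --- elemental formulas ----------------------------------------------------


@dataclass(frozen=True)
class ElementalFormula:
    """CHNOS composition (plus formal charge) of a molecule or pool."""

    n_C: float = 0
    n_H: float = 0
    n_N: float = 0
    n_O: float = 0
    n_S: float = 0
    charge_z: float = 0

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(
            self.n_C + other.n_C,
            self.n_H + other.n_H,
            self.n_N + other.n_N,
            self.n_O + other.n_O,
            self.n_S + other.n_S,
            self.charge_z + other.charge_z,
        )

    def __mul__(self, count: float) -> "ElementalFormula":
        return ElementalFormula(
            self.n_C * count,
            self.n_H * count,
            self.n_N * count,
            self.n_O * count,
            self.n_S * count,
            self.charge_z * count,
        )

    __rmul__ = __mul__


def zc(formula: ElementalFormula) -> float:
    """Average oxidation state of carbon; requires at least one carbon."""
    if formula.n_C < 1:
        raise ValueError("Z_C undefined for a formula with no carbon")
    return (
        formula.charge_z
        - formula.n_H
        + 3 * formula.n_N
        + 2 * formula.n_O
        + 2 * formula.n_S
    ) / formula.n_C


def _f(c, h, n, o, s=0, z=0):
    return ElementalFormula(c, h, n, o, s, z)


# Amino-acid residue formulas: the free amino acid minus one H2O lost on
# peptide-bond formation.
AA_RESIDUE_FORMULAS: Mapping[str, ElementalFormula] = {
    "A": _f(3, 5, 1, 1),
    "R": _f(6, 12, 4, 1),
    "N": _f(4, 6, 2, 2),
    "D": _f(4, 5, 1, 3),
    "C": _f(3, 5, 1, 1, 1),
    "E": _f(5, 7, 1, 3),
    "Q": _f(5, 8, 2, 2),
    "G": _f(2, 3, 1, 1),
    "H": _f(6, 7, 3, 1),
    "I": _f(6, 11, 1, 1),
    "L": _f(6, 11, 1, 1),
    "K": _f(6, 12, 2, 1),
    "M": _f(5, 9, 1, 1, 1),
    "F": _f(9, 9, 1, 1),
    "P": _f(5, 7, 1, 1),
    "S": _f(3, 5, 1, 2),
    "T": _f(4, 7, 1, 2),
    "W": _f(11, 10, 2, 1),
    "Y": _f(9, 9, 1, 2),
    "V": _f(5, 9, 1, 1),
}

# Ribonucleotide residues: the 5'-monophosphate minus one H2O per
# phosphodiester bond. Phosphorus is not carbon-bonded, so it does not
# enter Z_C bookkeeping; formulas are for the neutral (protonated) form.
RNA_RESIDUE_FORMULAS: Mapping[str, ElementalFormula] = {
    "A": _f(10, 12, 5, 6),  # AMP C10H14N5O7P - H2O
    "C": _f(9, 12, 3, 7),   # CMP C9H14N3O8P - H2O
    "G": _f(10, 12, 5, 7),  # GMP C10H14N5O8P - H2O
    "U": _f(9, 11, 2, 8),   # UMP C9H13N2O9P - H2O
}


def monomer_formula(monomer: str, alphabet: str) -> ElementalFormula:
    """Residue formula of one monomer.

    ``alphabet`` is ``"PROTEIN"`` (20 standard amino acids) or ``"RNA_NT"``
    (ACGU; a DNA ``T`` is accepted and mapped to ``U`` since chemical
    features describe the RNA-coding sequence).
    """
    if alphabet == "PROTEIN":
        try:
            return AA_RESIDUE_FORMULAS[monomer]
        except KeyError:
            raise ValueError(f"{monomer!r} is not a standard amino acid") from None
    if alphabet == "RNA_NT":
        m = "U" if monomer == "T" else monomer
        try:
            return RNA_RESIDUE_FORMULAS[m]
        except KeyError:
            raise ValueError(f"{monomer!r} is not a canonical nucleotide") from None
    raise ValueError(f"unknown alphabet {alphabet!r}")


# --- k-mer counting --------------------------------------------------------

def _encoding_table(alphabet: str) -> np.ndarray:
    table = np.full(256, -1, dtype=np.int64)
    for i, ch in enumerate(alphabet):
        table[ord(ch)] = i
    return table

_DNA_TABLE = _encoding_table(DNA_ALPHABET)
_AA_TABLE = _encoding_table(AA_ALPHABET)


def _encode(seq: str, table: np.ndarray) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return table[raw]


def _count_kmer_codes(codes: np.ndarray, k: int, n_alpha: int) -> np.ndarray:
    """Vector of k-mer counts over the full n_alpha**k space.

    Windows containing any non-canonical position (code < 0) are skipped.
    """
    n = codes.size
    out_dim = n_alpha**k
    if n < k:
        return np.zeros(out_dim, dtype=np.int64)
    n_win = n - k + 1
    window_code = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(k):
        c = codes[j : j + n_win]
        valid &= c >= 0
        window_code = window_code * n_alpha + np.where(c >= 0, c, 0)
    return np.bincount(window_code[valid], minlength=out_dim)


def count_kmers(
    seq: SequenceRecord | str, k: int, alphabet: str | None = None
) -> dict[str, int]:
    """Overlapping k-mer counts of one sequence as a sparse dict.

    Windows containing characters outside the canonical alphabet are
    skipped; for a fully canonical sequence the counts sum to
    ``len - k + 1``.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if isinstance(seq, SequenceRecord):
        residues = seq.residues
        if alphabet is None:
            alphabet = DNA_ALPHABET if seq.alphabet is Alphabet.DNA else AA_ALPHABET
    else:
        residues = seq.upper()
        if alphabet is None:
            raise ValueError("alphabet required when passing a bare string")
    table = _DNA_TABLE if alphabet == DNA_ALPHABET else _encoding_table(alphabet)
    counts = _count_kmer_codes(_encode(residues, table), k, len(alphabet))
    nz = np.nonzero(counts)[0]
    names = ["".join(t) for t in itertools.product(alphabet, repeat=k)]
    return {names[i]: int(counts[i]) for i in nz}


def _pooled_kmer_counts(
    seqs: Sequence[SequenceRecord], k: int, alphabet: str
) -> np.ndarray:
    table = _DNA_TABLE if alphabet == DNA_ALPHABET else _AA_TABLE
    total = np.zeros(len(alphabet) ** k, dtype=np.int64)
    for rec in seqs:
        total += _count_kmer_codes(_encode(rec.residues, table), k, len(alphabet))
    return total


def kmer_feature_vector(genome: GenomeRecord, spec: FeatureSpec) -> np.ndarray:
    """One genome's k-mer feature row under ``spec``.

    Counts are summed over all sequences in the collection named by the
    spec kind and projected onto the full lexicographic alphabet^k order;
    frequency normalization divides by the total count (all-zero rows are
    left as zeros).
    """
    collection = {
        "genomic_nt_kmer": genome.genomic,
        "cds_nt_kmer": genome.cds_nt,
        "aa_kmer": genome.proteins,
    }.get(spec.kind)
    if collection is None:
        raise ValueError(f"{spec.kind!r} is not a k-mer feature kind")
    if not collection:
        raise ValueError(
            f"genome {genome.genome_id!r} has no sequences for {spec.kind}"
        )
    counts = _pooled_kmer_counts(collection, spec.k, spec.alphabet).astype(float)
    if spec.collapse_revcomp:
        full = ["".join(t) for t in itertools.product(DNA_ALPHABET, repeat=spec.k)]
        canon = sorted({min(km, _revcomp(km)) for km in full})
        pos = {km: i for i, km in enumerate(canon)}
        folded = np.zeros(len(canon))
        for km, c in zip(full, counts):
            folded[pos[min(km, _revcomp(km))]] += c
        counts = folded
    if spec.normalization == "frequency":
        total = counts.sum()
        if total > 0:
            counts = counts / total
    return counts


def gc_content(seqs: Sequence[SequenceRecord]) -> float:
    """(G+C)/(A+C+G+T) pooled over sequences; ambiguity codes excluded."""
    counts = np.zeros(4, dtype=np.int64)
    for rec in seqs:
        codes = _encode(rec.residues, _DNA_TABLE)
        counts += np.bincount(codes[codes >= 0], minlength=4)
    total = counts.sum()
    if total == 0:
        raise ValueError("no unambiguous ACGT characters in input")
    return float((counts[1] + counts[2]) / total)  # C + G


def _pooled_formula(
    seqs: Sequence[SequenceRecord], formulas: Mapping[str, ElementalFormula],
    alphabet: str, table: np.ndarray,
) -> tuple[ElementalFormula, int]:
    """Summed residue formula and monomer count over pooled sequences."""
    counts = np.zeros(len(alphabet), dtype=np.int64)
    for rec in seqs:
        codes = table[np.frombuffer(rec.residues.encode("ascii"), np.uint8)]
        counts += np.bincount(codes[codes >= 0], minlength=len(alphabet))
    total = ElementalFormula()
    for ch, n in zip(alphabet, counts):
        if n:
            total = total + formulas[ch] * int(n)
    return total, int(counts.sum())


_RNA_TABLE = _encoding_table("ACGU")
_RNA_TABLE[ord("T")] = 3  # DNA T counted as U


def chemical_feature_vector(genome: GenomeRecord) -> np.ndarray:
    """Twelve chemical descriptors in the fixed CHEMICAL_FEATURE_NAMES order."""
    if not (genome.genomic and genome.cds_nt and genome.proteins):
        raise ValueError(
            f"genome {genome.genome_id!r}: chemical features need genomic, "
            "CDS and protein sequences"
        )
    aa_pool, n_aa = _pooled_formula(
        genome.proteins, AA_RESIDUE_FORMULAS, AA_ALPHABET, _AA_TABLE
    )
    nt_pool, n_nt = _pooled_formula(
        genome.cds_nt, RNA_RESIDUE_FORMULAS, "ACGU", _RNA_TABLE
    )
    if n_aa == 0 or n_nt == 0:
        raise ValueError(
            f"genome {genome.genome_id!r}: no canonical monomers to pool"
        )
    return np.array(
        [
            gene_count_feature(genome),
            gc_content(genome.genomic),
            aa_pool.n_C / n_aa,
            aa_pool.n_N / n_aa,
            aa_pool.n_O / n_aa,
            aa_pool.n_S / n_aa,
            nt_pool.n_C / n_nt,
            nt_pool.n_N / n_nt,
            nt_pool.n_O / n_nt,
            nt_pool.n_S / n_nt,
            zc(aa_pool),
            zc(nt_pool),
        ]
    )


def gene_count_feature(genome: GenomeRecord) -> int:
    """Number of coding sequences (falls back to the protein count)."""
    if genome.cds_nt:
        return len(genome.cds_nt)
    if genome.proteins:
        return len(genome.proteins)
    raise ValueError(f"genome {genome.genome_id!r} has no CDS or proteins")


# --- feature matrices ------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Genome-by-feature table with a recorded, hashable schema."""

    genome_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    spec: FeatureSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genome_ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genome_ids)} genomes x {len(self.feature_names)} features"
            )

    @property
    def schema_hash(self) -> str:
        payload = json.dumps(
            {
                "kind": self.spec.kind,
                "k": self.spec.k,
                "normalization": self.spec.normalization,
                "collapse_revcomp": self.spec.collapse_revcomp,
                "feature_names": self.feature_names,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.genome_ids, columns=self.feature_names
        )

    def subset(self, genome_ids: Iterable[str]) -> "FeatureMatrix":
        ids = list(genome_ids)
        pos = {g: i for i, g in enumerate(self.genome_ids)}
        missing = [g for g in ids if g not in pos]
        if missing:
            raise KeyError(f"genomes absent from feature matrix: {missing[:5]}")
        rows = [pos[g] for g in ids]
        return FeatureMatrix(ids, self.feature_names, self.values[rows], self.spec)

    def write_tsv(self, path: str | Path) -> None:
        """Write the matrix as TSV plus a JSON sidecar recording the spec."""
        path = Path(path)
        df = self.to_dataframe()
        df.index.name = "genome_id"
        df.to_csv(path, sep="\t")
        sidecar = {
            "kind": self.spec.kind,
            "k": self.spec.k,
            "normalization": self.spec.normalization,
            "collapse_revcomp": self.spec.collapse_revcomp,
            "schema_hash": self.schema_hash,
        }
        Path(str(path) + ".spec.json").write_text(json.dumps(sidecar) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        sidecar = json.loads(Path(str(path) + ".spec.json").read_text())
        spec = FeatureSpec(
            kind=sidecar["kind"],
            k=sidecar["k"],
            normalization=sidecar["normalization"],
            collapse_revcomp=sidecar.get("collapse_revcomp", False),
        )
        df = pd.read_csv(path, sep="\t", index_col="genome_id")
        fm = cls(
            [str(g) for g in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(dtype=float),
            spec,
        )
        if fm.schema_hash != sidecar["schema_hash"]:
            raise ValueError(f"{path}: schema hash mismatch with sidecar")
        return fm


def build_feature_matrix(dataset: Dataset, spec: FeatureSpec) -> FeatureMatrix:
    """Featurize every genome in dataset order under one spec."""
    names = spec.feature_names()
    rows = np.empty((len(dataset), len(names)), dtype=float)
    for i, genome in enumerate(dataset):
        try:
            if spec.kind == "chemical":
                rows[i] = chemical_feature_vector(genome)
            elif spec.kind == "gene_count":
                rows[i] = [gene_count_feature(genome)]
            else:
                rows[i] = kmer_feature_vector(genome, spec)
        except ValueError as exc:
            raise ValueError(f"genome {genome.genome_id!r}: {exc}") from exc
    return FeatureMatrix(dataset.genome_ids, names, rows, spec)
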