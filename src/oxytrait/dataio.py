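"""Reading, writing and assembly of labeled genome datasets.

A dataset is a collection of genomes, each carrying three sequence
collections (genomic contigs, CDS nucleotide sequences, translated
proteins), a seven-rank taxonomy, and an oxygen-utilization phenotype
harmonized from free-text source labels into a ternary scheme
(Aerobe / Anaerobe / Facultative) plus a derived binary scheme
(Tolerant / Intolerant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "Alphabet",
    "SequenceRecord",
    "Taxonomy",
    "RANKS",
    "GenomeRecord",
    "Dataset",
    "read_fasta",
    "write_fasta",
    "harmonize_label",
    "ternary_to_binary",
    "load_dataset",
    "load_label_map",
    "TERNARY_CLASSES",
    "BINARY_CLASSES",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

TERNARY_CLASSES = ("Aerobe", "Anaerobe", "Facultative")
BINARY_CLASSES = ("Intolerant", "Tolerant")

# Raw source labels -> ternary class. Keys are matched case-insensitively
# after whitespace trimming.
DEFAULT_LABEL_MAP: Mapping[str, str] = {
    "anaerobe": "Anaerobe",
    "obligate anaerobe": "Anaerobe",
    "facultative": "Facultative",
    "facultative anaerobe": "Facultative",
    "aerobe": "Aerobe",
    "microaerophilic": "Aerobe",
    "obligate aerobe": "Aerobe",
}

# Facultative organisms grow in the presence of O2, hence Tolerant.
TERNARY_TO_BINARY: Mapping[str, str] = {
    "Aerobe": "Tolerant",
    "Facultative": "Tolerant",
    "Anaerobe": "Intolerant",
}

_DNA_CHARS = frozenset("ACGTRYSWKMBDHVN")
# 20 standard residues plus ambiguity/extension codes (X B Z J), stop (*),
# selenocysteine (U) and pyrrolysine (O).
_PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZJOU*")


class Alphabet(str, Enum):
    DNA = "DNA"
    PROTEIN = "PROTEIN"


@dataclass(frozen=True)
class SequenceRecord:
    """A single named sequence with a declared alphabet.

    Residues are upper-cased on construction and validated against the
    IUPAC character set for the alphabet.
    """

    id: str
    residues: str
    alphabet: Alphabet

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has an empty sequence")
        object.__setattr__(self, "residues", self.residues.upper())
        allowed = _DNA_CHARS if self.alphabet is Alphabet.DNA else _PROTEIN_CHARS
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters {sorted(bad)} "
                f"not allowed in the {self.alphabet.value} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Taxonomy:
    """Seven-rank taxonomy (domain..species); lower ranks may be missing.

    A named rank requires all ranks above it to be named (no gaps).
    """

    ranks: Mapping[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.ranks) - set(RANKS)
        if unknown:
            raise ValueError(f"unknown taxonomy ranks: {sorted(unknown)}")
        filled = dict.fromkeys(RANKS, None)
        for r, v in self.ranks.items():
            filled[r] = v if v not in (None, "", "NA") else None
        object.__setattr__(self, "ranks", filled)
        seen_missing = False
        for r in RANKS:
            if filled[r] is None:
                seen_missing = True
            elif seen_missing:
                raise ValueError(
                    f"taxonomy has named rank {r!r} below a missing rank"
                )

    def at(self, rank: str) -> str | None:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return self.ranks[rank]


@dataclass
class GenomeRecord:
    """One organism: sequences, taxonomy, and (optionally) a phenotype."""

    genome_id: str
    genomic: list[SequenceRecord] = field(default_factory=list)
    cds_nt: list[SequenceRecord] = field(default_factory=list)
    proteins: list[SequenceRecord] = field(default_factory=list)
    taxonomy: Taxonomy = field(default_factory=Taxonomy)
    raw_label: str | None = None
    label: str | None = None
    completeness: float | None = None

    def __post_init__(self) -> None:
        if self.cds_nt and self.proteins and len(self.cds_nt) != len(self.proteins):
            raise ValueError(
                f"genome {self.genome_id!r}: {len(self.cds_nt)} CDS but "
                f"{len(self.proteins)} proteins"
            )
        if self.completeness is not None and not 0.0 <= self.completeness <= 1.0:
            raise ValueError(
                f"genome {self.genome_id!r}: completeness {self.completeness} "
                "outside [0, 1]"
            )


class Dataset:
    """An ordered collection of genomes with unique ids."""

    def __init__(self, records: Sequence[GenomeRecord], name: str = "dataset"):
        ids = [r.genome_id for r in records]
        dupes = {g for g in ids if ids.count(g) > 1}
        if dupes:
            raise ValueError(f"duplicate genome_ids: {sorted(dupes)}")
        self.records: list[GenomeRecord] = list(records)
        self.name = name
        self._index = {r.genome_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GenomeRecord]:
        return iter(self.records)

    def __getitem__(self, genome_id: str) -> GenomeRecord:
        return self._index[genome_id]

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self._index

    @property
    def genome_ids(self) -> list[str]:
        return [r.genome_id for r in self.records]

    def labels(self) -> list[str | None]:
        return [r.label for r in self.records]

    def subset(self, genome_ids: Iterable[str], name: str | None = None) -> "Dataset":
        ids = list(genome_ids)
        missing = [g for g in ids if g not in self._index]
        if missing:
            raise KeyError(f"genome ids not in dataset: {missing[:5]}")
        return Dataset([self._index[g] for g in ids], name=name or self.name)


def read_fasta(path: str | Path, alphabet: Alphabet | str) -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    The id is the header token before the first whitespace; sequence lines
    are concatenated and upper-cased. An empty file, or a record with no
    sequence, is an error.
    """
    alphabet = Alphabet(alphabet)
    path = Path(path)
    records: list[SequenceRecord] = []
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            seq_id = header.split()[0] if header.split() else header
            if not seq:
                raise ValueError(f"{path}: record {seq_id!r} has an empty sequence")
            records.append(SequenceRecord(seq_id, seq, alphabet))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, width: int = 60
) -> None:
    """Write records as FASTA with fixed-width line wrapping."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def load_label_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (raw_label, ternary_class) label-map override."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: label map needs two columns (raw, ternary)")
    raw_col, cls_col = df.columns[:2]
    mapping = {}
    for raw, cls in zip(df[raw_col], df[cls_col]):
        if cls not in TERNARY_CLASSES:
            raise ValueError(
                f"{path}: {cls!r} is not one of {TERNARY_CLASSES}"
            )
        mapping[str(raw).strip().lower()] = cls
    return mapping


def harmonize_label(raw: str, label_map: Mapping[str, str] | None = None) -> str:
    """Map a raw source phenotype string onto the ternary class scheme.

    Matching is case-insensitive after whitespace trimming. Unrecognized
    strings raise, listing the accepted values.
    """
    mapping = DEFAULT_LABEL_MAP if label_map is None else label_map
    key = raw.strip().lower()
    if key not in mapping:
        accepted = sorted(mapping)
        raise ValueError(
            f"unrecognized raw label {raw!r}; accepted values "
            f"(case-insensitive): {accepted}"
        )
    return mapping[key]


def ternary_to_binary(label: str) -> str:
    """Collapse the ternary phenotype to O2-tolerant vs O2-intolerant."""
    if label not in TERNARY_TO_BINARY:
        raise ValueError(f"{label!r} is not one of {TERNARY_CLASSES}")
    return TERNARY_TO_BINARY[label]


_MANDATORY_COLS = ("genome_id", "genomic_fasta", "cds_fasta", "protein_fasta")


def load_dataset(
    manifest: str | Path,
    name: str | None = None,
    label_map: Mapping[str, str] | None = None,
    errors: str = "raise",
) -> Dataset:
    """Assemble a :class:`Dataset` from a TSV manifest.

    The manifest has columns genome_id, genomic_fasta, cds_fasta,
    protein_fasta, the seven taxonomy ranks, and optionally raw_label and
    completeness. FASTA paths are resolved relative to the manifest's
    directory. Completeness values above 1 are treated as percentages.

    With ``errors="raise"`` (default) a row whose FASTA files cannot be
    read aborts the load with a message naming the row; ``errors="warn"``
    reports the row in a warning and drops it.
    """
    if errors not in ("raise", "warn"):
        raise ValueError("errors must be 'raise' or 'warn'")
    manifest = Path(manifest)
    df = pd.read_csv(manifest, sep="\t", comment="#", dtype=str)
    missing = [c for c in _MANDATORY_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{manifest}: missing mandatory columns {missing}")
    ids = df["genome_id"].tolist()
    dupes = sorted({g for g in ids if ids.count(g) > 1})
    if dupes:
        raise ValueError(f"{manifest}: duplicate genome_ids {dupes}")

    base = manifest.parent
    records: list[GenomeRecord] = []
    failed: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        gid = row["genome_id"]
        try:
            genomic = read_fasta(base / row["genomic_fasta"], Alphabet.DNA)
            cds = read_fasta(base / row["cds_fasta"], Alphabet.DNA)
            prots = read_fasta(base / row["protein_fasta"], Alphabet.PROTEIN)
        except (OSError, ValueError) as exc:
            failed.append((gid, str(exc)))
            continue
        tax = Taxonomy(
            {
                r: row[r]
                for r in RANKS
                if r in df.columns and isinstance(row[r], str) and row[r]
            }
        )
        raw = row.get("raw_label") if "raw_label" in df.columns else None
        raw = raw if isinstance(raw, str) and raw else None
        label = harmonize_label(raw, label_map) if raw is not None else None
        comp = None
        if "completeness" in df.columns and isinstance(row["completeness"], str):
            comp = float(row["completeness"])
            if comp > 1.0:  # percentage convention (e.g. CheckM output)
                comp /= 100.0
        records.append(
            GenomeRecord(
                genome_id=gid,
                genomic=genomic,
                cds_nt=cds,
                proteins=prots,
                taxonomy=tax,
                raw_label=raw,
                label=label,
                completeness=comp,
            )
        )
    if failed:
        detail = "; ".join(f"{g}: {m}" for g, m in failed)
        if errors == "raise":
            raise ValueError(f"{manifest}: unreadable rows — {detail}")
        warnings.warn(f"{manifest}: dropped unreadable rows — {detail}")
    return Dataset(records, name=name or manifest.stem)
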