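"""Reading and writing phased multi-locus allele data.

Two input dialects are supported:

* the pyRAD v3 ``.alleles`` text format, in which each locus is a block of
  lines ``<individual>_<0|1> <sequence>`` terminated by a line starting with
  ``//`` (pyRAD decorates that line with SNP annotation, which is ignored;
  an optional trailing ``|<id>`` token names the locus);
* a directory of per-locus FASTA files whose headers follow the same
  ``<individual>_<0|1>`` naming convention.

Both yield a :class:`Dataset` of diploid, phased loci: every individual
present at a locus carries exactly two allele sequences (allele 0 and
allele 1), all aligned to the same length.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import AlignmentError, FormatError, ParseError, PloidyError

VALID_CHARS = frozenset("ACGTN-")


@dataclass(frozen=True)
class AlleleRecord:
    """One phased allele of one individual at one locus."""

    individual_id: str
    allele_index: int  # 0 or 1
    sequence: str  # uppercase over {A,C,G,T,N,-}

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(
                f"empty sequence for {self.individual_id}_{self.allele_index}"
            )
        if self.allele_index not in (0, 1):
            raise FormatError(
                f"allele index must be 0 or 1, got {self.allele_index!r}"
            )


@dataclass
class Locus:
    """An aligned block of phased alleles for one marker.

    Invariants (checked by :meth:`validate`): all sequences share one
    alignment length, and every individual appears with exactly alleles
    0 and 1.
    """

    locus_id: str
    records: list[AlleleRecord]
    length: int

    def validate(self) -> None:
        for rec in self.records:
            if len(rec.sequence) != self.length:
                raise AlignmentError(
                    f"locus {self.locus_id}: sequence of {rec.individual_id}"
                    f"_{rec.allele_index} has length {len(rec.sequence)},"
                    f" expected {self.length}"
                )
        seen: dict[str, set[int]] = {}
        for rec in self.records:
            seen.setdefault(rec.individual_id, set())
            if rec.allele_index in seen[rec.individual_id]:
                raise PloidyError(
                    f"locus {self.locus_id}: duplicate allele"
                    f" {rec.individual_id}_{rec.allele_index}"
                )
            seen[rec.individual_id].add(rec.allele_index)
        for ind, idx in seen.items():
            if idx != {0, 1}:
                raise PloidyError(
                    f"locus {self.locus_id}: individual {ind} has alleles"
                    f" {sorted(idx)}; diploid phased data require exactly"
                    " alleles 0 and 1"
                )

    @property
    def individuals(self) -> list[str]:
        """Individuals present at this locus, in order of first appearance."""
        out: list[str] = []
        seen = set()
        for rec in self.records:
            if rec.individual_id not in seen:
                seen.add(rec.individual_id)
                out.append(rec.individual_id)
        return out

    def alleles_of(self, individual_id: str) -> tuple[str, str]:
        """Return the (allele 0, allele 1) sequences of one individual."""
        pair: dict[int, str] = {}
        for rec in self.records:
            if rec.individual_id == individual_id:
                pair[rec.allele_index] = rec.sequence
        if set(pair) != {0, 1}:
            raise PloidyError(
                f"locus {self.locus_id}: {individual_id} lacks two alleles"
            )
        return pair[0], pair[1]


@dataclass
class Dataset:
    """An ordered collection of loci plus the global individual roster."""

    loci: list[Locus] = field(default_factory=list)
    individuals: list[str] = field(default_factory=list)

    def validate(self) -> None:
        ids = [loc.locus_id for loc in self.loci]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate locus ids in dataset")
        roster = set(self.individuals)
        for loc in self.loci:
            loc.validate()
            missing = set(loc.individuals) - roster
            if missing:
                raise FormatError(
                    f"locus {loc.locus_id}: individuals {sorted(missing)}"
                    " absent from dataset roster"
                )

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def _finish_locus(
    raw: list[tuple[str, int, str, int]],
    locus_id: str,
    tolerate_haploid: bool,
) -> Locus:
    """Assemble and validate one locus from parsed (name, idx, seq, lineno)."""
    by_ind: dict[str, list[tuple[int, str, int]]] = {}
    order: list[str] = []
    for name, idx, seq, lineno in raw:
        if name not in by_ind:
            by_ind[name] = []
            order.append(name)
        by_ind[name].append((idx, seq, lineno))

    records: list[AlleleRecord] = []
    length = None
    for name in order:
        entries = by_ind[name]
        if len(entries) == 1 and tolerate_haploid:
            idx, seq, lineno = entries[0]
            entries = [(0, seq, lineno), (1, seq, lineno)]
        if len(entries) != 2:
            raise PloidyError(
                f"locus {locus_id}: individual {name} has {len(entries)}"
                " allele line(s); expected 2 (use tolerate_haploid to"
                " duplicate singletons)"
            )
        indices = sorted(e[0] for e in entries)
        if indices != [0, 1]:
            raise PloidyError(
                f"locus {locus_id}: individual {name} has allele indices"
                f" {indices}; expected [0, 1]"
            )
        for idx, seq, lineno in entries:
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise AlignmentError(
                    f"locus {locus_id}: line {lineno}: sequence length"
                    f" {len(seq)} != {length}"
                )
            records.append(AlleleRecord(name, idx, seq))
    locus = Locus(locus_id=locus_id, records=records, length=length or 0)
    locus.validate()
    return locus


def _split_label(label: str, lineno: int) -> tuple[str, int]:
    if label.endswith("_0"):
        return label[:-2], 0
    if label.endswith("_1"):
        return label[:-2], 1
    raise FormatError(
        f"line {lineno}: label {label!r} lacks the _0/_1 allele suffix"
    )


def _check_sequence(seq: str, lineno: int) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_CHARS
    if bad:
        raise ParseError(
            f"line {lineno}: sequence contains invalid characters"
            f" {sorted(bad)}"
        )
    return seq


def read_alleles(path: str | Path, tolerate_haploid: bool = False) -> Dataset:
    """Parse a pyRAD v3 ``.alleles`` file into a :class:`Dataset`.

    Blank lines are ignored.  Each locus block ends with a line starting
    with ``//``; anything after ``//`` is pyRAD decoration and is ignored,
    except a trailing ``|<id>`` token, which names the locus (otherwise the
    0-based ordinal is used).  A final block not terminated by ``//`` is
    accepted.  Input case is normalised to uppercase.
    """
    path = Path(path)
    loci: list[Locus] = []
    pending: list[tuple[str, int, str, int]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("//"):
                decoration = line.lstrip()[2:]
                locus_id = str(len(loci))
                if "|" in decoration:
                    tail = decoration.rsplit("|", 1)[1].strip()
                    if tail:
                        locus_id = tail
                loci.append(_finish_locus(pending, locus_id, tolerate_haploid))
                pending = []
                continue
            parts = line.split(None, 1)
            if len(parts) != 2 or not parts[1].strip():
                raise ParseError(
                    f"line {lineno}: expected '<label> <sequence>',"
                    f" got {line!r}"
                )
            label, seq = parts[0], parts[1].strip()
            name, idx = _split_label(label, lineno)
            pending.append((name, idx, _check_sequence(seq, lineno), lineno))
    if pending:
        loci.append(_finish_locus(pending, str(len(loci)), tolerate_haploid))
    return Dataset(loci=loci, individuals=_roster(loci))


def _roster(loci: list[Locus]) -> list[str]:
    """Union of individuals over loci, in stable order of first appearance."""
    out: list[str] = []
    seen = set()
    for loc in loci:
        for ind in loc.individuals:
            if ind not in seen:
                seen.add(ind)
                out.append(ind)
    return out


def read_loci_fasta_dir(
    directory: str | Path, tolerate_haploid: bool = False
) -> Dataset:
    """Read a directory of per-locus FASTA files.

    Files matching ``*.fasta``/``*.fa``/``*.fas`` are processed in
    lexicographic order; the file stem becomes the locus id.  Headers must
    be ``<individual>_<0|1>``.
    """
    directory = Path(directory)
    paths = sorted(
        p
        for p in directory.iterdir()
        if p.suffix.lower() in {".fasta", ".fa", ".fas"}
    )
    loci: list[Locus] = []
    for p in paths:
        raw: list[tuple[str, int, str, int]] = []
        for i, rec in enumerate(SeqIO.parse(str(p), "fasta")):
            name, idx = _split_label(rec.id, i + 1)
            raw.append((name, idx, _check_sequence(str(rec.seq), i + 1), i + 1))
        loci.append(_finish_locus(raw, p.stem, tolerate_haploid))
    return Dataset(loci=loci, individuals=_roster(loci))


def write_alleles(dataset: Dataset, path: str | Path) -> None:
    """Serialise a :class:`Dataset` back to the ``.alleles`` dialect.

    Locus ids are preserved via the ``//|<id>`` convention, so
    read ∘ write is the identity on individuals and per-locus records.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for loc in dataset.loci:
            width = max(
                (len(f"{r.individual_id}_{r.allele_index}") for r in loc.records),
                default=0,
            )
            for rec in loc.records:
                label = f"{rec.individual_id}_{rec.allele_index}"
                fh.write(f"{label.ljust(width)}    {rec.sequence}\n")
            fh.write(f"//|{loc.locus_id}\n")


def write_table_tsv(
    individuals: list[str], values: np.ndarray, path: str | Path
) -> None:
    """Write a square labelled matrix as TSV (header row and column)."""
    df = pd.DataFrame(values, index=individuals, columns=individuals)
    df.to_csv(path, sep="\t")


def write_matrix_tsv(matrix, path: str | Path, which: str = "score") -> None:
    """Write one field of a conspecificity matrix (``score``/``copresent``)."""
    values = getattr(matrix, which)
    write_table_tsv(list(matrix.individuals), values, path)


def read_matrix_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a TSV written by :func:`write_table_tsv`; round-trip inverse."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ParseError(f"{path}: row and column labels differ")
    return [str(x) for x in df.index], df.to_numpy()


def sha256_of(path: str | Path) -> str:
    """Hex digest of a file, for run manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
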