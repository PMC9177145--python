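"""Eluted-peptide sets: reading, validation, merging and set algebra.

A :class:`PeptideSet` is the deduplicated collection of peptide
sequences eluted from (attributed to) a single HLA-C allotype.  Eluted
ligand lists from different studies covering the same allotype are
merged by exact-string union with per-peptide provenance labels;
duplicate sequences are removed.  Peptide abundance is deliberately not
modelled: every unique sequence counts once.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from .alphabet import MAX_LENGTH, MIN_LENGTH, is_valid_peptide
from .allotypes import AllotypeRecord

log = logging.getLogger(__name__)


class PeptideValidationError(ValueError):
    """A sequence failed alphabet validation; message names the line."""


@dataclass(frozen=True)
class PeptideSet:
    """Deduplicated peptides for one allotype with per-peptide sources.

    ``sources`` maps each peptide to a sorted tuple of source labels
    (which input list(s) it came from); sorting makes merges
    order-independent.
    """

    allotype: AllotypeRecord
    peptides: frozenset[str]
    sources: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for seq in self.peptides:
            if not is_valid_peptide(seq):
                raise PeptideValidationError(f"invalid peptide sequence {seq!r}")
            if not (MIN_LENGTH <= len(seq) <= MAX_LENGTH):
                raise ValueError(
                    f"peptide {seq!r} has length {len(seq)}, outside {MIN_LENGTH}-{MAX_LENGTH}"
                )

    def __len__(self) -> int:
        return len(self.peptides)

    def __contains__(self, seq: str) -> bool:
        return seq in self.peptides

    def stratum(self, length: int) -> "PeptideSet":
        """The subset of peptides with exactly ``length`` residues."""
        kept = frozenset(p for p in self.peptides if len(p) == length)
        return PeptideSet(
            allotype=self.allotype,
            peptides=kept,
            sources={p: self.sources.get(p, ()) for p in kept},
        )

    def lengths(self) -> dict[int, int]:
        """Histogram of peptide lengths present in the set."""
        out: dict[int, int] = {}
        for p in self.peptides:
            out[len(p)] = out.get(len(p), 0) + 1
        return dict(sorted(out.items()))

    def sorted_peptides(self) -> list[str]:
        return sorted(self.peptides)


def _build(allotype: AllotypeRecord, seqs: Iterable[str], source: str) -> PeptideSet:
    uniq = frozenset(seqs)
    return PeptideSet(allotype, uniq, {p: (source,) if source else () for p in uniq})


def read_peptide_list(
    path: str | Path,
    fmt: Literal["lines", "csv"] = "lines",
    allotype: AllotypeRecord | None = None,
    source: str | None = None,
) -> PeptideSet | dict[str, PeptideSet]:
    """Read a peptide list from disk, validating and deduplicating.

    Two formats are supported: ``lines`` (one peptide per line, the
    target allotype given via ``allotype``) and ``csv`` (columns
    ``allotype,peptide[,source]``; returns a dict keyed by allotype
    name, records looked up in the bundled panel).

    Sequences are uppercased; a character outside the 20-letter alphabet
    raises :class:`PeptideValidationError` naming the line number.
    Sequences outside the 8-15 length range are dropped with a logged
    count (they are valid peptides but outside the analysis range).
    """
    path = Path(path)
    if source is None:
        source = path.name

    if fmt == "lines":
        if allotype is None:
            raise ValueError("format 'lines' requires an allotype record")
        seqs = _read_lines(path)
        if not seqs:
            log.warning("%s: empty peptide list", path)
        return _build(allotype, seqs, source)

    if fmt == "csv":
        from .allotypes import lookup_allotype

        per_allotype: dict[str, list[str]] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"allotype", "peptide"} <= set(reader.fieldnames):
                raise ValueError(f"{path}: expected CSV columns allotype,peptide")
            n_dropped = 0
            for lineno, row in enumerate(reader, start=2):
                seq = row["peptide"].strip().upper()
                if not is_valid_peptide(seq):
                    raise PeptideValidationError(
                        f"{path}:{lineno}: invalid peptide sequence {seq!r}"
                    )
                if not (MIN_LENGTH <= len(seq) <= MAX_LENGTH):
                    n_dropped += 1
                    continue
                per_allotype.setdefault(row["allotype"].strip(), []).append(seq)
        if n_dropped:
            log.warning("%s: dropped %d peptides outside length %d-%d", path, n_dropped, MIN_LENGTH, MAX_LENGTH)
        out: dict[str, PeptideSet] = {}
        for name, seqs in per_allotype.items():
            rec = lookup_allotype(name) if allotype is None else allotype
            out[name] = _build(rec, seqs, source)
        return out

    raise ValueError(f"unknown format {fmt!r}")


def _read_lines(path: Path) -> list[str]:
    seqs: list[str] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            seq = line.strip().upper()
            if not seq:
                continue
            if not is_valid_peptide(seq):
                raise PeptideValidationError(f"{path}:{lineno}: invalid peptide sequence {seq!r}")
            if not (MIN_LENGTH <= len(seq) <= MAX_LENGTH):
                n_dropped += 1
                continue
            seqs.append(seq)
    if n_dropped:
        log.warning("%s: dropped %d peptides outside length %d-%d", path, n_dropped, MIN_LENGTH, MAX_LENGTH)
    return seqs


def peptide_set(allotype: AllotypeRecord, seqs: Iterable[str], source: str = "") -> PeptideSet:
    """Construct a PeptideSet in memory (deduplicating, uppercasing)."""
    return _build(allotype, (s.upper() for s in seqs), source)


def merge_datasets(sets: list[PeptideSet]) -> PeptideSet:
    """Union the peptide lists for one allotype across studies.

    Duplicate sequences are removed; the merged per-peptide source
    labels are the sorted union of the inputs' labels, so the merge is
    idempotent and order-independent.
    """
    if not sets:
        raise ValueError("merge_datasets requires at least one PeptideSet")
    names = {s.allotype.name for s in sets}
    if len(names) != 1:
        raise ValueError(f"cannot merge peptide sets of different allotypes: {sorted(names)}")
    merged: dict[str, set[str]] = {}
    for s in sets:
        for p in s.peptides:
            merged.setdefault(p, set()).update(s.sources.get(p, ()))
    return PeptideSet(
        allotype=sets[0].allotype,
        peptides=frozenset(merged),
        sources={p: tuple(sorted(labels)) for p, labels in merged.items()},
    )


def partition_unique_shared(
    a: PeptideSet, b: PeptideSet, length: int
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Split two length-stratified sets into (unique-to-a, unique-to-b, shared).

    This is the unique/shared decomposition used to contrast the
    repertoires of two allotypes position by position: sequences bound
    by both carry no group information, so correlations are computed on
    the unique fractions.
    """
    sa = frozenset(p for p in a.peptides if len(p) == length)
    sb = frozenset(p for p in b.peptides if len(p) == length)
    if not sa:
        raise ValueError(f"no {length}mers in set for {a.allotype.name}")
    if not sb:
        raise ValueError(f"no {length}mers in set for {b.allotype.name}")
    shared = sa & sb
    return sa - shared, sb - shared, shared


def write_peptide_csv(sets: Iterable[PeptideSet], path: str | Path) -> None:
    """Write merged per-allotype peptide lists with provenance columns."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["allotype", "peptide", "length", "sources"])
        for s in sets:
            for p in s.sorted_peptides():
                writer.writerow([s.allotype.name, p, len(p), ";".join(s.sources.get(p, ()))])
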