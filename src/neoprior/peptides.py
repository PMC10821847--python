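"""Mutant/wild-type peptide design.

Two peptide forms are produced per mutation:

* the **long** (default 17-aa) synthesis form, mutation-centered with
  (len-1)/2 flanking residues on each side, truncated asymmetrically at
  protein termini (the short side keeps whatever is available; the other
  side is never extended beyond its own flank);
* the **short** MHC-I windows: for each preferred epitope length k, every
  k-mer of the mutant protein that covers the mutated residue.

All intervals are 1-based and closed, so the validated H-2Kb epitope of
Mapkbp1_W204C spans 199-206 and carries the mutant residue at offset 6.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io_core import (
    _AA_SET,
    MhcAllele,
    Proteome,
    SomaticVariant,
    ThresholdConfig,
    ValidationError,
    logger,
)


class ReferenceMismatchError(ValidationError):
    """The protein residue at the mutation site is not the expected one."""


@dataclass(frozen=True)
class PeptideCandidate:
    """A mutant or wild-type peptide with its position bookkeeping.

    ``start`` is the 1-based protein position of the first residue and
    ``mut_offset`` the 1-based position of the mutation site within the
    peptide (set for wild-type partners too, marking the differing site).
    """

    sequence: str
    source_id: str
    kind: str           # "mutant" | "wildtype"
    form: str           # "long" | "short"
    start: int
    mut_offset: int

    def __post_init__(self) -> None:
        if not 8 <= len(self.sequence) <= 17:
            raise ValidationError(
                f"{self.source_id}: peptide length {len(self.sequence)} "
                f"outside [8, 17]"
            )
        if self.kind not in ("mutant", "wildtype"):
            raise ValidationError(f"unknown peptide kind {self.kind!r}")
        if self.form not in ("long", "short"):
            raise ValidationError(f"unknown peptide form {self.form!r}")
        if not 1 <= self.mut_offset <= len(self.sequence):
            raise ValidationError(
                f"{self.source_id}: mut_offset {self.mut_offset} outside peptide"
            )

    @property
    def end(self) -> int:
        """1-based protein position of the last residue (closed interval)."""
        return self.start + len(self.sequence) - 1


def apply_mutation(proteome: Proteome, v: SomaticVariant) -> str:
    """Return the mutant protein sequence (one substitution).

    Raises :class:`ReferenceMismatchError` if the wild-type residue at the
    mutation position does not match the variant's reference residue.
    """
    if v.gene not in proteome:
        raise ValidationError(f"gene {v.gene!r} not in proteome")
    wild = proteome[v.gene]
    if not 1 <= v.protein_pos <= len(wild):
        raise ValidationError(
            f"{v.id}: position {v.protein_pos} outside protein of "
            f"length {len(wild)}"
        )
    found = wild[v.protein_pos - 1]
    if found != v.ref_aa:
        raise ReferenceMismatchError(
            f"reference mismatch for {v.gene} at position {v.protein_pos}: "
            f"expected {v.ref_aa!r}, found {found!r}"
        )
    return wild[: v.protein_pos - 1] + v.alt_aa + wild[v.protein_pos:]


def _has_standard_residues(seq: str) -> bool:
    return all(aa in _AA_SET for aa in seq)


def design_long_peptide(
    proteome: Proteome,
    v: SomaticVariant,
    cfg: ThresholdConfig,
) -> tuple[PeptideCandidate, PeptideCandidate]:
    """Design the mutation-centered long synthesis peptide and its
    wild-type partner over the identical interval.

    The window is centered on the mutation with flank = (len-1)/2 on each
    side; at a terminus the short side is truncated and the other side is
    NOT extended (keeping the natural flanking context).  The pair differs
    at exactly the mutation offset.
    """
    wild = proteome[v.gene]
    mutant = apply_mutation(proteome, v)
    L = len(wild)
    if L < 8:
        raise ValidationError(
            f"{v.id}: protein length {L} too short for peptide design (< 8)"
        )
    flank = (cfg.long_peptide_len - 1) // 2
    start = max(1, v.protein_pos - flank)
    end = min(L, v.protein_pos + flank)
    mut_offset = v.protein_pos - start + 1
    mut_seq = mutant[start - 1 : end]
    wt_seq = wild[start - 1 : end]
    for seq in (mut_seq, wt_seq):
        if not _has_standard_residues(seq):
            logger.warning("%s: long peptide contains non-standard residues; dropped", v.id)
            raise ValidationError(f"{v.id}: non-standard residues in long peptide")
    mut_pep = PeptideCandidate(mut_seq, v.id, "mutant", "long", start, mut_offset)
    wt_pep = PeptideCandidate(wt_seq, v.id, "wildtype", "long", start, mut_offset)
    return mut_pep, wt_pep


def window_count(L: int, pos: int, k: int) -> int:
    """Closed-form number of k-mer windows of a length-L protein covering
    position ``pos``: min(pos, L-k+1) - max(1, pos-k+1) + 1 (0 if k > L)."""
    if k > L:
        return 0
    return min(pos, L - k + 1) - max(1, pos - k + 1) + 1


def enumerate_epitopes(
    proteome: Proteome,
    v: SomaticVariant,
    allele: MhcAllele,
) -> list[PeptideCandidate]:
    """Every short mutant peptide covering the mutation, per allele length.

    Windows are emitted left-to-right for each k in the allele's preferred
    lengths.  Peptides with non-standard residues are dropped with a
    warning (they cannot be synthesized or scored).
    """
    mutant = apply_mutation(proteome, v)
    L = len(mutant)
    out: list[PeptideCandidate] = []
    for k in allele.preferred_lengths:
        lo = max(1, v.protein_pos - k + 1)
        hi = min(v.protein_pos, L - k + 1)
        for start in range(lo, hi + 1):
            seq = mutant[start - 1 : start - 1 + k]
            if not _has_standard_residues(seq):
                logger.warning("%s: window %d-%d has non-standard residues; dropped",
                               v.id, start, start + k - 1)
                continue
            out.append(PeptideCandidate(
                sequence=seq, source_id=v.id, kind="mutant", form="short",
                start=start, mut_offset=v.protein_pos - start + 1,
            ))
    return out


PEPTIDE_COLUMNS = ("source_id", "kind", "form", "start", "end", "mut_offset", "sequence")


def write_peptides_tsv(peptides: Iterable[PeptideCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PEPTIDE_COLUMNS) + "\n")
        for p in peptides:
            fh.write(f"{p.source_id}\t{p.kind}\t{p.form}\t{p.start}\t{p.end}"
                     f"\t{p.mut_offset}\t{p.sequence}\n")


def read_peptides_tsv(path: str | Path) -> list[PeptideCandidate]:
    peptides = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PEPTIDE_COLUMNS:
            raise ValidationError(f"{path}: unexpected peptide header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            sid, kind, form, start, _end, off, seq = line.split("\t")
            peptides.append(PeptideCandidate(
                sequence=seq, source_id=sid, kind=kind, form=form,
                start=int(start), mut_offset=int(off),
            ))
    return peptides


def design_all(
    proteome: Proteome,
    variants: Sequence[SomaticVariant],
    allele: MhcAllele,
    cfg: ThresholdConfig,
) -> list[PeptideCandidate]:
    """Long mutant/wild-type pair plus all short windows for each variant."""
    out: list[PeptideCandidate] = []
    for v in variants:
        mut_long, wt_long = design_long_peptide(proteome, v, cfg)
        out.extend((mut_long, wt_long))
        out.extend(enumerate_epitopes(proteome, v, allele))
    logger.info("peptides: designed %d candidates for %d variants",
                len(out), len(variants))
    return out
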