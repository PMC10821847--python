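"""Domain types, file formats, configuration and logging for the pipeline.

The pipeline operates at the protein level: a somatic missense variant is a
gene symbol plus a protein-level substitution (e.g. ``Mapkbp1_W204C``) with
its RNA evidence (variant allele frequency, read depth, and the parent
gene's TPM).  Genomic coordinates never enter the computation.

Positions are 1-based throughout, matching the ``W204C`` mutation notation
and closed epitope intervals such as 199-206.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("neoprior")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Index of each standard residue in PSSM weight matrices.
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class ValidationError(ValueError):
    """Malformed or out-of-range input data."""


class MutationIdError(ValidationError):
    """A mutation identifier that does not parse as <gene>_<AA><pos><AA>."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SomaticVariant:
    """A somatic missense mutation with RNA-level evidence.

    Attributes
    ----------
    gene : str
        Gene symbol of the parent gene.
    ref_aa, alt_aa : str
        Single-letter wild-type and mutant residues; must differ.
    protein_pos : int
        1-based residue index of the substitution in the protein.
    vaf : float
        Variant allele frequency in [0, 1].
    depth : int
        Read depth supporting the call (non-negative).
    tpm : float or None
        Transcripts-per-million of the parent gene; ``None`` when no
        expression evidence has been joined yet (treated as failing the
        expression rule downstream).
    """

    gene: str
    ref_aa: str
    protein_pos: int
    alt_aa: str
    vaf: float
    depth: int
    tpm: float | None = None

    def __post_init__(self) -> None:
        if self.ref_aa not in _AA_SET or self.alt_aa not in _AA_SET:
            raise ValidationError(
                f"{self.gene}: residues must be standard amino acids, got "
                f"{self.ref_aa!r}->{self.alt_aa!r}"
            )
        if self.ref_aa == self.alt_aa:
            raise ValidationError(
                f"{self.gene}: reference and alternate residue are both "
                f"{self.ref_aa!r}"
            )
        if self.protein_pos < 1:
            raise ValidationError(f"{self.gene}: protein position must be >= 1")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"{self.id}: VAF {self.vaf} outside [0, 1]")
        if self.depth < 0:
            raise ValidationError(f"{self.id}: negative depth {self.depth}")
        if self.tpm is not None and self.tpm < 0:
            raise ValidationError(f"{self.id}: negative TPM {self.tpm}")

    @property
    def id(self) -> str:
        """Canonical label ``<gene>_<ref><pos><alt>``."""
        return f"{self.gene}_{self.ref_aa}{self.protein_pos}{self.alt_aa}"

    @property
    def protein_change(self) -> str:
        return f"{self.ref_aa}{self.protein_pos}{self.alt_aa}"

    def with_tpm(self, tpm: float | None) -> "SomaticVariant":
        return replace(self, tpm=tpm)


@dataclass
class Proteome:
    """Mapping of gene symbol to amino-acid sequence (one protein per gene)."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        for gene, seq in self.records.items():
            if not seq:
                raise ValidationError(f"empty sequence for gene {gene!r}")

    def __contains__(self, gene: str) -> bool:
        return gene in self.records

    def __getitem__(self, gene: str) -> str:
        return self.records[gene]

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Proteome) and self.records == other.records


@dataclass(frozen=True)
class MhcAllele:
    """An MHC class I allele and the epitope lengths it presents.

    H-2Kb (the C57BL/6 mouse allele) canonically presents 8-9-mers, hence
    the default ``preferred_lengths``.
    """

    name: str = "H-2-Kb"
    preferred_lengths: tuple[int, ...] = (8, 9)

    def __post_init__(self) -> None:
        if not self.preferred_lengths:
            raise ValidationError("preferred_lengths must be non-empty")
        for k in self.preferred_lengths:
            if not 8 <= k <= 11:
                raise ValidationError(f"epitope length {k} outside [8, 11]")


@dataclass
class ThresholdConfig:
    """Every tunable threshold of the prioritization pipeline.

    Defaults are the study's published operating points: expression filter
    VAF >= 10%, depth >= 20, TPM >= 1; consensus cutoff median percentile
    rank <= 2%; top 20 mutations carried to synthesis as 17-aa long
    peptides; ELISPOT selection at strictly more than 100 spots.
    """

    min_vaf: float = 0.10
    min_depth: int = 20
    min_tpm: float = 1.0
    max_median_rank: float = 2.0
    top_n: int = 20
    min_spots: int = 100
    long_peptide_len: int = 17
    #: minimum predictors that must score a peptide for its median to count
    min_predictors: int = 4
    #: minimum mutant-supporting reads for a cell to count as mutant
    min_alt_reads: int = 1
    #: significance level for cross-reactivity and group comparisons
    alpha: float = 0.05

    def __post_init__(self) -> None:
        numeric = (
            self.min_vaf, self.min_depth, self.min_tpm, self.max_median_rank,
            self.top_n, self.min_spots, self.long_peptide_len,
            self.min_predictors, self.min_alt_reads, self.alpha,
        )
        if any(x < 0 for x in numeric):
            raise ValidationError("thresholds must be non-negative")
        if self.long_peptide_len % 2 == 0:
            raise ValidationError(
                f"long_peptide_len must be odd to center the mutation, "
                f"got {self.long_peptide_len}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "ThresholdConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**dict(data))

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# Mutation identifiers
# ---------------------------------------------------------------------------

_MUTID_RE = re.compile(r"^(?P<gene>[^_\s]+)_(?P<ref>[A-Za-z])(?P<pos>\d+)(?P<alt>[A-Za-z])$")


def parse_mutation_id(mut_id: str) -> tuple[str, str, int, str]:
    """Parse ``<gene>_<ref><pos><alt>`` into (gene, ref_aa, pos, alt_aa).

    >>> parse_mutation_id("Mapkbp1_W204C")
    ('Mapkbp1', 'W', 204, 'C')
    """
    m = _MUTID_RE.match(mut_id)
    if m is None:
        raise MutationIdError(
            f"mutation id {mut_id!r} does not match <gene>_<AA><pos><AA>"
        )
    gene, ref, pos_s, alt = m.group("gene", "ref", "pos", "alt")
    ref, alt = ref.upper(), alt.upper()
    if ref not in _AA_SET:
        raise MutationIdError(f"{mut_id!r}: {ref!r} is not an amino acid")
    if alt not in _AA_SET:
        raise MutationIdError(f"{mut_id!r}: {alt!r} is not an amino acid")
    if ref == alt:
        raise MutationIdError(
            f"{mut_id!r}: reference and alternate residue are identical ({ref!r})"
        )
    pos = int(pos_s)
    if pos < 1:
        raise MutationIdError(f"{mut_id!r}: position must be >= 1, got {pos}")
    return gene, ref, pos, alt


def format_mutation_id(gene: str, ref_aa: str, protein_pos: int, alt_aa: str) -> str:
    """Inverse of :func:`parse_mutation_id`."""
    return f"{gene}_{ref_aa}{protein_pos}{alt_aa}"


# ---------------------------------------------------------------------------
# Variant tables (TSV canonical; minimal VCF dialect)
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = ("gene", "protein_change", "vaf", "depth", "tpm")


def _variant_from_fields(gene: str, pchange: str, vaf: str, depth: str,
                         tpm: str, where: str) -> SomaticVariant:
    gene_parsed, ref, pos, alt = parse_mutation_id(f"{gene}_{pchange}")
    try:
        vaf_f = float(vaf)
        depth_i = int(float(depth))
        tpm_f = None if tpm in ("", "NA", "nan", ".") else float(tpm)
    except ValueError as exc:
        raise ValidationError(f"{where}: non-numeric field ({exc})") from None
    try:
        return SomaticVariant(gene=gene_parsed, ref_aa=ref, protein_pos=pos,
                              alt_aa=alt, vaf=vaf_f, depth=depth_i, tpm=tpm_f)
    except ValidationError as exc:
        raise ValidationError(f"{where}: {exc}") from None


def read_variants_tsv(path: str | Path) -> list[SomaticVariant]:
    """Read the canonical variant TSV (gene, protein_change, vaf, depth, tpm).

    The ``tpm`` column may be empty/NA when expression is joined later.
    Raises :class:`ValidationError` with the offending line number.
    """
    variants: list[SomaticVariant] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in VARIANT_COLUMNS[:4] if c not in header]
        if missing:
            raise ValidationError(f"{path}: missing columns {missing}")
        idx = {c: header.index(c) for c in header}
        has_tpm = "tpm" in idx
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ValidationError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            variants.append(_variant_from_fields(
                fields[idx["gene"]], fields[idx["protein_change"]],
                fields[idx["vaf"]], fields[idx["depth"]],
                fields[idx["tpm"]] if has_tpm else "",
                where=f"{path}:{lineno}",
            ))
    return variants


def write_variants_tsv(variants: Iterable[SomaticVariant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(VARIANT_COLUMNS) + "\n")
        for v in variants:
            tpm = "" if v.tpm is None else format(v.tpm, "g")
            fh.write(f"{v.gene}\t{v.protein_change}\t{v.vaf:g}\t{v.depth}\t{tpm}\n")


#: INFO keys of the minimal VCF dialect carrying protein-level annotation.
VCF_INFO_KEYS = ("GENE", "PCHANGE", "VAF", "DP")


def read_variants_vcf(path: str | Path) -> list[SomaticVariant]:
    """Read variants from the documented minimal VCF dialect.

    Protein-level annotation travels in INFO keys GENE, PCHANGE, VAF and
    DP; genomic coordinates are ignored (the pipeline is protein-level).
    """
    from cyvcf2 import VCF

    variants: list[SomaticVariant] = []
    for i, rec in enumerate(VCF(str(path)), start=1):
        info = {k: rec.INFO.get(k) for k in VCF_INFO_KEYS}
        missing = [k for k, val in info.items() if val is None]
        if missing:
            raise ValidationError(
                f"{path}: record {i}: missing INFO keys {missing}"
            )
        variants.append(_variant_from_fields(
            str(info["GENE"]), str(info["PCHANGE"]), str(info["VAF"]),
            str(info["DP"]), "", where=f"{path}: record {i}",
        ))
    return variants


def read_variants(path: str | Path, format: str | None = None) -> list[SomaticVariant]:
    """Read a variant table; format inferred from the extension if omitted."""
    if format is None:
        format = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "tsv":
        return read_variants_tsv(path)
    if format == "vcf":
        return read_variants_vcf(path)
    raise ValidationError(f"unknown variant format {format!r}")


# ---------------------------------------------------------------------------
# Expression table and FASTA
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> dict[str, float]:
    """Read the two-column gene -> TPM table."""
    tpm: dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene", "tpm"]:
            raise ValidationError(f"{path}: expected header 'gene\\ttpm'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            gene, value = line.split("\t")[:2]
            if gene in tpm:
                raise ValidationError(f"{path}:{lineno}: duplicate gene {gene!r}")
            try:
                tpm[gene] = float(value)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: non-numeric TPM {value!r}"
                ) from None
    return tpm


def write_expression_table(tpm: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\ttpm\n")
        for gene, value in tpm.items():
            fh.write(f"{gene}\t{value:g}\n")


def read_fasta(path: str | Path) -> Proteome:
    """Read a protein FASTA into a :class:`Proteome` (unique IDs required)."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValidationError(f"{path}: duplicate gene symbol {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return Proteome(records)


def write_fasta(proteome: Proteome, path: str | Path, wrap: int = 60) -> None:
    recs = [SeqRecord(Seq(seq), id=gene, description="")
            for gene, seq in proteome.records.items()]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=wrap)
    writer.write_file(recs)


def setup_logging(level: int = logging.INFO) -> None:
    """Send per-stage record counts and warnings to stderr."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("[%(levelname)s] %(name)s: %(message)s"))
    logger.handlers.clear()
    logger.addHandler(handler)
    logger.setLevel(level)
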