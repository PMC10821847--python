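"""MHC-I binding prediction: pluggable predictor ensemble and consensus.

Real predictor output enters as a long-form percentile-rank table
(peptide, predictor, rank in [0, 100], lower = stronger).  For
self-contained runs a mock ensemble of eight position-specific scoring
matrix (PSSM) predictors — one per published algorithm name, prefixed
``mock-`` — scores peptides and calibrates each raw score to a percentile
rank against a background of proteome-derived peptides:

    rank = 100 * #{background with raw score >= score} / B

(ties count against the candidate, the conservative choice).  The
consensus statistic is the per-peptide **median** rank across predictors;
a mutation's score is the minimum median over its spanning windows
(best-epitope convention), and it passes at median rank <= 2% (inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_core import (
    AA_INDEX,
    AMINO_ACIDS,
    MhcAllele,
    Proteome,
    SomaticVariant,
    ThresholdConfig,
    ValidationError,
    logger,
)
from .peptides import PeptideCandidate

#: The eight published algorithms the mock ensemble stands in for.
MOCK_PREDICTOR_NAMES = (
    "mock-NetMHCpan", "mock-NetMHC", "mock-NetMHCcons", "mock-PickPocket",
    "mock-MHCflurry", "mock-SMM", "mock-SMMPBMC", "mock-MHCnuggetsI",
)


def encode_peptide(peptide: str) -> np.ndarray:
    """Map a peptide to residue indices; raises on non-standard residues."""
    try:
        return np.array([AA_INDEX[aa] for aa in peptide], dtype=np.intp)
    except KeyError as exc:
        raise ValidationError(f"non-standard residue {exc} in {peptide!r}") from None


# ---------------------------------------------------------------------------
# Mock PSSM predictor
# ---------------------------------------------------------------------------

@dataclass
class PssmPredictor:
    """A fixed-length PSSM scorer calibrated against a background set.

    ``score_offsets`` holds per-sequence adjustments used by the synthetic
    generator to plant binders of chosen strength; background peptides are
    essentially never affected (an offset applies to one exact sequence),
    so the percentile calibration of all other peptides is untouched.
    """

    name: str
    allele: str
    length: int
    weights: np.ndarray                      # (length, 20)
    background_scores: np.ndarray            # sorted ascending, length B
    score_offsets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weights.shape != (self.length, 20):
            raise ValidationError(
                f"{self.name}: weight matrix shape {self.weights.shape} != "
                f"({self.length}, 20)"
            )
        if self.background_scores.size == 0:
            raise ValidationError(f"{self.name}: empty background")

    def score(self, peptide: str) -> float:
        """Raw score: PSSM sum plus any planted per-sequence offset."""
        return pssm_score(self, peptide) + self.score_offsets.get(peptide, 0.0)

    def percentile_rank(self, peptide: str) -> float:
        """Percentile rank in [0, 100]; 0 when the peptide beats the whole
        background, 100 when every background peptide scores at least as
        well."""
        s = self.score(peptide)
        bg = self.background_scores
        n_ge = bg.size - np.searchsorted(bg, s, side="left")
        return 100.0 * float(n_ge) / bg.size


def pssm_score(p: PssmPredictor, peptide: str) -> float:
    """Pure position-specific score: sum_i weights[i, residue_i]."""
    if len(peptide) != p.length:
        raise ValidationError(
            f"{p.name}: peptide length {len(peptide)} != predictor length "
            f"{p.length}"
        )
    codes = encode_peptide(peptide)
    return float(p.weights[np.arange(p.length), codes].sum())


def percentile_rank(p: PssmPredictor, peptide: str) -> float:
    return p.percentile_rank(peptide)


def _sample_background(proteome: Proteome, k: int, n: int,
                       rng: np.random.Generator) -> list[str]:
    """Random k-mers from the proteome (with replacement across proteins)."""
    genes = sorted(proteome.records)
    lengths = np.array([len(proteome.records[g]) for g in genes])
    eligible = np.flatnonzero(lengths >= k)
    if eligible.size == 0:
        raise ValidationError(f"no protein of length >= {k} for background")
    picks = rng.choice(eligible, size=n)
    out = []
    for gi in picks:
        seq = proteome.records[genes[gi]]
        start = int(rng.integers(0, len(seq) - k + 1))
        out.append(seq[start : start + k])
    return out


def _score_many(weights: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Vectorized PSSM scores for an (n, k) residue-index matrix."""
    k = weights.shape[0]
    return weights[np.arange(k)[None, :], codes].sum(axis=1)


@dataclass
class MockEnsemble:
    """Eight named mock predictors, each with one PSSM per epitope length."""

    allele: MhcAllele
    models: dict[str, dict[int, PssmPredictor]]

    @property
    def predictor_names(self) -> list[str]:
        return list(self.models)

    def rank(self, name: str, peptide: str) -> float:
        model = self.models[name].get(len(peptide))
        if model is None:
            raise ValidationError(
                f"{name}: no model for peptide length {len(peptide)}"
            )
        return model.percentile_rank(peptide)


def make_mock_ensemble(
    proteome: Proteome,
    allele: MhcAllele,
    seed: int,
    n_background: int = 10_000,
    names: Sequence[str] = MOCK_PREDICTOR_NAMES,
) -> MockEnsemble:
    """Build the deterministic mock predictor ensemble.

    Each (predictor, length) pair gets an independent standard-normal PSSM
    and its own proteome background of ``n_background`` peptides, so ranks
    of random peptides are approximately uniform on (0, 100] and
    independent across predictors.
    """
    root = np.random.default_rng(seed)
    models: dict[str, dict[int, PssmPredictor]] = {}
    for name in names:
        models[name] = {}
        for k in allele.preferred_lengths:
            rng = np.random.default_rng(root.integers(0, 2**31))
            weights = rng.normal(0.0, 1.0, size=(k, 20))
            bg = _sample_background(proteome, k, n_background, rng)
            codes = np.array([[AA_INDEX[aa] for aa in pep] for pep in bg],
                             dtype=np.intp)
            scores = np.sort(_score_many(weights, codes))
            models[name][k] = PssmPredictor(
                name=name, allele=allele.name, length=k,
                weights=weights, background_scores=scores,
            )
    return MockEnsemble(allele=allele, models=models)


# ---------------------------------------------------------------------------
# Rank matrix
# ---------------------------------------------------------------------------

@dataclass
class PredictorRankMatrix:
    """Long-form store of percentile ranks per (peptide, predictor)."""

    predictors: list[str]
    ranks: dict[str, dict[str, float]] = field(default_factory=dict)

    def add(self, peptide: str, predictor: str, rank: float) -> None:
        if not 0.0 <= rank <= 100.0:
            raise ValidationError(
                f"rank {rank} for {peptide}/{predictor} outside [0, 100]"
            )
        self.ranks.setdefault(peptide, {})[predictor] = rank

    def ranks_for(self, peptide: str) -> dict[str, float]:
        return self.ranks.get(peptide, {})

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("peptide\tpredictor\trank\n")
            for peptide in self.ranks:
                cells = self.ranks[peptide]
                for predictor in self.predictors:
                    if predictor in cells:
                        fh.write(f"{peptide}\t{predictor}\t{cells[predictor]:.6g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PredictorRankMatrix":
        predictors: list[str] = []
        matrix = cls(predictors=predictors)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["peptide", "predictor", "rank"]:
                raise ValidationError(f"{path}: unexpected rank header {header}")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                peptide, predictor, rank = line.split("\t")
                if predictor not in predictors:
                    predictors.append(predictor)
                try:
                    matrix.add(peptide, predictor, float(rank))
                except (ValueError, ValidationError) as exc:
                    raise ValidationError(f"{path}:{lineno}: {exc}") from None
        return matrix


def rank_peptides(
    ensemble: MockEnsemble,
    peptides: Iterable[PeptideCandidate | str],
) -> PredictorRankMatrix:
    """Score every (short) peptide with every mock predictor."""
    matrix = PredictorRankMatrix(predictors=list(ensemble.predictor_names))
    seen: set[str] = set()
    for pep in peptides:
        seq = pep if isinstance(pep, str) else pep.sequence
        if seq in seen:
            continue
        seen.add(seq)
        for name in ensemble.predictor_names:
            matrix.add(seq, name, ensemble.rank(name, seq))
    return matrix


# ---------------------------------------------------------------------------
# Consensus and prioritization
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    """Per-mutation aggregate of predictor percentile ranks."""

    mutation_id: str
    per_peptide_median: dict[str, float]
    best_peptide: str | None
    best_median_rank: float | None
    passes: bool
    unscored: bool = False
    #: peptides with partial (but sufficient) predictor coverage
    low_coverage: list[str] = field(default_factory=list)


def consensus(
    variants: Sequence[SomaticVariant],
    peptides: Sequence[PeptideCandidate],
    matrix: PredictorRankMatrix,
    cfg: ThresholdConfig,
) -> list[ConsensusResult]:
    """Median-rank consensus per peptide, min over peptides per mutation.

    A peptide needs ranks from at least ``cfg.min_predictors`` predictors
    (capped at the number of predictors in the matrix) to receive a
    median; with fewer it is unscored.  An even rank count takes the mean
    of the two central values (ordinary median).  A mutation with no
    scored peptide is flagged unscored and excluded from the pass set.
    """
    n_predictors = len(matrix.predictors)
    need = min(cfg.min_predictors, n_predictors) if n_predictors else cfg.min_predictors
    by_variant: dict[str, list[PeptideCandidate]] = {}
    for p in peptides:
        if p.form == "short" and p.kind == "mutant":
            by_variant.setdefault(p.source_id, []).append(p)

    results = []
    for v in variants:
        windows = by_variant.get(v.id, [])
        medians: dict[str, float] = {}
        low_cov: list[str] = []
        for p in windows:
            cells = matrix.ranks_for(p.sequence)
            if len(cells) < need:
                continue
            if len(cells) < n_predictors:
                low_cov.append(p.sequence)
            medians[p.sequence] = float(np.median(list(cells.values())))
        if not medians:
            logger.warning("consensus: %s has no scored peptide; excluded", v.id)
            results.append(ConsensusResult(
                mutation_id=v.id, per_peptide_median={}, best_peptide=None,
                best_median_rank=None, passes=False, unscored=True,
            ))
            continue
        best_peptide = min(medians, key=lambda s: (medians[s], s))
        best = medians[best_peptide]
        results.append(ConsensusResult(
            mutation_id=v.id, per_peptide_median=medians,
            best_peptide=best_peptide, best_median_rank=best,
            passes=best <= cfg.max_median_rank, low_coverage=low_cov,
        ))
    n_pass = sum(r.passes for r in results)
    logger.info("consensus: %d/%d mutations at median rank <= %g%%",
                n_pass, len(results), cfg.max_median_rank)
    return results


def prioritize(
    results: Sequence[ConsensusResult],
    variants: Sequence[SomaticVariant],
    cfg: ThresholdConfig,
) -> list[ConsensusResult]:
    """Top-N passing mutations: ascending best median rank, ties broken by
    descending TPM, then descending VAF, then mutation id."""
    by_id = {v.id: v for v in variants}

    def key(r: ConsensusResult):
        v = by_id.get(r.mutation_id)
        tpm = v.tpm if v is not None and v.tpm is not None else 0.0
        vaf = v.vaf if v is not None else 0.0
        return (r.best_median_rank, -tpm, -vaf, r.mutation_id)

    passing = sorted((r for r in results if r.passes), key=key)
    return passing[: cfg.top_n]


CONSENSUS_COLUMNS = ("mutation_id", "best_peptide", "best_median_rank", "passes")


def write_consensus_tsv(results: Iterable[ConsensusResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CONSENSUS_COLUMNS) + "\n")
        for r in results:
            rank = "" if r.best_median_rank is None else f"{r.best_median_rank:.6g}"
            fh.write(f"{r.mutation_id}\t{r.best_peptide or ''}\t{rank}"
                     f"\t{int(r.passes)}\n")
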