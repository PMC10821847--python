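"""Single-cell quantification of neoantigen expression.

Two read-outs, mirroring what droplet scRNA-seq can resolve about a
vaccine's targets:

* a per-cell **signature score** for the set of parent genes of the
  vaccine mutations, computed as the binned-control module score
  (signature mean minus the mean of expression-matched control genes
  drawn from bins of similar average expression);
* the per-group **proportion of tumor cells with detected mutant
  alleles**: among tumor cells with at least one read covering any of
  the queried mutation sites, the fraction carrying at least
  ``min_alt_reads`` mutant-supporting reads at any site.

Group comparisons use Fisher's exact test (proportions) and the
two-sided Wilcoxon rank-sum test (scores) against a reference group;
both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ValidationError, logger


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class CellSiteCounts:
    """Reference/mutant read counts at each queried site for one cell."""

    cell: str
    group: str
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)  # site -> (ref, alt)

    def __post_init__(self) -> None:
        for site, (ref, alt) in self.counts.items():
            if ref < 0 or alt < 0:
                raise ValidationError(f"{self.cell}/{site}: negative read count")

    def covers(self, sites: Iterable[str]) -> bool:
        return any(sum(self.counts.get(s, (0, 0))) >= 1 for s in sites)

    def has_mutant(self, sites: Iterable[str], min_alt_reads: int = 1) -> bool:
        return any(self.counts.get(s, (0, 0))[1] >= min_alt_reads for s in sites)


CELL_COUNT_COLUMNS = ("cell", "group", "site_id", "ref_reads", "alt_reads")


def read_cell_counts_tsv(path: str | Path) -> list[CellSiteCounts]:
    cells: dict[str, CellSiteCounts] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != CELL_COUNT_COLUMNS:
            raise ValidationError(f"{path}: unexpected cell-count header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cell, group, site, ref, alt = line.split("\t")
            if cell not in cells:
                cells[cell] = CellSiteCounts(cell=cell, group=group)
            elif cells[cell].group != group:
                raise ValidationError(
                    f"{path}:{lineno}: cell {cell!r} assigned to two groups"
                )
            cells[cell].counts[site] = (int(ref), int(alt))
    return list(cells.values())


def write_cell_counts_tsv(cells: Iterable[CellSiteCounts], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CELL_COUNT_COLUMNS) + "\n")
        for c in cells:
            for site, (ref, alt) in c.counts.items():
                fh.write(f"{c.cell}\t{c.group}\t{site}\t{ref}\t{alt}\n")


# ---------------------------------------------------------------------------
# Signature (module) score
# ---------------------------------------------------------------------------

def signature_score(
    expr: pd.DataFrame,
    signature: Sequence[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Binned-control module score per cell.

    Genes are ranked by mean expression across all cells and cut into
    ``n_bins`` equal-size bins; each signature gene contributes ``n_ctrl``
    control genes sampled (with replacement) from its bin.  The score is
    mean(signature expression) - mean(control expression) per cell, so a
    matrix where every gene is the same constant scores exactly 0, and a
    shift applied to *all* genes cancels.

    Parameters
    ----------
    expr : DataFrame
        cells x genes matrix of log-scale normalized expression.
    signature : sequence of str
        Gene symbols; all must be columns of ``expr``.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    missing = [g for g in signature if g not in expr.columns]
    if missing:
        raise ValidationError(f"signature genes absent from matrix: {missing}")
    if not np.isfinite(expr.values).all():
        raise ValidationError("expression matrix contains non-finite entries")

    gene_means = expr.mean(axis=0)
    order = gene_means.sort_values(kind="mergesort").index
    n_genes = len(order)
    # equal-occupancy bins over the mean-expression ranking
    bin_of = pd.Series(
        np.minimum((np.arange(n_genes) * n_bins) // n_genes, n_bins - 1),
        index=order,
    )
    by_bin = {b: idx.to_numpy() for b, idx in bin_of.groupby(bin_of).groups.items()}

    rng = np.random.default_rng(seed)
    sig_set = set(signature)
    control_genes: list[str] = []
    for g in signature:
        pool = np.array([x for x in by_bin[int(bin_of[g])] if x not in sig_set])
        if pool.size == 0:
            raise ValidationError(
                f"no control genes left in the expression bin of {g!r}; "
                f"increase the gene pool or lower n_bins"
            )
        control_genes.extend(rng.choice(pool, size=n_ctrl, replace=True))

    sig_mean = expr[list(signature)].mean(axis=1)
    ctrl_mean = expr[control_genes].mean(axis=1)
    score = sig_mean - ctrl_mean
    score.name = "signature_score"
    return score


# ---------------------------------------------------------------------------
# Mutant-allele proportions
# ---------------------------------------------------------------------------

@dataclass
class GroupProportion:
    group: str
    covered: int
    mutant: int

    @property
    def proportion(self) -> float | None:
        return self.mutant / self.covered if self.covered else None


def mutant_cell_proportion(
    cells: Sequence[CellSiteCounts],
    sites: Sequence[str],
    tumor_cells: set[str],
    min_alt_reads: int = 1,
) -> dict[str, GroupProportion]:
    """Per-group proportion of covered tumor cells with detected mutant
    alleles.

    Only tumor cells with at least one read covering any queried site
    enter the denominator; the numerator is those with at least
    ``min_alt_reads`` mutant reads at any site.  Groups with an empty
    denominator are reported with proportion ``None``.
    """
    if not sites:
        raise ValidationError("no mutation sites given")
    out: dict[str, GroupProportion] = {}
    for c in cells:
        if c.cell not in tumor_cells:
            continue
        gp = out.setdefault(c.group, GroupProportion(c.group, 0, 0))
        if not c.covers(sites):
            continue
        gp.covered += 1
        if c.has_mutant(sites, min_alt_reads):
            gp.mutant += 1
    for gp in out.values():
        if gp.covered == 0:
            logger.warning("group %s: no covered tumor cells; proportion undefined",
                           gp.group)
    return out


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    group: str
    reference: str
    p_value: float
    flags: list[str] = field(default_factory=list)


def compare_proportions(
    per_group: Mapping[str, GroupProportion],
    reference: str,
    method: str = "fisher",
) -> dict[str, ComparisonResult]:
    """Two-sided test of each group's mutant proportion vs the reference.

    Fisher's exact test on the 2x2 (mutant / non-mutant x group /
    reference); chi-square available as an alternative.  A table with a
    zero margin yields p = 1 with a flag.
    """
    if reference not in per_group:
        raise ValidationError(f"reference group {reference!r} absent")
    ref = per_group[reference]
    out: dict[str, ComparisonResult] = {}
    for name, gp in per_group.items():
        if name == reference:
            continue
        table = np.array([
            [gp.mutant, gp.covered - gp.mutant],
            [ref.mutant, ref.covered - ref.mutant],
        ])
        flags: list[str] = []
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            p = 1.0
            flags.append("degenerate table")
        elif method == "fisher":
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        elif method == "chi2":
            p = float(stats.chi2_contingency(table, correction=True)[1])
        else:
            raise ValidationError(f"unknown proportion test {method!r}")
        out[name] = ComparisonResult(group=name, reference=reference,
                                     p_value=p, flags=flags)
    return out


def compare_scores(
    scores: pd.Series,
    groups: pd.Series,
    reference: str,
    method: str = "wilcoxon",
) -> dict[str, ComparisonResult]:
    """Two-sided per-group test of signature scores vs the reference
    (Wilcoxon rank-sum by default; Welch t-test as alternative)."""
    groups = groups.reindex(scores.index)
    if (groups == reference).sum() == 0:
        raise ValidationError(f"reference group {reference!r} has no cells")
    ref_scores = scores[groups == reference]
    out: dict[str, ComparisonResult] = {}
    for name in groups.dropna().unique():
        if name == reference:
            continue
        grp_scores = scores[groups == name]
        if method == "wilcoxon":
            p = float(stats.mannwhitneyu(grp_scores, ref_scores,
                                         alternative="two-sided").pvalue)
        elif method == "ttest":
            p = float(stats.ttest_ind(grp_scores, ref_scores,
                                      equal_var=False).pvalue)
        else:
            raise ValidationError(f"unknown score test {method!r}")
        out[name] = ComparisonResult(group=name, reference=reference, p_value=p)
    return out


# ---------------------------------------------------------------------------
# Expression-matrix I/O (dense TSV or MTX triplet)
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> pd.DataFrame:
    """Read a cells x genes log-expression matrix.

    Dense TSV (cells in rows, genes in columns, first column = cell id)
    or an MTX triplet (genes x cells matrix file plus gene and cell
    lists, the usual 10x-style layout, transposed on load).
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        if genes_path is None or cells_path is None:
            raise ValidationError("MTX input needs gene and cell list files")
        mat = mmread(str(path)).toarray()
        genes = [line.strip() for line in open(genes_path) if line.strip()]
        cells = [line.strip() for line in open(cells_path) if line.strip()]
        if mat.shape != (len(genes), len(cells)):
            raise ValidationError(
                f"MTX shape {mat.shape} does not match {len(genes)} genes x "
                f"{len(cells)} cells"
            )
        return pd.DataFrame(mat.T, index=cells, columns=genes)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.duplicated().any():
        raise ValidationError(f"{path}: duplicate gene names")
    return df
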