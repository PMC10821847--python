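"""ELISPOT-based immunogenicity selection and cross-reactivity assessment.

A peptide is selected for the vaccine when its mean IFN-gamma spot count
across replicates under mutant-peptide stimulation is strictly greater
than the threshold (default: more than 100 spots).  Cross-reactivity asks
whether the wild-type counterpart also stimulates: it is flagged when the
wild-type arm itself clears the selection threshold, or when it is
statistically indistinguishable from the mutant arm (Welch t-test) while
sitting clearly above the negative-control background (> control mean +
3 SD).  Spot counts are used raw; negative-control counts are reported
alongside rather than subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_core import ThresholdConfig, ValidationError, logger


@dataclass
class ElispotRecord:
    """Replicate spot counts for one candidate peptide."""

    mutation_id: str
    mut_spots: list[int]
    wt_spots: list[int] = field(default_factory=list)
    ctrl_spots: list[int] = field(default_factory=list)
    pool: str | None = None

    def __post_init__(self) -> None:
        if not self.mut_spots:
            raise ValidationError(f"{self.mutation_id}: no mutant-arm replicates")
        for arm in (self.mut_spots, self.wt_spots, self.ctrl_spots):
            if any((not float(x).is_integer()) or x < 0 for x in arm):
                raise ValidationError(
                    f"{self.mutation_id}: spot counts must be non-negative integers"
                )

    @property
    def mut_mean(self) -> float:
        return float(np.mean(self.mut_spots))

    @property
    def wt_mean(self) -> float | None:
        return float(np.mean(self.wt_spots)) if self.wt_spots else None


def select_immunogenic(
    records: Sequence[ElispotRecord],
    cfg: ThresholdConfig,
) -> list[str]:
    """Ids whose mean mutant-arm spot count strictly exceeds ``min_spots``."""
    selected = [r.mutation_id for r in records if r.mut_mean > cfg.min_spots]
    logger.info("elispot: %d/%d peptides with mean spots > %d",
                len(selected), len(records), cfg.min_spots)
    return selected


@dataclass
class CrossReactivityResult:
    mutation_id: str
    mut_mean: float
    wt_mean: float | None
    ratio: float | None
    cross_reactive: bool | None     # None when not assessed
    p_value: float | None
    assessed: bool
    flags: list[str] = field(default_factory=list)


def cross_reactivity(
    records: Sequence[ElispotRecord],
    cfg: ThresholdConfig,
) -> dict[str, CrossReactivityResult]:
    """Mutant-vs-wild-type comparison per peptide.

    Requires >= 2 replicates in each arm for the Welch test; otherwise
    the record is flagged "not assessed".
    """
    out: dict[str, CrossReactivityResult] = {}
    for r in records:
        mut_mean = r.mut_mean
        if len(r.wt_spots) < 2 or len(r.mut_spots) < 2:
            out[r.mutation_id] = CrossReactivityResult(
                mutation_id=r.mutation_id, mut_mean=mut_mean,
                wt_mean=r.wt_mean, ratio=None, cross_reactive=None,
                p_value=None, assessed=False, flags=["not assessed"],
            )
            continue
        wt_mean = float(np.mean(r.wt_spots))
        flags: list[str] = []
        if mut_mean == 0.0:
            ratio = 0.0
            flags.append("zero mutant mean")
        else:
            ratio = wt_mean / mut_mean
        t_res = stats.ttest_ind(r.mut_spots, r.wt_spots, equal_var=False)
        p = float(t_res.pvalue)
        if np.isnan(p):  # zero variance in both arms with equal means
            p = 1.0
            flags.append("degenerate t-test")
        ctrl_guard = False
        if r.ctrl_spots:
            ctrl_mean = float(np.mean(r.ctrl_spots))
            ctrl_sd = float(np.std(r.ctrl_spots, ddof=1)) if len(r.ctrl_spots) > 1 else 0.0
            ctrl_guard = wt_mean > ctrl_mean + 3.0 * ctrl_sd
        cross = (wt_mean > cfg.min_spots) or (p >= cfg.alpha and ctrl_guard)
        out[r.mutation_id] = CrossReactivityResult(
            mutation_id=r.mutation_id, mut_mean=mut_mean, wt_mean=wt_mean,
            ratio=ratio, cross_reactive=cross, p_value=p, assessed=True,
            flags=flags,
        )
    return out


# ---------------------------------------------------------------------------
# TSV format: mutation_id, arm {mut, wt, ctrl}, replicate, spots
# ---------------------------------------------------------------------------

ELISPOT_COLUMNS = ("mutation_id", "arm", "replicate", "spots")
_ARMS = ("mut", "wt", "ctrl")


def read_elispot_tsv(path: str | Path) -> list[ElispotRecord]:
    arms: dict[str, dict[str, list[tuple[int, int]]]] = {}
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ELISPOT_COLUMNS:
            raise ValidationError(f"{path}: unexpected ELISPOT header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            mid, arm, rep, spots = line.split("\t")
            if arm not in _ARMS:
                raise ValidationError(f"{path}:{lineno}: unknown arm {arm!r}")
            if mid not in arms:
                arms[mid] = {a: [] for a in _ARMS}
                order.append(mid)
            arms[mid][arm].append((int(rep), int(spots)))
    records = []
    for mid in order:
        by_arm = {a: [s for _, s in sorted(arms[mid][a])] for a in _ARMS}
        records.append(ElispotRecord(
            mutation_id=mid, mut_spots=by_arm["mut"],
            wt_spots=by_arm["wt"], ctrl_spots=by_arm["ctrl"],
        ))
    return records


def write_elispot_tsv(records: Iterable[ElispotRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ELISPOT_COLUMNS) + "\n")
        for r in records:
            for arm, counts in (("mut", r.mut_spots), ("wt", r.wt_spots),
                                ("ctrl", r.ctrl_spots)):
                for i, s in enumerate(counts, start=1):
                    fh.write(f"{r.mutation_id}\t{arm}\t{i}\t{s}\n")
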