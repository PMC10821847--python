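"""Expression-aware somatic-variant filtering.

A variant survives only with adequate variant allele frequency, read depth,
and RNA-level expression of its parent gene (all comparisons inclusive:
VAF >= min_vaf, depth >= min_depth, TPM >= min_tpm).  Every failed rule is
recorded per variant, not just the first.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .io_core import SomaticVariant, ThresholdConfig, logger

RULES = ("vaf", "depth", "tpm")


@dataclass
class FilterReport:
    """Per-variant audit of the three-rule expression filter."""

    input_count: int
    pass_count: int
    per_variant: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "input_count": self.input_count,
            "pass_count": self.pass_count,
            "per_variant": self.per_variant,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def join_expression(
    variants: Sequence[SomaticVariant],
    expression: Mapping[str, float],
) -> list[SomaticVariant]:
    """Attach each variant's parent-gene TPM from the expression table.

    A gene absent from the table leaves TPM unset (the variant then fails
    the expression rule downstream); a warning is logged per missing gene.
    """
    missing: set[str] = set()
    joined = []
    for v in variants:
        tpm = expression.get(v.gene)
        if tpm is None:
            missing.add(v.gene)
        joined.append(v.with_tpm(tpm))
    if missing:
        logger.warning(
            "%d gene(s) absent from expression table (variants will fail "
            "the TPM rule): %s", len(missing),
            ", ".join(sorted(missing)[:5]) + ("..." if len(missing) > 5 else ""),
        )
    return joined


def failed_rules(v: SomaticVariant, cfg: ThresholdConfig) -> list[str]:
    """All rules the variant fails, in canonical (vaf, depth, tpm) order."""
    failures = []
    if v.vaf < cfg.min_vaf:
        failures.append("vaf")
    if v.depth < cfg.min_depth:
        failures.append("depth")
    tpm = v.tpm
    if tpm is None or math.isnan(tpm) or tpm < cfg.min_tpm:
        failures.append("tpm")
    return failures


def filter_expressed(
    variants: Sequence[SomaticVariant],
    cfg: ThresholdConfig,
) -> tuple[list[SomaticVariant], FilterReport]:
    """Apply the three-rule expression filter; returns (kept, report).

    The kept set equals the intersection of the three single-rule kept
    sets; all boundaries are inclusive, so a variant at exactly
    (min_vaf, min_depth, min_tpm) is kept.
    """
    kept: list[SomaticVariant] = []
    per_variant: dict[str, dict] = {}
    for v in variants:
        failures = failed_rules(v, cfg)
        per_variant[v.id] = {"kept": not failures, "failed_rules": failures}
        if not failures:
            kept.append(v)
    report = FilterReport(
        input_count=len(variants), pass_count=len(kept), per_variant=per_variant
    )
    logger.info("filter: %d/%d variants pass (vaf>=%g, depth>=%d, tpm>=%g)",
                report.pass_count, report.input_count,
                cfg.min_vaf, cfg.min_depth, cfg.min_tpm)
    return kept, report
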