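"""End-to-end orchestration with a reproducible run manifest.

Stages communicate only through documented TSV/FASTA/JSON files, so any
stage can be swapped for a real tool's output (e.g. genuine NetMHCpan
percentile ranks in place of the mock ensemble).  The manifest records
the configuration snapshot, input checksums, the per-stage candidate
funnel, and the seed; re-running with identical inputs and seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .binding import (
    PredictorRankMatrix,
    consensus,
    make_mock_ensemble,
    prioritize,
    rank_peptides,
    write_consensus_tsv,
)
from .filtering import filter_expressed, join_expression
from .immunogenicity import cross_reactivity, read_elispot_tsv, select_immunogenic
from .io_core import (
    MhcAllele,
    ThresholdConfig,
    ValidationError,
    logger,
    read_expression_table,
    read_fasta,
    read_variants,
    write_variants_tsv,
)
from .peptides import design_all, write_peptides_tsv
from .sc_expression import (
    compare_proportions,
    compare_scores,
    mutant_cell_proportion,
    read_cell_counts_tsv,
    read_expression_matrix,
    signature_score,
)
from .synthetic import apply_plants, sha256_of


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    version: str
    seed: int
    config: dict
    input_checksums: dict[str, str] = field(default_factory=dict)
    funnel: dict[str, int] = field(default_factory=dict)
    completed_stages: list[str] = field(default_factory=list)
    failed_stage: str | None = None

    #: funnel keys in pipeline order; counts must be non-increasing
    FUNNEL_ORDER = ("input_variants", "expressed", "consensus_pass", "top",
                    "synthesized", "selected")

    def check_monotone(self) -> None:
        values = [self.funnel[k] for k in self.FUNNEL_ORDER if k in self.funnel]
        if any(a < b for a, b in zip(values, values[1:])):
            raise StageError("manifest", f"funnel not non-increasing: {self.funnel}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version, "seed": self.seed, "config": self.config,
            "input_checksums": self.input_checksums, "funnel": self.funnel,
            "completed_stages": self.completed_stages,
            "failed_stage": self.failed_stage,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _load_config(config_path: str | Path) -> dict:
    with open(config_path) as fh:
        config = yaml.safe_load(fh) or {}
    if "inputs" not in config:
        raise ValidationError(f"{config_path}: missing 'inputs' section")
    return config


def run_all(config_path: str | Path, outdir: str | Path) -> RunManifest:
    """Run filter -> peptides -> rank -> consensus -> prioritize ->
    ELISPOT -> single-cell stages per the YAML config; returns the
    manifest (also written to ``outdir/manifest.json``).

    On a stage failure the partial manifest is written and a
    :class:`StageError` naming the stage is raised.
    """
    config_path = Path(config_path)
    config = _load_config(config_path)
    base = config_path.parent
    inputs = {k: base / v for k, v in config["inputs"].items()}
    cfg = ThresholdConfig.from_dict(config.get("thresholds", {}))
    allele_spec = config.get("allele", {})
    allele = MhcAllele(
        name=allele_spec.get("name", "H-2-Kb"),
        preferred_lengths=tuple(allele_spec.get("lengths", (8, 9))),
    )
    seed = int(config.get("seed", 0))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(version=__version__, seed=seed, config=config)
    for name, path in sorted(inputs.items()):
        if path.exists():
            manifest.input_checksums[name] = sha256_of(path)

    def fail(stage: str, exc: Exception) -> StageError:
        manifest.failed_stage = stage
        manifest.to_json(outdir / "manifest.json")
        return StageError(stage, str(exc))

    # ---- filter ------------------------------------------------------------
    stage = "filter"
    try:
        variants = read_variants(inputs["variants"])
        expression = read_expression_table(inputs["expression"])
        joined = join_expression(variants, expression)
        kept, report = filter_expressed(joined, cfg)
        write_variants_tsv(kept, outdir / "kept.tsv")
        report.to_json(outdir / "filter_report.json")
        manifest.funnel["input_variants"] = report.input_count
        manifest.funnel["expressed"] = report.pass_count
        manifest.completed_stages.append(stage)
    except (OSError, ValidationError, KeyError) as exc:
        raise fail(stage, exc) from exc

    # ---- peptides ------------------------------------------------------------
    stage = "peptides"
    try:
        proteome = read_fasta(inputs["proteome"])
        all_peptides = design_all(proteome, kept, allele, cfg)
        write_peptides_tsv(all_peptides, outdir / "peptides.tsv")
        short_mut = [p for p in all_peptides
                     if p.form == "short" and p.kind == "mutant"]
    except (OSError, ValidationError, KeyError) as exc:
        raise fail(stage, exc) from exc

    # ---- ranks ---------------------------------------------------------------
    stage = "rank"
    try:
        if "ranks" in inputs:
            matrix = PredictorRankMatrix.from_tsv(inputs["ranks"])
        else:
            mock_cfg = config.get("mock_rank", {})
            ens_seed = int(mock_cfg.get("seed", seed))
            ensemble = make_mock_ensemble(
                proteome, allele, seed=ens_seed,
                n_background=int(mock_cfg.get("n_background", 10_000)),
            )
            if "plants" in inputs:
                with open(inputs["plants"]) as fh:
                    apply_plants(ensemble, json.load(fh))
            matrix = rank_peptides(ensemble, short_mut)
        matrix.to_tsv(outdir / "ranks.tsv")
    except (OSError, ValidationError, KeyError) as exc:
        raise fail(stage, exc) from exc

    # ---- consensus + prioritize ---------------------------------------------
    stage = "consensus"
    try:
        results = consensus(kept, short_mut, matrix, cfg)
        write_consensus_tsv(results, outdir / "consensus.tsv")
        top = prioritize(results, kept, cfg)
        write_consensus_tsv(top, outdir / "top.tsv")
        manifest.funnel["consensus_pass"] = sum(r.passes for r in results)
        manifest.funnel["top"] = len(top)
        manifest.completed_stages.append(stage)
    except (OSError, ValidationError, KeyError) as exc:
        raise fail(stage, exc) from exc

    # ---- ELISPOT --------------------------------------------------------------
    if "elispot" in inputs:
        stage = "elispot"
        try:
            records = read_elispot_tsv(inputs["elispot"])
            selected = select_immunogenic(records, cfg)
            with open(outdir / "selected.tsv", "w") as fh:
                fh.write("mutation_id\tmean_spots\tselected\n")
                for r in records:
                    fh.write(f"{r.mutation_id}\t{r.mut_mean:.6g}"
                             f"\t{int(r.mutation_id in selected)}\n")
            xr = cross_reactivity(records, cfg)
            xr_payload = {
                mid: {"mut_mean": r.mut_mean, "wt_mean": r.wt_mean,
                      "ratio": r.ratio, "cross_reactive": r.cross_reactive,
                      "p_value": r.p_value, "assessed": r.assessed,
                      "flags": r.flags}
                for mid, r in xr.items()
            }
            with open(outdir / "cross_reactivity.json", "w") as fh:
                json.dump(xr_payload, fh, indent=1, sort_keys=True)
                fh.write("\n")
            manifest.funnel["synthesized"] = len(records)
            manifest.funnel["selected"] = len(selected)
            manifest.completed_stages.append(stage)
        except (OSError, ValidationError, KeyError) as exc:
            raise fail(stage, exc) from exc

    # ---- single-cell -----------------------------------------------------------
    sc_cfg = config.get("sc", {})
    reference = sc_cfg.get("reference_group", "PBS")
    sc_out: dict = {}
    if "cell_counts" in inputs and "sites" in inputs:
        stage = "sc-mutprop"
        try:
            cells = read_cell_counts_tsv(inputs["cell_counts"])
            sites = [s.strip() for s in open(inputs["sites"]) if s.strip()]
            tumor = {s.strip() for s in open(inputs["tumor_cells"])
                     if s.strip()} if "tumor_cells" in inputs \
                else {c.cell for c in cells}
            per_group = mutant_cell_proportion(cells, sites, tumor,
                                               min_alt_reads=cfg.min_alt_reads)
            tests = compare_proportions(
                per_group, reference,
                method=sc_cfg.get("proportion_test", "fisher"))
            sc_out["mutant_proportion"] = {
                g: {"covered": gp.covered, "mutant": gp.mutant,
                    "proportion": gp.proportion}
                for g, gp in sorted(per_group.items())
            }
            sc_out["proportion_tests"] = {
                g: {"p_value": t.p_value, "flags": t.flags}
                for g, t in sorted(tests.items())
            }
            manifest.completed_stages.append(stage)
        except (OSError, ValidationError, KeyError) as exc:
            raise fail(stage, exc) from exc

    if "expr_matrix" in inputs and "signature" in inputs:
        stage = "sc-signature"
        try:
            import pandas as pd

            expr = read_expression_matrix(inputs["expr_matrix"])
            signature = [s.strip() for s in open(inputs["signature"])
                         if s.strip()]
            groups = pd.read_csv(inputs["cell_groups"], sep="\t",
                                 index_col=0)["group"]
            scores = signature_score(
                expr, signature,
                n_bins=int(sc_cfg.get("n_bins", 25)),
                n_ctrl=int(sc_cfg.get("n_ctrl", 100)), seed=seed)
            scores.to_frame().to_csv(outdir / "signature_scores.tsv", sep="\t")
            tests = compare_scores(scores, groups, reference,
                                   method=sc_cfg.get("score_test", "wilcoxon"))
            grp = groups.reindex(scores.index)
            sc_out["signature"] = {
                "per_group": {
                    g: {"mean": float(scores[grp == g].mean()),
                        "sd": float(scores[grp == g].std(ddof=1)),
                        "n": int((grp == g).sum())}
                    for g in sorted(grp.dropna().unique())
                },
                "tests": {g: t.p_value for g, t in sorted(tests.items())},
            }
            manifest.completed_stages.append(stage)
        except (OSError, ValidationError, KeyError) as exc:
            raise fail(stage, exc) from exc

    if sc_out:
        with open(outdir / "sc_results.json", "w") as fh:
            json.dump(sc_out, fh, indent=1, sort_keys=True)
            fh.write("\n")

    manifest.check_monotone()
    manifest.to_json(outdir / "manifest.json")
    logger.info("run: funnel %s", manifest.funnel)
    return manifest
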