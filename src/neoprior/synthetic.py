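"""Synthetic study generator with planted ground truth.

Generates every input the pipeline consumes — proteome FASTA, somatic
variant table, gene-expression table, ELISPOT counts, per-cell
mutant-allele counts and a single-cell expression matrix — as a pure
function of a :class:`SimConfig`, together with a ``truth.json`` that is
a complete oracle for every downstream stage.

Statistical shape of the emulated study data:

* VAF ~ Beta, read depth ~ negative binomial, gene TPM ~ log-normal,
  each sampled conditionally on the variant's planted filter fate;
* predicted binding enters through planted per-sequence rank targets
  (strong binders at rank 0, moderate binders in a configurable band
  under the 2% cutoff); every other candidate window is kept clear of
  the cutoff so truth recovery is exact by construction;
* ELISPOT replicate counts are over-dispersed negative binomials whose
  immunogenic/non-immunogenic means straddle the 100-spot threshold;
* per-cell site coverage is sparse and mutant-allele detection among
  covered tumor cells is an exact Bernoulli draw at the planted
  per-group fraction;
* the signature genes carry a planted per-group log-unit shift on top
  of gene-specific baselines.

The default funnel (762 variants -> 224 expressed -> 60 predicted
binders -> top 20 -> 16 synthesized -> 7 immunogenic) mirrors the
published screening workflow as a convenience fixture for end-to-end
tests; it is not a claim that those counts re-derive from raw data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .binding import MockEnsemble, PssmPredictor, make_mock_ensemble, pssm_score
from .io_core import (
    AMINO_ACIDS,
    MhcAllele,
    Proteome,
    SomaticVariant,
    ThresholdConfig,
    ValidationError,
    logger,
    write_expression_table,
    write_fasta,
    write_variants_tsv,
)
from .immunogenicity import ElispotRecord, write_elispot_tsv
from .peptides import enumerate_epitopes
from .sc_expression import CellSiteCounts, write_cell_counts_tsv

#: rank (percent) below which a non-planted candidate window is lifted,
#: keeping the planted binder set exact at the 2% consensus cutoff
SUPPRESSION_FLOOR = 5.0
SUPPRESSION_TARGET = 50.0


@dataclass
class SimConfig:
    """All knobs of the synthetic study; generation is a pure function
    of this object."""

    seed: int = 0

    # proteome / variants
    n_genes: int = 800
    protein_len_min: int = 120
    protein_len_max: int = 600
    n_variants: int = 762
    n_expressed: int = 224
    frac_pass_vaf: float = 0.6
    frac_pass_depth: float = 0.8
    frac_pass_tpm: float = 0.6
    vaf_beta: tuple[float, float] = (2.0, 3.0)
    depth_nb_mean: float = 60.0
    depth_nb_dispersion: float = 5.0
    tpm_lognorm_mu: float = 1.0
    tpm_lognorm_sigma: float = 1.5

    # binding plants
    n_strong_binders: int = 20
    n_moderate_binders: int = 40
    moderate_rank_range: tuple[float, float] = (0.3, 1.8)
    background_size: int = 10_000
    planted_epitope_length: int = 8

    # ELISPOT
    n_synthesized: int = 16
    n_immunogenic: int = 7
    elispot_replicates: int = 3
    spots_mean_high: float = 300.0
    spots_mean_low: float = 20.0
    spots_wt_mean: float = 10.0
    spots_ctrl_mean: float = 5.0
    spots_nb_dispersion: float = 50.0

    # single cell
    groups: tuple[str, ...] = ("PBS", "vaccine", "checkpoint", "combined")
    n_cells_per_group: int = 900
    frac_tumor: float = 0.9
    site_coverage_p: float = 0.3
    mutant_frac: dict[str, float] = field(default_factory=lambda: {
        "PBS": 0.30, "vaccine": 0.15, "checkpoint": 0.20, "combined": 0.05,
    })
    n_sc_sites: int = 3
    signature_shift: dict[str, float] = field(default_factory=lambda: {
        "PBS": 0.0, "vaccine": -0.3, "checkpoint": -0.3, "combined": -1.0,
    })
    n_expr_genes: int = 200
    expr_baseline_range: tuple[float, float] = (0.0, 3.0)
    expr_noise_sd: float = 0.4

    def validate(self) -> None:
        if self.n_expressed > self.n_variants:
            raise ValidationError("n_expressed > n_variants")
        if self.n_variants > self.n_genes:
            raise ValidationError("n_variants > n_genes (one gene per variant)")
        if self.n_strong_binders + self.n_moderate_binders > self.n_expressed:
            raise ValidationError("planted binders exceed expressed variants")
        if self.n_synthesized > self.n_strong_binders:
            raise ValidationError("n_synthesized > top-N strong binders")
        if self.n_immunogenic > self.n_synthesized:
            raise ValidationError("n_immunogenic > n_synthesized")
        if self.n_sc_sites > self.n_immunogenic:
            raise ValidationError("n_sc_sites > n_immunogenic")
        for p in (self.frac_pass_vaf, self.frac_pass_depth, self.frac_pass_tpm,
                  self.site_coverage_p, self.frac_tumor,
                  *self.mutant_frac.values()):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")
        if set(self.groups) != set(self.mutant_frac) or \
                set(self.groups) != set(self.signature_shift):
            raise ValidationError("groups and per-group dicts disagree")
        if self.n_expr_genes < self.n_immunogenic:
            raise ValidationError("n_expr_genes smaller than signature size")
        lo, hi = self.moderate_rank_range
        if not 0.0 < lo <= hi <= 2.0:
            raise ValidationError("moderate_rank_range must sit inside (0, 2]")
        if self.protein_len_min < 50:
            raise ValidationError("protein_len_min must be >= 50")


# ---------------------------------------------------------------------------
# Binder planting
# ---------------------------------------------------------------------------

def plant_binder(
    ensemble: MockEnsemble,
    epitope: str,
    target_rank: float,
    predictor: str | None = None,
) -> None:
    """Pin an epitope's percentile rank to ``target_rank`` (in percent).

    Sets a per-sequence score offset so the epitope's raw score lands on
    the background quantile corresponding to the target; background
    peptides are untouched, so all other ranks keep their calibration.
    ``target_rank`` 0 places the epitope above the entire background.
    Applies to every predictor unless one is named.
    """
    k = len(epitope)
    names = [predictor] if predictor is not None else list(ensemble.models)
    for name in names:
        model = ensemble.models[name].get(k)
        if model is None:
            raise ValidationError(f"{name}: no model of length {k} to plant into")
        bg = model.background_scores
        B = bg.size
        base = pssm_score(model, epitope)
        if target_rank <= 0.0:
            target_score = float(bg[-1]) + 1.0
        else:
            m = max(1, min(B, round(target_rank * B / 100.0)))
            target_score = float(bg[B - m])  # m-th largest background score
        model.score_offsets[epitope] = target_score - base


def apply_plants(ensemble: MockEnsemble, plants: Sequence[dict]) -> None:
    """Apply a plants.json-style list of rank targets to the ensemble."""
    for entry in plants:
        plant_binder(ensemble, entry["peptide"], float(entry["target_rank"]),
                     entry.get("predictor"))


def _centered_window(seq: str, pos: int, k: int) -> tuple[str, int]:
    """The k-mer covering ``pos`` closest to centered, clipped to the protein."""
    start = pos - k // 2 + 1
    start = max(1, min(start, len(seq) - k + 1, pos))
    start = max(start, pos - k + 1)
    return seq[start - 1 : start - 1 + k], start


# ---------------------------------------------------------------------------
# Conditional marginal samplers
# ---------------------------------------------------------------------------

def _rejection(draw, accept, max_iter: int = 100_000):
    for _ in range(max_iter):
        x = draw()
        if accept(x):
            return x
    raise RuntimeError("rejection sampler failed to converge")


def _sample_vaf(rng, cfg: SimConfig, min_vaf: float, passes: bool) -> float:
    # conditions are checked on the 4-decimal value written to disk
    a, b = cfg.vaf_beta
    cond = (lambda x: x >= min_vaf) if passes else (lambda x: x < min_vaf)
    return float(_rejection(lambda: round(rng.beta(a, b), 4), cond))


def _sample_depth(rng, cfg: SimConfig, min_depth: int, passes: bool) -> int:
    theta, m = cfg.depth_nb_dispersion, cfg.depth_nb_mean
    p = theta / (theta + m)
    cond = (lambda x: x >= min_depth) if passes else (lambda x: x < min_depth)
    return int(_rejection(lambda: rng.negative_binomial(theta, p), cond))


def _sample_tpm(rng, cfg: SimConfig, min_tpm: float, passes: bool) -> float:
    mu, sigma = cfg.tpm_lognorm_mu, cfg.tpm_lognorm_sigma
    cond = (lambda x: x >= min_tpm) if passes else (lambda x: x < min_tpm)
    return float(_rejection(lambda: round(rng.lognormal(mu, sigma), 4), cond))


def _nb_counts(rng, mean: float, dispersion: float, n: int) -> list[int]:
    p = dispersion / (dispersion + mean)
    return [int(x) for x in rng.negative_binomial(dispersion, p, size=n)]


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    """Paths to every generated file plus the in-memory truth record."""

    outdir: Path
    proteome: Path
    variants: Path
    expression: Path
    plants: Path
    elispot: Path
    cell_counts: Path
    sites: Path
    tumor_cells: Path
    expr_matrix: Path
    cell_groups: Path
    signature_genes: Path
    truth_json: Path
    run_config: Path
    truth: dict


def simulate_study(cfg: SimConfig, outdir: str | Path) -> SimBundle:
    """Generate the full synthetic study bundle under ``outdir``.

    Deterministic: the same config (including seed) produces
    byte-identical files.  Raises on an infeasible config before
    anything is written.
    """
    cfg.validate()
    outdir = Path(outdir)
    rng = np.random.default_rng(cfg.seed)
    thresholds = ThresholdConfig(top_n=cfg.n_strong_binders,
                                 min_predictors=4)
    allele = MhcAllele()
    aa = np.array(list(AMINO_ACIDS))

    # ---- proteome ---------------------------------------------------------
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    lengths = rng.integers(cfg.protein_len_min, cfg.protein_len_max + 1,
                           size=cfg.n_genes)
    records = {g: "".join(rng.choice(aa, size=int(L)))
               for g, L in zip(genes, lengths)}
    proteome = Proteome(records)

    # ---- variants with planted filter fate --------------------------------
    variants: list[SomaticVariant] = []
    truth_variants: dict[str, dict] = {}
    expressed_flags = [i < cfg.n_expressed for i in range(cfg.n_variants)]
    for i in range(cfg.n_variants):
        gene = genes[i]
        prot = records[gene]
        pos = int(rng.integers(20, len(prot) - 19))
        ref = prot[pos - 1]
        alt = str(rng.choice([c for c in AMINO_ACIDS if c != ref]))
        if expressed_flags[i]:
            fate = {"vaf": True, "depth": True, "tpm": True}
        else:
            while True:
                fate = {
                    "vaf": bool(rng.random() < cfg.frac_pass_vaf),
                    "depth": bool(rng.random() < cfg.frac_pass_depth),
                    "tpm": bool(rng.random() < cfg.frac_pass_tpm),
                }
                if not all(fate.values()):
                    break
        vaf = _sample_vaf(rng, cfg, thresholds.min_vaf, fate["vaf"])
        depth = _sample_depth(rng, cfg, thresholds.min_depth, fate["depth"])
        tpm = _sample_tpm(rng, cfg, thresholds.min_tpm, fate["tpm"])
        v = SomaticVariant(gene=gene, ref_aa=ref, protein_pos=pos, alt_aa=alt,
                           vaf=vaf, depth=depth, tpm=tpm)
        variants.append(v)
        truth_variants[v.id] = {
            "pass_vaf": fate["vaf"], "pass_depth": fate["depth"],
            "pass_tpm": fate["tpm"], "expressed": all(fate.values()),
            "binder_class": "none", "target_rank": None,
            "planted_epitope": None, "synthesized": False,
            "immunogenic": False,
        }

    # expression table covers every gene; variant genes carry their fate TPM
    tpm_table: dict[str, float] = {v.gene: float(v.tpm) for v in variants}
    for g in genes[cfg.n_variants:]:
        tpm_table[g] = round(float(rng.lognormal(cfg.tpm_lognorm_mu,
                                                 cfg.tpm_lognorm_sigma)), 4)

    # ---- binder plants -----------------------------------------------------
    expressed = [v for v, e in zip(variants, expressed_flags) if e]
    order = rng.permutation(len(expressed))
    strong = [expressed[i] for i in order[: cfg.n_strong_binders]]
    moderate = [expressed[i] for i in
                order[cfg.n_strong_binders :
                      cfg.n_strong_binders + cfg.n_moderate_binders]]

    binding_seed = int(np.random.default_rng(cfg.seed + 101).integers(2**31))
    plants: list[dict] = []
    lo, hi = cfg.moderate_rank_range
    planted_epitopes: set[str] = set()
    for v in strong + moderate:
        mutant = records[v.gene][: v.protein_pos - 1] + v.alt_aa + \
            records[v.gene][v.protein_pos:]
        epitope, _ = _centered_window(mutant, v.protein_pos,
                                      cfg.planted_epitope_length)
        is_strong = v in strong
        target = 0.0 if is_strong else round(float(rng.uniform(lo, hi)), 2)
        plants.append({"peptide": epitope, "target_rank": target,
                       "predictor": None})
        planted_epitopes.add(epitope)
        t = truth_variants[v.id]
        t["binder_class"] = "strong" if is_strong else "moderate"
        t["target_rank"] = target
        t["planted_epitope"] = epitope

    # keep every other candidate window clear of the consensus cutoff so
    # the planted binder set is exactly what the pipeline recovers
    ensemble = make_mock_ensemble(proteome, allele, seed=binding_seed,
                                  n_background=cfg.background_size)
    apply_plants(ensemble, plants)
    for v in expressed:
        for p in enumerate_epitopes(proteome, v, allele):
            if p.sequence in planted_epitopes:
                continue
            for name in ensemble.predictor_names:
                if ensemble.rank(name, p.sequence) < SUPPRESSION_FLOOR:
                    plants.append({"peptide": p.sequence,
                                   "target_rank": SUPPRESSION_TARGET,
                                   "predictor": name})
                    plant_binder(ensemble, p.sequence, SUPPRESSION_TARGET, name)

    # ---- ELISPOT -----------------------------------------------------------
    synth_idx = rng.choice(len(strong), size=cfg.n_synthesized, replace=False)
    synthesized = [strong[i] for i in sorted(synth_idx)]
    immuno_idx = rng.choice(len(synthesized), size=cfg.n_immunogenic,
                            replace=False)
    immunogenic_ids = {synthesized[i].id for i in immuno_idx}
    elispot_records = []
    for v in synthesized:
        truth_variants[v.id]["synthesized"] = True
        hot = v.id in immunogenic_ids
        truth_variants[v.id]["immunogenic"] = hot
        mean = cfg.spots_mean_high if hot else cfg.spots_mean_low
        elispot_records.append(ElispotRecord(
            mutation_id=v.id,
            mut_spots=_nb_counts(rng, mean, cfg.spots_nb_dispersion,
                                 cfg.elispot_replicates),
            wt_spots=_nb_counts(rng, cfg.spots_wt_mean,
                                cfg.spots_nb_dispersion,
                                cfg.elispot_replicates),
            ctrl_spots=_nb_counts(rng, cfg.spots_ctrl_mean,
                                  cfg.spots_nb_dispersion,
                                  cfg.elispot_replicates),
        ))

    # ---- single-cell mutant-allele counts ----------------------------------
    immunogenic_variants = [v for v in synthesized if v.id in immunogenic_ids]
    site_idx = rng.choice(len(immunogenic_variants), size=cfg.n_sc_sites,
                          replace=False)
    sc_sites = [immunogenic_variants[i].id for i in sorted(site_idx)]
    decoy_sites = [v.id for v in immunogenic_variants if v.id not in sc_sites]

    cells: list[CellSiteCounts] = []
    tumor_ids: list[str] = []
    sc_truth: dict[str, dict] = {}
    for group in cfg.groups:
        f = cfg.mutant_frac[group]
        covered_n = mutant_n = 0
        for j in range(cfg.n_cells_per_group):
            cell_id = f"{group}_c{j:04d}"
            is_tumor = bool(rng.random() < cfg.frac_tumor)
            counts: dict[str, tuple[int, int]] = {}
            for site in sc_sites + decoy_sites:
                if rng.random() < cfg.site_coverage_p:
                    counts[site] = (1 + int(rng.poisson(0.7)), 0)
            covers_query = any(s in counts for s in sc_sites)
            is_mutant = bool(rng.random() < f)
            if covers_query and is_mutant:
                covered_q = [s for s in sc_sites if s in counts]
                site = covered_q[int(rng.integers(len(covered_q)))]
                ref, _ = counts[site]
                counts[site] = (ref, 1 + int(rng.poisson(0.5)))
            if not counts:
                continue
            cells.append(CellSiteCounts(cell=cell_id, group=group,
                                        counts=counts))
            if is_tumor:
                tumor_ids.append(cell_id)
                if covers_query:
                    covered_n += 1
                    if is_mutant:
                        mutant_n += 1
        sc_truth[group] = {"true_mutant_frac": f, "covered": covered_n,
                           "mutant": mutant_n}

    # ---- single-cell expression matrix with planted signature shift --------
    signature_genes = sorted({v.gene for v in immunogenic_variants})
    other = [g for g in genes if g not in signature_genes]
    expr_genes = signature_genes + other[: cfg.n_expr_genes - len(signature_genes)]
    expr_genes = sorted(expr_genes)
    b_lo, b_hi = cfg.expr_baseline_range
    baseline = {g: float(rng.uniform(b_lo, b_hi)) for g in expr_genes}
    tumor_set = set(tumor_ids)
    expr_cells = [c for c in cells if c.cell in tumor_set]
    n_cells, n_eg = len(expr_cells), len(expr_genes)
    base_row = np.array([baseline[g] for g in expr_genes])
    sig_mask = np.array([g in signature_genes for g in expr_genes])
    mat = np.empty((n_cells, n_eg))
    for i, c in enumerate(expr_cells):
        shift = cfg.signature_shift[c.group]
        row = base_row + rng.normal(0.0, cfg.expr_noise_sd, size=n_eg)
        row = row + shift * sig_mask
        mat[i] = row
    mat = np.round(mat, 3)

    # ---- write bundle -------------------------------------------------------
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in {
        "proteome": "proteome.fasta", "variants": "variants.tsv",
        "expression": "expression.tsv", "plants": "plants.json",
        "elispot": "elispot.tsv", "cell_counts": "cell_counts.tsv",
        "sites": "sites.txt", "tumor_cells": "tumor_cells.txt",
        "expr_matrix": "expr_matrix.tsv", "cell_groups": "cell_groups.tsv",
        "signature_genes": "signature_genes.txt", "truth_json": "truth.json",
        "run_config": "run_config.yaml",
    }.items()}

    write_fasta(proteome, paths["proteome"])
    out_variants = [v.with_tpm(None) for v in variants]   # TPM joined at run time
    write_variants_tsv(out_variants, paths["variants"])
    write_expression_table(dict(sorted(tpm_table.items())), paths["expression"])
    with open(paths["plants"], "w") as fh:
        json.dump(plants, fh, indent=1)
        fh.write("\n")
    write_elispot_tsv(elispot_records, paths["elispot"])
    write_cell_counts_tsv(cells, paths["cell_counts"])
    paths["sites"].write_text("".join(s + "\n" for s in sc_sites))
    paths["tumor_cells"].write_text("".join(c + "\n" for c in tumor_ids))
    paths["signature_genes"].write_text(
        "".join(g + "\n" for g in signature_genes))
    with open(paths["expr_matrix"], "w") as fh:
        fh.write("cell\t" + "\t".join(expr_genes) + "\n")
        for i, c in enumerate(expr_cells):
            fh.write(c.cell + "\t" +
                     "\t".join(format(x, ".3f") for x in mat[i]) + "\n")
    with open(paths["cell_groups"], "w") as fh:
        fh.write("cell\tgroup\n")
        for c in cells:
            fh.write(f"{c.cell}\t{c.group}\n")

    truth = {
        "seed": cfg.seed,
        "funnel": {
            "input_variants": cfg.n_variants,
            "expressed": cfg.n_expressed,
            "consensus_pass": cfg.n_strong_binders + cfg.n_moderate_binders,
            "top": cfg.n_strong_binders,
            "synthesized": cfg.n_synthesized,
            "selected": cfg.n_immunogenic,
        },
        "variants": truth_variants,
        "binding_seed": binding_seed,
        "sc": {
            "sites": sc_sites,
            "signature_genes": signature_genes,
            "signature_shift": dict(cfg.signature_shift),
            "groups": sc_truth,
        },
    }
    with open(paths["truth_json"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")

    run_config = {
        "seed": cfg.seed,
        "inputs": {
            "variants": "variants.tsv", "expression": "expression.tsv",
            "proteome": "proteome.fasta", "plants": "plants.json",
            "elispot": "elispot.tsv", "cell_counts": "cell_counts.tsv",
            "sites": "sites.txt", "tumor_cells": "tumor_cells.txt",
            "expr_matrix": "expr_matrix.tsv", "cell_groups": "cell_groups.tsv",
            "signature": "signature_genes.txt",
        },
        "thresholds": thresholds.to_dict(),
        "allele": {"name": allele.name,
                   "lengths": list(allele.preferred_lengths)},
        "mock_rank": {"seed": binding_seed,
                      "n_background": cfg.background_size},
        "sc": {"reference_group": cfg.groups[0], "n_bins": 25,
               "n_ctrl": 100, "proportion_test": "fisher",
               "score_test": "wilcoxon"},
    }
    with open(paths["run_config"], "w") as fh:
        yaml.safe_dump(run_config, fh, sort_keys=True)

    logger.info("simulate: wrote bundle to %s (%d variants, %d cells)",
                outdir, len(variants), len(cells))
    return SimBundle(outdir=outdir, truth=truth, **paths)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
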