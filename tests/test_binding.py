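"""PSSM scoring, percentile-rank calibration, consensus, prioritization."""

import numpy as np
import pytest

from neoprior import (
    ConsensusResult,
    MhcAllele,
    PredictorRankMatrix,
    Proteome,
    PssmPredictor,
    SomaticVariant,
    ThresholdConfig,
    ValidationError,
    consensus,
    make_mock_ensemble,
    percentile_rank,
    prioritize,
    pssm_score,
    rank_peptides,
)
from neoprior.io_core import AA_INDEX, AMINO_ACIDS
from neoprior.peptides import PeptideCandidate
from neoprior.synthetic import plant_binder


def predictor(weights, background):
    return PssmPredictor(
        name="p", allele="H-2-Kb", length=weights.shape[0],
        weights=weights, background_scores=np.sort(np.asarray(background, float)),
    )


def random_proteome(rng, n=40, length=120):
    aa = list(AMINO_ACIDS)
    return Proteome({f"G{i:03d}": "".join(rng.choice(aa, size=length))
                     for i in range(n)})


class TestPssmScore:
    def test_zero_matrix_scores_zero(self):
        p = predictor(np.zeros((8, 20)), [0.0])
        assert pssm_score(p, "ACDEFGHI") == 0.0

    def test_score_is_positionwise_sum(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(2, 20))
        p = predictor(w, [0.0])
        assert pssm_score(p, "AC") == pytest.approx(
            w[0, AA_INDEX["A"]] + w[1, AA_INDEX["C"]])

    def test_position_symmetric_matrix_permutation_invariant(self):
        rng = np.random.default_rng(1)
        row = rng.normal(size=20)
        p = predictor(np.tile(row, (8, 1)), [0.0])
        assert pssm_score(p, "ACDEFGHI") == pytest.approx(pssm_score(p, "IHGFEDCA"))

    def test_length_mismatch(self):
        p = predictor(np.zeros((8, 20)), [0.0])
        with pytest.raises(ValidationError):
            pssm_score(p, "ACDEFGHIK")


class TestPercentileRank:
    def test_extremes(self):
        w = np.zeros((8, 20))
        w[:, AA_INDEX["W"]] = 10.0
        p = predictor(w, np.linspace(1.0, 50.0, 200))
        assert percentile_rank(p, "WWWWWWWW") == 0.0    # beats all background
        assert percentile_rank(p, "AAAAAAAA") == 100.0  # below all background

    def test_ties_count_against_candidate(self):
        p = predictor(np.zeros((8, 20)), [0.0, 1.0, 2.0, 3.0])
        # candidate scores 0.0, tied with one background peptide
        assert percentile_rank(p, "ACDEFGHI") == 100.0

    def test_matches_naive_recount(self):
        rng = np.random.default_rng(2)
        proteome = random_proteome(rng)
        ens = make_mock_ensemble(proteome, MhcAllele(preferred_lengths=(8,)),
                                 seed=3, n_background=500)
        model = ens.models[ens.predictor_names[0]][8]
        aa = list(AMINO_ACIDS)
        for _ in range(300):
            pep = "".join(rng.choice(aa, size=8))
            naive = 100.0 * np.mean(model.background_scores >= model.score(pep))
            assert model.percentile_rank(pep) == pytest.approx(naive)

    def test_empty_background_rejected(self):
        with pytest.raises(ValidationError):
            PssmPredictor(name="p", allele="a", length=8,
                          weights=np.zeros((8, 20)),
                          background_scores=np.array([]))


def result_matrix(rows):
    """rows: {peptide: {predictor: rank}}"""
    preds: list[str] = []
    for cells in rows.values():
        for name in cells:
            if name not in preds:
                preds.append(name)
    m = PredictorRankMatrix(predictors=preds)
    for pep, cells in rows.items():
        for name, rank in cells.items():
            m.add(pep, name, rank)
    return m


def short_peptide(seq, source_id):
    return PeptideCandidate(sequence=seq, source_id=source_id, kind="mutant",
                            form="short", start=1, mut_offset=1)


def make_variant(i, vaf=0.5, tpm=5.0):
    return SomaticVariant(f"G{i:03d}", "W", 10, "C", vaf=vaf, depth=50, tpm=tpm)


EIGHT = [f"pred{i}" for i in range(8)]


class TestConsensus:
    def test_even_count_median_fails_inclusive_cutoff(self, cfg):
        ranks = [0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0]
        v = make_variant(0)
        m = result_matrix({"ACDEFGHI": dict(zip(EIGHT, ranks))})
        (r,) = consensus([v], [short_peptide("ACDEFGHI", v.id)], m, cfg)
        assert r.best_median_rank == pytest.approx(2.25)
        assert not r.passes

    def test_boundary_median_passes(self, cfg):
        v = make_variant(0)
        m = result_matrix({"ACDEFGHI": {n: 2.0 for n in EIGHT}})
        (r,) = consensus([v], [short_peptide("ACDEFGHI", v.id)], m, cfg)
        assert r.best_median_rank == 2.0
        assert r.passes

    def test_predictor_order_invariance(self, cfg):
        rng = np.random.default_rng(4)
        ranks = list(rng.uniform(0, 100, size=8))
        v = make_variant(0)
        m1 = result_matrix({"ACDEFGHI": dict(zip(EIGHT, ranks))})
        m2 = result_matrix({"ACDEFGHI": dict(zip(reversed(EIGHT), ranks))})
        r1 = consensus([v], [short_peptide("ACDEFGHI", v.id)], m1, cfg)[0]
        r2 = consensus([v], [short_peptide("ACDEFGHI", v.id)], m2, cfg)[0]
        assert r1.best_median_rank == pytest.approx(r2.best_median_rank)

    def test_matches_sort_based_median_oracle(self, cfg):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(4, 9))
            ranks = list(rng.uniform(0, 100, size=n))
            v = make_variant(0)
            m = result_matrix({"ACDEFGHI": dict(zip(EIGHT[:n], ranks))})
            (r,) = consensus([v], [short_peptide("ACDEFGHI", v.id)], m, cfg)
            s = sorted(ranks)
            oracle = (s[(n - 1) // 2] + s[n // 2]) / 2.0
            assert r.best_median_rank == pytest.approx(oracle)

    def test_min_over_peptides_and_monotonicity(self, cfg):
        v = make_variant(0)
        peps = [short_peptide("ACDEFGHI", v.id), short_peptide("CDEFGHIK", v.id)]
        m = result_matrix({
            "ACDEFGHI": {n: 10.0 for n in EIGHT},
            "CDEFGHIK": {n: 1.0 for n in EIGHT},
        })
        (r,) = consensus([v], peps, m, cfg)
        assert r.best_peptide == "CDEFGHIK"
        assert r.best_median_rank == 1.0
        # removing the non-best peptide leaves the best median unchanged
        (r2,) = consensus([v], peps[1:], m, cfg)
        assert r2.best_median_rank == r.best_median_rank
        # adding a peptide never increases the best median
        peps3 = peps + [short_peptide("DEFGHIKL", v.id)]
        m.add("DEFGHIKL", EIGHT[0], 50.0)
        m3 = result_matrix({
            "ACDEFGHI": {n: 10.0 for n in EIGHT},
            "CDEFGHIK": {n: 1.0 for n in EIGHT},
            "DEFGHIKL": {n: 50.0 for n in EIGHT},
        })
        (r3,) = consensus([v], peps3, m3, cfg)
        assert r3.best_median_rank <= r.best_median_rank

    def test_partial_coverage_flag_and_unscored(self, cfg):
        v = make_variant(0)
        pep = short_peptide("ACDEFGHI", v.id)
        # 4 of 8 predictors: still scored, flagged low coverage
        m4 = result_matrix({"ACDEFGHI": {n: 1.0 for n in EIGHT[:4]}})
        m4.predictors = list(EIGHT)
        (r,) = consensus([v], [pep], m4, cfg)
        assert r.passes and "ACDEFGHI" in r.low_coverage
        # 3 of 8: unscored, excluded from pass set
        m3 = result_matrix({"ACDEFGHI": {n: 1.0 for n in EIGHT[:3]}})
        m3.predictors = list(EIGHT)
        (r,) = consensus([v], [pep], m3, cfg)
        assert r.unscored and not r.passes

    def test_zero_peptides_flagged(self, cfg):
        v = make_variant(0)
        m = result_matrix({})
        m.predictors = list(EIGHT)
        (r,) = consensus([v], [], m, cfg)
        assert r.unscored and not r.passes and r.best_peptide is None


class TestPrioritize:
    def _results(self, ids_ranks):
        return [
            ConsensusResult(mutation_id=mid, per_peptide_median={"X": rank},
                            best_peptide="X", best_median_rank=rank,
                            passes=rank <= 2.0)
            for mid, rank in ids_ranks
        ]

    def test_top_n_cap(self, cfg):
        results = self._results([(f"G{i:03d}_W10C", 0.1 + i * 0.01)
                                 for i in range(60)])
        variants = [make_variant(i) for i in range(60)]
        top = prioritize(results, variants, cfg)
        assert len(top) == 20
        assert [r.mutation_id for r in top] == \
            [f"G{i:03d}_W10C" for i in range(20)]

    def test_fewer_passing_than_top_n(self, cfg):
        results = self._results([(f"G{i:03d}_W10C", 0.5) for i in range(5)])
        variants = [make_variant(i) for i in range(5)]
        assert len(prioritize(results, variants, cfg)) == 5

    def test_tie_breaks_tpm_then_vaf(self, cfg):
        results = self._results([("A_W10C", 1.0), ("B_W10C", 1.0),
                                 ("C_W10C", 1.0)])
        variants = [
            SomaticVariant("A", "W", 10, "C", vaf=0.2, depth=50, tpm=5.0),
            SomaticVariant("B", "W", 10, "C", vaf=0.4, depth=50, tpm=5.0),
            SomaticVariant("C", "W", 10, "C", vaf=0.1, depth=50, tpm=9.0),
        ]
        top = prioritize(results, variants, cfg)
        # C first on TPM; then B over A on VAF
        assert [r.mutation_id for r in top] == ["C_W10C", "B_W10C", "A_W10C"]


class TestPlantedRecovery:
    def test_pass_set_equals_planted_set(self, cfg):
        """Planted strong binders pass the 2% consensus cutoff; unplanted
        mutations do not (40 simulated mutations, 8 mock predictors)."""
        rng = np.random.default_rng(7)
        proteome = random_proteome(rng, n=40, length=120)
        allele = MhcAllele(preferred_lengths=(8,))
        ens = make_mock_ensemble(proteome, allele, seed=11, n_background=10_000)

        from neoprior.peptides import enumerate_epitopes, apply_mutation

        variants, all_peps = [], []
        genes = sorted(proteome.records)
        for i, gene in enumerate(genes):
            wild = proteome.records[gene]
            pos = 60
            ref = wild[pos - 1]
            alt = "C" if ref != "C" else "A"
            v = SomaticVariant(gene, ref, pos, alt, vaf=0.5, depth=50, tpm=5.0)
            variants.append(v)
            all_peps.extend(enumerate_epitopes(proteome, v, allele))

        planted_ids = {v.id for v in variants[:8]}
        for v in variants[:8]:
            mutant = apply_mutation(proteome, v)
            plant_binder(ens, mutant[56:64], target_rank=0.5)

        matrix = rank_peptides(ens, all_peps)
        results = consensus(variants, all_peps, matrix, cfg)
        assert {r.mutation_id for r in results if r.passes} == planted_ids

    def test_rank_matrix_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(8)
        m = result_matrix({
            "ACDEFGHI": {n: float(r) for n, r in
                         zip(EIGHT, rng.uniform(0, 100, 8).round(4))},
            "CDEFGHIK": {n: float(r) for n, r in
                         zip(EIGHT, rng.uniform(0, 100, 8).round(4))},
        })
        path = tmp_path / "ranks.tsv"
        m.to_tsv(path)
        m2 = PredictorRankMatrix.from_tsv(path)
        assert m2.predictors == m.predictors
        for pep in m.ranks:
            for name in EIGHT:
                assert m2.ranks[pep][name] == pytest.approx(m.ranks[pep][name])
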