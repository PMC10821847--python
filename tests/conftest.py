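import pytest

from neoprior import MhcAllele, Proteome, SimConfig, ThresholdConfig, simulate_study


@pytest.fixture
def cfg():
    return ThresholdConfig()


@pytest.fixture
def allele():
    return MhcAllele()


@pytest.fixture
def carrier_proteome():
    """Synthetic carrier protein embedding the wild-type Mapkbp1 window.

    The published mutant epitope RHIKFCYL spans 199-206 with the mutant
    residue C at 204; the wild-type context therefore reads RHIKFWYL.
    The rest of the sequence is synthetic filler (the real Mapkbp1
    sequence is not part of this package).
    """
    import numpy as np

    rng = np.random.default_rng(42)
    from neoprior.io_core import AMINO_ACIDS

    aa = list(AMINO_ACIDS)
    seq = list("".join(rng.choice(aa, size=400)))
    seq[198:206] = "RHIKFWYL"
    return Proteome({"Mapkbp1": "".join(seq)})


def small_sim_config(seed: int = 7) -> SimConfig:
    """A scaled-down study: same structure as the default funnel, sized
    for fast unit tests."""
    return SimConfig(
        seed=seed,
        n_genes=100, n_variants=80, n_expressed=30,
        n_strong_binders=5, n_moderate_binders=8,
        n_synthesized=5, n_immunogenic=3, n_sc_sites=2,
        n_cells_per_group=120, background_size=2000, n_expr_genes=60,
    )


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return simulate_study(small_sim_config(), outdir)
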