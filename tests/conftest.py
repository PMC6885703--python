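import numpy as np
import pytest

from madeconv.encoding import (
    AllelePseudoSequence,
    FeatureLayout,
    blosum_encoding,
)


@pytest.fixture(scope="session")
def enc():
    return blosum_encoding()


@pytest.fixture(scope="session")
def layout9():
    """Class I layout over lengths 8-11 with 34-residue pseudo-sequences."""
    return FeatureLayout(core_len=9, length_bounds=(8, 11), pseudo_len=34)


@pytest.fixture(scope="session")
def pseudo_pair():
    rng = np.random.default_rng(42)
    from madeconv.encoding import ALPHABET
    mk = lambda: "".join(ALPHABET[i] for i in rng.integers(0, 20, size=34))
    return (AllelePseudoSequence("AL-01", mk()),
            AllelePseudoSequence("AL-02", mk()))


@pytest.fixture(scope="session")
def tiny_trained_run():
    """A small trained two-allele-panel run shared by engine/metrics tests.

    World: 2 panel alleles with SA data plus background SA alleles; one
    two-allele panel.  Training is deliberately short but long enough that
    annotation of well-separated motifs is reliable.
    """
    from madeconv.engine import run_nnalign_ma
    from madeconv.network import TrainConfig
    from madeconv.simulate import FixtureSpec, build_training_bundle, make_world

    spec = FixtureSpec(
        n_alleles=2,
        panel_layout=((0, 1), (0,)),
        ma_only=(),
        low_abundance=(),
        n_ma_per_panel=100,
        n_sa_el=100,
        n_sa_ba=30,
        n_background_sa=4,
        n_sa_el_background=80,
        max_motif_pcc=0.15,
    )
    world = make_world(spec, 21)
    bundle = build_training_bundle(world, 21)
    config = TrainConfig(hidden_sizes=(10,), seeds_per_size=1, n_partitions=5,
                         n_iterations=30, burn_in=10, early_stopping=False,
                         length_bounds=spec.length_bounds,
                         n_rescale_peptides=1000, rescale_shift=50.0)
    run = run_nnalign_ma(bundle.sa, bundle.ma, world.panels,
                         world.pseudo_table, world.proteome, config, seed=21)
    return world, bundle, run
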