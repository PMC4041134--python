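import dataclasses

import pytest

from mirflow.simdata import SyntheticSpec, build_genome


def small_spec(**overrides) -> SyntheticSpec:
    """A fast, fully-featured synthetic study for unit tests."""
    base = dict(
        seed=11,
        genome_length=40_000,
        n_mirnas=8,
        n_known=4,
        n_de_up=2,
        n_de_down=2,
        de_fold_changes=[4.0, 4.0, 0.25, 0.25],
        depth_control=20_000,
        depth_treatment=20_000,
        n_decoys=4,
        background_fraction=0.02,
        n_background_positions=10,
    )
    base.update(overrides)
    return SyntheticSpec(**base)


@pytest.fixture(scope="session")
def tiny_spec() -> SyntheticSpec:
    return small_spec()


@pytest.fixture(scope="session")
def tiny_study(tiny_spec):
    """(genome, truth) shared across tests; treat as read-only."""
    return build_genome(tiny_spec)


@pytest.fixture(scope="session")
def tiny_run(tiny_spec):
    from mirflow.pipeline import run_synthetic_study

    return run_synthetic_study(tiny_spec)


def vary(spec: SyntheticSpec, **overrides) -> SyntheticSpec:
    return dataclasses.replace(spec, **overrides)
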