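import numpy as np
import pytest

from tpmtox import (
    AbrahamDescriptors,
    ChemicalRecord,
    ChemicalSet,
    PhaseSystem,
    SyntheticConfig,
    generate_set,
)


@pytest.fixture(scope="session")
def polymer_system():
    """A hand-written hydrophobic polymer-water LFER system."""
    return PhaseSystem(
        phase="polymer_A", counter_medium="water",
        c=0.2, e=0.4, s=-0.7, a=-1.8, b=-3.2, v=3.1,
        provenance="test fixture",
    )


@pytest.fixture(scope="session")
def air_water_system():
    return PhaseSystem(
        phase="air", counter_medium="water",
        c=-0.99, e=0.58, s=-2.55, a=-3.81, b=-4.84, v=0.87,
        provenance="test fixture",
    )


@pytest.fixture
def tiny_set():
    """Three chemicals with hand-picked descriptors and toxicities."""
    recs = (
        ChemicalRecord(
            id="chem1", name="one",
            descriptors=AbrahamDescriptors(E=0.6, S=0.5, A=0.3, B=0.4, V=0.8, L=3.9),
            log_lc50=-3.0, moa="baseline",
        ),
        ChemicalRecord(
            id="chem2", name="two",
            descriptors=AbrahamDescriptors(E=0.1, S=0.9, A=0.0, B=0.7, V=1.2, L=5.1),
            log_lc50=-4.5, moa="baseline",
        ),
        ChemicalRecord(
            id="chem3", name="three",
            descriptors=AbrahamDescriptors(E=1.3, S=0.2, A=0.6, B=0.1, V=2.0),
            log_lc50=None, moa="less_inert",
        ),
    )
    return ChemicalSet("tiny", recs)


@pytest.fixture(scope="session")
def noiseless_draw():
    """Small noiseless synthetic draw: toxicity exactly linear in logK."""
    cfg = SyntheticConfig(
        n_per_group={"baseline": 20, "less_inert": 12, "reactive": 0},
        true_neg_log_burden={"baseline": 1.4, "less_inert": 1.9, "reactive": 1.4},
        residual_sd=0.0,
        seed=11,
    )
    cset, truth = generate_set(cfg)
    return cfg, cset, truth


@pytest.fixture(scope="session")
def noisy_draw():
    """One draw under the default study conditions (n=115/73/75, sd=0.32)."""
    cfg = SyntheticConfig(seed=42)
    cset, truth = generate_set(cfg)
    return cfg, cset, truth


def group_arrays(cset, truth, group):
    """(subset, logK array) for one mode-of-action group of a draw."""
    sub = cset.subset(group)
    logk = np.asarray(truth["per_group"][group]["logk"], dtype=float)
    return sub, logk
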