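import pytest

from chromoreg import DeRecord, SimConfig, generate


@pytest.fixture(scope="session")
def small_bundle():
    """A 3-chromosome synthetic genome with mixed states."""
    cfg = SimConfig(
        n_chromosomes=3,
        genes_per_chromosome=[30, 20, 10],
        state_frequencies=(0.1, 0.08),
        seed=11,
    )
    return generate(cfg)


def records_from_states(states: dict[str, str]) -> list[DeRecord]:
    """DE records realising a given gene -> state mapping."""
    fc = {"U": 3.0, "D": -3.0, "O": 0.1}
    return [
        DeRecord(
            gene_id=g,
            value_cond1=10.0,
            value_cond2=10.0 * 2 ** fc[s],
            log2_fold_change=fc[s],
            q_value=0.001 if s in "UD" else 0.8,
            significant=s in "UD",
        )
        for g, s in states.items()
    ]
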