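import numpy as np
import pytest

from toxprospect.synthetic import (
    GeneratorConfig,
    generate_assembly_views,
    generate_precursors,
    generate_reference_set,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared across tests (fixed seed)."""
    config = GeneratorConfig(seed=11, n_precursors=60)
    records, truths = generate_precursors(config)
    views, truths = generate_assembly_views(records, truths, config)
    reference, alignments = generate_reference_set(truths, config)
    return {
        "config": config,
        "records": records,
        "truths": truths,
        "views": views,
        "reference": reference,
        "alignments": alignments,
    }


def random_protein(rng: np.random.Generator, length: int, alphabet: str = AA) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))
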