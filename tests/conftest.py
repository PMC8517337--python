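import pandas as pd
import pytest

from evfrac import (
    SyntheticConfig,
    build_presence_matrix,
    classify_table,
    compute_frequencies,
    fisher_differential,
    generate_study,
    partition_by_ratio,
)


@pytest.fixture(scope="session")
def study():
    """One default-condition synthetic meta-study shared across tests."""
    return generate_study(SyntheticConfig(rng_seed=11))


@pytest.fixture(scope="session")
def study_stats(study):
    """Classified labels, presence matrix, protein stats and partition for `study`."""
    labels, summary = classify_table(study.protocols)
    matrix = build_presence_matrix(study.identifications, labels)
    stats = fisher_differential(compute_frequencies(matrix))
    partition = partition_by_ratio(stats)
    return {
        "labels": labels,
        "summary": summary,
        "matrix": matrix,
        "stats": stats,
        "partition": partition,
    }


def toy_labels():
    return pd.DataFrame(
        {"dataset_id": ["d1", "d2"], "label": ["SEV", "LEV"], "reason": ["OK", "OK"]}
    )
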