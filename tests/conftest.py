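"""Shared synthetic fixtures.

The heavyweight objects (generated world + trained model) are
session-scoped so the many search/network/CLI tests reuse one SVM fit.
"""

import pytest

from spps import (
    FixtureSpec,
    ProteinDatabase,
    SVMParams,
    generate_database,
    train_svm,
)

SMALL_SPEC = FixtureSpec(n_proteins=60, n_pairs=160, seed=11)


@pytest.fixture(scope="session")
def small_world():
    """(db, dataset) for a 60-protein / 160-pair benchmark."""
    return generate_database(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_model(small_world):
    db, data = small_world
    return train_svm(data, db, params=SVMParams(tune=False, seed=1234))


@pytest.fixture(scope="session")
def db20(small_world):
    """First 20 proteins of the small world, annotations carried over."""
    db, _ = small_world
    records = list(db)[:20]
    ids = {r.id for r in records}
    anns = [a for pid, a in db.annotations.items() if pid in ids]
    kept = [
        type(a)(
            protein_id=a.protein_id,
            function=a.function,
            disease=a.disease,
            tissue_specificity=a.tissue_specificity,
            subcellular_location=a.subcellular_location,
            known_partners={p for p in a.known_partners if p in ids},
        )
        for a in anns
    ]
    return ProteinDatabase(records, kept, species="synthetic")


@pytest.fixture(scope="session")
def db15(small_world):
    db, _ = small_world
    return ProteinDatabase(list(db)[:15], species="synthetic")
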