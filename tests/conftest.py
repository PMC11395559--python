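"""Shared fixtures.

The trained-model fixtures are session-scoped because pretraining the
reference model and fine-tuning the task heads are the expensive steps; the
same trained models back both the behavioral unit tests and the acceptance
suite.  Every fixture is fully seeded, so the suite is deterministic.
"""

import numpy as np
import pytest

from dnalm_probe import (
    NextKmerClassifier,
    Prom300Classifier,
    ReferenceMaskedLM,
    SubsequenceSamplingScheme,
    SyntheticGenomeSpec,
    SyntheticPromoterSpec,
    TrainingConfig,
    build_masked_dataset,
    build_next_kmer_dataset,
    build_prom300_dataset,
    build_vocabulary,
    generate_genome,
    generate_promoters,
    sample_subsequences,
)

PERIOD_UNIT = "ACGTTAG"  # period 7 does not divide the 510-nt chunk, so
# next-k-mer chunks cycle through all phases


@pytest.fixture(scope="session")
def vocab4():
    return build_vocabulary(4)


@pytest.fixture(scope="session")
def periodic_genome():
    return generate_genome(
        SyntheticGenomeSpec(mode="periodic", length=1_300_000, repeat_unit=PERIOD_UNIT, seed=1)
    )


@pytest.fixture(scope="session")
def iid_genome():
    return generate_genome(SyntheticGenomeSpec(mode="iid", length=1_300_000, seed=10))


def _pretrain(genome, seed):
    scheme = SubsequenceSamplingScheme(p_full=0.5, full_len=60, min_len=20, seed=seed)
    subseqs = sample_subsequences([genome], scheme, k=4, count=2000)
    return ReferenceMaskedLM(k=4, seed=0).fit(subseqs)


@pytest.fixture(scope="session")
def periodic_model(periodic_genome):
    """Reference MLM pretrained on the periodic (fully context-determined) genome."""
    return _pretrain(periodic_genome, seed=1)


@pytest.fixture(scope="session")
def iid_model(iid_genome):
    """Reference MLM pretrained on the context-free iid genome."""
    return _pretrain(iid_genome, seed=2)


@pytest.fixture(scope="session")
def periodic_masked_samples(vocab4):
    held = generate_genome(
        SyntheticGenomeSpec(mode="periodic", length=100_000, repeat_unit=PERIOD_UNIT, seed=2)
    )
    subs = sample_subsequences(
        [held], SubsequenceSamplingScheme(full_len=60, min_len=20, seed=3), k=4, count=300
    )
    return build_masked_dataset(subs, vocab4, seed=5)


@pytest.fixture(scope="session")
def iid_masked_samples(vocab4):
    held = generate_genome(SyntheticGenomeSpec(mode="iid", length=150_000, seed=11))
    subs = sample_subsequences(
        [held], SubsequenceSamplingScheme(full_len=60, min_len=20, seed=3), k=4, count=300
    )
    return build_masked_dataset(subs, vocab4, seed=5)


@pytest.fixture(scope="session")
def periodic_nextkmer(periodic_genome, periodic_model):
    """(classifier, dataset) fine-tuned on the periodic genome, k=4."""
    ds = build_next_kmer_dataset([periodic_genome], k=4, max_samples=2500, seed=0)
    clf = NextKmerClassifier(model=periodic_model, k=4, config=TrainingConfig.desk_scale())
    return clf.fit_dataset(ds), ds


@pytest.fixture(scope="session")
def iid_nextkmer(iid_genome, iid_model):
    """(classifier, dataset) fine-tuned on the iid genome, k=4."""
    ds = build_next_kmer_dataset([iid_genome], k=4, max_samples=2500, seed=0)
    clf = NextKmerClassifier(model=iid_model, k=4, config=TrainingConfig.desk_scale())
    return clf.fit_dataset(ds), ds


@pytest.fixture(scope="session")
def prom300_control(iid_model):
    """(classifier, test_records) for planted-motif promoters vs shuffles."""
    promoters = generate_promoters(SyntheticPromoterSpec(n=250, seed=7))
    records = build_prom300_dataset(promoters, seed=8)
    rng = np.random.default_rng(0)
    order = rng.permutation(len(records))
    train = [records[i] for i in order[:400]]
    test = [records[i] for i in order[400:]]
    cfg = TrainingConfig.desk_scale(batch_size=16)
    clf = Prom300Classifier(model=iid_model, config=cfg)
    clf.fit([r.seq for r in train], [r.label for r in train])
    return clf, test
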