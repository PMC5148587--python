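import numpy as np
import pytest

import frfiwsa as fw


@pytest.fixture(scope="session")
def toy():
    dataset, truth = fw.separable_toy()
    return dataset, truth


@pytest.fixture(scope="session")
def toy_ranking(toy):
    dataset, _ = toy
    return fw.f_information_ranking(dataset)


@pytest.fixture(scope="session")
def toy_filtered(toy, toy_ranking):
    dataset, _ = toy
    return fw.filter_top_genes(dataset, toy_ranking, 2)


@pytest.fixture(scope="session")
def toy_hand_kb(toy):
    """Two hand-written rules over the toy's first gene: low -> class 1,
    high -> class 2, with an evenly spaced canonical partition per gene."""
    dataset, _ = toy

    def canonical(lo, hi):
        s = hi - lo
        return fw.MembershipPointSet((
            lo, lo + .25 * s, lo + .5 * s, lo + .375 * s, lo + .5 * s,
            lo + .75 * s, lo + .625 * s, lo + .75 * s, hi))

    mfs = [canonical(float(r.min()), float(r.max())) for r in dataset.values]
    a1 = np.zeros(dataset.n_genes, dtype=int)
    a1[0] = 1
    a2 = np.zeros(dataset.n_genes, dtype=int)
    a2[0] = 3
    return fw.KnowledgeBase(
        mfs, [fw.Rule(1, a1, 1), fw.Rule(1, a2, 2)], n_classes=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_kb(f, c, n_rules_per_class, gene_ranges, rng):
    """A random feasible knowledge base for oracle comparisons."""
    mfs = [fw.init_membership_points(lo, hi, rng) for lo, hi in gene_ranges]
    rules = fw.encode_rule_set(f, c, n_rules_per_class, rng)
    return fw.KnowledgeBase(mfs, rules, n_classes=c)
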