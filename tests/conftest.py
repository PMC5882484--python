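import numpy as np
import pytest

import confomer as cf


@pytest.fixture(scope="session")
def benzene():
    return cf.parse_smiles("c1ccccc1")


@pytest.fixture(scope="session")
def ethanol():
    return cf.parse_smiles("CCO")


@pytest.fixture(scope="session")
def hetero_split():
    """The canonical heteroscedastic vector dataset, split 2000/2000."""
    X, y = cf.make_vector_dataset(cf.heteroscedastic_spec(n=4000, seed=42))
    return (X[:2000], y[:2000]), (X[2000:], y[2000:])


@pytest.fixture(scope="session")
def ccp_by_ncm(hetero_split):
    """One 10-fold CCP per nonconformity measure on the shared train set."""
    train, _test = hetero_split
    params = cf.SvrParams(cost=1.0, epsilon=1e-3)
    out = {}
    for kind in ("abs_diff", "normalized", "log_normalized"):
        beta = 1.0 if kind == "log_normalized" else 0.0
        out[kind] = cf.ccp_fit(
            train, k=10, params=params,
            ncm=cf.NonconformityConfig(kind=kind, beta=beta),
            seed=42, n_features=200,
        )
    return out


@pytest.fixture(scope="session")
def strong_split():
    """The strongly heteroscedastic dataset, split 1500/1500."""
    X, y = cf.make_vector_dataset(
        cf.strongly_heteroscedastic_spec(n=3000, seed=42))
    return (X[:1500], y[:1500]), (X[1500:], y[1500:])


@pytest.fixture(scope="session")
def strong_ccps(strong_split):
    """CCPs per nonconformity measure on the strongly heteroscedastic
    training set (efficiency benchmarks)."""
    train, _test = strong_split
    params = cf.SvrParams(cost=1.0, epsilon=1e-3)
    out = {}
    for kind in ("abs_diff", "normalized", "log_normalized"):
        beta = 1.0 if kind == "log_normalized" else 0.0
        out[kind] = cf.ccp_fit(
            train, k=10, params=params,
            ncm=cf.NonconformityConfig(kind=kind, beta=beta),
            seed=42, n_features=200,
        )
    return out


@pytest.fixture(scope="session")
def molecule_split():
    """Synthetic-label molecule dataset with vocabulary and CSR matrices."""
    from confomer.linear_model import vectors_to_csr

    comps = cf.make_molecule_dataset(500, seed=11)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(comps))
    test = [comps[i] for i in perm[:100]]
    train = [comps[i] for i in perm[100:]]
    vocab = cf.build_vocabulary(train, (1, 2, 3), 1)
    Xtr = vectors_to_csr([cf.vectorize(c.mol, vocab) for c in train],
                         len(vocab))
    Xte = vectors_to_csr([cf.vectorize(c.mol, vocab) for c in test],
                         len(vocab))
    ytr = np.array([c.y for c in train])
    yte = np.array([c.y for c in test])
    return {"train": train, "test": test, "vocab": vocab,
            "Xtr": Xtr, "Xte": Xte, "ytr": ytr, "yte": yte}
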