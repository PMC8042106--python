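"""Shared fixtures.

The two session fixtures at the bottom run the full diagnostic pipeline at
study scale (10 pairs, 10 trials, all three algorithms) once per session; the
acceptance tests share them instead of re-running the pipeline per test.
"""

import numpy as np
import pytest

import promisig as ps


@pytest.fixture(scope="session")
def small_library():
    """Two qualifying pairs at default sizes (50+50 ST, 100 DT), local mode."""
    return ps.generate_library(ps.LibraryConfig(n_pairs=2, seed=11))


@pytest.fixture(scope="session")
def small_pair_model(small_library):
    """A balanced dataset, one split, and a fitted SVM for the first pair."""
    lib = small_library[0]
    ds = ps.balance_dataset(lib.pair, lib.st_a, lib.st_b, lib.dt, seed=3)
    trial = ps.make_trials(ds, n_trials=1, master_seed=3)[0]
    fps = {c.compound_id: ps.fingerprint(c.smiles) for c in ds.compounds}
    ids = [c.compound_id for c in ds.compounds]
    X = np.stack([fps[i][0].bits for i in ids])
    y = np.array([1 if c.klass == "DT" else -1 for c in ds.compounds])
    rows = {cid: i for i, cid in enumerate(ids)}
    train = sorted(rows[c] for c in trial.train)
    test = sorted(rows[c] for c in trial.test)
    model = ps.train(
        "svm", X[train], y[train], ps.CVConfig(seed=3), pair_id=lib.pair.pair_id
    )
    return {
        "library": lib,
        "dataset": ds,
        "fps": fps,
        "ids": ids,
        "X": X,
        "y": y,
        "train": train,
        "test": test,
        "model": model,
    }


_STUDY_SEED = 2021


@pytest.fixture(scope="session")
def local_run():
    """Study-scale local-mode run: 10 pairs x 10 trials x 3 algorithms."""
    config = ps.RunConfig.from_seed(
        _STUDY_SEED,
        library=ps.LibraryConfig(n_pairs=10, mode="local"),
        n_trials=10,
    )
    return ps.run_experiment(config)


@pytest.fixture(scope="session")
def global_run():
    """Same library sizes and seed, global mode (shared signature)."""
    config = ps.RunConfig.from_seed(
        _STUDY_SEED,
        library=ps.LibraryConfig(n_pairs=10, mode="global"),
        n_trials=10,
        attribution=False,
    )
    return ps.run_experiment(config)
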