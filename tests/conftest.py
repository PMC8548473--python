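import pytest

from morphnet.corpus import from_records
from morphnet.simulate import SimParams, simulate_dyad


def make_table(rows, **common):
    """Build a validated corpus table from terse row dicts."""
    records = []
    for row in rows:
        rec = {
            "dyad_id": "dyad1",
            "session_index": 1,
            "age_days": 664,
            "speaker": "CS",
            "person": "",
            "number": "",
            "gender": "",
            "count": 1,
        }
        rec.update(common)
        rec.update(row)
        records.append(rec)
    return from_records(records)


@pytest.fixture
def fig_example_table():
    """Two wordforms on one root: l-m-d in Piel past and future 3SgM."""
    rows = [
        {"root": "l-m-d", "binyan": "Piel", "temporal": "Past",
         "person": "3", "number": "Sg", "gender": "Masc"},
        {"root": "l-m-d", "binyan": "Piel", "temporal": "Future",
         "person": "3", "number": "Sg", "gender": "Masc"},
    ]
    return make_table(rows)


@pytest.fixture
def worked_example_table():
    """Four roots sharing the Qal present feminine singular pattern."""
    rows = [
        {"root": root, "binyan": "Qal", "temporal": "Present",
         "number": "Sg", "gender": "Fm"}
        for root in ("r-?-y", "k-?-b", "n-w-H", "b-w-?")
    ]
    return make_table(rows, dyad_id="dyad2", session_index=3, age_days=641)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dyad shared across tests (8 sessions)."""
    params = SimParams(
        n_sessions=8,
        age_end_days=664 + 8 * 3,
        cds_tokens_mean=250.0,
        cs_tokens_mean=60.0,
    )
    table, truth = simulate_dyad(params, seed=42)
    return params, table, truth


@pytest.fixture(scope="session")
def default_sim():
    """One default-parameter simulated dyad (47 sessions)."""
    table, truth = simulate_dyad(SimParams(), seed=1)
    return table, truth


def random_bipartite_network(rng, max_roots=8, max_patterns=8):
    """A random small bipartite network with >=1 link (for oracle tests)."""
    import numpy as np

    from morphnet.networks import BipartiteNetwork

    n_r = int(rng.integers(1, max_roots + 1))
    n_p = int(rng.integers(1, max_patterns + 1))
    roots = tuple(f"r-{i}-x" for i in range(n_r))
    patterns = tuple(f"P.{j}" for j in range(n_p))
    mask = rng.random((n_r, n_p)) < 0.4
    if not mask.any():
        mask[rng.integers(n_r), rng.integers(n_p)] = True
    edges = {
        (roots[i], patterns[j]): 1
        for i in range(n_r)
        for j in range(n_p)
        if mask[i, j]
    }
    active_r = tuple(sorted({r for r, _ in edges}))
    active_p = tuple(sorted({p for _, p in edges}))
    return BipartiteNetwork("d", "CS", 1, 700, active_r, active_p, edges)
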