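import numpy as np
import pandas as pd
import pytest

from microtrans.pedigree_kinship import PedigreeTable
from microtrans.simdata import SimConfig, simulate_dataset


def make_pedigree(rows):
    """rows: (id, dam, sire, sex[, birth_day])."""
    recs = []
    for r in rows:
        rid, dam, sire, sex = r[:4]
        birth = r[4] if len(r) > 4 else 0
        recs.append({"id": rid, "dam": dam, "sire": sire, "sex": sex,
                     "subspecies": "MMM", "deme": "d0", "birth_day": birth})
    return PedigreeTable(pd.DataFrame(recs))


@pytest.fixture(scope="session")
def trio_pedigree():
    return make_pedigree([
        ("F1", None, None, "F", 0),
        ("M1", None, None, "M", 0),
        ("kid", "F1", "M1", "F", 30),
    ])


@pytest.fixture(scope="session")
def small_dataset():
    """One-subspecies simulated data set reused by read-only tests."""
    cfg = SimConfig(
        n_founders_per_subspecies=10, max_individuals_per_subspecies=50,
        n_asv=60, depth_range=(1000, 3000), visits_per_mouse=80,
        subspecies=("MMM",), p_litter_per_cycle=0.3, sections=("colon",),
        seed=11,
    )
    return simulate_dataset(cfg)


def random_pedigree(rng, n, p_parents=0.7):
    """Random sex-consistent pedigree of n individuals in birth order."""
    rows = []
    males, females = [], []
    for k in range(n):
        sex = "M" if rng.random() < 0.5 else "F"
        dam = sire = None
        if males and females and rng.random() < p_parents:
            dam = females[int(rng.integers(len(females)))]
            sire = males[int(rng.integers(len(males)))]
        rid = f"i{k}"
        rows.append((rid, dam, sire, sex, k))
        (males if sex == "M" else females).append(rid)
    return make_pedigree(rows)


def recursive_kinship(pedigree):
    """Independent path-counting kinship oracle (recursive, memoised).

    Returns 2x the kinship matrix with diagonal 1 + F, for comparison with
    the tabular-method numerator relationship matrix.
    """
    t = pedigree.table.set_index("id")
    order = pedigree.topological_order()
    pos = {m: k for k, m in enumerate(order)}
    memo = {}

    def phi(a, b):
        if a is None or b is None:
            return 0.0
        key = (a, b) if a <= b else (b, a)
        if key in memo:
            return memo[key]
        if a == b:
            val = 0.5 * (1.0 + phi(t.at[a, "dam"], t.at[a, "sire"]))
        else:
            # recurse on the later-born member
            young = a if pos[a] > pos[b] else b
            old = b if young == a else a
            val = 0.5 * (phi(t.at[young, "dam"], old) + phi(t.at[young, "sire"], old))
        memo[key] = val
        return val

    ids = pedigree.ids
    n = len(ids)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            K[i, j] = K[j, i] = 2.0 * phi(ids[i], ids[j])
    return K
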