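"""Shared fixtures: small hand-built pedigrees and cached simulations."""

import numpy as np
import pandas as pd
import pytest

from pedgibbs.pedigree import from_records


@pytest.fixture(scope="session")
def trio_ped():
    """Two unrelated founders and their offspring."""
    return from_records(
        [
            ("A", None, None, "M", 1990),
            ("B", None, None, "F", 1990),
            ("C", "A", "B", "F", 1995),
        ]
    )


@pytest.fixture(scope="session")
def fullsib_ped():
    """Full sibs C, D from unrelated founders; E is their (inbred) offspring."""
    return from_records(
        [
            ("A", None, None, "M", 1990),
            ("B", None, None, "F", 1990),
            ("C", "A", "B", "M", 1995),
            ("D", "A", "B", "F", 1995),
            ("E", "C", "D", "M", 2000),
        ]
    )


def random_pedigree(rng, n=50, n_founders=6, start_year=1990):
    """Random multi-generation pedigree with plenty of inbreeding."""
    recs = []
    for i in range(n):
        if i < n_founders:
            recs.append((f"I{i}", None, None, "M" if i % 2 else "F", start_year))
        else:
            males = [j for j in range(i) if j % 2 == 1]
            females = [j for j in range(i) if j % 2 == 0]
            s = int(rng.choice(males))
            d = int(rng.choice(females))
            recs.append(
                (f"I{i}", f"I{s}", f"I{d}", "M" if i % 2 else "F",
                 start_year + i // n_founders)
            )
    return from_records(recs)


@pytest.fixture(scope="session")
def tiny_fixture():
    from pedgibbs.synthetic_data import make_fixture

    return make_fixture("tiny")


@pytest.fixture(scope="session")
def paperlike_fixture():
    from pedgibbs.synthetic_data import make_fixture

    return make_fixture("paperlike")


def intercept_only_table(y, year=2000):
    """Degenerate phenotype table whose design reduces to an intercept."""
    n = len(y)
    return pd.DataFrame(
        {
            "calf_id": ["X0"] * n,
            "dam_id": ["X1"] * n,
            "sire_id": [""] * n,
            "survival": y,
            "calving_year": [year] * n,
            "parity": ["multiparous"] * n,
            "dam_age_days": [1000.0] * n,
            "litter_code": ["F"] * n,
        }
    )


@pytest.fixture(scope="session")
def intercept_ped():
    return from_records(
        [("X0", None, None, "F", 2000), ("X1", None, None, "F", 1995)]
    )
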