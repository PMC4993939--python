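from __future__ import annotations

import pytest

from fabflux import (
    FluxBalanceModel,
    build_curated_network,
    enumerate_elementary_modes,
    packaged_expression_table,
)


@pytest.fixture(scope="session")
def curated():
    return build_curated_network()


@pytest.fixture(scope="session")
def curated_ems(curated):
    return enumerate_elementary_modes(curated)


@pytest.fixture(scope="session")
def reference_fba(curated):
    return FluxBalanceModel.reference_problem(curated).fit()


@pytest.fixture(scope="session")
def expression_records():
    return packaged_expression_table()


def emset_key(emset):
    """Order-free canonical representation of a mode set for equality checks."""
    return sorted(
        tuple(sorted((r, str(c)) for r, c in m.coefficients.items() if c != 0))
        for m in emset
    )
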