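"""Shared fixtures: the three experimentally characterized precursors.

All sequences and printed masses are inputs to the tests; expected values in
individual test modules are either published observations or frozen outputs
of the independent oracles defined alongside the tests.
"""

import pytest

# Lp1 (citrulassin-like), Lp2 (leepeptin), Lp3 (chaxapeptin) precursors
LP1_PRECURSOR = "MKKAYEAPTLVRLGSFRRKTGLLQRSGNDRLILSKN"
LP2_PRECURSOR = "MEHDEKTPYETPAVYGLGAFAEETGLYGVRNDEEINWHFDYWT"
LP3_PRECURSOR = "MTELQPEAYEAPSLIEVGEFSEDTLGFGSKPLDSFGLNFF"

LEEPEPTIN_CORE = "LYGVRNDEEINWHFDYWT"
LEEPEPTIN_RING = 8
CHAXAPEPTIN_CORE = "GFGSKPLDSFGLNFF"


@pytest.fixture
def lp2_precursor() -> str:
    return LP2_PRECURSOR


@pytest.fixture
def lp3_precursor() -> str:
    return LP3_PRECURSOR


@pytest.fixture
def lp1_precursor() -> str:
    return LP1_PRECURSOR
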