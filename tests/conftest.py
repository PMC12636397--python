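"""Shared fixtures: synthetic homeodomains with controlled rule profiles."""

from __future__ import annotations

import pytest

from hdcoop import HDSequence, default_ruleset

# A synthetic rule-compliant homeodomain: arginines at 2/3/5, no E4, P26,
# non-basic 28, E32, E42, A43, R44, Q46, Q50, N51. Padding residues are
# alanine — only rule/heuristic-relevant positions matter for these tests.
_BASE = list("A" * 60)
for _pos, _aa in {
    2: "R", 3: "R", 4: "N", 5: "R", 26: "P", 28: "V", 32: "E",
    42: "E", 43: "A", 44: "R", 46: "Q", 50: "Q", 51: "N",
}.items():
    _BASE[_pos - 1] = _aa
COMPLIANT_RESIDUES = "".join(_BASE)


def make_hd(
    seq_id: str = "syn", family: str = "PairedLike", offset: int | None = None,
    **substitutions: str,
) -> HDSequence:
    """Synthetic HD from the compliant scaffold; kwargs like p44="Q" substitute."""
    residues = list(COMPLIANT_RESIDUES)
    for key, aa in substitutions.items():
        pos = int(key.lstrip("p"))
        residues[pos - 1] = aa
    return HDSequence(seq_id, family, "".join(residues), hd_start_in_protein=offset)


@pytest.fixture
def ruleset():
    return default_ruleset()


@pytest.fixture
def compliant_seq():
    return make_hd("compliant")


@pytest.fixture
def crx_like():
    """Synthetic stand-in for a CRX-type K50 domain: carries E4 and K50."""
    return make_hd("CRX", p4="E", p50="K")


@pytest.fixture
def phox2b_like():
    """Synthetic stand-in for a PHOX2B-type fully compliant Q50 domain."""
    return make_hd("PHOX2B")


@pytest.fixture
def arx_like():
    """Synthetic stand-in for an ARX-type fully compliant Q50 domain."""
    return make_hd("ARX")
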