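"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from phylocurate.io import AlignedSequence, OGAlignment

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def mk_aln(og_id: str, rows: list[tuple[str, str, str]]) -> OGAlignment:
    """Build an OGAlignment from (taxon_id, seq_id, residues) triples."""
    return OGAlignment(og_id, [AlignedSequence(t, s, r) for t, s, r in rows])


def random_aligned_rows(
    rng: np.random.Generator, n_rows: int, n_cols: int, gap_prob: float = 0.3
) -> list[tuple[str, str, str]]:
    """Random gappy rows for property tests (taxa all distinct)."""
    rows = []
    for i in range(n_rows):
        chars = [
            "-" if rng.random() < gap_prob else AA20[rng.integers(0, 20)]
            for _ in range(n_cols)
        ]
        rows.append((f"t{i:02d}", f"s{i}", "".join(chars)))
    return rows


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231114)
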