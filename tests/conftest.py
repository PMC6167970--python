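"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from gilakit.rad_filtering import MISSING_GT, LocusRecord


def make_record(
    contig: str = "c1",
    pos: int = 1,
    ref: str = "A",
    alts: tuple[str, ...] = ("G",),
    genotypes: list[str] | None = None,
    depths=None,
    n: int = 4,
) -> LocusRecord:
    """Build a LocusRecord with simple defaults for ``n`` individuals."""
    if genotypes is None:
        genotypes = ["0/0"] * n
    if depths is None:
        depths = np.full(len(genotypes), 30)
    return LocusRecord(
        contig=contig, pos=pos, ref=ref, alts=alts,
        genotypes=list(genotypes), depths=np.asarray(depths),
    )


def typed_record(contig: str, n_typed: int, n_total: int, pos: int = 1) -> LocusRecord:
    """Record typed in the first ``n_typed`` of ``n_total`` individuals."""
    gts = ["0/1"] * n_typed + [MISSING_GT] * (n_total - n_typed)
    return make_record(contig=contig, pos=pos, genotypes=gts, n=n_total)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
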