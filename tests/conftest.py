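"""Shared fixtures: small deterministic libraries and guide factories."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pairscreen import GuideRecord, build_pair_set
from pairscreen.simulate import _random_protospacers

_PROTOS = _random_protospacers(np.random.default_rng(20240917), 400)
_counter = itertools.count()


def fresh_protospacer() -> str:
    return _PROTOS[next(_counter) % len(_PROTOS)]


@pytest.fixture(scope="session")
def proto_pool() -> list[str]:
    """A pool of distinct 20-mers for building ad-hoc guides."""
    return list(_PROTOS)


def make_guides(n_genes: int, guides_per_gene: int = 2, start: int = 0) -> list[GuideRecord]:
    protos = iter(_PROTOS[start:])
    out = []
    for i in range(1, n_genes + 1):
        for k in range(1, guides_per_gene + 1):
            out.append(GuideRecord(f"G{i:03d}_g{k}", f"G{i:03d}", next(protos)))
    return out


def make_nt(n: int = 15, start: int = 300) -> list[GuideRecord]:
    protos = iter(_PROTOS[start:])
    return [
        GuideRecord(f"NT_{j:02d}", "NT", next(protos), "non_targeting")
        for j in range(1, n + 1)
    ]


@pytest.fixture(scope="session")
def nt_guides() -> list[GuideRecord]:
    return make_nt()


@pytest.fixture(scope="session")
def mini_design(nt_guides):
    """3 genes x 2 guides plus the 15 NT controls."""
    return build_pair_set(make_guides(3), nt_guides, orientation_seed=11)
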