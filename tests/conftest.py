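import json
from importlib import resources

import numpy as np
import pytest

from domainscout.msa import Msa


@pytest.fixture(scope="session")
def raw_property_table() -> dict:
    """The shipped property classes, read directly from package data so the
    enumeration oracles do not depend on the PropertyTable code path."""
    with resources.files("domainscout.data").joinpath("properties.json").open() as fh:
        raw = json.load(fh)
    return {p["name"]: set(p["members"]) for p in raw["properties"]}


@pytest.fixture
def small_msa() -> Msa:
    return Msa(
        (
            ("s1", "MKVLAT-GD"),
            ("s2", "MKVLATSGD"),
            ("s3", "MRVLATSGE"),
        )
    )


def random_profile_hmm(rng: np.random.Generator, M: int):
    """A structurally valid random model (normalized rows, uniform entry)."""
    from domainscout.hmm import ProfileHMM

    def dirichlet(shape):
        x = rng.gamma(1.0, size=shape)
        return x / x.sum(axis=-1, keepdims=True)

    t = dirichlet((M, 4))
    t[M - 1] = [0.0, 0.0, 0.0, 1.0]
    ti = dirichlet((M, 2))
    td = dirichlet((M, 2))
    td[M - 1] = [1.0, 0.0]
    bg = dirichlet(20)
    return ProfileHMM(
        match_emissions=dirichlet((M, 20)),
        insert_emissions=np.tile(bg, (M + 1, 1)),
        t_mm=t[:, 0], t_mi=t[:, 1], t_md=t[:, 2], t_me=t[:, 3],
        t_im=ti[:, 0], t_ii=ti[:, 1],
        t_dm=td[:, 0], t_dd=td[:, 1],
        entry=np.full(M, 1.0 / M),
        background=bg,
    )
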