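"""Shared fixtures: small synthetic datasets and site-record builders."""

from __future__ import annotations

import numpy as np
import pytest

from sispec.annotation import SiteRecord
from sispec.simulate import BASES, SimulationConfig, simulate_triplet_alignment


def make_site_records(ds) -> list[SiteRecord]:
    """SiteRecords (with ingroup columns) from a TripletDataset, as the
    pipeline would construct them after intersection + polymorphism attach."""
    cfg = ds.config
    n_int, L = cfg.n_introns, cfg.intron_length
    sites = []
    for i in range(n_int):
        for k in range(L):
            col = "".join(BASES[b] for b in ds.haplotypes[:, i, k])
            sites.append(
                SiteRecord(
                    intron_id=f"i{i}",
                    chrom={"A": "2R", "B": "2R"},
                    pos={"A": i * L + k, "B": i * L + k},
                    ref_allele={
                        "A": BASES[ds.refs["in1"][i, k]],
                        "B": BASES[ds.refs["in2"][i, k]],
                    },
                    outgroup_allele=BASES[ds.refs["out"][i, k]],
                    ingroup_column=col,
                    intron_id_b=f"i{i}",
                )
            )
    return sites


@pytest.fixture(scope="session")
def triplet_dataset():
    """A mid-sized simulation with a planted GC-favoring force."""
    cfg = SimulationConfig(
        gamma=1.5,
        kappa=3.0,
        n=21,
        n_introns=600,
        seed=11,
        theta_ws=380,
        theta_sw=350,
        theta_neu=250,
    )
    return simulate_triplet_alignment(cfg)


@pytest.fixture(scope="session")
def triplet_sites(triplet_dataset):
    return make_site_records(triplet_dataset)
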