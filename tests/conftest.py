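"""Shared fixtures: small synthetic studies generated once per session."""

import pandas as pd
import pytest

from homeolyze.synth import (
    SimConfig,
    generate_counts,
    generate_reads,
    generate_truth,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=101, n_genes=600)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    """Default-condition study: truth, counts, samples for 600 genes."""
    truth = generate_truth(small_cfg)
    counts, samples = generate_counts(truth, small_cfg)
    return {"truth": truth, "counts": counts, "samples": samples,
            "lengths": truth["length"], "config": small_cfg}


@pytest.fixture(scope="session")
def readsim(tmp_path_factory):
    """Error-free read-level simulation for one polyploid (oracle fixture)."""
    cfg = SimConfig(seed=9, n_genes=60, error_rate=0.0, chimera_rate=0.0,
                    depth=100)
    truth = generate_truth(cfg)
    out = tmp_path_factory.mktemp("readsim")
    files = generate_reads(truth, cfg, out, accessions=["Maxxa"])
    files["truth"] = truth
    files["config"] = cfg
    return files


@pytest.fixture()
def toy_counts():
    """Hand-sized class-count table for two accessions (1 diploid, 1 polyploid)."""
    rows = []
    samples = pd.DataFrame(
        {
            "sample_id": ["A2_1", "A2_2", "Mx_1", "Mx_2"],
            "accession": ["A2", "A2", "Mx", "Mx"],
            "genome": ["A", "A", "AD", "AD"],
            "replicate": [1, 2, 1, 2],
        }
    )
    for g, (a, d, x, n) in {
        "g1": (10, 20, 1, 30),
        "g2": (5, 5, 0, 10),
    }.items():
        for sid, genome in zip(samples["sample_id"], samples["genome"]):
            if genome == "A":
                rows.append((g, sid, a + d, 0, 0, n))
            else:
                rows.append((g, sid, a, d, x, n))
    counts = pd.DataFrame(
        rows, columns=["gene_id", "sample_id", "n_A", "n_D", "n_X", "n_N"]
    )
    return counts, samples
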