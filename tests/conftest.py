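import pathlib

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import rbnskit as rk

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

#: Conditions of the standard planted recovery experiment: two motif
#: families at weight 4, 50k reads per sample, seed 1.
PLANTED_AFFINITIES = {"YGAC": 4.0, "GACR": 4.0}
PLANTED_N = 50_000
PLANTED_SEED = 1


def random_inserts(rng: np.random.Generator, n: int, length: int = 20) -> list[str]:
    bases = np.array(list("ACGT"))
    return ["".join(bases[rng.integers(0, 4, length)]) for _ in range(n)]


@pytest.fixture(scope="session")
def planted_run(tmp_path_factory) -> dict:
    """Simulate the standard planted experiment and run the full pipeline once.

    Shared by the recovery tests; everything downstream (enrichment table,
    selection, consensus) is recomputed from the emitted FASTQ files.
    """
    d = tmp_path_factory.mktemp("planted")
    spec = rk.RBNSSimSpec(
        n_pulldown=PLANTED_N, n_control=PLANTED_N,
        affinities=dict(PLANTED_AFFINITIES), seed=PLANTED_SEED,
    )
    sim_manifest = rk.simulate_rbns_reads(spec, out_dir=d)
    run_manifest = rk.run_rbns_pipeline(
        d / "pulldown.fastq", d / "control.fastq", d / "out"
    )
    table = pd.read_csv(d / "out" / "enrichment_6.tsv", sep="\t", comment="#")
    consensus_path = d / "out" / "consensus.txt"
    return {
        "dir": d,
        "sim_manifest": sim_manifest,
        "run_manifest": run_manifest,
        "enrichment_6": table,
        "selected": list(table.loc[table["selected"] == 1]
                         .sort_values("rank")["kmer"]),
        "consensus": consensus_path.read_text().strip()
                     if consensus_path.exists() else "",
    }
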