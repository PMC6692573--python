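import numpy as np
import pytest

from drafts import synthetic_data as sd
from drafts.library_io import Construct, Library
from drafts.read_processing import QcTally, process_fastq


@pytest.fixture(scope="session")
def tiny_library() -> Library:
    return Library(
        [
            Construct("A", "ACGT" * 10, "AAAACCCCGGGG", "TTAAGGAG"),
            Construct("B", "TTGACAACGT" * 4, "TTTTAAAACCCC", "TTAAGGAG"),
        ],
        name="tiny",
    )


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """60-construct simulated sample processed end to end (moderate depth)."""
    outdir = tmp_path_factory.mktemp("sim_small")
    lib, truth = sd.generate_library(60, seed=11)
    sd.assign_truth(lib, truth, seed=12)
    sim = sd.simulate_reads(
        lib, truth, outdir, depth_dna=60_000, depth_rna=60_000, seed=13
    )
    tally = QcTally()
    reads = []
    for (kind, rep), path in sim.fastq.items():
        reads.extend(
            process_fastq(lib, path, kind, rep, adaptor=sd.DEFAULT_ADAPTOR, tally=tally)
        )
    return {"lib": lib, "truth": truth, "sim": sim, "reads": reads, "tally": tally}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
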