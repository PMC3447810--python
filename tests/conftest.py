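import numpy as np
import pytest

from promotile.pipeline import PipelineConfig, run_all
from promotile.simulate import SimulationParams, simulate_genome, simulate_tiling


@pytest.fixture(scope="session")
def synthetic_run():
    """Full default pipeline run on the seed-1 synthetic dataset."""
    return run_all(PipelineConfig(seed=1, n_reps=10000))


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Seed-1 synthetic genome + truth + raw replicate tracks."""
    params = SimulationParams(seed=1)
    genome, genes, truth = simulate_genome(params)
    tracks = simulate_tiling(truth)
    return genome, genes, truth, tracks


@pytest.fixture()
def toy_genome_fasta(tmp_path):
    rng = np.random.default_rng(7)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
    path = tmp_path / "genome.fasta"
    path.write_text(f">chr1 toy\n{seq}\n")
    return path, seq


def write_gff(tmp_path, rows, name="genes.gff3"):
    """rows: (type, start1, end1, strand, id) in GFF3 1-based coords."""
    lines = ["##gff-version 3"]
    for ftype, s, e, strand, fid in rows:
        lines.append(
            f"chr1\ttest\t{ftype}\t{s}\t{e}\t.\t{strand}\t.\tID={fid}"
        )
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path
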