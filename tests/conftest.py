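import numpy as np
import pytest

from tsrnakit import SimConfig, simulate_counts, simulate_truth, emit_fastq
from tsrnakit.reference import ReferenceSet, TRNAGeneRecord
from tsrnakit.simulate import sample_names


def _random_body(rng, length=72, anticodon="AGG", a_start=34):
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length)
    body = arr.tobytes().decode()
    return body[: a_start - 1] + anticodon + body[a_start + 2 :]


@pytest.fixture(scope="session")
def pro_agg_family():
    """Four identical Pro-AGG isodecoders (mature length 75, CCA included)."""
    rng = np.random.default_rng(42)
    body = _random_body(rng, length=72, anticodon="AGG", a_start=34)
    genes = [
        TRNAGeneRecord.from_parts(
            gene_id=f"Pro-AGG-{i}", body_seq=body, anticodon_start=34,
            leader_seq="GATTACA" * 3, trailer_seq="TTGACCA" * 4)
        for i in range(1, 5)
    ]
    return ReferenceSet(genes=genes)


@pytest.fixture(scope="session")
def sim_refs():
    """A modest random reference set used by alignment tests."""
    cfg = SimConfig(n_families=6, isodecoders_per_family=3, n_species=10,
                    rng_seed=5)
    _, refs = simulate_truth(cfg)
    return refs


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """Error-free synthetic study: truth, counts and FASTQ files."""
    cfg = SimConfig(n_species=60, depth=20_000, error_rate=0.0,
                    n_per_group=2, rng_seed=11)
    manifest, refs = simulate_truth(cfg)
    counts = simulate_counts(manifest, cfg)
    outdir = tmp_path_factory.mktemp("fastq")
    paths = emit_fastq(manifest, counts, outdir, cfg)
    return {"cfg": cfg, "manifest": manifest, "refs": refs,
            "counts": counts, "paths": paths,
            "samples": sample_names(cfg)}
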