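import numpy as np
import pandas as pd
import pytest

from ecomethyl.genome import GenomeSpec
from ecomethyl.pipeline import run_pipeline


def make_sites(rows):
    """Build a CX-style site frame from (chrom, pos, strand, meth, unmeth, context)."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "meth_count", "unmeth_count", "context"]
    )
    df["trinucleotide"] = df["context"].map({"CG": "CGA", "CHG": "CAG", "CHH": "CAT"})
    return df


def random_sites(rng, chrom="chr1", size=10_000, n=300, contexts=("CG", "CHG", "CHH")):
    pos = np.sort(rng.choice(np.arange(1, size + 1), size=n, replace=False))
    depth = rng.integers(0, 40, size=n)
    meth = rng.binomial(depth, rng.random(n))
    return make_sites(
        [
            (
                chrom,
                int(p),
                "+" if i % 2 == 0 else "-",
                int(m),
                int(d - m),
                contexts[i % len(contexts)],
            )
            for i, (p, d, m) in enumerate(zip(pos, depth, meth))
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_genome():
    return GenomeSpec(chrom_sizes={"chr1": 10_000, "chr2": 8_000})


@pytest.fixture(scope="session")
def toy_run(tmp_path_factory):
    """One full pipeline run on the default toy dataset, shared by recovery tests."""
    outdir = tmp_path_factory.mktemp("toy_run")
    cfg = outdir / "config.yaml"
    cfg.write_text("seed: 1\npermutation:\n  n_perm: 1000\n")
    manifest = run_pipeline(cfg, outdir=outdir / "out")
    return outdir / "out", manifest
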