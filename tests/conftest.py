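import numpy as np
import pandas as pd
import pytest

from lncnet.simulate import SimulationConfig, generate_dataset
from lncnet.types import ExpressionMatrix, Transcript, STAGES, N_REPLICATES


def make_design():
    return {f"{st}_{r}": (st, r) for st in STAGES for r in range(1, N_REPLICATES + 1)}


def make_expression(values: dict[str, list[float]], counts: dict[str, list[int]] | None = None):
    design = make_design()
    samples = list(design)
    fpkm = pd.DataFrame(values, index=samples).T
    fpkm.columns = samples
    cdf = None
    if counts is not None:
        cdf = pd.DataFrame(counts, index=samples).T
        cdf.columns = samples
    return ExpressionMatrix(fpkm=fpkm, design=design, counts=cdf)


def random_transcripts(rng: np.random.Generator, n: int, n_chrom: int = 3) -> list[Transcript]:
    """Random valid transcript models for round-trip and oracle tests."""
    out = []
    for i in range(n):
        n_ex = int(rng.integers(1, 6))
        pos = int(rng.integers(1, 500_000))
        exons = []
        for _ in range(n_ex):
            length = int(rng.integers(50, 2000))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(100, 5000))
        out.append(
            Transcript(
                transcript_id=f"T{i:04d}",
                gene_id=f"G{i:04d}",
                chrom=f"chr{int(rng.integers(1, n_chrom + 1))}",
                strand="+" if rng.random() < 0.5 else "-",
                exons=tuple(exons),
                class_code=str(rng.choice(["=", "u", "x", "j", "c"])),
                biotype=str(rng.choice(["mRNA", "lncRNA_novel", "TUCP", "unclassified"])),
            )
        )
    return out


SMALL_CONFIG = SimulationConfig(
    seed=7,
    n_mrna=60,
    n_lncrna=30,
    n_lncrna_annotated=5,
    n_tucp=10,
    n_single_exon=5,
    n_short=5,
    n_low_expression=5,
    n_mirna=6,
    trans_pair_count=4,
    planted_triads=3,
    n_gene_sets=6,
    gene_set_size=8,
    n_ppi_edges=40,
)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_dataset(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_bundle():
    """The full-scale study-condition bundle (2,000 transcripts, seed 1)."""
    return generate_dataset(SimulationConfig(seed=1))
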