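from __future__ import annotations

import numpy as np
import pytest

from casscan.genome_io import Contig, GeneRecord, GenomeAnnotation
from casscan.synthetic_panel import SyntheticPanelConfig, simulate_panel

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def make_genome(
    strain_id: str,
    genes: list[tuple],
    length: int | None = None,
    circular: bool = False,
    contig_id: str = "chr",
):
    """Compact genome builder: genes = [(gene_id, start, end, strand[, seq])]."""
    records = [
        GeneRecord(
            gene_id=g[0], contig_id=contig_id, start=g[1], end=g[2], strand=g[3],
            protein_seq=g[4] if len(g) > 4 else None,
        )
        for g in genes
    ]
    if length is None:
        length = max(max(g.start, g.end) for g in records) + 100
    return GenomeAnnotation(
        strain_id=strain_id,
        contigs=[Contig(contig_id, length, circular)],
        genes=records,
    )


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(len(AA20), size=length))


def mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(out)) < rate):
        out[i] = AA20.replace(out[i], "")[int(rng.integers(19))]
    return "".join(out)


@pytest.fixture(scope="session")
def zero_div_panel():
    """Small noise-free panel with both variants present."""
    cfg = SyntheticPanelConfig(
        n_strains=16, seed=11, divergence=0.0, switch_prob=0.3,
        target_odds_ratio=2.0,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def default_panel():
    """Small panel with divergence and loss, for end-to-end smoke tests."""
    cfg = SyntheticPanelConfig(
        n_strains=12, seed=5, divergence=0.05, switch_prob=0.3, loss_prob=0.1,
        target_odds_ratio=2.67,
    )
    return simulate_panel(cfg)
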