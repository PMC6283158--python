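from __future__ import annotations

import numpy as np
import pytest

from splicescreen.annotation import TranscriptModel, mark_reference_isoforms
from splicescreen.psi import QuantTable
from splicescreen.simulate import SimConfig, simulate


def random_annotation(rng: np.random.Generator, n_genes: int = 4):
    """Random multi-isoform gene models on a shared coordinate grid.

    Exon/intron lengths are drawn from small discrete sets so isoforms
    frequently share splice-site boundaries, exercising every event type.
    """
    transcripts = []
    cursor = 101
    for g in range(n_genes):
        gene = f"G{g}"
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(rng.integers(2, 7))
        locus_end = cursor
        models = []
        for i in range(k):
            pos = cursor + int(rng.choice([0, 10, 20]))
            exons = []
            for _ in range(int(rng.integers(1, 5))):
                el = int(rng.choice([20, 30, 40]))
                exons.append((pos, pos + el - 1))
                pos += el + int(rng.choice([10, 15, 20]))
            models.append((f"{gene}.{i + 1}", tuple(exons)))
            locus_end = max(locus_end, exons[-1][1])
        with_cds = rng.random() < 0.7
        for tid, exons in models:
            cds = None
            if with_cds and tid.endswith(".1"):
                trimmed = [list(iv) for iv in exons]
                trimmed[0][0] += 3
                trimmed[-1][1] -= 3
                if all(e >= s for s, e in trimmed):
                    cds = tuple(tuple(iv) for iv in trimmed)
            transcripts.append(
                TranscriptModel(tid, gene, "chr1", strand, exons, cds)
            )
        cursor = locus_end + 200
    return mark_reference_isoforms(transcripts)


def quant_from_dataset(ds) -> QuantTable:
    design = {
        row["sample"]: (row["condition"], int(row["replicate"]))
        for _, row in ds.design.iterrows()
    }
    return QuantTable(list(ds.design["sample"]), design, ds.tpm)


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    out = tmp_path_factory.mktemp("sim_small")
    return simulate(SimConfig(seed=11, n_genes=40), out_dir=out)


@pytest.fixture(scope="session")
def sim_bench(tmp_path_factory):
    """Larger dataset for recovery-style checks."""
    return simulate(SimConfig(seed=23, n_genes=300))
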