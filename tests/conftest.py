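import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from hic3d.genome_layout import ChromosomeRecord, GenomeLayout
from hic3d.inference import STATUS_INFERRED, StructureModel


@pytest.fixture
def two_chrom_layout() -> GenomeLayout:
    """A 2-chromosome toy layout: 100 kb + 50 kb at 10 kb (10 + 5 beads)."""
    return GenomeLayout(
        chromosomes=(
            ChromosomeRecord("chrA", 100_000),
            ChromosomeRecord("chrB", 50_000),
        ),
        resolution=10_000,
    )


@pytest.fixture
def straight_chain_model(two_chrom_layout) -> StructureModel:
    """Unit-spaced straight chains: chrA along x, chrB along x offset in y."""
    model = StructureModel.empty(two_chrom_layout)
    model.coords[:10] = np.column_stack(
        [np.arange(10.0), np.zeros(10), np.zeros(10)]
    )
    model.coords[10:] = np.column_stack(
        [np.arange(5.0), np.full(5, 30.0), np.zeros(5)]
    )
    model.status[:] = STATUS_INFERRED
    return model


def write_fasta(path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k:k + 60] + "\n")
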