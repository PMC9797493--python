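import pandas as pd
import pytest

from seedloh import GenomeLayout, GenomicInterval, default_arabidopsis_layout


@pytest.fixture
def small_layout() -> GenomeLayout:
    """A tiny two-chromosome genome for fast, exact bookkeeping tests."""
    return GenomeLayout(
        chromosomes=[("chrA", 250_000), ("chrB", 400_000)],
        loci={
            "TT8": GenomicInterval("chrA", 120_000, 124_643),
            "TT4": GenomicInterval("chrB", 200_000, 201_789),
        },
    )


@pytest.fixture
def arabidopsis_layout() -> GenomeLayout:
    return default_arabidopsis_layout()


@pytest.fixture
def uniform_bins() -> pd.DataFrame:
    """Six 100-kb bins of identical depth on one chromosome."""
    return pd.DataFrame(
        {
            "chrom": ["chrA"] * 6,
            "start": [i * 100_000 for i in range(6)],
            "end": [(i + 1) * 100_000 for i in range(6)],
            "mean_depth": [10.0] * 6,
        }
    )
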