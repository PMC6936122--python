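import io

import numpy as np
import pytest

from rbpcons.conservation import ConservationProfile, ConservationRecord
from rbpcons.io import AlignmentRow, GenomicInterval, MafBlock


MAF_TEXT = """\
##maf version=1
a score=1234.5
s hg19.chr1 100 50 + 249250621 ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTAC
s panTro2.chr1 200 48 + 229974691 ACGTACGTACGTACGTACGT--GTACGTACGTACGTACGTACGTACGTAC

a score=99
s hg19.chr1 300 20 + 249250621 ACGTACGTACGTACGTACGT
s mm9.chr4 50 20 - 155630120 ACGTACGTACGTACGTACGT
s rn4.chr7 70 20 + 143002779 ACGTACGTACGTACGTACGT
"""


@pytest.fixture
def maf_stream():
    return io.StringIO(MAF_TEXT)


def make_block(chrom, start, length, species, score=0.0, ref="hg"):
    """Build a MafBlock with the given distinct species present."""
    text = "A" * length
    rows = [
        AlignmentRow(f"{ref}.{chrom}", start, length, "+", 10**9, text)
    ]
    for s in species:
        rows.append(AlignmentRow(f"{s}.scaf1", start, length, "+", 10**9, text))
    return MafBlock(score=score, rows=rows)


def make_profile(name, percents, total_species=46, n_unmapped=0):
    """Build a ConservationProfile with fabricated mapped P values."""
    records = []
    for i, p in enumerate(percents):
        site = GenomicInterval("chrF", 100 * i, 100 * i + 20, f"{name}_s{i}")
        records.append(
            ConservationRecord(
                site=site, mapped=True, block_id=i,
                n_species=max(1, round(p / 100 * total_species)), percent=float(p),
            )
        )
    for i in range(n_unmapped):
        site = GenomicInterval("chrF", 10**6 + 100 * i, 10**6 + 100 * i + 20)
        records.append(ConservationRecord(site=site, mapped=False))
    return ConservationProfile(name, records, total_species)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
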