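import pandas as pd
import pytest
from hypothesis import settings

from dmsflow.table import Table

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def counts_table():
    """Small barcode count table used across transform tests."""
    return Table(
        pd.DataFrame(
            {
                "barcode": ["BC1", "BC2", "BC3"],
                "count": [10, 5, 3],
            }
        )
    )


@pytest.fixture
def barcode_map():
    return Table(
        pd.DataFrame(
            {
                "barcode": ["BC1", "BC3"],
                "sequence": ["ATGAAA", "ATGCCC"],
            }
        )
    )


def write_fastq(path, records, qual_char="I"):
    """records: list of (read_id, sequence) or (read_id, sequence, qual_str)."""
    lines = []
    for rec in records:
        rid, seq = rec[0], rec[1]
        qual = rec[2] if len(rec) > 2 else qual_char * len(seq)
        lines.append(f"@{rid}\n{seq}\n+\n{qual}\n")
    path.write_text("".join(lines))
    return path
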