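import pandas as pd
import pytest

from mitocpr.io import SequenceRecord


@pytest.fixture
def toy_plate_table() -> pd.DataFrame:
    """Two plates x two media, one replicate, four genes.

    Plate means are 100 (p1) and 200 (p2) on each medium, so grand-mean
    normalization has a known closed form (factors 1.5 and 0.75).
    """
    rows = []
    for medium in ("selective", "permissive"):
        for plate, sizes in (("p1", [80, 120]), ("p2", [160, 240])):
            for i, size in enumerate(sizes):
                gene = f"{plate}_g{i}"
                rows.append(
                    {
                        "gene_id": gene,
                        "plate_id": f"{plate}-{medium}",
                        "row": i + 1,
                        "col": 1,
                        "replicate": 1,
                        "medium": medium,
                        "size_px": float(size),
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_alignment() -> list[SequenceRecord]:
    return [
        SequenceRecord("s1", "MKTAA"),
        SequenceRecord("s2", "MKTCA"),
        SequenceRecord("s3", "MKDCA"),
    ]
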