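import gzip

import pytest

from targetasm import ReadRecord


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return str(path)


def write_fastq(path, records, compress=False):
    opener = gzip.open if compress else open
    with opener(path, "wt") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    return str(path)


def write_fof(path, files):
    with open(path, "w") as fh:
        for f in files:
            fh.write(f"{f}\n")
    return str(path)


@pytest.fixture
def make_reads():
    """Build in-memory ReadRecords from (id, seq) pairs."""

    def _make(pairs, source="mem"):
        return [ReadRecord(rid, seq, source) for rid, seq in pairs]

    return _make
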