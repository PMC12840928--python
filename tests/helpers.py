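"""Shared test construction helpers."""

from mtdemog.alignment import Alignment, SequenceRecord


def make_alignment(seqs, ids=None, regions=None):
    ids = ids or [f"s{i + 1}" for i in range(len(seqs))]
    regions = regions or [None] * len(seqs)
    return Alignment(tuple(
        SequenceRecord(i, s, region=r) for i, s, r in zip(ids, seqs, regions)))
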