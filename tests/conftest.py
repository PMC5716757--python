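import pytest

from repeatlock.fixtures import TranscriptFixtureSpec, make_repeat_transcript
from repeatlock.seqmodel import apply_variant, parse_hgvs_c
from repeatlock.stabilize import enumerate_stabilizing_edits, find_coding_repeats, rank_edits


@pytest.fixture(scope="session")
def default_transcript():
    t, truth = make_repeat_transcript()
    return t, truth


@pytest.fixture(scope="session")
def default_design(default_transcript):
    """Transcript, repeat, deletion variant and ranked candidate edits."""
    t, truth = default_transcript
    v = parse_hgvs_c(truth["frameshift_variant"])
    (r,) = find_coding_repeats(t, min_len=8)
    edits = rank_edits(enumerate_stabilizing_edits(t, r, v))
    return t, r, v, edits


@pytest.fixture(scope="session")
def parental_cds(default_transcript):
    """The uncorrected, frameshifted allele's CDS."""
    t, truth = default_transcript
    return apply_variant(t.cds, parse_hgvs_c(truth["frameshift_variant"]))
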