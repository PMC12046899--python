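"""Shared global pairwise aligner configuration."""

from Bio import Align


def make_aligner() -> Align.PairwiseAligner:
    """Global affine aligner: match +1, mismatch -1, gap open -2, extend -0.5."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    return aligner
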