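"""Small helpers shared across test modules."""

from ardrapipe import FragmentSet, to_band_pattern


def make_pattern(lengths, min_len=60, tol=0.01):
    frag = FragmentSet(parent_len=sum(lengths),
                       fragment_lengths=tuple(lengths))
    return to_band_pattern(frag, min_detectable_len=min_len,
                           log_tolerance=tol)
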