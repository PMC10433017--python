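from ddxfusion import RankedDDxList


def make_list(generator_id, ids):
    """Shorthand constructor for ranked lists in tests."""
    return RankedDDxList(generator_id, tuple(ids))
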