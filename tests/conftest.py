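import pytest

from archaeoprom import load_table


@pytest.fixture(scope="session")
def table():
    """Packaged unified nearest-neighbor dG37 table."""
    return load_table("default")


def make_core(slice_seq: str, filler: str = "G") -> str:
    """100-nt core promoter whose −32..−25 slice reads ``slice_seq``.

    The slice occupies 0-based offsets 48..47+len within the core.
    """
    assert len(slice_seq) <= 52
    return filler * 48 + slice_seq + filler * (52 - len(slice_seq))
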