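import numpy as np
import pytest

from nmrmap.io_formats import Peak, PeakList, ResidueID, SIS1_DOMAINS


def make_peaklist(label, rows):
    """rows: (number, aa, h_ppm, n_ppm, intensity[, status])"""
    peaks = []
    for row in rows:
        num, aa, h, n, inten = row[:5]
        status = row[5] if len(row) > 5 else "ok"
        peaks.append(Peak(h_ppm=h, n_ppm=n, intensity=inten,
                          assignment=ResidueID(number=num, aa=aa),
                          status=status))
    return PeakList(label=label, peaks=peaks)


@pytest.fixture
def sis1_domains():
    return SIS1_DOMAINS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
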