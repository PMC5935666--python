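import numpy as np
import pytest

import fluorens as fl


@pytest.fixture
def axis2048() -> fl.FrequencyAxis:
    """A 2048-point window around the protein resonances."""
    return fl.FrequencyAxis.from_window(-83.0, -85.5, 2048)


@pytest.fixture
def axis1024() -> fl.FrequencyAxis:
    return fl.FrequencyAxis.from_window(-83.0, -85.0, 1024)


@pytest.fixture
def single_peak() -> fl.LorentzianPeak:
    return fl.LorentzianPeak(center=-83.8, fwhm=0.12, area=1.0)


@pytest.fixture
def two_resolved_peaks() -> list[fl.LorentzianPeak]:
    # separated by ~5x FWHM
    return [
        fl.LorentzianPeak(-83.8, 0.12, 1.0),
        fl.LorentzianPeak(-84.4, 0.12, 0.8),
    ]
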